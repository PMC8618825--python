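"""Seed index, chaining, reciprocal-best netting and coverage."""

import numpy as np
import pytest

from newgene.codons import revcomp
from newgene.genome_align import (
    AlignParams,
    align_genomes,
    build_seed_index,
    coverage,
    reciprocal_best_net,
)
from newgene.model import Interval, RepeatTrack


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(rng, seq, p):
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < p)[0]:
        out[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(out)


# ---------------------------------------------------------------- seeding


def test_seed_index_enumerates_kmer_positions(rng):
    seq = _rand_seq(rng, 200)
    idx = build_seed_index({"c": seq}, k=8, max_occ=0)
    # oracle: naive enumeration
    naive = {}
    for i in range(len(seq) - 7):
        naive.setdefault(seq[i : i + 8], []).append(i)
    for kmer, positions in list(naive.items())[:50]:
        from newgene.genome_align import _kmer_codes, encode

        code, valid = _kmer_codes(encode(kmer), 8)
        lo = np.searchsorted(idx.uniq, code[0])
        assert idx.uniq[lo] == code[0]
        got = sorted(idx.pos[idx.uoff[lo] : idx.uoff[lo + 1]])
        assert got == positions


def test_seed_index_excludes_n_and_capped_kmers():
    seq = "ACGTACGTNNACGTACGT" + "A" * 100
    idx = build_seed_index({"c": seq}, k=8, max_occ=10)
    starts = set(idx.pos.tolist())
    for i in range(1, 10):  # windows touching the NN block
        assert 18 - 8 + i not in starts or "N" not in seq[18 - 8 + i :][:8]
    # poly-A k-mer occurs ~93 times > ceiling, must be masked
    from newgene.genome_align import _kmer_codes, encode

    code, _ = _kmer_codes(encode("A" * 8), 8)
    assert code[0] not in idx.uniq


def test_seed_index_requires_k_at_least_8():
    with pytest.raises(ValueError, match="k must be"):
        build_seed_index({"c": "ACGTACGT"}, k=4)


# ---------------------------------------------------------------- alignment


def test_identical_sequences_single_dominant_chain(rng):
    seq = _rand_seq(rng, 10_000)
    chains = align_genomes({"f": seq}, {"q": seq})
    assert chains
    best = max(chains, key=lambda c: c.score)
    assert best.q_strand == "+"
    assert (best.f_end - best.f_start) >= 0.99 * len(seq)
    cov = coverage([("f", Interval(0, len(seq)))],
                   [type(best)(**{**best.__dict__, "reciprocal_best": True})])
    assert cov[0] >= 0.99


def test_reverse_complement_query_found_on_minus_strand(rng):
    seq = _rand_seq(rng, 5_000)
    chains = align_genomes({"f": seq}, {"q": revcomp(seq)})
    best = max(chains, key=lambda c: c.score)
    assert best.q_strand == "-"
    assert (best.f_end - best.f_start) >= 0.99 * len(seq)


def test_divergent_pair_coverage_and_sw_score_oracle(rng):
    """10% divergence: chain covers >=90%; on an indel-free 1 kb piece the
    chain block score equals the quadratic Smith-Waterman optimum run on
    the same scoring (no gaps needed, so scores must agree closely)."""
    seq = _rand_seq(rng, 10_000)
    qry = _mutate(rng, seq, 0.10)
    chains = align_genomes({"f": seq}, {"q": qry})
    best = max(chains, key=lambda c: c.score)
    span = sum(b.f_end - b.f_start for b in best.blocks)
    assert span >= 0.90 * len(seq)

    a, b = seq[2000:3000], qry[2000:3000]
    # quadratic local DP oracle (match +1, mismatch -1, affine 4/1)
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e9)
    F = np.full((n + 1, m + 1), -1e9)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - 1, H[i, j - 1] - 5)
            F[i, j] = max(F[i - 1, j] - 1, H[i - 1, j] - 5)
            diag = H[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else -1)
            H[i, j] = max(0, diag, E[i, j], F[i, j])
    sw = H.max()
    sub = align_genomes({"f": a}, {"q": b}, AlignParams(min_chain_score=20))
    got = max(c.score for c in sub)
    assert got <= sw + 1e-9
    assert got >= 0.9 * sw


def test_chain_scores_recomputable_from_blocks(rng):
    params = AlignParams()
    seq = _rand_seq(rng, 8_000)
    qry = _mutate(rng, seq, 0.05)
    # plant one deletion to force a gap penalty
    qry = qry[:4000] + qry[4050:]
    chains = align_genomes({"f": seq}, {"q": qry}, params)
    best = max(chains, key=lambda c: c.score)
    block_sum = sum(b.score for b in best.blocks)
    gap_pen = block_sum - best.score
    n_gaps = len(best.blocks) - 1
    assert gap_pen >= 0
    if n_gaps:
        assert gap_pen <= n_gaps * (params.gap_open + params.gap_extend * 400)


def test_empty_genomes_align_to_nothing():
    assert align_genomes({}, {"q": "ACGT" * 100}) == []
    assert align_genomes({"f": "ACGT" * 100}, {}) == []


def test_repeat_soft_masking_blocks_seeding_inside_repeats(rng):
    unit = _rand_seq(rng, 300)
    seq = _rand_seq(rng, 2_000) + unit + _rand_seq(rng, 2_000)
    track = RepeatTrack.from_raw({"f": [(2_000, 2_300)]})
    chains = align_genomes({"f": seq}, {"q": unit}, focal_repeats=track)
    assert not chains  # seeds in the repeat are masked, nothing anchors


# ---------------------------------------------------------------- netting


def test_unique_homolog_is_reciprocal_best(rng):
    seq = _rand_seq(rng, 6_000)
    qry = _mutate(rng, seq, 0.03)
    f2q = align_genomes({"f": seq}, {"q": qry})
    q2f = align_genomes({"q": qry}, {"f": seq})
    net = reciprocal_best_net(f2q, q2f)
    rb = [c for c in net if c.reciprocal_best]
    assert rb
    assert coverage([("f", Interval(0, len(seq)))], rb)[0] > 0.95


def test_duplicated_query_copy_yields_single_flag(rng):
    """Two identical query copies of one focal segment: netting must
    keep exactly one reciprocal-best mapping for the focal segment."""
    focal_seg = _rand_seq(rng, 3_000)
    fgenome = {"f": _rand_seq(rng, 1_000) + focal_seg + _rand_seq(rng, 1_000)}
    qgenome = {
        "q": _rand_seq(rng, 500) + focal_seg + _rand_seq(rng, 800)
        + focal_seg + _rand_seq(rng, 500)
    }
    f2q = align_genomes(fgenome, qgenome)
    q2f = align_genomes(qgenome, fgenome)
    net = reciprocal_best_net(f2q, q2f)
    rb = [c for c in net if c.reciprocal_best]
    focal_iv = Interval(1_000, 4_000)
    hits = [c for c in rb if c.f_interval().overlap(focal_iv) > 1_500]
    assert len(hits) == 1


def test_netting_idempotent(rng):
    seq = _rand_seq(rng, 6_000)
    qry = _mutate(rng, seq, 0.05)
    f2q = align_genomes({"f": seq}, {"q": qry})
    q2f = align_genomes({"q": qry}, {"f": seq})
    once = reciprocal_best_net(f2q, q2f)
    twice = reciprocal_best_net(
        [c for c in once], reciprocal_best_net(q2f, f2q)
    )
    def sig(chains):
        return [
            (c.f_chrom, c.f_start, c.f_end, c.q_seq, c.q_start, c.q_end,
             c.reciprocal_best)
            for c in chains
        ]
    assert sig([c for c in twice if c.reciprocal_best]) == sig(
        [c for c in once if c.reciprocal_best]
    )


def test_disjoint_alignments_produce_no_flags(rng):
    f2q = align_genomes({"f": _rand_seq(rng, 3000)}, {"q": _rand_seq(rng, 3000)})
    q2f = []
    assert all(not c.reciprocal_best for c in reciprocal_best_net(f2q, q2f))


# ---------------------------------------------------------------- coverage


def test_coverage_trivial_cases(rng):
    seq = _rand_seq(rng, 4_000)
    f2q = align_genomes({"f": seq}, {"q": seq})
    net = reciprocal_best_net(f2q, align_genomes({"q": seq}, {"f": seq}))
    inside = coverage([("f", Interval(100, 200))], net)[0]
    assert inside == pytest.approx(1.0, abs=0.02)
    assert coverage([("f", Interval(0, 100))], [])[0] == 0.0
    with pytest.raises(ValueError, match="unknown chromosome"):
        coverage([("nope", Interval(0, 10))], net, known_chroms={"f"})


def test_pipeline_scale_presence_property(small_sim):
    """On simulator output, >=95% of ancestral genes keep >=0.5
    reciprocal-best exon coverage in a deep outgroup species."""
    from newgene.genome_align import PRESETS

    fg = small_sim.genomes["focal"]
    qg = small_sim.genomes["out4"]
    f2q = align_genomes(fg, qg, PRESETS["far"],
                        focal_repeats=small_sim.focal_repeats)
    q2f = align_genomes(qg, fg, PRESETS["far"])
    net = reciprocal_best_net(f2q, q2f)
    genes = [
        g for g in small_sim.gene_models["focal"]
        if g.gene_id.startswith("anc") and g.placed
    ]
    ok = 0
    for g in genes:
        covs = coverage([(g.chromosome, e) for e in g.exons], net)
        ok += min(covs) >= 0.5
    assert ok / len(genes) >= 0.95
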