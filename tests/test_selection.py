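"""Codon alignment, NG86 vs ML Ka/Ks, LRT and filters."""

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from newgene.model import SelectionResult
from newgene.selection import (
    align_codons,
    codon_align_pair,
    de_novo_ortholog_orf,
    ks_filter,
    lrt,
    ml_kaks,
    ng86_kaks,
    paralog_test,
    simulate_codon_pair,
)

CDS_A = (
    "ATGAAGACCCTGCTGGTGGCCGGCGCCGTGCTGCTGAGCGCCTTCAGCGCCAGCGCC"
    "ACCGACGGCCAGTGGCAGCGCGTGGCCGAGAAGCTGGGCATCTAA"
)


# ---------------------------------------------------------------- alignment


def test_identical_cds_gap_free_alignment():
    aln = codon_align_pair("a", CDS_A, "b", CDS_A)
    assert aln.n_codons == len(CDS_A) // 3 - 1  # stop codon dropped
    assert aln.codons_a == aln.codons_b


def test_one_aa_deletion_becomes_one_codon_gap():
    # remove one internal codon from b
    b = CDS_A[:30] + CDS_A[33:]
    aln = codon_align_pair("a", CDS_A, "b", b)
    assert aln.n_dropped == 1  # exactly the one gapped column
    assert aln.n_codons == len(b) // 3 - 1


def test_translation_mismatch_is_an_error():
    with pytest.raises(ValueError, match="mismatch at codon"):
        align_codons("MK", "MK", "ATGAAG", "ATGGAG", "a", "b")


# ---------------------------------------------------------------- NG86


def test_ng86_identical_pair_is_zero():
    aln = codon_align_pair("a", CDS_A, "b", CDS_A)
    r = ng86_kaks(aln)
    assert r.ka == 0.0 and r.ks == 0.0


def test_ng86_single_synonymous_change():
    # CTG -> CTA at codon 4 (both Leu)
    b = CDS_A[:11] + "A" + CDS_A[12:]
    aln = codon_align_pair("a", CDS_A, "b", b)
    r = ng86_kaks(aln)
    assert r.ka == 0.0
    assert r.ks > 0.0


def test_ng86_matches_independent_oracle(rng):
    """Cross-check pathway counting + JC against the Biopython NG86
    implementation on simulated pairs."""
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(3):
            aln = simulate_codon_pair(rng, 150, t=0.4, kappa=2.0, omega=0.3)
            dn, ds = cal_dn_ds(
                CodonSeq("".join(aln.codons_a)),
                CodonSeq("".join(aln.codons_b)),
                method="NG86",
            )
            mine = ng86_kaks(aln)
            assert mine.ka == pytest.approx(dn, abs=1e-6)
            assert mine.ks == pytest.approx(ds, abs=1e-6)


def test_ng86_saturation_flag():
    aln = simulate_codon_pair(
        np.random.default_rng(0), 100, t=30.0, kappa=2.0, omega=5.0
    )
    r = ng86_kaks(aln)
    assert r.ks_saturated or r.ka_saturated or (r.ks > 1.0)


# ---------------------------------------------------------------- ML


def test_ml_identical_sequences_t_to_zero():
    aln = codon_align_pair("a", CDS_A, "b", CDS_A)
    fit = ml_kaks(aln)
    assert fit.t < 1e-3
    # at t = 0 the likelihood is that of zero-change data: n * log(1/61)
    assert fit.lnl == pytest.approx(aln.n_codons * np.log(1 / 61), rel=1e-3)


def test_ml_nested_models_lnl_ordering(rng):
    aln = simulate_codon_pair(rng, 300, t=0.6, kappa=2.0, omega=0.3)
    alt = ml_kaks(aln)
    null = ml_kaks(aln, fix_omega=0.5)
    assert alt.lnl >= null.lnl - 1e-6


def test_ml_recovers_omega_roughly(rng):
    hits = 0
    for i in range(10):
        aln = simulate_codon_pair(rng, 500, t=0.8, kappa=2.0, omega=0.2)
        fit = ml_kaks(aln)
        hits += abs(fit.omega - 0.2) <= 0.1
    assert hits >= 8


def test_ml_and_ng86_rank_agree(rng):
    """The two estimators order pairs by omega consistently."""
    omegas = np.linspace(0.05, 1.5, 12)
    ml_vals, ng_vals = [], []
    for i, w in enumerate(omegas):
        aln = simulate_codon_pair(rng, 400, t=0.5, kappa=2.0, omega=float(w))
        ml_vals.append(ml_kaks(aln).omega)
        r = ng86_kaks(aln)
        ng_vals.append(r.ka / r.ks if r.ks > 0 else np.inf)
    rho, _ = spearmanr(ml_vals, ng_vals)
    assert rho >= 0.8


# ---------------------------------------------------------------- LRT


@pytest.mark.parametrize(
    "two_delta,expected,tol",
    [(3.841, 0.050, 0.001), (0.0, 1.0, 1e-12), (10.0, 0.00157, 0.00002)],
)
def test_lrt_chi_square_spot_values(two_delta, expected, tol):
    p = lrt(two_delta / 2.0, 0.0)
    assert p == pytest.approx(expected, abs=tol)


def test_lrt_rejects_optimizer_failure():
    with pytest.raises(ValueError, match="optimiser failure"):
        lrt(0.0, 5.0)


# ---------------------------------------------------------------- filters


def _res(gid, ka, ks):
    return SelectionResult(
        gene_id=gid, partner_id="p", ka=ka, ks=ks, omega_hat=ka / max(ks, 1e-9),
        lnl_alt=0.0, lnl_null=0.0, p_value=0.5, null_omega=0.5,
    )


def test_ks_filter_prefilters_and_iqr():
    results = [
        _res("a", 0.1, 0.1), _res("b", 0.1, 0.2), _res("c", 0.1, 0.3),
        _res("d", 0.1, 0.4),
        _res("iqr", 0.1, 4.5),   # IQR outlier: Q1=0.2 Q3=0.4 bounds [-0.1,0.7]
        _res("ka", 0.6, 0.3),    # Ka > 0.5
        _res("ks", 0.1, 5.5),    # Ks > 5
    ]
    out = {r.gene_id: r for r in ks_filter(results)}
    assert out["ka"].filtered == "ka_gt_0.5"
    assert out["ks"].filtered == "ks_gt_5"
    assert out["iqr"].filtered == "ks_iqr_outlier"
    for g in "abcd":
        assert out[g].filtered == "none"


def test_ks_filter_warns_with_few_values():
    results = [_res("a", 0.1, 0.1), _res("b", 0.1, 0.2)]
    with pytest.warns(UserWarning, match="IQR filter skipped"):
        ks_filter(results)


def test_verdict_monotone_in_alpha(rng):
    """Lowering the significance threshold never adds verdicts."""
    from newgene.selection import apply_verdicts
    from newgene.codons import CODONS

    results = []
    for i in range(20):
        aln = simulate_codon_pair(rng, 200, t=0.5, kappa=2.0,
                                  omega=float(rng.uniform(0.05, 1.0)))
        alt = ml_kaks(aln)
        null = ml_kaks(aln, fix_omega=0.5)
        results.append(
            SelectionResult(
                gene_id=f"g{i}", partner_id="p", ka=alt.ka, ks=alt.ks,
                omega_hat=alt.omega, lnl_alt=alt.lnl, lnl_null=null.lnl,
                p_value=lrt(alt.lnl, null.lnl), null_omega=0.5,
            )
        )
    strict = {
        r.gene_id for r in apply_verdicts(list(results), alpha=0.01)
        if r.verdict == "negative_selection"
    }
    loose = {
        r.gene_id for r in apply_verdicts(list(results), alpha=0.05)
        if r.verdict == "negative_selection"
    }
    assert strict <= loose


def test_paralog_test_too_short_is_filtered():
    short = "ATG" + "GCC" * 10 + "TAA"
    r = paralog_test("a", short, "b", short)
    assert r.filtered == "too_short"
    assert r.verdict == "filtered"


# ---------------------------------------------------------------- de novo ORF


def _embed(orf, rng, flank=2000):
    left = "".join(rng.choice(list("ACGT"), flank))
    right = "".join(rng.choice(list("ACGT"), flank))
    return left + orf + right, flank


def test_de_novo_orf_recovered_from_sister_region(rng):
    from newgene.codons import translate

    prot = translate(CDS_A)
    seq, off = _embed(CDS_A, rng)
    genome = {"q1": seq}
    orf = de_novo_ortholog_orf(prot, genome, "q1", off, off + len(CDS_A),
                               flank=1000)
    assert orf is not None
    assert orf["protein"] == prot
    assert orf["start"] == off and orf["strand"] == "+"


def test_de_novo_orf_stop_disrupted_returns_none(rng):
    from newgene.codons import translate

    prot = translate(CDS_A)
    broken = CDS_A[:45] + "TGA" + CDS_A[48:]
    seq, off = _embed(broken, rng)
    # region intentionally short of other ORFs; a stop mid-way truncates
    # the candidate below the minimum length
    orf = de_novo_ortholog_orf(prot, {"q1": seq}, "q1", off,
                               off + len(broken), flank=200, min_codons=30)
    assert orf is None


def test_de_novo_orf_chromosome_edge_truncates_flank(rng):
    from newgene.codons import translate

    prot = translate(CDS_A)
    seq = CDS_A + "".join(rng.choice(list("ACGT"), 100))
    orf = de_novo_ortholog_orf(prot, {"q1": seq}, "q1", 0, len(CDS_A),
                               flank=10_000)
    assert orf is not None and orf["start"] == 0
    with pytest.raises(ValueError, match="outside the genome"):
        de_novo_ortholog_orf(prot, {"q1": seq}, "q1", 0, len(seq) + 5)
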