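"""Simulator: determinism, ORF integrity, planted events, expression."""

import numpy as np
import pytest

from newgene.codons import STOP_CODONS, spliced_cds, translate
from newgene.simulate import (
    PlannedEvent,
    SimulationConfig,
    evolve_branch,
    nb_draw,
    plant_event,
    simulate_ancestral_genome,
    simulate_expression,
    simulate_ladder,
)

from conftest import small_config


def _orfs_ok(state):
    genome = state.decode()
    for g in state.genes:
        cds = "".join(genome[g.chrom][s:e] for s, e in g.exons)
        assert len(cds) % 3 == 0
        assert cds[:3] == "ATG", g.gene_id
        assert cds[-3:] in STOP_CODONS, g.gene_id
        inner = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        assert not any(c in STOP_CODONS for c in inner), g.gene_id


def test_ancestral_genome_counts_and_orfs():
    cfg = SimulationConfig(
        seed=5, n_chromosomes=1, chromosome_length=250_000,
        n_ancestral_genes=50, events_per_branch={},
    )
    state = simulate_ancestral_genome(cfg)
    named = [g for g in state.genes if g.gene_id.startswith("anc")]
    assert len(named) == 50
    _orfs_ok(state)


def test_zero_genes_gives_pure_intergenic_genome():
    cfg = SimulationConfig(
        seed=5, n_chromosomes=1, chromosome_length=100_000,
        n_ancestral_genes=0, events_per_branch={}, scaffold_length=0,
        repeat_density=0.0,
    )
    state = simulate_ancestral_genome(cfg)
    assert state.genes == []
    assert len(state.seqs["chr1"]) >= 100_000 * 0.9


def test_genes_that_do_not_fit_raise():
    cfg = SimulationConfig(
        seed=5, n_chromosomes=1, chromosome_length=20_000,
        n_ancestral_genes=60, events_per_branch={},
    )
    with pytest.raises(ValueError, match="chromosome_length"):
        simulate_ancestral_genome(cfg)


def test_same_seed_identical_output(tmp_path):
    from newgene.simulate import write_outputs

    cfg = SimulationConfig(
        seed=9, n_chromosomes=1, chromosome_length=120_000,
        n_ancestral_genes=12,
        events_per_branch={4: {"dna_duplication": 1, "de_novo": 1}},
    )
    a, b = tmp_path / "a", tmp_path / "b"
    write_outputs(simulate_ladder(cfg), a)
    write_outputs(simulate_ladder(cfg), b)
    for name in ("focal.fa", "focal.gff3", "truth.tsv", "fpkm.tsv",
                 "counts.tsv", "focal.repeats.bed"):
        assert (a / name).read_bytes() == (b / name).read_bytes(), name


def test_zero_rate_changes_nothing(rng):
    cfg = SimulationConfig(
        seed=5, n_chromosomes=1, chromosome_length=100_000,
        n_ancestral_genes=10, events_per_branch={},
        substitution_rate=0.0, indel_rate=0.0,
    )
    state = simulate_ancestral_genome(cfg)
    before = {c: a.copy() for c, a in state.seqs.items()}
    evolve_branch(state, 50.0, cfg, rng)
    for c in before:
        assert np.array_equal(before[c], state.seqs[c])


def test_neutral_divergence_matches_expected_rate(rng):
    """10 Myr at 0.002 subs/site/Myr on neutral sequence: the observed
    divergence of a 50 kb intergenic stretch sits inside a 4-sigma
    binomial envelope around the expected 1 - exp(-mu*t)."""
    cfg = SimulationConfig(
        seed=5, n_chromosomes=1, chromosome_length=100_000,
        n_ancestral_genes=0, scaffold_length=0, repeat_density=0.0,
        events_per_branch={}, substitution_rate=0.002, indel_rate=0.0,
    )
    state = simulate_ancestral_genome(cfg)
    before = state.seqs["chr1"][:50_000].copy()
    evolve_branch(state, 10.0, cfg, rng)
    after = state.seqs["chr1"][:50_000]
    observed = float(np.mean(before != after))
    rate_t = 0.002 * 10.0
    # multiple hits can revert or coincide: expected observable divergence
    # is bounded by the Poisson-hit probability and its 3/4 saturation
    expected = 1.0 - np.exp(-rate_t)  # Poisson hit probability; revertants
    sd = np.sqrt(expected * (1 - expected) / 50_000)  # are O(rate_t^2)
    assert abs(observed - expected) < 4 * sd + 0.001


def test_orfs_survive_evolution(rng):
    cfg = small_config(seed=3)
    state = simulate_ancestral_genome(
        cfg, np.random.default_rng(3)
    )
    evolve_branch(state, 80.0, cfg, rng)
    _orfs_ok(state)


def test_coordinates_remap_after_indels(rng):
    cfg = SimulationConfig(
        seed=11, n_chromosomes=1, chromosome_length=150_000,
        n_ancestral_genes=15, events_per_branch={},
        substitution_rate=0.0, indel_rate=5e-4,
    )
    state = simulate_ancestral_genome(cfg)
    genome0 = state.decode()
    cds0 = {
        g.gene_id: "".join(genome0[g.chrom][s:e] for s, e in g.exons)
        for g in state.genes
    }
    evolve_branch(state, 20.0, cfg, rng)
    genome1 = state.decode()
    assert len(genome1["chr1"]) != len(genome0["chr1"])  # indels happened
    for g in state.genes:  # exonic sequence untouched, coordinates exact
        cds1 = "".join(genome1[g.chrom][s:e] for s, e in g.exons)
        assert cds1 == cds0[g.gene_id]


# ---------------------------------------------------------------- planting


def _mini_state(seed=21):
    cfg = SimulationConfig(
        seed=seed, n_chromosomes=1, chromosome_length=200_000,
        n_ancestral_genes=20,
        events_per_branch={3: {"de_novo": 1}},
    )
    return cfg, simulate_ancestral_genome(cfg)


def test_dna_duplication_copies_exon_structure(rng):
    cfg, state = _mini_state()
    parent = next(g for g in state.genes if len(g.exons) == 3)
    ev = PlannedEvent("dupX", 3, "dna_duplication", parent.gene_id, 0.3)
    rec = plant_event(state, ev, cfg, rng)
    child = next(g for g in state.genes if g.gene_id == "dupX")
    assert len(child.exons) == 3
    assert rec.parent_gene_id == parent.gene_id
    _orfs_ok(state)


def test_retroposition_child_is_intronless_spliced_copy(rng):
    cfg, state = _mini_state()
    genome0 = state.decode()
    parent = next(g for g in state.genes if len(g.exons) >= 2)
    parent_cds = "".join(genome0[parent.chrom][s:e] for s, e in parent.exons)
    ev = PlannedEvent("retroX", 3, "retroposition", parent.gene_id, 0.3)
    plant_event(state, ev, cfg, rng)
    child = next(g for g in state.genes if g.gene_id == "retroX")
    assert len(child.exons) == 1
    genome1 = state.decode()
    child_cds = genome1[child.chrom][child.exons[0][0] : child.exons[0][1]]
    assert child_cds == parent_cds


def test_retroposition_rejects_single_exon_parent(rng):
    cfg, state = _mini_state()
    victim = state.genes[0]
    victim.exons = victim.exons[:1]  # force a single-exon parent
    ev = PlannedEvent("retroY", 3, "retroposition", victim.gene_id, 0.3)
    with pytest.raises(ValueError, match="multi-exon"):
        plant_event(state, ev, cfg, rng)


def test_de_novo_child_keeps_partial_ancestral_core(rng):
    cfg, state = _mini_state()
    rid = sorted(state.reserved)[0]
    chrom, s0, e0, n_total = state.reserved[rid]
    core_before = state.decode()[chrom][s0:e0]
    ev = PlannedEvent("dnX", 3, "de_novo", None, 1.0, reserved_id=rid)
    plant_event(state, ev, cfg, rng)
    child = next(g for g in state.genes if g.gene_id == "dnX")
    assert len(child.exons) == 1
    assert child.cds_length == 3 * n_total
    genome = state.decode()
    cds = genome[chrom][child.exons[0][0] : child.exons[0][1]]
    # ancestral core survives inside the new ORF, nearly intact
    core_len = len(core_before)
    inner = cds[3 * max(1, (n_total - core_len // 3) // 2) :][: core_len]
    same = sum(a == b for a, b in zip(inner, core_before))
    assert same / core_len > 0.8
    _orfs_ok(state)


def test_truth_conservation_per_branch_and_mechanism(small_sim):
    cfg = small_sim.config
    got = {}
    for t in small_sim.truth:
        got.setdefault(t.true_branch, {}).setdefault(t.true_mechanism, 0)
        got[t.true_branch][t.true_mechanism] += 1
    assert got == cfg.events_per_branch


# ---------------------------------------------------------------- expression


def test_silent_genes_are_all_zero(small_sim):
    fpkm = small_sim.fpkm
    silent = fpkm.df.index[(fpkm.df == 0).all(axis=1)]
    assert len(silent) > 0
    counts = small_sim.counts
    assert (counts.df.loc[silent] == 0).all(axis=None)


def test_planted_fold_change_recovered_in_expectation(rng):
    """Monte-Carlo on the generator's NB model: the empirical mean ratio
    of a 4-fold gene approaches 4 at n = 1000 draws per side."""
    mu = 50.0
    left = nb_draw(rng, np.full(1000, mu), 0.05)
    right = nb_draw(rng, np.full(1000, 4 * mu), 0.05)
    ratio = right.mean() / left.mean()
    assert ratio == pytest.approx(4.0, rel=0.1)


def test_fold_change_one_means_equal_sides(small_sim):
    cfg = small_sim.config
    counts = small_sim.counts
    asym = set(small_sim.asymmetric_genes)
    normal = [g for g in counts.genes if g not in asym]
    lcols = counts.columns_where(stage=cfg.asym_stage, tissue=cfg.asym_tissue,
                                 side="L")
    rcols = counts.columns_where(stage=cfg.asym_stage, tissue=cfg.asym_tissue,
                                 side="R")
    l = counts.df.loc[normal, lcols].to_numpy().mean()
    r = counts.df.loc[normal, rcols].to_numpy().mean()
    assert r / l == pytest.approx(1.0, abs=0.15)
    planted_l = counts.df.loc[sorted(asym), lcols].to_numpy().mean()
    planted_r = counts.df.loc[sorted(asym), rcols].to_numpy().mean()
    assert planted_r / planted_l > 2.5  # configured 4-fold, NB noise allowed
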