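"""Expression evidence, age-group contrasts and the left/right test."""

import numpy as np
import pandas as pd
import pytest

from newgene.io import ExpressionMatrix
from newgene.model import AgeCall
from newgene.expression import (
    age_group_stats,
    asymmetry_scan,
    call_expression,
    de_novo_tissue_counts,
    nb_differential_test,
    nb_wald_test,
    size_factors,
)


def _fpkm(rows, tissues=("brain", "liver", "muscle"), reps=2):
    cols = [f"{t}|||{r + 1}" for t in tissues for r in range(reps)]
    return ExpressionMatrix(
        pd.DataFrame(rows, columns=cols)
    )


def test_call_expression_threshold_and_breadth():
    m = _fpkm(
        {"g1": [0.6, 0.6, 0.0, 0.0, 0.0, 0.0],
         "g2": [0.0] * 6,
         "g3": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5]}.values(),
    )
    m.df.index = ["g1", "g2", "g3"]
    calls = {c.gene_id: c for c in call_expression(m)}
    assert calls["g1"].expressed and calls["g1"].breadth == 1
    assert not calls["g2"].expressed
    assert not calls["g3"].expressed  # strict > 0.5


def test_replicates_average_before_threshold():
    m = _fpkm([[0.9, 0.3, 0, 0, 0, 0]])  # mean 0.6 > 0.5
    m.df.index = ["g"]
    assert call_expression(m)[0].expressed


def test_expressed_count_monotone_in_threshold(rng):
    vals = rng.lognormal(0.0, 1.5, size=(50, 6))
    m = _fpkm(vals)
    m.df.index = [f"g{i}" for i in range(50)]
    counts = [
        sum(c.expressed for c in call_expression(m, threshold=t))
        for t in (0.1, 0.5, 1.0, 2.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_age_group_stats_identical_groups_null():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(1.0, 1.0, size=(60, 6))
    m = _fpkm(vals)
    m.df.index = [f"g{i}" for i in range(60)]
    calls = [AgeCall(f"g{i}", branch=0 if i < 30 else 3) for i in range(60)]
    out = age_group_stats(calls, m)
    assert out["rank_sum_p"] > 0.05
    assert out["n"] == {"old": 30, "young": 30}


def test_age_group_stats_small_group_no_crash():
    m = _fpkm([[1, 1, 1, 1, 1, 1]] * 5)
    m.df.index = [f"g{i}" for i in range(5)]
    calls = [AgeCall("g0", branch=0)] + [
        AgeCall(f"g{i}", branch=4) for i in range(1, 5)
    ]
    out = age_group_stats(calls, m)
    assert 0 <= out["rank_sum_p"] <= 1


def test_age_group_stats_requires_both_groups():
    m = _fpkm([[1, 1, 1, 1, 1, 1]])
    m.df.index = ["g0"]
    with pytest.raises(ValueError, match="non-empty"):
        age_group_stats([AgeCall("g0", branch=4)], m)


def test_de_novo_tissue_counts_partition():
    m = _fpkm(
        [[5, 5, 5, 5, 5, 5],      # all tissues
         [5, 5, 0, 0, 0, 0],      # single tissue
         [5, 5, 5, 5, 0, 0],      # two tissues
         [0, 0, 0, 0, 0, 0]],     # silent
    )
    m.df.index = ["a", "s", "m", "z"]
    calls = call_expression(m)
    out = de_novo_tissue_counts(calls)
    assert out["all_tissues"] == 1
    assert out["single_tissue"] == 1
    assert out["multi_tissue"] == 1
    assert out["expressed"] == 3
    assert (
        out["all_tissues"] + out["single_tissue"] + out["multi_tissue"]
        == out["expressed"]
    )


# ---------------------------------------------------------------- NB test


def test_identical_sides_null_result():
    lfc, p = nb_wald_test(np.array([10, 12, 11]), np.array([10, 12, 11]))
    assert lfc == 0.0
    assert p > 0.9


def test_all_zero_gene_is_not_an_error():
    lfc, p = nb_wald_test(np.zeros(3), np.zeros(3))
    assert (lfc, p) == (0.0, 1.0)


def test_swap_symmetry():
    l = np.array([5, 9, 7])
    r = np.array([30, 25, 35])
    lfc1, p1 = nb_wald_test(l, r, dispersion=0.05)
    lfc2, p2 = nb_wald_test(r, l, dispersion=0.05)
    assert lfc1 == pytest.approx(-lfc2)
    assert p1 == pytest.approx(p2)


def test_requires_two_replicates():
    with pytest.raises(ValueError, match=">=2 replicates"):
        nb_wald_test(np.array([5]), np.array([5, 6]))


def test_size_factors_normalise_depth(rng):
    base = rng.lognormal(3, 1, size=(200, 1))
    counts = np.round(base * [1.0, 1.0, 4.0, 4.0]).astype(float)
    sf = size_factors(counts)
    assert sf[2] / sf[0] == pytest.approx(4.0, rel=0.1)
    assert np.prod(sf) == pytest.approx(1.0, rel=1e-6)


def _counts_matrix(rng, n_null=300, n_fold=30, fold=4.0, disp=0.05):
    from newgene.simulate import nb_draw

    cols = [f"muscle|{s}|Pro|{r + 1}" for s in "LR" for r in range(3)]
    rows, idx = [], []
    for i in range(n_null + n_fold):
        mu = rng.lognormal(3.0, 1.0)
        mur = mu * (fold if i >= n_null else 1.0)
        rows.append(
            list(nb_draw(rng, np.full(3, mu), disp))
            + list(nb_draw(rng, np.full(3, mur), disp))
        )
        idx.append(f"g{i}")
    df = pd.DataFrame(rows, columns=cols, index=idx)
    return ExpressionMatrix(df, counts=True)


def test_nb_test_detects_planted_fold_changes(rng):
    m = _counts_matrix(rng)
    res = {r.gene_id: r for r in nb_differential_test(m, "Pro", "muscle")}
    planted = [f"g{i}" for i in range(300, 330)]
    power = np.mean([res[g].significant for g in planted])
    assert power >= 0.7
    null_rate = np.mean([res[f"g{i}"].significant for i in range(300)])
    assert null_rate < 0.12


def test_asymmetry_scan_bh_column_and_structure(rng):
    m = _counts_matrix(rng, n_null=40, n_fold=5)
    df = asymmetry_scan(m)
    assert set(df["stage"]) == {"Pro"}
    assert (df["p_adj_bh"] >= df["p_value"] - 1e-12).all()


def test_pipeline_level_planted_stage_has_most_degs(small_sim):
    """The stage/tissue carrying the planted asymmetric genes shows the
    largest number of significant left/right differences."""
    df = asymmetry_scan(small_sim.counts)
    per = (
        df.groupby(["stage", "tissue"])["significant"].sum().sort_values()
    )
    top_stage, top_tissue = per.index[-1]
    cfg = small_sim.config
    assert (top_stage, top_tissue) == (cfg.asym_stage, cfg.asym_tissue)
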