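"""Expression evidence, age-group contrasts and left/right asymmetry.

Expression evidence follows the FPKM > 0.5 rule: replicates are averaged
per tissue first, a gene is expressed when at least one tissue clears
the threshold, and breadth is the number of clearing tissues. Age-group
contrasts compare old (branches 0-1) against lineage-specific young
genes with a two-sided rank-sum test on log2 median FPKM.

The left/right test is a deliberately simple negative-binomial Wald
test — an explicit, fully specified stand-in for the established
differential-expression package used in the original study: library
size factors by median-of-ratios, per-gene method-of-moments dispersion
pooled within sides, and a Wald z statistic on the log2 fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .model import AgeCall, DifferentialResult, ExpressionCall

FPKM_THRESHOLD = 0.5


# ------------------------------------------------------------ evidence


def call_expression(
    matrix: ExpressionMatrix, threshold: float = FPKM_THRESHOLD
) -> list[ExpressionCall]:
    """Per-gene expression calls from an FPKM matrix (strict > threshold
    on the replicate-mean per tissue)."""
    if matrix.df.isna().any(axis=None):
        bad = matrix.df.index[matrix.df.isna().any(axis=1)][0]
        raise ValueError(f"missing FPKM values (first offender: {bad})")
    tissues = matrix.meta["tissue"]
    by_tissue = matrix.df.T.groupby(tissues).mean().T  # genes x tissues
    out = []
    for gid, row in by_tissue.iterrows():
        over = row > threshold
        out.append(
            ExpressionCall(
                gene_id=gid,
                expressed=bool(over.any()),
                breadth=int(over.sum()),
                tissue_means={t: round(float(v), 4) for t, v in row.items()},
            )
        )
    return out


# ------------------------------------------------------------ age groups


def age_group_stats(
    calls: list[AgeCall],
    matrix: ExpressionMatrix,
    young_branch: int = 2,
    pseudocount: float = 0.1,
) -> dict:
    """Old (branch < young_branch) vs young expression contrast.

    Per gene: median FPKM across columns, log2 with pseudocount. Returns
    group medians, breadth distributions and a two-sided rank-sum
    (Mann-Whitney) p-value.
    """
    branch = {c.gene_id: c.branch for c in calls if not c.excluded}
    med = matrix.df.median(axis=1)
    expr_calls = {c.gene_id: c for c in call_expression(matrix)}
    groups: dict[str, list] = {"old": [], "young": []}
    breadth: dict[str, list] = {"old": [], "young": []}
    for gid, b in branch.items():
        if gid not in med.index:
            continue
        grp = "young" if b >= young_branch else "old"
        groups[grp].append(np.log2(float(med[gid]) + pseudocount))
        breadth[grp].append(expr_calls[gid].breadth)
    if not groups["old"] or not groups["young"]:
        raise ValueError("both age groups must be non-empty")
    stat, p = stats.mannwhitneyu(
        groups["old"], groups["young"], alternative="two-sided"
    )
    return {
        "median_log2_fpkm": {
            g: float(np.median(v)) for g, v in groups.items()
        },
        "breadth_mean": {g: float(np.mean(v)) for g, v in breadth.items()},
        "n": {g: len(v) for g, v in groups.items()},
        "rank_sum_p": float(p),
    }


def de_novo_tissue_counts(calls: list[ExpressionCall]) -> dict:
    """Tissue breakdown for (de novo) expression calls: per-tissue
    expressed counts plus the all/single/multi-tissue partition."""
    if not calls:
        return {"per_tissue": {}, "all_tissues": 0, "single_tissue": 0,
                "multi_tissue": 0, "expressed": 0}
    tissues = list(calls[0].tissue_means)
    per_tissue = {
        t: sum(1 for c in calls if c.tissue_means[t] > FPKM_THRESHOLD)
        for t in tissues
    }
    expressed = [c for c in calls if c.expressed]
    n_all = sum(1 for c in expressed if c.breadth == len(tissues))
    n_single = sum(1 for c in expressed if c.breadth == 1)
    return {
        "per_tissue": per_tissue,
        "all_tissues": n_all,
        "single_tissue": n_single,
        "multi_tissue": len(expressed) - n_all - n_single,
        "expressed": len(expressed),
    }


# ------------------------------------------------------------ NB Wald test


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples); all-ones when no
    gene is expressed in every sample."""
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        return np.ones(counts.shape[1])
    logc = np.log(counts[pos].astype(float))
    ref = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - ref, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def mom_dispersion(nl: np.ndarray, nr: np.ndarray) -> float:
    """Method-of-moments NB dispersion from one gene's normalised counts
    (within-side residual variance beyond Poisson; may be negative)."""
    ml, mr = nl.mean(), nr.mean()
    dof = nl.size + nr.size - 2
    var = float(
        ((nl - ml) ** 2).sum() + ((nr - mr) ** 2).sum()
    ) / dof
    mbar = (ml + mr) / 2.0
    return (var - mbar) / (mbar**2) if mbar > 0 else 0.0


def nb_wald_test(
    left: np.ndarray,
    right: np.ndarray,
    sf_left=None,
    sf_right=None,
    dispersion: float | None = None,
) -> tuple[float, float]:
    """(log2 fold change right/left, p) for one gene's replicate counts.

    Wald z on the log2 fold change of normalised side means with NB
    variance ``mu + dispersion * mu^2``. With ``dispersion=None`` the
    gene's own method-of-moments estimate is used; the matrix-level
    driver passes the mean dispersion pooled across genes, which at 3
    replicates per side is what keeps the test calibrated. All-zero
    genes return (0, 1).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size < 2 or right.size < 2:
        raise ValueError("need >=2 replicates per side")
    if sf_left is None:
        sf_left = np.ones(left.size)
    if sf_right is None:
        sf_right = np.ones(right.size)
    nl = left / sf_left
    nr = right / sf_right
    ml, mr = nl.mean(), nr.mean()
    if ml <= 0 and mr <= 0:
        return 0.0, 1.0
    if dispersion is None:
        dispersion = mom_dispersion(nl, nr)
    alpha = max(float(dispersion), 1e-8)
    pseudo = 0.5
    lfc = np.log2((mr + pseudo) / (ml + pseudo))
    # variance of log mean per side under NB(mu, alpha)
    v_l = (1.0 / (ml + pseudo) + alpha) / left.size
    v_r = (1.0 / (mr + pseudo) + alpha) / right.size
    se = np.sqrt(v_l + v_r) / np.log(2.0)
    z = lfc / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(lfc), p


def nb_differential_test(
    matrix: ExpressionMatrix,
    stage: str,
    tissue: str,
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Left-vs-right Wald tests for every gene at one stage/tissue.

    Dispersion is moderated across genes: the per-gene method-of-moments
    estimates are pooled by their mean and the pooled value is used for
    every gene (per-gene estimates at a few replicates are too noisy to
    keep the Wald test calibrated; see docs/methods.md).
    """
    lcols = matrix.columns_where(tissue=tissue, stage=stage, side="L")
    rcols = matrix.columns_where(tissue=tissue, stage=stage, side="R")
    if len(lcols) < 2 or len(rcols) < 2:
        raise ValueError("need >=2 replicates per side")
    sub = matrix.df[lcols + rcols].to_numpy()
    sf = size_factors(sub)
    sf_l, sf_r = sf[: len(lcols)], sf[len(lcols) :]
    nl_all = sub[:, : len(lcols)] / sf_l
    nr_all = sub[:, len(lcols) :] / sf_r
    moms = [
        mom_dispersion(nl_all[i], nr_all[i])
        for i in range(sub.shape[0])
        if nl_all[i].mean() + nr_all[i].mean() > 0
    ]
    pooled = float(np.mean(moms)) if moms else 0.0
    out = []
    for i, gid in enumerate(matrix.df.index):
        lfc, p = nb_wald_test(
            sub[i, : len(lcols)], sub[i, len(lcols) :], sf_l, sf_r,
            dispersion=pooled,
        )
        out.append(
            DifferentialResult(
                gene_id=gid, stage=stage, tissue=tissue,
                log2_fold_change=round(lfc, 4), p_value=p,
                significant=bool(p < alpha),
            )
        )
    return out


def asymmetry_scan(
    matrix: ExpressionMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Run the left/right test over every stage x tissue combination and
    attach a BH-adjusted column (reported, not used for the flag)."""
    stages = sorted(set(matrix.meta["stage"]) - {""})
    tissues = sorted(set(matrix.meta["tissue"]) - {""})
    rows = []
    for st in stages:
        for ti in tissues:
            try:
                results = nb_differential_test(matrix, st, ti, alpha=alpha)
            except ValueError:
                continue
            for r in results:
                rows.append(
                    {
                        "gene_id": r.gene_id, "stage": st, "tissue": ti,
                        "log2_fold_change": r.log2_fold_change,
                        "p_value": r.p_value, "significant": r.significant,
                    }
                )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj_bh"] = (
            df.groupby(["stage", "tissue"])["p_value"]
            .transform(lambda p: stats.false_discovery_control(p, method="bh"))
        )
    return df
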