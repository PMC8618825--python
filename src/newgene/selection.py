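"""Pairwise Ka/Ks estimation and fixed-omega likelihood-ratio tests.

Two estimators are provided. The primary one is maximum likelihood under
a GY94-style codon model: uniform frequencies over the 61 sense codons,
transition/transversion ratio kappa, selection parameter omega, rate
matrix normalised to one expected substitution per codon per unit of
branch length t. Nested fits with omega free vs fixed (0.5 for the
paralog constraint test, 1.0 for the de novo neutrality test) give a
likelihood-ratio test against chi-square df=1. The secondary estimator
is Nei-Gojobori (1986) pathway counting with Jukes-Cantor correction,
kept as an independent cross-check of the ML machinery.

Quality filters follow the study design: pairs with Ka > 0.5 or Ks > 5,
and pairs whose Ks lies outside 1.5 x IQR of the remaining Ks
distribution, are excluded from verdicts (such partners are likely not
genuine closest paralogs).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codons import AA_OF, BASES, CODONS, CODON_INDEX, STOP_CODONS, revcomp, translate
from .mechanism import make_protein_aligner
from .model import CodonAlignment, SelectionResult

MIN_CODONS = 30
LRT_TOL = 1e-3

# ------------------------------------------------------------ codon alignment


def align_codons(
    aligned_prot_a: str,
    aligned_prot_b: str,
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignment:
    """Expand a protein alignment to codons (pal2nal-style back-threading).

    Each protein must translate its CDS exactly (a terminal stop codon on
    the CDS is allowed). Gap and stop-containing columns are dropped from
    the retained columns but counted.
    """
    for name, prot, cds in ((id_a, aligned_prot_a, cds_a), (id_b, aligned_prot_b, cds_b)):
        plain = prot.replace("-", "")
        trans = translate(cds)
        if plain != trans:
            bad = next(
                (i for i, (x, y) in enumerate(zip(plain, trans)) if x != y),
                min(len(plain), len(trans)),
            )
            raise ValueError(
                f"{name}: protein/CDS mismatch at codon {bad} "
                f"({plain[bad:bad+1]!r} vs {trans[bad:bad+1]!r})"
            )
    if len(aligned_prot_a) != len(aligned_prot_b):
        raise ValueError("aligned proteins differ in length")
    ia = ib = 0
    codons_a, codons_b = [], []
    dropped = 0
    for ca, cb in zip(aligned_prot_a, aligned_prot_b):
        codon_a = cds_a[3 * ia : 3 * ia + 3] if ca != "-" else None
        codon_b = cds_b[3 * ib : 3 * ib + 3] if cb != "-" else None
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if codon_a is None or codon_b is None:
            dropped += 1
            continue
        if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
            dropped += 1
            continue
        codons_a.append(codon_a)
        codons_b.append(codon_b)
    return CodonAlignment(id_a, id_b, codons_a, codons_b, n_dropped=dropped)


def codon_align_pair(
    id_a: str, cds_a: str, id_b: str, cds_b: str
) -> CodonAlignment:
    """Protein-guided codon alignment of two CDSs (global protein step)."""
    pa, pb = translate(cds_a), translate(cds_b)
    aligner = make_protein_aligner()
    aligner.mode = "global"
    aligner.open_end_gap_score = -1.0
    aligner.extend_end_gap_score = -0.5
    top = aligner.align(pa, pb)[0]
    sa, sb = str(top[0]), str(top[1])
    return align_codons(sa, sb, cds_a, cds_b, id_a, id_b)


# ------------------------------------------------------------ NG86 oracle


@dataclass
class NG86Result:
    ka: float
    ks: float
    ka_saturated: bool = False
    ks_saturated: bool = False


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three changes at ``pos`` that are synonymous
    (changes to stop codons count as nonsynonymous)."""
    aa = AA_OF[codon]
    syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt not in STOP_CODONS and AA_OF[alt] == aa:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> float:
    return sum(_syn_fraction(codon, p) for p in range(3))


def _pair_differences(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts for a codon pair."""
    diff = [p for p in range(3) if ca[p] != cb[p]]
    if not diff:
        return 0.0, 0.0
    syn_tot = non_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = ca
        syn = non = 0
        ok = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AA_OF[cur] == AA_OF[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_tot += syn
            non_tot += non
            n_paths += 1
    if n_paths == 0:  # all pathways blocked by stops: count ignoring stops
        for order in itertools.permutations(diff):
            cur = ca
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if nxt in STOP_CODONS or AA_OF.get(cur) is None:
                    non_tot += 1
                elif AA_OF[cur] == AA_OF.get(nxt, "?"):
                    syn_tot += 1
                else:
                    non_tot += 1
                cur = nxt
            n_paths += 1
    return syn_tot / n_paths, non_tot / n_paths


def _jc(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    if p <= 0:
        return 0.0, False
    return -0.75 * np.log(1 - 4.0 * p / 3.0), False


def ng86_kaks(alignment: CodonAlignment) -> NG86Result:
    """Nei-Gojobori pathway-averaged Ka and Ks with JC correction."""
    if alignment.n_codons == 0:
        raise ValueError("no usable codon columns")
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        s_a, s_b = _codon_sites(ca), _codon_sites(cb)
        S += (s_a + s_b) / 2.0
        N += 3.0 - (s_a + s_b) / 2.0
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    ks, ks_sat = _jc(Sd / S) if S > 0 else (float("nan"), True)
    ka, ka_sat = _jc(Nd / N) if N > 0 else (float("nan"), True)
    return NG86Result(ka=ka, ks=ks, ka_saturated=ka_sat, ks_saturated=ks_sat)


# ------------------------------------------------------------ GY94 ML


def _pair_structure():
    n = len(CODONS)
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            ii.append(i)
            jj.append(j)
            ts.append({ci[p], cj[p]} in ({"A", "G"}, {"C", "T"}))
            syn.append(AA_OF[ci] == AA_OF[cj])
    return (
        np.array(ii), np.array(jj),
        np.array(ts, dtype=bool), np.array(syn, dtype=bool),
    )


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN = _pair_structure()
_NC = len(CODONS)


def _rate_matrix(kappa: float, omega: float):
    """Normalised GY94 rate matrix (uniform codon frequencies) plus the
    nonsynonymous fraction of the total flux."""
    rates = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    Q = np.zeros((_NC, _NC))
    Q[_PAIR_I, _PAIR_J] = rates
    lam = Q.sum() / _NC  # expected substitutions per codon per unit t
    np.fill_diagonal(Q, -Q.sum(axis=1))
    frac_nonsyn = rates[~_PAIR_SYN].sum() / rates.sum()
    return Q / lam, frac_nonsyn


def _transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    # uniform frequencies make Q symmetric, so eigh applies
    w, v = np.linalg.eigh(Q)
    P = (v * np.exp(w * t)) @ v.T
    return np.clip(P, 1e-300, None)


def _count_matrix(alignment: CodonAlignment) -> np.ndarray:
    M = np.zeros((_NC, _NC))
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        M[CODON_INDEX[ca], CODON_INDEX[cb]] += 1.0
    return M


def _lnl(counts: np.ndarray, t: float, kappa: float, omega: float) -> float:
    Q, _ = _rate_matrix(kappa, omega)
    P = _transition_probs(Q, t)
    return float((counts * np.log(P)).sum() - counts.sum() * np.log(_NC))


@dataclass
class MLResult:
    lnl: float
    t: float
    kappa: float
    omega: float
    ka: float
    ks: float


_T_GRID = (0.02, 0.1, 0.4, 1.0, 2.5, 6.0)
_K_GRID = (1.0, 2.0, 4.0)
_W_GRID = (0.05, 0.3, 1.0, 3.0)
_BOUNDS = {"t": (1e-6, 50.0), "kappa": (0.05, 20.0), "omega": (1e-4, 10.0)}


def ml_kaks(
    alignment: CodonAlignment, fix_omega: Optional[float] = None
) -> MLResult:
    """Maximum-likelihood (t, kappa, omega) fit; deterministic via a fixed
    coarse grid followed by one bounded quasi-Newton refinement."""
    if alignment.n_codons < 1:
        raise ValueError("empty codon alignment")
    counts = _count_matrix(alignment)

    if fix_omega is None:
        grid = [(t, k, w) for t in _T_GRID for k in _K_GRID for w in _W_GRID]

        def neg(x):
            return -_lnl(counts, np.exp(x[0]), np.exp(x[1]), np.exp(x[2]))

        best = max(grid, key=lambda g: _lnl(counts, *g))
        x0 = np.log(best)
        bounds = [tuple(np.log(_BOUNDS[k])) for k in ("t", "kappa", "omega")]
    else:
        grid = [(t, k) for t in _T_GRID for k in _K_GRID]

        def neg(x):
            return -_lnl(counts, np.exp(x[0]), np.exp(x[1]), fix_omega)

        best = max(grid, key=lambda g: _lnl(counts, g[0], g[1], fix_omega))
        x0 = np.log(best)
        bounds = [tuple(np.log(_BOUNDS[k])) for k in ("t", "kappa")]

    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    lnl = -float(res.fun)
    if not np.isfinite(lnl):
        raise ValueError("non-finite likelihood")
    t_hat = float(np.exp(res.x[0]))
    k_hat = float(np.exp(res.x[1]))
    w_hat = float(fix_omega if fix_omega is not None else np.exp(res.x[2]))
    ka, ks = _ml_ka_ks(t_hat, k_hat, w_hat)
    return MLResult(lnl=lnl, t=t_hat, kappa=k_hat, omega=w_hat, ka=ka, ks=ks)


def _ml_ka_ks(t: float, kappa: float, omega: float) -> tuple[float, float]:
    """Per-site Ka and Ks implied by the fitted model parameters."""
    _, frac_n = _rate_matrix(kappa, omega)
    _, frac_n1 = _rate_matrix(kappa, 1.0)  # mutational opportunity
    n_sites = 3.0 * frac_n1
    s_sites = 3.0 - n_sites
    ka = t * frac_n / n_sites if n_sites > 0 else float("nan")
    ks = t * (1.0 - frac_n) / s_sites if s_sites > 0 else float("nan")
    return ka, ks


def lrt(lnl_alt: float, lnl_null: float) -> float:
    """p-value of 2(lnL_alt - lnL_null) against chi-square df=1."""
    two_delta = 2.0 * (lnl_alt - lnl_null)
    if two_delta < -LRT_TOL:
        raise ValueError(
            f"lnL_alt < lnL_null by {-two_delta / 2:.4g}: optimiser failure"
        )
    return float(chi2.sf(max(two_delta, 0.0), df=1))


# ------------------------------------------------------------ pair testing


def paralog_test(
    id_a: str,
    cds_a: str,
    id_b: str,
    cds_b: str,
    null_omega: float = 0.5,
) -> SelectionResult:
    """Full Ka/Ks + fixed-omega LRT for one gene/partner CDS pair."""
    aln = codon_align_pair(id_a, cds_a, id_b, cds_b)
    if aln.n_codons < MIN_CODONS:
        return SelectionResult(
            gene_id=id_a, partner_id=id_b, ka=float("nan"), ks=float("nan"),
            omega_hat=float("nan"), lnl_alt=float("nan"),
            lnl_null=float("nan"), p_value=float("nan"),
            null_omega=null_omega, filtered="too_short", verdict="filtered",
        )
    alt = ml_kaks(aln)
    null = ml_kaks(aln, fix_omega=null_omega)
    p = lrt(alt.lnl, null.lnl)
    return SelectionResult(
        gene_id=id_a, partner_id=id_b, ka=alt.ka, ks=alt.ks,
        omega_hat=alt.omega, lnl_alt=alt.lnl, lnl_null=null.lnl,
        p_value=p, null_omega=null_omega,
    )


def ks_filter(results: list[SelectionResult]) -> list[SelectionResult]:
    """Flag Ka > 0.5, Ks > 5, then 1.5 x IQR Ks outliers (quartiles by
    linear interpolation, computed on the prefiltered set)."""
    for r in results:
        if r.filtered != "none":
            continue
        if r.ka > 0.5:
            r.filtered = "ka_gt_0.5"
        elif r.ks > 5.0:
            r.filtered = "ks_gt_5"
    pool = [r for r in results if r.filtered == "none" and np.isfinite(r.ks)]
    if len(pool) < 4:
        warnings.warn("fewer than 4 Ks values; IQR filter skipped")
    else:
        ks_vals = np.array([r.ks for r in pool])
        q1, q3 = np.percentile(ks_vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for r in pool:
            if not lo <= r.ks <= hi:
                r.filtered = "ks_iqr_outlier"
    for r in results:
        if r.filtered != "none":
            r.verdict = "filtered"
    return results


def apply_verdicts(
    results: list[SelectionResult], alpha: float = 0.05
) -> list[SelectionResult]:
    """negative_selection iff unfiltered, omega_hat below the null and
    the LRT rejects at ``alpha``."""
    for r in results:
        if r.filtered != "none":
            r.verdict = "filtered"
        elif r.omega_hat < r.null_omega and r.p_value < alpha:
            r.verdict = "negative_selection"
        else:
            r.verdict = "not_significant"
    return results


# ------------------------------------------------------------ de novo ORF


def de_novo_ortholog_orf(
    protein: str,
    genome: dict[str, str],
    chrom: str,
    start: int,
    end: int,
    flank: int = 10_000,
    min_codons: int = 30,
    score_floor: float = 50.0,
):
    """Reconstruct the orthologous ORF of a de novo gene in a sister
    genome: take the homologous interval +-10 kb, scan all six frames for
    ATG-initiated ORFs, and return the longest ORF whose protein aligns
    to the query without stops or frameshifts (single-frame by
    construction). None when nothing of >= ``min_codons`` qualifies.
    """
    if chrom not in genome:
        raise ValueError(f"unknown sequence {chrom!r}")
    L = len(genome[chrom])
    if start < 0 or end > L:
        raise ValueError("homolog location outside the genome")
    lo, hi = max(0, start - flank), min(L, end + flank)
    region = genome[chrom][lo:hi]
    aligner = make_protein_aligner()
    candidates = []
    for strand, seq in (("+", region), ("-", revcomp(region))):
        for frame in range(3):
            i = frame
            orf_start = None
            while i + 3 <= len(seq):
                codon = seq[i : i + 3]
                if orf_start is None:
                    if codon == "ATG":
                        orf_start = i
                elif codon in STOP_CODONS or "N" in codon:
                    n_codons = (i - orf_start) // 3
                    if n_codons >= min_codons:
                        candidates.append((strand, orf_start, i + 3, seq))
                    orf_start = None
                i += 3
            if orf_start is not None and (i - orf_start) // 3 >= min_codons:
                candidates.append((strand, orf_start, i, seq))
    best = None
    for strand, s, e, seq in candidates:
        cds = seq[s:e]
        prot = translate(cds)
        if "*" in prot or not prot:
            continue
        aln = aligner.align(protein, prot)
        if float(aln.score) < score_floor:
            continue
        key = (len(prot), float(aln.score), -s)
        if best is None or key > best[0]:
            if strand == "+":
                gs, ge = lo + s, lo + e
            else:
                gs, ge = hi - e, hi - s
            best = (key, {
                "protein": prot, "cds": cds, "chrom": chrom,
                "start": gs, "end": ge, "strand": strand,
            })
    return best[1] if best else None


# ------------------------------------------------------------ simulation


def simulate_codon_pair(
    rng: np.random.Generator,
    n_codons: int,
    t: float,
    kappa: float,
    omega: float,
) -> CodonAlignment:
    """Simulate an aligned codon pair under the GY94 model (ancestor from
    the stationary uniform distribution, descendant via P(t))."""
    Q, _ = _rate_matrix(kappa, omega)
    P = _transition_probs(Q, t)
    P = P / P.sum(axis=1, keepdims=True)
    anc = rng.integers(0, _NC, n_codons)
    desc = np.empty(n_codons, dtype=np.int64)
    for i in np.unique(anc):
        sel = anc == i
        desc[sel] = rng.choice(_NC, size=int(sel.sum()), p=P[i])
    return CodonAlignment(
        "sim_a", "sim_b",
        [CODONS[i] for i in anc], [CODONS[i] for i in desc],
    )
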