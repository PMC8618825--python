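"""Synteny-based gene-age dating (SBP core).

Each focal gene's exons are tested for presence in every query species
using reciprocal-best alignment coverage; the gene's origination branch
follows from Dollo parsimony on the ladder (single gain on the focal
path, losses free), taking the oldest exon's age. Exclusion filters
mirror the study design: genes with more than 70% of their exonic bases
in repeats, and genes on unplaced scaffolds, are excluded.

Branch indices run 0..B: 0 = present in every sampled species (older
than the deepest split), B = focal-species-specific. "Lineage-specific"
genes are those on branches >= the configured lineage branch (default
2, i.e. postdating the split from the sampled outgroup clades).
"""

from __future__ import annotations

import pandas as pd

from .genome_align import coverage
from .model import (
    AgeCall,
    AlignmentChain,
    GeneModel,
    PresenceProfile,
    RepeatTrack,
    SpeciesLadder,
)

#: first branch counted as lineage-specific in summaries
LINEAGE_BRANCH = 2


def call_presence(
    gene: GeneModel,
    species_chains: dict[str, list[AlignmentChain]],
    threshold: float = 0.5,
) -> PresenceProfile:
    """Per-species, per-exon reciprocal-best coverage and presence flags.

    An exon is present in a species iff its coverage is >= threshold; the
    gene is present iff any exon is.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    exons = gene.exons
    if not exons:
        raise ValueError(f"gene {gene.gene_id} has no exons")
    cov: dict[str, list[float]] = {}
    present: dict[str, bool] = {}
    for sp, chains in species_chains.items():
        c = coverage([(gene.chromosome, e) for e in exons], chains)
        cov[sp] = [round(x, 4) for x in c]
        present[sp] = any(x >= threshold for x in c)
    return PresenceProfile(
        gene_id=gene.gene_id,
        exon_coverage=cov,
        present=present,
        threshold=threshold,
    )


def assign_branch(profile: PresenceProfile, ladder: SpeciesLadder) -> AgeCall:
    """Dollo-parsimony branch assignment from an exon presence profile.

    Each exon originates on the branch above the MRCA (on the focal path)
    of the species where it is present; presence in either member of an
    outgroup cherry counts as presence in that clade. The gene takes the
    oldest (minimum-index) exon age.
    """
    species = set(profile.exon_coverage)
    missing = set(ladder.taxa) - species - {ladder.focal}
    if missing:
        raise ValueError(f"profile lacks species {sorted(missing)}")
    B = ladder.terminal_branch
    n_exons = len(next(iter(profile.exon_coverage.values())))
    exon_branches = []
    for j in range(n_exons):
        present = {
            sp for sp in species if profile.exon_coverage[sp][j] >= profile.threshold
        }
        branch = B
        for s in range(1, B + 1):  # splits oldest first
            if ladder.clade_of_split(s) & present:
                branch = s - 1
                break
        exon_branches.append(branch)
    return AgeCall(gene_id=profile.gene_id, branch=min(exon_branches))


def apply_filters(
    calls: list[AgeCall],
    genes: list[GeneModel],
    repeats: RepeatTrack,
    repeat_threshold: float = 0.70,
) -> list[AgeCall]:
    """Exclude unplaced-scaffold genes and genes whose exonic span
    overlaps repeats by strictly more than the threshold."""
    by_id = {g.gene_id: g for g in genes}
    out = []
    for call in calls:
        g = by_id[call.gene_id]
        excluded, reason = False, "none"
        if not g.placed:
            excluded, reason = True, "unplaced"
        elif repeats.overlap_fraction(g.chromosome, g.exons) > repeat_threshold:
            excluded, reason = True, "repeat_overlap"
        out.append(
            AgeCall(
                gene_id=call.gene_id,
                branch=call.branch,
                excluded=excluded,
                exclusion_reason=reason,
            )
        )
    return out


def emergence_rate(n_genes: int, duration: float) -> float:
    """New genes per Myr, reported to one decimal."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return round(n_genes / duration, 1)


def proportion(part: int, whole: int) -> float:
    """Percentage part/whole, reported to one decimal."""
    if whole <= 0:
        raise ValueError("whole must be > 0")
    if not 0 <= part <= whole:
        raise ValueError("need 0 <= part <= whole")
    return round(100.0 * part / whole, 1)


def date_genes(
    genes: list[GeneModel],
    species_chains: dict[str, list[AlignmentChain]],
    ladder: SpeciesLadder,
    repeats: RepeatTrack,
    threshold: float = 0.5,
) -> tuple[list[PresenceProfile], list[AgeCall]]:
    """Presence profiles + filtered age calls for every focal gene."""
    profiles = [call_presence(g, species_chains, threshold) for g in genes]
    calls = [assign_branch(p, ladder) for p in profiles]
    return profiles, apply_filters(calls, genes, repeats)


def branch_summary(calls: list[AgeCall], ladder: SpeciesLadder) -> pd.DataFrame:
    """Per-branch counts, durations and emergence rates (excluded genes
    are dropped from branch counts and listed separately)."""
    rows = []
    kept = [c for c in calls if not c.excluded]
    for b in range(ladder.n_branches):
        n = sum(1 for c in kept if c.branch == b)
        dur = ladder.branch_duration(b)
        rows.append(
            {
                "branch": b,
                "n_genes": n,
                "duration_myr": dur,
                "rate_per_myr": emergence_rate(n, dur) if dur else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = sum(1 for c in calls if c.excluded)
    df.attrs["n_total"] = len(calls)
    return df
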