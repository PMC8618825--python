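"""Shared domain types for the new-gene origination pipeline.

All genomic intervals are 0-based half-open ``[start, end)`` on the + strand
of their sequence. Format readers/writers (:mod:`newgene.io`) convert at the
boundary (GFF3 is 1-based closed, BED 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class Interval:
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval]
    cds: list[Interval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(
                    f"CDS interval outside exons in transcript {self.transcript_id}"
                )

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def exon_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """A focal-genome gene with its transcripts.

    ``placed`` is False for genes on unplaced scaffolds; ``coding_ok`` is
    False when no transcript has a CDS whose length is divisible by 3
    (such genes stay in the dating set but are unusable for Ka/Ks).
    """

    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[Transcript]
    placed: bool = True
    coding_ok: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def span(self) -> Interval:
        return Interval(
            min(t.exons[0].start for t in self.transcripts),
            max(t.exons[-1].end for t in self.transcripts),
        )

    @property
    def exons(self) -> list[Interval]:
        """Union of exon intervals over transcripts (merged)."""
        ivs = sorted(
            (e for t in self.transcripts for e in t.exons), key=lambda iv: iv.start
        )
        merged: list[Interval] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1].end:
                merged[-1] = Interval(merged[-1].start, max(merged[-1].end, iv.end))
            else:
                merged.append(iv)
        return merged

    def longest_transcript(self) -> Transcript:
        """Transcript with the longest CDS (ties by id); used for the proteome."""
        return max(self.transcripts, key=lambda t: (t.cds_length, t.transcript_id))

    @property
    def n_cds_exons(self) -> int:
        return len(self.longest_transcript().cds)


@dataclass
class RepeatTrack:
    """Per-chromosome sorted, merged, half-open repeat intervals."""

    intervals: dict[str, list[Interval]]

    @classmethod
    def from_raw(cls, raw: dict[str, list[tuple[int, int]]]) -> "RepeatTrack":
        merged: dict[str, list[Interval]] = {}
        for chrom, ivs in raw.items():
            out: list[Interval] = []
            for s, e in sorted(ivs):
                if out and s <= out[-1].end:
                    out[-1] = Interval(out[-1].start, max(out[-1].end, e))
                else:
                    out.append(Interval(s, e))
            merged[chrom] = out
        return cls(merged)

    def overlap_fraction(self, chrom: str, intervals: list[Interval]) -> float:
        """Fraction of the given (disjoint) intervals covered by repeats."""
        total = sum(len(iv) for iv in intervals)
        if total == 0:
            return 0.0
        reps = self.intervals.get(chrom, [])
        cov = sum(iv.overlap(r) for iv in intervals for r in reps)
        return cov / total


@dataclass
class SpeciesLadder:
    """Dated ladder phylogeny along the focal lineage.

    ``splits`` lists, oldest first, the focal-path divergences as
    ``(clade_taxa, age_Myr)`` where ``clade_taxa`` are the taxa of the
    subtree splitting off the focal path at that node. With B splits there
    are B+1 branches indexed 0..B: branch 0 predates the oldest split
    (gene present in every sampled species), branch B is the terminal
    focal branch (focal-only genes).
    """

    taxa: list[str]
    focal: str
    splits: list[tuple[frozenset, float]]

    def __post_init__(self) -> None:
        ages = [a for _, a in self.splits]
        if any(b >= a for a, b in zip(ages, ages[1:])):
            raise ValueError("split ages must strictly decrease toward the focal tip")
        covered = set().union(*(c for c, _ in self.splits)) | {self.focal}
        if covered != set(self.taxa):
            raise ValueError("splits do not partition the taxa")

    @property
    def n_branches(self) -> int:
        """B + 1, the number of age categories."""
        return len(self.splits) + 1

    @property
    def terminal_branch(self) -> int:
        return len(self.splits)

    def branch_duration(self, branch: int) -> Optional[float]:
        """Myr spanned by a branch; None for branch 0 (unbounded above)."""
        B = self.terminal_branch
        if not 0 <= branch <= B:
            raise ValueError(f"branch {branch} outside 0..{B}")
        if branch == 0:
            return None
        upper = self.splits[branch - 1][1]
        lower = self.splits[branch][1] if branch < B else 0.0
        return upper - lower

    def age_of_split(self, branch: int) -> float:
        """Age (Myr) of the split that closes the given branch (1..B)."""
        return self.splits[branch - 1][1]

    def clade_of_split(self, branch: int) -> frozenset:
        return self.splits[branch - 1][0]


MECHANISMS = ("dna_duplication", "retroposition", "de_novo")


@dataclass
class GroundTruthEvent:
    """Simulator record of one planted gene-birth event."""

    gene_id: str
    true_branch: int
    true_mechanism: str
    parent_gene_id: Optional[str]
    true_omega: float

    def __post_init__(self) -> None:
        if self.true_mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.true_mechanism}")
        if self.true_mechanism == "de_novo" and self.parent_gene_id is not None:
            raise ValueError("de novo events have no parent")
        if self.true_mechanism != "de_novo" and self.parent_gene_id is None:
            raise ValueError("duplication events need a parent")


@dataclass
class Block:
    """One gap-free aligned block pair (focal +strand coordinates)."""

    f_start: int
    f_end: int
    q_start: int
    q_end: int
    score: float


@dataclass
class AlignmentChain:
    """Scored colinear chain of blocks between focal and query genome.

    Query coordinates are on the + strand of the query sequence; for
    ``q_strand == '-'`` the blocks pair focal forward positions with the
    reverse complement read right-to-left (block q coordinates remain
    +strand intervals).
    """

    f_chrom: str
    f_start: int
    f_end: int
    q_seq: str
    q_start: int
    q_end: int
    q_strand: str
    score: float
    blocks: list[Block]
    reciprocal_best: bool = False

    def f_interval(self) -> Interval:
        return Interval(self.f_start, self.f_end)

    def q_interval(self) -> Interval:
        return Interval(self.q_start, self.q_end)


@dataclass
class PresenceProfile:
    gene_id: str
    exon_coverage: dict[str, list[float]]  # species -> per-exon coverage fraction
    present: dict[str, bool]  # species -> any-exon presence
    threshold: float = 0.5  # coverage cutoff the present flags derive from

    def exon_present(self, species: str) -> list[bool]:
        return [c >= self.threshold for c in self.exon_coverage[species]]


@dataclass
class AgeCall:
    gene_id: str
    branch: int
    excluded: bool = False
    exclusion_reason: str = "none"  # repeat_overlap | unplaced | none


@dataclass
class MechanismCall:
    gene_id: str
    mechanism: str  # dna_duplication | retroposition | de_novo | unclassified
    parent_gene_id: Optional[str]
    evidence: dict = field(default_factory=dict)


@dataclass
class CodonAlignment:
    """Pairwise codon alignment; only gap-free, stop-free columns are
    kept for likelihood work."""

    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]
    n_dropped: int = 0  # gap- or stop-containing columns removed

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class SelectionResult:
    gene_id: str
    partner_id: str
    ka: float
    ks: float
    omega_hat: float
    lnl_alt: float
    lnl_null: float
    p_value: float
    null_omega: float
    filtered: str = "none"  # ka_gt_0.5 | ks_gt_5 | ks_iqr_outlier | too_short | none
    verdict: str = "not_significant"  # negative_selection | not_significant | filtered


@dataclass
class ExpressionCall:
    gene_id: str
    expressed: bool
    breadth: int
    tissue_means: dict[str, float]


@dataclass
class DifferentialResult:
    gene_id: str
    stage: str
    tissue: str
    log2_fold_change: float
    p_value: float
    significant: bool
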