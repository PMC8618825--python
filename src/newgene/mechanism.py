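"""Origin-mechanism classification of lineage-specific genes.

Three mechanisms are distinguished from paralog structure and outgroup
homology: a gene with a focal paralog is a duplicate — a retrogene if
the parent has >=2 CDS exons while the copy has exactly one (intron loss
through reverse transcription), otherwise a DNA-mediated duplicate. A
gene without any paralog whose locus still shows homologous (reciprocal
-best) sequence in a pre-origination species, with no annotated gene
overlapping that sequence, is a de novo gene. Genes with neither kind of
evidence are reported unclassified, never forced into a class.

Paralog search is Smith-Waterman over the focal proteome (BLOSUM62,
affine gaps 11/1), an explicit stand-in for the BLAST step of the
original analysis; an optional external-homology table can veto de novo
calls (e.g. hits against microbial databases screened elsewhere).
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .age_dating import proportion
from .model import (
    AgeCall,
    AlignmentChain,
    GeneModel,
    Interval,
    MechanismCall,
    SpeciesLadder,
)
from .codons import spliced_cds, translate

SCORE_FLOOR = 50.0
MIN_COVERAGE = 0.30  # of the shorter protein
MIN_OUTGROUP_COV = 0.10  # homology-evidence floor for de novo calls


def make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def build_proteome(
    genes: list[GeneModel], genome: dict[str, str]
) -> dict[str, str]:
    """Longest-transcript protein per coding gene."""
    prots = {}
    for g in genes:
        if not g.coding_ok:
            continue
        t = g.longest_transcript()
        cds = spliced_cds(genome, g.chromosome, g.strand, t.cds)
        prot = translate(cds)
        if prot and "*" not in prot:
            prots[g.gene_id] = prot
    return prots


def _kmer_set(prot: str, k: int = 4) -> set[str]:
    return {prot[i : i + k] for i in range(len(prot) - k + 1)}


def find_parent(
    gene_id: str,
    proteome: dict[str, str],
    score_floor: float = SCORE_FLOOR,
    min_coverage: float = MIN_COVERAGE,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Optional[tuple[str, float, float]]:
    """Best focal paralog of ``gene_id``: (parent_id, score, identity).

    Best hit by local-alignment score with alignment coverage of at
    least ``min_coverage`` of the shorter protein; ties broken by gene
    id. None when nothing clears the score floor.
    """
    if gene_id not in proteome:
        raise ValueError(f"gene {gene_id} has no valid CDS/protein")
    query = proteome[gene_id]
    qkmers = _kmer_set(query)
    aligner = aligner or make_protein_aligner()
    best: Optional[tuple[str, float, float]] = None
    for pid in sorted(proteome):
        if pid == gene_id:
            continue
        target = proteome[pid]
        if len(qkmers & _kmer_set(target)) < 2:
            continue  # cheap shared-word prefilter, mirrors BLAST seeding
        aln = aligner.align(query, target)
        score = float(aln.score)
        if score < score_floor:
            continue
        top = aln[0]
        counts = top.counts()
        aln_len = counts.identities + counts.mismatches + counts.gaps
        shorter = min(len(query), len(target))
        covered = counts.identities + counts.mismatches
        if covered < min_coverage * shorter:
            continue
        identity = counts.identities / aln_len if aln_len else 0.0
        if best is None or score > best[1]:
            best = (pid, score, identity)
    return best


def outgroup_noncoding_homology(
    gene: GeneModel,
    species_chains: dict[str, list[AlignmentChain]],
    species_genes: dict[str, list[GeneModel]],
    pre_species: set[str],
    min_coverage: float = MIN_OUTGROUP_COV,
) -> tuple[bool, list[str]]:
    """Does any pre-origination species carry homologous sequence at the
    gene's locus that is not part of an annotated gene there?

    Uses reciprocal-best blocks overlapping the gene's exons; the mapped
    query intervals must avoid annotated gene spans in that species.
    """
    exons = gene.exons
    exonic = sum(len(e) for e in exons)
    supporting = []
    for sp in sorted(pre_species):
        chains = species_chains.get(sp, [])
        hits: list[tuple[str, Interval]] = []
        covered = 0
        for c in chains:
            if not c.reciprocal_best or c.f_chrom != gene.chromosome:
                continue
            for b in c.blocks:
                for e in exons:
                    ov = min(b.f_end, e.end) - max(b.f_start, e.start)
                    if ov > 0:
                        covered += ov
                        hits.append((c.q_seq, Interval(b.q_start, b.q_end)))
        if covered < min_coverage * exonic:
            continue
        spans = [
            (g.chromosome, g.span)
            for g in species_genes.get(sp, [])
        ]
        coding_hit = any(
            qseq == chrom and qiv.overlap(spn) > 0
            for qseq, qiv in hits
            for chrom, spn in spans
        )
        if not coding_hit:
            supporting.append(sp)
    return bool(supporting), supporting


def classify_mechanism(
    gene: GeneModel,
    age: AgeCall,
    parent: Optional[GeneModel],
    parent_hit: Optional[tuple[str, float, float]],
    outgroup_evidence: tuple[bool, list[str]],
) -> MechanismCall:
    """Apply the mechanism rules to one lineage-specific gene."""
    if age is None:
        raise ValueError(f"gene {gene.gene_id} has no age call")
    evidence: dict = {"child_cds_exons": gene.n_cds_exons}
    if parent is not None:
        evidence["parent_cds_exons"] = parent.n_cds_exons
        evidence["parent_score"] = parent_hit[1]
        evidence["parent_identity"] = round(parent_hit[2], 4)
        if parent.n_cds_exons >= 2 and gene.n_cds_exons == 1:
            mech = "retroposition"
        else:
            mech = "dna_duplication"
        return MechanismCall(
            gene_id=gene.gene_id,
            mechanism=mech,
            parent_gene_id=parent.gene_id,
            evidence=evidence,
        )
    has_hom, species = outgroup_evidence
    evidence["outgroup_noncoding_homology"] = has_hom
    evidence["supporting_species"] = ",".join(species)
    mech = "de_novo" if has_hom else "unclassified"
    return MechanismCall(
        gene_id=gene.gene_id, mechanism=mech, parent_gene_id=None,
        evidence=evidence,
    )


def classify_genes(
    genes: list[GeneModel],
    calls: list[AgeCall],
    genome: dict[str, str],
    species_chains: dict[str, list[AlignmentChain]],
    species_genes: dict[str, list[GeneModel]],
    ladder: SpeciesLadder,
    lineage_branch: int = 2,
    external_homology: Optional[set[str]] = None,
) -> list[MechanismCall]:
    """Classify every non-excluded lineage-specific gene.

    ``external_homology`` is an optional veto set of gene ids with hits
    in external (e.g. microbial) databases; such genes cannot be called
    de novo and come out unclassified instead.
    """
    by_id = {g.gene_id: g for g in genes}
    age_by_id = {c.gene_id: c for c in calls}
    proteome = build_proteome(genes, genome)
    aligner = make_protein_aligner()
    out: list[MechanismCall] = []
    for call in calls:
        if call.excluded or call.branch < lineage_branch:
            continue
        gene = by_id[call.gene_id]
        if gene.gene_id not in proteome:
            continue
        hit = find_parent(gene.gene_id, proteome, aligner=aligner)
        parent = by_id[hit[0]] if hit else None
        pre_species = set()
        for s in range(1, call.branch + 1):
            pre_species |= ladder.clade_of_split(s)
        ev = (False, [])
        if parent is None:
            ev = outgroup_noncoding_homology(
                gene, species_chains, species_genes, pre_species
            )
        mc = classify_mechanism(gene, age_by_id[gene.gene_id], parent, hit, ev)
        if (
            mc.mechanism == "de_novo"
            and external_homology
            and gene.gene_id in external_homology
        ):
            mc.mechanism = "unclassified"
            mc.evidence["external_homology_veto"] = True
        out.append(mc)
    return out


def partition_summary(calls: list[MechanismCall]) -> pd.DataFrame:
    """Counts and percentages per mechanism over the classified set."""
    classified = [c for c in calls if c.mechanism != "unclassified"]
    total = len(classified)
    rows = []
    for mech in ("dna_duplication", "retroposition", "de_novo"):
        n = sum(1 for c in classified if c.mechanism == mech)
        rows.append(
            {
                "mechanism": mech,
                "n": n,
                "percent": proportion(n, total) if total else 0.0,
            }
        )
    rows.append(
        {
            "mechanism": "unclassified",
            "n": len(calls) - total,
            "percent": float("nan"),
        }
    )
    return pd.DataFrame(rows)
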