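"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
closed) and BED (0-based half-open) are converted at this boundary.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignmentChain,
    Block,
    GeneModel,
    GroundTruthEvent,
    Interval,
    RepeatTrack,
    SpeciesLadder,
    Transcript,
)

_VALID_BASES = re.compile(r"^[ACGTN]*$")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- FASTA


def read_genome(path) -> dict[str, str]:
    """Read a genome FASTA into ``{sequence_name: uppercase sequence}``.

    Rejects duplicate headers and characters outside {A,C,G,T,N}.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ParseError(f"duplicated FASTA header {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not _VALID_BASES.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ParseError(f"invalid characters {bad} in record {rec.id!r}")
        genome[rec.id] = seq
    if not genome:
        raise ParseError(f"no FASTA records in {path}")
    return genome


def write_genome(genome: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------- GFF3


def _attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gene_models(
    path, chromosomes: Optional[Iterable[str]] = None
) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file.

    GFF3 1-based closed coordinates become 0-based half-open. If
    ``chromosomes`` is given, genes on other sequences get
    ``placed=False``. Genes whose every transcript has a CDS length not
    divisible by 3 are kept but flagged ``coding_ok=False``.
    """
    placed_set = set(chromosomes) if chromosomes is not None else None
    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_data: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attr = fields
            try:
                iv = Interval(int(start) - 1, int(end))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            a = _attrs(attr)
            if ftype == "gene":
                genes[a["ID"]] = {"chrom": chrom, "strand": strand}
            elif ftype == "mRNA":
                tx_parent[a["ID"]] = a["Parent"]
                tx_data[a["ID"]] = {"exons": [], "cds": []}
            elif ftype == "exon":
                tx_data[a["Parent"]]["exons"].append(iv)
            elif ftype == "CDS":
                tx_data[a["Parent"]]["cds"].append(iv)
    out: list[GeneModel] = []
    for gid, g in genes.items():
        txs = []
        for tid, parent in tx_parent.items():
            if parent != gid:
                continue
            txs.append(
                Transcript(tid, tx_data[tid]["exons"], tx_data[tid]["cds"])
            )
        if not txs:
            raise ParseError(f"gene {gid} has no mRNA features")
        txs.sort(key=lambda t: t.transcript_id)
        coding_ok = any(t.cds_length % 3 == 0 and t.cds_length > 0 for t in txs)
        if not coding_ok:
            warnings.warn(
                f"gene {gid}: no transcript with CDS length divisible by 3; "
                "flagged unusable for selection analysis"
            )
        placed = True if placed_set is None else g["chrom"] in placed_set
        out.append(
            GeneModel(
                gene_id=gid,
                chromosome=g["chrom"],
                strand=g["strand"],
                transcripts=txs,
                placed=placed,
                coding_ok=coding_ok,
            )
        )
    out.sort(key=lambda g: g.gene_id)
    return out


def write_gene_models(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            sp = g.span
            fh.write(
                f"{g.chromosome}\tnewgene\tgene\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chromosome}\tnewgene\tmRNA\t{t.exons[0].start + 1}\t"
                    f"{t.exons[-1].end}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chromosome}\tnewgene\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\tParent={t.transcript_id}\n"
                    )
                for c in t.cds:
                    fh.write(
                        f"{g.chromosome}\tnewgene\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{g.strand}\t0\tParent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------- BED


def read_repeats(path) -> RepeatTrack:
    """Read a BED file (0-based half-open) into a merged RepeatTrack."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            raw.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return RepeatTrack.from_raw(raw)


def write_repeats(track: RepeatTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            for iv in track.intervals[chrom]:
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------- ladder


def read_ladder(path_or_string, focal: str) -> SpeciesLadder:
    """Build a SpeciesLadder from a rooted newick tree with Myr branch lengths.

    The tree must be ultrametric and strictly bifurcating along the path
    from the focal tip to the root (a ladder); node ages are recovered from
    root-to-tip path lengths.
    """
    src = str(path_or_string)
    if "(" in src:
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if focal not in taxa:
        raise ParseError(f"focal species {focal!r} not among tree taxa")
    if len(tree.seed_node.child_nodes()) != 2:
        raise ParseError("tree is unrooted or has a polytomy at the root")
    focal_leaf = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == focal
    )
    splits: list[tuple[frozenset, float]] = []
    node = focal_leaf
    age = 0.0
    while node.parent_node is not None:
        age += node.edge.length
        parent = node.parent_node
        sibs = [c for c in parent.child_nodes() if c is not node]
        if len(sibs) != 1:
            raise ParseError("polytomy on the focal path; ladder required")
        clade = frozenset(lf.taxon.label for lf in sibs[0].leaf_iter())
        splits.append((clade, age))
        node = parent
    splits.reverse()  # oldest first
    return SpeciesLadder(taxa=sorted(taxa), focal=focal, splits=splits)


def write_ladder(ladder: SpeciesLadder, path) -> None:
    """Serialise a ladder back to newick (focal-path caterpillar)."""

    def clade_newick(clade: frozenset, height: float) -> str:
        members = sorted(clade)
        if len(members) == 1:
            return f"{members[0]}:{height:g}"
        if len(members) == 2:  # cherries: split them at half their height
            h = height / 2.0
            return f"({members[0]}:{h:g},{members[1]}:{h:g}):{h:g}"
        raise ValueError("only tips and cherries supported off the focal path")

    inner = f"{ladder.focal}:{ladder.splits[-1][1]:g}"
    prev_age = 0.0
    ages = [a for _, a in ladder.splits]
    for i in range(len(ladder.splits) - 1, -1, -1):
        clade, age = ladder.splits[i]
        parent_age = ages[i - 1] if i > 0 else None
        stem = f":{parent_age - age:g}" if parent_age is not None else ""
        inner = f"({inner},{clade_newick(clade, age)}){stem}"
        prev_age = age
    with open(path, "w") as fh:
        fh.write(f"[&R] {inner};\n")


# ---------------------------------------------------------------- matrices


class ExpressionMatrix:
    """Gene x sample matrix with per-column metadata.

    Column names encode metadata as ``tissue|side|stage|replicate`` (any
    suffix fields may be absent). FPKM matrices hold non-negative reals,
    count matrices non-negative integers.
    """

    META_FIELDS = ("tissue", "side", "stage", "replicate")

    def __init__(self, df: pd.DataFrame, counts: bool = False):
        if (df.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if counts and not (df.values == df.values.astype(int)).all():
            raise ValueError("count matrix must be integer-valued")
        self.df = df.astype(int) if counts else df.astype(float)
        self.counts = counts
        meta = {}
        for col in df.columns:
            parts = col.split("|")
            meta[col] = {
                f: (parts[i] if i < len(parts) else "")
                for i, f in enumerate(self.META_FIELDS)
            }
        self.meta = pd.DataFrame.from_dict(meta, orient="index")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    def columns_where(self, **kw) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        for k, v in kw.items():
            mask &= self.meta[k] == v
        return list(self.meta.index[mask])

    @classmethod
    def read(cls, path, counts: bool = False) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, counts=counts)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------- chains


_CHAIN_COLS = [
    "f_chrom", "f_start", "f_end", "q_seq", "q_start", "q_end",
    "q_strand", "score", "reciprocal_best", "blocks",
]


def write_chains(chains: list[AlignmentChain], path) -> None:
    rows = []
    for c in chains:
        blocks = ",".join(
            f"{b.f_start}:{b.f_end}:{b.q_start}:{b.q_end}:{b.score:g}"
            for b in c.blocks
        )
        rows.append(
            [c.f_chrom, c.f_start, c.f_end, c.q_seq, c.q_start, c.q_end,
             c.q_strand, f"{c.score:g}", int(c.reciprocal_best), blocks]
        )
    pd.DataFrame(rows, columns=_CHAIN_COLS).to_csv(path, sep="\t", index=False)


def read_chains(path) -> list[AlignmentChain]:
    df = pd.read_csv(path, sep="\t", dtype={"blocks": str})
    out = []
    for row in df.itertuples(index=False):
        blocks = []
        if isinstance(row.blocks, str) and row.blocks:
            for tok in row.blocks.split(","):
                fs, fe, qs, qe, sc = tok.split(":")
                blocks.append(Block(int(fs), int(fe), int(qs), int(qe), float(sc)))
        out.append(
            AlignmentChain(
                f_chrom=row.f_chrom, f_start=int(row.f_start), f_end=int(row.f_end),
                q_seq=row.q_seq, q_start=int(row.q_start), q_end=int(row.q_end),
                q_strand=row.q_strand, score=float(row.score), blocks=blocks,
                reciprocal_best=bool(row.reciprocal_best),
            )
        )
    return out


# ---------------------------------------------------------------- truth table


def write_truth(events: list[GroundTruthEvent], path) -> None:
    rows = [
        [e.gene_id, e.true_branch, e.true_mechanism,
         e.parent_gene_id or "", e.true_omega]
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "true_branch", "true_mechanism", "parent_gene_id",
                 "true_omega"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        GroundTruthEvent(
            gene_id=str(r.gene_id),
            true_branch=int(r.true_branch),
            true_mechanism=str(r.true_mechanism),
            parent_gene_id=str(r.parent_gene_id) or None,
            true_omega=float(r.true_omega),
        )
        for r in df.itertuples(index=False)
    ]
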