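"""Forward genome-evolution simulator with planted gene-birth events.

Generates a ladder of genomes descending from a common ancestor: an
ancestral genome with multi-exon protein-coding genes, interspersed
repeats and reserved intergenic segments is evolved along a dated ladder
phylogeny under an HKY-like substitution process. Coding sites respect a
per-gene omega by proposal-rejection (nonsynonymous proposals accepted
with probability omega; nonsense proposals always rejected, so ORFs stay
intact). Indels are confined to intergenic/intronic sequence, with gene
coordinates remapped exactly.

On chosen focal-path branches the simulator plants gene-birth events of
known mechanism — DNA-mediated duplication (genomic copy incl. introns),
retroposition (intronless insertion of the spliced CDS of a multi-exon
parent) and de novo origination (an ORF assembled over an ancestral
intergenic core plus novel flanking insertion, so outgroups retain
partial non-coding homology) — and records the ground truth.

All simulated genes sit on the + strand; see docs/methods.md for what
that simplification does and does not exercise.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as ngio
from .codons import AA_BY_INT, STOP_INTS, TS_PARTNER, codon_int
from .model import (
    GeneModel,
    GroundTruthEvent,
    Interval,
    RepeatTrack,
    SpeciesLadder,
    Transcript,
)

_DECODE = np.array(list("ACGT"))

#: default ladder: focal-path split ages in Myr, oldest first
DEFAULT_SPLITS = (
    (("out3", "out4"), 80.0),
    (("out1", "out2"), 73.7),
    (("sp4",), 65.0),
    (("sp3",), 55.0),
    (("sister",), 41.8),
)


def default_ladder() -> SpeciesLadder:
    taxa = sorted({"focal"} | {t for c, _ in DEFAULT_SPLITS for t in c})
    return SpeciesLadder(
        taxa=taxa,
        focal="focal",
        splits=[(frozenset(c), a) for c, a in DEFAULT_SPLITS],
    )


@dataclass
class SimulationConfig:
    """Knobs of the simulated world; defaults emulate the study design
    at desk scale (a ~2 Mb focal genome instead of ~500 Mb)."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    scaffold_length: int = 30_000
    n_scaffold_genes: int = 2
    n_ancestral_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_codons: tuple[int, int] = (30, 100)
    intron_length: tuple[int, int] = (100, 800)
    gc_content: float = 0.42
    substitution_rate: float = 0.001  # subs/site/Myr
    ts_tv: float = 2.0
    indel_rate: float = 2e-5  # events/site/Myr, intergenic/intronic only
    indel_mean_length: float = 3.0
    indel_max_length: int = 50
    repeat_families: int = 3
    repeat_unit_length: int = 400
    repeat_density: float = 0.05
    # planted events per focal-path branch: branch -> mechanism -> count
    events_per_branch: dict = field(
        default_factory=lambda: {
            b: {"dna_duplication": 5, "retroposition": 3, "de_novo": 2}
            for b in (2, 3, 4, 5)
        }
    )
    omega_ancestral: float = 0.2
    omega_dna_duplication: float = 0.25
    omega_retroposition: float = 0.25
    omega_de_novo: float = 1.0
    de_novo_codons: tuple[int, int] = (120, 200)
    de_novo_ancestral_fraction: float = 0.4
    # expression model
    fpkm_tissues: tuple = ("brain", "liver", "muscle", "eye", "gonad_m", "gonad_f")
    fpkm_replicates: int = 2
    fpkm_meanlog: float = 1.0
    fpkm_sdlog: float = 1.2
    silent_fraction_old: float = 0.05
    silent_fraction_duplicate: float = 0.26
    silent_fraction_de_novo: float = 0.65
    count_stages: tuple = ("Pre", "Pro", "Clim", "Post")
    count_tissues: tuple = ("eye", "muscle", "skin")
    count_replicates: int = 3
    count_scale: float = 30.0
    nb_dispersion: float = 0.05
    n_asymmetric: int = 9
    asym_fold_change: float = 4.0
    asym_stage: str = "Pro"
    asym_tissue: str = "muscle"

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "repeat_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        ladder = default_ladder()
        for b in self.events_per_branch:
            if not 0 <= b <= ladder.terminal_branch:
                raise ValueError(f"planted-event branch {b} outside focal path")


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    exons: list[list[int]]  # [[start, end), ...] sorted, all coding, +strand
    omega: float

    def positions(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(s, e, dtype=np.int64) for s, e in self.exons]
        )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeState:
    seqs: dict[str, np.ndarray]
    genes: list[SimGene]
    repeats: dict[str, list[list[int]]]
    reserved: dict[str, list]  # res_id -> [chrom, start, end, total_codons]

    def copy(self) -> "GenomeState":
        return GenomeState(
            seqs={c: a.copy() for c, a in self.seqs.items()},
            genes=copy.deepcopy(self.genes),
            repeats=copy.deepcopy(self.repeats),
            reserved=copy.deepcopy(self.reserved),
        )

    def decode(self) -> dict[str, str]:
        return {c: "".join(_DECODE[a]) for c, a in self.seqs.items()}


# ------------------------------------------------------------ construction


def _random_seq(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _random_sense_codon(rng) -> list[int]:
    while True:
        c = rng.integers(0, 4, 3)
        if codon_int(*c) not in STOP_INTS:
            return list(c)


def _random_orf(rng, n_codons: int) -> np.ndarray:
    """ATG + (n-2) sense codons + stop, as base codes."""
    out = [0, 3, 2]  # ATG as base codes
    for _ in range(n_codons - 2):
        out.extend(_random_sense_codon(rng))
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    out.extend("ACGT".index(b) for b in stop)
    return np.array(out, dtype=np.uint8)


def _make_gene_parts(rng, cfg: SimulationConfig):
    """(sequence, relative exon intervals) for one random multi-exon gene."""
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_codons = rng.integers(cfg.exon_codons[0], cfg.exon_codons[1] + 1, n_ex)
    orf = _random_orf(rng, int(exon_codons.sum()))
    parts, exons = [], []
    pos = 0
    cds_off = 0
    for i, nc in enumerate(exon_codons):
        ex = orf[cds_off : cds_off + 3 * nc]
        parts.append(ex)
        exons.append([pos, pos + len(ex)])
        pos += len(ex)
        cds_off += 3 * nc
        if i < n_ex - 1:
            ilen = int(rng.integers(*cfg.intron_length))
            parts.append(_random_seq(rng, ilen, cfg.gc_content))
            pos += ilen
    return np.concatenate(parts), exons


def simulate_ancestral_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GenomeState:
    """Build the ancestral genome: genes, repeats and reserved de novo
    cores placed without overlap, random intergenic sequence between."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_denovo = sum(
        m.get("de_novo", 0) for m in config.events_per_branch.values()
    )
    # pre-build features
    feats = []  # (kind, payload)
    for i in range(config.n_ancestral_genes):
        seq, exons = _make_gene_parts(rng, config)
        feats.append(("gene", f"anc{i:04d}", seq, exons))
    monomers = [
        _random_seq(rng, config.repeat_unit_length, 0.5)
        for _ in range(config.repeat_families)
    ]
    genome_len = config.n_chromosomes * config.chromosome_length
    n_rep = int(config.repeat_density * genome_len / config.repeat_unit_length)
    for i in range(n_rep):
        base = monomers[i % len(monomers)].copy()
        nmut = rng.binomial(len(base), 0.02)
        if nmut:
            at = rng.integers(0, len(base), nmut)
            base[at] = (base[at] + rng.integers(1, 4, nmut)) % 4
        feats.append(("repeat", f"rep{i:04d}", base, None))
    for i in range(n_denovo):
        n_total = int(rng.integers(*config.de_novo_codons))
        core_codons = max(10, round(n_total * config.de_novo_ancestral_fraction))
        seq = _random_seq(rng, 3 * core_codons, cfg_gc(config))
        feats.append(("reserved", f"res{i:03d}", seq, n_total))
    order = rng.permutation(len(feats))
    feats = [feats[i] for i in order]

    per_chrom: list[list] = [[] for _ in range(config.n_chromosomes)]
    for i, f in enumerate(feats):
        per_chrom[i % config.n_chromosomes].append(f)

    seqs: dict[str, np.ndarray] = {}
    genes: list[SimGene] = []
    repeats: dict[str, list[list[int]]] = {}
    reserved: dict[str, list] = {}
    for ci, chrom_feats in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        feat_len = sum(len(f[2]) for f in chrom_feats)
        slack = config.chromosome_length - feat_len
        if slack < 100 * (len(chrom_feats) + 1):
            raise ValueError(
                "features do not fit without overlap; increase chromosome_length"
            )
        gaps = rng.multinomial(
            slack - 100 * (len(chrom_feats) + 1),
            np.full(len(chrom_feats) + 1, 1 / (len(chrom_feats) + 1)),
        ) + 100
        parts = []
        pos = 0
        repeats[chrom] = []
        for f, gap in zip(chrom_feats, gaps[:-1]):
            parts.append(_random_seq(rng, int(gap), config.gc_content))
            pos += int(gap)
            kind, name, seq, extra = f
            parts.append(seq)
            if kind == "gene":
                genes.append(
                    SimGene(
                        gene_id=name,
                        chrom=chrom,
                        exons=[[pos + s, pos + e] for s, e in extra],
                        omega=config.omega_ancestral,
                    )
                )
            elif kind == "repeat":
                repeats[chrom].append([pos, pos + len(seq)])
            else:
                reserved[name] = [chrom, pos, pos + len(seq), extra]
            pos += len(seq)
        parts.append(_random_seq(rng, int(gaps[-1]), config.gc_content))
        seqs[chrom] = np.concatenate(parts)
    # unplaced scaffold with a couple of old genes
    if config.scaffold_length > 0:
        chrom = "scaffold_1"
        parts = []
        pos = 0
        repeats[chrom] = []
        for i in range(config.n_scaffold_genes):
            gap = config.scaffold_length // (config.n_scaffold_genes + 1) // 2
            parts.append(_random_seq(rng, gap, config.gc_content))
            pos += gap
            seq, exons = _make_gene_parts(rng, config)
            genes.append(
                SimGene(
                    gene_id=f"scf{i:02d}",
                    chrom=chrom,
                    exons=[[pos + s, pos + e] for s, e in exons],
                    omega=config.omega_ancestral,
                )
            )
            parts.append(seq)
            pos += len(seq)
        parts.append(_random_seq(rng, 2000, config.gc_content))
        seqs[chrom] = np.concatenate(parts)
    genes.sort(key=lambda g: (g.chrom, g.exons[0][0]))
    return GenomeState(seqs=seqs, genes=genes, repeats=repeats, reserved=reserved)


def cfg_gc(config: SimulationConfig) -> float:
    return config.gc_content


# ------------------------------------------------------------ evolution


_TV_TABLE = np.array(
    [[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8
)  # the two transversion targets per base


def _coding_maps(state: GenomeState, chrom: str):
    """owner (gene index or -1) and CDS offset per position for a chromosome."""
    L = state.seqs[chrom].shape[0]
    owner = np.full(L, -1, dtype=np.int32)
    cdsoff = np.full(L, -1, dtype=np.int32)
    for gi, g in enumerate(state.genes):
        if g.chrom != chrom:
            continue
        off = 0
        for s, e in g.exons:
            owner[s:e] = gi
            cdsoff[s:e] = np.arange(off, off + (e - s))
            off += e - s
    return owner, cdsoff


def _feature_mask(state: GenomeState, chrom: str) -> np.ndarray:
    """True where indels are forbidden (exons, repeats, reserved, margins)."""
    L = state.seqs[chrom].shape[0]
    mask = np.zeros(L, dtype=bool)
    pad = 10
    for g in state.genes:
        if g.chrom != chrom:
            continue
        for s, e in g.exons:
            mask[max(0, s - pad) : min(L, e + pad)] = True
    for s, e in state.repeats.get(chrom, []):
        mask[max(0, s - pad) : min(L, e + pad)] = True
    for c, s, e, _n in state.reserved.values():
        if c == chrom:
            mask[max(0, s - pad) : min(L, e + pad)] = True
    return mask


def _remap(values: np.ndarray, breaks: np.ndarray, deltas: np.ndarray):
    """Shift coordinates by the cumulative indel delta before each value."""
    idx = np.searchsorted(breaks, values, side="right")
    shift = np.concatenate([[0], np.cumsum(deltas)])[idx]
    return values + shift


def _apply_indels(state: GenomeState, chrom: str, indels: list[tuple]):
    """indels: (pos, delta, insert_codes or None), non-overlapping, sorted.

    Deletions are (pos, -l, None) removing [pos, pos+l); insertions are
    (pos, +l, codes) inserting before pos. Features never intersect
    deleted ranges, so interval endpoints shift rigidly.
    """
    if not indels:
        return
    seq = state.seqs[chrom]
    parts = []
    cur = 0
    for pos, delta, ins in indels:
        if delta < 0:
            parts.append(seq[cur:pos])
            cur = pos - delta
        else:
            parts.append(seq[cur:pos])
            parts.append(ins)
            cur = pos
    parts.append(seq[cur:])
    state.seqs[chrom] = np.concatenate(parts)
    # breakpoints: coordinates >= break shift by delta
    breaks = np.array(
        [pos - delta if delta < 0 else pos for pos, delta, _ in indels],
        dtype=np.int64,
    )
    deltas = np.array([d for _, d, _ in indels], dtype=np.int64)
    for g in state.genes:
        if g.chrom != chrom:
            continue
        for ex in g.exons:
            ex[0] = int(_remap(np.array([ex[0]]), breaks, deltas)[0])
            ex[1] = int(_remap(np.array([ex[1]]), breaks, deltas)[0])
    for iv in state.repeats.get(chrom, []):
        iv[0] = int(_remap(np.array([iv[0]]), breaks, deltas)[0])
        iv[1] = int(_remap(np.array([iv[1]]), breaks, deltas)[0])
    for rec in state.reserved.values():
        if rec[0] == chrom:
            rec[1] = int(_remap(np.array([rec[1]]), breaks, deltas)[0])
            rec[2] = int(_remap(np.array([rec[2]]), breaks, deltas)[0])


def evolve_branch(
    state: GenomeState,
    duration: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenomeState:
    """Evolve the genome in place for ``duration`` Myr; returns ``state``.

    Substitutions follow an HKY-like kernel (transition:transversion =
    ts_tv); at coding sites nonsynonymous proposals are accepted with
    probability the gene's omega and nonsense proposals are rejected.
    Indels hit intergenic/intronic sequence only.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    kappa = config.ts_tv
    p_ts = kappa / (kappa + 2.0)
    for chrom in state.seqs:
        seq = state.seqs[chrom]
        L = seq.shape[0]
        n_sub = rng.poisson(config.substitution_rate * duration * L)
        if n_sub:
            owner, cdsoff = _coding_maps(state, chrom)
            gene_pos_cache: dict[int, np.ndarray] = {}
            pos = rng.integers(0, L, n_sub)
            cur = seq[pos]
            is_ts = rng.random(n_sub) < p_ts
            tv_pick = rng.integers(0, 2, n_sub)
            new = np.where(
                is_ts, TS_PARTNER[cur], _TV_TABLE[cur, tv_pick]
            ).astype(np.uint8)
            accept_u = rng.random(n_sub)
            coding = owner[pos] >= 0
            seq[pos[~coding]] = new[~coding]
            for i in np.nonzero(coding)[0]:
                p = int(pos[i])
                gi = int(owner[p])
                g = state.genes[gi]
                gp = gene_pos_cache.get(gi)
                if gp is None:
                    gp = g.positions()
                    gene_pos_cache[gi] = gp
                off = int(cdsoff[p])
                ci = off // 3
                cpos = gp[3 * ci : 3 * ci + 3]
                codon = seq[cpos].copy()
                codon[off % 3] = new[i]
                ival = codon_int(*codon)
                old_ival = codon_int(*seq[cpos])
                n_codons = g.cds_length // 3
                if ci == 0:
                    continue  # protect the start codon
                if ci == n_codons - 1:
                    if ival in STOP_INTS:  # stop stays a stop
                        seq[p] = new[i]
                    continue
                if ival in STOP_INTS:
                    continue  # no nonsense substitutions
                if AA_BY_INT[ival] == AA_BY_INT[old_ival]:
                    seq[p] = new[i]
                elif accept_u[i] < g.omega:
                    seq[p] = new[i]
        n_ind = rng.poisson(config.indel_rate * duration * L)
        if n_ind:
            forbidden = _feature_mask(state, chrom)
            L = state.seqs[chrom].shape[0]
            raw_pos = rng.integers(50, L - 100, n_ind)
            is_ins = rng.random(n_ind) < 0.5
            lens = np.minimum(
                rng.geometric(1.0 / config.indel_mean_length, n_ind),
                config.indel_max_length,
            )
            events = []
            for p, ins, l in zip(raw_pos, is_ins, lens):
                p, l = int(p), int(l)
                if ins:
                    if forbidden[p]:
                        continue
                    events.append((p, l, _random_seq(rng, l, config.gc_content)))
                else:
                    if forbidden[p : p + l].any():
                        continue
                    events.append((p, -l, None))
            events.sort(key=lambda e: e[0])
            pruned = []
            last_end = -1
            for p, d, ins in events:
                end = p - d if d < 0 else p
                if p <= last_end:
                    continue
                pruned.append((p, d, ins))
                last_end = end
            _apply_indels(state, chrom, pruned)
    return state


# ------------------------------------------------------------ planting


@dataclass
class PlannedEvent:
    gene_id: str
    branch: int
    mechanism: str
    parent_gene_id: Optional[str]
    omega: float
    reserved_id: Optional[str] = None  # de novo only


def _insertion_site(
    state: GenomeState, rng: np.random.Generator, length: int
) -> tuple[str, int]:
    chroms = [c for c in state.seqs if c.startswith("chr")]
    for _ in range(200):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        forbidden = _feature_mask(state, chrom)
        L = state.seqs[chrom].shape[0]
        p = int(rng.integers(1000, L - 1000))
        if not forbidden[p - 50 : p + 50].any():
            return chrom, p
    raise RuntimeError("could not find an intergenic insertion site")


def plant_event(
    state: GenomeState,
    event: PlannedEvent,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GroundTruthEvent:
    """Insert one gene-birth event into the genome; returns the truth record."""
    genes_by_id = {g.gene_id: g for g in state.genes}
    if event.mechanism == "dna_duplication":
        parent = genes_by_id[event.parent_gene_id]
        span0 = parent.exons[0][0]
        span1 = parent.exons[-1][1]
        seq = state.seqs[parent.chrom][span0:span1].copy()
        rel_exons = [[s - span0, e - span0] for s, e in parent.exons]
        chrom, pos = _insertion_site(state, rng, len(seq))
        _apply_indels(state, chrom, [(pos, len(seq), seq)])
        state.genes.append(
            SimGene(
                gene_id=event.gene_id,
                chrom=chrom,
                exons=[[pos + s, pos + e] for s, e in rel_exons],
                omega=event.omega,
            )
        )
    elif event.mechanism == "retroposition":
        parent = genes_by_id[event.parent_gene_id]
        if len(parent.exons) < 2:
            raise ValueError("retroposition requires a multi-exon parent")
        seq = np.concatenate(
            [state.seqs[parent.chrom][s:e] for s, e in parent.exons]
        )
        chrom, pos = _insertion_site(state, rng, len(seq))
        _apply_indels(state, chrom, [(pos, len(seq), seq)])
        state.genes.append(
            SimGene(
                gene_id=event.gene_id,
                chrom=chrom,
                exons=[[pos, pos + len(seq)]],
                omega=event.omega,
            )
        )
    elif event.mechanism == "de_novo":
        chrom, s, e, n_total = state.reserved.pop(event.reserved_id)
        seq = state.seqs[chrom]
        # kill stop codons in the ancestral core (minimal edits, frame from s)
        for cstart in range(s, e, 3):
            if codon_int(*seq[cstart : cstart + 3]) in STOP_INTS:
                seq[cstart + 1] = 1  # middle base -> C
        core_codons = (e - s) // 3
        n_pre = max(1, (n_total - core_codons) // 2)
        n_suf = n_total - core_codons - n_pre
        pre = _random_orf(rng, n_pre + 2)[: 3 * n_pre]  # ATG + sense codons
        suf_parts = []
        for _ in range(n_suf - 1):
            suf_parts.extend(_random_sense_codon(rng))
        stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
        suf_parts.extend("ACGT".index(b) for b in stop)
        suf = np.array(suf_parts, dtype=np.uint8)
        _apply_indels(
            state, chrom, [(s, len(pre), pre), (e, len(suf), suf)]
        )
        start = s  # prefix inserted before the (remapped) core start
        end = s + len(pre) + (e - s) + len(suf)
        state.genes.append(
            SimGene(
                gene_id=event.gene_id,
                chrom=chrom,
                exons=[[start, end]],
                omega=event.omega,
            )
        )
    else:
        raise ValueError(f"unknown mechanism {event.mechanism}")
    return GroundTruthEvent(
        gene_id=event.gene_id,
        true_branch=event.branch,
        true_mechanism=event.mechanism,
        parent_gene_id=event.parent_gene_id,
        true_omega=event.omega,
    )


# ------------------------------------------------------------ full ladder


@dataclass
class SimulationResult:
    config: SimulationConfig
    ladder: SpeciesLadder
    genomes: dict[str, dict[str, str]]
    gene_models: dict[str, list[GeneModel]]
    focal_repeats: RepeatTrack
    truth: list[GroundTruthEvent]
    fpkm: "ngio.ExpressionMatrix"
    counts: "ngio.ExpressionMatrix"
    asymmetric_genes: list[str]


def _to_gene_models(state: GenomeState) -> list[GeneModel]:
    out = []
    for g in sorted(state.genes, key=lambda g: g.gene_id):
        ivs = [Interval(s, e) for s, e in g.exons]
        out.append(
            GeneModel(
                gene_id=g.gene_id,
                chromosome=g.chrom,
                strand="+",
                transcripts=[Transcript(f"{g.gene_id}.t1", ivs, list(ivs))],
                placed=not g.chrom.startswith("scaffold"),
            )
        )
    return out


def _plan_events(
    config: SimulationConfig,
    state: GenomeState,
    rng: np.random.Generator,
) -> dict[int, list[PlannedEvent]]:
    """Choose parents/reserved segments for every configured event."""
    anc = [
        g
        for g in state.genes
        if g.gene_id.startswith("anc") and not g.chrom.startswith("scaffold")
    ]
    # distinct parents per event: a shared parent would make sibling copies
    # each other's best paralog and blur the retro/DNA evidence
    multi = [g for g in anc if len(g.exons) >= 2]
    multi_pool = [multi[i] for i in rng.permutation(len(multi))]
    any_pool = [anc[i] for i in rng.permutation(len(anc))]
    res_ids = sorted(state.reserved)
    res_iter = iter(res_ids)
    plans: dict[int, list[PlannedEvent]] = {}
    omega = {
        "dna_duplication": config.omega_dna_duplication,
        "retroposition": config.omega_retroposition,
        "de_novo": config.omega_de_novo,
    }
    for branch in sorted(config.events_per_branch):
        plans[branch] = []
        counts = config.events_per_branch[branch]
        for mech in ("dna_duplication", "retroposition", "de_novo"):
            for i in range(counts.get(mech, 0)):
                if mech == "de_novo":
                    parent = None
                    rid = next(res_iter)
                elif mech == "retroposition":
                    parent = multi_pool.pop().gene_id
                    any_pool = [g for g in any_pool if g.gene_id != parent]
                    rid = None
                else:
                    parent = any_pool.pop().gene_id
                    multi_pool = [g for g in multi_pool if g.gene_id != parent]
                    rid = None
                tag = {"dna_duplication": "dup", "retroposition": "retro",
                       "de_novo": "denovo"}[mech]
                plans[branch].append(
                    PlannedEvent(
                        gene_id=f"{tag}_b{branch}_{i:02d}",
                        branch=branch,
                        mechanism=mech,
                        parent_gene_id=parent,
                        omega=omega[mech],
                        reserved_id=rid,
                    )
                )
    return plans


def simulate_ladder(config: SimulationConfig) -> SimulationResult:
    """Run the full forward simulation along the default dated ladder."""
    rng = np.random.default_rng(config.seed)
    ladder = default_ladder()
    state = simulate_ancestral_genome(config, rng)
    plans = _plan_events(config, state, rng)
    truth: list[GroundTruthEvent] = []
    tip_states: dict[str, GenomeState] = {}

    ages = [a for _, a in ladder.splits] + [0.0]
    # events on branch 0 (pre-root) would be planted before any split
    for ev in plans.get(0, []):
        truth.append(plant_event(state, ev, config, rng))
    for b in range(1, ladder.terminal_branch + 1):
        # split b happens at age ages[b-1]: the off-path clade branches off
        clade, age = ladder.splits[b - 1]
        for taxon in sorted(clade):
            tip = state.copy()
            evolve_branch(tip, age, config, rng)
            tip_states[taxon] = tip
        for ev in plans.get(b, []):
            truth.append(plant_event(state, ev, config, rng))
        evolve_branch(state, ages[b - 1] - ages[b], config, rng)
    tip_states[ladder.focal] = state

    genomes = {sp: st.decode() for sp, st in tip_states.items()}
    gene_models = {sp: _to_gene_models(st) for sp, st in tip_states.items()}
    focal_repeats = RepeatTrack.from_raw(
        {
            c: [(s, e) for s, e in ivs]
            for c, ivs in state.repeats.items()
        }
    )
    fpkm, counts, asym = simulate_expression(
        gene_models[ladder.focal], truth, config,
        np.random.default_rng(config.seed + 1),
    )
    return SimulationResult(
        config=config,
        ladder=ladder,
        genomes=genomes,
        gene_models=gene_models,
        focal_repeats=focal_repeats,
        truth=truth,
        fpkm=fpkm,
        counts=counts,
        asymmetric_genes=asym,
    )


# ------------------------------------------------------------ expression


def simulate_expression(
    genes: list[GeneModel],
    truth: list[GroundTruthEvent],
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """FPKM and count matrices with planted silent and asymmetric genes.

    A configured fraction of each gene class is silent (all-zero rows);
    counts are negative-binomial around a per-gene mean; asymmetric genes
    get a right/left fold change at one stage/tissue.
    """
    mech = {t.gene_id: t.true_mechanism for t in truth}
    gene_ids = [g.gene_id for g in genes]
    silent_p = {}
    for gid in gene_ids:
        m = mech.get(gid)
        if m is None:
            silent_p[gid] = config.silent_fraction_old
        elif m == "de_novo":
            silent_p[gid] = config.silent_fraction_de_novo
        else:
            silent_p[gid] = config.silent_fraction_duplicate
    silent = {gid: rng.random() < silent_p[gid] for gid in gene_ids}
    base = {
        gid: float(rng.lognormal(config.fpkm_meanlog, config.fpkm_sdlog))
        for gid in gene_ids
    }
    # asymmetric genes: planted duplicates, forced expressed
    dup_ids = [t.gene_id for t in truth if t.true_mechanism != "de_novo"]
    asym = dup_ids[: config.n_asymmetric]
    for gid in asym:
        silent[gid] = False

    fpkm_cols = [
        f"{t}|||{r + 1}"
        for t in config.fpkm_tissues
        for r in range(config.fpkm_replicates)
    ]
    fpkm = np.zeros((len(gene_ids), len(fpkm_cols)))
    all_tissues = tuple(dict.fromkeys(config.fpkm_tissues + config.count_tissues))
    tissue_effect = {
        (gid, t): float(rng.lognormal(0.0, 0.5))
        for gid in gene_ids
        for t in all_tissues
    }
    for i, gid in enumerate(gene_ids):
        if silent[gid]:
            continue
        j = 0
        for t in config.fpkm_tissues:
            mu = base[gid] * tissue_effect[(gid, t)]
            for _r in range(config.fpkm_replicates):
                fpkm[i, j] = mu * rng.lognormal(0.0, 0.3)
                j += 1
    fpkm_df = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"),
                           columns=fpkm_cols).round(3)

    count_cols = [
        f"{t}|{side}|{st}|{r + 1}"
        for st in config.count_stages
        for t in config.count_tissues
        for side in ("L", "R")
        for r in range(config.count_replicates)
    ]
    alpha = config.nb_dispersion
    counts = np.zeros((len(gene_ids), len(count_cols)), dtype=np.int64)
    for i, gid in enumerate(gene_ids):
        if silent[gid]:
            continue
        for j, col in enumerate(count_cols):
            t, side, st, _r = col.split("|")
            mu = base[gid] * config.count_scale * tissue_effect[(gid, t)]
            if (
                gid in asym
                and st == config.asym_stage
                and t == config.asym_tissue
                and side == "R"
            ):
                mu *= config.asym_fold_change
            counts[i, j] = nb_draw(rng, mu, alpha)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=count_cols
    )
    return (
        ngio.ExpressionMatrix(fpkm_df),
        ngio.ExpressionMatrix(counts_df, counts=True),
        asym,
    )


def nb_draw(rng: np.random.Generator, mu, alpha: float):
    """Negative-binomial draw(s) with mean mu and variance mu + alpha*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


# ------------------------------------------------------------ output


def write_outputs(result: SimulationResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, genome in result.genomes.items():
        ngio.write_genome(genome, out / f"{sp}.fa")
        ngio.write_gene_models(result.gene_models[sp], out / f"{sp}.gff3")
    ngio.write_repeats(result.focal_repeats, out / "focal.repeats.bed")
    ngio.write_ladder(result.ladder, out / "ladder.nwk")
    result.fpkm.write(out / "fpkm.tsv")
    result.counts.write(out / "counts.tsv")
    ngio.write_truth(result.truth, out / "truth.tsv")
    with open(out / "asymmetric.tsv", "w") as fh:
        fh.write("gene_id\n")
        for gid in result.asymmetric_genes:
            fh.write(gid + "\n")
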