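"""End-to-end pipeline orchestration and the summary report.

``run_all`` drives every stage on a simulated (or on-disk) dataset:
genome alignment + reciprocal-best netting, age dating, mechanism
classification, Ka/Ks selection tests, expression and asymmetry
analysis, and finally ``build_report``, which assembles the headline
statistics (per-branch counts, emergence rates, mechanism proportions,
selection and expression summaries) with conservation identities
checked as it goes. TSVs are the stable interface; the JSON report is
their machine twin.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as ngio
from .age_dating import (
    LINEAGE_BRANCH,
    branch_summary,
    date_genes,
    emergence_rate,
    proportion,
)
from .codons import spliced_cds
from .expression import (
    age_group_stats,
    asymmetry_scan,
    call_expression,
    de_novo_tissue_counts,
)
from .genome_align import AlignParams, PRESETS, align_genomes, reciprocal_best_net
from .mechanism import classify_genes, partition_summary
from .model import AgeCall, GeneModel, MechanismCall, SelectionResult, SpeciesLadder
from .selection import (
    apply_verdicts,
    de_novo_ortholog_orf,
    ks_filter,
    paralog_test,
)
from .simulate import SimulationConfig, simulate_ladder, write_outputs

log = logging.getLogger("newgene")


@dataclass
class PipelineOptions:
    presence_threshold: float = 0.5
    repeat_threshold: float = 0.70
    lineage_branch: int = LINEAGE_BRANCH
    alpha: float = 0.05
    near_age: float = 50.0  # preset switch points (Myr)
    far_age: float = 72.0


def preset_for_age(age: float, opts: PipelineOptions) -> AlignParams:
    if age <= opts.near_age:
        return PRESETS["near"]
    if age <= opts.far_age:
        return PRESETS["mid"]
    return PRESETS["far"]


def align_all(
    genomes: dict[str, dict[str, str]],
    ladder: SpeciesLadder,
    focal_repeats,
    opts: PipelineOptions,
) -> dict[str, list]:
    """Reciprocal-best chains of every query species against the focal
    genome, with divergence-dependent presets."""
    focal = genomes[ladder.focal]
    ages = {}
    for b in range(1, ladder.terminal_branch + 1):
        for sp in ladder.clade_of_split(b):
            ages[sp] = ladder.age_of_split(b)
    out = {}
    for sp in sorted(ages):
        params = preset_for_age(ages[sp], opts)
        t0 = time.perf_counter()
        f2q = align_genomes(focal, genomes[sp], params, focal_repeats=focal_repeats)
        q2f = align_genomes(genomes[sp], focal, params)
        out[sp] = reciprocal_best_net(f2q, q2f)
        log.info(
            "aligned %s (%d chains, %.1fs)", sp, len(out[sp]),
            time.perf_counter() - t0,
        )
    return out


def run_selection(
    genes: list[GeneModel],
    mech_calls: list[MechanismCall],
    focal_genome: dict[str, str],
    sister_genome: Optional[dict[str, str]],
    sister_chains: Optional[list],
    alpha: float = 0.05,
) -> list[SelectionResult]:
    """Paralog constraint tests (omega0 = 0.5) for duplicates and sister
    -ortholog neutrality tests (omega0 = 1) for de novo genes."""
    by_id = {g.gene_id: g for g in genes}

    def cds_of(gid: str) -> str:
        g = by_id[gid]
        t = g.longest_transcript()
        return spliced_cds(focal_genome, g.chromosome, g.strand, t.cds)

    results: list[SelectionResult] = []
    dup_results: list[SelectionResult] = []
    for mc in mech_calls:
        if mc.mechanism in ("dna_duplication", "retroposition"):
            r = paralog_test(
                mc.gene_id, cds_of(mc.gene_id),
                mc.parent_gene_id, cds_of(mc.parent_gene_id),
                null_omega=0.5,
            )
            dup_results.append(r)
        elif mc.mechanism == "de_novo" and sister_genome is not None:
            loc = _sister_locus(by_id[mc.gene_id], sister_chains)
            if loc is None:
                continue
            from .codons import translate

            prot = translate(cds_of(mc.gene_id))
            orf = de_novo_ortholog_orf(
                prot, sister_genome, loc[0], loc[1], loc[2]
            )
            if orf is None:
                continue
            r = paralog_test(
                mc.gene_id, cds_of(mc.gene_id),
                f"sister:{orf['chrom']}:{orf['start']}", orf["cds"],
                null_omega=1.0,
            )
            results.append(r)
    ks_filter(dup_results)
    results.extend(dup_results)
    return apply_verdicts(results, alpha=alpha)


def _sister_locus(gene: GeneModel, chains) -> Optional[tuple[str, int, int]]:
    """Sister-genome interval homologous to the gene's exons (via
    reciprocal-best blocks)."""
    if not chains:
        return None
    hits = []
    for c in chains:
        if not c.reciprocal_best or c.f_chrom != gene.chromosome:
            continue
        for b in c.blocks:
            for e in gene.exons:
                if min(b.f_end, e.end) - max(b.f_start, e.start) > 0:
                    hits.append((c.q_seq, b.q_start, b.q_end))
    if not hits:
        return None
    seqs = {h[0] for h in hits}
    best_seq = max(seqs, key=lambda s: sum(h[2] - h[1] for h in hits if h[0] == s))
    sel = [h for h in hits if h[0] == best_seq]
    return best_seq, min(h[1] for h in sel), max(h[2] for h in sel)


def build_report(
    ages: list[AgeCall],
    mechanisms: list[MechanismCall],
    selection: list[SelectionResult],
    expression_calls,
    deg: pd.DataFrame,
    ladder: SpeciesLadder,
    lineage_branch: int = LINEAGE_BRANCH,
) -> dict:
    """Assemble the summary report; every ratio is recomputable from the
    printed numerator/denominator and conservation identities hold."""
    mech_ids = {m.gene_id for m in mechanisms}
    age_ids = {a.gene_id for a in ages}
    orphans = sorted(mech_ids - age_ids)
    if orphans:
        raise ValueError(f"mechanism calls without age calls: {orphans[:5]}")

    kept = [a for a in ages if not a.excluded]
    branch_counts = {
        b: sum(1 for a in kept if a.branch == b)
        for b in range(ladder.n_branches)
    }
    assert sum(branch_counts.values()) == len(kept)
    lineage = [a for a in kept if a.branch >= lineage_branch]
    B = ladder.terminal_branch
    n_terminal = branch_counts[B]

    mech_counts = {
        m: sum(1 for c in mechanisms if c.mechanism == m)
        for m in ("dna_duplication", "retroposition", "de_novo", "unclassified")
    }
    n_classified = sum(
        v for k, v in mech_counts.items() if k != "unclassified"
    )
    mech_pct = {
        m: (proportion(mech_counts[m], n_classified) if n_classified else 0.0)
        for m in ("dna_duplication", "retroposition", "de_novo")
    }

    tested = [r for r in selection if r.filtered == "none"]
    negative = [r for r in tested if r.verdict == "negative_selection"]

    expr_by_id = {c.gene_id: c for c in expression_calls}
    dup_ids = [
        c.gene_id for c in mechanisms
        if c.mechanism in ("dna_duplication", "retroposition")
    ]
    dn_ids = [c.gene_id for c in mechanisms if c.mechanism == "de_novo"]
    dup_expr = [g for g in dup_ids if g in expr_by_id and expr_by_id[g].expressed]
    dn_calls = [expr_by_id[g] for g in dn_ids if g in expr_by_id]
    dn_expr = [c for c in dn_calls if c.expressed]

    deg_summary = []
    if deg is not None and not deg.empty:
        for (st, ti), sub in deg.groupby(["stage", "tissue"]):
            deg_summary.append(
                {"stage": st, "tissue": ti,
                 "n_significant": int(sub["significant"].sum())}
            )
        deg_summary.sort(key=lambda d: (-d["n_significant"], d["stage"], d["tissue"]))

    report = {
        "schema_version": 1,
        "branch_counts": branch_counts,
        "n_dated": len(ages),
        "n_excluded": len(ages) - len(kept),
        "lineage_specific_total": len(lineage),
        "emergence": {
            "terminal_branch": B,
            "terminal_n": n_terminal,
            "terminal_duration_myr": ladder.branch_duration(B),
            "terminal_rate_per_myr": emergence_rate(
                n_terminal, ladder.branch_duration(B)
            ),
            "lineage_n": len(lineage),
            "lineage_duration_myr": ladder.age_of_split(lineage_branch),
            "lineage_rate_per_myr": emergence_rate(
                len(lineage), ladder.age_of_split(lineage_branch)
            ),
        },
        "mechanisms": {
            "counts": mech_counts,
            "n_classified": n_classified,
            "percent": mech_pct,
        },
        "selection": {
            "n_tested": len(tested),
            "n_filtered": len(selection) - len(tested),
            "n_negative_selection": len(negative),
            "negative_percent": (
                proportion(len(negative), len(tested)) if tested else 0.0
            ),
        },
        "expression": {
            "duplicates_expressed": len(dup_expr),
            "duplicates_total": len(dup_ids),
            "duplicates_expressed_percent": (
                proportion(len(dup_expr), len(dup_ids)) if dup_ids else 0.0
            ),
            "de_novo_expressed": len(dn_expr),
            "de_novo_total": len(dn_ids),
            "de_novo_expressed_percent": (
                proportion(len(dn_expr), len(dn_ids)) if dn_ids else 0.0
            ),
            "de_novo_tissues": de_novo_tissue_counts(dn_calls),
        },
        "asymmetry": {"per_stage_tissue": deg_summary},
    }
    return report


@dataclass
class PipelineResult:
    config: SimulationConfig
    ladder: SpeciesLadder
    ages: list[AgeCall]
    mechanisms: list[MechanismCall]
    selection: list[SelectionResult]
    deg: pd.DataFrame
    report: dict


def run_all(
    config: SimulationConfig,
    outdir,
    opts: PipelineOptions = PipelineOptions(),
) -> PipelineResult:
    """Simulate a dataset and run every analysis stage over it.

    Deterministic given ``config.seed``; intermediate files are kept in
    ``outdir`` (chains, ages, mechanisms, selection, expression, report).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    sim = simulate_ladder(config)
    write_outputs(sim, out / "data")
    log.info("simulated dataset (%.1fs)", time.perf_counter() - t0)

    ladder = sim.ladder
    chains = align_all(sim.genomes, ladder, sim.focal_repeats, opts)
    for sp, ch in chains.items():
        ngio.write_chains(ch, out / f"chains.{sp}.tsv")

    genes = sim.gene_models[ladder.focal]
    profiles, ages = date_genes(
        genes, chains, ladder, sim.focal_repeats, opts.presence_threshold
    )
    presence_cols = {
        p.gene_id: {f"present_{sp}": v for sp, v in p.present.items()}
        for p in profiles
    }
    ages_df = pd.DataFrame(
        [
            {"gene_id": a.gene_id, "branch": a.branch, "excluded": a.excluded,
             "reason": a.exclusion_reason, **presence_cols[a.gene_id]}
            for a in ages
        ]
    )
    ages_df.to_csv(out / "ages.tsv", sep="\t", index=False)
    branch_summary(ages, ladder).to_csv(out / "summary.tsv", sep="\t", index=False)

    mech = classify_genes(
        genes, ages, sim.genomes[ladder.focal], chains,
        {sp: sim.gene_models[sp] for sp in sim.gene_models if sp != ladder.focal},
        ladder, lineage_branch=opts.lineage_branch,
    )
    pd.DataFrame(
        [
            {"gene_id": m.gene_id, "mechanism": m.mechanism,
             "parent": m.parent_gene_id or "", **m.evidence}
            for m in mech
        ]
    ).to_csv(out / "mechanisms.tsv", sep="\t", index=False)
    partition_summary(mech).to_csv(out / "mechanism_summary.tsv", sep="\t",
                                   index=False)

    sister = sorted(ladder.clade_of_split(ladder.terminal_branch))[0]
    sel = run_selection(
        genes, mech, sim.genomes[ladder.focal],
        sim.genomes.get(sister), chains.get(sister), alpha=opts.alpha,
    )
    pd.DataFrame([asdict(r) for r in sel]).to_csv(
        out / "selection.tsv", sep="\t", index=False
    )

    expr = call_expression(sim.fpkm)
    pd.DataFrame(
        [
            {"gene_id": c.gene_id, "expressed": c.expressed,
             "breadth": c.breadth}
            for c in expr
        ]
    ).to_csv(out / "expression.tsv", sep="\t", index=False)
    deg = asymmetry_scan(sim.counts, alpha=opts.alpha)
    deg.to_csv(out / "deg.tsv", sep="\t", index=False)

    report = build_report(
        ages, mech, sel, expr, deg, ladder, lineage_branch=opts.lineage_branch
    )
    report["provenance"] = {
        "seed": config.seed,
        "n_genes": len(genes),
        "n_truth_events": len(sim.truth),
        "stages": {
            "ages": len(ages), "mechanisms": len(mech),
            "selection": len(sel), "expression": len(expr),
            "deg_rows": 0 if deg is None or deg.empty else int(len(deg)),
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("pipeline complete (%.1fs total)", time.perf_counter() - t0)
    return PipelineResult(
        config=config, ladder=ladder, ages=ages, mechanisms=mech,
        selection=sel, deg=deg, report=report,
    )
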