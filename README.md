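# newgene

Identification and analysis of lineage-specific new genes from whole-genome
comparisons, modelled on the synteny-based pipeline (SBP) used to study gene
origination in flatfishes: every gene of a focal genome is dated onto a branch
of a dated ladder phylogeny from reciprocal-best genome alignments, each
young gene is classified by origin mechanism (DNA-mediated duplicate,
retrogene, de novo gene), selection is tested with fixed-ω Ka/Ks
likelihood-ratio tests, and expression evidence plus left/right asymmetric
expression are called from RNA-seq matrices.

Real genome assemblies at this scale are not shippable, so the package
includes a first-class forward genome simulator that evolves an 8-taxon
ladder of genomes from a common ancestor and *plants* gene-birth events of
known branch and mechanism. Every stage of the pipeline is therefore
verifiable against ground truth, end to end, on a laptop.

## Who this is for

Comparative genomicists who want a transparent, fully testable desk-scale
implementation of SBP-style gene dating and new-gene analysis — either to
study the method's behaviour (error modes, parameter sensitivity) or as a
reference implementation whose every statistic is reproducible from code.

## The methods in brief

- **Age dating.** A gene's exons are scored present/absent in each query
  species by coverage (≥ 0.5 by default) under reciprocal-best alignment
  chains. Dollo parsimony (single gain on the focal path, losses free)
  places each exon's origin on the branch above the MRCA of the species
  carrying it; the gene takes its oldest exon's branch. Branch indices run
  0 (shared by all sampled species) to B (focal-specific). Genes with > 70%
  exonic repeat overlap or on unplaced scaffolds are excluded.
- **Genome alignment.** Seed-and-extend: exact k-mer seeds (repeat-soft-
  masked, occurrence-capped) merged along diagonals, x-drop extended,
  chained colinearly with affine gap costs, then netted so that each focal
  base is covered by at most one reciprocal-best chain. Reciprocity is the
  same-locus check that separates paralogous copies from orthologous loci.
- **Mechanism.** Best focal paralog by Smith–Waterman (BLOSUM62, gaps 11/1,
  score floor 50, ≥ 30% coverage of the shorter protein). Multi-exon parent
  with single-CDS-exon copy → retrogene; any other paralog → DNA duplicate;
  no paralog but non-coding reciprocal-best homology in a pre-origination
  species → de novo; otherwise unclassified.
- **Selection.** Protein-guided codon alignment; maximum likelihood under a
  GY94-style codon model (uniform codon frequencies, κ, ω); LRT of free ω
  against ω₀ = 0.5 (paralog constraint test) or ω₀ = 1 (de novo neutrality
  test against the sister-species ORF reconstructed from ± 10 kb flanks),
  p from χ²(1). Pairs with Ka > 0.5, Ks > 5 or Ks outside 1.5 × IQR are
  filtered. Nei–Gojobori (1986) counting is kept as an independent check.
- **Expression.** Expressed ⇔ FPKM > 0.5 in ≥ 1 tissue (replicates averaged
  first); breadth = number of clearing tissues; old-vs-young contrasts by
  rank-sum test. Left/right asymmetry by a negative-binomial Wald test with
  median-of-ratios size factors and pooled method-of-moments dispersion.

## Worked example

Simulate the default world (two 1-Mb chromosomes, 200 ancestral genes, 40
planted birth events on branches 2–5) and run every stage:

```sh
newgene run-all --seed 1 --out run/
```

This writes per-species FASTA/GFF3, chain files, `ages.tsv`,
`mechanisms.tsv`, `selection.tsv`, `expression.tsv`, `deg.tsv` and
`report.json` under `run/`, and prints the emergence summary:

```json
{
  "terminal_branch": 5,
  "terminal_n": 10,
  "terminal_duration_myr": 41.8,
  "terminal_rate_per_myr": 0.2,
  "lineage_n": 40,
  "lineage_duration_myr": 73.7,
  "lineage_rate_per_myr": 0.5
}
```

Reading: 40 genes were dated to the young branches (2–5) of the ladder —
exactly the 40 planted events; 10 of them are focal-species-specific
(branch 5), giving an emergence rate of 10/41.8 ≈ 0.2 genes per Myr on the
terminal branch and 40/73.7 ≈ 0.5 per Myr averaged over the whole young
lineage. The mechanism table in `report.json` for this seed reads 21 DNA
duplicates, 13 retrogenes and 6 de novo genes against a planted truth of
20/12/8: recovery is 38/40 — the two misses are de novo genes whose random
proteins drew spurious paralog hits exactly at the score floor, the same
failure mode a BLAST-based pipeline has.

The same stages are available individually (`newgene simulate`, `align`,
`age`, `expression`, `asymmetry`); see `--help` on each.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline numbers from scratch: it simulates the
default dataset with the given seed, runs alignment, dating, mechanism
classification, selection and expression analysis, and writes the
acceptance JSON to `--out` (the run's full `report.json` is left beside it
in `results/pipeline_run/`). Runtime is about 2–4 minutes on one CPU.
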