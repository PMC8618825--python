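# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and states plainly what the synthetic world does and
does not establish.

## The dated ladder and branch indices

The focal lineage is modelled as a ladder: along the path from the focal
tip to the root, B clades split off at strictly decreasing ages. B splits
define B+1 age categories ("branches") indexed 0..B: a gene on branch 0
predates the oldest sampled split (it is present in every sampled
species); a gene on branch B arose after the focal–sister split and is
focal-specific. The default configuration mirrors the flatfish study
design: an 8-taxon ladder with the focal–sister split at 41.8 Myr and the
split from the nearest sampled outgroup clade at 73.7 Myr; the remaining
focal-path node ages (55, 65, 80 Myr) are not printed in the source study
and were chosen once as realistic interpolations. "Lineage-specific" genes
are those on branches ≥ 2, i.e. absent from all non-ladder outgroup
clades; emergence rates divide branch counts by branch durations in Myr
(the lineage-average rate divides the lineage-specific total by the age of
the split that opens branch 2).

Dating is pure Dollo parsimony: one gain on the focal path, losses free,
absence treated as never-present. No probabilistic gain/loss model is
fitted; the known consequence is that a gene lost in all outgroups is
dated too young. The exhaustive-parsimony oracle test covers every one of
the 2^8 presence patterns.

## Genome alignment

The aligner is a reproducible stand-in for a production genome aligner,
not a general-purpose tool. Exact k-mer seeds (default k = 12; k-mers with
N, k-mers starting in soft-masked repeats, and k-mers above an occurrence
ceiling of 20 are excluded) are merged along diagonals into gap-free
segments (merge gap 100 bp; segments need ≥ 2 seeds, which suppresses the
~n²/4^k random-match noise), x-drop extended (x = 20, cap 64 bp per side,
always scored +1/−1 regardless of preset so that mild mismatch presets
cannot license random-walk extensions), and chained greedily in colinear
order with affine gap costs (open 4, extend 1 per bp of diagonal shift,
max gap 2 kb, band 400 bp). Chain scores are recomputable as block scores
minus gap penalties. Three presets (near/mid/far) vary k and the mismatch
penalty with query divergence, standing in for unpublished per-species
parameter sets.

Netting selects per-base best chains independently on each side (later
chains have overlapping blocks clipped, so each focal base is covered by
at most one reciprocal-best chain) and then flags a focal-side winner as
reciprocal-best only if the query-side winners overlapping its query
interval map back onto its focal interval with ≥ 50% mutual coverage on
both genomes. This block-level formulation is deliberate: chain-level
"mutual 50% overlap" fails whenever the two directions chain the same
homology into different extents, silently erasing whole regions (we
measured exactly that before switching). Ties are broken by
(score, focal coordinate, query coordinate), making netting deterministic
and idempotent.

Presence calls use a coverage threshold of 0.5 of an exon by
reciprocal-best blocks; the source study never states its cutoff, so the
value is configurable and logged. Coverage is computed over blocks, not
chain spans, so an insertion bridged by a chain gap does not count as
covered — this is what lets partially novel de novo exons fall below the
presence threshold in outgroups while remaining detectable homology.

## Origin mechanisms

Paralog search is local protein alignment (BLOSUM62, affine 11/1) over the
longest-transcript proteome, with a shared 4-mer prefilter standing in for
BLAST word seeding. A hit needs score ≥ 50 and ≥ 30% alignment coverage of
the shorter protein; ties break by gene id. The retrogene rule is strict —
parent with ≥ 2 CDS exons, copy with exactly 1 — so partial intron loss
scores as DNA duplication. De novo calls additionally require
reciprocal-best homology (≥ 10% of exonic bases) in at least one
pre-origination species with no annotated gene overlapping the mapped
interval; genes with neither paralog nor outgroup homology stay
unclassified rather than being forced into a class. An optional external
-homology table can veto de novo calls (the horizontal-transfer and Pfam
screens of the original analysis are out of scope here).

The dominant error mode, measured on the synthetic world, is a spurious
Smith–Waterman hit at the score floor turning a de novo gene into an
apparent duplicate (2 of 40 planted events at the default scale). The
floor of 50 raw score is low by BLAST e-value standards but is kept as the
stated design; raising it trades this error for missed genuine parents.

## Ka/Ks and the fixed-ω LRTs

Codon alignments are protein-guided: a global protein alignment is
back-threaded onto the CDSs; gap- and stop-containing columns are dropped
(complete deletion), and pairs with fewer than 30 clean codons are flagged
`too_short` rather than tested.

The ML estimator uses a GY94-style model: 61 sense codons with uniform
frequencies, transition/transversion ratio κ, nonsynonymous factor ω,
single-position changes only, rate matrix normalised to one expected
substitution per codon per unit t. Uniform frequencies make Q symmetric,
so P(t) comes from one eigendecomposition. Codon frequencies are uniform
rather than F3×4 because the original codeml settings are unstated; the
rate-matrix builder keeps a hook for other frequency choices. Optimisation
is deterministic: a fixed coarse grid over (t, κ, ω) followed by one
bounded L-BFGS-B refinement in log space (t ∈ [1e-6, 50], κ ∈ [0.05, 20],
ω ∈ [1e-4, 10]). Reported Ka and Ks convert (t, κ, ω) into per-site rates
using the ω = 1 matrix for the site normalisation, codeml-style.

The LRT compares free ω against ω fixed at 0.5 (paralog constraint, after
Betrán-style reasoning: both copies of a duplicate pair share
substitutions, so ω significantly below 0.5 indicates constraint) or at
1.0 (de novo neutrality against the sister-species ORF). p = χ²(1) tail of
2ΔlnL; a negative 2Δ within 1e-3 is clamped to zero, beyond that it raises
(optimiser failure, never silently absorbed). The verdict
`negative_selection` additionally requires ω̂ < ω₀ — the one-sided reading
of "significantly lower". Calibration was verified by simulation: at
ω = 0.5 truth the rejection rate at p < 0.05 is within the exact binomial
interval over hundreds of replicates (and a Gillespie path simulation,
independent of the matrix-exponential sampler, agrees).

Filters follow the stated rules in a stated order: Ka > 0.5 and Ks > 5
first, then the 1.5 × IQR Ks fence computed on the prefiltered set with
linear-interpolation quartiles. Whether the original analysis applied the
IQR fence before or after the prefilters is unstated; the order here is
explicit, and one published worked example that contradicts this order is
noted in the test suite rather than reproduced.

The de novo ortholog ORF search takes the reciprocal-best homologous
interval ± 10 kb in the sister genome, scans all six frames for
ATG-initiated ORFs of ≥ 30 codons, and returns the longest whose protein
aligns to the query above the score floor; scanning within a single frame
guarantees the returned alignment has no frameshifts or internal stops.

## Expression and asymmetry

Expression evidence uses the study's FPKM > 0.5 rule, strict inequality,
with replicates averaged per tissue before thresholding (the source is
silent on replicate handling; averaging is the stated choice). Breadth is
the number of clearing tissues. Age-group contrasts compare old (branches
0–1) to young (≥ 2) genes on log2 median FPKM (pseudocount 0.1) with a
two-sided Mann–Whitney test.

The left/right test is an explicitly simplified stand-in for the
established differential-expression package used in the original study:
median-of-ratios size factors; per-gene method-of-moments dispersion
(within-side residual variance beyond Poisson); a Wald z on the log2 fold
change of normalised side means with NB variance (1/μ + α)/n per side and
a 0.5 pseudocount. One deliberate departure from a fully per-gene
dispersion: at 3 replicates per side the per-gene estimate has 4 degrees
of freedom, and no reference distribution makes the resulting Wald
statistic calibrated (measured type-I error 0.079 with a normal reference,
0.021 with t₄, 0.068 with a Welch–Satterthwaite df). The per-gene
estimates are therefore pooled by their mean across the matrix and the
common dispersion is used for every gene — the classic common-dispersion
moderation — which brings the measured type-I error to 0.040–0.062 across
seeds at the generator's default dispersion with ~0.98 power for 4-fold
changes. Raw p < 0.05 defines significance, as in the source analysis; a
BH-adjusted column is emitted for transparency but not used for the flag.

## The simulator: what it emulates, what it does not

The generator's defaults are the stated world: an 8-taxon ladder with the
divergence times above; two 1-Mb chromosomes plus one unplaced scaffold;
200 ancestral multi-exon genes (2–6 exons of 30–100 codons, introns
100–800 bp); interspersed repeats at 5% density from 3 monomer families;
HKY-like substitutions at 0.001/site/Myr (κ = 2) with per-gene ω enforced
by proposal-rejection (nonsense proposals always rejected, so ORFs stay
intact — start and stop codons are protected); indels (2e-5/site/Myr,
geometric lengths, cap 50) confined to intergenic/intronic sequence with
exact coordinate remapping. Ten planted events per young branch (5 DNA
duplications, 3 retropositions, 2 de novo) with distinct parents per
event.

Two modelling choices deserve emphasis. First, planted de novo exons are
part novel insertion, part ancestral intergenic core (default ancestral
fraction 0.4). A fully ancestral de novo exon would be fully alignable in
every outgroup and thus dated branch 0 by any alignment-presence method —
the method could never recover the planted branch, and the classifier's
requirement of outgroup homology for de novo calls could never coexist
with correct dating. Partial novelty mirrors real de novo births, which
typically incorporate repeat-derived or otherwise novel sequence, and
makes the stated world internally consistent: outgroups retain detectable
(≥ 10%) but sub-threshold (< 50%) homology. Second, all simulated genes
sit on the + strand; strand handling in alignment is exercised by unit
tests, but the pipeline-level tests do not cover minus-strand gene
plumbing.

Other simplifications: outgroup cherry members evolve independently from
the split (no shared stem branch); no recombination, rearrangement or
gene loss; expression parameters (log-normal FPKM baseline meanlog 1.0,
sdlog 1.2; NB dispersion 0.05; silent fractions 0.05/0.26/0.65 for
old/duplicate/de novo genes; nine 4-fold left/right genes at one
stage/tissue) are synthetic, chosen to echo the published summary
fractions, not fitted to any real FPKM distribution. A green end-to-end
test therefore establishes that the pipeline recovers planted truth under
these conditions — not that it would perform equally on real assemblies
with annotation error, assembly gaps, segmental duplications or lineage
sorting.

## Known limitations

- Dollo dating inherits SBP's no-loss assumption; gene loss in outgroups
  inflates young-branch counts.
- The aligner is exact-seed based; homology below ~25% identity per k-mer
  window is invisible regardless of chaining.
- The paralog score floor admits occasional random hits (see above).
- Old-gene selection fractions are not computed: ancestral genes in the
  simulation have no paralogs by construction, so the corresponding report
  field is meaningful only on data with old duplicate pairs.
- The NB test models a single stage/tissue contrast at a time; no shared
  variance across contrasts, no fold-change shrinkage.
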