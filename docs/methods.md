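# Methods

This note documents the models behind `xistlink`: what each stage
computes, what the synthetic-data generator does and does not emulate,
the parameters that matter, and the numerical and design choices made
where the underlying science left the design open.

## 1. Silencing profile

The DE stage consumes a finished differential-expression table; no count
modelling, normalization or dispersion estimation happens here.

**Filtering.** Down: adj *p* < cutoff (strict) and log₂FC ≤ −cutoff
(inclusive); up: mirrored. Defaults 0.01 and 1.0, with 0.5 as the
supported relaxed fold-change cutoff. Both conditions are required
jointly.

**Clustering.** Down-regulated genes on one chromosome are chained by
single linkage: genes link when their anchor positions differ by
strictly less than the window (default 5 Mb), and clusters are connected
components with ≥ 2 members. Chaining is intentional — a cluster may span
more than one window through intermediates. The anchor is the gene
*start* coordinate (deterministic, matches common annotation practice);
a midpoint anchor is available. On sorted 1-D anchors single linkage
reduces to chaining consecutive gaps, which is what the implementation
does; the test suite checks it against brute-force transitive closure of
the pairwise graph.

**Ranking.** Chromosomes are ranked on three criteria — *n↓*, percentage
down, clustered *n↓* — by average rank (symmetric and scale-free; the
three criteria were originally applied qualitatively). Chromosomes with
fewer than `min_clustered = 4` clustered down genes are flagged excluded
but kept in the report. Ties break by higher percentage, then chromosome
id. The percentage denominator is the number of genes of that chromosome
*in the input table*, not an external annotation total, to avoid
annotation-version dependence; with full annotation tables the two
denominators coincide up to filtering.

**Coordinates.** 1-based inclusive internally (the convention of printed
coordinate spans, whose thousands separators the reader strips); the gap
between non-overlapping clusters is downstream start − upstream end, so
adjacent spans are 1 bp apart and the 72,824,480–74,124,449 /
135,301,535–136,178,014 cluster pair on Chr 1 is 61,177,086 bp apart.
BED export converts to 0-based half-open. Overlapping spans gap to 0
with a warning. Reported cluster widths are always the computed spans;
published rounded widths are not reconciled. Note the source figure
caption and text disagree on which segments belong to which cluster; we
follow the caption (B/E in the proximal cluster near 73 Mb, A/C in the
distal cluster near 136 Mb).

## 2. Co-localization

A spot co-localizes with a territory when its distance to the territory
centre is ≤ radius + margin. The margin (default 0 µm) absorbs
segmentation slack; visual per-section scoring has no exact geometric
equivalent, and sphere overlap is the simplest model supporting the
counting logic. Each territory is creditable by at most one Xic spot —
two transgene copies on two homolog territories should count as 2, not
let one territory absorb both — so the per-cell count is a maximum
bipartite matching (computed by assignment on the 0/1 eligibility
matrix; an exhaustive matching oracle verifies it in tests).

Summaries tabulate cells by count *k* ∈ {0..4} and report the percentage
with *k* ≥ 1 and *k* ≥ 2. Pairwise condition comparisons use Fisher's
exact test on the binary *k* ≥ threshold collapse (threshold 2 for TG
linkage — two transgene copies; 1 for WT transient-contact baselines).
An R×C test over the full pattern distribution would be an alternative
reading; the binary collapse matches the two-category percentages the
analysis is built on and is what we implement.

`call_linkage` declares a chromosome linked when (a) its TG *k* ≥ 2
frequency is not significantly below the Chr X positive control
(two-tailed) and (b) it significantly exceeds every other candidate
autosome (one-tailed, greater). Degenerate inputs (single-cell
reference; all conditions identical) produce explicit warnings rather
than silent calls.

## 3. 3D distance statistic

Distances are Euclidean, centre-to-centre, in µm. Per nucleus the two
shortest segment↔Xic distances are selected and averaged. Two selection
policies exist because the source procedure does not state whether the
two measurements may share a spot:

- `require_distinct=True` (default): greedy — take the globally closest
  pair, remove both spots, take the closest remaining pair. Two
  independent proximity events, one per transgene copy. Greedy is not
  always the minimum-weight 2-pair matching; tests quantify that
  discrepancies are rare (< 10% of random 4×4 matrices) and the greedy
  total is never smaller than the optimum.
- `require_distinct=False`: the two smallest matrix entries.

Cells without two eligible pairs under the chosen policy are excluded
and counted (returned as an exclusion tally, logged by the pipeline),
mirroring the eligibility rule that only nuclei with enough resolvable
signals are scored.

Normalization is per segment probe: each TG per-cell average minus the
median WT per-cell average *for that probe* (probes are hybridized
separately, so "across all WT cells" is read per probe). Normalized
values are shift-invariant and the WT set self-normalizes to median 0;
negative values are meaningful (TG closer than the WT baseline).
Segments are compared with Welch's unequal-variance *t*-test (the
conservative default when only "independent 2-group *t*-test" is
specified) and ranked by median normalized distance; exact median ties
order by segment id and carry a tie flag.

## 4. Synthetic-data generator

The generator is the acceptance surface: it emulates the *statistical
structure* of the study inputs with known ground truth.

**DE tables.** Per chromosome, `n_genes_per_chromosome` (default 100)
genes at sorted uniform positions. On the target chromosome,
`n_silenced_clusters` (2) windows of `cluster_width` (1.5 Mb), placed
≥ 10 Mb apart, each receive `genes_per_cluster` (4) planted genes with
log₂FC ~ Normal(−2.5, 0.8) — silenced two- to ten-fold, matching the
observed range from ~58% to >95% reduction — and adjusted *p* ~
Beta(0.5, 500) (concentrated near 0). Background genes: log₂FC ~
Normal(0, 0.3), *p* ~ Uniform(0, 1). FPKM pairs are generated as
lognormal WT baselines with FPKM_TG = FPKM_WT·2^log₂FC, so fold-changes
and reductions are exactly consistent. Adjusted *p*-values are drawn
directly rather than obtained by simulating counts and re-testing: the
DE test is upstream of this pipeline's scope. Truth labels mark planted
genes and their cluster index. A real DE table differs in ways the
generator does not model — correlated expression, annotation gaps,
chromosome-dependent gene density, secondary (trans) effects — so
passing recovery tests demonstrates the *inference machinery*, not
robustness to those effects.

**Nuclei.** Nucleus: sphere of radius 5 µm. Territories: spheres of
radius 1 µm (fixed), centres uniform in the inset sphere of radius
nucleus − territory so territories (and their spots) remain inside the
nucleus; overlaps are permitted — no real geometry is implied beyond
what the overlap logic needs. Karyotype: tetraploid male (4 copies per
autosome, 2 per sex chromosome), configurable. Endogenous Xic: one spot
uniform in each X territory. TG cells add two transgenic Xic spots: when
linked, inside two randomly chosen target-chromosome territories,
anchored within 0.3·radius of the centre; when unlinked, uniform in the
nucleus (null model). Segment spots appear in every target-chromosome
territory: uniform, except in transgene-carrying territories, where the
spot is placed at distance *d* from the transgene spot with
E[*d*] = *c·g*^(1/3) (prefactor *c* = 0.002 µm/bp^⅓, exponent ⅓ — a
globular-polymer default; both are config knobs), *d* drawn with a
Gamma(shape 4, mean 1) multiplicative factor and placed by rejection
sampling inside the territory. The expectation contract is exact up to
boundary truncation at large separations; monotonicity in *g* — the
property the analysis depends on — always holds and is tested by Monte
Carlo.

**Transient contacts.** Independently per territory not genetically
linked to an Xic spot, with probability `contact_probability` (0.02) the
territory relocates so a randomly chosen Xic spot sits just inside its
boundary. Together with chance volume overlap this yields WT ≥ 1
co-localization frequencies around 10–20% of cells, the observed
baseline range; chromosome-specific contact enrichment (one autosome was
observed at an elevated 27%) is deliberately *not* modelled — the
mechanism is unknown and the parameter is not calibrated to it.

**Measurement model.** Isotropic Gaussian localization noise (sd
0.05 µm) per spot, spots pushed outside the nucleus projected back to
its surface; same-probe spots closer than the resolvability threshold
(0.3 µm) merge to their centroid. The model omits chromatic aberration,
anisotropic axial (z) blur, probe hybridization failure, and
segmentation artifacts.

**Null calibration.** With contacts off and the transgene unlinked, the
frequency at which an Xic spot falls inside an unlinked territory equals
the volume-overlap expectation of the generative geometry; the test
computes that expectation with an independent direct-sampling oracle.

## 5. Recovery-test design and statistical power

The recovery suites (also run by `scripts/acceptance.py`) use these
problem sizes, chosen as the smallest that give stable rates:

- chromosome ranking: 100 seeded DE tables, default generator;
- linkage calling: 100 seeds × 100 TG cells/condition, paints 1/4/9
  with Chr X reference;
- segment ranking: 100 seeds × 50 cells/genotype, probes at genomic
  separations 0.25 / 30 / 45 / 62.5 Mb from the integration site.

The segment-probe layout deserves explanation. The median of *n* = 50 WT
per-cell averages has a seed-to-seed standard error of ≈ 0.17 µm (the WT
distances are inter-territory and broadly distributed), and the
normalization subtracts an independent such median per probe. Probes
250 kb apart — the spacing of the two same-cluster probes in the real
design — differ in expected intra-territory distance by < 0.1 µm under
*d* = 0.002·*g*^⅓, below that noise floor: same-cluster probes are
spatially unresolvable by this statistic at these cell counts, which is
consistent with the original observation that a probe > 60 Mb away can
show a median comparable to the nearest probe. The recovery suite
therefore spaces its probes across the 0.25–62 Mb separation range the
probe set spans, where the expected-distance differences (≥ 0.4 µm)
exceed the noise floor with margin (Δ*d*/√2·SE ≳ 2 for every
competitor). The default `segment_positions`, in contrast, keep the
realistic same-cluster layout.

## 6. Known limitations

- Territories are fixed-radius spheres with uniform centres; no volume
  exclusion, no radial preference, no size scaling with chromosome
  length — so chromosome-size effects on co-localization are absent by
  construction.
- The power-law distance model applies only within transgene-carrying
  territories; segment spots elsewhere are uniform, ignoring intra-
  territory chromatin organisation.
- Linkage calling assumes the candidate set includes at least one
  genuinely unlinked autosome to serve as contrast; with a single
  candidate and no controls the call degenerates (warned).
- The pipeline starts from tables. Alignment, quantification, DE
  testing, image acquisition and spot segmentation are out of scope.
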