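# Methods

## The analysis model

`crossheart` compares transcriptional injury responses between two species
whose experiments share a design but not a genome. The unit of comparison
is the one-to-one ortholog pair: both species' raw gene-level counts are
joined row-wise into a single pairs × samples matrix, so that one
normalization and one fold-change scale apply to both species at once.
Everything downstream operates on this combined matrix.

The design assumed throughout is *one pooled library per condition and
time point* (several hearts pooled per library), with an untouched 0 h
sample per species as baseline and sham-operated and cryoinjured samples
along the time course. With no replicates there is no within-group
variance to estimate, which dictates three choices:

- fold changes are simple per-sample ratios of normalized counts against
  the baseline, not model-based estimates;
- differential expression is defined by an effect-size threshold
  (|log2 FC| ≥ 2 in at least one contrast), not a test;
- module-level significance comes from Sample-Level Enrichment Analysis
  (SLEA), whose null is resampled *within each sample* and therefore needs
  no replication.

### Normalization

Size factors use the median-of-ratios estimator: for sample *j*,
`s_j = median over reference genes g of k_gj / geomean_j'(k_gj')`, where
reference genes are those with a strictly positive count in every sample.
The median of an even list is the mean of the two central values. Factors
are estimated once on the combined cross-species matrix (joint
normalization); a per-species mode exists for sensitivity analysis.

A property worth knowing: because the per-gene geometric mean includes
every sample, multiplying one of *m* samples' counts by *c* moves its
factor by `c^((m-1)/m)` and every other factor by `c^(-1/m)`. Factor
*ratios* are therefore exactly equivariant (×c), and the normalized matrix
changes only by the global constant `c^(1/m)` — size factors, like
sequencing depth itself, are defined up to a common scale. The tests
assert this exact law.

### Fold changes

`log2((x + p) / (x_0h + p))` with pseudocount `p = 1` on normalized
counts. The pseudocount keeps zero baselines finite in a no-replicate
design; it is configurable and recorded in the run manifest. Before
computing fold changes for SLEA-bound analyses, pairs must show at least
5 normalized counts in *every* sample entering any declared contrast
(baselines included) — an expression floor that removes ratio noise from
barely-detected genes.

### DEG selection, clustering, PCA

DEGs: |log2 FC| ≥ threshold (default 2, boundary inclusive; a strict mode
exists) in ≥ 1 contrast. Clustering of the DEG fold-change matrix uses
Euclidean distance and complete linkage — the defaults of the classic R
heatmap function this style of figure comes from — with no row scaling,
since fold changes are already on a common scale. Equal-distance merges
follow the lowest-index-first convention of scipy, making dendrograms
deterministic. The `discordant_clusters` helper cuts the tree at *k*
clusters and ranks them by |mean FC_A − mean FC_B| over matched times; it
is a quantitative stand-in for visually picking discordant gene blocks
and is deliberately simple.

PCA runs on log2(x+1)-transformed normalized counts of untouched and
cryoinjured samples, genes centered, samples as observations, via full
SVD. The log transform is the field-standard variance stabilization for
count PCA; a raw-counts mode is available and the choice is recorded in
output metadata.

### GO enrichment

Exact one-sided hypergeometric tails (`P(X ≥ k)` and `P(X ≤ k)`, no
normal approximation) per module, with the over- and under-representation
p-value families Benjamini–Hochberg adjusted *separately* — the
convention of ontology-tree enrichment tools that report each direction as
its own one-sided test; joint adjustment would double the family size.
The default background ("annotated") is the set of measured genes carrying
at least one module annotation; a whole-matrix background is a switch.
Modules with fewer than 5 members in the background are skipped (logged,
configurable). Optional OBO input propagates annotations from descendants
to ancestors (is_a/part_of edges only) before testing; cycles are
rejected.

### SLEA

Each contrast column of the fold-change matrix is linearly mapped to
[−10, +10] by min–max (`x → 20(x−min)/(max−min) − 10`) and then centered
by subtracting the column mean. Min–max was chosen over symmetric
max-|x| scaling because the explicit centering step would be redundant
under a zero-preserving map; the `maxabs` mode is exposed for sensitivity
analysis. A constant column cannot be scaled and maps to zeros with a
warning.

For each (module, column), the observed statistic is the mean of the
module members' values in that column. The null is the set of means of
10,000 random gene sets of identical size, drawn uniformly *without
replacement from the same column*; `Z = (obs − mean_null)/sd_null` with
the sample standard deviation (n−1). Null draws are cached per
(column, size) — all same-size modules share one null — and are a pure
function of the seed, so results are bit-reproducible. A degenerate null
(sd = 0) yields Z = 0 plus a flag, never ±∞. Significance is strict:
|Z| > 4. Z is stored raw; the heatmap clips at ±10 for display only.

Cross-species differential responders are ranked by
`max over matched times of |Z_A − Z_B|` for the cryoinjury contrasts
(default matched times 6, 48, 72 h), ties broken by module name. The
original identification of such modules was visual; this ranking rule is
the package's own, chosen for transparency.

## The synthetic generator

The generator emulates the pooled two-species design: species A sampled at
0 h, 6 h, 24 h, 48 h, 72 h, 120 h and species B at 0 h, 6 h, 48 h, 72 h,
144 h; untouched at 0 h only; sham and cryoinjured libraries at each
positive time; one library per slot (replicates optional). Defaults encode
the reference recovery experiment: 2000 orthologs, ten disjoint 50-gene
modules, five responsive to cryoinjury only in species A.

A responsive gene's log2 fold change follows a pulse: 0 at t = 0, linear
rise to the amplitude at the peak time, then exponential decay with a
48 h half-life. Only qualitative dynamics are known for the comparator
species (muted, delayed), encoded as defaults `amplitude_B = 0.4 ×
amplitude_A` and `peak_time_B = 2 × peak_time_A`; sham responses are the
cryoinjury pulse scaled by `sham_fraction_of_amplitude` (default 0.3).
Counts are negative binomial with mean
`baseline × size_factor × 2^fc(t)` and variance `μ + φμ²`.

Free parameters with no stated empirical values, fixed once at values
realistic for pooled bulk libraries: per-species lognormal baselines
(ln-mean 4.0 ≈ 55 counts, ln-sd 1.5), dispersion φ = 0.05 (pooling
averages out much biological variance), lognormal size factors (ln-sd
0.3). Species baselines are drawn independently, so the dominant
expression axis separates species — matching the PCA structure of real
cross-species data.

What the generator does *not* emulate: read-level artifacts, mapping bias
between genomes, paralog cross-hybridization, batch effects, compositional
(mRNA-amount) shifts, and genuinely correlated co-expression outside the
planted modules. Passing recovery tests therefore shows the pipeline's
statistics are correct and calibrated under the stated noise model, not
that real cross-species data are free of these confounders.

## Numerical and procedural choices

- **Thresholds** (all configurable, all logged in the manifest): ≥ 5 total
  raw reads per pair (boundary inclusive, summed over both species — the
  stricter joint reading; a per-species switch exists); ≥ 5 normalized
  counts per contrasted sample; DEG |log2 FC| ≥ 2 (inclusive; the strict
  variant is a switch); pathway-export |log2 FC| > 1 (strict);
  SLEA |Z| > 4 (strict); FDR 0.05; n_rand = 10,000.
- **One-to-many orthologs**: every participant of a non-unique relation is
  dropped; choosing a representative would require an expression-based
  tie-break with no principled basis.
- **Ortholog-map header detection**: a first row is treated as a header
  only when its tokens are unique, reappear nowhere among the ids, and
  look like labels rather than identifiers (no digits while the ids carry
  digits); a short headerless file of unique ids is never truncated.
- **Seeds**: one top-level seed; per-stage seeds are derived through
  `numpy.random.SeedSequence`, so stages rerun in isolation reproduce the
  full run exactly. All outputs are byte-stable under a fixed config.
- **Filtering order**: the min-read filter applies after joining (the
  ortholog set is an input, so pre-join filtering is not reconstructible);
  the normalized-count floor applies when building the fold-change matrix,
  not to the combined counts, since it is scoped to module analyses.
- **Problem sizes**: the bundled reference run uses 2000 orthologs and
  10 modules; the null-calibration experiment a 2000 × 6 matrix with 500
  random size-50 modules at n_rand = 10,000 — large enough for stable
  module statistics while keeping a full run under a minute on one core.

## Known limitations

- No replicate-based inference anywhere: effect-size thresholds and
  resampling nulls stand in for tests, as the design dictates.
- SLEA nulls treat genes as exchangeable within a column; correlated
  modules (co-regulated neighborhoods) make the null slightly liberal.
- The combined-matrix normalization assumes the two species' libraries are
  comparable after a single scale factor; strong compositional differences
  between species would violate this.
- Proprietary pathway/upstream-regulator scoring is out of scope; the
  pipeline only exports the ranked signed-FC gene list such tools consume.
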