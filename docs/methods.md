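# Methods

`domnet` implements a weighted molecular correlation network analysis
for dissolved organic matter (DOM) measured by direct-infusion,
negative-mode HR-MS during plant-litter decomposition, together with
the surrounding processing: peak filtering, molecular formula
assignment, pathway-coverage statistics and convergence/divergence
trend summaries. Because the raw experimental data this kind of study
rests on are large instrument files, the package ships a synthetic
generator that emulates the study design end to end and gives every
downstream stage a known ground truth.

## The study design being emulated

Four litter types (beech, oak, pine, grass) from two sites are
decomposed in triplicate; leachates are collected on days 2, 4, 8, 15
and 22, giving 4 × 2 × 3 × 5 = 120 leachate samples. Day 0 stands for
the initial litter material; it is represented in the design but not in
the default feature matrix, so the default matrix is 200 features × 120
samples (`include_day0=True` adds the 24 day-0 columns when an analysis
wants the initial state as an anchor).

## Synthetic data model

Features are grouped into blocks, each with a latent driver:

* **litter** — indicator of one litter type × a linear time ramp
  (day / max day): litter-specific patterns that consolidate over time;
* **convergence** — the same, for a subset of litter types: molecular
  patterns shared by several litters that grow in concert;
* **time** — the ramp in every sample;
* **noise** — no shared signal (background).

Log intensity of feature *f* in sample *s* is
`a_f + b · z_s + sigma · eps_fs`, with `a_f ~ N(mu_block, 0.5)` a
feature baseline, `z_s` the block's latent profile and `eps` standard
normal. `b` is solved per block from the target within-block Pearson
correlation `r` (default 0.9) via `b = sigma·sqrt(r/(1−r))/sd(z)`, so
the noise-free limit gives exactly proportional features (r = 1).
Intensities are exponentiated and each sample column normalised to sum
to one (the paper-style relative-abundance convention; the intensity
normalisation of the original instrument pipeline is unknown, so this
is an explicit, configurable assumption).

Two numerical consequences of that closure shaped the defaults:

* **Background weight.** Closure (dividing by the column total) injects
  a common-mode signal into every feature. If the responsive blocks
  carry a large share of total intensity, even driver-free background
  features end up strongly correlated with one another through the
  shared denominator. The default therefore gives background features a
  50-fold higher baseline mean (`background_weight = 50`), mirroring
  real DOM spectra in which a broad unstructured hump carries most of
  the signal. With this default the background block's mean pairwise
  r is ≈ 0.04 while the planted blocks sit within ±0.15 of the 0.9
  target.
* **Disjoint block drivers.** The default planted structure is two
  litter-specific blocks (beech, pine) plus one convergence block
  shared by oak and grass, plus a background block (50 features each).
  Using disjoint litter subsets keeps between-block correlations at or
  below zero, which is the planted-structure regime the module-recovery
  guarantees refer to. Overlapping subsets are fully supported but
  yield genuinely correlated blocks that average-linkage clustering
  may merge — that is a property of the data, not a detection failure.

Peak lists are generated by inverting the matrix: peak m/z is the
formula's monoisotopic neutral mass minus the proton mass
(1.007276466 u; [M−H]⁻, singly charged), jittered uniformly within a
configurable ppm error (default 0.2 ppm in the pipeline, consistent
with a 240k-resolution instrument under internal calibration — at this
accuracy formula assignment at 2 ppm tolerance is essentially
error-free, while 0.5 ppm jitter already produces a noticeable
misassignment rate). A configurable fraction of peaks receives
S/N ≤ 4; those draws are weighted toward the weakest intensities
because signal-to-noise tracks intensity — uniform dropout would
censor strong background peaks and distort every distance-based
statistic downstream. Blank masses, when configured, are injected into
every sample and into the returned blank list.

Annotations: an exact fraction of formulas (default 20%) is annotated;
each annotated formula maps to `1 + Poisson(1.9)` isomeric compounds
(mean 2.9 structure suggestions per matched formula), each compound to
one pathway plus occasional extras; pathway sizes are inflated beyond
the seen members so coverages stay below one.

What the generator does **not** emulate: isotopologues and adducts,
mass-dependent resolution, intensity-dependent ppm error, censoring of
litter-specific features below detection in inactive samples,
compositional structure of real KEGG pathways, and any site effect
(sites are replicated but carry no planted signal, matching the
finding that sites mattered little). Passing tests therefore
demonstrate correctness of the algorithms under a controlled data
model, not performance on real spectra.

## Peak filtering and formula assignment

Peaks are kept when S/N is *strictly* greater than 4 (the threshold is
a filter parameter), m/z lies within the 175–1000 acquisition window,
and no blank peak lies within a ppm window (default 2 ppm — floating
m/z values never match exactly). Filtering is idempotent.

Formula assignment enumerates CHNOS compositions exhaustively within
configurable element ranges (defaults C 1–100, H 0–200, N 0–5, O 0–80,
S 0–2, typical of DOM Orbitrap practice). The search sorts the
(C, N, O, S) sub-grid by mass once and solves the hydrogen count per
query, which is exact: for tolerances far below the hydrogen mass only
the two nearest integer H counts can qualify, and both are checked
against the exact ppm criterion (relative to the candidate mass).
Candidates then pass chemical-plausibility filters (0.3 ≤ H/C ≤ 2.5,
O/C ≤ 1.2, even-electron rule: H+N even and DBE ≥ 0), each
individually switchable, and are sorted by |ppm error| with ties broken
by fewer heteroatoms (N+S) then lower H — a deterministic, documented
convention. The test suite verifies candidate sets against an
independent full-grid enumeration oracle.

## Network construction

* Similarity: Pearson correlation between all feature pairs across
  samples. Zero-variance features are excluded (undefined r) with a
  warning.
* Signed adjacency: `A_ij = (0.5 · (1 + cor_ij))^p`, power `p = 9` by
  default. `A(1) = 1`, `A(−1) = 0`, `A(0) = 0.5^9 = 0.001953125`;
  elementwise monotone in `cor`, and increasing `p` never increases an
  off-diagonal entry.
* Scale-free fit: connectivity `k_i = Σ_{j≠i} A_ij` is binned into
  equal-width bins; R² and slope of the `log10 p(k) ~ log10 <k>`
  regression are reported. Note that a small planted-block design is
  *not* scale-free — its connectivity distribution is bimodal — so on
  synthetic runs this statistic is a diagnostic, not a quality gate.
  Fewer than three non-empty bins (including the all-equal case) is
  reported as undefined.
* Modules: average-linkage (UPGMA) agglomerative clustering of node
  dissimilarities, `D = 1 − A` by default; `1 − TOM` (topological
  overlap) is available as the conventional WGCNA variant. The tree is
  cut at a constant height, default 0.995 of the maximum merge height;
  a fixed-cluster-count cut (`maxclust`) is provided as the simpler
  alternative for exploratory use. Clusters below the minimum module
  size (default 30) become grey (unassigned). Modules are named by
  descending size with the conventional WGCNA palette (turquoise, blue,
  brown, yellow, …) so module names are comparable across analyses.
* Module eigenvalues: per module, features are standardized across
  samples (zero mean, unit variance); the eigenvalue vector is the
  first right singular vector of the block scaled by √n_samples (so a
  rank-1 module returns its common standardized profile exactly), with
  the sign oriented to correlate positively with the module's mean
  standardized profile. Variance explained is s₁²/Σs². A
  single-feature module returns its standardized profile with a
  warning.

## Embedding

Classical (Torgerson) MDS: squared dissimilarities are double-centred,
the Gram matrix eigendecomposed, and the top-k positive-eigenvalue axes
scaled by √eigenvalue. `1 − A` matrices are generally non-Euclidean;
negative eigenvalues are truncated and the full spectrum plus the
positive-mass fraction captured by the retained axes are reported. Axis
signs are fixed deterministically (largest-|coordinate| entry positive,
first index on ties). Euclidean-realizable inputs are recovered exactly
up to a rigid transform (verified to Procrustes RMS < 1e-8).

## Pathway statistics

Matching is by exact canonical formula string — exact-mass data cannot
distinguish isomers, so one formula may witness several compounds.
Reported statistics: match rate (matched / assigned formulas) and mean
structure suggestions (mean distinct compound hits among matched
formulas).

Pathway intensity sums apply the deduplication rule: a formula
contributes its relative intensity at most once per pathway regardless
of how many isomeric members it matches there, and once to each
distinct pathway it matches. The sum is invariant to duplicated DB
records by construction.

Coverage is detected members / pathway size, clamped to [0, 1]. The
numerator counts distinct compounds by default (one formula may witness
several members); formula counting is available as a switch. Whether a
pathway "size" should count compounds, reactions or orthologs is
genuinely open; the packaged schema records one size per pathway and
treats it as a compound count. Cross-group dispersion uses the sample
standard deviation (ddof = 1) across groups, reported per pathway and
as the overall mean SD. In the pipeline, groups are litter × site ×
day combinations and a formula counts as detected in a group when its
group-mean relative intensity exceeds `1/n_features` (configurable
factor); with annotations that do not vary by group this dispersion is
small by construction.

The companion coverage table for a second dataset (e.g. 16S-based
functional predictions) is consumed as input, never computed — the
methods that produce such predictions are outside this package. The
joint comparison classifies pathways into quadrants (both-high,
dom-only, other-only, both-low) at a configurable coverage threshold
and flags, rather than drops, pathways present in only one table.

## Trends

PCA is computed on the covariance of the (sample × feature) matrix via
SVD of the centred data — the standard ordination of abundance tables —
with per-group centroid paths ordered by day. The between-group
distance trend computes, per day, Euclidean distances between litter
groups either as centroid distances or as the mean over all cross-group
sample pairs (default: all pairs, the neutral reading of a "pairwise
distance matrix"), and summarises the series as
`100 · (d_final − d_initial)/d_initial`; positive values mean
divergence. Scaling all intensities by c > 0 scales distances by c and
leaves the percent change unchanged. A zero initial distance makes the
percent change undefined and is an error.

## Overlay

The overlay cross-tabulates each pathway's matched formulas over module
labels: counts, row-normalised fractions, a concentration index (the
maximum module fraction) and a ubiquity flag (set when no module holds
at least the threshold fraction, default 0.5 — the operational reading
of "spread ubiquitously"). Hypergeometric enrichment per
(pathway, module) with Benjamini–Hochberg correction across the table
is available but off by default: it is an extension beyond the visual
argument such analyses usually make, and is labelled as such.

## Determinism and problem sizes

All randomness flows from a single integer seed; stage seeds are small
fixed offsets of it. Two runs with the same configuration produce
byte-identical outputs (floats are written with a fixed `%.12g`
format). The default synthetic conditions — 200 features × 120
samples — are the package's standard working size: large enough that
correlation, clustering and eigendecomposition behave as at scale,
small enough that the full pipeline, the test suite and the acceptance
script each run in seconds.

## Known limitations

* Exact reproduction of the original 6999-node network and its
  10-module partition is not attempted: the true assignment settings
  and the clustering cut parameters of the original analysis are not
  recoverable, and the raw data are not shipped.
* Only [M−H]⁻ singly charged ions are modelled; no isotope-pattern
  scoring, adducts or recalibration.
* The constant-height tree cut is simpler than dynamic hybrid cutting;
  deeply nested module structure may need the TOM dissimilarity or a
  lower cut height.
* Compositional (closure) effects are handled in the generator by the
  background-weight mechanism, not removed by a log-ratio transform;
  analyses of real data with strong closure may prefer CLR-transformed
  inputs, which the matrix contract (any non-negative table) permits.
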