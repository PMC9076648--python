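# domnet

Weighted molecular correlation networks for dissolved organic matter
(DOM) metabolomics.

When plant litter decomposes, the water-leachable DOM carries
signatures of both the litter source and the microbial community
working on it. Direct-infusion HR-MS of such leachates yields thousands
of exact masses per sample; assigning elemental compositions (sum
formulas) and correlating their relative abundances across a designed
sample series turns those peak lists into a molecular network whose
subnetworks (modules) separate litter-specific, time-driven and shared
("convergent") molecular patterns. `domnet` is a library + CLI for that
analysis, aimed at environmental chemists and microbial ecologists who
work with litter-decomposition or soil-DOM time series.

## What it computes

Starting from per-sample peak lists `(m/z, intensity, S/N)` plus
blanks:

1. **Filtering & formula assignment** — keep peaks with S/N > 4 inside
   m/z 175–1000, remove blank masses (ppm window), and assign CHNOS sum
   formulas by exhaustive enumeration within element ranges at a ppm
   tolerance, with standard DOM plausibility filters (H/C, O/C,
   even-electron rule). Result: a formula × sample relative-intensity
   matrix (columns sum to 1).
2. **Signed weighted network** — Pearson correlation r between all
   formula pairs, soft-thresholded into a signed adjacency

       A_ij = (0.5 · (1 + r_ij))^p ,   p = 9 by default,

   so anticorrelation maps to near-zero edge weight. Modules are found
   by average-linkage clustering of the dissimilarity 1 − A (or
   1 − TOM) and named by size with the conventional WGCNA palette; each
   module is summarised per sample by its eigenvalue vector (PC1 sample
   scores of the standardized module block).
3. **3-D embedding** — classical multidimensional scaling of the
   network dissimilarity.
4. **Pathway coverage** — matching assigned formulas against a
   KEGG-style compound→pathway table: match rate, mean structure
   suggestions per matched formula, per-pathway coverage
   (detected members / pathway size), deduplicated intensity sums (one
   intensity contribution per formula per pathway, however many isomers
   it matches), cross-group coverage dispersion, and a quadrant
   comparison against an external coverage table (e.g. 16S-based
   functional predictions).
5. **Convergence/divergence** — PCA trajectories by litter group and
   the percent change of between-group Euclidean distance from the
   first to the last sampling day.
6. **Overlay** — distribution of each pathway's annotated molecules
   across network modules, with a concentration index and ubiquity
   flag.

A synthetic generator emulates the full study design (4 litter types ×
2 sites × 3 replicates × 5 leachate days = 120 samples) with planted
correlated feature blocks, lognormal noise and annotation tables, so
every stage can be validated against a known ground truth. See
`docs/methods.md` for the model and all defaults.

## Worked example

```python
import warnings
from domnet import (generate_feature_matrix, correlation_matrix, signed_adjacency,
                    detect_modules, module_eigenvalues, classical_mds,
                    group_distance_trend)
from domnet.synthetic import planted_recovery_ari

matrix, meta, truth = generate_feature_matrix()   # default design, seed 0
print("matrix:", matrix.shape)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")               # background features may be dropped
    cor = correlation_matrix(matrix)
adj = signed_adjacency(cor, power=9)
modules = detect_modules(adj)
print("modules:", modules.sizes.to_dict())
print("recovery ARI:", planted_recovery_ari(truth, modules.labels))
eig = module_eigenvalues(matrix, modules)
print("variance explained:", {k: round(v, 3) for k, v in eig.variance_explained.items()})
emb = classical_mds(1 - adj, k=3)
print("embedding axes:", emb.coordinates.shape,
      "positive mass captured:", round(emb.positive_mass_fraction, 3))
trend = group_distance_trend(matrix, meta)
print("between-litter distance change: %+.1f%%" % trend.percent_change)
```

prints

```
matrix: (200, 120)
modules: {'turquoise': 50, 'blue': 50, 'brown': 50, 'grey': 50}
recovery ARI: 1.0
variance explained: {'turquoise': 0.939, 'blue': 0.942, 'brown': 0.905}
embedding axes: (200, 3) positive mass captured: 0.618
between-litter distance change: +7.7%
```

The three planted feature blocks (beech-specific, pine-specific, and a
convergence block shared by oak and grass) come back as the turquoise,
blue and brown modules with an adjusted Rand index of 1.0; the 50
unstructured background features stay grey. Each module's first
principal component explains ≥ 90% of its block variance, and the
litter groups drift apart by ~8% over the 22-day series — the planted
divergence.

The same analysis from a shell:

```bash
domnet run --seed 1 --out runs/demo          # simulate → assign → network →
                                             # embed → coverage → trend → overlay
domnet simulate --seed 1 --out sim/          # or stage by stage
domnet assign --peaks sim/peaks --blanks sim/blanks.tsv --out features.tsv
domnet network --features features.tsv --power 9 --out net/
```

All outputs are TSV/JSON/GraphML; every matrix is re-readable with
`domnet.io`.

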