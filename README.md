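# loopmut

Somatic mutation landscapes around chromatin loop anchor points.

Chromatin loops detected by Hi-C are tethered at loop anchor points (LAPs),
typically 5-kb regions containing convergently oriented CTCF motifs. In
cancer genomes these anchors sit inside broad regions of *reduced*
single-nucleotide variant (SNV) rates yet carry a sharp excess of SNVs at the
CTCF motif itself and an excess of structural-variant (SV) breakpoints —
they behave as fragile sites. Anchors also coincide with meiotic
recombination hotspots and are enriched for the degenerate 13-bp PRDM9 core
motif `CCTCCCTNNCCAC`. `loopmut` packages the statistical machinery needed
to quantify these patterns from interval sets (BED), somatic call tables
(ICGC-style TSV) and genome FASTA:

- **Interval algebra and window grids** — merge/overlap operations on
  0-based half-open intervals; 1-Mb windows centred on feature midpoints,
  tiled by 5-kb bins, with blacklist filtering.
- **Anchor-set construction** — the union anchor set from per-cell-line
  loop-motif BEDs (motifs merged so each is counted once, then expanded to
  5 kb around the merged midpoint), control CTCF sites away from anchors,
  and the stringent non-CTCF anchor subset.
- **Mutation-rate meta-profiles** — per-bin aggregate counts X and rates in
  events·sample⁻¹·Mb⁻¹, with exact (Garwood) two-sided 95% Poisson
  intervals on X: lower = ½χ²(α/2, 2X), upper = ½χ²(1−α/2, 2X+2), identical
  to R's `poisson.test`. Fine 20-bp motif-oriented profiles and
  flank-resampling focal tests.
- **Circular-permutation overlap statistics** — a null that rigidly rotates
  one feature set per chromosome (wrapping at the ends), shift curves,
  product-of-marginals composition expectations with hypergeometric tails,
  GWAS-region permutation inputs, and anchors-per-gene proportion tests.
- **Feature modelling** — per-window predictor matrices, Spearman panels
  with bootstrap CIs, and %IncMSE variable importance from bagged
  regression trees with out-of-bag permutation.
- **Synthetic data** — a generator that plants all of the above structure
  (rate dip, focal peak, breakpoint enrichment, hotspot co-location, motif
  planting, DSB fold) into a desk-scale genome with full ground truth.

## Worked example

```python
import loopmut as lm

# Exact Poisson interval on an aggregate count: a 5-kb window at
# 4 SNVs/sample/Mb over 2284 samples and 11085 window placements.
x, lo, hi = lm.poisson_ci_aggregate(4, 5000, 2284, 11085)
print(f"aggregate SNVs: {x}  95% CI: [{lo}, {hi}]")

# A synthetic cohort with the canonical anchor-centred structure planted.
cfg = lm.SimulationConfig(seed=1, n_samples=500)
bundle = lm.simulate_bundle(cfg)
grid = lm.build_window_grid(bundle.anchors.laps, bundle.layout, 1_000_000, 5_000)
profile = lm.compute_meta_profile(bundle.catalog, grid)
print(profile.to_frame().iloc[[0, 99, 100, 199]].to_string(index=False))

res = lm.circular_permutation_test(
    bundle.anchors.laps, bundle.hotspots, bundle.layout, n_perm=1000, seed=2
)
print(res.summary())
```

Output:

```
aggregate SNVs: 506363  95% CI: [504970, 507760]
 offset  count  rate   ci_low  ci_high
-500000   1248 2.496 2.359424 2.638419
  -5000   1019 2.038 1.914774 2.167076
      0   1023 2.046 1.922528 2.175321
 495000   1350 2.700 2.557876 2.847966
circular permutation: observed=32, null=23.2+/-4.5, z=1.96, p=4.20e-02 (1000 permutations)
```

The profile table shows the planted behaviour: the outermost 5-kb bins run
near the 4 SNVs·sample⁻¹·Mb⁻¹ background (attenuated because neighbouring
anchors keep the whole window inside the dip), while the central bins around
offset 0 drop towards half that rate — the planted dip depth of 0.5. The
permutation line reports the observed count of anchors touching a hotspot
against the rotation null; at this small scale (200 anchors, 16% planted
co-location over a ~12% background) the excess is visible but borderline,
which is why the full-scale analysis uses many more anchors.

A `loopmut` console script wraps the same stages
(`simulate`, `build-anchors`, `profile`, `fine-profile`, `permtest`,
`shift`, `composition`, `model`, `report`), each driven by a YAML config
plus `--seed`, writing TSV tables and JSON reports stamped with version,
seed and input checksums.

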