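# cytoniche

Tools for the analytical chain of large-scale cytogeographic surveys of
mixed-ploidy plants: from flow-cytometry ploidy calling, through population
cytotype-composition statistics, to environmental-niche comparison between
cytotypes in PCA environment space.

## Who this is for

Plant biosystematists and ecologists who survey a polyploid complex across
its range (populations genotyped by flow cytometry, sites characterized by
climate/soil layers) and want to quantify whether cytotypes differ in their
realized environmental niches — and to test those workflows end-to-end on
synthetic surveys with known ground truth.

## What it computes

**Ploidy calling.** A sample's relative fluorescence (RF = sample G0/G1 peak
over an internal-standard peak) is called against per-stain, per-ploidy
calibration envelopes `[min, max]`; histograms with CV ≥ 5% are rejected and
RF values inside two overlapping envelopes are flagged ambiguous rather than
forced.

**Composition.** Populations are tabulated by exact cytotype combination
(pure 5x, 4x+5x, …) giving the mixed-ploidy fraction and per-cytotype
uniform-to-mixed odds.

**Niche analysis.** Occurrences are spatially thinned per region (no two
retained points closer than the region's threshold, maximizing retention),
availability is sampled within a 20-km buffer at 100× the occurrence count,
and a pairwise PCA of the standardized environmental variables (pairwise
|r| ≤ 0.7 after greedy collinearity filtering) defines the niche plane.  On
an R×R grid (default 200×200) the occupancy surface is

    z  ∝  occurrence density / background density      (Σz = 1)

smoothed with separable Gaussian kernels.  Niche comparisons then report:

* **Schoener's D** = 1 − ½ Σ|z₁ − z₂| ∈ [0, 1];
* **equivalency test** — pool the two occurrence sets, re-split at the
  original sizes, rebuild grids, repeat (default 1 000×); observed D in the
  lower/upper 2.5% tail ⇒ less/more equivalent than chance;
* **similarity test** — compare observed D to D against niches resampled
  from the *other* cytotype's background, both directions;
* **niche dynamics** — within the intersection of both backgrounds'
  75%- or 95%-mass regions, expansion E (higher-ploidy occupancy mass where
  the lower niche is absent), unfilling U (the converse) and stabilities
  S_e = 1 − E, S_n = 1 − U;
* **optimum and breadth** — mean and variance of axis scores of 100 grid
  cells resampled from the occupied niche, repeated 1 000×, summarized by
  95% central intervals.

A seeded synthetic-data generator produces every input with known truth:
two latent environmental gradients (humidity/soil and seasonality) drive a
correlated 13-variable panel over a site lattice; cytotypes occupy Gaussian
niche envelopes; contact-zone populations mix with a configurable rate; RF
measurements come from the calibration means with configurable spread.

## Worked example

```python
import cytoniche as cn

cfg = cn.RunConfig(seed=42, n_sites=3000, lattice_extent_km=300.0,
                   grid_resolution=100, reps_equivalency=200,
                   reps_similarity=200, reps_optimum=1000)
bundle = cn.run_pairwise_analysis(cfg, "out")
```

This simulates a three-cytotype survey (4x, 5x, 6x with progressively
narrower envelopes), runs every ordered pair through thinning → background →
PCA → grids → tests → dynamics, and writes one JSON report per pair plus
`summary.csv`:

```
cytotype_low cytotype_high     D     equivalency similarity_low_to_high similarity_high_to_low  E_p95  U_p95
          4x            5x 0.575 more_equivalent           more_similar           more_similar    0.0  0.001
          4x            6x 0.462              ns           more_similar           more_similar    0.0  0.104
          5x            6x 0.504 more_equivalent           more_similar           more_similar    0.0  0.070
```

Read: the 4x and 5x niches overlap moderately (D = 0.575) and are judged
more equivalent than random re-splits of their pooled occurrences (null mean
0.475); every higher-ploidy niche shows zero expansion beyond its
lower-ploidy partner but nonzero unfilling (U_p95 up to 0.104) — the niche
contraction signature built into the simulated envelopes.  The same run
reports each cytotype's niche optimum with its 95% resampling interval
(e.g. 4x axis 1: [−0.693, 0.285]) and the 26.7% mixed-ploidy population
fraction of the simulated survey in `composition.json`.

The same pipeline is reachable from the shell:

```bash
cytoniche simulate --seed 42 --out sim/
cytoniche assign-ploidy sim/rf_measurements.csv --out calls.csv
cytoniche compose sim/populations.csv --out composition.json
cytoniche run-all --config cfg.yaml --out out/
cytoniche summary out/
```

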