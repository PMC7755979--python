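# Methods

This note documents the statistical procedures implemented in `cytoniche`,
the assumptions behind them, the defaults that matter, and the places where
the design was genuinely open.

## Ploidy calling from relative fluorescence

Ploidy is inferred by comparing a sample's relative fluorescence (RF) to
per-(stain, ploidy) calibration envelopes `[min_rf, max_rf]` established on
chromosome-counted plants.  Containment is closed: the bounds are observed
extremes of verified plants, so a value equal to a bound is evidence for
that cytotype.  Histograms with CV ≥ 5.0% (strict inequality for
acceptance) are rejected before calling.  An RF inside two or more
envelopes — the tetraploid and pentaploid propidium-iodide envelopes
overlap on [1.66, 1.71] — produces an `ambiguous` call carrying the full
candidate set; resolving such plants by chromosome counts or by the spatial
coherence of RF values is deliberately out of scope, so downstream code
must treat ambiguity as missing ploidy, not pick a side.  The bundled
`rf_variation` helper reports the within-cytotype envelope width as
100·(max − min)/min, rounded to one decimal; this definition reproduces the
published variation column of the reference calibration for all
propidium-iodide rows (one DAPI row differs by 0.1, attributable to
rounding of the printed bounds).

## Composition statistics

Populations with fewer than two analysed individuals are excluded (a
singleton cannot reveal mixture), then each population contributes one
count to its exact cytotype combination.  The uniform-to-mixed odds of a
cytotype are `uniform_count / Σ mixed_counts_containing_it`, undefined
(`None`) when the cytotype never co-occurs.  Percentages are reported to
2 d.p. and odds to 1 d.p.; raw ratios are retained in the JSON output.

## Spatial thinning

Within each region stratum no two retained points may be closer than the
stratum threshold (defaults mirror a survey design with 40 km in densely
sampled regions and 15 km elsewhere).  Thinning maximizes retention:
conflict-graph components with ≤ 18 points are solved exactly by
branch-and-bound maximum independent set; larger components fall back to
the randomized greedy heuristic (repeatedly delete the point with most
sub-threshold neighbours, random tie-break, best of 10 seeded restarts).
The exact branch guarantees optimality on all small instances — the regime
where a brute-force oracle can certify it — while the greedy branch keeps
worst-case cost linear-ish in practice.  Mixed-ploidy populations
contribute their coordinate to every participating cytotype's point set
before thinning, because stratification is per cytotype.

All geometry is spherical great-circle distance (haversine, R = 6371 km);
no projected CRS is supported.

## Background (availability) sampling

Each cytotype's background is drawn from candidate sites within 20 km of
any of its occurrences, at 100× the occurrence count, uniformly **with
replacement** — the target count generally exceeds the number of distinct
~1-km cells a 20-km buffer contains.  A caveat that matters for synthetic
work: if the candidate lattice is much coarser than the buffer radius, a
"background" degenerates to the occurrence sites themselves and
availability-corrected statistics become unstable.  Synthetic scenarios in
the test suite therefore use lattices whose spacing is a small fraction of
the buffer (300–500 km extent at 3 000–4 000 sites), standing in for the
~1-km climate and soil cells a real analysis would ingest.

## PCA-env and occupancy grids

Variables are greedily decollinearized (while any pairwise |r| exceeds
0.70, drop the variable with the largest mean absolute correlation), then
standardized over the pooled background of the two compared groups and
eigen-decomposed; axes 1–2 with a positive-peak sign convention define the
niche plane.  The PCA is recalibrated per compared pair, since
availability is defined per cytotype; a global mode is available for
multi-cytotype panels.

The grid spans the pooled background score range per axis, padded by one
bandwidth, at R = 200 cells per axis by default.  Densities are separable
Gaussian product kernels evaluated at cell centers; per-axis kernel SDs
follow the normal-reference rule 1.06·min(sd, IQR/1.34)·n^(−1/5) computed
once on the pooled background scores.  Computing bandwidths on the
background (not per occurrence set) keeps the grid frame fixed across
permutations, which both matches the fixed-availability logic of the
permutation tests and makes a thousand replicates cheap: each permutation
only re-smooths occurrence scores (one rank-n matrix product).

Occupancy is `z ∝ occ_density / env_density`, normalized to Σz = 1.  Two
relative floors make the surfaces well-defined: cells with background
density below 10⁻⁶ of its maximum are unavailable (z forced to 0,
preventing ratio blow-ups in absent environments), and occurrence density
below 10⁻⁶ of its own maximum is zeroed so the occupied region (z > 0) of
a Gaussian-smoothed niche has finite support — without that floor every
grid cell is "occupied" and support-based statistics are meaningless.  An
uncorrected mode (z ∝ occurrence density on the available cells) is
exposed everywhere; it is the better-behaved surface for optimum/breadth
estimation (below).

## Overlap and permutation tests

Schoener's D = 1 − ½ Σ|z₁ − z₂| on unit-mass surfaces: 0 for disjoint,
1 for identical niches.  The equivalency test re-splits the pooled
occurrences into sets of the original sizes (default 1 000 reps) and
judges the observed D against the 2.5%/97.5% null quantiles; the
similarity test replaces one group by draws of its occurrence count from
the *other* group's background (without replacement when possible) and is
applied in both directions.  Verdicts are reported with the observed D's
empirical quantile position rather than a p-value.

Calibration caveat: the equivalency null is exchangeable — hence exact —
only when both groups are corrected against a **shared** availability.
When each group carries its own background and the two availability
supports differ, permuted occurrences land in environments the other
group's background barely contains, the corrected ratio surface
concentrates there, and the test becomes anti-conservative.  The package's
null-calibration tests therefore pair same-distribution groups with a
shared pooled-buffer background (measured abstention ≥ 90% over 50 seeded
runs at 2.5% + 2.5% tails, for the equivalency test and both similarity
directions); users comparing groups with strongly disjoint availability
should prefer the uncorrected surface or interpret corrected-mode verdicts
cautiously.

## Niche dynamics (expansion / stability / unfilling)

The analysis region at quantile p is the intersection of the two
backgrounds' top-p%-of-density-mass cells ("quantile of environmental
density" is read as a mass threshold; a value-percentile mode is provided
for comparison).  Within the region, E is the z-mass of the higher-ploidy
niche on cells where the lower niche is absent (z = 0 after flooring),
divided by the higher niche's z-mass in the region; U swaps the roles;
S_e = 1 − E and S_n = 1 − U by construction, so those identities are exact
regardless of data.  Identical grids give exactly (E, U) = (0, 0), and a
niche strictly inside another gives E = 0 with U > 0 — the contraction
signature.  Indices weight cells by occupancy mass, not raw cell counts,
matching a "proportion of niche space" reading with density weighting.

## Niche optimum and breadth

Per replicate (default 1 000), 100 cells are drawn with replacement from
the occupied cells (z > 0) and the mean and variance of their axis scores
recorded; distributions are summarized by 95% central intervals, and two
cytotypes are called different on an axis when their intervals are
disjoint.  Draws are **density-weighted** by default: weighting by z
mirrors procedures that resample occurrence records, and estimates the
mean of the occupancy density.  The alternative — uniform draws over
occupied cells — estimates the centroid of the smoothed support, which is
dragged around by the 5.3-bandwidth kernel halo of any outlying occurrence
and is measurably biased on synthetic surveys; it remains available via
`weighted=False`.  For recovery benchmarks the uncorrected surface is used:
at realistic grid scales the corrected ratio adds heavy-tailed noise from
thin-availability cells that inflates the optimum estimator's variance
without changing its target when availability is flat.

These resampling intervals quantify within-niche resampling spread only;
they do not include the sampling error of the occurrence set itself.
Recovery of a known optimum inside the interval therefore requires
occurrence counts where that error is small relative to the interval
width — the recovery benchmark uses ~100–200 occurrences per cytotype,
comparable to the larger per-cytotype samples of real continental surveys.

## Synthetic surveys and what they do (not) show

The generator emulates: two latent environmental gradients driving a
13-variable correlated panel (loadings chosen so the default panel
survives the |r| ≤ 0.70 filter) over a regular lattice mapped to lon/lat
equirectangularly; Gaussian niche envelopes sampled by acceptance
thinning; contact-zone mixing (a population mixes with probability
`base_mixing_rate`, default 0.25, wherever two envelopes exceed a 0.05
support threshold — a free parameter, not an estimate of any observed
mixture rate); individuals per population as 2 + NegBin with mean ≈ 13 and
SD ≈ 14, matching the right-skew of real sampling effort; and RF values
from the calibration means with configurable spread and CV-gate failure
rate.

Latent gradients have **uniform** marginals (a rank transform of a
position-plus-noise field, unit variance).  This is deliberate: under flat
availability, acceptance thinning reproduces the Gaussian envelope exactly
as the occurrence distribution, so the declared optima and breadths are
the true moments of the occurrence process and recovery tests have
well-defined targets.  (With, say, Gaussian availability the realized
occurrence mean is shrunk toward the availability center and the
generator's "truth" would be systematically wrong about its own output.)
Envelopes should sit ≥ 2 SD inside the gradient range [−√3, √3]; an
envelope truncated by the sampled range has its realized optimum shifted
inward — an identifiability limit of any niche survey, not an artifact.

What passing synthetic tests does **not** show: real surveys have spatially
autocorrelated sampling effort, non-Gaussian niches, interpolated (not
lattice) environmental layers, and availability structures far from flat,
so calibration and recovery results here bound behaviour under idealized
conditions rather than guarantee it in the field.

## Heat load and Gower dissimilarity

Heat load uses the published log-scale regression on latitude, slope and
folded aspect (equation 2 of McCune & Keon 2002, J. Veg. Sci. 13:603–606;
coefficients transcribed verbatim into a single constants block), with
aspect folded about the NE–SW axis as A′ = |180° − |aspect − 225°|| — so
A′ = 180° (southwest) maximizes the index through its −1.376·cos A′ term —
and the result exponentiated to an arithmetic scale.  Latitudes outside
the regression's stated 30–60° validity range warn but still return the
extrapolation.  Gower dissimilarity averages range-normalized absolute
differences (quantitative and rank-coded ordinal fields; the Podani
ordinal correction is not implemented) with 0/1 mismatches (binary,
categorical), dropping missing fields pairwise with weight
renormalization.

## Reproducibility and problem sizes

One global seed fans out to named child streams (`SeedSequence`-based), so
every stage is independently reproducible and two runs with the same
config hash are byte-identical.  Default test-suite problem sizes —
2 500–12 000 lattice sites, grids of 50–120 cells per axis, 25–200
permutation reps — were chosen so the full synthetic battery, including a
50-run null-calibration study and a 20-replicate recovery study, completes
in well under a minute on one core; production analyses should use the
200×200 grid and 1 000 reps the defaults of `RunConfig` provide.

## Known limitations

* The corrected-occupancy equivalency test is anti-conservative across
  strongly differing availabilities (see above).
* Ambiguous ploidy calls are flagged, never resolved.
* No raster I/O: environmental values must arrive as per-site tables.
* The dynamics indices depend on the quantile semantics chosen for the
  analysis region; the mass-based default and value-based alternative can
  differ for very peaked backgrounds.
* Thinning optimality is guaranteed only for conflict components ≤ 18
  points; larger components use a heuristic with restarts.
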