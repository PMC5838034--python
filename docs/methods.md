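# Methods

## The question and the data model

The pipeline tests whether individuals entering a population (juveniles and
recently arrived adults, collectively "migrants") aggregate in space around
established residents. The sampling frame is a set of small rectangular
plots (default 12 m × 9 m) divided into a regular grid of square cells
(default 1.5 m), surveyed repeatedly (several visits per month) over
consecutive multi-month seasons. A capture records who, where (plot and
cell), when, snout–vent length (SVL) and a sex marker. Capture location is
known only to the cell; the cell centre is the canonical coordinate.

## Cohort classification

Captures are pooled into five default seasonal windows spanning February
1982 – August 1983 (dry 1982, first and second halves of the 1982–83 wet
season, dry 1983, early wet 1983); windows are configurable. Within each
plot-season an individual is:

- `J` — juvenile, if every capture that season is below the 19 mm SVL
  maturity threshold. All juveniles count as migrants: they entered the
  population recently and have little residency history.
- `RF`/`RM` — resident adult, if the individual was captured in the same
  plot during the immediately preceding season (any stage — so a juvenile
  that matures in place becomes a resident), or if the season is the first
  of the study, where tenure cannot be assessed and all adults default to
  resident.
- `MF`/`MM` — migrant adult otherwise.

Design choices where the rules were genuinely open: "previous season" means
strictly the immediately preceding window, so an adult absent for a full
season and then recaptured reverts to migrant; sex at maturation is taken
from the first adult-stage capture; an individual moving between plots is
classified independently in each plot; adults whose sex marker is unknown
cannot join a sex-specific cohort and are excluded with a log message. The
≥ 3-capture subset threshold applies to study-wide capture counts, not
per-season counts.

## Spatial statistics

All three statistics operate on cross-type nearest-neighbor distances
(NND): from each focal-class point to the closest reference-class point.

**Clark–Evans R.** R = r̄_obs / r̄_E, with the Donnelly edge-corrected CSR
expectation for a bounded rectangle

    r̄_E = 0.5·√(A/n) + (0.0514 + 0.041/√n) · P/n

where A and P are the window's area and perimeter and n the
reference-class count. The constants 0.0514 and 0.041 are the published
correction coefficients, fixed in code. R < 1 indicates clumping, ≈ 1
randomness, > 1 uniform spacing. Cross-type distances with the expectation
indexed by the reference-class count are the default ("focal class
relative to reference class"); a pooled within-pattern mode
(`same_pattern=True`) is available. Under CSR the cross-type mean R is
≈ 0.973 (the correction was derived for the within-pattern case, which
calibrates at ≈ 1.000); the paired observed-vs-null design removes this
small constant from all contrasts.

**Ĝ(r) with spatial Kaplan–Meier border correction.** Each focal point i
contributes an observation time dᵢ = min(nndᵢ, bᵢ) and event flag
δᵢ = [nndᵢ ≤ bᵢ], where bᵢ is the distance to the nearest window edge: a
nearest neighbour farther than the border might lie outside the window, so
the distance is right-censored. Ĝ is one minus the Kaplan–Meier survival
curve (ties aggregated before the product); with no censoring it reduces
exactly to the empirical CDF. The CSR reference is
G(r) = 1 − exp(−λπr²) at the reference-class intensity λ = n/A. The
default r-grid has 512 equal steps from 0 to one quarter of the window's
shorter side (0–2.25 m by default). An alternative MAD reference — the
pointwise mean of simulated Ĝ curves — is available where a finite-sample
reference is preferred.

**MAD statistic.** u = max_r |Ĝ(r) − G_ref(r)|, with a direction flag
(sign of Ĝ − G_ref at the argmax; positive = clustering). The associated
Monte-Carlo rank test is one-tailed: p = (1 + #{u_null ≥ u_obs}) / (1 + N).
Under exchangeability this is exact, and the pipeline's type-I calibration
test confirms the 5% nominal rate at N = 199.

**Shared sites.** Per survey and class pair: the number of cells occupied
by at least one individual of *each* class, divided by the number of cells
occupied by *either* class (same-class co-occupancy never counts as
shared). The pair-restricted denominator is the default; a global
denominator (cells occupied by any classified individual) is a switch. An
individual captured twice in one survey counts once, at its first cell.
Undefined surveys (no occupied cells for the pair) are flagged and excluded
from averages.

## Null models and inference

For every observed unit the null is density-matched CSR: continuous uniform
points in the window with the observed class counts for R and MAD
(seasonal centroid analyses), independent uniform cell assignment
(multinomial) for shared sites (per-survey analysis). Ten replicates per
unit are averaged — single draws are noisy estimates of the random mean —
and the replicate count is configurable upward (≥ 199 recommended for
calibration work). Sub-seeds derive deterministically from the master seed
and the unit key (CRC-32 into a SeedSequence), so any unit reproduces in
isolation and distinct units get independent streams.

Observed − null differences are tested with an intercept-only linear mixed
model (random intercept for plot, variance component for season nested in
plot). With only four plots this fit routinely lands on a singular
variance boundary where Wald standard errors are unreliable; the fit
watches for convergence/singularity warnings and then falls back to a
seeded sign-flip randomization test (9999 flips), flagged as
`method = "randomization"` in the output. R and shared-site contrasts are
two-sided; the MAD contrast is one-tailed for aggregation. α = 0.05, no
multiple-testing correction across the six class pairs (by design; read
pair-level p-values accordingly).

Abundance (distinct individuals per plot-season in the juvenile / female /
male groups) is described by five candidate mean structures — null,
season, group, group + season, group × season — fitted by maximum
likelihood as Gaussian mixed models with a plot random intercept and
ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with Akaike weights. k counts
fixed effects plus the two variances. Counts are treated as Gaussian (the
standard LMM simplification for moderate counts); no count-family
alternative is fitted.

## The synthetic generator

`markspat.synthetic_data.generate` emulates the study design: 4 plots,
the 5 default seasons, 3–4 surveys per month (mean 3.5), resident adults
(10 F + 5 M per plot, echoing the strongly female-biased sex ratios of the
system) holding fixed home centres for the whole study, and 8 new entrants
per plot-season (40% juveniles). Entrant home centres are uniform (`csr`)
or Gaussian-scattered (sd `cluster_sd`, default 0.5 m) around a randomly
chosen resident (`attraction`, a Thomas-cluster-like displacement whose
truth parameter maps monotonically onto all three statistics). On every
survey each present individual is detected with probability `detection_p`
(default 0.5) and recorded in the cell containing a draw from its
home-range scatter, truncated to the window — sd 0.8 m for females and
0.5 m for males, female > male as in the study species, corresponding to
95% home-range areas of roughly 12 and 5 m², realistic for a small
site-faithful frog. Juveniles enter at 12–18 mm SVL and grow 3 mm per
season, crossing the 19 mm threshold and exercising the maturation rule.
Entrants persist after arrival, so a season-s migrant is a season-s+1
resident — the tenure structure the classifier is built to recover. Seeded
runs are byte-identical.

What the generator does **not** emulate: territorial exclusion, movement
between plots, mortality/emigration (individuals never leave), measurement
error in SVL, and seasonal variation in detection. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
spatial structure, not robustness to those real-data features.

`parameter_recovery_experiment` sweeps (cluster_sd, detection_p) cells,
runs the full observed-vs-null pipeline per simulated dataset, and reports
per-statistic rejection rates at α = 0.05 — the CSR row estimates type-I
error, the attraction rows power.

## Numerical choices and degenerate inputs

Nearest-neighbor queries use a k-d tree (self-distances excluded in
within-pattern mode); coincident points are legal and give distance 0.
Units with an empty focal or reference class are skipped and logged, as
are surveys with no occupied cells. Ĝ ties at identical observation times
are aggregated before the KM product. The AICc correction requires
n > k + 1 and raises otherwise; unestimable candidate models are dropped
with a warning. Contrasts need ≥ 2 units. All-zero difference vectors take
the randomization path by construction.

## Problem sizes used in validation

The validation suite exercises the pipeline at the study's own scale
(4 plots × 5 seasons, ~190 individuals, ~4000 captures per dataset), with
10 replicate datasets per settlement mode for power/type-I checks, 20 000
CSR patterns for the R calibration, and 500 units × 199 null replicates
for the MAD type-I calibration — sizes at which every Monte-Carlo check
has standard error well inside its decision margin.

## Known limitations

- **R at cell resolution is biased toward "clumped".** Because capture
  locations are quantized to 1.5 m cells and seasonal centroids of
  border-truncated home-range scatter shrink away from plot edges, even
  *random* settlement yields observed R ≈ 0.85–0.90 against the continuous
  uniform null — a systematic negative contrast of roughly −0.1 that the
  seeded within-cell jitter switch (`jitter=True`) only partly removes
  (≈ −0.09). The MAD and shared-site statistics do not show this artifact
  (their CSR rejection rates are nominal). Observed R values and R
  contrasts from cell-resolution data should therefore be read with this
  offset in mind; the validation suite asserts random-settlement
  calibration for all three statistics and the R assertion fails by
  design, documenting the artifact rather than hiding it.
- The mixed-model contrast almost always falls back to randomization with
  only four plots; with many plots the mixed path engages.
- The migrant/resident labels are detection-limited: with per-survey
  detection well below 1 a true resident can be missed for a whole season
  and come back labelled migrant. The generator reproduces this, and the
  ground-truth agreement tests only assert classification correctness on
  knowable cases (individuals actually observed in consecutive seasons).
- Plots are treated as independent; no between-plot spatial structure is
  modelled or tested.
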