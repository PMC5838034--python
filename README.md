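# markspat

Spatial aggregation analysis for gridded mark-recapture data.

`markspat` asks a habitat-selection question: when new individuals —
juveniles and recently arrived ("migrant") adults — settle in a habitat
patch, do they place themselves near established residents (conspecific
attraction), at random, or apart from them? It was built around the classic
study system of a small territorial poison frog surveyed repeatedly in
gridded forest plots (12 m × 9 m, forty-eight 1.5 m × 1.5 m cells, several
surveys per month over consecutive seasons), but any capture table with
individual IDs, plot/cell coordinates, dates, body sizes and sex markers
fits.

## What it computes

Starting from one capture per row, the pipeline:

1. **Pools captures into seasons** and classifies every individual per plot
   and season into cohorts: juveniles (`J`, SVL < 19 mm), resident adults
   (`RF`/`RM`, observed in the same plot the previous season), and migrant
   adults (`MF`/`MM`, new arrivals). A dataset restricted to individuals
   captured ≥ 3 times removes transient visitors.
2. **Estimates seasonal centroids** — the mean of an individual's capture
   cell centres — and, per (plot, season, class pair), three spatial
   statistics:
   - the **Clark–Evans R** with the Donnelly border-corrected CSR
     expectation
     `r̄_E = ½√(A/n) + (0.0514 + 0.041/√n)·P/n`
     (A area, P perimeter, n reference-class points); R < 1 indicates
     clumping, R ≈ 1 randomness, R > 1 uniform spacing;
   - the **nearest-neighbor distance distribution function** Ĝ(r),
     border-corrected with the spatial Kaplan–Meier estimator (an NND
     exceeding a point's distance to the window edge is right-censored),
     against the CSR reference G(r) = 1 − exp(−λπr²);
   - the **MAD statistic** u = max_r |Ĝ(r) − G(r)|, a proxy for
     aggregation strength.
3. **Measures per-survey shared sites**: the proportion of occupied grid
   cells holding individuals of both classes of a focal migrant–resident
   pair.
4. **Simulates density-matched CSR nulls** (N = 10 replicates per unit,
   averaged) and tests each statistic's observed − null paired difference
   with an intercept-only mixed model (plot and season-within-plot random
   effects), falling back to a seeded sign-flip randomization test whenever
   the mixed fit is singular — which it flags in the output.
5. **Ranks five candidate abundance models** (null, season, age-sex group,
   group + season, group × season) fitted as Gaussian mixed models with a
   plot random intercept, by AICc with Akaike weights.

A synthetic-data generator with known settlement truth (`csr` vs
`attraction` modes) makes the whole pipeline testable without any field
data, including type-I error and power experiments.

## Worked example

Simulate an attraction-mode dataset (migrant home centres Gaussian-scattered
0.5 m around randomly chosen residents) and run the full analysis:

```sh
markspat simulate --out demo --mode attraction --cluster-sd 0.5 --seed 11
markspat run-all demo/captures.csv --out demo_results --seed 11
```

prints (abridged):

```text
full dataset: 3915 captures of 188 individuals
subsetted (>= 3 captures): 3909 captures of 185 individuals

        statistic          pair  mean_observed  mean_null  estimate  p_value  n_units        method
                R          J-RF         0.5223     0.9789   -0.4566   0.0001       16 randomization
            MAD_u          J-RF         0.6128     0.4495    0.1633   0.0006       16 randomization
shared_proportion          J-RF         0.0659     0.0391    0.0268   0.0001      204 randomization
                R J,MF,MM-RF,RM         0.4967     0.9769   -0.4802   0.0001       16 randomization
            MAD_u J,MF,MM-RF,RM         0.5289     0.3213    0.2076   0.0001       16 randomization
shared_proportion J,MF,MM-RF,RM         0.1127     0.0714    0.0412   0.0001      210 randomization
```

Read: juveniles sit much closer to resident females than CSR predicts
(observed mean R 0.52 against a null mean of 0.98, paired p ≈ 1e-4), their
Ĝ(r) exceeds its CSR reference (positive MAD contrast), and they share
occupied cells with residents roughly twice as often as the
density-matched null — the planted attraction truth, recovered. Columns:
`estimate` is the mean per-unit observed − null difference, `n_units` the
number of plot-seasons (or plot-surveys) entering the contrast, `method`
the test actually used.

Other subcommands: `classify`, `rvalue`, `gfunction`, `shared-sites`,
`nulls`, `contrast`, `abundance`, `power` (type-I/power grid over the
generator truth parameters), and `show-config` for every default. All
commands are thin wrappers over the `markspat` library API
(`markspat.run_full_pipeline`, `markspat.clark_evans_r`, …).

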