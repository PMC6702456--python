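# Methods

Statistical model, numerical choices, and design decisions behind the
`lungstage` package. Everything here is implemented in the package and
exercised by the test suite; published quantities used for calibration are
named as such.

## 1. Data model

A patient is a `CohortRecord`: an identifier, a fine anatomic category
(histology ∈ {ADC, SCC}; T ∈ {T1a, T1b, T1c, T2a, T2b, T3, T4};
N ∈ {N0–N3}; M ∈ {M0, M1a, M1b, M1c}), a follow-up time in months, and an
event indicator (1 = death from the cancer, 0 = censored: alive, lost, or
dead of another cause). There are 2 × 7 × 4 × 4 = 224 fine cells, of which
112 per histology; coarsening T to T1–T4 and M to M0/M1 gives the 64
`SubgroupKey`s (2 × 4 × 4 × 2) used for clustering.

Three stage maps ship with the package:

* **`eighth_edition_map`** — the 8th-edition AJCC/UICC grouping at fine
  granularity (112 cells per histology; histology never affects the
  anatomic assignment). IA1/IA2/IA3 are collapsed to IA throughout.
* **`eighth_edition_coarse_map`** — the same system keyed by coarse
  `SubgroupKey`s. A coarse T2 or M1 cell spans fine cells with different
  sub-stages; the map uses the representative fine cell (T2 → T2a,
  M1 → M1a). Consequence: coarse T2N0M0 maps to IB, and sub-stage IIA
  (exactly T2bN0M0 in the 8th edition) has no coarse preimage. This is why
  evaluation always uses the fine map; the coarse map exists as the baseline
  that the published modification edits.
* **`paper_modified_map`** — the published modification: fifteen
  histology × T × N (M0) cells reassigned, every other cell carried over
  from the coarse 8th edition and flagged `"default"` (in particular all
  M1 cells remain IV). The fifteen reassignments, flagged `"paper"`:

  | Histology | Cells | From → To |
  | --- | --- | --- |
  | ADC | T1N1 | IIB → IB |
  | ADC | T1N2, T2N1, T3N0 | (IIIA / IIB / IIB) → IIA |
  | ADC | T4N0, T3N1, T4N1, T2N2 | IIIA → IIB |
  | ADC | T3N2, T4N2, T2N3 | IIIB → IIIA |
  | ADC | T3N3, T4N3 | IIIC → IIIB |
  | SCC | T1N0 | IA → IB |
  | SCC | T2N0 | IB → IIA |

  Two reading choices were required. The statement "IIIC to IIIB, IIIB to
  IIIA, IIIA to IIB" is interpreted cell-wise as "each listed cell moves one
  sub-stage down", which is the only reading consistent with the
  individually enumerated cells. For squamous T2N0 the coarse cell spans IB
  (T2a) and IIA (T2b); the stated "one sub-stage up" is applied to the
  representative T2a reading, giving IIA. Both choices are table-driven in
  `tests/test_staging_maps.py` so any revision is a one-line change.

Sub-stages nest into stages with pattern (2, 2, 3, 1): I = {IA, IB},
II = {IIA, IIB}, III = {IIIA, IIIB, IIIC}, IV = {IV}.

## 2. Survival estimation

`km_estimate` is the product-limit estimator on a monthly grid
(`grid_step = 1.0` by default). Times are binned by ceiling to the grid;
within a grid time, events are processed before censorings (the standard
convention: a patient censored at t is still at risk for deaths at t).
`css_at` evaluates the right-continuous step function; beyond the last grid
point the last value is carried forward and flagged as extrapolated by
`css_at_flagged`. `regrid` resamples a curve onto a new grid by the same
step-function convention, so `css_at` is invariant under regridding (a
hypothesis property test).

`logrank_patient` is the classical two-sample log-rank test: at each
distinct event time, observed minus hypergeometrically expected events in
group A, variance `n_A n_B d (n − d) / (n² (n − 1))`, χ²(1) reference.
It is the oracle the curve distance is validated against.

## 3. The curve χ² distance (core contribution)

`curve_chi2_distance` computes a log-rank-type statistic from two survival
curves alone. With survival proportions `a_i`, `b_i` at grid times
`t_1 < t_2 < …` (and `a_0 = b_0 = 1`), set per-capita risk sets
`n_i = a_{i-1} + b_{i-1}`, death fraction `d_i = (a_{i-1} − a_i) +
(b_{i-1} − b_i)`, and accumulate

```
O_i − E_i = (a_{i-1} − a_i) − a_{i-1} d_i / n_i
V_i       = a_{i-1} b_{i-1} d_i (a_i + b_i) / n_i³        # per capita
chi²      = (Σ (O_i − E_i))² / Σ V_i                      # × N for finite N
```

Note `a_i + b_i = n_i − d_i`, so `V_i` is the hypergeometric variance with
risk sets replaced by `N`-scaled survival proportions and the `−1` in the
denominator dropped. Two modes:

* `n_per_group="infinite"` (default for clustering): the per-capita
  statistic above. It is symmetric, zero iff the curves are identical on
  the grid, and the finite-`N` statistic is exactly `N` times it — so any
  common `N` only rescales all pairwise distances and cannot change the
  dendrogram topology (tested).
* finite `n_per_group` with `finite_correction=True`: the variance
  denominator uses `N·n_i − 1` in place of `N·n_i`, i.e.
  `V_i = N² a_{i-1} b_{i-1} d_i (n_i − d_i) / (n_i² (N n_i − 1))`. For two
  uncensored groups of equal size `N` whose times are snapped to the grid,
  the curve statistic then equals the patient-level log-rank **exactly**
  (acceptance criterion 1 asserts agreement to 1e-10 relative; without the
  correction the agreement is within 2% at n = 500 and tightens as `N`
  grows). Censoring breaks exactness because the KM risk set is no longer
  `N · a_{i-1}`; the statistic remains a well-behaved dissimilarity, which
  is all the clustering requires.

Both routes (patient-level and curve-level) are kept in the package and
compared in tests; they are never collapsed into one implementation.

## 4. Regrouping pipeline

* `build_curve_set`: one KM curve per coarse subgroup on a shared monthly
  grid spanning the whole cohort; subgroups with fewer than
  `min_group_size = 30` patients are excluded and reported.
* `build_distance_matrix`: per-capita curve χ² for every pair.
* `agglomerate`: `scipy.cluster.hierarchy.linkage` on the condensed matrix,
  average linkage by default (complete and single supported). The distance
  is not Euclidean, so centroid/Ward methods are rejected.
* `cut_and_label`: `cut_tree` at `k = 8`; clusters are ordered by pooled
  5-year CSS (patient-weighted mean of member curve values at 60 months),
  ties broken by pooled median survival, then by cluster size; the ordered
  clusters are named IA, IB, IIA, IIB, IIIA, IIIB, IIIC, IV following the
  (2, 2, 3, 1) nesting pattern.
* `derive_stage_map`: the labelled clusters as a `StageMap` (source
  `"derived"`); excluded subgroups fall back to their coarse 8th-edition
  assignment, flagged `"default"`.
* `export_newick`: the dendrogram as an ultrametric Newick string (leaf
  depth = half the merge height), round-tripped against dendropy in tests.

## 5. Evaluation

* **Adjacent-stage Cox HRs** (`hazard_ratio_adjacent_stages`): a two-group
  Cox proportional-hazards fit per adjacent pair (I–II, II–III, III–IV and
  the seven sub-stage pairs), covariate 1 = earlier group, so HR < 1 means
  the earlier group does better. The solver is a purpose-built
  Newton–Raphson for a single binary covariate (Breslow ties by default,
  Efron available), tolerance 1e-8, ≤ 50 iterations; complete separation is
  detected and returned as a flagged non-converged fit with an infinite CI
  instead of raising. Validated against scikit-survival (Breslow) and
  lifelines (Efron) to 1e-6 and against a dense partial-likelihood grid
  search.
* **Harrell's C** (`harrell_c`): predictor = stage or sub-stage rank. A
  pair is comparable if the shorter time has the event (tied times: exactly
  one event, the event is treated as earlier); tied predictions count 0.5.
  The implementation is an O(n · L) descending-time sweep over the ≤ 8
  ordinal ranks, exact against brute-force enumeration (acceptance
  criterion 5), with a seeded percentile bootstrap CI (B = 1000 default).
  Cohorts with no comparable pairs return C = 0.5 flagged degenerate.
* **Calibration** (`calibration_points`): per stage (or sub-stage) and
  horizon (36 and 60 months), predicted = training-cohort KM, observed =
  test-cohort KM, with a bootstrap CI on the observed value.

## 6. Synthetic cohort generator

The registry extract behind the published numbers is not redistributable, so
all pipeline stages run on simulated cohorts. **The generator's defaults are
the study conditions; they were fixed from published numbers before any
acceptance outcome was seen and are not tuned to test results.**

`seer_like_config` builds a cohort as a mixture over coarse subgroups:

* histology mix 66.0% ADC / 34.0% SCC (published);
* sub-stage composition from the published patient counts
  (IA 27,193 … IV 48,619, total 124,788), split evenly across the coarse
  cells of each sub-stage;
* exponential event times per histology × sub-stage cell. Rates come from
  `rate_from_css(S₅, 60) = −ln(S₅)/60`. Four histology-specific 5-year CSS
  values are published (ADC IB 56.3%, SCC IA 56.1%, ADC IIB 43.5%,
  SCC IB 43.6%) and are used exactly (`source="printed"`). Every other
  histology × sub-stage cell multiplies the pooled sub-stage rate by a
  proportional-hazards factor φ_h = mean of ln(S_hist)/ln(S_pooled) over
  that histology's printed cells (φ_ADC ≈ 0.871, φ_SCC ≈ 1.344); these are
  flagged `source="interpolated"` in the config dump;
* independent Uniform(0, 120)-month censoring (a 10-year accrual window
  with study-end cutoff); time = min(event, censor), event indicator
  accordingly;
* fine T/M subdescriptors are drawn uniformly among the fine cells
  consistent with the coarse key, restricted by the sub-stage the cell was
  calibrated for (so a T2N0 cell calibrated as IB emits only T2a).

Known limitations: exponential hazards are memoryless (real
cancer-specific hazards fall with time since diagnosis), censoring is
independent and uniform rather than empirically shaped, within-sub-stage
heterogeneity beyond histology is absent, and the headline registry
quantities (C-index 0.722 vs 0.643, the published adjacent-stage HR table)
depend on the real cohort's correlation structure and are **not**
reproduction targets — acceptance is property-based plus calibration
round-trips against the printed rates, and a qualitative direction check
(criterion 8: on a cohort where ADC sits one hazard tier better than SCC
within each anatomic cell, the derived regrouping's C-index is at least the
8th edition's).

`tiered_config` plants explicit per-subgroup exponential rates and is the
harness for the cluster-recovery and discrimination tests.

## 7. Reproducibility

One seed drives everything. The pipeline derives named 31-bit substream
seeds with `numpy.random.SeedSequence(seed).spawn` (one per random stage:
simulation, each C-index bootstrap, each calibration bootstrap), so stages
are independently reproducible and two runs with the same seed write
byte-identical artifacts regardless of output directory (tested at the byte
level). `scripts/acceptance.py` uses the same spawning scheme for its six
targets. Cohort CSVs store times via `repr(float)` for lossless round-trips.

## 8. Problem sizes and budgets

The full test suite (unit + property + acceptance) runs in well under a
minute on a single core; the largest acceptance problems are 100 Cox
replicates at 2,000 patients each, six KM round-trips at 20,000 patients,
and two 16,000-patient clustering runs. `lungstage run-all` at the default
n = 20,000 and B = 1000 bootstrap replicates completes in a few minutes.
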