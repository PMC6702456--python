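import numpy as np
import pytest

from lungstage.evaluate import (
    calibration_points,
    cox_two_group,
    harrell_c,
    hazard_ratio_adjacent_stages,
)
from lungstage.staging_maps import (
    SUBSTAGES,
    TNMCategory,
    eighth_edition_map,
)
from lungstage.survival_core import CohortRecord

from conftest import exponential_records, make_records

EIGHTH = eighth_edition_map()

# One fine TNM cell per 8th-edition sub-stage, used to plant stage-specific
# hazards in synthetic cohorts.
CELL_OF_SUBSTAGE = {
    "IA": TNMCategory("ADC", "T1a", "N0", "M0"),
    "IB": TNMCategory("ADC", "T2a", "N0", "M0"),
    "IIA": TNMCategory("ADC", "T2b", "N0", "M0"),
    "IIB": TNMCategory("ADC", "T3", "N0", "M0"),
    "IIIA": TNMCategory("ADC", "T4", "N0", "M0"),
    "IIIB": TNMCategory("ADC", "T3", "N2", "M0"),
    "IIIC": TNMCategory("ADC", "T3", "N3", "M0"),
    "IV": TNMCategory("ADC", "T1a", "N0", "M1a"),
}


def staged_cohort(rates_by_substage, n_per_group, seed, snap=True):
    recs = []
    for i, (sub, rate) in enumerate(rates_by_substage.items()):
        recs += exponential_records(rate, n_per_group, seed=seed + i,
                                    snap_months=snap,
                                    category=CELL_OF_SUBSTAGE[sub],
                                    prefix=f"{sub}_")
    return recs


class TestCoxTwoGroup:
    def test_identical_groups_hr_one(self):
        recs = make_records([2, 5, 7, 9, 12], events=[1, 1, 0, 1, 1])
        fit = cox_two_group(recs, list(recs))
        assert fit.beta == pytest.approx(0.0, abs=1e-10)
        assert fit.hr == pytest.approx(1.0)
        assert fit.converged

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_grid_search_oracle_on_toy_data(self, ties):
        """Newton-Raphson lands on the partial-likelihood maximum found by a
        dense grid search."""
        a = make_records([1, 3, 5, 7, 9], events=[1, 0, 1, 1, 0])
        b = make_records([2, 2, 4, 6, 8], events=[1, 1, 0, 1, 1], prefix="b")
        fit = cox_two_group(a, b, ties=ties)

        times = np.array([r.time for r in a + b])
        events = np.array([r.event for r in a + b])
        x = np.array([0] * 5 + [1] * 5)

        def loglik(beta):
            ll = 0.0
            for t in np.unique(times[events == 1]):
                at_risk = times >= t
                dead = (times == t) & (events == 1)
                d = dead.sum()
                ll += beta * x[dead].sum()
                if ties == "breslow":
                    ll -= d * np.log(np.exp(beta * x[at_risk]).sum())
                else:
                    full = np.exp(beta * x[at_risk]).sum()
                    tied = np.exp(beta * x[dead]).sum()
                    for ell in range(d):
                        ll -= np.log(full - ell / d * tied)
            return ll

        grid = np.linspace(fit.beta - 2, fit.beta + 2, 40001)
        best = grid[np.argmax([loglik(b_) for b_ in grid])]
        assert fit.beta == pytest.approx(best, abs=1e-4)

    def test_breslow_matches_scikit_survival(self):
        sksurv_lm = pytest.importorskip("sksurv.linear_model")
        a = exponential_records(0.05, 400, seed=1)
        b = exponential_records(0.10, 400, seed=2)
        fit = cox_two_group(a, b, ties="breslow")
        y = np.array([(True, r.time) for r in a + b],
                     dtype=[("e", bool), ("t", float)])
        X = np.array([[0.0]] * 400 + [[1.0]] * 400)
        ref = sksurv_lm.CoxPHSurvivalAnalysis(ties="breslow").fit(X, y)
        assert fit.beta == pytest.approx(float(ref.coef_[0]), abs=1e-6)

    def test_efron_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        a = exponential_records(0.05, 300, seed=3)
        b = exponential_records(0.10, 300, seed=4)
        fit = cox_two_group(a, b, ties="efron")
        df = pd.DataFrame({"t": [r.time for r in a + b],
                           "e": [r.event for r in a + b],
                           "x": [0] * 300 + [1] * 300})
        ref = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert fit.beta == pytest.approx(float(ref.params_["x"]), abs=1e-6)
        assert fit.se == pytest.approx(float(ref.standard_errors_["x"]), abs=1e-6)

    def test_parameter_recovery_true_hr_two(self):
        a = exponential_records(0.05, 5000, seed=5, snap_months=False)
        b = exponential_records(0.10, 5000, seed=6, snap_months=False)
        fit = cox_two_group(a, b)
        assert 1.8 <= fit.hr <= 2.2
        assert fit.ci95[0] < fit.hr < fit.ci95[1]

    def test_complete_separation_flagged_not_raised(self):
        a = make_records([10, 11, 12], events=[0, 0, 0])
        b = make_records([1, 2, 3], events=[1, 1, 1], prefix="b")
        fit = cox_two_group(a, b)
        assert not fit.converged
        assert fit.ci95 == (0.0, float("inf"))

    def test_zero_events_error(self):
        a = make_records([1, 2], events=[0, 0])
        with pytest.raises(ValueError, match="event"):
            cox_two_group(a, list(a))


class TestAdjacentHazardRatios:
    def test_row_counts(self):
        rates = {s: 0.005 * 2 ** i for i, s in enumerate(SUBSTAGES)}
        recs = staged_cohort(rates, 150, seed=7)
        assert len(hazard_ratio_adjacent_stages(recs, EIGHTH, "stage")) == 3
        assert len(hazard_ratio_adjacent_stages(recs, EIGHTH, "substage")) == 7

    def test_identical_survival_gives_unit_hr(self):
        rates = {s: 0.02 for s in SUBSTAGES}
        recs = staged_cohort(rates, 400, seed=8)
        fits = hazard_ratio_adjacent_stages(recs, EIGHTH, "stage")
        for row in fits:
            assert row.fit.ci95[0] < 1.0 < row.fit.ci95[1]

    def test_planted_stage_hazards_recovered(self):
        """With hazards 0.005/0.02/0.06/0.15 per stage, every adjacent HR is
        below 1 (earlier over later) and significant."""
        stage_rates = {"IA": 0.005, "IB": 0.005, "IIA": 0.02, "IIB": 0.02,
                       "IIIA": 0.06, "IIIB": 0.06, "IIIC": 0.06, "IV": 0.15}
        recs = staged_cohort(stage_rates, 700, seed=9)
        fits = hazard_ratio_adjacent_stages(recs, EIGHTH, "stage")
        assert len(fits) == 3
        for row in fits:
            assert row.fit.hr < 1.0
            assert row.fit.p < 0.05

    def test_empty_group_skipped(self):
        rates = {"IA": 0.01, "IV": 0.1}
        recs = staged_cohort(rates, 100, seed=10)
        fits = hazard_ratio_adjacent_stages(recs, EIGHTH, "stage")
        assert [(f.earlier, f.later) for f in fits] == []


def brute_force_concordance(times, ranks, events):
    """Exhaustive pairwise enumeration of Harrell's C for an ordinal predictor."""
    conc = tie = comp = 0.0
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                if events[i] + events[j] != 1:
                    continue
                short, lng = (i, j) if events[i] == 1 else (j, i)
            elif times[i] < times[j]:
                if events[i] != 1:
                    continue
                short, lng = i, j
            else:
                if events[j] != 1:
                    continue
                short, lng = j, i
            comp += 1
            if ranks[short] > ranks[lng]:
                conc += 1
            elif ranks[short] == ranks[lng]:
                tie += 1
    if comp == 0:
        return 0.5, 0.0
    return (conc + 0.5 * tie) / comp, comp


def random_staged_cohort(rng, n):
    cells = list(CELL_OF_SUBSTAGE.values())
    recs = []
    for i in range(n):
        cell = cells[rng.integers(0, len(cells))]
        recs.append(CohortRecord(
            patient_id=f"r{i}", category=cell,
            time=float(rng.integers(1, 40)), event=int(rng.integers(0, 2))))
    return recs


class TestHarrellC:
    def test_perfect_ordering_gives_one(self):
        # Stage order exactly orders uncensored survival times.  Times are
        # tied within each sub-stage so every comparable pair crosses groups
        # (within-group pairs share a rank and would count 0.5).
        recs = []
        for i, sub in enumerate(SUBSTAGES):
            times = [1000.0 - 100 * i] * 10
            recs += make_records(times, category=CELL_OF_SUBSTAGE[sub],
                                 prefix=f"{sub}_")
        res = harrell_c(recs, EIGHTH, level="substage", n_boot=0)
        assert res.c == 1.0

    def test_single_stage_gives_half(self):
        recs = make_records([1, 2, 3, 4, 5])
        res = harrell_c(recs, EIGHTH, level="stage", n_boot=0)
        assert res.c == 0.5

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(50):
            n = int(rng.integers(10, 100))
            recs = random_staged_cohort(rng, n)
            if sum(r.event for r in recs) == 0:
                continue
            for level in ("stage", "substage"):
                res = harrell_c(recs, EIGHTH, level=level, n_boot=0)
                ranks = [EIGHTH.stage_of_category(r.category).stage_rank
                         if level == "stage"
                         else EIGHTH.stage_of_category(r.category).substage_rank
                         for r in recs]
                c_ref, n_ref = brute_force_concordance(
                    [r.time for r in recs], ranks, [r.event for r in recs])
                assert res.c == pytest.approx(c_ref, abs=1e-12)
                assert res.n_pairs == n_ref

    def test_matches_sksurv_on_tie_free_data(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(77)
        cells = list(CELL_OF_SUBSTAGE.values())
        recs = [CohortRecord(f"s{i}", cells[rng.integers(0, 8)],
                             float(rng.exponential(30)), int(rng.integers(0, 2)))
                for i in range(300)]
        res = harrell_c(recs, EIGHTH, level="substage", n_boot=0)
        ranks = np.array([EIGHTH.stage_of_category(r.category).substage_rank
                          for r in recs], dtype=float)
        ref = sksurv_metrics.concordance_index_censored(
            np.array([bool(r.event) for r in recs]),
            np.array([r.time for r in recs]), ranks)
        assert res.c == pytest.approx(float(ref[0]), abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self):
        rates = {s: 0.004 * 2 ** i for i, s in enumerate(SUBSTAGES)}
        recs = staged_cohort(rates, 60, seed=13)
        res = harrell_c(recs, EIGHTH, level="substage", n_boot=200, seed=1)
        assert res.ci95[0] <= res.c <= res.ci95[1]


class TestCalibration:
    def test_self_calibration_is_exact(self):
        rates = {s: 0.005 * 2 ** i for i, s in enumerate(SUBSTAGES)}
        recs = staged_cohort(rates, 120, seed=15)
        rows = calibration_points(recs, recs, EIGHTH, n_boot=50, seed=2)
        for row in rows:
            assert row.predicted == pytest.approx(row.observed)
            assert 0.0 <= row.predicted <= 1.0
            assert row.ci95[0] <= row.observed <= row.ci95[1]

    def test_well_specified_model_recovers(self):
        """Test cohort drawn from the training cohort's true per-stage
        exponential rates: predicted and observed agree to within Monte-Carlo
        noise at n = 10,000."""
        stage_rates = {"IA": 0.008, "IB": 0.008, "IIA": 0.025, "IIB": 0.025,
                       "IIIA": 0.06, "IIIB": 0.06, "IIIC": 0.06, "IV": 0.15}
        train = staged_cohort(stage_rates, 1250, seed=16, snap=False)
        test = staged_cohort(stage_rates, 1250, seed=61, snap=False)
        rows = calibration_points(train, test, EIGHTH, n_boot=0)
        assert rows, "no calibration rows produced"
        for row in rows:
            assert abs(row.predicted - row.observed) < 0.02

    def test_missing_test_group_omitted(self):
        train = staged_cohort({"IA": 0.01, "IV": 0.1}, 100, seed=17)
        test = staged_cohort({"IA": 0.01}, 100, seed=18)
        rows = calibration_points(train, test, EIGHTH, n_boot=0)
        assert {r.group.stage for r in rows} == {"I"}
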