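"""Kaplan-Meier estimation and log-rank machinery on a monthly grid.

Two routes to the same statistic live here on purpose.  ``logrank_patient``
is the classical two-sample log-rank test on patient-level records and acts
as the reference.  ``curve_chi2_distance`` computes the same chi-square from
two survival *curves* alone, replacing risk-set counts by N x accumulated
survival proportions — the large-N limit used to turn the log-rank statistic
into a distance between Kaplan-Meier curves for clustering.  With the
optional finite-N variance correction the two agree exactly on uncensored
groups whose event times sit on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .staging_maps import TNMCategory

DEFAULT_GRID_STEP = 1.0  # months; registry survival is month-granular


@dataclass(frozen=True)
class CohortRecord:
    """One patient: TNM classification, follow-up in months, cancer-death flag."""

    patient_id: str
    category: TNMCategory
    time: float
    event: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(
                f"patient {self.patient_id}: follow-up time must be finite and "
                f"non-negative, got {self.time!r}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"patient {self.patient_id}: event must be 0 (censored) or 1 "
                f"(cancer death), got {self.event!r}"
            )


@dataclass
class SurvivalCurve:
    """Step survival function S(t) on an increasing grid, with S(0) = 1 implicit.

    ``grid[k]`` is the right end of interval k; ``s[k]`` the survival
    probability there.  ``n_at_risk``/``n_events`` are per-interval counts
    when the curve came from a Kaplan-Meier fit.
    """

    grid: np.ndarray
    s: np.ndarray
    n_at_risk: Optional[np.ndarray] = None
    n_events: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.s.shape:
            raise ValueError("grid and s must be 1-d arrays of equal length")
        if len(self.grid) and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if len(self.grid) and self.grid[0] <= 0:
            raise ValueError("grid points must be positive (t0 = 0 is implicit)")
        if np.any(self.s < -1e-12) or np.any(self.s > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(np.concatenate(([1.0], self.s))) > 1e-12):
            raise ValueError("survival must be non-increasing with S(0) = 1")


@dataclass(frozen=True)
class LogrankResult:
    """Log-rank chi-square statistic with its two-sided chi2(1 df) p-value."""

    chi2: float
    p: float


def km_estimate(records: Sequence[CohortRecord],
                grid_step: float = DEFAULT_GRID_STEP) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate evaluated on a monthly grid.

    Censored subjects leave risk sets without a survival drop; at a tied time
    point events are processed before censorings (the censored subject is
    still at risk for the tied event).  The grid spans ``grid_step`` up to
    the last observed follow-up, inclusive.
    """
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    # Product-limit factors at distinct event times.
    n = len(times)
    s_run = 1.0
    event_times: List[float] = []
    s_values: List[float] = []
    d_at: List[int] = []
    r_at: List[int] = []
    i = 0
    while i < n:
        t = times[i]
        j = i
        d = 0
        while j < n and times[j] == t:
            d += int(events[j])
            j += 1
        at_risk = n - i  # ties: censorings at t remain at risk for events at t
        if d > 0:
            s_run *= 1.0 - d / at_risk
            event_times.append(t)
            s_values.append(s_run)
            d_at.append(d)
            r_at.append(at_risk)
        i = j

    t_max = float(times[-1])
    n_points = max(1, int(np.ceil(t_max / grid_step - 1e-9)))
    grid = grid_step * np.arange(1, n_points + 1)

    ev = np.array(event_times, dtype=float)
    sv = np.array(s_values, dtype=float)
    # Right-continuous step lookup: S(g) = value at last event time <= g.
    idx = np.searchsorted(ev, grid, side="right") - 1
    s = np.where(idx >= 0, sv[np.maximum(idx, 0)], 1.0) if len(ev) else np.ones_like(grid)

    # Per-interval bookkeeping on the grid: events in (g_{k-1}, g_k], at risk
    # at the interval start.
    edges = np.concatenate(([0.0], grid))
    n_events_grid = np.histogram(times[events == 1], bins=edges)[0]
    n_at_risk_grid = np.array([(times > e).sum() + (times == e).sum() if e == 0
                               else (times > e).sum()
                               for e in edges[:-1]])
    return SurvivalCurve(grid=grid, s=s,
                         n_at_risk=n_at_risk_grid.astype(int),
                         n_events=n_events_grid.astype(int))


def css_at(curve: SurvivalCurve, horizon: float) -> float:
    """Survival probability S(horizon) of a step curve (right-continuous).

    A horizon beyond the last grid point returns the last observed value
    (an extrapolation; callers needing the flag use :func:`css_at_flagged`).
    """
    value, _ = css_at_flagged(curve, horizon)
    return value


def css_at_flagged(curve: SurvivalCurve, horizon: float) -> Tuple[float, bool]:
    """Like :func:`css_at` but also reports whether the value is extrapolated."""
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0 or len(curve.grid) == 0:
        return 1.0, False
    idx = np.searchsorted(curve.grid, horizon, side="right") - 1
    if idx < 0:
        return 1.0, False
    extrapolated = horizon > curve.grid[-1]
    return float(curve.s[min(idx, len(curve.s) - 1)]), bool(extrapolated)


def regrid(curve: SurvivalCurve, grid: Union[Sequence[float], np.ndarray]) -> SurvivalCurve:
    """Right-continuous step interpolation of a curve onto a new grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (len(grid) > 1 and not np.all(np.diff(grid) > 0)):
        raise ValueError("target grid must be strictly increasing")
    s = np.array([css_at(curve, g) for g in grid])
    return SurvivalCurve(grid=grid, s=s)


def logrank_patient(group_a: Sequence[CohortRecord],
                    group_b: Sequence[CohortRecord]) -> LogrankResult:
    """Classical two-sample log-rank test on patient-level records.

    Per distinct event time: observed minus expected events in group A under
    the hypergeometric model, with the matching variance; the statistic is
    (sum(O - E))^2 / sum(V) on 1 df.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta = np.array([r.time for r in group_a], dtype=float)
    ea = np.array([r.event for r in group_a], dtype=int)
    tb = np.array([r.time for r in group_b], dtype=float)
    eb = np.array([r.event for r in group_b], dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank statistic undefined with zero events")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        da = ((ta == t) & (ea == 1)).sum()
        db = ((tb == t) & (eb == 1)).sum()
        n_tot = na + nb
        d = da + db
        if n_tot == 0 or d == 0:
            continue
        e_a = na * d / n_tot
        o_minus_e += da - e_a
        if n_tot > 1:
            var += d * (n_tot - d) * na * nb / (n_tot ** 2 * (n_tot - 1))
    if var <= 0:
        return LogrankResult(chi2=0.0, p=1.0)
    chi2 = o_minus_e ** 2 / var
    return LogrankResult(chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1)))


def curve_chi2_distance(a: SurvivalCurve, b: SurvivalCurve,
                        n_per_group: Union[int, str] = "infinite",
                        finite_correction: bool = False) -> LogrankResult:
    """Log-rank chi-square distance between two survival curves.

    Treats both curves as arising from equal-size groups of ``n_per_group``
    patients each (``"infinite"`` returns the per-capita statistic, which is
    what the clustering distance matrix uses — the common factor N cannot
    change the clustering).  Risk sets are N x the accumulated survival
    proportions a_{i-1}, b_{i-1}; per interval i with increments
    da = a_{i-1} - a_i, db = b_{i-1} - b_i, d = da + db, n = a_{i-1} + b_{i-1}:

        O_i = da,   E_i = a_{i-1} d / n,
        V_i = a_{i-1} b_{i-1} d (a_i + b_i) / n^3,

    and chi2_percapita = (sum(O - E))^2 / sum(V).  Because the curve-only view
    has no censoring, a_i + b_i = n - d and V_i is the large-N limit of the
    hypergeometric variance.  ``finite_correction`` replaces N n by N n - 1
    in the variance denominator, reproducing the patient-level statistic
    exactly for uncensored grid-aligned groups (requires a finite N).
    """
    if len(a.grid) != len(b.grid) or not np.allclose(a.grid, b.grid):
        raise ValueError(
            "curves are on incompatible grids; regrid() both onto a shared "
            "monthly grid first"
        )
    infinite = isinstance(n_per_group, str)
    if infinite and n_per_group != "infinite":
        raise ValueError("n_per_group must be a positive integer or 'infinite'")
    if not infinite and n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    if finite_correction and infinite:
        raise ValueError("finite_correction requires a finite n_per_group")

    sa = np.concatenate(([1.0], a.s))
    sb = np.concatenate(([1.0], b.s))
    a_prev, a_cur = sa[:-1], sa[1:]
    b_prev, b_cur = sb[:-1], sb[1:]
    da = a_prev - a_cur
    db = b_prev - b_cur
    d = da + db
    n_risk = a_prev + b_prev

    active = (d > 0) & (n_risk > 0)
    o_minus_e = np.zeros_like(d)
    o_minus_e[active] = da[active] - a_prev[active] * d[active] / n_risk[active]

    v = np.zeros_like(d)
    if finite_correction:
        n_int = float(n_per_group)
        # Exact hypergeometric variance with counts N * proportions.
        num = (n_int ** 2) * a_prev * b_prev * d * (n_risk - d)
        den = n_risk ** 2 * (n_int * n_risk - 1)
        ok = active & (n_int * n_risk > 1)
        v[ok] = num[ok] / den[ok]
        sum_v = v.sum()
        if sum_v <= 0:
            return LogrankResult(chi2=0.0, p=1.0)
        # (N * sum(O - E))^2 / sum(V_N)
        chi2 = (n_int ** 2) * (o_minus_e.sum()) ** 2 / sum_v
    else:
        v[active] = (a_prev[active] * b_prev[active] * d[active]
                     * (a_cur[active] + b_cur[active]) / n_risk[active] ** 3)
        sum_v = v.sum()
        if sum_v <= 0:
            return LogrankResult(chi2=0.0, p=1.0)
        chi2_percapita = o_minus_e.sum() ** 2 / sum_v
        chi2 = chi2_percapita if infinite else float(n_per_group) * chi2_percapita
    chi2 = float(max(chi2, 0.0))
    return LogrankResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)))


def curve_to_tsv(curve: SurvivalCurve) -> str:
    """Serialize a curve as TSV (time_months, survival, n_at_risk, n_events)."""
    lines = ["time_months\tsurvival\tn_at_risk\tn_events"]
    nar = curve.n_at_risk if curve.n_at_risk is not None else [""] * len(curve.grid)
    nev = curve.n_events if curve.n_events is not None else [""] * len(curve.grid)
    for t, s, r, e in zip(curve.grid, curve.s, nar, nev):
        lines.append(f"{t:g}\t{s:.10g}\t{r}\t{e}")
    return "\n".join(lines) + "\n"
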