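"""Comparison of staging systems: hazard ratios, concordance, calibration.

A staging system is judged by three standard yardsticks: Cox hazard ratios
between adjacent stages (a well-separated system has ratios well below 1,
earlier stage over later), Harrell's concordance index of the ordinal stage
rank against cancer-specific survival, and calibration of training-cohort
Kaplan-Meier predictions against held-out observations at 3 and 5 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .staging_maps import STAGES, SUBSTAGES, StageLabel, StageMap
from .survival_core import CohortRecord

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CoxFit:
    """Two-group Cox proportional-hazards fit (single binary covariate)."""

    beta: float
    se: float
    hr: float
    ci95: Tuple[float, float]
    p: float
    converged: bool
    n_events: int


@dataclass(frozen=True)
class AdjacentHR:
    """Hazard ratio of the earlier stage relative to the adjacent later stage."""

    earlier: str
    later: str
    fit: CoxFit


@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    ci95: Tuple[float, float]
    n_pairs: float
    degenerate: bool = False


@dataclass(frozen=True)
class CalibrationRow:
    group: StageLabel
    horizon: float
    predicted: float
    observed: float
    ci95: Tuple[float, float]


def _risk_table(times: np.ndarray, events: np.ndarray, x: np.ndarray):
    """Per distinct event time: at-risk counts and event counts by covariate arm."""
    order = np.argsort(times, kind="stable")
    times, events, x = times[order], events[order], x[order]
    event_times = np.unique(times[events == 1])
    n0 = np.array([((times >= t) & (x == 0)).sum() for t in event_times], dtype=float)
    n1 = np.array([((times >= t) & (x == 1)).sum() for t in event_times], dtype=float)
    d0 = np.array([((times == t) & (events == 1) & (x == 0)).sum()
                   for t in event_times], dtype=float)
    d1 = np.array([((times == t) & (events == 1) & (x == 1)).sum()
                   for t in event_times], dtype=float)
    return n0, n1, d0, d1


def _cox_score_info(beta: float, n0, n1, d0, d1, ties: str):
    """Score U(beta) and observed information I(beta) for the binary covariate."""
    eb = np.exp(beta)
    if ties == "breslow":
        pi = n1 * eb / (n0 + n1 * eb)
        d = d0 + d1
        u = float(np.sum(d1 - d * pi))
        info = float(np.sum(d * pi * (1.0 - pi)))
        return u, info
    # Efron: within a tie of d events, the event group's contribution to the
    # denominator is removed in fractions l/d, l = 0..d-1.
    u = 0.0
    info = 0.0
    for k in range(len(n0)):
        d = int(d0[k] + d1[k])
        if d == 0:
            continue
        for ell in range(d):
            frac = ell / d
            denom = (n0[k] - frac * d0[k]) + (n1[k] - frac * d1[k]) * eb
            pi = (n1[k] - frac * d1[k]) * eb / denom
            u += (d1[k] / d) - pi
            info += pi * (1.0 - pi)
    return float(u), float(info)


def cox_two_group(group_a: Sequence[CohortRecord],
                  group_b: Sequence[CohortRecord],
                  ties: str = "breslow",
                  tol: float = 1e-8,
                  max_iter: int = 50) -> CoxFit:
    """Cox fit of a single binary covariate (1 = group B) by Newton-Raphson.

    Breslow tie handling by default (month-granular data has heavy ties);
    ``ties="efron"`` is available.  Monotone partial likelihood (all events
    in one arm) or non-convergence yields a flagged fit with infinite-bound
    confidence interval rather than an exception.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    times = np.array([r.time for r in group_a] + [r.time for r in group_b])
    events = np.array([r.event for r in group_a] + [r.event for r in group_b])
    x = np.array([0] * len(group_a) + [1] * len(group_b))
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("Cox fit requires at least one event")

    n0, n1, d0, d1 = _risk_table(times, events, x)

    def flagged(beta: float) -> CoxFit:
        hr = float(np.exp(np.clip(beta, -700, 700)))
        return CoxFit(beta=float(beta), se=float("inf"), hr=hr,
                      ci95=(0.0, float("inf")), p=float("nan"),
                      converged=False, n_events=n_events)

    if d1.sum() == 0 or d0.sum() == 0:
        # Complete separation of event arms: likelihood is monotone in beta.
        return flagged(float("-inf") if d1.sum() == 0 else float("inf"))

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        u, info = _cox_score_info(beta, n0, n1, d0, d1, ties)
        if info <= 0:
            return flagged(beta)
        step = u / info
        beta += step
        if abs(beta) > 15:
            return flagged(beta)
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        return flagged(beta)

    _, info = _cox_score_info(beta, n0, n1, d0, d1, ties)
    se = float(1.0 / np.sqrt(info))
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return CoxFit(beta=float(beta), se=se, hr=hr, ci95=ci, p=p,
                  converged=True, n_events=n_events)


def _stage_groups(records: Sequence[CohortRecord], stage_map: StageMap,
                  level: str) -> Dict[str, List[CohortRecord]]:
    if level not in ("stage", "substage"):
        raise ValueError("level must be 'stage' or 'substage'")
    names = STAGES if level == "stage" else SUBSTAGES
    groups: Dict[str, List[CohortRecord]] = {name: [] for name in names}
    for r in records:
        label = stage_map.stage_of_category(r.category)
        groups[label.stage if level == "stage" else label.substage].append(r)
    return groups


def hazard_ratio_adjacent_stages(records: Sequence[CohortRecord],
                                 stage_map: StageMap,
                                 level: str = "stage",
                                 ties: str = "breslow") -> List[AdjacentHR]:
    """One Cox fit per adjacent stage pair, earlier stage over later (HR < 1 good).

    Pairs in which either group is empty (or has no events) are skipped with
    a logged warning.
    """
    groups = _stage_groups(records, stage_map, level)
    names = STAGES if level == "stage" else SUBSTAGES
    out: List[AdjacentHR] = []
    for earlier, later in zip(names[:-1], names[1:]):
        ga, gb = groups[earlier], groups[later]
        if not ga or not gb:
            logger.warning("skipping %s to %s: empty stage group", earlier, later)
            continue
        if sum(r.event for r in ga) + sum(r.event for r in gb) == 0:
            logger.warning("skipping %s to %s: no events", earlier, later)
            continue
        # Covariate 1 = earlier stage, so hr = hazard(earlier) / hazard(later).
        fit = cox_two_group(gb, ga, ties=ties)
        out.append(AdjacentHR(earlier=earlier, later=later, fit=fit))
    return out


def _concordance_counts(times: np.ndarray, ranks: np.ndarray,
                        events: np.ndarray, n_levels: int):
    """Concordant / tied / comparable pair counts for an ordinal risk predictor.

    A pair is comparable when the strictly shorter time carries an event, or
    when times tie with exactly one event (the death precedes the censoring).
    Concordant: the higher predicted rank (higher risk) dies first; rank ties
    credit 0.5.  Linear sweep over decreasing time with one counter per rank.
    """
    order = np.argsort(times, kind="stable")[::-1]
    times, ranks, events = times[order], ranks[order], events[order]
    later_counts = np.zeros(n_levels, dtype=np.int64)
    concordant = 0.0
    tied = 0.0
    comparable = 0.0
    i = 0
    n = len(times)
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        block = slice(i, j)
        ev = events[block] == 1
        ev_ranks = ranks[block][ev]
        cen_ranks = ranks[block][~ev]
        # events at t vs everyone with strictly longer time
        cum_lower = np.concatenate(([0], np.cumsum(later_counts)))
        for r in ev_ranks:
            comparable += later_counts.sum()
            concordant += cum_lower[r]          # later subject has lower risk
            tied += later_counts[r]
        # events at t vs censored at t (death precedes the tied censoring)
        if len(ev_ranks) and len(cen_ranks):
            cen_hist = np.bincount(cen_ranks, minlength=n_levels)
            cum_cen = np.concatenate(([0], np.cumsum(cen_hist)))
            for r in ev_ranks:
                comparable += cen_hist.sum()
                concordant += cum_cen[r]
                tied += cen_hist[r]
        later_counts += np.bincount(ranks[block], minlength=n_levels)
        i = j
    return concordant, tied, comparable


def harrell_c(records: Sequence[CohortRecord], stage_map: StageMap,
              level: str = "stage", n_boot: int = 1000,
              seed: Optional[int] = None) -> ConcordanceResult:
    """Harrell's concordance index of the ordinal stage rank.

    The predictor is the stage (or sub-stage) rank, higher = higher risk.
    The 95% CI is a bootstrap percentile interval over patients
    (``n_boot`` resamples, seeded); ``n_boot=0`` skips the bootstrap and
    returns a degenerate interval at the point estimate.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    names = STAGES if level == "stage" else SUBSTAGES
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=np.int64)
    labels = [stage_map.stage_of_category(r.category) for r in records]
    ranks = np.array([lab.stage_rank if level == "stage" else lab.substage_rank
                      for lab in labels], dtype=np.int64)
    if events.sum() == 0:
        raise ValueError("concordance undefined with zero events")

    def c_of(t, r, e):
        conc, tie, comp = _concordance_counts(t, r, e, len(names))
        if comp == 0:
            return 0.5, 0.0
        return (conc + 0.5 * tie) / comp, comp

    c, n_pairs = c_of(times, ranks, events)
    if n_pairs == 0:
        return ConcordanceResult(c=0.5, ci95=(0.5, 0.5), n_pairs=0.0,
                                 degenerate=True)
    if n_boot <= 0:
        return ConcordanceResult(c=float(c), ci95=(float(c), float(c)),
                                 n_pairs=float(n_pairs))
    rng = np.random.default_rng(seed)
    n = len(records)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b], _ = c_of(times[idx], ranks[idx], events[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ConcordanceResult(c=float(c), ci95=(float(lo), float(hi)),
                             n_pairs=float(n_pairs))


def _km_at(times: np.ndarray, events: np.ndarray, horizon: float) -> float:
    """Product-limit survival at a horizon from raw arrays (fast bootstrap path)."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = len(t)
    s = 1.0
    i = 0
    while i < n and t[i] <= horizon:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += int(e[j])
            j += 1
        if d > 0:
            s *= 1.0 - d / (n - i)
        i = j
    return s


def calibration_points(train: Sequence[CohortRecord],
                       test: Sequence[CohortRecord],
                       stage_map: StageMap,
                       horizons: Sequence[float] = (36.0, 60.0),
                       level: str = "stage",
                       n_boot: int = 1000,
                       seed: Optional[int] = None) -> List[CalibrationRow]:
    """Predicted (training KM) vs observed (test KM) survival per stage group.

    The 95% CI on the observed value is a bootstrap percentile interval over
    test patients of the group.  Groups absent from the test cohort are
    omitted with a logged warning.
    """
    train_groups = _stage_groups(train, stage_map, level)
    test_groups = _stage_groups(test, stage_map, level)
    rng = np.random.default_rng(seed)
    rows: List[CalibrationRow] = []
    names = STAGES if level == "stage" else SUBSTAGES
    for name in names:
        tr, te = train_groups[name], test_groups[name]
        if not tr:
            continue
        if not te:
            logger.warning("calibration: group %s absent from test cohort", name)
            continue
        label = (StageLabel.from_substage(name) if level == "substage"
                 else StageLabel(name, {"I": "IA", "II": "IIA",
                                        "III": "IIIA", "IV": "IV"}[name]))
        tr_t = np.array([r.time for r in tr])
        tr_e = np.array([r.event for r in tr])
        te_t = np.array([r.time for r in te])
        te_e = np.array([r.event for r in te])
        for h in horizons:
            predicted = _km_at(tr_t, tr_e, h)
            observed = _km_at(te_t, te_e, h)
            if n_boot > 0:
                boots = np.empty(n_boot)
                m = len(te)
                for b in range(n_boot):
                    idx = rng.integers(0, m, size=m)
                    boots[b] = _km_at(te_t[idx], te_e[idx], h)
                lo, hi = np.percentile(boots, [2.5, 97.5])
            else:
                lo = hi = observed
            rows.append(CalibrationRow(group=label, horizon=float(h),
                                       predicted=float(predicted),
                                       observed=float(observed),
                                       ci95=(float(lo), float(hi))))
    return rows
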