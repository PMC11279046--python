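"""Step 3: Kaplan-Meier curves, log-rank testing and the constrained
minimal-p cutpoint search.

A probe's prognostic threshold is found by scanning every midpoint
between consecutive distinct beta values, discarding candidates that
would leave either group smaller than ``max(min_group_abs,
ceil(min_group_frac * n))``, and keeping the admissible threshold with
the smallest two-group log-rank p (ties go to the smallest threshold).
The full scan trace is retained so the selection is auditable, and an
opt-in permutation correction guards against the optimism inherent in
minimal-p selection.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "ThresholdResult",
    "km_curve",
    "logrank",
    "threshold_scan",
    "permutation_adjusted_p",
    "km_plot_table",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate for one group."""

    event_times: np.ndarray        # distinct event times, sorted (days)
    at_risk: np.ndarray            # risk-set size just before each event time
    events: np.ndarray             # deaths at each event time
    survival: np.ndarray           # S(t) just after each event time
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12) or np.any(np.diff(self.at_risk) > 0):
            raise ValidationError("survival curve must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "group": self.label,
            }
        )


class LogrankResult(NamedTuple):
    chi2: float
    p_value: float
    n_events: int


@dataclass(frozen=True)
class ThresholdResult:
    probe_id: str
    threshold: float
    hyper_side: str                # which side of the cut is "hyper" (always above)
    n_low: int
    n_high: int
    deaths_low: int
    deaths_high: int
    logrank_chi2: float
    logrank_p: float
    trace: pd.DataFrame            # all candidate thresholds with p and group sizes
    min_group_size: int
    min_group_abs: int
    min_group_frac: float
    n_excluded_missing: int = 0


def km_curve(times, events, label: str = "") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    The curve steps only at event times; censored subjects leave the
    risk set after their time (standard convention: a censoring tied
    with an event is still at risk for that event).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("cannot estimate a survival curve from no subjects")
    if np.any(t <= 0):
        raise ValidationError("survival times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size
    uniq, start = np.unique(t, return_index=True)
    at_risk_all = n - start
    deaths_all = np.add.reduceat(e, start)
    mask = deaths_all > 0
    at_risk, deaths, times_out = at_risk_all[mask], deaths_all[mask], uniq[mask]
    survival = np.cumprod(1.0 - deaths / at_risk)
    return SurvivalCurve(event_times=times_out, at_risk=at_risk, events=deaths,
                         survival=survival, label=label)


def _logrank_many(
    times: np.ndarray, events: np.ndarray, group_high: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Two-group log-rank for many group assignments at once.

    ``group_high`` is an (n, B) boolean matrix: column j assigns each
    subject to the "high" group for threshold j.  Returns (chi2, p)
    arrays of length B plus the total event count.  Uses the standard
    observed-minus-expected statistic with hypergeometric variance over
    distinct event times, chi-square on 1 df.
    """
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    G = group_high[order]
    n = t.size
    uniq, start = np.unique(t, return_index=True)
    at_risk = (n - start).astype(float)                      # (K,)
    d = np.add.reduceat(e, start).astype(float)              # deaths per time
    # group-1 risk sets: suffix sums of membership in time order
    suffix = np.cumsum(G[::-1], axis=0)[::-1].astype(float)  # (n, B)
    n1 = suffix[start]                                       # (K, B)
    d1 = np.add.reduceat(e[:, None] * G, start, axis=0).astype(float)

    mask = d > 0
    n_events = int(d[mask].sum())
    if n_events == 0:
        B = G.shape[1]
        return np.zeros(B), np.ones(B), 0
    dk, nk = d[mask, None], at_risk[mask, None]
    n1k, d1k = n1[mask], d1[mask]
    O = d1k.sum(axis=0)
    E = (dk * n1k / nk).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = dk * (n1k / nk) * (1.0 - n1k / nk) * (nk - dk) / (nk - 1.0)
    var_terms = np.where(nk > 1, var_terms, 0.0)
    V = var_terms.sum(axis=0)
    chi2 = np.where(V > 0, (O - E) ** 2 / np.where(V > 0, V, 1.0), 0.0)
    p = np.where(V > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p, n_events


def logrank(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-sided two-group log-rank test (chi-square, 1 df).

    With zero events in both groups the statistic is 0 and p = 1.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.zeros((times.size, 1), dtype=bool)
    group[: ta.size, 0] = True
    chi2, p, n_events = _logrank_many(times, events, group)
    if n_events == 0:
        logger.warning("log-rank with zero events: statistic undefined, reporting p = 1")
    return LogrankResult(float(chi2[0]), float(p[0]), n_events)


def _align(beta: pd.Series, clinical: ClinicalTable) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Match beta values to clinical rows, dropping patients missing either."""
    shared = [p for p in beta.index if p in clinical.data.index]
    b = beta.loc[shared]
    ok = b.notna()
    n_excluded = len(beta) - int(ok.sum())
    if n_excluded:
        logger.info("threshold scan: %d patients excluded (missing marker or clinical)",
                    n_excluded)
    b = b[ok]
    clin = clinical.data.loc[b.index]
    return (b.to_numpy(dtype=float), clin["time"].to_numpy(dtype=float),
            clin["event"].to_numpy(dtype=int), n_excluded)


def threshold_scan(
    beta: pd.Series,
    clinical: ClinicalTable,
    min_group_frac: float = 0.01,
    min_group_abs: int = 2,
    probe_id: str = "",
) -> ThresholdResult:
    """Constrained minimal-p log-rank cutpoint search for one probe.

    ``beta`` is indexed by patient id.  Candidate thresholds are the
    midpoints of consecutive distinct sorted beta values; candidates
    that leave a group smaller than ``max(min_group_abs,
    ceil(min_group_frac * n))`` are inadmissible.  Among admissible
    candidates the smallest log-rank p wins, ties going to the smallest
    threshold.  The full trace (every candidate with its p and group
    sizes) is kept on the result.
    """
    x, times, events, n_excluded = _align(beta, clinical)
    n = x.size
    floor = max(min_group_abs, 1)
    if n < 2 * floor:
        raise ValidationError(f"need at least {2 * floor} patients, have {n}")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValidationError("all beta values identical: no candidate thresholds")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    min_group = max(min_group_abs, math.ceil(min_group_frac * n))

    high = x[:, None] > candidates[None, :]
    n_high = high.sum(axis=0)
    n_low = n - n_high
    admissible = (n_high >= min_group) & (n_low >= min_group)
    if not admissible.any():
        raise ValidationError(
            f"no admissible threshold: every split leaves a group below "
            f"{min_group} (= max(min_group_abs={min_group_abs}, "
            f"ceil(min_group_frac={min_group_frac} * n={n})))"
        )
    chi2, p, _ = _logrank_many(times, events, high)
    trace = pd.DataFrame(
        {
            "threshold": candidates,
            "n_low": n_low,
            "n_high": n_high,
            "chi2": chi2,
            "p_value": p,
            "admissible": admissible,
        }
    )
    adm = trace[trace["admissible"]]
    best = adm.sort_values(["p_value", "threshold"], kind="mergesort").iloc[0]
    j = int(best.name)
    sel_high = high[:, j]
    return ThresholdResult(
        probe_id=probe_id,
        threshold=float(best["threshold"]),
        hyper_side="above",
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        deaths_low=int(events[~sel_high].sum()),
        deaths_high=int(events[sel_high].sum()),
        logrank_chi2=float(best["chi2"]),
        logrank_p=float(best["p_value"]),
        trace=trace,
        min_group_size=min_group,
        min_group_abs=min_group_abs,
        min_group_frac=min_group_frac,
        n_excluded_missing=n_excluded,
    )


def permutation_adjusted_p(
    beta: pd.Series,
    clinical: ClinicalTable,
    scan_result: ThresholdResult,
    n_permutations: int,
    seed: int,
) -> float:
    """Permutation correction for the optimism of minimal-p selection.

    Survival rows (time, event) are permuted against the beta values and
    the full constrained scan is re-run each time; the adjusted p is
    ``(1 + #{permutation min-p <= observed min-p}) / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    x, times, events, _ = _align(beta, clinical)
    n = x.size
    distinct = np.unique(x)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    high = x[:, None] > candidates[None, :]
    n_high = high.sum(axis=0)
    admissible = (n_high >= scan_result.min_group_size) & \
                 (n - n_high >= scan_result.min_group_size)
    high = high[:, admissible]

    rng = np.random.default_rng(seed)
    observed = scan_result.logrank_p
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        _, p, _ = _logrank_many(times[perm], events[perm], high)
        if p.min() <= observed:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def km_plot_table(
    result: ThresholdResult,
    clinical: ClinicalTable,
    beta: pd.Series,
) -> tuple[SurvivalCurve, SurvivalCurve, pd.DataFrame]:
    """Kaplan-Meier curves of the two groups defined by the selected
    threshold, labeled hypo (below) and hyper (above), plus a tidy
    plot-ready table."""
    x, times, events, _ = _align(beta, clinical)
    high = x > result.threshold
    low_curve = km_curve(times[~high], events[~high], label="hypo")
    high_curve = km_curve(times[high], events[high], label="hyper")
    table = pd.concat([low_curve.to_frame(), high_curve.to_frame()], ignore_index=True)
    table.insert(0, "probe_id", result.probe_id)
    return low_curve, high_curve, table
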