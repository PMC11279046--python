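"""Step 1: paired differential-methylation testing and candidate selection.

For each CpG probe the tumor-minus-normal differences across matched
patients are tested with a paired t test, p-values are adjusted by the
Benjamini-Hochberg step-up at a configured FDR level, and a
complete-separation "effect size" filter keeps only probes whose tumor
and normal value ranges are disjoint across every patient.  Candidates
must pass both filters.
"""
from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MatchedPairSet, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedTResult",
    "paired_t_test",
    "bh_adjust",
    "separation_filter",
    "run_discovery",
    "select_candidates",
    "manhattan_table",
]

# flag labels for degenerate per-probe outcomes
FLAG_OK = ""
FLAG_ZERO_SD = "degenerate: infinite t"
FLAG_ALL_EQUAL = "degenerate: zero difference"
FLAG_TOO_FEW = "skipped: fewer than 2 complete pairs"


class PairedTResult(NamedTuple):
    t_statistic: float
    p_value: float
    mean_difference: float
    n: int
    flag: str


def _complete_diffs(pairs: MatchedPairSet) -> tuple[np.ndarray, np.ndarray]:
    """Tumor-normal differences with per-probe complete-case masking.

    Returns (differences, valid mask), both probes x patients; pairs with
    a missing value on either side are masked for that probe only.
    """
    normal, tumor = pairs.normal_values, pairs.tumor_values
    valid = ~(np.isnan(normal) | np.isnan(tumor))
    return np.where(valid, tumor - normal, np.nan), valid


def _paired_t_table(pairs: MatchedPairSet) -> pd.DataFrame:
    """Vectorized paired t test over every probe.

    t = mean(d) / (sd(d) / sqrt(n)) with the n-1 sample standard
    deviation; two-sided p from the t distribution on n-1 degrees of
    freedom.  Degenerate probes (zero variance, or fewer than two
    complete pairs) are flagged rather than dropped silently.
    """
    diffs, valid = _complete_diffs(pairs)
    n = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(np.where(valid, diffs, np.nan), axis=1)
        sd = np.array([
            np.std(row[ok], ddof=1) if ok.sum() >= 2 else np.nan
            for row, ok in zip(diffs, valid)
        ])
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 1, 1))

    flag = np.full(len(t), FLAG_OK, dtype=object)
    too_few = n < 2
    # sd of a constant difference vector is zero only up to rounding noise
    zero_sd = (~too_few) & (sd <= np.abs(mean) * 1e-12)
    inf_t = zero_sd & (mean != 0.0)
    all_eq = zero_sd & (mean == 0.0)
    flag[too_few] = FLAG_TOO_FEW
    flag[inf_t] = FLAG_ZERO_SD
    flag[all_eq] = FLAG_ALL_EQUAL
    p[inf_t] = 0.0
    p[all_eq] = 1.0
    t[all_eq] = 0.0
    p[too_few] = np.nan
    mean[n == 0] = np.nan

    return pd.DataFrame(
        {
            "probe_id": pairs.probe_ids,
            "n_pairs": n,
            "mean_difference": mean,
            "t_statistic": t,
            "p_value": p,
            "flag": flag,
        }
    )


def paired_t_test(pairs: MatchedPairSet, probe: str) -> PairedTResult:
    """Paired t test of tumor vs normal beta for one probe."""
    i = pairs.normal.data.index.get_loc(probe)
    sub = _paired_t_table(pairs).iloc[i]
    return PairedTResult(
        t_statistic=float(sub["t_statistic"]),
        p_value=float(sub["p_value"]),
        mean_difference=float(sub["mean_difference"]),
        n=int(sub["n_pairs"]),
        flag=str(sub["flag"]),
    )


def bh_adjust(
    p_values: np.ndarray | pd.Series,
    q: float = 0.01,
    method: str = "bh",
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up (default)
    or plain Bonferroni.

    Returns (adjusted values, reject flags).  BH rejects the k smallest
    p-values where k = max{i : p_(i) <= i*q/m}; the adjusted values are
    the standard monotone-enforced ones.  An empty input yields empty
    output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < q <= 1:
        raise ValidationError("the FDR level must lie in (0, 1]")
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValidationError(f"unknown correction method {method!r}")
    reject, q_values, _, _ = multipletests(p, alpha=q, method=sm_method)
    return q_values, reject


def separation_filter(pairs: MatchedPairSet, probe: str) -> str:
    """Complete-separation direction of one probe: ``hyper`` when every
    tumor value exceeds every normal value, ``hypo`` for the reverse,
    ``none`` otherwise (strict inequalities; ties count as overlap)."""
    i = pairs.normal.data.index.get_loc(probe)
    return _separation_directions(pairs)[i]


def _separation_directions(pairs: MatchedPairSet) -> np.ndarray:
    diffs, valid = _complete_diffs(pairs)
    normal = np.where(valid, pairs.normal_values, np.nan)
    tumor = np.where(valid, pairs.tumor_values, np.nan)
    n = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        t_min = np.nanmin(np.where(valid, tumor, np.inf), axis=1)
        t_max = np.nanmax(np.where(valid, tumor, -np.inf), axis=1)
        n_min = np.nanmin(np.where(valid, normal, np.inf), axis=1)
        n_max = np.nanmax(np.where(valid, normal, -np.inf), axis=1)
    out = np.full(len(n), "none", dtype=object)
    enough = n >= 2
    out[enough & (t_min > n_max)] = "hyper"
    out[enough & (t_max < n_min)] = "hypo"
    return out


def run_discovery(
    pairs: MatchedPairSet,
    q: float = 0.01,
    correction: str = "bh",
    separation: bool = True,
) -> pd.DataFrame:
    """Full step-1 table: one row per probe with test, FDR and filter results.

    Columns: probe_id, n_pairs, mean_difference, t_statistic, p_value,
    q_value, rejected, direction, is_candidate, flag.  Probes with fewer
    than two complete pairs are kept in the table (flagged) but excluded
    from the adjustment and can never be candidates.  With
    ``separation=False`` the direction is taken from the sign of the
    mean difference and the range-disjointness requirement is waived.
    """
    records = _paired_t_table(pairs)
    testable = records["p_value"].notna().to_numpy()
    q_values = np.full(len(records), np.nan)
    rejected = np.zeros(len(records), dtype=bool)
    if testable.any():
        q_values[testable], rejected[testable] = bh_adjust(
            records.loc[testable, "p_value"].to_numpy(), q=q, method=correction
        )
    records["q_value"] = q_values
    records["rejected"] = rejected

    if separation:
        direction = _separation_directions(pairs)
    else:
        sign = np.sign(records["mean_difference"].to_numpy())
        direction = np.where(sign > 0, "hyper", np.where(sign < 0, "hypo", "none"))
        direction = np.where(testable, direction, "none")
    records["direction"] = direction
    records["is_candidate"] = rejected & (records["direction"] != "none")
    n_cand = int(records["is_candidate"].sum())
    logger.info("discovery: %d probes tested, %d FDR-significant, %d candidates",
                int(testable.sum()), int(rejected.sum()), n_cand)
    return records


def select_candidates(records: pd.DataFrame, q_threshold: float = 0.01) -> pd.DataFrame:
    """Rows passing both filters, sorted by p ascending then probe id.

    ``records`` must come from :func:`run_discovery` (its ``rejected``
    flags already encode the step-up decision at the level it was run
    with); ``q_threshold`` re-checks the monotone adjusted values so a
    stricter level can be applied post hoc.
    """
    mask = (
        records["rejected"]
        & (records["q_value"] <= q_threshold)
        & (records["direction"] != "none")
    )
    out = records[mask].sort_values(["p_value", "probe_id"], kind="mergesort")
    return out.reset_index(drop=True)


def manhattan_table(
    records: pd.DataFrame,
    annotation: ProbeAnnotation,
    neg_log10_cap: float = 320.0,
) -> tuple[pd.DataFrame, int]:
    """Plot-ready table (chromosome, position, -log10 p, candidate flag).

    Probes absent from the annotation are dropped; the dropped count is
    returned so row conservation is checkable.  Flagged p = 0 records
    are capped at ``neg_log10_cap``.
    """
    ann = annotation.data
    keep = records["probe_id"].isin(ann.index)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("manhattan table: %d probes without annotation dropped", n_dropped)
    sub = records[keep]
    p = sub["p_value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neg = np.where(p > 0, -np.log10(p), neg_log10_cap)
    neg = np.minimum(neg, neg_log10_cap)
    table = pd.DataFrame(
        {
            "probe_id": sub["probe_id"].to_numpy(),
            "chromosome": ann.loc[sub["probe_id"], "chromosome"].to_numpy(),
            "position": ann.loc[sub["probe_id"], "position"].to_numpy(),
            "neg_log10_p": neg,
            "is_candidate": sub["is_candidate"].to_numpy(),
        }
    )
    return table, n_dropped
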