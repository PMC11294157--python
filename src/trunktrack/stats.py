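"""Cohort-level agreement statistics between tracking models.

Each tracking model is compared against the Definition Model across
participants: mean absolute per-participant difference, a Wilcoxon
signed-rank test on the paired differences (the Shapiro-Wilk gate on the
differences is what motivates the nonparametric test), and a two-way
mixed-effects intraclass correlation with its 95% confidence interval,
interpreted as poor (<0.50), moderate (0.50-0.75), good (0.75-0.90) or
excellent (>0.90).
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (AllZeroDifferences, DegenerateVariance, LengthMismatch,
                     MissingReference, SampleTooSmall, SingleSexCohort)
from .metrics import METRIC_NAMES
from .models import TRACKING_MODELS, TrunkModel

ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 25

#: column layout of a metric table
METRIC_TABLE_COLUMNS = ("subject", "sex", "model", "task", "metric", "value")


# ---------------------------------------------------------------------------
# quality control

def qc_filter(cohort, max_dropout_fraction: float = 0.10):
    """Exclude participants whose trials show full-marker-set flicker.

    A participant is excluded when, in any trial, the fraction of frames
    with at least half of ALL markers simultaneously missing exceeds
    *max_dropout_fraction*.  Occlusion limited to individual trunk markers
    does not trigger exclusion.

    *cohort* may be a mapping ``subject -> iterable of MarkerTrialSet`` or
    any object with a ``participants`` attribute whose elements expose
    ``subject`` and ``trials`` (mapping kind -> trial).

    Returns ``(retained_subjects, excluded)`` where *excluded* is a list of
    ``(subject, reason)`` pairs.
    """
    if hasattr(cohort, "participants"):
        groups = {p.subject: list(p.trials.values()) for p in cohort.participants}
    else:
        groups = {s: list(trials) for s, trials in cohort.items()}
    if not groups:
        raise ValueError("cohort is empty")
    retained, excluded = [], []
    for subject, trials in groups.items():
        reason = None
        for trial in trials:
            masks = np.stack([trial.occluded[m] for m in trial.markers])
            n_missing = masks.sum(axis=0)
            flicker = n_missing >= math.ceil(masks.shape[0] / 2)
            frac = float(flicker.mean())
            if frac > max_dropout_fraction:
                reason = (f"{trial.kind}: {frac:.0%} of frames with >= half "
                          "of all markers missing")
                break
        if reason is None:
            retained.append(subject)
        else:
            excluded.append((subject, reason))
    return retained, excluded


# ---------------------------------------------------------------------------
# paired-difference statistics

def mean_paired_difference(values_a, values_b) -> float:
    """Mean over participants of the absolute per-participant difference."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise LengthMismatch("paired samples must be 1-D and equal length")
    return float(np.mean(np.abs(a - b)))


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p for the signed-rank statistic, ties via mid-ranks.

    Dynamic programme over the distribution of W+ with ranks doubled to
    integers, enumerating all 2^n equally likely sign patterns implicitly.
    """
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= 2.0 ** n
    w2 = int(np.rint(2 * w_plus))
    p_le = float(counts[:w2 + 1].sum())
    p_ge = float(counts[w2:].sum())
    return w_plus, min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(diffs, zero_method: str = "wilcox") -> tuple[float, float]:
    """Wilcoxon signed-rank W+ statistic and two-sided p-value.

    Exact distribution (mid-rank ties handled) for n <= 25 after zero
    removal; tie-corrected normal approximation beyond.  Zeros are dropped
    by default (classic Wilcoxon convention); ``zero_method="pratt"``
    keeps them in the ranking.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or d.size < 1:
        raise LengthMismatch("need a 1-D vector of paired differences")
    if np.all(d == 0):
        warnings.warn("all paired differences are zero", AllZeroDifferences)
        return 0.0, 1.0
    if zero_method == "pratt":
        res = sps.wilcoxon(d, zero_method="pratt", method="approx")
        return float(res.statistic), float(res.pvalue)
    d = d[d != 0]
    if d.size <= EXACT_WILCOXON_MAX_N:
        return _exact_signed_rank_p(d)
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False,
                       method="approx")
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (gate for the nonparametric analyses)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not (3 <= x.size <= 5000):
        raise SampleTooSmall("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateVariance("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# intraclass correlation (two-way mixed effects, single measurement)

def icc_two_way_mixed(ratings, form: str = "absolute",
                      confidence: float = 0.95) -> tuple[float, float, float]:
    """ICC of a two-way mixed-effects, single-measurement model.

    ``form="absolute"`` gives McGraw-Wong ICC(A,1) (absolute agreement,
    the default used for model-vs-Definition comparisons); ``form=
    "consistency"`` gives ICC(C,1).  The confidence interval comes from
    the F distribution.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("ratings must be (participants, raters>=2)")
    n, k = X.shape
    if n < 3:
        raise SampleTooSmall("ICC needs at least 3 participants")
    if not np.all(np.isfinite(X)):
        raise ValueError("ratings must be finite")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((X - grand) ** 2))
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 0:
        raise DegenerateVariance("no between-participant variance")
    alpha = 1.0 - confidence
    scale = msr  # degeneracy checks relative to the dominant mean square
    degenerate_err = mse <= 1e-12 * scale

    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if degenerate_err:
            return 1.0, 1.0, 1.0
        F = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = F / sps.f.ppf(1 - alpha / 2, df1, df2)
        f_u = F * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
        return float(icc), float(lo), float(hi)
    if form != "absolute":
        raise ValueError("form must be 'absolute' or 'consistency'")

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if degenerate_err and msc <= 1e-12 * scale:
        # identical columns: point agreement, interval collapses
        return 1.0, 1.0, 1.0
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isinf(a) or np.isinf(b):
        return float(icc), float(icc), float(icc)
    num = (a * msc + b * mse) ** 2
    den = ((a * msc) ** 2 / (k - 1)
           + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    v = num / den if den > 0 else 1.0
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo = (n * (msr - f_l * mse)
          / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
    hi = (n * (f_u * msr - mse)
          / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    lo, hi = min(lo, icc), max(hi, icc)
    return float(icc), float(lo), float(hi)


def icc_band(icc: float) -> str:
    """Agreement band: poor <0.50 <= moderate <0.75 <= good <=0.90 < excellent."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# cohort comparison tables

def _check_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(METRIC_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"metric table lacks columns {sorted(missing)}")
    return table


def compare_models(table: pd.DataFrame, icc_form: str = "absolute",
                   ) -> pd.DataFrame:
    """Agreement of each tracking model with the Definition Model.

    For every (model, task, metric) the participants' values are paired
    with their Definition-Model values, yielding the mean absolute
    difference, the Wilcoxon signed-rank p on the signed differences, the
    ICC with its 95% CI and the agreement band.  Rows are ordered as
    M-STRN, No-Thorax, No-Sternum x (mean, max, min, ROM) per task.
    """
    table = _check_metric_table(table)
    ref = table[table["model"] == TrunkModel.DEFINITION.value]
    if ref.empty:
        raise MissingReference("no Definition-Model rows in the table")
    ref_idx = ref.set_index(["subject", "task", "metric"])["value"]

    rows = []
    task_order = [t for t in ("gait", "dvj") if t in set(table["task"])]
    for model in TRACKING_MODELS:
        sub = table[table["model"] == model.value]
        if sub.empty:
            continue
        for task in task_order:
            for metric in METRIC_NAMES:
                cell = sub[(sub["task"] == task) & (sub["metric"] == metric)]
                if cell.empty:
                    continue
                cell = cell.sort_values("subject")
                try:
                    ref_vals = ref_idx.loc[
                        [(s, task, metric) for s in cell["subject"]]].to_numpy()
                except KeyError as exc:
                    raise MissingReference(
                        f"Definition value missing for {exc}") from exc
                vals = cell["value"].to_numpy(dtype=float)
                diffs = vals - ref_vals
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", AllZeroDifferences)
                    _, p = wilcoxon_signed_rank(diffs)
                icc, lo, hi = icc_two_way_mixed(
                    np.column_stack([ref_vals, vals]), form=icc_form)
                rows.append({
                    "model": model.value, "task": task, "metric": metric,
                    "n": len(vals),
                    "mean_abs_diff": float(np.mean(np.abs(diffs))),
                    "wilcoxon_p": p,
                    "icc": icc, "icc_ci_low": lo, "icc_ci_high": hi,
                    "band": icc_band(icc),
                })
    return pd.DataFrame(rows)


def sex_difference_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Female/male group means and signed male-minus-female differences.

    Group means are rounded to two decimals before differencing, matching
    the precision at which such tables are reported.
    """
    table = _check_metric_table(table)
    sexes = set(table["sex"].dropna())
    if not {"F", "M"} <= sexes:
        warnings.warn("only one sex label present; differences omitted",
                      SingleSexCohort)
    rows = []
    order = [TrunkModel.DEFINITION, *TRACKING_MODELS]
    task_order = [t for t in ("gait", "dvj") if t in set(table["task"])]
    for model in order:
        sub = table[table["model"] == model.value]
        if sub.empty:
            continue
        for task in task_order:
            for metric in METRIC_NAMES:
                cell = sub[(sub["task"] == task) & (sub["metric"] == metric)]
                if cell.empty:
                    continue
                f_vals = cell[cell["sex"] == "F"]["value"]
                m_vals = cell[cell["sex"] == "M"]["value"]
                f_mean = round(float(f_vals.mean()), 2) if len(f_vals) else np.nan
                m_mean = round(float(m_vals.mean()), 2) if len(m_vals) else np.nan
                diff = (round(m_mean - f_mean, 2)
                        if np.isfinite(f_mean) and np.isfinite(m_mean)
                        else np.nan)
                rows.append({
                    "model": model.value, "task": task, "metric": metric,
                    "female_mean": f_mean, "male_mean": m_mean,
                    "male_minus_female": diff,
                })
    return pd.DataFrame(rows)
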