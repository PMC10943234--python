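"""Session-level behavioral statistics.

Covers the cohort analyses run on the per-subject summaries: a
split-half comparison of freezing totals (habituation check), per-minute
freezing probabilities with a linear trend over bins, and Pearson
correlations of behavioral measures against external covariates with an
optional log transform.

Notes on the statistical choices:

* The split-half comparison is an independent-samples, equal-variance
  t test of per-subject first-half vs second-half freezing totals, so
  with n subjects the degrees of freedom are 2n - 2 (18 subjects give
  df = 34).  A paired test would be the more orthodox design for
  within-subject halves; the independent-samples form is retained
  deliberately to match the published analysis.
* Freezing durations are strongly right-skewed, so correlations can
  log-transform the y variable.  The transform is ln(y + 1); the +1
  offset keeps subjects with zero freezing in the analysis.
* Confidence intervals for Pearson r use the Fisher z transform.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import FreezingBout
from .errors import InputError, UndefinedStatisticError

__all__ = [
    "split_half_totals",
    "split_half_test",
    "minute_bins",
    "grand_mean_trend",
    "correlate",
    "read_subject_table",
    "write_subject_table",
]


def split_half_totals(
    bouts: Sequence[FreezingBout], session_length_s: float
) -> tuple[float, float]:
    """Freezing seconds in the first and second halves of a session.

    A bout straddling the midpoint is apportioned to each half by its
    overlap with that half.
    """
    if session_length_s <= 0:
        raise InputError("session length must be positive")
    mid = session_length_s / 2.0
    first = second = 0.0
    for b in bouts:
        lo = b.start_s
        hi = lo + b.duration_s
        first += max(0.0, min(hi, mid) - lo)
        second += max(0.0, hi - max(lo, mid))
    return first, second


def split_half_test(
    bouts_per_subject: Sequence[Sequence[FreezingBout]],
    session_length_s: float,
) -> tuple[float, int, float]:
    """Independent-samples t test of first- vs second-half freezing.

    Returns (t, df, p) with df = 2n - 2.  Raises
    :class:`UndefinedStatisticError` when both halves have zero
    variance across subjects.
    """
    if len(bouts_per_subject) < 2:
        raise InputError("need at least 2 subjects")
    halves = np.array(
        [split_half_totals(b, session_length_s) for b in bouts_per_subject]
    )
    first, second = halves[:, 0], halves[:, 1]
    if first.std() == 0.0 and second.std() == 0.0:
        if np.allclose(first, second):
            # no variance and no difference: t = 0 by convention
            return 0.0, 2 * len(first) - 2, 1.0
        raise UndefinedStatisticError("zero variance in both halves")
    res = sps.ttest_ind(first, second, equal_var=True)
    df = 2 * len(first) - 2
    return float(res.statistic), df, float(res.pvalue)


def minute_bins(
    bouts: Sequence[FreezingBout],
    n_scores: int,
    fps: float,
    bin_length_s: float = 60.0,
) -> np.ndarray:
    """Per-bin freezing probability for one subject.

    Bins of ``bin_length_s`` partition the trace without overlap (the
    final bin may be shorter); each entry is the fraction of that bin's
    scores that fall inside a freezing bout.
    """
    if n_scores < 1 or fps <= 0 or bin_length_s <= 0:
        raise InputError("invalid bin geometry")
    bin_frames = int(round(bin_length_s * fps))
    if bin_frames < 1 or bin_frames > n_scores:
        raise InputError("session shorter than one bin")
    inside = np.zeros(n_scores, dtype=bool)
    for b in bouts:
        inside[b.start_index : b.end_index + 1] = True
    n_bins = int(np.ceil(n_scores / bin_frames))
    probs = np.empty(n_bins)
    for k in range(n_bins):
        seg = inside[k * bin_frames : (k + 1) * bin_frames]
        probs[k] = seg.mean()
    return probs


def grand_mean_trend(matrix: np.ndarray) -> tuple[float, float]:
    """Linear trend of the grand-mean freezing probability over bins.

    ``matrix`` is subjects x bins.  Returns the Pearson (r, p) of the
    grand mean against the bin index 1..K.  Raises
    :class:`UndefinedStatisticError` when the grand-mean series is
    constant (e.g. a cohort frozen for entire sessions).
    """
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    grand = m.mean(axis=0)
    if grand.size < 3:
        raise InputError("need at least 3 bins for a trend")
    if np.ptp(grand) == 0.0:
        raise UndefinedStatisticError("grand-mean series is constant")
    res = sps.pearsonr(np.arange(1, grand.size + 1, dtype=float), grand)
    return float(res.statistic), float(res.pvalue)


def correlate(
    table: pd.DataFrame,
    x: str,
    y: str,
    log_transform_y: bool = False,
    ci_level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Pearson correlation between two subject-table columns.

    With ``log_transform_y``, y is transformed to ``ln(y + 1)`` first
    (the offset keeps zero-freezing subjects defined).  Returns
    (r, p, (ci_low, ci_high)) with a Fisher-z confidence interval.
    """
    sub = table[[x, y]].dropna()
    if len(sub) < 3:
        raise InputError("need at least 3 complete pairs")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if log_transform_y:
        if np.any(yv < 0):
            raise InputError("log transform requires non-negative y")
        yv = np.log1p(yv)
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise UndefinedStatisticError("correlation undefined for a constant column")
    res = sps.pearsonr(xv, yv)
    ci = res.confidence_interval(confidence_level=ci_level)
    return float(res.statistic), float(res.pvalue), (float(ci.low), float(ci.high))


def write_subject_table(table: pd.DataFrame, path) -> None:
    if "source_id" not in table.columns:
        raise InputError("subject table needs a source_id column")
    table.to_csv(path, index=False)


def read_subject_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "source_id" not in df.columns:
        raise InputError("subject table needs a source_id column")
    if df["source_id"].duplicated().any():
        raise InputError("source_id values must be unique")
    return df
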