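"""Vocal state-change detection by binary segmentation.

Dolphin groups switch between vocal states — bouts of intense whistling,
near silence, and everything in between — on a time scale of roughly a
minute.  This module locates those switches as changepoints in the mean
or in the variance of the (smoothed) per-second whistle-count series,
using greedy binary segmentation with a Gaussian likelihood cost, and
summarizes how many changepoints fall in each experimental period.

Conventions
-----------
A changepoint index ``i`` is a Python slice boundary: the left segment is
``series[:i]`` and the right segment starts at ``series[i]``.  Masked
seconds split the series into contiguous runs that are segmented
independently; a changepoint can never be placed across a gap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


@dataclass
class ChangepointResult:
    """Changepoint locations and per-segment parameter estimates."""

    kind: str                      # "mean" or "variance"
    indices: list[int]             # global slice-boundary positions, sorted
    segment_params: list[float]    # per-segment sample mean or sample variance
    penalty_value: float
    max_cpts: int
    n: int                         # length of the analyzed series
    n_analyzed: int                # number of unmasked points actually segmented

    @property
    def n_changepoints(self) -> int:
        return len(self.indices)


@dataclass
class ChangepointSummary:
    """Per-experiment changepoint counts by period and their differences."""

    cee_id: str
    mean_pre: int
    mean_exposure: int
    mean_post: int
    var_pre: int
    var_exposure: int
    var_post: int

    @property
    def delta_mean(self) -> int:
        return abs(self.mean_pre - self.mean_exposure)

    @property
    def delta_var(self) -> int:
        return abs(self.var_pre - self.var_exposure)


def smooth(values: np.ndarray, window_s: int = 5, mask: np.ndarray | None = None) -> np.ndarray:
    """Centered moving average, shrinking the window symmetrically at edges.

    Masked bins are excluded from their neighbours' averages and come out
    as NaN when every bin in their window is masked.  Accepts a
    :class:`~whistlecee.counting.CountSeries` or a plain array.
    """
    if hasattr(values, "counts"):           # CountSeries duck-typing
        if mask is None:
            mask = values.mask
        values = values.counts
    y = np.asarray(values, dtype=float)
    n = y.size
    if window_s < 1 or window_s % 2 == 0:
        raise ValueError("window_s must be a positive odd integer")
    ok = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    half = window_s // 2
    num = np.where(ok, y, 0.0)
    den = ok.astype(float)
    csum = np.concatenate([[0.0], np.cumsum(num)])
    cden = np.concatenate([[0.0], np.cumsum(den)])
    out = np.full(n, np.nan)
    idx = np.arange(n)
    # symmetric shrink: at distance d from an edge the effective half-width is d
    eff = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - eff, idx + eff + 1
    tot = csum[hi] - csum[lo]
    cnt = cden[hi] - cden[lo]
    nonzero = cnt > 0
    out[nonzero] = tot[nonzero] / cnt[nonzero]
    out[~ok] = np.nan
    return out


def _segment_cost_mean(csum, csum2, a, b):
    """Twice the negative Gaussian log-likelihood (up to constants) of
    segment [a, b) under a segment-specific mean and unit common variance
    (the convention of the classical Normal mean-change statistic: the
    cost is the residual sum of squares, so the series scale matters and
    the analysis is meant for raw count-scale data)."""
    n = b - a
    s = csum[b] - csum[a]
    s2 = csum2[b] - csum2[a]
    return s2 - s * s / n


def _segment_cost_var(csum_c2, a, b):
    """n * log(sigma_hat^2) for segment [a, b) with the variance taken
    around the global (common) mean."""
    n = b - a
    s2 = csum_c2[b] - csum_c2[a]
    return n * np.log(max(s2 / n, _VAR_FLOOR))


def _best_split(cost, a, b, min_seg):
    """Best single split of [a, b): (gain, split) maximizing the cost drop."""
    best_gain, best_t = -np.inf, None
    parent = cost(a, b)
    for t in range(a + min_seg, b - min_seg + 1):
        g = parent - cost(a, t) - cost(t, b)
        if g > best_gain:
            best_gain, best_t = g, t
    return best_gain, best_t


def _binseg_run(y, kind, penalty, max_cpts, min_seg):
    """Binary segmentation of one contiguous (gap-free) array; returns
    slice-boundary indices local to ``y``."""
    n = y.size
    if n < 2 * min_seg:
        return []
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y * y)])
    if kind == "mean":
        if float(np.var(y)) < _VAR_FLOOR:
            return []
        cost = lambda a, b: _segment_cost_mean(csum, csum2, a, b)
    elif kind == "variance":
        mu0 = float(np.mean(y))
        c2 = np.concatenate([[0.0], np.cumsum((y - mu0) ** 2)])
        cost = lambda a, b: _segment_cost_var(c2, a, b)
    else:
        raise ValueError(f"kind must be 'mean' or 'variance', got {kind!r}")

    cpts: list[int] = []
    # candidate best split per active segment, keyed by (a, b)
    candidates: dict[tuple[int, int], tuple[float, int | None]] = {
        (0, n): _best_split(cost, 0, n, min_seg)
    }
    while len(cpts) < max_cpts:
        (a, b), (gain, t) = max(candidates.items(), key=lambda kv: kv[1][0])
        if t is None or gain <= penalty:
            break
        cpts.append(t)
        del candidates[(a, b)]
        candidates[(a, t)] = _best_split(cost, a, t, min_seg)
        candidates[(t, b)] = _best_split(cost, t, b, min_seg)
        if not candidates:
            break
    return sorted(cpts)


def default_penalty(n: int) -> float:
    """MBIC-style per-changepoint penalty, 3 log n on the -2 log-likelihood scale."""
    return 3.0 * np.log(max(n, 2))


def default_min_seg(kind: str) -> int:
    # a sample variance needs at least two points
    return 2 if kind == "variance" else 1


def binseg(
    series: np.ndarray,
    kind: str = "mean",
    penalty: float | None = None,
    max_cpts: int | None = None,
    min_seg: int | None = None,
) -> ChangepointResult:
    """Detect mean- or variance-changepoints by greedy binary segmentation.

    At each step the split with the largest reduction in twice the
    negative Gaussian log-likelihood is taken (segment-specific mean with
    common variance for ``kind="mean"``; common mean with segment-specific
    variance for ``kind="variance"``); recursion stops when the best
    reduction is at most ``penalty`` or ``max_cpts`` is reached.  NaN
    values (masked seconds) split the series into independent runs.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if min_seg is None:
        min_seg = default_min_seg(kind)
    if penalty is None:
        penalty = default_penalty(n)
    if max_cpts is None:
        max_cpts = max(1, n // 10)
    ok = np.isfinite(y)
    n_analyzed = int(ok.sum())
    if n_analyzed < 2 * min_seg:
        warnings.warn("series too short for changepoint analysis; empty result")
        return ChangepointResult(kind, [], [], penalty, max_cpts, n, n_analyzed)

    indices: list[int] = []
    # contiguous unmasked runs
    boundaries = np.flatnonzero(np.diff(ok.astype(int)) != 0) + 1
    runs = np.split(np.arange(n), boundaries)
    for run in runs:
        if run.size == 0 or not ok[run[0]]:
            continue
        local = _binseg_run(y[run], kind, penalty, max_cpts - len(indices), min_seg)
        indices.extend(int(run[0]) + t for t in local)
    indices = sorted(indices)

    # per-segment parameter estimates between consecutive changepoints,
    # within runs (segments never span a masked gap)
    params: list[float] = []
    seg_edges = [0, *indices, n]
    for a, b in zip(seg_edges, seg_edges[1:]):
        vals = y[a:b][ok[a:b]]
        if vals.size == 0:
            params.append(np.nan)
        elif kind == "mean":
            params.append(float(np.mean(vals)))
        else:
            params.append(float(np.var(vals, ddof=1)) if vals.size > 1 else 0.0)
    return ChangepointResult(kind, indices, params, penalty, max_cpts, n, n_analyzed)


def count_by_period(
    mean_result: ChangepointResult,
    var_result: ChangepointResult,
    phase_bounds=(0, 600, 1200, 1800),
    cee_id: str = "",
) -> ChangepointSummary:
    """Count changepoints per experimental period (a changepoint belongs to
    the period containing its index)."""
    b0, b1, b2, b3 = phase_bounds

    def split(result):
        idx = np.asarray(result.indices)
        return (
            int(((idx >= b0) & (idx < b1)).sum()),
            int(((idx >= b1) & (idx < b2)).sum()),
            int(((idx >= b2) & (idx < b3)).sum()),
        )

    m = split(mean_result)
    v = split(var_result)
    return ChangepointSummary(cee_id, *m, *v)


def switch_rate(results: list[ChangepointResult]) -> float:
    """Overall vocal state-switching rate: changepoints per analyzed minute."""
    if not results:
        raise ValueError("no changepoint results")
    total_cpts = sum(r.n_changepoints for r in results)
    total_minutes = sum(r.n_analyzed for r in results) / 60.0
    if total_minutes <= 0:
        raise ValueError("zero analyzed minutes")
    return total_cpts / total_minutes


def write_summary_csv(summaries: list[ChangepointSummary], path) -> None:
    rows = [
        {
            "cee_id": s.cee_id,
            "cpt_mean_pre": s.mean_pre,
            "cpt_mean_exposure": s.mean_exposure,
            "cpt_var_pre": s.var_pre,
            "cpt_var_exposure": s.var_exposure,
            "delta_mean": s.delta_mean,
            "delta_var": s.delta_var,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
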