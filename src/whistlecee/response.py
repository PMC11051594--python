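"""Multi-scale response variables around sonar pings.

Three scales of acoustic response are quantified for every experiment:

* 10-min scale — ``periodDiff``, the absolute difference in median
  per-second whistle count between the pre-exposure and exposure phases;
* 20-s and 5-s scales — ``pingChange``, the mean per-second whistle
  count in a window after each ping minus the mean in the equal window
  before it (controls use pseudo-ping timestamps, computed identically);
* first-ping fold change, the ratio of total whistles in the 5 s after
  to the 5 s before the first ping of the exposure.

The after-window by default starts at the *end* of the 1.6-s
transmission, because whistle elevations occur once the signal has been
transmitted, with suppression during the transmission itself; alignment
to the onset is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import CountSeries

logger = logging.getLogger(__name__)


@dataclass
class PingSchedule:
    """Ordered ping (or pseudo-ping) onsets for one exposure phase."""

    cee_id: str
    onsets_s: np.ndarray
    duration_s: float = 1.6
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.onsets_s.size == 0:
            raise ValueError("a PingSchedule needs at least one ping")
        gaps = np.diff(self.onsets_s)
        if np.any(gaps <= 0):
            raise ValueError("ping onsets must be strictly increasing")
        if np.any(gaps <= self.duration_s):
            raise ValueError("inter-onset gap must exceed the ping duration")

    @property
    def n_pings(self) -> int:
        return self.onsets_s.size

    def to_dict(self) -> dict:
        return {
            "cee_id": self.cee_id,
            "onsets_s": [float(o) for o in self.onsets_s],
            "duration_s": float(self.duration_s),
            "is_pseudo": bool(self.is_pseudo),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PingSchedule":
        return cls(d["cee_id"], np.asarray(d["onsets_s"]), d["duration_s"], d["is_pseudo"])


def ping_windows(
    schedule: PingSchedule,
    window_s: float,
    align: str = "offset",
    allow_cycle_overlap: bool = True,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Before/after analysis windows for each ping.

    With ``align="offset"`` (default) the before-window ends at ping onset
    and the after-window starts at ping end; with ``align="onset"`` both
    reference the onset.  A window may never contain an adjacent ping's
    transmission.  With 25-s ping spacing, windows longer than about 12 s
    necessarily share seconds with the neighbouring cycle's windows; that
    reuse is permitted by default (the 20-s analysis needs it) and refused
    when ``allow_cycle_overlap`` is false.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    d = schedule.duration_s if align == "offset" else 0.0
    gaps = np.diff(schedule.onsets_s)
    min_gap = float(gaps.min()) if gaps.size else math.inf
    # after-window must end before the next onset; before-window must start
    # after the previous transmission's end
    if schedule.duration_s + window_s > min_gap + 1e-9:
        raise ValueError(
            f"window_s={window_s} overlaps an adjacent ping transmission "
            f"(ping duration {schedule.duration_s}, minimal spacing {min_gap})"
        )
    if not allow_cycle_overlap and d + 2 * window_s > min_gap + 1e-9:
        raise ValueError(
            f"window_s={window_s} makes adjacent cycles' windows overlap "
            f"(need ping_dur + 2*window <= spacing {min_gap})"
        )
    out = []
    for o in schedule.onsets_s:
        before = (o - window_s, o)
        after = (o + d, o + d + window_s)
        out.append((before, after))
    return out


def _window_mean(cs: CountSeries, lo: float, hi: float) -> float:
    """Mean per-second count over unmasked whole-second bins intersecting
    [lo, hi); NaN when every bin in the window is masked."""
    a = max(0, int(math.floor(lo)))
    b = min(len(cs), int(math.ceil(hi)))
    if b <= a:
        return math.nan
    sel = cs.mask[a:b]
    if not sel.any():
        return math.nan
    return float(np.mean(cs.counts[a:b][sel]))


def _window_total(cs: CountSeries, lo: float, hi: float) -> float:
    a = max(0, int(math.floor(lo)))
    b = min(len(cs), int(math.ceil(hi)))
    if b <= a or not cs.mask[a:b].any():
        return math.nan
    return float(np.sum(cs.counts[a:b][cs.mask[a:b]]))


def period_median_difference(cs: CountSeries, meta: dict | None = None) -> dict | None:
    """10-min-scale record: |median(exposure) - median(pre)| over unmasked bins.

    Returns ``None`` (logged) when either period is fully masked.
    """
    pre = cs.masked_values("pre")
    exp = cs.masked_values("exposure")
    if pre.size == 0 or exp.size == 0:
        logger.warning("%s: a full period is masked; periodDiff record dropped", cs.cee_id)
        return None
    rec = {
        "ceeNum": cs.cee_id,
        "periodDiff": float(abs(np.median(exp) - np.median(pre))),
        "median_pre": float(np.median(pre)),
        "median_exposure": float(np.median(exp)),
    }
    if meta:
        rec.update(meta)
    return rec


def ping_change_series(
    cs: CountSeries,
    schedule: PingSchedule,
    window_s: float,
    align: str = "offset",
    meta: dict | None = None,
) -> pd.DataFrame:
    """Per-ping ``pingChange`` records (mean after-window − mean before-window).

    Pseudo-ping schedules from control experiments are handled
    identically.  Pings with a fully masked window are dropped and logged.
    The ``times`` column is the ping order index, the sequencing variable
    for the AR(1) correlation structure.
    """
    windows = ping_windows(schedule, window_s, align=align)
    rows = []
    for k, ((b_lo, b_hi), (a_lo, a_hi)) in enumerate(windows, start=1):
        before = _window_mean(cs, b_lo, b_hi)
        after = _window_mean(cs, a_lo, a_hi)
        if math.isnan(before) or math.isnan(after):
            logger.warning("%s ping %d: fully masked window; record dropped", cs.cee_id, k)
            continue
        rec = {
            "ceeNum": cs.cee_id,
            "ping_index": k,
            "times": k,
            "pingChange": after - before,
            "window_s": window_s,
            "before_mean": before,
            "after_mean": after,
        }
        if meta:
            rec.update(meta)
        rows.append(rec)
    return pd.DataFrame(rows)


def first_ping_fold_change(cs: CountSeries, schedule: PingSchedule, window_s: float = 5.0) -> float | None:
    """Total whistles in the 5 s after the first ping over the 5 s before.

    Returns ``None`` (undefined, never infinity) when the before-window
    total is zero or a window is fully masked.
    """
    (b, a) = ping_windows(schedule, window_s)[0]
    before = _window_total(cs, *b)
    after = _window_total(cs, *a)
    if math.isnan(before) or math.isnan(after) or before == 0:
        return None
    return after / before


def flag_pronounced_first_ping(records: pd.DataFrame) -> bool:
    """Whether the first ping's change exceeds the 75th percentile of the
    experiment's per-ping change distribution (linear-interpolation
    percentile convention)."""
    if len(records) < 4:
        raise ValueError("need at least 4 pings to assess the first-ping percentile")
    changes = records.sort_values("ping_index")["pingChange"].to_numpy(dtype=float)
    return bool(changes[0] > np.percentile(changes, 75))


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
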