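"""Per-second whistle counting.

Detection tables (one row per automatically detected whistle fragment)
are filtered — sonar-harmonic annotations removed, detections restricted
to the closest included buoy each minute — and binned into per-second
whistle counts with an inclusion mask and experiment-phase labels.

The count metric is the number of whistle detections *starting* within a
1-s bin: a fragment longer than 1 s still contributes only to its start
bin, so the per-second series sums to the number of surviving detections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["cee_id", "buoy_id", "start_s", "duration_s"]
ANNOTATION_COLUMNS = ["cee_id", "buoy_id", "start_s", "end_s"]

PHASES = ("pre", "exposure", "post")
DEFAULT_PHASE_BOUNDS = (0, 600, 1200, 1800)


def empty_detections() -> pd.DataFrame:
    return pd.DataFrame(columns=DETECTION_COLUMNS)


def validate_detections(det: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DETECTION_COLUMNS if c not in det.columns]
    if missing:
        raise ValueError(f"detection table missing columns {missing}")
    if len(det) and (det["start_s"] < 0).any():
        raise ValueError("detection start_s must be >= 0")
    if len(det) and (det["duration_s"] <= 0).any():
        raise ValueError("detection duration_s must be > 0")
    return det


@dataclass
class CountSeries:
    """Masked per-second whistle counts for one experiment.

    Attributes
    ----------
    counts
        Integer whistle detections starting in each 1-s bin.
    mask
        True where the bin is usable (closest buoy within range).
    phase
        One of ``pre`` / ``exposure`` / ``post`` per bin.
    """

    counts: np.ndarray
    mask: np.ndarray
    phase: np.ndarray
    cee_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.counts) == len(self.mask) == len(self.phase)):
            raise ValueError("counts, mask and phase must have equal length")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    def masked_values(self, phase: str | None = None) -> np.ndarray:
        """Counts over unmasked bins, optionally restricted to one phase."""
        keep = self.mask.copy()
        if phase is not None:
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r}")
            keep &= self.phase == phase
        return self.counts[keep].astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cee_id": self.cee_id,
                "t_s": np.arange(len(self)),
                "count": self.counts,
                "mask": self.mask,
                "phase": self.phase,
            }
        )


def phase_labels(duration_s: int, phase_bounds=DEFAULT_PHASE_BOUNDS) -> np.ndarray:
    """Per-second phase labels from strictly increasing phase boundaries."""
    bounds = list(phase_bounds)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("phase_bounds must be strictly increasing")
    if len(bounds) != 4:
        raise ValueError("expected 4 phase bounds (start/pre|exposure|post/end)")
    t = np.arange(duration_s)
    out = np.empty(duration_s, dtype=object)
    out[:] = "post"
    out[t < bounds[2]] = "exposure"
    out[t < bounds[1]] = "pre"
    return out


def remove_annotated_detections(det: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Drop detections overlapping an annotated sonar-harmonic interval.

    Overlap is on the same buoy, between the detection's half-open extent
    ``[start, start + duration)`` and the annotation's ``[start, end)``;
    touching endpoints do not overlap.
    """
    validate_detections(det)
    if len(ann) == 0 or len(det) == 0:
        return det.copy()
    if (ann["end_s"] <= ann["start_s"]).any():
        raise ValueError("annotation end_s must exceed start_s")
    keep = np.ones(len(det), dtype=bool)
    d_start = det["start_s"].to_numpy(dtype=float)
    d_end = d_start + det["duration_s"].to_numpy(dtype=float)
    d_buoy = det["buoy_id"].to_numpy()
    for _, a in ann.iterrows():
        hit = (d_buoy == a["buoy_id"]) & (d_start < a["end_s"]) & (d_end > a["start_s"])
        keep &= ~hit
    return det.loc[keep].reset_index(drop=True)


def stitch_closest_buoy(det: pd.DataFrame, sel) -> pd.DataFrame:
    """Keep only detections recorded on the selected buoy of an included minute.

    ``sel`` is a :class:`~whistlecee.geometry.BuoySelection`; a detection
    survives iff the minute containing its start time selected its buoy
    and is included.
    """
    validate_detections(det)
    if len(det) == 0:
        return det.copy()
    by_minute = {
        int(r["minute_index"]): (r["closest_buoy_id"], bool(r["included"]))
        for _, r in sel.table.iterrows()
    }
    minutes = (det["start_s"].to_numpy(dtype=float) // 60).astype(int)
    keep = np.array(
        [
            m in by_minute and by_minute[m][1] and by_minute[m][0] == b
            for m, b in zip(minutes, det["buoy_id"])
        ]
    )
    return det.loc[keep].reset_index(drop=True)


def bin_per_second(
    det: pd.DataFrame,
    duration_s: int,
    sel=None,
    phase_bounds=DEFAULT_PHASE_BOUNDS,
    cee_id: str = "",
) -> CountSeries:
    """Bin detection start times into per-second counts.

    Bin ``k`` counts detections with ``start_s`` in ``[k, k+1)``.  The mask
    comes from the buoy selection when given, else all bins are usable.
    """
    validate_detections(det)
    starts = det["start_s"].to_numpy(dtype=float)
    if len(starts) and starts.max() >= duration_s:
        raise ValueError("detection start_s beyond the experiment duration")
    counts = np.bincount(starts.astype(int), minlength=duration_s) if len(starts) else np.zeros(duration_s, dtype=int)
    mask = sel.included_seconds(duration_s) if sel is not None else np.ones(duration_s, dtype=bool)
    return CountSeries(counts=counts, mask=mask, phase=phase_labels(duration_s, phase_bounds), cee_id=cee_id)


def _summary(values: np.ndarray) -> dict[str, float]:
    # linear-interpolation percentile convention (numpy default), fixed for
    # reproducibility of the median/IQR statistics
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "median": float(q50),
        "iqr": float(q75 - q25),
        "n": int(values.size),
    }


def summarize_cee(cs: CountSeries) -> dict:
    """Whistle-count summary (mean, SD, median, IQR) overall and per phase.

    The overall median is the ``medWhist`` covariate of the response
    models.  Raises when every bin is masked; a fully-masked phase yields
    ``None`` for that phase.
    """
    overall = cs.masked_values()
    if overall.size == 0:
        raise ValueError("all bins masked: no usable data to summarize")
    out = {"overall": _summary(overall)}
    for ph in PHASES:
        vals = cs.masked_values(ph)
        out[ph] = _summary(vals) if vals.size else None
    out["med_whist"] = out["overall"]["median"]
    return out


# ---------------------------------------------------------------------------
# CSV interfaces

def read_detections_csv(path) -> pd.DataFrame:
    return validate_detections(pd.read_csv(path))


def read_annotations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_count_series_csv(cs: CountSeries, path) -> None:
    cs.to_frame().to_csv(path, index=False)


def read_count_series_csv(path) -> CountSeries:
    df = pd.read_csv(path)
    cee = str(df["cee_id"].iloc[0]) if len(df) else ""
    return CountSeries(
        counts=df["count"].to_numpy(),
        mask=df["mask"].to_numpy(dtype=bool),
        phase=df["phase"].to_numpy(dtype=object),
        cee_id=cee,
    )
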