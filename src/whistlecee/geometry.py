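"""Group-to-buoy geometry: great-circle distances, track interpolation,
closest-buoy selection and the distance-based exclusion mask.

Passive acoustic recordings are only usable when the recording buoy is
close enough to the focal dolphin group for whistles to be detected
reliably; beyond ~1.6 km the detection probability of a typical whistle
drops off sharply.  This module turns per-minute GPS fixes for the focal
group and up to three drifting buoys into a per-minute record of which
buoy was closest and whether that minute passes the distance threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mean Earth radius in metres.
EARTH_RADIUS_M = 6_371_000.0

#: Default buoy-to-group exclusion distance in metres.
DEFAULT_THRESHOLD_M = 1600.0


@dataclass
class Track:
    """Timestamped GPS fixes for a single platform (buoy or focal group).

    Parameters
    ----------
    platform_id
        Identifier, e.g. ``"group"`` or ``"buoy_1"``.
    t_s
        Fix times in seconds from the start of the experiment, strictly
        increasing.
    lat_deg, lon_deg
        Coordinates in decimal degrees.
    """

    platform_id: str
    t_s: np.ndarray
    lat_deg: np.ndarray
    lon_deg: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.lat_deg = np.asarray(self.lat_deg, dtype=float)
        self.lon_deg = np.asarray(self.lon_deg, dtype=float)
        if not (self.t_s.shape == self.lat_deg.shape == self.lon_deg.shape):
            raise ValueError("t_s, lat_deg and lon_deg must have equal length")
        if self.t_s.ndim != 1 or self.t_s.size == 0:
            raise ValueError("a Track needs at least one fix")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError(f"timestamps of {self.platform_id} not strictly increasing")
        if np.any(np.abs(self.lat_deg) > 90.0):
            raise ValueError("latitude out of [-90, 90]")
        if np.any(np.abs(self.lon_deg) > 180.0):
            raise ValueError("longitude out of [-180, 180]")

    def __len__(self) -> int:
        return self.t_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "platform_id": self.platform_id,
                "t_s": self.t_s,
                "lat_deg": self.lat_deg,
                "lon_deg": self.lon_deg,
            }
        )


@dataclass
class BuoySelection:
    """Per-minute closest-buoy record with the distance exclusion flag.

    ``table`` has one row per minute of the experiment with columns
    ``minute_index``, ``closest_buoy_id``, ``distance_m`` and ``included``.
    A minute is the half-open interval ``[60k, 60(k+1))``.
    """

    table: pd.DataFrame
    threshold_m: float = DEFAULT_THRESHOLD_M
    cee_id: str = ""

    def included_seconds(self, duration_s: int) -> np.ndarray:
        """Expand the per-minute inclusion flags to a per-second boolean mask."""
        mask = np.zeros(int(duration_s), dtype=bool)
        for _, row in self.table.iterrows():
            k = int(row["minute_index"])
            lo, hi = 60 * k, min(60 * (k + 1), int(duration_s))
            if lo < duration_s:
                mask[lo:hi] = bool(row["included"])
        return mask

    def buoy_for_minute(self) -> dict[int, str | None]:
        return {
            int(r["minute_index"]): (None if pd.isna(r["closest_buoy_id"]) else r["closest_buoy_id"])
            for _, r in self.table.iterrows()
        }

    @property
    def mean_distance_m(self) -> float:
        """Mean group-to-closest-buoy distance over minutes with a valid fix
        (the per-experiment ``buoyDist`` covariate used in the models)."""
        d = self.table["distance_m"].to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        return float(np.mean(d)) if d.size else float("nan")


def haversine_distance(
    p1: tuple[float, float],
    p2: tuple[float, float],
    radius_m: float = EARTH_RADIUS_M,
) -> float:
    """Great-circle distance in metres between two (lat, lon) points in degrees.

    Uses the haversine formula, which is numerically stable for the short
    (sub-100 km) ranges involved here.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    lat1, lon1 = p1
    lat2, lon2 = p2
    for lat in (lat1, lat2):
        if abs(lat) > 90.0:
            raise ValueError("latitude out of [-90, 90]")
    for lon in (lon1, lon2):
        if abs(lon) > 180.0:
            raise ValueError("longitude out of [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    a = min(1.0, a)
    return 2.0 * radius_m * math.asin(math.sqrt(a))


def interpolate_positions(track: Track, grid_s: np.ndarray | float) -> Track:
    """Resample a track onto a time grid by coordinate-wise linear interpolation.

    ``grid_s`` is either an explicit array of query times or a scalar grid
    step; a scalar produces the regular grid from the first to the last fix
    (inclusive of both endpoints when the span is a multiple of the step).
    Extrapolation outside the fix span is refused.
    """
    if len(track) < 2:
        raise ValueError("interpolation needs at least two fixes")
    if np.isscalar(grid_s):
        step = float(grid_s)
        if step <= 0:
            raise ValueError("grid step must be positive")
        grid = np.arange(track.t_s[0], track.t_s[-1] + 1e-9, step)
    else:
        grid = np.asarray(grid_s, dtype=float)
    if grid.size == 0:
        raise ValueError("empty interpolation grid")
    if grid.min() < track.t_s[0] - 1e-9 or grid.max() > track.t_s[-1] + 1e-9:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] outside fix span "
            f"[{track.t_s[0]}, {track.t_s[-1]}] for {track.platform_id}"
        )
    lat = np.interp(grid, track.t_s, track.lat_deg)
    lon = np.interp(grid, track.t_s, track.lon_deg)
    return Track(track.platform_id, grid, lat, lon)


def _distances_on_grid(group: Track, buoy: Track, grid: np.ndarray) -> np.ndarray:
    """Distance series between two tracks at the given times (NaN where a
    track does not cover a time)."""
    out = np.full(grid.size, np.nan)
    lo = max(group.t_s[0], buoy.t_s[0])
    hi = min(group.t_s[-1], buoy.t_s[-1])
    ok = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    if not ok.any():
        return out
    g = interpolate_positions(group, grid[ok])
    b = interpolate_positions(buoy, grid[ok])
    out[ok] = [
        haversine_distance((g.lat_deg[i], g.lon_deg[i]), (b.lat_deg[i], b.lon_deg[i]))
        for i in range(int(ok.sum()))
    ]
    return out


def select_closest_buoy(
    group: Track,
    buoys: list[Track],
    threshold_m: float = DEFAULT_THRESHOLD_M,
    duration_s: int | None = None,
    cee_id: str = "",
) -> BuoySelection:
    """Pick the closest buoy each minute and flag minutes beyond the threshold.

    Distances are evaluated at the start of each minute (t = 60k) after
    linear interpolation of all tracks.  The minimal-distance buoy is
    selected; ties break to the lexicographically lowest ``platform_id``.
    ``included`` is false when the minimal distance exceeds ``threshold_m``
    or when no buoy covers the minute (logged).
    """
    if not buoys:
        raise ValueError("at least one buoy track required")
    if duration_s is None:
        duration_s = int(group.t_s[-1])
    n_min = int(np.ceil(duration_s / 60.0))
    grid = 60.0 * np.arange(n_min)
    # sort for the documented lowest-id tie-break
    buoys = sorted(buoys, key=lambda t: t.platform_id)
    dmat = np.vstack([_distances_on_grid(group, b, grid) for b in buoys])

    rows = []
    for k in range(n_min):
        col = dmat[:, k]
        if np.all(np.isnan(col)):
            logger.warning("minute %d of %s: no buoy track coverage; excluded", k, cee_id or "CEE")
            rows.append((k, None, np.nan, False))
            continue
        j = int(np.nanargmin(col))
        d = float(col[j])
        rows.append((k, buoys[j].platform_id, d, d <= threshold_m))
    table = pd.DataFrame(rows, columns=["minute_index", "closest_buoy_id", "distance_m", "included"])
    return BuoySelection(table=table, threshold_m=threshold_m, cee_id=cee_id)


# ---------------------------------------------------------------------------
# CSV interfaces

def read_track_csv(path) -> list[Track]:
    """Read a Track CSV (platform_id, t_s, lat_deg, lon_deg) into Track objects."""
    df = pd.read_csv(path)
    tracks = []
    for pid, sub in df.groupby("platform_id", sort=True):
        sub = sub.sort_values("t_s")
        tracks.append(Track(str(pid), sub["t_s"].to_numpy(), sub["lat_deg"].to_numpy(), sub["lon_deg"].to_numpy()))
    return tracks


def write_track_csv(tracks: list[Track], path) -> None:
    pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(path, index=False)


def write_selection_csv(sel: BuoySelection, path) -> None:
    out = sel.table.copy()
    out.insert(0, "cee_id", sel.cee_id)
    out.to_csv(path, index=False)
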