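"""Synthetic controlled-exposure experiments with known ground truth.

No field recordings are distributed with the original study, so every
stage of the pipeline is exercised against simulated experiments whose
statistical structure mirrors what the analysis assumes:

* per-second whistle counts are Poisson (optionally negative-binomial)
  conditional on a latent vocal state that switches as a continuous-time
  Markov chain — about once per minute for mean states and once per
  3.5 minutes for variance states under baseline conditions;
* a 30-min experiment splits into 10-min pre-exposure / exposure /
  post-exposure phases, with up to 24 sonar pings of 1.6 s every 25 s
  during the exposure (controls carry pseudo-ping timestamps only);
* sonar elicits a multiplicative burst of whistling in the seconds after
  each ping (up to ~15x), decaying within ~10 s, with optional silence
  during the 1.6-s transmission itself;
* the focal group and up to three drifting buoys follow smooth
  random-walk tracks fixed once per minute, with a scenario in which a
  buoy drifts across the 1.6-km exclusion range.

All randomness flows from a single integer seed; a fixed seed gives
bit-identical output bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counting import CountSeries, phase_labels
from .geometry import Track, EARTH_RADIUS_M
from .response import PingSchedule

__all__ = [
    "SimConfig",
    "CEEMeta",
    "SimulatedCEE",
    "simulate_vocal_states",
    "simulate_whistle_train",
    "make_ping_schedule",
    "inject_ping_response",
    "simulate_tracks",
    "simulate_cee",
    "write_cee_bundle",
]

#: Degrees of latitude per metre at the study-area latitude scale.
_DEG_PER_M_LAT = 180.0 / (math.pi * EARTH_RADIUS_M)


@dataclass
class SimConfig:
    """Parameters of one simulated controlled-exposure experiment.

    Defaults reproduce the study design: 30-min experiments in three
    10-min phases, 24 pings of 1.6 s every 25 s, baseline mean-state
    switching once per minute and variance-state switching once per
    3.5 minutes, group sizes in the tens to hundreds.
    """

    cee_id: str = "sim_01"
    cee_type: str = "control"                     # "control" | "mfas"
    duration_s: int = 1800
    phase_bounds: tuple[int, int, int, int] = (0, 600, 1200, 1800)
    n_states: int = 2
    state_intensities: tuple[float, ...] = (0.3, 4.6)   # whistles / s, control range
    mean_switch_rate: float = 1.0                 # switches / min
    variance_switch_rate: float = 1.0 / 3.5       # switches / min
    count_dist: str = "poisson"                   # "poisson" | "nbinom"
    nb_dispersion: float = 5.0                    # NB theta when count_dist="nbinom"
    state_dispersions: tuple[float, ...] | None = None   # per-state NB theta (variance states)
    response_fold: float = 1.0
    response_duration_s: float = 5.0
    response_decay_s: float = 10.0
    suppress_during_ping: bool = False
    n_pings: int = 24
    ping_interval_s: float = 25.0
    ping_dur_s: float = 1.6
    n_buoys: int = 3
    group_speed_mps: float = 1.5
    buoy_speed_mps: float = 0.25
    group_size: int = 150
    subspecies: str = "Db"                        # "Db" | "Dd"
    rl_max_db: float | None = None
    track_scenario: str = "default"               # "default" | "crossing"
    origin_lat_deg: float = 33.35
    origin_lon_deg: float = -118.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if list(self.phase_bounds) != sorted(set(self.phase_bounds)):
            raise ValueError("phase_bounds must be strictly increasing")
        if self.phase_bounds[-1] != self.duration_s:
            raise ValueError("duration_s must equal the last phase bound")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if len(self.state_intensities) != self.n_states:
            raise ValueError("state_intensities must have one entry per state")
        if any(i < 0 for i in self.state_intensities):
            raise ValueError("state intensities must be non-negative")
        if self.response_fold < 0:
            raise ValueError("response_fold must be >= 0")
        if self.cee_type not in ("control", "mfas"):
            raise ValueError("cee_type must be 'control' or 'mfas'")

    @property
    def switch_rate(self) -> dict[str, float]:
        return {"mean": self.mean_switch_rate, "variance": self.variance_switch_rate}


@dataclass
class CEEMeta:
    """Experiment-level metadata mirroring the study's summary table."""

    cee_id: str
    cee_type: str
    subspecies: str
    group_size: int
    rl_max_db: float | None = None
    rl_range_db: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cee_type == "control" and (self.rl_max_db is not None or self.rl_range_db is not None):
            raise ValueError("received-level fields apply to sonar experiments only")


@dataclass
class SimulatedCEE:
    """Complete simulated experiment bundle with ground truth."""

    config: SimConfig
    detections: pd.DataFrame
    counts: CountSeries
    tracks: list[Track]            # group track first, then buoys
    schedule: PingSchedule
    meta: CEEMeta
    truth: dict                    # state sequences + injected response windows

    @property
    def group_track(self) -> Track:
        return self.tracks[0]

    @property
    def buoy_tracks(self) -> list[Track]:
        return self.tracks[1:]


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, stream]))


def simulate_vocal_states(config: SimConfig, which: str = "mean",
                          rng: np.random.Generator | None = None,
                          return_times: bool = False):
    """Per-second latent vocal-state labels from a continuous-time Markov
    chain with exponential holding times.

    The total switch rate is ``mean_switch_rate`` or
    ``variance_switch_rate`` (per minute); at each switch the chain jumps
    uniformly to one of the other states, so the expected number of
    switches over the experiment is rate x duration-in-minutes.
    """
    if which not in ("mean", "variance"):
        raise ValueError("which must be 'mean' or 'variance'")
    if config.duration_s <= 0:
        raise ValueError("non-positive duration")
    rate_per_s = config.switch_rate[which] / 60.0
    if rate_per_s == 0.0:
        if config.n_states != 1:
            raise ValueError("zero switch rate requires n_states = 1")
        states = np.zeros(config.duration_s, dtype=int)
        return (states, np.empty(0)) if return_times else states
    if config.n_states < 2:
        raise ValueError("switching requires n_states >= 2")
    if rng is None:
        rng = _spawn(config.seed, 1 if which == "mean" else 2)
    states = np.empty(config.duration_s, dtype=int)
    switch_times = []
    t = 0.0
    s = int(rng.integers(config.n_states))
    while t < config.duration_s:
        hold = rng.exponential(1.0 / rate_per_s)
        a, b = int(t), min(int(math.ceil(t + hold)), config.duration_s)
        # discretize to 1-s bins: a second containing a switch takes the incoming state
        states[a:b] = s
        t += hold
        if t < config.duration_s:
            switch_times.append(t)
        others = [k for k in range(config.n_states) if k != s]
        s = int(rng.choice(others))
    if return_times:
        return states, np.asarray(switch_times)
    return states


def _draw_counts(intensity: np.ndarray, config: SimConfig, rng: np.random.Generator,
                 theta: np.ndarray | float | None = None) -> np.ndarray:
    if config.count_dist == "poisson":
        return rng.poisson(intensity)
    if config.count_dist == "nbinom":
        if theta is None:
            theta = config.nb_dispersion
        theta = np.broadcast_to(np.asarray(theta, dtype=float), intensity.shape)
        out = np.zeros(intensity.size, dtype=int)
        pos = intensity > 0
        out[pos] = rng.negative_binomial(
            theta[pos], theta[pos] / (theta[pos] + intensity[pos])
        )
        return out
    raise ValueError(f"unknown count_dist {config.count_dist!r}")


def _detections_from_counts(counts: np.ndarray, config: SimConfig,
                            rng: np.random.Generator, buoy_id: str) -> pd.DataFrame:
    n = int(counts.sum())
    if n == 0:
        return pd.DataFrame(columns=["cee_id", "buoy_id", "start_s", "duration_s"])
    seconds = np.repeat(np.arange(counts.size), counts)
    starts = seconds + rng.uniform(0.0, 1.0, size=n)
    # whistle fragments are typically a few tenths of a second
    durations = rng.gamma(shape=2.0, scale=0.15, size=n) + 0.05
    return pd.DataFrame(
        {"cee_id": config.cee_id, "buoy_id": buoy_id,
         "start_s": np.sort(starts), "duration_s": durations[np.argsort(starts)]}
    )


def simulate_whistle_train(states: np.ndarray, config: SimConfig,
                           rng: np.random.Generator | None = None
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-second whistle counts and a detection table from a state sequence.

    Counts are conditionally independent given the state, with mean equal
    to the state's intensity; detection start times are uniform within
    their second.
    """
    states = np.asarray(states, dtype=int)
    if states.min() < 0 or states.max() >= len(config.state_intensities):
        raise ValueError("state labels index invalid intensities")
    if rng is None:
        rng = _spawn(config.seed, 3)
    intensity = np.asarray(config.state_intensities, dtype=float)[states]
    theta = None
    if config.state_dispersions is not None:
        if len(config.state_dispersions) != config.n_states:
            raise ValueError("state_dispersions must have one entry per state")
        theta = np.asarray(config.state_dispersions, dtype=float)[states]
    counts = _draw_counts(intensity, config, rng, theta=theta)
    det = _detections_from_counts(counts, config, rng, buoy_id="buoy_1")
    return counts, det


def make_ping_schedule(start_s: float, n_pings: int = 24, interval_s: float = 25.0,
                       ping_dur_s: float = 1.6, phase_end_s: float | None = None,
                       cee_id: str = "", is_pseudo: bool = False) -> PingSchedule:
    """Regular ping schedule: ping k starts at ``start_s + (k-1) * interval_s``.

    Refuses schedules whose last transmission would overrun the exposure
    phase (default phase length 600 s).
    """
    if n_pings < 1:
        raise ValueError("n_pings must be >= 1")
    if interval_s <= ping_dur_s:
        raise ValueError("ping duration must be shorter than the interval")
    if phase_end_s is None:
        phase_end_s = start_s + 600.0
    onsets = start_s + interval_s * np.arange(n_pings)
    if onsets[-1] + ping_dur_s > phase_end_s:
        raise ValueError(
            f"schedule overruns the exposure phase: last ping ends at "
            f"{onsets[-1] + ping_dur_s:.1f} > {phase_end_s:.1f}"
        )
    return PingSchedule(cee_id=cee_id, onsets_s=onsets, duration_s=ping_dur_s, is_pseudo=is_pseudo)


def _response_multiplier_bins(onset: float, config: SimConfig, n_bins: int,
                              next_onset: float | None) -> dict[int, float]:
    """Mean intensity multiplier per 1-s bin for one ping's response window:
    a flat ``response_fold`` for ``response_duration_s`` after the ping
    end, then exponential decay of the excess with time constant
    ``response_decay_s / 3``; the transmission seconds get 0 when
    suppression is on.  Truncated at the next ping's onset."""
    mult: dict[int, float] = {}
    end = onset + config.ping_dur_s
    flat_end = end + config.response_duration_s
    tau = config.response_decay_s / 3.0
    excess = config.response_fold - 1.0
    limit = next_onset if next_onset is not None else n_bins
    # the decayed excess is negligible after ~8 time constants
    tail_end = min(limit, flat_end + 8.0 * tau, n_bins)

    def m(t: float) -> float:
        if t < end:
            return 1.0
        if t < flat_end:
            return config.response_fold
        return 1.0 + excess * math.exp(-(t - flat_end) / tau)

    def mean_mult(lo: float, hi: float) -> float:
        # exact integral of the piecewise profile over [lo, hi)
        total = 0.0
        a = lo
        for cut in (end, flat_end, hi):
            b = min(hi, cut)
            if b <= a:
                continue
            if a >= flat_end:
                total += (b - a) + excess * tau * (
                    math.exp(-(a - flat_end) / tau) - math.exp(-(b - flat_end) / tau)
                )
            elif a >= end:
                total += config.response_fold * (b - a)
            else:
                total += (b - a)
            a = b
        return total / (hi - lo)

    if config.suppress_during_ping:
        for k in range(int(onset), min(int(math.ceil(end)), n_bins)):
            mult[k] = 0.0
    for k in range(int(end), int(math.ceil(tail_end))):
        if k >= n_bins:
            break
        if config.suppress_during_ping and k in mult:
            continue
        lo, hi = max(float(k), end), float(k + 1)
        if lo >= hi:
            continue
        v = mean_mult(lo, hi) * (hi - lo) + (lo - k) * 0.0
        # seconds straddling the transmission end mix suppressed (or
        # unmodified) transmission time with response time
        lead = lo - k
        lead_mult = 0.0 if config.suppress_during_ping else 1.0
        mult[k] = lead * lead_mult + v
    return mult


def inject_ping_response(counts: np.ndarray, schedule: PingSchedule, config: SimConfig,
                         intensity: np.ndarray, rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Resample counts around each ping to add the acoustic response.

    Seconds in a response window are redrawn with intensity scaled by the
    response profile (flat ``response_fold`` for ``response_duration_s``
    after the transmission ends, excess decaying exponentially);
    transmission seconds are zeroed when ``suppress_during_ping``.
    Seconds outside all windows are returned unchanged.  Returns the new
    counts and the list of (start, end) response windows.
    """
    counts = np.asarray(counts).copy()
    intensity = np.asarray(intensity, dtype=float)
    n = counts.size
    if schedule.onsets_s[-1] + schedule.duration_s > n:
        raise ValueError("counts do not cover the ping schedule")
    ends = schedule.onsets_s + config.ping_dur_s
    if np.any(ends[:-1] + config.response_duration_s > schedule.onsets_s[1:]):
        raise ValueError("response windows of consecutive pings overlap")
    if rng is None:
        rng = _spawn(config.seed, 4)
    null_response = config.response_fold == 1.0 and not config.suppress_during_ping
    windows = []
    for i, onset in enumerate(schedule.onsets_s):
        end = onset + config.ping_dur_s
        windows.append((float(end), float(end + config.response_duration_s)))
        if null_response:
            # the multiplier profile is identically 1: leave counts untouched
            continue
        nxt = schedule.onsets_s[i + 1] if i + 1 < schedule.n_pings else None
        mult = _response_multiplier_bins(onset, config, n, nxt)
        for k, m in mult.items():
            lam = intensity[k] * m
            counts[k] = 0 if lam == 0 else _draw_counts(np.array([lam]), config, rng)[0]
    return counts, windows


def _random_walk(rng: np.random.Generator, n_fixes: int, speed: float,
                 x0: float, y0: float, heading0: float, heading_sd: float = 0.3,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random walk in local metres: persistent heading with small
    per-minute turns, constant speed."""
    x = np.empty(n_fixes)
    y = np.empty(n_fixes)
    x[0], y[0] = x0, y0
    heading = heading0
    for i in range(1, n_fixes):
        heading += rng.normal(0.0, heading_sd)
        x[i] = x[i - 1] + 60.0 * speed * math.cos(heading)
        y[i] = y[i - 1] + 60.0 * speed * math.sin(heading)
    return x, y


def _to_track(pid: str, t: np.ndarray, x: np.ndarray, y: np.ndarray, config: SimConfig) -> Track:
    lat0, lon0 = config.origin_lat_deg, config.origin_lon_deg
    lat = lat0 + y * _DEG_PER_M_LAT
    lon = lon0 + x * _DEG_PER_M_LAT / math.cos(math.radians(lat0))
    return Track(pid, t, lat, lon)


def simulate_tracks(config: SimConfig, rng: np.random.Generator | None = None) -> list[Track]:
    """GPS tracks for the focal group and the drifting buoys, one fix per
    minute (inclusive endpoints).

    The default scenario starts each buoy within ~500 m of the group.  The
    ``"crossing"`` scenario sends the last buoy radially away from a start
    ~1.4 km out at a speed exceeding the group's, guaranteeing its
    distance crosses the 1.6-km exclusion threshold during the experiment.
    """
    if config.group_speed_mps < 0 or config.buoy_speed_mps < 0:
        raise ValueError("speeds must be non-negative")
    if rng is None:
        rng = _spawn(config.seed, 5)
    n_fixes = config.duration_s // 60 + 1
    t = 60.0 * np.arange(n_fixes)
    gx, gy = _random_walk(rng, n_fixes, config.group_speed_mps, 0.0, 0.0,
                          heading0=rng.uniform(0, 2 * math.pi))
    tracks = [_to_track("group", t, gx, gy, config)]
    for j in range(config.n_buoys):
        pid = f"buoy_{j + 1}"
        crossing = config.track_scenario == "crossing" and j == config.n_buoys - 1
        if crossing:
            theta = rng.uniform(0, 2 * math.pi)
            r0 = 1400.0
            speed = config.group_speed_mps + 1.0
            bx = r0 * math.cos(theta) + 60.0 * speed * math.cos(theta) * np.arange(n_fixes)
            by = r0 * math.sin(theta) + 60.0 * speed * math.sin(theta) * np.arange(n_fixes)
        else:
            r0, theta = rng.uniform(100.0, 500.0), rng.uniform(0, 2 * math.pi)
            bx, by = _random_walk(rng, n_fixes, config.buoy_speed_mps,
                                  r0 * math.cos(theta), r0 * math.sin(theta),
                                  heading0=rng.uniform(0, 2 * math.pi), heading_sd=0.15)
        tracks.append(_to_track(pid, t, bx, by, config))
    return tracks


def simulate_cee(config: SimConfig) -> SimulatedCEE:
    """Compose a full simulated experiment.

    Controls get a pseudo-ping schedule (the sonar timestamps with no
    injected response or suppression); sonar experiments get the response
    injection.  Reproducible bit-exactly for a fixed ``config.seed``.
    """
    rng_counts = _spawn(config.seed, 3)
    rng_inject = _spawn(config.seed, 4)
    rng_tracks = _spawn(config.seed, 5)
    rng_det = _spawn(config.seed, 6)

    states = simulate_vocal_states(config, "mean") if (
        config.n_states > 1 and config.mean_switch_rate > 0
    ) else np.zeros(config.duration_s, dtype=int)
    intensity = np.asarray(config.state_intensities, dtype=float)[states]
    counts = _draw_counts(intensity, config, rng_counts)

    schedule = make_ping_schedule(
        start_s=float(config.phase_bounds[1]), n_pings=config.n_pings,
        interval_s=config.ping_interval_s, ping_dur_s=config.ping_dur_s,
        phase_end_s=float(config.phase_bounds[2]), cee_id=config.cee_id,
        is_pseudo=(config.cee_type == "control"),
    )
    windows: list[tuple[float, float]] = []
    if config.cee_type == "mfas" and (config.response_fold != 1.0 or config.suppress_during_ping):
        counts, windows = inject_ping_response(counts, schedule, config, intensity, rng_inject)

    # every recorder detects the whistle train (fragment start times drawn
    # independently per buoy within their second)
    det = pd.concat(
        [
            _detections_from_counts(counts, config, rng_det, buoy_id=f"buoy_{j + 1}")
            for j in range(config.n_buoys)
        ],
        ignore_index=True,
    )
    tracks = simulate_tracks(config, rng_tracks)
    cs = CountSeries(
        counts=counts, mask=np.ones(config.duration_s, dtype=bool),
        phase=phase_labels(config.duration_s, config.phase_bounds), cee_id=config.cee_id,
    )
    rl_range = None
    if config.cee_type == "mfas" and config.rl_max_db is not None:
        rl_range = (config.rl_max_db - 8.0, config.rl_max_db)
    meta = CEEMeta(
        cee_id=config.cee_id, cee_type=config.cee_type, subspecies=config.subspecies,
        group_size=config.group_size,
        rl_max_db=config.rl_max_db if config.cee_type == "mfas" else None,
        rl_range_db=rl_range,
    )
    truth = {"states": states, "response_windows": windows, "intensity": intensity}
    return SimulatedCEE(config=config, detections=det, counts=cs, tracks=tracks,
                        schedule=schedule, meta=meta, truth=truth)


def write_cee_bundle(cee: SimulatedCEE, outdir: str | Path) -> dict[str, Path]:
    """Serialize a simulated experiment to the pipeline's CSV/YAML formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": outdir / f"{cee.config.cee_id}_detections.csv",
        "tracks": outdir / f"{cee.config.cee_id}_tracks.csv",
        "meta": outdir / f"{cee.config.cee_id}_meta.yaml",
    }
    det = cee.detections.copy()
    det.to_csv(paths["detections"], index=False, float_format="%.9f")
    pd.concat([t.to_frame() for t in cee.tracks], ignore_index=True).to_csv(
        paths["tracks"], index=False, float_format="%.9f"
    )
    meta = {
        "cee": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cee.meta).items()},
        "schedule": cee.schedule.to_dict(),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cee.config).items()},
    }
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths
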