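"""Locomotor track processing.

Converts raw pose-estimation tracks (one tracked center-point per animal)
into cleaned trajectories, movement bouts, hourly activity series on the
zeitgeber clock, and smoothed group mean profiles.

Pipeline: low-confidence frames (likelihood < 0.90) and tracking jumps
(> 2 cm per frame) are removed and linearly interpolated; an animal counts
as moving when its speed is at least 0.03 cm/s sustained for at least 3 s
(6 frames at 2 fps); everything else is treated as tracking noise. Bout
distance is summed into wall-clock hourly bins and normalized to each
animal's maximum hourly movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LocomotorTrack",
    "ActivitySeries",
    "GroupProfile",
    "Bout",
    "read_pose_csv",
    "write_pose_csv",
    "clean_track",
    "detect_movement",
    "bin_hourly",
    "group_mean_profile",
]


@dataclass
class LocomotorTrack:
    """Frame-level positions of one animal with tracking likelihoods.

    ``t`` is seconds since recording start at uniform 1/fps spacing;
    ``x``/``y`` are arena coordinates in cm; ``zt_offset_h`` is the ZT hour
    at the first frame (ZT0 = lights-on, or the coldest point of a dark
    temperature cycle).
    """

    animal_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    zt_offset_h: float = 0.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.likelihood) == n):
            raise ValueError("track arrays must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("t must be strictly increasing and uniform")
        if np.any((self.likelihood < 0) | (self.likelihood > 1)):
            raise ValueError("likelihood must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def fps(self) -> float:
        if len(self.t) < 2:
            return float("nan")
        return 1.0 / (self.t[1] - self.t[0])

    def displacement(self) -> np.ndarray:
        """Per-frame displacement in cm; frame i holds the step (i-1) -> i, frame 0 is 0."""
        d = np.zeros(self.n_frames)
        if self.n_frames > 1:
            d[1:] = np.hypot(np.diff(self.x), np.diff(self.y))
        return d


@dataclass
class Bout:
    start: int  # frame index, inclusive
    stop: int  # frame index, exclusive
    duration_s: float
    distance_cm: float


@dataclass
class ActivitySeries:
    """Hourly activity of one animal on the ZT clock."""

    animal_id: str
    zt_hours: np.ndarray  # integer hour label of each bin (not wrapped)
    distance_cm: np.ndarray
    pct_active: np.ndarray
    norm_distance: np.ndarray
    inactive: bool = False  # animal never moved; norm_distance defined as all-zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zt_h": self.zt_hours,
                "distance_cm": self.distance_cm,
                "pct_active": self.pct_active,
                "norm_distance": self.norm_distance,
            }
        )


@dataclass
class GroupProfile:
    group: str
    zt_hours: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_animals: int
    smoothed: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zt_h": self.zt_hours,
                "mean": self.mean,
                "sem": self.sem,
                "smoothed": self.smoothed,
            }
        )


# ---------------------------------------------------------------------------
# pose CSV dialect (3 header rows: scorer / bodyparts / coords)
# ---------------------------------------------------------------------------

def read_pose_csv(path, fps: float = 2.0, zt_offset_h: float = 0.0,
                  animal_id: str | None = None) -> LocomotorTrack:
    """Read a markerless-tracking output CSV with a single bodypart.

    The dialect has three header rows (scorer, bodyparts, coords) and an
    index column; data columns are x, y, likelihood. Empty coordinate cells
    yield likelihood 0 for that frame.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed pose CSV header in {path}: {exc}") from exc
    coords = [c[2].strip().lower() for c in df.columns]
    for needed in ("x", "y", "likelihood"):
        if needed not in coords:
            raise ValueError(
                f"pose CSV {path}: third header row (coords) lacks required "
                f"column '{needed}'; found {coords}"
            )
    bodyparts = sorted({c[1] for c in df.columns})
    if len(bodyparts) != 1:
        raise ValueError(f"pose CSV {path}: expected exactly one bodypart, got {bodyparts}")
    bp = bodyparts[0]
    scorer = df.columns[0][0]
    x = pd.to_numeric(df[(scorer, bp, "x")], errors="coerce").to_numpy(float)
    y = pd.to_numeric(df[(scorer, bp, "y")], errors="coerce").to_numpy(float)
    lik = pd.to_numeric(df[(scorer, bp, "likelihood")], errors="coerce").to_numpy(float)
    missing = np.isnan(x) | np.isnan(y) | np.isnan(lik)
    lik[missing] = 0.0
    x[np.isnan(x)] = 0.0
    y[np.isnan(y)] = 0.0
    n = len(x)
    t = np.arange(n) / float(fps)
    return LocomotorTrack(
        animal_id=animal_id or str(bp),
        t=t, x=x, y=y, likelihood=lik, zt_offset_h=zt_offset_h,
    )


def write_pose_csv(track: LocomotorTrack, path, scorer: str = "tracker") -> None:
    cols = pd.MultiIndex.from_product(
        [[scorer], [track.animal_id], ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"],
    )
    df = pd.DataFrame(
        np.column_stack([track.x, track.y, track.likelihood]), columns=cols
    )
    df.to_csv(path, float_format="%.6f")


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _interpolate_bad(x: np.ndarray, y: np.ndarray, bad: np.ndarray):
    """Replace bad frames by linear interpolation between nearest good frames.

    Leading/trailing bad frames take the nearest good value.
    """
    good = ~bad
    if not good.any():
        raise ValueError("all frames fail quality filters; nothing to interpolate from")
    idx = np.arange(len(x))
    xi = np.interp(idx, idx[good], x[good])
    yi = np.interp(idx, idx[good], y[good])
    return xi, yi


def clean_track(track: LocomotorTrack, likelihood_min: float = 0.90,
                max_jump_cm: float = 2.0) -> LocomotorTrack:
    """Remove low-likelihood frames and tracking jumps, interpolating over them.

    Frames with likelihood below ``likelihood_min`` are invalidated first;
    then frames entered by a displacement above ``max_jump_cm`` (computed on
    the likelihood-interpolated track) are invalidated too. All invalid
    frames get x, y linearly interpolated between the nearest valid frames;
    the jump rule is re-checked once after interpolation. Output length
    equals input length; likelihood values are preserved.
    """
    bad = track.likelihood < likelihood_min
    x, y = _interpolate_bad(track.x, track.y, bad)

    for _ in range(2):  # jump pass + one re-check, no fixpoint iteration
        step = np.zeros(len(x))
        step[1:] = np.hypot(np.diff(x), np.diff(y))
        jump = step > max_jump_cm
        if not jump.any():
            break
        bad = bad | jump
        x, y = _interpolate_bad(track.x, track.y, bad)

    return replace(track, x=x, y=y)


# ---------------------------------------------------------------------------
# movement bouts
# ---------------------------------------------------------------------------

def detect_movement(track: LocomotorTrack, v_min: float = 0.03,
                    min_dur_s: float = 3.0):
    """Segment a cleaned track into movement bouts.

    Speed at frame i is the displacement (i-1)->i times fps (frame 0 has
    speed 0). Maximal runs of frames with speed >= ``v_min`` cm/s lasting
    >= ``min_dur_s`` seconds are bouts; all other movement is noise.

    Returns
    -------
    mask : boolean array, True inside bouts
    bouts : list of Bout
    """
    fps = track.fps
    speed = track.displacement() * fps
    fast = speed >= v_min
    min_frames = int(round(min_dur_s * fps))
    mask = np.zeros(len(speed), dtype=bool)
    bouts: list[Bout] = []
    disp = track.displacement()
    i = 0
    n = len(fast)
    while i < n:
        if fast[i]:
            j = i
            while j < n and fast[j]:
                j += 1
            if j - i >= min_frames:
                mask[i:j] = True
                bouts.append(
                    Bout(
                        start=i,
                        stop=j,
                        duration_s=(j - i) / fps,
                        distance_cm=float(disp[i:j].sum()),
                    )
                )
            i = j
        else:
            i += 1
    return mask, bouts


# ---------------------------------------------------------------------------
# hourly binning and group profiles
# ---------------------------------------------------------------------------

def bin_hourly(track: LocomotorTrack, mask: np.ndarray) -> ActivitySeries:
    """Sum bout movement into wall-clock hourly bins on the ZT clock.

    The hour label of frame i is floor(zt_offset_h + t_i/3600); a partial
    first hour is binned to its clock hour. ``norm_distance`` is each bin's
    bout distance divided by the animal's maximum hourly distance (all zero,
    with the ``inactive`` flag set, if the animal never moved).
    """
    if track.n_frames == 0:
        raise ValueError("cannot bin an empty track")
    if len(mask) != track.n_frames:
        raise ValueError("mask length does not match track")
    hour = np.floor(track.zt_offset_h + track.t / 3600.0).astype(int)
    disp = track.displacement()
    hours = np.arange(hour.min(), hour.max() + 1)
    dist = np.zeros(len(hours))
    pct = np.zeros(len(hours))
    for k, h in enumerate(hours):
        in_h = hour == h
        dist[k] = disp[in_h & mask].sum()
        pct[k] = 100.0 * mask[in_h].mean() if in_h.any() else 0.0
    mx = dist.max()
    if mx > 0:
        norm = dist / mx
        inactive = False
    else:
        norm = np.zeros_like(dist)
        inactive = True
    return ActivitySeries(
        animal_id=track.animal_id,
        zt_hours=hours,
        distance_cm=dist,
        pct_active=pct,
        norm_distance=norm,
        inactive=inactive,
    )


def moving_average_even(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average for an even window: bin t averages t-w/2 .. t+w/2-1.

    Edges shrink the window to the available bins.
    """
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + window - half)
        out[i] = values[lo:hi].mean()
    return out


def group_mean_profile(series: list[ActivitySeries], group: str = "group",
                       smooth_h: int = 4, exclude_inactive: bool = True) -> GroupProfile:
    """Pointwise mean/SEM of member norm_distance plus a smoothed mean.

    Fully inactive animals (all-zero normalized series) are excluded from
    the average. Smoothing is a centered moving average over ``smooth_h``
    hourly bins (an even window covers bins t-2 .. t+1 for smooth_h=4).
    """
    members = [s for s in series if not (exclude_inactive and s.inactive)]
    if not members:
        raise ValueError("no active series to average")
    grid = members[0].zt_hours
    for s in members[1:]:
        if len(s.zt_hours) != len(grid) or np.any(s.zt_hours != grid):
            raise ValueError("activity series are not on a common ZT grid")
    mat = np.vstack([s.norm_distance for s in members])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(len(members)) if len(members) > 1 else np.zeros_like(mean)
    smoothed = moving_average_even(mean, smooth_h)
    return GroupProfile(
        group=group,
        zt_hours=grid,
        mean=mean,
        sem=sem,
        n_animals=len(members),
        smoothed=smoothed,
        meta={"smooth_h": smooth_h, "smoothing": "centered even window t-2..t+1"},
    )
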