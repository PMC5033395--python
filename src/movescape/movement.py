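"""Movement metrics and the foraging/travel speed threshold.

A *step* is the straight segment between two consecutive fixes; its speed
distribution in ungulates is a mixture of short foraging/resting movements
and long directional travel.  The broken-stick (change-point) model fits a
continuous two-segment line to the natural-log frequency distribution of
movement rates; its breakpoint is the speed threshold above which steps are
treated as directional travel and fed to the step-selection models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PHASE_CALENDAR",
    "BrokenStickFit",
    "net_displacement",
    "assign_phase",
    "compute_steps",
    "subsample_steps",
    "broken_stick_threshold",
    "filter_long_steps",
]

#: Default phase windows as (start, end) inclusive (month, day) pairs.
#: Spring movement deliberately overlaps summer residency (Jul-Aug).
PHASE_CALENDAR: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "winter_residency": ((1, 1), (3, 31)),
    "spring_movement": ((4, 1), (8, 31)),
    "summer_residency": ((7, 1), (8, 31)),
    "autumn_movement": ((9, 1), (11, 30)),
}

# single-label priority for steps: movement phases first (they feed the SSF)
_PHASE_PRIORITY = [
    "spring_movement",
    "autumn_movement",
    "winter_residency",
    "summer_residency",
]


@dataclass
class BrokenStickFit:
    """Two-segment fit to log frequency of movement rates."""

    threshold: float  # m/min
    slopes: tuple[float, float]  # (below, above)
    rss: float
    degenerate: bool
    n_bins: int = 0


def net_displacement(track: pd.DataFrame) -> pd.DataFrame:
    """Straight-line distance (km) from the first fix to every fix."""
    if len(track) == 0:
        raise ValueError("empty track")
    t = track.sort_values("timestamp")
    dx = t["x"].to_numpy() - t["x"].iloc[0]
    dy = t["y"].to_numpy() - t["y"].iloc[0]
    return pd.DataFrame(
        {"timestamp": t["timestamp"].to_numpy(), "nd_km": np.hypot(dx, dy) / 1000.0}
    )


def _window_mask(ts: pd.Series, window) -> np.ndarray:
    (m0, d0), (m1, d1) = window
    if (m1, d1) < (m0, d0):
        raise ValueError(f"malformed phase window: end {m1}-{d1} before start {m0}-{d0}")
    md = ts.dt.month * 100 + ts.dt.day
    return ((md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)).to_numpy()


def assign_phase(track: pd.DataFrame, calendar=None) -> pd.DataFrame:
    """Label each fix with every phase window containing its date.

    Windows may overlap (a July fix is both summer residency and spring
    movement); one boolean column ``in_<phase>`` is added per window, plus a
    single ``phase`` label resolved by priority (movement phases first,
    ``other`` when no window applies).
    """
    calendar = calendar or PHASE_CALENDAR
    out = track.copy()
    ts = pd.to_datetime(out["timestamp"])
    for name, window in calendar.items():
        out[f"in_{name}"] = _window_mask(ts, window)
    phase = np.full(len(out), "other", dtype=object)
    for name in reversed([p for p in _PHASE_PRIORITY if p in calendar]):
        phase[out[f"in_{name}"].to_numpy()] = name
    for name in calendar:
        if name not in _PHASE_PRIORITY:
            phase[out[f"in_{name}"].to_numpy()] = name
    out["phase"] = phase
    return out


def compute_steps(track: pd.DataFrame, nominal_interval: float | None = None) -> pd.DataFrame:
    """Steps between successive fixes of one or more animals.

    Returns one row per step with start/end geometry, length (m), duration
    (min), speed (m/min) and the signed turn angle in degrees in (-180, 180]
    relative to the previous step's bearing (NaN for each track's first
    step).  A step inherits the phase label of its start fix.  When
    ``nominal_interval`` (minutes) is given, steps spanning a gap longer
    than twice that interval are discarded.
    """
    frames = []
    for aid, t in track.groupby("animal_id", sort=False):
        t = t.sort_values("timestamp")
        ts = pd.to_datetime(t["timestamp"]).to_numpy()
        if len(ts) > 1 and (np.diff(ts) <= np.timedelta64(0)).any():
            raise ValueError(f"duplicate or unordered timestamps for animal {aid}")
        if len(ts) < 2:
            continue
        x, y = t["x"].to_numpy(), t["y"].to_numpy()
        dx, dy = np.diff(x), np.diff(y)
        dur = np.diff(ts) / np.timedelta64(1, "m")
        length = np.hypot(dx, dy)
        bearing = np.degrees(np.arctan2(dy, dx))
        turn = np.full(len(dx), np.nan)
        if len(dx) > 1:
            d = bearing[1:] - bearing[:-1]
            turn[1:] = -((-d + 180.0) % 360.0 - 180.0)  # map to (-180, 180]
        step = pd.DataFrame(
            {
                "animal_id": aid,
                "t_start": ts[:-1],
                "t_end": ts[1:],
                "x_start": x[:-1],
                "y_start": y[:-1],
                "x_end": x[1:],
                "y_end": y[1:],
                "length": length,
                "duration": dur,
                "speed": length / dur,
                "turn_angle": turn,
            }
        )
        if "phase" in t.columns:
            step["phase"] = t["phase"].to_numpy()[:-1]
        for col in t.columns:
            if col.startswith("in_"):
                step[col] = t[col].to_numpy()[:-1]
        frames.append(step)
    if not frames:
        return pd.DataFrame(
            columns=["animal_id", "t_start", "t_end", "x_start", "y_start", "x_end",
                     "y_end", "length", "duration", "speed", "turn_angle"]
        )
    steps = pd.concat(frames, ignore_index=True)
    if nominal_interval is not None:
        keep = steps["duration"] <= 2 * nominal_interval
        dropped = int((~keep).sum())
        if dropped:
            log.info("discarded %d steps spanning gaps > %.0f min", dropped, 2 * nominal_interval)
        steps = steps[keep].reset_index(drop=True)
    return steps


def subsample_steps(steps: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Equal-weight subsample: up to ``n`` steps per animal, uniform without
    replacement.  Animals with fewer than ``n`` steps keep them all (logged)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    parts = []
    for aid, t in steps.groupby("animal_id", sort=True):
        if len(t) <= n:
            if len(t) < n:
                log.warning("animal %s has only %d steps (< %d requested)", aid, len(t), n)
            parts.append(t)
        else:
            parts.append(t.iloc[np.sort(rng.choice(len(t), size=n, replace=False))])
    return pd.concat(parts, ignore_index=True)


def _two_segment_rss(x, y, brk):
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - brk, 0.0)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def broken_stick_threshold(speeds, n_bins: int = 50) -> BrokenStickFit:
    """Breakpoint of the two-segment fit to log_e speed-bin frequencies.

    Speeds are binned into ``n_bins`` equal-width bins over the 0.1-99.9
    percentile range; the natural log of non-zero bin counts is regressed on
    bin midpoints with a continuous two-segment line, the breakpoint grid-
    searched over every interior bin boundary.  The RSS-minimising breakpoint
    is the threshold separating foraging from long directional movements.
    """
    speeds = np.asarray(speeds, dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if speeds.size < 100:
        raise ValueError("need at least 100 speeds")
    if n_bins < 6:
        raise ValueError("need at least 6 bins")
    lo, hi = np.percentile(speeds, [0.1, 99.9])
    if hi <= lo:
        return BrokenStickFit(float(speeds[0]), (0.0, 0.0), 0.0, True, 0)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(speeds, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    nz = counts > 0
    x, y = mids[nz], np.log(counts[nz])
    # candidates: interior bin boundaries with >= 3 populated bins per side
    candidates = [e for e in edges[1:-1] if (x < e).sum() >= 3 and (x > e).sum() >= 3]
    if not candidates:
        raise ValueError("too few populated bins on one side of every candidate breakpoint")
    X1 = np.column_stack([np.ones_like(x), x])
    c1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(np.sum((y - X1 @ c1) ** 2))
    best = min((_two_segment_rss(x, y, b) + (b,) for b in candidates), key=lambda r: r[0])
    rss, coef, brk = best
    slope_below, slope_above = float(coef[1]), float(coef[1] + coef[2])
    # slopes indistinguishable (single-regime data): relative difference
    # below 1%, or the two-segment fit buys essentially nothing over a line
    scale = max(abs(slope_below), abs(slope_above), 1e-12)
    degenerate = abs(coef[2]) <= 0.01 * scale or (rss1 - rss) <= 1e-9 * max(1.0, rss1)
    return BrokenStickFit(float(brk), (slope_below, slope_above), rss, bool(degenerate), n_bins)


def filter_long_steps(steps: pd.DataFrame, fit: BrokenStickFit) -> pd.DataFrame:
    """Steps strictly faster than the broken-stick threshold."""
    if fit.degenerate:
        raise ValueError(
            "degenerate broken-stick fit: no two-regime structure; inspect the speed distribution"
        )
    return steps[steps["speed"] > fit.threshold].reset_index(drop=True)
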