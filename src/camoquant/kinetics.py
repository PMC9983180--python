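"""Colour-change kinetics: proportional luminance change over time.

In the rapid-change experiment each fish is moved from a black to a white
compartment and its dorsal-patch luminance-channel catch is measured at
0, 5, 10, 15, 20, 25 and 60 s.  The response is summarized as the
proportional change ``(L_t - L_0) / (L_60 - L_0)``, which is 0 at t=0 and 1
at t=60 by construction and is invariant to affine rescaling of the
luminance axis.  Fish whose total change |L_60 - L_0| falls below a small
tolerance did not respond and are excluded before this normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "STANDARD_TIMES_S",
    "NONRESPONSE_TOL",
    "exclude_nonresponders",
    "proportional_change",
    "proportional_change_curve",
    "summarize_rate",
    "time_to_fraction",
    "read_trajectories_csv",
]

logger = logging.getLogger(__name__)

STANDARD_TIMES_S = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 60.0)

#: A fish changing less than this (luminance-channel catch units) between
#: t=0 and t=60 s is treated as a non-responder.
NONRESPONSE_TOL = 0.001


@dataclass(frozen=True)
class Trajectory:
    """Per-fish time series of luminance-channel catches."""

    fish_id: str
    species: str
    times_s: tuple[float, ...]
    luminance: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        lum = np.asarray(self.luminance, dtype=float)
        if t.shape != lum.shape or t.ndim != 1:
            raise ValueError("times and luminance must be equal-length 1-D sequences")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0.0 or t[-1] != 60.0:
            raise ValueError("a trajectory must include t=0 and t=60 s")
        if np.any(lum <= 0):
            raise ValueError("luminance catches must be positive")
        object.__setattr__(self, "times_s", tuple(t))
        object.__setattr__(self, "luminance", tuple(lum))

    @property
    def total_change(self) -> float:
        return self.luminance[-1] - self.luminance[0]


def exclude_nonresponders(trajs: list[Trajectory],
                          tol: float = NONRESPONSE_TOL) -> list[Trajectory]:
    """Drop trajectories with |L_60 - L_0| < tol; removals are logged."""
    kept = []
    for tr in trajs:
        if abs(tr.total_change) < tol:
            logger.info(
                "excluding non-responder %s (%s): |L60 - L0| = %.5f < %.5f",
                tr.fish_id, tr.species, abs(tr.total_change), tol,
            )
        else:
            kept.append(tr)
    return kept


def proportional_change(traj: Trajectory, t: float,
                        tol: float = NONRESPONSE_TOL) -> float:
    """(L_t - L_0) / (L_60 - L_0) at a sampled time point."""
    if abs(traj.total_change) < tol:
        raise ZeroDivisionError(
            f"trajectory {traj.fish_id}: total change below tolerance; "
            "exclude non-responders first"
        )
    times = np.asarray(traj.times_s)
    idx = np.nonzero(np.isclose(times, t))[0]
    if idx.size == 0:
        raise ValueError(f"t={t} s not among sampled times {traj.times_s}")
    lum = np.asarray(traj.luminance)
    return float((lum[idx[0]] - lum[0]) / traj.total_change)


def proportional_change_curve(traj: Trajectory) -> np.ndarray:
    """Proportional change at every sampled time point."""
    return np.array([proportional_change(traj, t) for t in traj.times_s])


def summarize_rate(trajs: list[Trajectory]) -> pd.DataFrame:
    """Per-time-point median and interquartile range of proportional change.

    All trajectories must share the same sampling times.  Values are not
    clipped to [0, 1]: overshoot in non-monotone fish is real signal.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    times = trajs[0].times_s
    for tr in trajs[1:]:
        if tr.times_s != times:
            raise ValueError("trajectories have differing sampling times")
    mat = np.vstack([proportional_change_curve(tr) for tr in trajs])
    return pd.DataFrame({
        "time_s": times,
        "median": np.median(mat, axis=0),
        "q25": np.quantile(mat, 0.25, axis=0),
        "q75": np.quantile(mat, 0.75, axis=0),
        "n": len(trajs),
    })


def time_to_fraction(summary: pd.DataFrame, p: float,
                     method: str = "interpolate") -> float:
    """First time the median proportional-change curve reaches fraction p.

    ``interpolate`` (default) interpolates linearly between sampled medians;
    ``nearest`` returns the first sampled time whose median >= p.  If the
    median curve never reaches p within 60 s, returns ``inf`` (reported as
    "> 60 s").
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    t = summary["time_s"].to_numpy(dtype=float)
    med = summary["median"].to_numpy(dtype=float)
    reached = np.nonzero(med >= p)[0]
    if reached.size == 0:
        return float("inf")
    i = reached[0]
    if method == "nearest":
        return float(t[i])
    if method != "interpolate":
        raise ValueError("method must be 'interpolate' or 'nearest'")
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    m0, m1 = med[i - 1], med[i]
    return float(t0 + (p - m0) / (m1 - m0) * (t1 - t0))


def read_trajectories_csv(path) -> list[Trajectory]:
    """Read long-format CSV (fish_id, species, time_s, luminance)."""
    df = pd.read_csv(path)
    required = {"fish_id", "species", "time_s", "luminance"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out = []
    for (fid, sp), g in df.groupby(["fish_id", "species"], sort=False):
        g = g.sort_values("time_s")
        out.append(Trajectory(str(fid), str(sp),
                              tuple(g["time_s"]), tuple(g["luminance"])))
    return out
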