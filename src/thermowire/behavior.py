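"""Behavioral statistics: treadmill odor responses, arena occupancy, speed modes.

Covers the three quantifications used on walking flies:

* tethered (spherical-treadmill) odor responses — per-trial change in moving
  speed over the first 2 s of stimulation relative to the 3-s pre-stimulus
  baseline, discarding flies whose baseline walking is below 2 mm/s;
* free-walking odor occupancy — the time-normalized integral, over the first
  7 minutes, of the fraction of flies within 5 cm of the odor source;
* the bimodal walking-speed distribution — a point mass of inactive frames
  near zero plus a Gaussian a*exp[-((x-b)/c)^2] over active speeds, whose
  amplitude estimates activity level and whose mean the active walking speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InvalidArgumentError

__all__ = [
    "TrajectorySet",
    "SpeedDistribution",
    "GaussianActiveFit",
    "TreadmillResult",
    "treadmill_response",
    "at_source_fraction",
    "odor_occupancy",
    "fit_speed_modes",
    "walking_speeds",
]

ARENA_RADIUS_CM = 20.1
SOURCE_THRESHOLD_CM = 5.0
OCCUPANCY_WINDOW_S = 420.0


@dataclass(frozen=True)
class TrajectorySet:
    """Tracked positions of a group of flies in a circular arena.

    ``positions`` has columns (fly, t_s, x_cm, y_cm) on a common frame grid;
    the origin is the arena center.
    """

    positions: pd.DataFrame
    source_xy: tuple[float, float]
    arena_radius: float = ARENA_RADIUS_CM
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        df = self.positions
        missing = [c for c in ("fly", "t_s", "x_cm", "y_cm") if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"positions missing columns {missing}")
        if len(df):
            r = np.hypot(df["x_cm"], df["y_cm"]).to_numpy()
            if np.any(r > self.arena_radius * 1.05 + 0.5):
                raise InvalidArgumentError("positions fall outside the arena")
            for _, g in df.groupby("fly"):
                t = g["t_s"].to_numpy()
                if np.any(np.diff(t) <= 0):
                    raise InvalidArgumentError("time must be strictly increasing per fly")
        sx, sy = self.source_xy
        if np.hypot(sx, sy) > self.arena_radius:
            raise InvalidArgumentError("odor source must lie inside the arena")

    @property
    def n_flies(self) -> int:
        return int(self.positions["fly"].nunique())

    @property
    def duration_s(self) -> float:
        return float(self.positions["t_s"].max()) if len(self.positions) else 0.0


@dataclass(frozen=True)
class TreadmillResult:
    """Per-trial speed changes and the per-fly summary of a treadmill session."""

    trials: pd.DataFrame  # columns: onset_s, basal, response, delta
    session_basal: float
    mean_delta: float
    included: bool


def treadmill_response(
    speed: np.ndarray,
    frame_rate: float,
    onsets_s,
    basal_window_s: float = 3.0,
    response_window_s: float = 2.0,
    min_basal: float = 2.0,
) -> TreadmillResult:
    """Odor-evoked speed change for one tethered fly.

    Per trial, delta = mean speed in the first ``response_window_s`` after
    onset minus the basal speed in the ``basal_window_s`` before onset.
    Trials whose windows fall outside the recording are skipped with a
    warning.  The fly is excluded (``included=False``, NaN mean) when its
    session-average basal speed is below ``min_basal`` mm/s.
    """
    speed = np.asarray(speed, float)
    if speed.ndim != 1 or speed.size == 0:
        raise InvalidArgumentError("speed must be a non-empty 1-D series")
    onsets = sorted(float(o) for o in onsets_s)
    n = speed.size
    rows = []
    for onset in onsets:
        i0 = int(round((onset - basal_window_s) * frame_rate))
        i1 = int(round(onset * frame_rate))
        i2 = int(round((onset + response_window_s) * frame_rate))
        if i0 < 0 or i2 > n:
            warnings.warn(
                f"trial at {onset} s extends past the recording; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        basal = float(speed[i0:i1].mean())
        response = float(speed[i1:i2].mean())
        rows.append({"onset_s": onset, "basal": basal, "response": response,
                     "delta": response - basal})
    trials = pd.DataFrame(rows, columns=["onset_s", "basal", "response", "delta"])
    if trials.empty:
        return TreadmillResult(trials, np.nan, np.nan, False)
    session_basal = float(trials["basal"].mean())
    included = session_basal >= min_basal
    mean_delta = float(trials["delta"].mean()) if included else float("nan")
    return TreadmillResult(trials, session_basal, mean_delta, included)


def at_source_fraction(
    trajs: TrajectorySet, threshold: float = SOURCE_THRESHOLD_CM
) -> pd.Series:
    """Fraction of flies within ``threshold`` cm of the source, per frame.

    Indexed by time (s); values in [0, 1].  Empty for an empty trajectory set.
    """
    df = trajs.positions
    if df.empty:
        return pd.Series(dtype=float, name="at_source_fraction")
    sx, sy = trajs.source_xy
    near = np.hypot(df["x_cm"] - sx, df["y_cm"] - sy) <= threshold
    frac = near.groupby(df["t_s"]).mean()
    frac.name = "at_source_fraction"
    return frac


def odor_occupancy(
    trajs: TrajectorySet,
    threshold: float = SOURCE_THRESHOLD_CM,
    window_s: float = OCCUPANCY_WINDOW_S,
) -> float:
    """Time-normalized integral of the at-source fraction over the first window.

    1 when every fly spends the whole window at the odor source; 0 when no
    fly ever comes within the threshold.
    """
    if trajs.duration_s < window_s:
        raise InvalidArgumentError(
            f"recording lasts {trajs.duration_s:.1f} s but the occupancy window "
            f"requires at least {window_s:.1f} s"
        )
    frac = at_source_fraction(trajs, threshold)
    t = frac.index.to_numpy(float)
    mask = t <= window_s
    return float(np.trapezoid(frac.to_numpy()[mask], t[mask]) / (t[mask][-1] - t[mask][0]))


def walking_speeds(trajs: TrajectorySet) -> np.ndarray:
    """Walking speed (mm/s) pooled over flies and frames, by central differences."""
    speeds = []
    for _, g in trajs.positions.groupby("fly"):
        t = g["t_s"].to_numpy(float)
        x = g["x_cm"].to_numpy(float)
        y = g["y_cm"].to_numpy(float)
        if t.size < 3:
            continue
        vx = np.gradient(x, t)
        vy = np.gradient(y, t)
        speeds.append(np.hypot(vx, vy) * 10.0)  # cm/s -> mm/s
    if not speeds:
        return np.empty(0)
    return np.concatenate(speeds)


@dataclass(frozen=True)
class SpeedDistribution:
    """Probability-mass histogram of walking speed with its inactive peak."""

    bin_centers: np.ndarray
    probabilities: np.ndarray
    zero_peak_mass: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise InvalidArgumentError("probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class GaussianActiveFit:
    """Gaussian a*exp[-((x-b)/c)^2] fitted to the active-speed mode.

    ``amplitude`` (a) is on the probability-per-bin scale and estimates
    activity level; ``mean`` (b, mm/s) the typical active walking speed;
    ``width`` (c, mm/s) the Gaussian width parameter.  ``ci`` maps each
    parameter to its 95% confidence half-interval from the fit covariance.
    """

    amplitude: float
    mean: float
    width: float
    ci: dict

    def __post_init__(self) -> None:
        if not (0.0 < self.amplitude <= 1.0):
            raise InvalidArgumentError("amplitude must lie in (0, 1]")
        if not (self.mean > 0 and self.width > 0):
            raise InvalidArgumentError("mean and width must be > 0")


def _gauss(x, a, b, c):
    return a * np.exp(-(((x - b) / c) ** 2))


def fit_speed_modes(
    speeds: np.ndarray,
    inactive_cut: float = 1.0,
    bin_width: float = 1.0,
) -> tuple[SpeedDistribution, GaussianActiveFit]:
    """Decompose pooled walking speeds into an inactive peak and an active Gaussian.

    Frames below ``inactive_cut`` mm/s form the zero peak; the Gaussian is
    fitted by least squares to the probability-mass histogram (bins of
    ``bin_width`` mm/s) above the cut.  Raises :class:`FitError` when the
    active mode is empty or degenerate (e.g. all samples identical).
    """
    speeds = np.asarray(speeds, float)
    if speeds.size < 10:
        raise InvalidArgumentError("need at least 10 speed samples")
    if np.any(speeds < 0):
        raise InvalidArgumentError("speeds must be non-negative")
    zero_mass = float(np.mean(speeds < inactive_cut))
    hi = float(speeds.max())
    if hi <= inactive_cut:
        raise FitError("all samples fall below the inactive cut; no active mode to fit")
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(speeds, bins=edges)
    probs = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    dist = SpeedDistribution(centers, probs, zero_mass)

    active = centers >= inactive_cut
    x, y = centers[active], probs[active]
    active_speeds = speeds[speeds >= inactive_cut]
    if np.ptp(active_speeds) < 1e-9 or np.count_nonzero(y) < 3:
        raise FitError("active speeds are degenerate; Gaussian fit is not identifiable")
    p0 = (max(y.max(), 1e-6), float(active_speeds.mean()),
          max(float(active_speeds.std()) * np.sqrt(2.0), bin_width))
    try:
        popt, pcov = curve_fit(_gauss, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    a, b, c = float(popt[0]), float(popt[1]), float(abs(popt[2]))
    if not np.all(np.isfinite(pcov)):
        raise FitError("Gaussian fit covariance is singular (degenerate active mode)")
    half = 1.96 * np.sqrt(np.diag(pcov))
    fit = GaussianActiveFit(
        amplitude=a, mean=b, width=c,
        ci={"amplitude": float(half[0]), "mean": float(half[1]), "width": float(half[2])},
    )
    return dist, fit
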