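"""Aggregate motility and merging kinematics from trajectory tables.

Per-track speed and path-directness measures, the ensemble mean-squared
displacement scaling exponent, relative-distance series of merging pairs
with constant-acceleration (quadratic) fits and distance-dependent force
law fits, and cohort-level summary statistics (merge-class fractions,
Spearman correlations, unpaired t-test of merger vs non-merger speeds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .detect import NON_MERGER, THREE_SPOT_MERGER, TWO_SPOT_MERGER

__all__ = [
    "Trajectory",
    "KinematicsFit",
    "MSDResult",
    "ForceLawFit",
    "average_speed",
    "distance_over_displacement",
    "msd_exponent",
    "relative_distance",
    "merging_kinematics",
    "collision_point_kinematics",
    "force_law_fit",
    "cohort_summary",
    "MIN_MERGING_POINTS",
]

# Merging trajectories with fewer positions than this are excluded from
# kinematic fitting (their dynamics cannot be determined accurately).
MIN_MERGING_POINTS = 20


@dataclass
class Trajectory:
    """One aggregate track: times, positions, and optional areas."""

    track_id: int
    times: np.ndarray  # (n,) strictly increasing
    positions: np.ndarray  # (n, 2)
    areas: np.ndarray | None = None
    merge_class: str = NON_MERGER

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 2):
            raise ValueError("times must be (n,) and positions (n, 2)")
        if self.times.size < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.areas is not None:
            self.areas = np.asarray(self.areas, dtype=float)

    @property
    def n(self) -> int:
        return self.times.size

    def path_length(self) -> float:
        steps = np.diff(self.positions, axis=0)
        return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


@dataclass
class KinematicsFit:
    """Constant-acceleration fit d(t) = d0 - v0*t - (a/2)*t^2.

    ``acceleration`` is the closing acceleration: positive when the
    approach speeds up (relative distance concave down).  ``v0`` is the
    initial closing speed and ``d0`` the initial separation.
    """

    acceleration: float
    v0: float
    d0: float
    rms_residual: float
    n_points: int


@dataclass
class MSDResult:
    """Power-law fit MSD(t) ~ prefactor * t^alpha on log-log axes."""

    alpha: float
    prefactor: float
    lags: np.ndarray
    msd: np.ndarray


@dataclass
class ForceLawFit:
    """Distance-dependent force law fit a(d) for a merging pair.

    ``model='exponential'`` fits a(d) = A0 * exp(-n d); ``model='power'``
    fits a(d) = A0 / d^n.  Fits whose exponent standard error reaches 50%
    of |n| (or that fail to converge) are flagged ``excluded``.
    """

    model: str
    A0: float
    n: float
    se_A0: float
    se_n: float
    excluded: bool
    reason: str = ""


def average_speed(traj: Trajectory) -> float:
    """Total path length divided by elapsed time."""
    elapsed = traj.times[-1] - traj.times[0]
    if elapsed <= 0:
        raise ValueError("zero elapsed time")
    return traj.path_length() / elapsed


def distance_over_displacement(traj: Trajectory) -> float:
    """Path length over net displacement (>= 1; straight line gives 1).

    Returns NaN when the net displacement is zero (undefined, excluded
    from cohort averages rather than reported as infinite).
    """
    net = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    if net == 0:
        return np.nan
    return traj.path_length() / net


def msd_exponent(
    trajs: Sequence[Trajectory],
    max_lag_fraction: float = 0.5,
) -> MSDResult:
    """Anomalous-diffusion exponent from the ensemble MSD.

    Squared displacement from each track's first point is averaged over
    tracks at common lag times (tracks are assumed uniformly sampled with
    a shared frame interval).  A least-squares line on log-log axes over
    lags up to ``max_lag_fraction`` of the shortest track's duration gives
    the exponent alpha (1 diffusive, 2 ballistic).
    """
    if not trajs:
        raise ValueError("no trajectories given")
    n_min = min(t.n for t in trajs)
    max_lag = max(2, int(np.floor((n_min - 1) * max_lag_fraction)))
    if max_lag < 5:
        raise ValueError(
            f"insufficient lags for MSD fit: {max_lag} < 5 "
            "(tracks too short for the requested lag fraction)"
        )
    lags_idx = np.arange(1, max_lag + 1)
    dt0 = trajs[0].times[1] - trajs[0].times[0]
    sq = np.empty((len(trajs), max_lag))
    for ti, tr in enumerate(trajs):
        disp = tr.positions[lags_idx] - tr.positions[0]
        sq[ti] = np.sum(disp**2, axis=1)
    msd = sq.mean(axis=0)
    lags_t = lags_idx * dt0
    good = msd > 0
    if np.sum(good) < 5:
        raise ValueError("insufficient nonzero MSD values for log-log fit")
    slope, intercept = np.polyfit(np.log(lags_t[good]), np.log(msd[good]), 1)
    return MSDResult(
        alpha=float(slope),
        prefactor=float(np.exp(intercept)),
        lags=lags_t,
        msd=msd,
    )


def relative_distance(
    a: Trajectory, b: Trajectory
) -> tuple[np.ndarray, np.ndarray]:
    """Separation |r_A(t) - r_B(t)| at the common times of both tracks."""
    common, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    if common.size == 0:
        raise ValueError("trajectories share no common times")
    delta = a.positions[ia] - b.positions[ib]
    return common, np.hypot(delta[:, 0], delta[:, 1])


def merging_kinematics(
    times: np.ndarray,
    d_rel: np.ndarray,
    *,
    min_points: int = MIN_MERGING_POINTS,
) -> KinematicsFit:
    """Constant-acceleration (quadratic) fit to a relative-distance series.

    Least squares of d(t) = c0 + c1*t + c2*t^2; reported as initial
    separation d0 = c0, initial closing speed v0 = -c1, and closing
    acceleration a = -2*c2 so an accelerating approach is positive.
    """
    times = np.asarray(times, dtype=float)
    d_rel = np.asarray(d_rel, dtype=float)
    if times.size != d_rel.size:
        raise ValueError("times and d_rel must have equal length")
    if times.size < min_points:
        raise ValueError(
            f"merging trajectory has {times.size} points; "
            f"at least {min_points} required for kinematic fitting"
        )
    t0 = times - times[0]
    c2, c1, c0 = np.polyfit(t0, d_rel, 2)
    resid = d_rel - (c0 + c1 * t0 + c2 * t0**2)
    return KinematicsFit(
        acceleration=float(-2.0 * c2),
        v0=float(-c1),
        d0=float(c0),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=times.size,
    )


def _accel_vs_distance(
    times: np.ndarray, d_rel: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closing acceleration estimated by central second differences of a
    3-point moving average of d_rel (the smoothing tames frame noise that
    second differences would otherwise amplify)."""
    d = np.convolve(d_rel, np.ones(3) / 3.0, mode="valid")
    t = times[1:-1]
    dt = np.diff(times).mean()
    a = -(d[2:] - 2.0 * d[1:-1] + d[:-2]) / dt**2
    return d[1:-1], a


def collision_point_kinematics(
    a: Trajectory,
    b: Trajectory,
    *,
    min_points: int = MIN_MERGING_POINTS,
) -> tuple[KinematicsFit, KinematicsFit]:
    """Constant-acceleration fits of each partner's distance to the
    collision point.

    The collision point is taken as the midpoint of the two tracks at
    their last common time.  Each track's distance-to-collision series is
    fit with the same quadratic model as :func:`merging_kinematics`,
    giving one acceleration per aggregate instead of one per pair.
    """
    common, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    if common.size == 0:
        raise ValueError("trajectories share no common times")
    collision = 0.5 * (a.positions[ia[-1]] + b.positions[ib[-1]])
    fits = []
    for tr, idx in ((a, ia), (b, ib)):
        d = np.linalg.norm(tr.positions[idx] - collision, axis=1)
        fits.append(merging_kinematics(common, d, min_points=min_points))
    return fits[0], fits[1]


def force_law_fit(
    times: np.ndarray,
    d_rel: np.ndarray,
    model: str = "exponential",
) -> ForceLawFit:
    """Fit a distance-dependent force law to a merging pair's acceleration.

    Acceleration is estimated by differencing the smoothed d_rel series,
    then fit against distance under the chosen model by nonlinear least
    squares.  Non-convergence or a relative exponent error >= 50% flags the
    fit as excluded rather than raising.
    """
    if model not in ("exponential", "power"):
        raise ValueError("model must be 'exponential' or 'power'")
    times = np.asarray(times, dtype=float)
    d_rel = np.asarray(d_rel, dtype=float)
    if times.size < 7:
        return ForceLawFit(model, np.nan, np.nan, np.nan, np.nan, True, "too short")
    d, a = _accel_vs_distance(times, d_rel)
    ok = d > 0
    d, a = d[ok], a[ok]
    if d.size < 5:
        return ForceLawFit(model, np.nan, np.nan, np.nan, np.nan, True, "too short")

    if model == "exponential":
        func = lambda x, A0, n: A0 * np.exp(-n * x)  # noqa: E731
        p0 = (np.mean(a) if np.mean(a) != 0 else 1.0, 1.0 / np.mean(d))
    else:
        func = lambda x, A0, n: A0 / x**n  # noqa: E731
        p0 = (np.mean(a) if np.mean(a) != 0 else 1.0, 0.5)
    try:
        popt, pcov = optimize.curve_fit(func, d, a, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return ForceLawFit(model, np.nan, np.nan, np.nan, np.nan, True, "no convergence")
    se = np.sqrt(np.diag(pcov))
    A0, n = popt
    excluded = not np.isfinite(se[1]) or abs(n) == 0 or se[1] / abs(n) >= 0.5
    return ForceLawFit(
        model=model,
        A0=float(A0),
        n=float(n),
        se_A0=float(se[0]),
        se_n=float(se[1]),
        excluded=bool(excluded),
        reason="exponent error >= 50%" if excluded else "",
    )


def _min_nn_distance_per_track(trajs: Sequence[Trajectory]) -> dict[int, float]:
    """Average over frames of each track's per-frame minimum distance to any
    co-existing track (plain nearest neighbor, not Voronoi)."""
    times = sorted({t for tr in trajs for t in tr.times})
    per_track: dict[int, list[float]] = {tr.track_id: [] for tr in trajs}
    index = [dict(zip(tr.times, range(tr.n))) for tr in trajs]
    for t in times:
        present = [
            (tr.track_id, tr.positions[index[k][t]])
            for k, tr in enumerate(trajs)
            if t in index[k]
        ]
        if len(present) < 2:
            continue
        ids = [p[0] for p in present]
        xy = np.array([p[1] for p in present])
        dmat = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
        np.fill_diagonal(dmat, np.inf)
        mins = dmat.min(axis=1)
        for tid, m in zip(ids, mins):
            per_track[tid].append(float(m))
    return {
        tid: float(np.mean(v)) if v else np.nan for tid, v in per_track.items()
    }


def cohort_summary(
    trajs: Sequence[Trajectory],
    *,
    merging_accelerations: dict[int, float] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Cohort statistics over classified trajectories.

    Returns a one-row DataFrame with per-class counts/fractions and mean
    speeds and path-directness ratios, the Spearman correlation of merging
    acceleration vs total merged area (if accelerations are supplied), the
    Spearman correlation of non-merger speed vs mean minimum
    nearest-neighbor distance, and the unpaired t-test (Student by
    default, Welch with ``equal_var=False``) of merger vs non-merger
    speeds.  Statistics whose inputs are degenerate come back NaN.
    """
    rows = []
    for tr in trajs:
        rows.append(
            {
                "track_id": tr.track_id,
                "merge_class": tr.merge_class,
                "speed": average_speed(tr),
                "dist_over_disp": distance_over_displacement(tr),
                "mean_area": float(np.mean(tr.areas)) if tr.areas is not None else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    out: dict[str, float] = {"n_tracks": len(df)}
    for cls in (NON_MERGER, TWO_SPOT_MERGER, THREE_SPOT_MERGER):
        sub = df[df.merge_class == cls]
        out[f"n_{cls}"] = len(sub)
        out[f"frac_{cls}"] = len(sub) / len(df) if len(df) else np.nan
        out[f"mean_speed_{cls}"] = sub.speed.mean() if len(sub) >= 2 else np.nan
        out[f"mean_dist_over_disp_{cls}"] = (
            sub.dist_over_disp.mean() if len(sub) >= 2 else np.nan
        )

    mergers = df[df.merge_class != NON_MERGER]
    non = df[df.merge_class == NON_MERGER]
    out["mean_speed_mergers"] = mergers.speed.mean() if len(mergers) >= 2 else np.nan
    if len(mergers) >= 2 and len(non) >= 2 and (
        mergers.speed.std() > 0 or non.speed.std() > 0
    ):
        tstat, pval = stats.ttest_ind(
            mergers.speed, non.speed, equal_var=equal_var
        )
        out["speed_ttest_t"], out["speed_ttest_p"] = float(tstat), float(pval)
    else:
        out["speed_ttest_t"] = out["speed_ttest_p"] = np.nan

    if merging_accelerations:
        sub = df[df.track_id.isin(merging_accelerations)]
        accel = np.array([merging_accelerations[t] for t in sub.track_id])
        area = sub.mean_area.to_numpy()
        ok = np.isfinite(accel) & np.isfinite(area)
        if np.sum(ok) >= 3:
            rho, p = stats.spearmanr(accel[ok], area[ok])
            out["spearman_accel_area"], out["spearman_accel_area_p"] = float(rho), float(p)
        else:
            out["spearman_accel_area"] = out["spearman_accel_area_p"] = np.nan
    else:
        out["spearman_accel_area"] = out["spearman_accel_area_p"] = np.nan

    non_trajs = [tr for tr in trajs if tr.merge_class == NON_MERGER]
    if len(non_trajs) >= 3:
        min_nn = _min_nn_distance_per_track(list(trajs))
        speeds = np.array([average_speed(tr) for tr in non_trajs])
        nn = np.array([min_nn[tr.track_id] for tr in non_trajs])
        ok = np.isfinite(speeds) & np.isfinite(nn)
        if np.sum(ok) >= 3 and np.std(nn[ok]) > 0 and np.std(speeds[ok]) > 0:
            rho, p = stats.spearmanr(speeds[ok], nn[ok])
            out["spearman_speed_min_nn"], out["spearman_speed_min_nn_p"] = (
                float(rho),
                float(p),
            )
        else:
            out["spearman_speed_min_nn"] = out["spearman_speed_min_nn_p"] = np.nan
    else:
        out["spearman_speed_min_nn"] = out["spearman_speed_min_nn_p"] = np.nan

    return pd.DataFrame([out])
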