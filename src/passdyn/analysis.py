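"""Measurement operators over simulated (or imported) sessions.

Implements the study's analysis suite: per-target pass rates and 50 %
transition points (with their E/A conversion), trajectory time
normalisation, chord-deviation curvature and initial movement angles,
velocity profiles, trajectory heat maps, K-means clustering of release
locations with a Monte-Carlo reference for choosing k, and radial
distribution fits (Gaussian / exponential / lognormal) with one-sample
Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline
from sklearn.cluster import KMeans

from .movement import Trajectory
from .simulate import SessionResult

__all__ = [
    "NormalizedTrajectory",
    "CurvatureResult",
    "VelocityProfile",
    "PassRateTable",
    "TransitionEstimate",
    "ClusterResult",
    "DistributionFitResult",
    "time_normalize",
    "curvature_area",
    "velocity_profile",
    "pass_rate_by_target",
    "transition_point",
    "point_biserial",
    "trajectory_heatmap",
    "optimal_clusters",
    "fit_radial_distribution",
    "pass_locations",
]


@dataclass(frozen=True)
class NormalizedTrajectory:
    """A trajectory resampled to n equally-spaced-in-time (x, y) points."""

    points: np.ndarray  # (n, 2)
    movement_class: str | None = None

    def __post_init__(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")


def time_normalize(traj: Trajectory, n: int = 512) -> NormalizedTrajectory:
    """Cubic-spline resample of x(t), y(t) at ``n`` uniform times.

    Endpoints are preserved exactly.  Requires at least 4 strictly
    increasing samples (the spline order); ``n`` = 2 returns the endpoints.
    """
    if len(traj) < 4:
        raise ValueError("need at least 4 samples to time-normalize")
    if not np.all(np.diff(traj.t) > 0):
        raise ValueError("trajectory times must be strictly increasing")
    if n < 2:
        raise ValueError("n must be >= 2")
    tt = np.linspace(traj.t[0], traj.t[-1], n)
    sx = CubicSpline(traj.t, traj.x)
    sy = CubicSpline(traj.t, traj.y)
    pts = np.column_stack([sx(tt), sy(tt)])
    pts[0] = (traj.x[0], traj.y[0])
    pts[-1] = (traj.x[-1], traj.y[-1])
    return NormalizedTrajectory(points=pts, movement_class=traj.movement_class)


@dataclass(frozen=True)
class CurvatureResult:
    """Chord-deviation curvature and initial-angle measures of one movement.

    ``area`` is the signed area (m^2) between the path and the straight
    line joining its endpoints, positive when the path lies above the
    chord (toward larger y).  Angles are degrees counter-clockwise from
    the +x axis; ``deviation`` = initial angle - straight-line angle,
    wrapped to (-180, 180].
    """

    area: float
    initial_angle: float
    straight_line_angle: float
    deviation: float


def _angle_deg(dx: float, dy: float) -> float:
    """Counter-clockwise angle from +x in [0, 360)."""
    return math.degrees(math.atan2(dy, dx)) % 360.0


def _wrap_deg(a: float) -> float:
    """Wrap degrees to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return a if a != -180.0 else 180.0


def curvature_area(nt: NormalizedTrajectory) -> CurvatureResult:
    """Signed chord-deviation area and initial movement angle.

    The perpendicular offset of every point from the chord is integrated
    over arc position by the trapezoidal rule; the offset sign is taken
    along the chord normal with positive y component ("above" the chord).
    The initial angle is measured between the 1st and 9th points of the
    time-normalised path.
    """
    p = nt.points
    p0, p1 = p[0], p[-1]
    chord = p1 - p0
    clen = float(np.hypot(*chord))
    if clen < 1e-12:
        raise ValueError("coincident endpoints: chord is degenerate")
    u = chord / clen
    nrm = np.array([-u[1], u[0]])
    if nrm[1] < 0 or (nrm[1] == 0 and nrm[0] < 0):
        nrm = -nrm
    rel = p - p0
    s = rel @ u
    off = rel @ nrm
    area = float(np.trapezoid(off, s))

    if len(p) < 9:
        raise ValueError("need at least 9 points for the initial angle")
    d9 = p[8] - p[0]
    if not np.any(d9):
        raise ValueError("points 1 and 9 coincide: initial angle undefined")
    initial = _angle_deg(d9[0], d9[1])
    straight = _angle_deg(chord[0], chord[1])
    return CurvatureResult(
        area=area,
        initial_angle=initial,
        straight_line_angle=straight,
        deviation=_wrap_deg(initial - straight),
    )


@dataclass(frozen=True)
class VelocityProfile:
    """Time-normalised speed profile of one movement."""

    profile: np.ndarray
    peak: float
    peak_fraction: float


def velocity_profile(traj: Trajectory, n: int = 512) -> VelocityProfile:
    """Speed profile from the raw samples, resampled to ``n`` points.

    Speeds are finite-difference estimates from the (non-normalised)
    position time series, then spline-resampled to uniform normalised
    time; returns the peak and its position in normalised time.
    """
    if len(traj) < 4:
        raise ValueError("need at least 4 samples for a velocity profile")
    if not np.all(np.diff(traj.t) > 0):
        raise ValueError("trajectory times must be strictly increasing")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    speed = np.hypot(vx, vy)
    tt = np.linspace(traj.t[0], traj.t[-1], n)
    prof = CubicSpline(traj.t, speed)(tt)
    i = int(np.argmax(prof))
    return VelocityProfile(
        profile=prof, peak=float(prof[i]), peak_fraction=i / (n - 1)
    )


@dataclass(frozen=True)
class PassRateTable:
    """Per-target pass fractions for one presentation condition."""

    rates: np.ndarray  # (20,)
    counts: np.ndarray  # (20,)
    target_ys: np.ndarray  # (20,) metres
    order_condition: str


def pass_rate_by_target(
    session: SessionResult,
    order_condition: str,
    blocks: Sequence[int] | None = None,
) -> PassRateTable:
    """Pass fraction per target under one presentation condition.

    Restricting ``blocks`` to a single ordered block reproduces the
    published denominators (5 per target for ascending and descending, 10
    for random).
    """
    trials = [
        t
        for t in session.trials
        if t.spec.order_condition == order_condition
        and (blocks is None or t.spec.block_index in blocks)
    ]
    if not trials:
        raise ValueError(f"no trials with condition {order_condition!r}")
    counts = np.zeros(20, dtype=int)
    passes = np.zeros(20, dtype=int)
    for t in trials:
        i = t.spec.target_index - 1
        counts[i] += 1
        passes[i] += t.decision == "pass"
    if np.any(counts == 0):
        raise ValueError("some targets were never presented in this condition")
    ys = np.array([p.y for p in session.task.target_locations])
    return PassRateTable(
        rates=passes / counts, counts=counts, target_ys=ys,
        order_condition=order_condition,
    )


@dataclass(frozen=True)
class TransitionEstimate:
    """Estimated 50 % pass/no-pass transition point."""

    transition_ea: float
    transition_target_y: float
    order_condition: str


def transition_point(
    pass_rates: np.ndarray,
    target_ys: np.ndarray,
    reach: float,
    order_condition: str = "",
) -> TransitionEstimate | None:
    """Interpolated target distance at which half the decisions are passes.

    Scans the rate curve (ordered by target distance) for the first
    crossing of 0.5 and linearly interpolates the crossing distance, which
    may fall between target locations; converts to E/A by dividing by the
    reach.  Returns None when the rates never span 0.5.
    """
    r = np.asarray(pass_rates, dtype=float)
    y = np.asarray(target_ys, dtype=float)
    if r.shape != y.shape or r.ndim != 1:
        raise ValueError("pass_rates and target_ys must be equal-length 1-D")
    order = np.argsort(y)
    r, y = r[order], y[order]
    for i in range(len(r) - 1):
        lo, hi = r[i] - 0.5, r[i + 1] - 0.5
        if lo == 0.0:
            yc = y[i]
        elif lo < 0.0 <= hi or lo > 0.0 >= hi:
            yc = y[i] + (0.5 - r[i]) / (r[i + 1] - r[i]) * (y[i + 1] - y[i])
        else:
            continue
        if reach <= 0:
            raise ValueError(f"reach must be positive, got {reach}")
        return TransitionEstimate(
            transition_ea=float(yc / reach),
            transition_target_y=float(yc),
            order_condition=order_condition,
        )
    return None


def point_biserial(binary: Sequence[int], continuous: Sequence[float]) -> float:
    """Point-biserial correlation of a 0/1 series with a continuous one.

    Identical to the Pearson correlation with the dichotomous variable
    coded 0/1; raises on constant input.
    """
    b = np.asarray(binary, dtype=float)
    c = np.asarray(continuous, dtype=float)
    if b.shape != c.shape:
        raise ValueError("series must have equal length")
    if np.all(b == b[0]) or np.all(c == c[0]):
        raise ValueError("point-biserial requires non-constant series")
    return float(stats.pointbiserialr(b, c).correlation)


def trajectory_heatmap(
    trajectories: Iterable[Trajectory],
    nx: int,
    ny: int,
    bounds: tuple[float, float, float, float],
) -> np.ndarray:
    """Per-cell sample counts of trajectory points over a spatial grid.

    ``bounds`` is (xmin, xmax, ymin, ymax); the returned array has shape
    (nx, ny).  Published grids: 310 x 170 or 930 x 510 for the human data,
    1240 x 680 for the lower-variance simulated pickup movements.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    xmin, xmax, ymin, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate bounds")
    xs = np.concatenate([t.x for t in trajectories] or [np.empty(0)])
    ys = np.concatenate([t.y for t in trajectories] or [np.empty(0)])
    counts, _, _ = np.histogram2d(
        xs, ys, bins=(nx, ny), range=((xmin, xmax), (ymin, ymax))
    )
    return counts


@dataclass(frozen=True)
class ClusterResult:
    """K-means selection of the number of release-location clusters."""

    optimal_k: int
    centers: np.ndarray
    sse_by_k: dict[int, float]
    reference_sse_by_k: dict[int, float]


def optimal_clusters(
    points: np.ndarray,
    k_max: int = 3,
    n_ref: int = 100,
    rng: np.random.Generator | int | None = None,
    n_init: int = 10,
) -> ClusterResult:
    """Choose the number of clusters by a Monte-Carlo reference gap.

    Fits K-means for k = 1..k_max and compares each within-cluster SSE to
    the mean SSE of ``n_ref`` uniform samples over the points' bounding
    box; the optimal k maximises (reference SSE - observed SSE), ties
    resolved toward the smaller k.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < k_max:
        raise ValueError(f"need at least k_max={k_max} points")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def sse(data: np.ndarray, k: int) -> tuple[float, np.ndarray]:
        km = KMeans(
            n_clusters=k, n_init=n_init,
            random_state=int(rng.integers(2**31)),
        ).fit(data)
        return float(km.inertia_), km.cluster_centers_

    sse_by_k: dict[int, float] = {}
    centers_by_k: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        sse_by_k[k], centers_by_k[k] = sse(pts, k)

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    ref_sse = {k: 0.0 for k in range(1, k_max + 1)}
    for _ in range(n_ref):
        ref = rng.uniform(lo, hi, size=pts.shape)
        for k in range(1, k_max + 1):
            ref_sse[k] += sse(ref, k)[0]
    ref_sse = {k: v / n_ref for k, v in ref_sse.items()}

    gaps = {k: ref_sse[k] - sse_by_k[k] for k in sse_by_k}
    optimal_k = min(gaps, key=lambda k: (-gaps[k], k))
    return ClusterResult(
        optimal_k=optimal_k,
        centers=centers_by_k[optimal_k],
        sse_by_k=sse_by_k,
        reference_sse_by_k=ref_sse,
    )


@dataclass(frozen=True)
class FamilyFit:
    """One candidate family's fit to the radial spread."""

    params: tuple[float, ...]
    ks_statistic: float
    p_value: float


@dataclass(frozen=True)
class DistributionFitResult:
    """KS comparison of radial-spread models around the release centroid."""

    fits: dict[str, FamilyFit]
    best_family: str


def fit_radial_distribution(
    points: np.ndarray, squared: bool = True
) -> DistributionFitResult:
    """Fit the spread of points around their centroid and rank families.

    Computes the (squared, by default) Euclidean distance of every point
    from the centroid, fits Gaussian, exponential and lognormal families
    by maximum likelihood, and applies one-sample KS tests; the best
    family has the largest p-value.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 8:
        raise ValueError("need an (n >= 8, 2) array of points")
    center = pts.mean(axis=0)
    d = np.sum((pts - center) ** 2, axis=1)
    if not squared:
        d = np.sqrt(d)
    if np.all(d < 1e-15):
        raise ValueError("all points identical: radial spread degenerate")

    fits: dict[str, FamilyFit] = {}
    for name, dist, fixed in (
        ("gaussian", stats.norm, {}),
        ("exponential", stats.expon, {"floc": 0.0}),
        ("lognormal", stats.lognorm, {"floc": 0.0}),
    ):
        params = dist.fit(d, **fixed)
        ks = stats.kstest(d, dist.cdf, args=params)
        fits[name] = FamilyFit(
            params=tuple(float(p) for p in params),
            ks_statistic=float(ks.statistic),
            p_value=float(ks.pvalue),
        )
    best = max(fits, key=lambda k: fits[k].p_value)
    return DistributionFitResult(fits=fits, best_family=best)


def pass_locations(session: SessionResult, frame: str = "table") -> np.ndarray:
    """(n, 2) array of release locations from a session's passing trials."""
    from .task import to_table_frame

    out = []
    for t in session.trials:
        if t.pass_location is not None:
            p = t.pass_location
            if frame == "table":
                p = to_table_frame(p, session.task.frame)
            out.append((p.x, p.y))
    return np.asarray(out, dtype=float).reshape(-1, 2)
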