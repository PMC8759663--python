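"""Synthetic-data generators with known ground truth.

Every analysis stage in the package has a matching generator here whose
parameters are the ground truth that the analysis must recover: merging
pairs built from the constant-acceleration law, track ensembles with
diffusive or ballistic scaling, agent scenes with planted dense clusters
for segmentation, and polydisperse hard-sphere packings mirroring the
observed spot-size coefficient of variation (~0.3).  Generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .kinematics import Trajectory
from .spatial import PointPattern, hard_sphere_pattern

__all__ = [
    "gen_merger_pair",
    "gen_scaling_tracks",
    "gen_planted_aggregates",
    "gen_polydisperse_packing",
]


def gen_merger_pair(
    a: float,
    v0: float,
    d0: float,
    noise_sd: float,
    n_points: int,
    dt: float,
    rng: np.random.Generator,
    *,
    track_ids: tuple[int, int] = (0, 1),
) -> tuple[Trajectory, Trajectory]:
    """Two tracks approaching head-on with constant closing acceleration.

    The separation follows d_rel(t) = d0 - v0*t - (a/2)*t^2, truncated
    strictly before contact (d_rel <= 0); each track sits at +/- d_rel/2
    on the x axis with i.i.d. Gaussian positional noise of sd ``noise_sd``
    added per coordinate.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if v0 <= 0 and a <= 0:
        raise ValueError("parameters yield no approach (v0 <= 0 and a <= 0)")
    t = np.arange(n_points) * dt
    d = d0 - v0 * t - 0.5 * a * t**2
    keep = d > 0
    # separation must still be shrinking within the kept window
    t, d = t[keep], d[keep]
    if t.size < 2:
        raise ValueError("contact occurs before the second sample; shrink dt")
    xa = np.column_stack([+d / 2.0, np.zeros_like(d)])
    xb = np.column_stack([-d / 2.0, np.zeros_like(d)])
    if noise_sd > 0:
        xa = xa + rng.normal(0.0, noise_sd, xa.shape)
        xb = xb + rng.normal(0.0, noise_sd, xb.shape)
    return (
        Trajectory(track_ids[0], t, xa),
        Trajectory(track_ids[1], t, xb),
    )


def contact_time(a: float, v0: float, d0: float) -> float:
    """Analytic root of d0 - v0*t - (a/2)*t^2 = 0 (first positive root)."""
    if a == 0:
        if v0 <= 0:
            raise ValueError("no contact: v0 <= 0 with zero acceleration")
        return d0 / v0
    disc = v0**2 + 2.0 * a * d0
    if disc < 0:
        raise ValueError("no real contact time for these parameters")
    roots = [(-v0 + s * np.sqrt(disc)) / a for s in (+1, -1)]
    pos = [r for r in roots if r > 0]
    if not pos:
        raise ValueError("no positive contact time for these parameters")
    return float(min(pos))


def gen_scaling_tracks(
    alpha_target: int,
    n_tracks: int,
    n_points: int,
    dt: float,
    rng: np.random.Generator,
    *,
    diffusion: float = 1.0,
    speed: float = 1.0,
) -> list[Trajectory]:
    """Track ensembles with known MSD scaling.

    ``alpha_target=1``: Brownian tracks with increments of variance
    ``2*diffusion*dt`` per axis (MSD = 4*D*t).  ``alpha_target=2``: each
    track moves with a constant random-heading velocity of magnitude
    ``speed`` (MSD = v^2 t^2).
    """
    if alpha_target not in (1, 2):
        raise ValueError("alpha_target must be 1 (diffusive) or 2 (ballistic)")
    t = np.arange(n_points) * dt
    tracks = []
    for k in range(n_tracks):
        if alpha_target == 1:
            steps = rng.normal(0.0, np.sqrt(2.0 * diffusion * dt), (n_points - 1, 2))
            pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        else:
            heading = rng.uniform(0.0, 2.0 * np.pi)
            v = speed * np.array([np.cos(heading), np.sin(heading)])
            pos = t[:, None] * v[None, :]
        tracks.append(Trajectory(k, t, pos))
    return tracks


def gen_planted_aggregates(
    n_clusters: int,
    agents_per_cluster: int,
    cluster_radius: float,
    n_free: int,
    grid_size: int,
    rng: np.random.Generator,
    *,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Agent scene with dense planted discs plus uniform free agents.

    Cluster centers are placed sequentially with pairwise separation
    > 4 * cluster_radius (also kept away from the periodic seam by the
    same margin).  Returns (positions, cluster_centers); the centers are
    the segmentation ground truth.
    """
    if n_clusters < 0 or n_free < 0:
        raise ValueError("counts must be non-negative")
    centers: list[np.ndarray] = []
    margin = 4.0 * cluster_radius
    tries = 0
    while len(centers) < n_clusters:
        cand = rng.uniform(margin, grid_size - margin, size=2)
        if all(np.linalg.norm(cand - c) > margin for c in centers):
            centers.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_clusters} clusters with separation "
                f"> {margin:.3g} on a {grid_size} px grid"
            )
    chunks = []
    for c in centers:
        # uniform over the disc
        r = cluster_radius * np.sqrt(rng.random(agents_per_cluster))
        th = rng.uniform(0.0, 2.0 * np.pi, agents_per_cluster)
        chunks.append(c + np.column_stack([r * np.cos(th), r * np.sin(th)]))
    if n_free:
        chunks.append(rng.uniform(0.0, grid_size, size=(n_free, 2)))
    positions = np.vstack(chunks) if chunks else np.empty((0, 2))
    return positions % grid_size, np.asarray(centers).reshape(-1, 2)


def gen_polydisperse_packing(
    n: int,
    L: float,
    mean_d: float,
    cv: float = 0.3,
    rng: np.random.Generator | None = None,
    *,
    max_rejections: int = 1_000_000,
) -> tuple[PointPattern, np.ndarray]:
    """Hard-sphere packing with Gaussian-distributed radii.

    Each accepted point carries a radius drawn from a Gaussian with mean
    ``mean_d / 2`` and coefficient of variation ``cv`` (truncated at zero);
    a candidate is rejected when closer to an accepted point than the sum
    of their radii.  ``cv=0`` reduces exactly to a monodisperse packing
    with minimum spacing ``mean_d``.
    """
    if rng is None:
        raise ValueError("an explicit rng is required for reproducibility")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        pat = hard_sphere_pattern(n, L, mean_d, rng, max_rejections=max_rejections)
        return pat, np.full(n, mean_d / 2.0)

    mean_r = mean_d / 2.0
    pts: list[np.ndarray] = []
    radii: list[float] = []
    rejections = 0
    while len(pts) < n:
        cand = rng.uniform(0.0, L, size=2)
        r = max(rng.normal(mean_r, cv * mean_r), 0.0)
        if pts:
            d = np.linalg.norm(np.asarray(pts) - cand, axis=1)
            if np.any(d < np.asarray(radii) + r):
                rejections += 1
                if rejections >= max_rejections:
                    raise RuntimeError(
                        f"polydisperse packing saturated at {len(pts)}/{n} points"
                    )
                continue
        pts.append(cand)
        radii.append(r)
        rejections = 0
    return PointPattern(points=np.asarray(pts), L=L), np.asarray(radii)
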