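"""Density-based aggregate segmentation and frame-to-frame track linking.

Segmentation follows the density rules used for simulated aggregate
snapshots: for every pixel, count agents within a fixed radius of the pixel
center; pixels where the count exceeds a threshold belong to an aggregate;
8-connected components smaller than a minimum pixel area are discarded.
Detections are then linked through time by greedy nearest-neighbor
assignment within a distance gate, with track coalescence recorded as merge
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "DensityMap",
    "AggregateDetection",
    "Track",
    "MergeEvent",
    "local_density_map",
    "segment_aggregates",
    "link_tracks",
    "classify_merging",
    "NON_MERGER",
    "TWO_SPOT_MERGER",
    "THREE_SPOT_MERGER",
]

NON_MERGER = "non_merger"
TWO_SPOT_MERGER = "two_spot_merger"
THREE_SPOT_MERGER = "three_spot_merger"


@dataclass
class DensityMap:
    """Per-pixel agent counts within ``radius`` px of each pixel center."""

    counts: np.ndarray  # (grid_size, grid_size)
    radius: float


@dataclass
class AggregateDetection:
    """One segmented aggregate in one frame."""

    frame: int
    centroid: tuple[float, float]  # px, pixel-center coordinates
    area: int  # px^2 == member pixel count
    id: int = -1


@dataclass
class Track:
    """A time-ordered chain of detections of one aggregate."""

    track_id: int
    detections: list[AggregateDetection] = field(default_factory=list)
    merge_class: str = NON_MERGER

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([d.centroid for d in self.detections])


@dataclass
class MergeEvent:
    """Coalescence of >=2 tracks into one surviving track."""

    frame: int
    participants: list[int]  # track ids ending at or spanning the merge
    survivor: int


def local_density_map(
    positions: np.ndarray, radius: float, grid_size: int
) -> DensityMap:
    """Count agents within ``radius`` px of every pixel center.

    Pixel centers sit at (i + 0.5, j + 0.5); distances use the periodic
    (minimum-image) metric, matching the periodic simulation domain.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    positions = np.asarray(positions, dtype=float)
    counts = np.zeros((grid_size, grid_size), dtype=np.int64)
    if positions.size == 0:
        return DensityMap(counts, radius)
    L = float(grid_size)
    tree = cKDTree(positions % L, boxsize=L)
    centers_1d = np.arange(grid_size) + 0.5
    cx, cy = np.meshgrid(centers_1d, centers_1d, indexing="ij")
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    n = tree.query_ball_point(centers, radius, return_length=True)
    counts[:] = n.reshape(grid_size, grid_size)
    return DensityMap(counts, radius)


# 8-connectivity structuring element
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _periodic_centroid(ix: np.ndarray, iy: np.ndarray, grid_size: int) -> tuple[float, float]:
    """Mean of member pixel centers under the periodic metric (circular
    mean per axis), so components wrapping a boundary get a sane centroid."""
    out = []
    for idx in (ix, iy):
        theta = (idx + 0.5) * 2.0 * np.pi / grid_size
        mean_angle = np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
        out.append((mean_angle * grid_size / (2.0 * np.pi)) % grid_size)
    return float(out[0]), float(out[1])


def segment_aggregates(
    density: DensityMap,
    count_threshold: float = 40,
    min_area: int = 10,
    *,
    frame: int = 0,
    periodic: bool = True,
) -> list[AggregateDetection]:
    """Threshold-and-label segmentation of a density map.

    Pixels with counts strictly exceeding ``count_threshold`` are aggregate
    pixels; 8-connected components with fewer than ``min_area`` pixels are
    discarded.  With ``periodic=True`` components touching opposite edges
    are merged across the wrap before the area cut.
    """
    mask = density.counts > count_threshold
    labels, n_labels = ndimage.label(mask, structure=_STRUCT8)
    if n_labels == 0:
        return []
    grid_size = mask.shape[0]

    # Union labels across the periodic seam.
    parent = list(range(n_labels + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    if periodic:
        for axis in (0, 1):
            lo = np.take(labels, 0, axis=axis)
            hi = np.take(labels, -1, axis=axis)
            m = labels.shape[1 - axis]
            for off in (-1, 0, 1):  # 8-connectivity across the seam
                idx = np.arange(m)
                jdx = (idx + off) % m
                a, b = lo[idx], hi[jdx]
                both = (a > 0) & (b > 0)
                for la, lb in zip(a[both], b[both]):
                    union(int(la), int(lb))

    roots = np.array([find(l) for l in range(n_labels + 1)])
    merged = roots[labels]

    detections: list[AggregateDetection] = []
    next_id = 0
    for lab in np.unique(merged):
        if lab == 0:
            continue
        ix, iy = np.nonzero(merged == lab)
        if ix.size < min_area:
            continue
        if periodic:
            centroid = _periodic_centroid(ix, iy, grid_size)
        else:
            centroid = (float(np.mean(ix) + 0.5), float(np.mean(iy) + 0.5))
        detections.append(
            AggregateDetection(frame=frame, centroid=centroid, area=int(ix.size), id=next_id)
        )
        next_id += 1
    return detections


def default_link_gate(detections_by_frame: list[list[AggregateDetection]]) -> float:
    """3x the mean frame-to-frame nearest-centroid displacement, a loose
    gate adequate for sparse, slow aggregates."""
    disps: list[float] = []
    for prev, cur in zip(detections_by_frame[:-1], detections_by_frame[1:]):
        if not prev or not cur:
            continue
        prev_xy = np.array([d.centroid for d in prev])
        cur_xy = np.array([d.centroid for d in cur])
        tree = cKDTree(cur_xy)
        d, _ = tree.query(prev_xy, k=1)
        disps.extend(d)
    if not disps:
        return np.inf
    return 3.0 * float(np.mean(disps))


def coalescence_gate(detections_by_frame: list[list[AggregateDetection]]) -> float:
    """Linking gate sized for merge detection.

    When two aggregates coalesce, the surviving centroid jumps by about one
    aggregate radius, far more than the frame-to-frame jitter of an
    isolated aggregate.  This gate adds the mean equivalent radius
    (sqrt(area/pi)) to the jitter-based default so coalescence is linked as
    a merge instead of a track death next to an unrelated track birth;
    widening it much further starts chaining unrelated neighbors.
    """
    base = default_link_gate(detections_by_frame)
    areas = [d.area for dets in detections_by_frame for d in dets]
    if not areas:
        return base
    mean_radius = float(np.mean(np.sqrt(np.asarray(areas) / np.pi)))
    return base + mean_radius


def link_tracks(
    detections_by_frame: list[list[AggregateDetection]],
    max_link_distance: float | None = None,
) -> tuple[list[Track], list[MergeEvent]]:
    """Greedy nearest-neighbor linking of detections into tracks.

    Frame to frame, candidate (track head, detection) pairs within the gate
    are linked in ascending distance order, each side used once (the greedy
    equivalent of mutual nearest neighbors).  A leftover track whose
    nearest in-gate detection was claimed by a closer track terminates
    there and is recorded as merging into the claimant's track; leftover
    detections start new tracks.
    """
    if max_link_distance is None:
        max_link_distance = default_link_gate(detections_by_frame)

    tracks: list[Track] = []
    merge_events: list[MergeEvent] = []
    active: dict[int, Track] = {}  # track_id -> track with head in prev frame
    next_id = 0

    for frame_idx, dets in enumerate(detections_by_frame):
        if not active:
            for det in dets:
                tr = Track(track_id=next_id, detections=[det])
                tracks.append(tr)
                active[next_id] = tr
                next_id += 1
            continue
        if not dets:
            active.clear()
            continue

        head_ids = list(active.keys())
        heads = np.array([active[i].detections[-1].centroid for i in head_ids])
        det_xy = np.array([d.centroid for d in dets])
        dist = np.linalg.norm(heads[:, None, :] - det_xy[None, :, :], axis=2)

        order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
        track_used: set[int] = set()
        det_used: set[int] = set()
        det_owner: dict[int, int] = {}  # detection idx -> winning track id
        for ti, di in order:
            if dist[ti, di] > max_link_distance:
                break
            if ti in track_used or di in det_used:
                continue
            track_used.add(int(ti))
            det_used.add(int(di))
            det_owner[int(di)] = head_ids[ti]
            active[head_ids[ti]].detections.append(dets[di])

        # Unmatched tracks: merge into the owner of their nearest in-gate
        # detection, else terminate.
        merged_into: dict[int, list[int]] = {}
        new_active: dict[int, Track] = {
            det_owner[di]: active[det_owner[di]] for di in det_owner
        }
        for ti, tid in enumerate(head_ids):
            if ti in track_used:
                continue
            in_gate = dist[ti] <= max_link_distance
            if np.any(in_gate):
                di = int(np.argmin(np.where(in_gate, dist[ti], np.inf)))
                if di in det_owner:
                    merged_into.setdefault(di, []).append(tid)
        for di, losers in merged_into.items():
            survivor = det_owner[di]
            merge_events.append(
                MergeEvent(
                    frame=frame_idx,
                    participants=sorted(losers) + [survivor],
                    survivor=survivor,
                )
            )
        for di, det in enumerate(dets):
            if di not in det_used:
                tr = Track(track_id=next_id, detections=[det])
                tracks.append(tr)
                new_active[next_id] = tr
                next_id += 1
        active = new_active

    return tracks, merge_events


def classify_merging(
    tracks: list[Track], merge_events: list[MergeEvent]
) -> dict[str, float]:
    """Assign merge classes to tracks and return cohort fractions.

    Merge participation is counted transitively through survivor chains:
    tracks connected through any sequence of merge events belong to one
    merge group, and a track's partner count is the group size minus one.
    0 partners -> non-merger, 1 -> two-spot merger, >=2 -> three-spot
    merger (merged with two or more other aggregates).
    """
    parent: dict[int, int] = {t.track_id: t.track_id for t in tracks}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ev in merge_events:
        ids = [i for i in ev.participants if i in parent]
        for other in ids[1:]:
            ra, rb = find(ids[0]), find(other)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    group_size: dict[int, int] = {}
    for t in tracks:
        r = find(t.track_id)
        group_size[r] = group_size.get(r, 0) + 1

    counts = {NON_MERGER: 0, TWO_SPOT_MERGER: 0, THREE_SPOT_MERGER: 0}
    for t in tracks:
        partners = group_size[find(t.track_id)] - 1
        if partners == 0:
            t.merge_class = NON_MERGER
        elif partners == 1:
            t.merge_class = TWO_SPOT_MERGER
        else:
            t.merge_class = THREE_SPOT_MERGER
        counts[t.merge_class] += 1

    n = len(tracks)
    reduction = sum(len(ev.participants) - 1 for ev in merge_events)
    return {
        "n_tracks": n,
        "frac_non_merger": counts[NON_MERGER] / n if n else np.nan,
        "frac_two_spot": counts[TWO_SPOT_MERGER] / n if n else np.nan,
        "frac_three_spot": counts[THREE_SPOT_MERGER] / n if n else np.nan,
        "count_reduction_frac": reduction / n if n else np.nan,
    }
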