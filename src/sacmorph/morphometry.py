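"""Single-cell dendrite morphometry.

All metrics operate on an :class:`~sacmorph.types.Arbor` and mirror the
standard reconstruction-based measurements for planar radially symmetric
neurons: total dendritic length, branch-point count, convex-hull field
area, Sholl intersection profiles (with a 10%-of-radial-extent
normalization so cells of different sizes are comparable), single-plane
dendrite self-crossings, dendrite caliber / hypertrophy classification,
and soma area.

Conventions (documented in docs/methods.md): Sholl spheres are centred on
the soma centroid in 3-D; an endpoint exactly at radius ``r`` counts as
outside the sphere; segments sharing a node never count as self-crossings
(touching at a shared node is branching, not crossing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import DegenerateGeometryError, ParameterError
from .types import DENDRITE, SOMA, Arbor


@dataclass
class ShollProfile:
    """Sholl intersection counts at a fixed radius step plus decile means."""

    radii: np.ndarray            # (k,) strictly increasing, constant step
    intersections: np.ndarray    # (k,) counts
    normalized_bins: np.ndarray  # (10,) mean count per 10% of radial extent
    radial_extent: float


@dataclass
class MorphometryResult:
    total_length: float
    n_branch_points: int
    field_area: float
    n_self_crossings: int
    max_caliber: float
    is_hypertrophic: bool
    soma_area: float
    radial_extent: float


def total_length(arbor: Arbor) -> float:
    """Summed Euclidean length (um) of all non-soma-internal segments."""
    arbor.validate()
    parent, child = arbor.length_segments()
    if not (arbor.node_type == DENDRITE).any():
        warnings.warn("arbor has no dendrite nodes; total length is 0")
        return 0.0
    return float(np.linalg.norm(arbor.xyz[child] - arbor.xyz[parent], axis=1).sum())


def count_branch_points(arbor: Arbor) -> int:
    """Dendrite nodes with two or more children; the root/soma never counts."""
    arbor.validate()
    counts = arbor.children_counts()
    mask = (counts >= 2) & (arbor.node_type == DENDRITE) & (arbor.parent_index >= 0)
    return int(mask.sum())


def field_area_convex_hull(arbor: Arbor) -> float:
    """Dendritic field area: 2-D convex hull of dendrite node xy positions (um^2)."""
    arbor.validate()
    pts = arbor.xyz[arbor.node_type == DENDRITE][:, :2]
    if len(pts) < 3:
        raise DegenerateGeometryError("need >= 3 dendrite nodes for a hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate dendrite geometry: {exc}") from exc
    return float(hull.volume)  # 2-D "volume" is area


def sholl_profile(arbor: Arbor, step: float = 1.0) -> ShollProfile:
    """Sholl intersections at radii ``step, 2*step, ...`` up to the radial extent.

    A segment intersects the sphere of radius ``r`` when exactly one of its
    endpoint distances from the soma center is ``< r`` (an endpoint exactly
    at ``r`` lies outside).
    """
    arbor.validate()
    if step <= 0:
        raise ParameterError("step must be > 0")
    center = arbor.soma_center
    extent = arbor.radial_extent
    radii = np.arange(step, extent + 0.5 * step, step)
    radii = radii[radii <= extent]
    parent, child = arbor.dendrite_segments()
    if len(child) == 0 or len(radii) == 0:
        radii = radii if len(radii) else np.array([step])
        empty = np.zeros(len(radii), dtype=int)
        return ShollProfile(radii, empty, normalize_sholl(radii, empty, max(extent, step)),
                            extent)
    d_par = np.linalg.norm(arbor.xyz[parent] - center, axis=1)
    d_chi = np.linalg.norm(arbor.xyz[child] - center, axis=1)
    inside_par = d_par[:, None] < radii[None, :]
    inside_chi = d_chi[:, None] < radii[None, :]
    inter = (inside_par ^ inside_chi).sum(axis=0)
    return ShollProfile(radii, inter.astype(int),
                        normalize_sholl(radii, inter, extent), extent)


def normalize_sholl(radii: np.ndarray, intersections: np.ndarray,
                    radial_extent: float) -> np.ndarray:
    """Mean intersection count over each successive 10% of the radial extent.

    Bin ``k`` (1-based) averages the counts at radii with
    ``(k-1)/10 < r/extent <= k/10``; empty bins are 0.
    """
    if radial_extent <= 0:
        raise ParameterError("radial_extent must be > 0")
    radii = np.asarray(radii, dtype=float)
    intersections = np.asarray(intersections, dtype=float)
    rel = radii / radial_extent
    bins = np.zeros(10)
    for k in range(10):
        mask = (rel > k / 10.0) & (rel <= (k + 1) / 10.0)
        if mask.any():
            bins[k] = intersections[mask].mean()
    return bins


def count_self_crossings(arbor: Arbor, z_tol: float = 0.5,
                         _chunk: int = 400_000) -> int:
    """Dendrite self-crossings in single z-planes.

    Counts unordered pairs of node-disjoint dendrite segments whose xy
    projections properly intersect and whose interpolated z values at the
    crossing point differ by at most ``z_tol`` um (emulating a crossing
    visible within one confocal z-plane).
    """
    arbor.validate()
    if z_tol < 0:
        raise ParameterError("z_tol must be >= 0")
    parent, child = arbor.dendrite_segments()
    m = len(child)
    if m < 2:
        return 0
    a = arbor.xyz[parent]
    b = arbor.xyz[child]
    nodes = np.column_stack([parent, child])

    # two segments can only cross if their xy midpoints are within the sum of
    # their half-lengths; prune pairs with a KD-tree at the max segment length
    mid = (a[:, :2] + b[:, :2]) / 2.0
    seg_len = np.linalg.norm(b[:, :2] - a[:, :2], axis=1)
    pairs = cKDTree(mid).query_pairs(r=float(seg_len.max()) + 1e-9,
                                     output_type="ndarray")
    if len(pairs) == 0:
        return 0
    ii, jj = pairs[:, 0], pairs[:, 1]
    total = 0
    for s in range(0, len(ii), _chunk):
        i = ii[s:s + _chunk]
        j = jj[s:s + _chunk]
        # exclude pairs sharing any node
        share = (
            (nodes[i, 0] == nodes[j, 0]) | (nodes[i, 0] == nodes[j, 1])
            | (nodes[i, 1] == nodes[j, 0]) | (nodes[i, 1] == nodes[j, 1])
        )
        p1, p2 = a[i, :2], b[i, :2]
        q1, q2 = a[j, :2], b[j, :2]
        r = p2 - p1
        sv = q2 - q1
        denom = r[:, 0] * sv[:, 1] - r[:, 1] * sv[:, 0]
        qp = q1 - p1
        t_num = qp[:, 0] * sv[:, 1] - qp[:, 1] * sv[:, 0]
        u_num = qp[:, 0] * r[:, 1] - qp[:, 1] * r[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = t_num / denom
            u = u_num / denom
        with np.errstate(invalid="ignore"):
            proper = (np.abs(denom) > 1e-12) & (t > 0) & (t < 1) & (u > 0) & (u < 1)
            cand = proper & ~share
            if cand.any():
                zi = a[i, 2] + t * (b[i, 2] - a[i, 2])
                zj = a[j, 2] + u * (b[j, 2] - a[j, 2])
                total += int((cand & (np.abs(zi - zj) <= z_tol)).sum())
    return total


def classify_hypertrophic(arbor: Arbor, threshold: float = 1.0,
                          proximal_exclusion: float = 5.0) -> tuple[float, bool]:
    """Max dendrite caliber (diameter, um) beyond the soma taper, and the
    hypertrophic call: caliber strictly greater than ``threshold``."""
    arbor.validate()
    dist = arbor.node_distances()
    mask = (arbor.node_type == DENDRITE) & (dist > proximal_exclusion)
    if not mask.any():
        raise DegenerateGeometryError(
            f"no dendrite nodes beyond proximal_exclusion={proximal_exclusion:g} um"
        )
    max_caliber = float((2.0 * arbor.radius[mask]).max())
    return max_caliber, max_caliber > threshold


def soma_area(arbor: Arbor) -> float:
    """Soma cross-section area (um^2).

    One soma node gives a disc of its radius; two give the larger disc;
    three or more give the xy convex hull of the soma nodes.
    """
    arbor.validate()
    mask = arbor.node_type == SOMA
    n = int(mask.sum())
    if n == 0:
        raise DegenerateGeometryError("arbor has no soma node")
    if n <= 2:
        return float(np.pi * arbor.radius[mask].max() ** 2)
    try:
        return float(ConvexHull(arbor.xyz[mask][:, :2]).volume)
    except QhullError:
        return float(np.pi * arbor.radius[mask].max() ** 2)


def morphometry(arbor: Arbor, sholl_step: float = 1.0,
                z_tol: float = 0.5) -> tuple[MorphometryResult, ShollProfile]:
    """All scalar metrics plus the Sholl profile for one cell."""
    sholl = sholl_profile(arbor, step=sholl_step)
    max_cal, hyper = classify_hypertrophic(arbor)
    result = MorphometryResult(
        total_length=total_length(arbor),
        n_branch_points=count_branch_points(arbor),
        field_area=field_area_convex_hull(arbor),
        n_self_crossings=count_self_crossings(arbor, z_tol=z_tol),
        max_caliber=max_cal,
        is_hypertrophic=hyper,
        soma_area=soma_area(arbor),
        radial_extent=arbor.radial_extent,
    )
    return result, sholl
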