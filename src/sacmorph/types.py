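"""Core in-memory containers.

The five data types every analysis module consumes:

* :class:`Arbor` -- a rooted tree of 3-D nodes with radii (one reconstructed
  starburst amacrine cell); the unit of all morphometry.
* :class:`PointPattern` -- soma centers in a rectangular window; the unit of
  mosaic-spacing analysis.
* :class:`DirectionalResponseSet` -- per-unit spike counts per direction per
  epoch from a multielectrode recording; the unit of DSGC classification.
* :class:`PunctaSet` -- synaptic puncta centers and volumes tied to a parent
  arbor; the unit of synapse compartmentalization.
* :class:`LaminationProfile` -- fluorescence intensity versus normalized IPL
  depth; the unit of stratification analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError

SOMA = 1
DENDRITE = 3


@dataclass
class Arbor:
    """Rooted neuronal tree in SWC conventions.

    Nodes are stored as parallel arrays ordered so that every parent appears
    before its children.  ``parent_index[i]`` is the positional index of node
    ``i``'s parent (-1 for the root).  ``node_type`` uses SWC codes: 1 for
    soma, 3 for dendrite.
    """

    ids: np.ndarray            # (n,) int
    parent_index: np.ndarray   # (n,) int, -1 for root
    xyz: np.ndarray            # (n, 3) float, micrometres
    radius: np.ndarray         # (n,) float, micrometres
    node_type: np.ndarray      # (n,) int

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.parent_index = np.asarray(self.parent_index, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.node_type = np.asarray(self.node_type, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise ParameterError("arbor has no nodes")
        roots = np.flatnonzero(self.parent_index == -1)
        if len(roots) != 1:
            raise ParameterError(f"arbor must have exactly one root, found {len(roots)}")
        if np.any(self.parent_index >= np.arange(n)):
            raise ParameterError("parents must precede children in node order")
        if np.any(self.radius < 0):
            raise ParameterError("node radii must be non-negative")

    @property
    def soma_center(self) -> np.ndarray:
        """Centroid of the soma-typed nodes (falls back to the root)."""
        mask = self.node_type == SOMA
        if not mask.any():
            return self.xyz[0].copy()
        return self.xyz[mask].mean(axis=0)

    def node_distances(self) -> np.ndarray:
        """Euclidean distance of every node from the soma center."""
        return np.linalg.norm(self.xyz - self.soma_center, axis=1)

    @property
    def radial_extent(self) -> float:
        """Maximum node distance from the soma center, in micrometres."""
        return float(self.node_distances().max())

    def dendrite_segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Parent/child positional indices of segments whose child is a dendrite node."""
        child = np.flatnonzero((self.parent_index >= 0) & (self.node_type == DENDRITE))
        return self.parent_index[child], child

    def length_segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segments counted toward total dendritic length.

        Every parent->child segment except those internal to the soma (both
        endpoints soma-typed).
        """
        child = np.flatnonzero(self.parent_index >= 0)
        parent = self.parent_index[child]
        soma_internal = (self.node_type[child] == SOMA) & (self.node_type[parent] == SOMA)
        return parent[~soma_internal], child[~soma_internal]

    def children_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        valid = self.parent_index[self.parent_index >= 0]
        np.add.at(counts, valid, 1)
        return counts


@dataclass
class PointPattern:
    """Planar point pattern (soma centers) in a rectangular observation window."""

    points: np.ndarray                      # (n, 2) float, micrometres
    window: tuple[float, float, float, float]  # (x_min, y_min, x_max, y_max)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        x0, y0, x1, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise ParameterError("window must have positive area")
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if np.any((x < x0) | (x > x1) | (y < y0) | (y > y1)):
                raise ParameterError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0)


@dataclass
class DirectionalResponseSet:
    """Spike counts of sorted units to motion in evenly spaced directions.

    ``counts[unit_id]`` is an (epochs x directions) integer array.  Direction
    angles are in degrees, evenly spaced, with an even count so every
    direction has an exact opposite.
    """

    directions_deg: np.ndarray              # (d,) float
    epoch_dur_s: float
    unit_ids: list[str]
    counts: list[np.ndarray]                # per unit, (epochs, d) int
    ground_truth_ds: list[bool] | None = None  # simulator labels, if known

    def __post_init__(self) -> None:
        self.directions_deg = np.asarray(self.directions_deg, dtype=float)
        d = len(self.directions_deg)
        if d < 2 or d % 2:
            raise ParameterError("direction count must be even and >= 2")
        if len(self.unit_ids) != len(self.counts):
            raise ParameterError("unit_ids and counts length mismatch")
        self.counts = [np.asarray(c, dtype=np.int64).reshape(-1, d) for c in self.counts]
        for c in self.counts:
            if (c < 0).any():
                raise ParameterError("spike counts must be non-negative")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


@dataclass
class PunctaSet:
    """Synaptic puncta (centers and volumes) tied to a parent arbor."""

    xyz: np.ndarray            # (n, 3) float, micrometres
    volumes: np.ndarray        # (n,) float, cubic micrometres
    soma_center: np.ndarray    # (3,) float
    arbor_radial_extent: float

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.volumes = np.asarray(self.volumes, dtype=float).reshape(-1)
        self.soma_center = np.asarray(self.soma_center, dtype=float).reshape(3)
        if len(self.volumes) != len(self.xyz):
            raise ParameterError("xyz and volumes length mismatch")
        if len(self.volumes) and np.any(self.volumes <= 0):
            raise ParameterError("puncta volumes must be positive")
        if self.arbor_radial_extent <= 0:
            raise ParameterError("arbor_radial_extent must be positive")

    @property
    def n(self) -> int:
        return len(self.volumes)


@dataclass
class LaminationProfile:
    """Fluorescence intensity sampled along normalized IPL depth.

    Depth 0 is the INL/IPL border and depth 1 the IPL/GCL border by package
    convention (flip upstream if acquired the other way).
    """

    depths: np.ndarray       # (n,) float in [0, 1], ascending
    intensities: np.ndarray  # (n,) float >= 0

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float).reshape(-1)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if len(self.depths) != len(self.intensities):
            raise ParameterError("depths and intensities length mismatch")
        if len(self.depths):
            if self.depths.min() < 0 or self.depths.max() > 1:
                raise ParameterError("depths must lie in [0, 1]")
            if np.any(np.diff(self.depths) < 0):
                raise ParameterError("depths must be ascending")
            if np.any(self.intensities < 0):
                raise ParameterError("intensities must be non-negative")


def make_arbor(nodes: Sequence[tuple]) -> Arbor:
    """Build an :class:`Arbor` from ``(id, parent_id, x, y, z, radius, type)`` rows.

    Accepts arbitrary node ids; parents must appear before children.
    """
    ids = np.array([n[0] for n in nodes], dtype=np.int64)
    parent_ids = np.array([n[1] for n in nodes], dtype=np.int64)
    xyz = np.array([[n[2], n[3], n[4]] for n in nodes], dtype=float)
    radius = np.array([n[5] for n in nodes], dtype=float)
    ntype = np.array([n[6] for n in nodes], dtype=np.int64)
    index_of = {int(i): k for k, i in enumerate(ids)}
    parent_index = np.array(
        [-1 if p == -1 else index_of[int(p)] for p in parent_ids], dtype=np.int64
    )
    arbor = Arbor(ids, parent_index, xyz, radius, ntype)
    arbor.validate()
    return arbor
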