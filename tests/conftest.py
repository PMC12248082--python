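"""Shared fixtures: small hand-built arbors with known metrics."""

from __future__ import annotations

import numpy as np
import pytest

from sacmorph.types import DENDRITE, SOMA, Arbor, make_arbor


@pytest.fixture
def y_tree() -> Arbor:
    """Soma at origin, trunk to (0,10,0), daughters to (+-5, 20, 0).

    Total length 10 + 2*sqrt(125); one branch point.
    """
    return make_arbor([
        (1, -1, 0, 0, 0, 4.0, SOMA),
        (2, 1, 0, 10, 0, 0.4, DENDRITE),
        (3, 2, -5, 20, 0, 0.3, DENDRITE),
        (4, 2, 5, 20, 0, 0.3, DENDRITE),
    ])


def star_arbor(n_rays: int = 4, length: float = 50.0, spacing: float = 1.0,
               soma_radius: float = 4.0) -> Arbor:
    """``n_rays`` straight radial dendrites of the given length, nodes every
    ``spacing`` um; no branch points."""
    nodes = [(1, -1, 0.0, 0.0, 0.0, soma_radius, SOMA)]
    nid = 2
    for i in range(n_rays):
        ang = 2 * np.pi * i / n_rays
        prev = 1
        k = 1
        while k * spacing <= length + 1e-9:
            r = k * spacing
            nodes.append((nid, prev, r * np.cos(ang), r * np.sin(ang), 0.0, 0.3,
                          DENDRITE))
            prev = nid
            nid += 1
            k += 1
    return make_arbor(nodes)


def chain_arbor(points: list[tuple[float, float, float]],
                radius: float = 0.3) -> Arbor:
    """A single unbranched dendrite through the given points; soma at the first."""
    nodes = [(1, -1, *points[0], 4.0, SOMA)]
    for k, p in enumerate(points[1:], start=2):
        nodes.append((k, k - 1, *p, radius, DENDRITE))
    return make_arbor(nodes)


def grid_arbor(m: int, n: int) -> Arbor:
    """Tree whose dendrites form ``m`` horizontal x ``n`` vertical coplanar
    segments crossing in exactly ``m * n`` points.

    The soma sits at (0.5, 0.5); connector segments to each bar's start are
    collinear with other connectors or touch bars only at endpoints, so they
    add no proper crossings.
    """
    nodes = [(1, -1, 0.5, 0.5, 0.0, 1.0, SOMA)]
    nid = 2
    for i in range(1, m + 1):  # horizontal bars at y = i
        nodes.append((nid, 1, 0.5, float(i), 0.0, 0.3, DENDRITE))
        nodes.append((nid + 1, nid, n + 0.5, float(i), 0.0, 0.3, DENDRITE))
        nid += 2
    for j in range(1, n + 1):  # vertical bars at x = j
        nodes.append((nid, 1, float(j), 0.5, 0.0, 0.3, DENDRITE))
        nodes.append((nid + 1, nid, float(j), m + 0.5, 0.0, 0.3, DENDRITE))
        nid += 2
    return make_arbor(nodes)


def rigid_transform(arbor: Arbor, angle: float = 0.0,
                    translation=(0.0, 0.0, 0.0)) -> Arbor:
    """Rotate about the z axis then translate; metrics should be invariant."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    xyz = arbor.xyz @ rot.T + np.asarray(translation)
    return Arbor(arbor.ids.copy(), arbor.parent_index.copy(), xyz,
                 arbor.radius.copy(), arbor.node_type.copy())
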