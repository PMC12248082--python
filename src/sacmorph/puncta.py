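"""Synaptic puncta quantification.

Counts, volumes, straight-line soma distances and the outer-third
compartmentalization fraction of presynaptic puncta, after exclusion of
sub-resolution puncta below 0.5 um equivalent diameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .types import PunctaSet

logger = logging.getLogger(__name__)

MIN_DIAMETER_UM = 0.5
OUTER_THIRD_BOUNDARY = 2.0 / 3.0


@dataclass
class PunctaStats:
    count: int
    mean_volume: float | None
    volumes: np.ndarray
    distances: np.ndarray
    normalized_distances: np.ndarray
    mean_distance: float | None = None


def equivalent_diameters(puncta: PunctaSet) -> np.ndarray:
    """Volume-equivalent sphere diameter, ``(6 V / pi)^(1/3)``, per punctum."""
    return np.cbrt(6.0 * puncta.volumes / math.pi)


def filter_puncta(puncta: PunctaSet, min_diameter: float = MIN_DIAMETER_UM) -> PunctaSet:
    """Drop puncta strictly smaller than ``min_diameter`` (equivalent diameter).

    A punctum exactly at the threshold is retained: only those *smaller*
    than the cutoff are excluded.
    """
    if min_diameter < 0:
        raise ParameterError("min_diameter must be >= 0")
    keep = equivalent_diameters(puncta) >= min_diameter
    return PunctaSet(puncta.xyz[keep], puncta.volumes[keep],
                     puncta.soma_center, puncta.arbor_radial_extent)


def puncta_stats(puncta: PunctaSet) -> PunctaStats:
    """Counts, volumes and (normalized) straight-line soma distances.

    Normalized distance is distance / arbor radial extent, clipped to
    [0, 1.05]; clip events are logged since they indicate puncta outside
    the reconstructed arbor.
    """
    if puncta.arbor_radial_extent <= 0:
        raise ParameterError("arbor_radial_extent must be > 0")
    if puncta.n == 0:
        return PunctaStats(0, None, np.empty(0), np.empty(0), np.empty(0), None)
    d = np.linalg.norm(puncta.xyz - puncta.soma_center, axis=1)
    norm = d / puncta.arbor_radial_extent
    n_clip = int((norm > 1.05).sum())
    if n_clip:
        logger.warning("clipped %d normalized puncta distances above 1.05", n_clip)
    norm = np.clip(norm, 0.0, 1.05)
    return PunctaStats(
        count=puncta.n,
        mean_volume=float(puncta.volumes.mean()),
        volumes=puncta.volumes.copy(),
        distances=d,
        normalized_distances=norm,
        mean_distance=float(d.mean()),
    )


def compartmentalization_fraction(puncta: PunctaSet,
                                  boundary: float = OUTER_THIRD_BOUNDARY) -> float:
    """Fraction of puncta beyond the given normalized soma distance.

    The default boundary of 2/3 measures compartmentalization of synaptic
    outputs to the outer third of the dendritic arbor.
    """
    if puncta.n == 0:
        raise ParameterError("compartmentalization undefined for an empty puncta set")
    stats = puncta_stats(puncta)
    return float((stats.normalized_distances > boundary).mean())
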