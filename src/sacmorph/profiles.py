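"""IPL lamination profiling and background-normalized ROI intensity.

Lamination profiles are reduced to 20 equal depth bins holding intensity
*fractions*, so sections of different IPL thickness and staining strength
are directly comparable.  ROI quantification divides each cell's mean
fluorescence by the mean of the inverse (background) ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateProfileError, ParameterError
from .types import LaminationProfile

N_BINS = 20


@dataclass
class ROIIntensitySet:
    """Per-cell mean ROI intensities plus the background (inverse ROI) mean."""

    cell_means: np.ndarray
    background_mean: float

    def __post_init__(self) -> None:
        self.cell_means = np.asarray(self.cell_means, dtype=float).reshape(-1)
        if np.any(self.cell_means < 0) or self.background_mean < 0:
            raise ParameterError("intensities must be non-negative")


def bin_lamination(profile: LaminationProfile) -> np.ndarray:
    """Fraction of total intensity in each of 20 equal IPL depth bins.

    Bin ``k`` (1-based) collects depths in ``((k-1)/20, k/20]``; depth 0
    joins the first bin.  Total intensity of zero is degenerate and raises
    rather than dividing by zero.
    """
    total = profile.intensities.sum()
    if total <= 0:
        raise DegenerateProfileError("profile carries zero total intensity")
    idx = np.ceil(profile.depths * N_BINS).astype(int) - 1
    idx = np.clip(idx, 0, N_BINS - 1)  # depth 0 -> bin 1
    bins = np.zeros(N_BINS)
    np.add.at(bins, idx, profile.intensities)
    return bins / total


def normalized_intensity(rois: ROIIntensitySet) -> np.ndarray:
    """Per-cell fluorescence normalized to the background ROI mean."""
    if rois.background_mean <= 0:
        raise DegenerateProfileError("background mean must be > 0 for normalization")
    return rois.cell_means / rois.background_mean


def band_concentration(binned: np.ndarray, halfwidth: int = 1) -> float:
    """Fraction of intensity within ``halfwidth`` bins of the two tallest bins.

    A scalar summary of how concentrated a lamination profile is in its two
    strata; used for group comparisons of binned profiles.
    """
    binned = np.asarray(binned, dtype=float)
    if len(binned) != N_BINS:
        raise ParameterError(f"expected {N_BINS} bins")
    order = np.argsort(binned)[::-1]
    peaks = [int(order[0])]
    for k in order[1:]:
        if abs(int(k) - peaks[0]) > halfwidth:
            peaks.append(int(k))
            break
    keep = np.zeros(N_BINS, dtype=bool)
    for p in peaks:
        keep[max(0, p - halfwidth):p + halfwidth + 1] = True
    return float(binned[keep].sum())
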