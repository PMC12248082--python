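"""Direction-selective ganglion cell (DSGC) classification.

The pipeline consumes per-unit spike counts to motion in evenly spaced
directions and applies, in order: a 400-total-spike floor, the direction
selectivity index DSI = (P - N) / (P + N) over the preferred and opposite
(null) directions, a least-squares von Mises tuning fit
``r(theta) = baseline + amplitude * exp(kappa * (cos(theta - mu) - 1))``
scored by R^2, and a 10-average-spikes floor in the preferred direction.
Units with DSI > 0.37 and fit R^2 > 0.5 passing both spike floors are
classified as putative DSGCs.  Tuning sharpness is reported as the full
width at half maximum (FWHM) of the fitted curve above baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ParameterError
from .types import DirectionalResponseSet

DSI_THRESHOLD = 0.37
FIT_THRESHOLD = 0.5
MIN_TOTAL_SPIKES = 400
MIN_PREFERRED_AVG = 10.0


@dataclass
class TuningFit:
    mu: float          # preferred angle of the fit, degrees in [0, 360)
    kappa: float       # concentration, dimensionless >= 0
    amplitude: float   # spikes above baseline at the preferred direction
    baseline: float    # spikes
    fit_quality: float  # R^2 in (-inf, 1]


@dataclass
class DSGCRecord:
    unit_id: str
    total_spikes: int
    dsi: float
    fit: TuningFit | None
    preferred_direction: float
    avg_spikes_per_epoch: float
    avg_spikes_preferred: float
    tuning_width_fwhm: float
    is_dsgc: bool
    reason: str  # "" for classified DSGCs, else the first failed criterion


def filter_min_spikes(responses: DirectionalResponseSet,
                      min_total: int = MIN_TOTAL_SPIKES) -> list[str]:
    """Unit ids whose summed counts over all epochs and directions reach the floor."""
    return [
        uid for uid, c in zip(responses.unit_ids, responses.counts)
        if int(c.sum()) >= min_total
    ]


def compute_dsi(mean_counts: np.ndarray,
                directions_deg: np.ndarray) -> tuple[float, float, float]:
    """DSI plus preferred and null direction from per-direction mean counts.

    Preferred is the direction of maximal mean count (ties break toward the
    smaller angle); null is its exact opposite, which exists because the
    direction count is even.
    """
    mean_counts = np.asarray(mean_counts, dtype=float)
    directions_deg = np.asarray(directions_deg, dtype=float)
    d = len(directions_deg)
    if d < 2 or d % 2:
        raise ParameterError("direction count must be even and >= 2")
    if not np.any(mean_counts > 0):
        raise ParameterError("all mean counts are zero; DSI undefined")
    i_pref = int(np.argmax(mean_counts))  # first max = smallest angle on sorted grid
    i_null = (i_pref + d // 2) % d
    p, n = mean_counts[i_pref], mean_counts[i_null]
    return float((p - n) / (p + n)), float(directions_deg[i_pref]), float(directions_deg[i_null])


def _vm_model(theta_rad: np.ndarray, baseline: float, amplitude: float,
              kappa: float, mu_rad: float) -> np.ndarray:
    return baseline + amplitude * np.exp(kappa * (np.cos(theta_rad - mu_rad) - 1.0))


def fit_von_mises(mean_counts: np.ndarray,
                  directions_deg: np.ndarray) -> TuningFit:
    """Deterministic least-squares von Mises fit to a tuning curve.

    Every observed direction seeds one optimizer start for ``mu`` (in a
    fixed order), guarding against local minima; the best residual wins.
    Flat curves (zero variance across directions) are defined to have
    ``fit_quality`` 0 and ``kappa`` 0 rather than raising.
    """
    y = np.asarray(mean_counts, dtype=float)
    theta = np.deg2rad(np.asarray(directions_deg, dtype=float))
    if len(y) < 4:
        raise ParameterError("need >= 4 directions for a von Mises fit")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return TuningFit(mu=float(directions_deg[0]), kappa=0.0, amplitude=0.0,
                         baseline=float(y.mean()), fit_quality=0.0)

    span = max(y.max() - y.min(), 1e-9)
    lower = np.array([0.0, 0.0, 0.0, -2.0 * math.pi])
    upper = np.array([np.inf, np.inf, 1e3, 4.0 * math.pi])

    def residual(x: np.ndarray) -> np.ndarray:
        return _vm_model(theta, *x) - y

    def jacobian(x: np.ndarray) -> np.ndarray:
        _b, amp, kappa, mu = x
        delta = theta - mu
        e = np.exp(kappa * (np.cos(delta) - 1.0))
        return np.column_stack([
            np.ones_like(theta),            # d/d baseline
            e,                              # d/d amplitude
            amp * e * (np.cos(delta) - 1.0),  # d/d kappa
            amp * e * kappa * np.sin(delta),  # d/d mu
        ])

    best = None
    for mu0 in theta:
        x0 = np.array([max(y.min(), 1e-9), span, 2.0, mu0])
        x0 = np.clip(x0, lower + 1e-12, upper - 1e-12)
        try:
            res = least_squares(residual, x0, jac=jacobian,
                                bounds=(lower, upper), method="trf",
                                x_scale="jac", max_nfev=100)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        return TuningFit(mu=float(directions_deg[0]), kappa=0.0, amplitude=0.0,
                         baseline=float(y.mean()), fit_quality=0.0)
    baseline, amplitude, kappa, mu_rad = best.x
    ss_res = float((2.0 * best.cost))
    mu_deg = math.degrees(mu_rad) % 360.0
    return TuningFit(mu=mu_deg, kappa=float(kappa), amplitude=float(amplitude),
                     baseline=float(baseline), fit_quality=1.0 - ss_res / ss_tot)


_LN2 = math.log(2.0)


def tuning_width_fwhm(fit: TuningFit) -> float:
    """FWHM (degrees) of the fitted tuning curve above its baseline.

    Closed form ``2 * arccos(1 - ln2 / kappa)``; broad curves with
    ``kappa < ln2 / 2`` never fall to half amplitude, so their width is the
    full circle, 360 degrees.
    """
    if fit.amplitude <= 0 or fit.kappa <= 0:
        raise ParameterError("FWHM undefined for amplitude = 0 or kappa = 0")
    if fit.kappa < _LN2 / 2.0:
        return 360.0
    return math.degrees(2.0 * math.acos(1.0 - _LN2 / fit.kappa))


def classify_units(responses: DirectionalResponseSet,
                   dsi_threshold: float = DSI_THRESHOLD,
                   fit_threshold: float = FIT_THRESHOLD,
                   min_total: int = MIN_TOTAL_SPIKES,
                   min_preferred: float = MIN_PREFERRED_AVG) -> list[DSGCRecord]:
    """Full per-unit classification; failing units are recorded, never dropped.

    ``is_dsgc`` requires total spikes >= ``min_total``, DSI strictly above
    ``dsi_threshold``, fit R^2 strictly above ``fit_threshold`` and an
    average of at least ``min_preferred`` spikes per epoch in the preferred
    direction.
    """
    records: list[DSGCRecord] = []
    dirs = responses.directions_deg
    for uid, counts in zip(responses.unit_ids, responses.counts):
        total = int(counts.sum())
        mean_counts = counts.mean(axis=0)
        avg_epoch = float(counts.mean())
        if not np.any(mean_counts > 0):
            records.append(DSGCRecord(uid, total, float("nan"), None, float("nan"),
                                      avg_epoch, 0.0, float("nan"), False, "no_spikes"))
            continue
        dsi, pref, _null = compute_dsi(mean_counts, dirs)
        fit = fit_von_mises(mean_counts, dirs)
        avg_pref = float(mean_counts[int(np.argmax(mean_counts))])
        try:
            fwhm = tuning_width_fwhm(fit)
        except ParameterError:
            fwhm = float("nan")
        reason = ""
        if total < min_total:
            reason = "min_total_spikes"
        elif not dsi > dsi_threshold:
            reason = "dsi"
        elif not fit.fit_quality > fit_threshold:
            reason = "fit_quality"
        elif not avg_pref >= min_preferred:
            reason = "min_preferred_spikes"
        records.append(DSGCRecord(uid, total, dsi, fit, pref, avg_epoch, avg_pref,
                                  fwhm, reason == "", reason))
    return records


def records_to_rows(records: list[DSGCRecord]) -> list[dict]:
    """Flatten classification records for CSV export."""
    rows = []
    for r in records:
        rows.append({
            "unit_id": r.unit_id,
            "total_spikes": r.total_spikes,
            "dsi": r.dsi,
            "fit_quality": r.fit.fit_quality if r.fit else float("nan"),
            "mu_deg": r.fit.mu if r.fit else float("nan"),
            "kappa": r.fit.kappa if r.fit else float("nan"),
            "fwhm_deg": r.tuning_width_fwhm,
            "avg_spikes_epoch": r.avg_spikes_per_epoch,
            "avg_spikes_preferred": r.avg_spikes_preferred,
            "is_dsgc": r.is_dsgc,
            "reason": r.reason,
        })
    return rows
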