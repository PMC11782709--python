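"""Image-based static-tissue background-phase correction and flow rates.

Implements the standard second-order polynomial static-tissue fit: pixels
that are bright (time-averaged magnitude above a fraction of the image
maximum) and temporally quiet (temporal standard deviation of the velocity
below a fraction of the image's maximum SD) are taken as stationary tissue;
a second-order 2D polynomial is fitted to their time-averaged phase
difference and extrapolated over the full field of view, then subtracted
from the velocity maps before flow quantification.

Because the steady-state phase error depends on tissue relaxation times and
on flow, the static-tissue extrapolation is systematically biased in the
vessel — the effect this package exists to demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import PolynomialField, design_matrix, normalized_grid

__all__ = [
    "StaticMask",
    "FlowResult",
    "static_mask",
    "fit_background",
    "fit_background_per_phase",
    "apply_correction",
    "flow_rate",
]


@dataclass
class StaticMask:
    """Boolean static-tissue mask plus the thresholds that produced it."""

    mask: np.ndarray
    magnitude_threshold_frac: float = 0.20
    tsd_threshold_frac: float = 0.10

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FlowResult:
    """Flow rate over an ROI: per cardiac phase and heart-phase averaged."""

    per_phase_ml_s: np.ndarray
    mean_ml_s: float
    roi_area_mm2: float


def static_mask(
    mag_stack: np.ndarray,
    velocity_stack: np.ndarray,
    magnitude_threshold_frac: float = 0.20,
    tsd_threshold_frac: float = 0.10,
    sd_on_magnitude: bool = False,
    sd_floor: float = 1e-9,
) -> StaticMask:
    """Mask of stationary-tissue pixels.

    A pixel is static iff its time-averaged magnitude is at least
    ``magnitude_threshold_frac`` of the image maximum AND the temporal SD of
    its velocity is at most ``tsd_threshold_frac`` of the image's maximum
    temporal SD. The SD criterion is applied to the velocity time series by
    default (it must reject pulsatile flow, which the fit targets); set
    ``sd_on_magnitude`` to threshold the magnitude SD instead. Pixels whose
    SD falls below the absolute ``sd_floor`` always count as static — this
    keeps the relative threshold meaningful on noiseless synthetic data
    where the maximum SD is mere float jitter.
    """
    mag = np.asarray(mag_stack, dtype=float)
    vel = np.asarray(velocity_stack, dtype=float)
    if mag.ndim != 3 or vel.shape != mag.shape:
        raise ValueError("stacks must be (n_phases, ny, nx) and co-registered")
    if mag.shape[0] < 2:
        raise ValueError("temporal SD needs at least 2 cardiac phases")
    tavg = mag.mean(axis=0)
    sd = (mag if sd_on_magnitude else vel).std(axis=0)
    mask = (tavg >= magnitude_threshold_frac * tavg.max()) & (
        (sd <= tsd_threshold_frac * sd.max()) | (sd < sd_floor)
    )
    return StaticMask(
        mask=mask,
        magnitude_threshold_frac=magnitude_threshold_frac,
        tsd_threshold_frac=tsd_threshold_frac,
    )


def fit_background(
    phase_timeavg: np.ndarray,
    mask: StaticMask | np.ndarray,
    weights: np.ndarray | None = None,
    units: str = "pct_venc",
) -> PolynomialField:
    """Least-squares second-order polynomial fit on masked pixels.

    ``phase_timeavg`` is the time-averaged phase-difference image (any
    units; the returned field carries ``units``). The polynomial basis uses
    the same normalized pixel-centre coordinates as the phantom renderer, so
    a polynomial truth field is recovered exactly. An optional per-pixel
    weight image (e.g. magnitude) turns the fit into weighted least squares.
    """
    m = mask.mask if isinstance(mask, StaticMask) else np.asarray(mask, dtype=bool)
    img = np.asarray(phase_timeavg, dtype=float)
    if img.shape != m.shape:
        raise ValueError("mask and image shapes differ")
    if m.sum() < 6:
        raise ValueError(f"need at least 6 masked pixels, got {int(m.sum())}")
    x, y = normalized_grid(*img.shape)
    a = design_matrix(x[m], y[m])
    b = img[m]
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[m])
        a = a * w[:, None]
        b = b * w
    if np.linalg.matrix_rank(a) < 6:
        raise ValueError(
            "degenerate mask geometry: polynomial design matrix is rank-deficient"
        )
    coeffs, *_ = np.linalg.lstsq(a, b, rcond=None)
    return PolynomialField(coeffs=coeffs, units=units)


def fit_background_per_phase(
    phase_stack: np.ndarray,
    mask: StaticMask | np.ndarray,
    weights: np.ndarray | None = None,
    units: str = "pct_venc",
) -> list[PolynomialField]:
    """Experimental: one polynomial fit per cardiac phase.

    Because the steady-state phase error of stationary tissue evolves
    differently from the vessel's over the cycle, a time-resolved fit can
    worsen flow quantification rather than improve it; this variant makes
    no quantitative claims and exists for exploration.
    """
    stack = np.asarray(phase_stack, dtype=float)
    return [fit_background(img, mask, weights=weights, units=units) for img in stack]


def apply_correction(
    velocity_stack: np.ndarray, field: PolynomialField, venc_cms: float
) -> np.ndarray:
    """Subtract the extrapolated background field from the velocity maps.

    The field (in %venc or rad) is converted to cm/s and subtracted from
    every cardiac phase.
    """
    vel = np.asarray(velocity_stack, dtype=float)
    bg = field.on_grid(*vel.shape[1:])
    if field.units == "pct_venc":
        bg_cms = bg / 100.0 * venc_cms
    elif field.units == "rad":
        bg_cms = bg / np.pi * venc_cms
    else:
        raise ValueError(f"unknown field units {field.units!r}")
    return vel - bg_cms[None, :, :]


def flow_rate(
    velocity_stack: np.ndarray, roi_mask: np.ndarray, pixel_area_mm2: float
) -> FlowResult:
    """ROI flow rate in mL/s per cardiac phase and heart-phase averaged.

    ``flow = sum_pixels v [cm/s] * pixel_area [cm^2]`` gives cm^3/s = mL/s.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    vel = np.asarray(velocity_stack, dtype=float)
    area_cm2 = pixel_area_mm2 / 100.0
    per_phase = vel[:, roi].sum(axis=1) * area_cm2
    return FlowResult(
        per_phase_ml_s=per_phase,
        mean_ml_s=float(per_phase.mean()),
        roi_area_mm2=float(roi.sum() * pixel_area_mm2),
    )
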