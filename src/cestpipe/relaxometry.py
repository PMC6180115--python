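"""Per-pixel ADC, T1 and T2 quantification.

ADC comes from a monoexponential fit S(b) = S0 exp(-b ADC); T2 from
S(TE) = S0 exp(-TE/T2); T1 from a three-parameter magnitude fit
S(TI) = |A - B exp(-TI/T1*)| with the Look-Locker correction
T1 = T1* (B/A - 1).  All fits are bounded nonlinear least squares seeded
by a log-linear (or null-point) estimate; pixels that cannot be fitted are
set to NaN and counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .zspec import ParametricMap

logger = logging.getLogger(__name__)


@dataclass
class RelaxometrySeries:
    """A grid of signal decays/recoveries indexed by b, TI or TE."""

    modality: str                 # diffusion | t1 | t2
    control: np.ndarray           # b (s/mm^2) | TI (ms) | TE (ms), increasing
    signal: np.ndarray            # (ny, nx, n_control)
    mask: np.ndarray              # (ny, nx) bool

    def __post_init__(self) -> None:
        if self.modality not in ("diffusion", "t1", "t2"):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.control = np.asarray(self.control, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.control.size < 3:
            raise ValueError("need at least 3 control points")
        if not np.all(np.diff(self.control) > 0):
            raise ValueError("control values must be strictly increasing")
        if self.signal.shape != self.mask.shape + (self.control.size,):
            raise ValueError("signal shape must be grid + (n_control,)")
        if np.any(self.signal[np.isfinite(self.signal)] < 0):
            raise ValueError("signals must be non-negative")


def _exp_decay_pixel(x: np.ndarray, y: np.ndarray, rate_bounds: tuple[float, float]):
    """Fit y = s0 exp(-rate x); log-linear seed refined by bounded NLS.

    Returns (s0, rate) or None for degenerate pixels (non-positive or
    non-decaying signal).
    """
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        return None
    slope, intercept = np.polyfit(x, np.log(y), 1)
    rate0 = float(np.clip(-slope, rate_bounds[0], rate_bounds[1]))
    s00 = float(np.exp(intercept))
    if np.ptp(y) == 0:  # perfectly flat: rate 0 exactly
        return s00 if rate_bounds[0] == 0 else None, 0.0

    def resid(p):
        return p[0] * np.exp(-p[1] * x) - y

    def jac(p):
        e = np.exp(-p[1] * x)
        return np.column_stack([e, -p[0] * x * e])

    sol = least_squares(resid, [s00, rate0], jac=jac,
                        bounds=([0.0, rate_bounds[0]], [np.inf, rate_bounds[1]]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return float(sol.x[0]), float(sol.x[1])


def fit_adc(series: RelaxometrySeries) -> ParametricMap:
    """ADC map (mm^2/s) from a monoexponential fit, ADC >= 0 enforced."""
    if series.modality != "diffusion":
        raise ValueError("fit_adc requires a diffusion series")
    out = np.full(series.mask.shape, np.nan)
    n_failed = 0
    for iy, ix in np.argwhere(series.mask):
        fit = _exp_decay_pixel(series.control, series.signal[iy, ix], (0.0, 0.1))
        if fit is None or fit[0] is None:
            n_failed += 1
            continue
        out[iy, ix] = fit[1]
    if n_failed:
        logger.info("fit_adc: %d degenerate pixels set to NaN", n_failed)
    return ParametricMap("adc", out, "mm^2/s", series.mask.copy())


def fit_t2(series: RelaxometrySeries) -> ParametricMap:
    """T2 map (ms) from S(TE) = S0 exp(-TE/T2) with T2 > 0."""
    if series.modality != "t2":
        raise ValueError("fit_t2 requires a t2 series")
    out = np.full(series.mask.shape, np.nan)
    n_failed = 0
    for iy, ix in np.argwhere(series.mask):
        y = series.signal[iy, ix]
        fit = _exp_decay_pixel(series.control, y, (1e-6, 10.0))
        if fit is None or fit[0] is None or fit[1] <= 0 or np.ptp(y) == 0:
            n_failed += 1
            continue
        out[iy, ix] = 1.0 / fit[1]
    if n_failed:
        logger.info("fit_t2: %d non-decaying pixels set to NaN", n_failed)
    return ParametricMap("t2", out, "ms", series.mask.copy())


def _t1_pixel(ti: np.ndarray, y: np.ndarray):
    """Three-parameter magnitude fit with polarity restoration.

    Magnitude data lose the sign of the recovery before its null point.  Every
    plausible sign pattern (negate the first k samples, k around the signal
    minimum) is fitted with the signed model A - B exp(-TI/T1*); the lowest
    residual wins.  Returns (A, B, T1*) or None.
    """
    if np.any(~np.isfinite(y)) or np.all(y == 0):
        return None
    kmin = int(np.argmin(y))
    best = None
    for k in range(0, min(kmin + 2, ti.size) + 1):
        signed = y.copy()
        signed[:k] *= -1.0
        a0 = float(y[-1]) if y[-1] > 0 else 1.0
        b0 = float(a0 - signed[0])
        t10 = float(ti[kmin] / np.log(2.0)) if y[kmin] < y[-1] else float(np.mean(ti))
        b0 = max(b0, 1e-6)
        t10 = max(t10, 1e-3)

        def resid(p):
            return p[0] - p[1] * np.exp(-ti / p[2]) - signed

        def jac(p):
            e = np.exp(-ti / p[2])
            return np.column_stack([np.ones_like(ti), -e, -p[1] * ti * e / p[2] ** 2])

        try:
            sol = least_squares(resid, [a0, b0, t10], jac=jac,
                                bounds=([0.0, 0.0, 1e-3], [np.inf, np.inf, 1e7]),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None
    return float(best.x[0]), float(best.x[1]), float(best.x[2])


def fit_t1_look_locker(series: RelaxometrySeries) -> ParametricMap:
    """T1 map (ms) from Look-Locker inversion recovery.

    Applies the apparent-T1 correction T1 = T1* (B/A - 1); pixels with
    B/A <= 1 cannot be corrected and are set to NaN.
    """
    if series.modality != "t1":
        raise ValueError("fit_t1_look_locker requires a t1 series")
    if series.control.size < 4:
        raise ValueError("need at least 4 inversion times")
    out = np.full(series.mask.shape, np.nan)
    n_failed = 0
    for iy, ix in np.argwhere(series.mask):
        fit = _t1_pixel(series.control, series.signal[iy, ix])
        if fit is None:
            n_failed += 1
            continue
        a, b, t1_star = fit
        if a <= 0 or b / a <= 1.0:
            n_failed += 1
            continue
        out[iy, ix] = t1_star * (b / a - 1.0)
    if n_failed:
        logger.info("fit_t1_look_locker: %d uncorrectable pixels set to NaN", n_failed)
    return ParametricMap("t1", out, "ms", series.mask.copy())
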