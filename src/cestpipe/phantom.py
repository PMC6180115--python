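"""Digital tumor phantoms and forward simulation of the image series.

A phantom is an elliptical tumor ROI on a square single-slice grid with
smooth (low-order polynomial) ground-truth maps for every quantity the
pipeline estimates: the five Lorentzian pools, a B0-shift field, ADC, T1
and T2.  Simulated magnitudes carry Rician noise scaled to the per-pixel
reference signal, as appropriate for magnitude MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AcquisitionConfig
from .relaxometry import RelaxometrySeries
from .zspec import NOMINAL_CENTERS, LorentzianPeak, ZSpectrumGrid, model_zspectrum

#: nominal (amplitude, fwhm ppm) per pool at B1,rms = 3 uT
DEFAULT_POOLS = {
    "water": {"center": 0.0, "amplitude": 0.80, "fwhm": 2.0},
    "hydroxyl": {"center": 1.2, "amplitude": 0.03, "fwhm": 1.0},
    "amine": {"center": 2.4, "amplitude": 0.04, "fwhm": 1.2},
    "amide": {"center": 3.5, "amplitude": 0.05, "fwhm": 1.0},
    "noe_mt": {"center": -3.0, "amplitude": 0.10, "fwhm": 5.0},
}

#: baseline tissue values: ADC mm^2/s, T1 ms, T2 ms (typical colorectal xenograft)
DEFAULT_ADC = 1.0e-3
DEFAULT_T1 = 1800.0
DEFAULT_T2 = 40.0
REFERENCE_SIGNAL = 100.0  # arbitrary scanner units for S0


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: mask plus per-pixel parameter maps."""

    mask: np.ndarray                                   # (n, n) bool ellipse
    pools: dict[str, dict[str, np.ndarray]]            # name -> center/amplitude/fwhm maps
    b0_shift_map: np.ndarray                           # ppm
    adc_map: np.ndarray                                # mm^2/s
    t1_map: np.ndarray                                 # ms
    t2_map: np.ndarray                                 # ms

    def scaled(self, multipliers: dict[str, float]) -> "PhantomTruth":
        """New truth with pool amplitudes / ADC scaled (effect-model hook).

        ``multipliers`` maps quantity names (pool name -> amplitude scale,
        or ``"adc"``) to multiplicative factors; amplitudes are clipped to 1.
        """
        pools = {n: {k: v.copy() for k, v in m.items()} for n, m in self.pools.items()}
        adc = self.adc_map.copy()
        for key, fac in multipliers.items():
            if key == "adc":
                adc = adc * fac
            elif key in pools:
                pools[key]["amplitude"] = np.clip(pools[key]["amplitude"] * fac, 0.0, 1.0)
            else:
                raise KeyError(f"unknown effect target {key!r}")
        return PhantomTruth(self.mask.copy(), pools, self.b0_shift_map.copy(),
                            adc, self.t1_map.copy(), self.t2_map.copy())

    def pixel_peaks(self, iy: int, ix: int) -> list[LorentzianPeak]:
        return [
            LorentzianPeak(name, float(m["center"][iy, ix]),
                           float(m["amplitude"][iy, ix]), float(m["fwhm"][iy, ix]))
            for name, m in self.pools.items()
        ]


def _ramps(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalised coordinate ramps in [-1, 1] across the grid."""
    c = (np.arange(n) - (n - 1) / 2.0) / max((n - 1) / 2.0, 1.0)
    return np.meshgrid(c, c, indexing="ij")


def make_phantom(config: AcquisitionConfig,
                 truth_overrides: dict | None = None) -> PhantomTruth:
    """Construct a deterministic elliptical tumor phantom.

    The mask is a centred ellipse with semi-axes 0.35 and 0.27 of the grid
    (~30% coverage).  Truth maps vary smoothly: pool amplitudes carry a
    gentle linear ramp (+/-15%), the B0-shift field is a +/-0.08 ppm tilt,
    and ADC/T1/T2 carry +/-10% ramps around their baseline values.

    ``truth_overrides`` replaces scalar baselines before the ramps are
    applied, e.g. ``{"amide": {"amplitude": 0.07}}`` or ``{"*": {"amplitude":
    0.0}}`` for every pool; top-level keys ``"adc"``, ``"t1"``, ``"t2"``
    override the relaxometry baselines.  Amplitude overrides outside [0, 1]
    are rejected.
    """
    n = config.grid_size
    yy, xx = _ramps(n)
    mask = (yy / 0.70) ** 2 + (xx / 0.54) ** 2 <= 1.0

    base = {name: dict(vals) for name, vals in DEFAULT_POOLS.items()}
    adc0, t10, t20 = DEFAULT_ADC, DEFAULT_T1, DEFAULT_T2
    if truth_overrides:
        for key, val in truth_overrides.items():
            if key == "adc":
                adc0 = float(val)
            elif key == "t1":
                t10 = float(val)
            elif key == "t2":
                t20 = float(val)
            elif key == "*":
                for name in base:
                    base[name].update(val)
            elif key in base:
                base[key].update(val)
            else:
                raise KeyError(f"unknown truth override {key!r}")
        for name, vals in base.items():
            if not 0.0 <= vals["amplitude"] <= 1.0:
                raise ValueError(f"{name} amplitude override outside [0, 1]")
            if vals["fwhm"] <= 0:
                raise ValueError(f"{name} fwhm override must be positive")

    pools: dict[str, dict[str, np.ndarray]] = {}
    for i, (name, vals) in enumerate(base.items()):
        sign = 1.0 if i % 2 == 0 else -1.0
        amp = vals["amplitude"] * (1.0 + sign * 0.15 * xx)
        pools[name] = {
            "center": np.full((n, n), vals["center"]),
            "amplitude": np.clip(amp, 0.0, 1.0),
            "fwhm": np.full((n, n), vals["fwhm"]),
        }
    return PhantomTruth(
        mask=mask,
        pools=pools,
        b0_shift_map=0.08 * yy,                 # |shift| <= 0.08 ppm, within the 0.1 ppm drift bound
        adc_map=adc0 * (1.0 + 0.10 * xx),
        t1_map=t10 * (1.0 + 0.10 * yy),
        t2_map=t20 * (1.0 - 0.10 * xx),
    )


def rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of ``clean`` plus complex Gaussian noise of scale ``sigma``."""
    if sigma == 0:
        return np.asarray(clean, dtype=float).copy()
    re = clean + rng.normal(0.0, sigma, size=np.shape(clean))
    im = rng.normal(0.0, sigma, size=np.shape(clean))
    return np.hypot(re, im)


def simulate_cest_series(truth: PhantomTruth, config: AcquisitionConfig) -> ZSpectrumGrid:
    """Forward-simulate the saturation image series plus reference image.

    Per pixel the signal at each offset is reference x Z(offset) with Z from
    the five-pool Lorentzian model evaluated at that pixel's truth (including
    its B0 shift); Rician noise of scale ``noise_sigma`` x reference is added
    to every magnitude, including the reference image itself.  Pixels outside
    the mask contain noise only.
    """
    if truth.mask.shape != (config.grid_size, config.grid_size):
        raise ValueError("phantom and config grid sizes differ")
    rng = np.random.default_rng(config.seed)
    offsets = config.offsets
    n = config.grid_size
    clean = np.zeros((n, n, offsets.size))
    ref_clean = np.full((n, n), REFERENCE_SIGNAL)
    for iy, ix in np.argwhere(truth.mask):
        z = model_zspectrum(offsets, truth.pixel_peaks(iy, ix),
                            b0_shift=float(truth.b0_shift_map[iy, ix]))
        clean[iy, ix] = REFERENCE_SIGNAL * z
    sigma = config.noise_sigma * REFERENCE_SIGNAL
    signal = rician(clean, sigma, rng)
    reference = rician(ref_clean, sigma, rng)
    if sigma == 0:
        # keep exactly-noiseless background at zero signal
        signal[~truth.mask] = 0.0
    return ZSpectrumGrid(offsets=offsets, signal=signal, reference=reference,
                         mask=truth.mask.copy())


def simulate_relaxometry(truth: PhantomTruth, config: AcquisitionConfig,
                         modality: str, *, ll_ratio: float = 1.8) -> RelaxometrySeries:
    """Forward-simulate a diffusion, T1 or T2 series from the phantom truth.

    diffusion: S(b) = S0 exp(-b ADC); t2: S(TE) = S0 exp(-TE/T2);
    t1 (Look-Locker readout): S(TI) = |A - B exp(-TI/T1*)| with B/A =
    ``ll_ratio`` and apparent T1* = T1 / (ll_ratio - 1), so that the standard
    correction T1 = T1* (B/A - 1) returns the true T1.  Rician noise is
    added as for the CEST series.
    """
    if modality not in ("diffusion", "t1", "t2"):
        raise ValueError(f"unknown modality {modality!r}")
    if ll_ratio <= 1.0:
        raise ValueError("ll_ratio must exceed 1 (B > A)")
    rng = np.random.default_rng(config.seed + {"diffusion": 1, "t1": 2, "t2": 3}[modality])
    n = config.grid_size
    if truth.mask.shape != (n, n):
        raise ValueError("phantom and config grid sizes differ")

    if modality == "diffusion":
        control = np.asarray(config.b_values, dtype=float)
        decay = np.exp(-control[None, None, :] * truth.adc_map[..., None])
    elif modality == "t2":
        control = np.asarray(config.echo_times, dtype=float)
        decay = np.exp(-control[None, None, :] / truth.t2_map[..., None])
    else:
        control = np.asarray(config.inversion_times, dtype=float)
        t1_star = truth.t1_map / (ll_ratio - 1.0)
        decay = np.abs(1.0 - ll_ratio * np.exp(-control[None, None, :] / t1_star[..., None]))

    clean = REFERENCE_SIGNAL * decay
    clean[~truth.mask] = 0.0
    signal = rician(clean, config.noise_sigma * REFERENCE_SIGNAL, rng)
    if config.noise_sigma == 0:
        signal[~truth.mask] = 0.0
    return RelaxometrySeries(modality=modality, control=control, signal=signal,
                             mask=truth.mask.copy())
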