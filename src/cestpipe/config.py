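"""Acquisition configuration shared by the simulators and fitters."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

# Defaults mirror a preclinical 9.4 T protocol: Z-spectrum sampled -6..6 ppm
# at 0.12 ppm (101 offsets) with the normalisation reference at 8000 ppm,
# diffusion b-values spanning 150-1070 s/mm^2.
DEFAULT_B_VALUES = (150.0, 334.0, 518.0, 702.0, 886.0, 1070.0)
DEFAULT_INVERSION_TIMES = (50.0, 150.0, 350.0, 700.0, 1200.0, 2000.0, 3500.0, 5000.0)
DEFAULT_ECHO_TIMES = (10.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0, 120.0)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling scheme and noise level for all simulated acquisitions.

    Parameters
    ----------
    offset_min, offset_max, offset_step
        Saturation offset grid in ppm. The default grid is -6 to 6 ppm at
        0.12 ppm, giving 101 samples with one at 0 ppm.
    reference_offset
        Offset (ppm) of the unsaturated reference image S0.
    b_values
        Diffusion weightings in s/mm^2.
    inversion_times, echo_times
        TI and TE samples in ms for T1 (Look-Locker) and T2 mapping.
    grid_size
        Pixels per side of the (square, single-slice) image grid.
    noise_sigma
        Rician noise scale as a fraction of the per-pixel reference signal.
    seed
        Base seed; identical config + seed reproduce bit-identical output.
    """

    offset_min: float = -6.0
    offset_max: float = 6.0
    offset_step: float = 0.12
    reference_offset: float = 8000.0
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    inversion_times: tuple[float, ...] = DEFAULT_INVERSION_TIMES
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    grid_size: int = 64
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offset_min >= self.offset_max:
            raise ValueError("offset_min must be < offset_max")
        if self.offset_step <= 0:
            raise ValueError("offset_step must be positive")
        if self.grid_size <= 0:
            raise ValueError("grid_size must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        offs = self.offsets
        if not np.all(np.diff(offs) > 0):
            raise ValueError("offset grid must be strictly ascending")
        if np.min(np.abs(offs)) > self.offset_step / 2:
            raise ValueError("offset grid must include a sample near 0 ppm")
        for name in ("b_values", "inversion_times", "echo_times"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size and not np.all(np.diff(vals) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def offsets(self) -> np.ndarray:
        """Strictly ascending saturation offsets in ppm."""
        n = int(round((self.offset_max - self.offset_min) / self.offset_step)) + 1
        return np.round(self.offset_min + self.offset_step * np.arange(n), 9)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        for name in ("b_values", "inversion_times", "echo_times"):
            if name in d:
                d[name] = tuple(float(v) for v in d[name])
        return cls(**d)

    def config_hash(self) -> str:
        """Stable short hash used for output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
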