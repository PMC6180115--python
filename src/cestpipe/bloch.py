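"""Continuous-wave steady-state two-pool Bloch-McConnell solution.

Serves as an independent physical forward model: spectra generated here are
not Lorentzian sums, so fitting them with the phenomenological five-pool
model cross-checks that peak positions are recovered from physically
generated data. Water is pool a, the exchanging solute pool b.
"""

from __future__ import annotations

import numpy as np

GAMMA_HZ_PER_T = 42.577e6  # proton gyromagnetic ratio / 2pi


def simulate_two_pool_bm(
    offsets_ppm,
    *,
    exchange_rate: float,
    pool_fraction: float,
    pool_offset_ppm: float,
    t1_water: float = 2.0,
    t2_water: float = 0.06,
    t1_solute: float = 1.0,
    t2_solute: float = 0.01,
    b1_ut: float = 3.0,
    b0_t: float = 9.4,
) -> np.ndarray:
    """Steady-state Z value under CW saturation at each offset.

    Parameters
    ----------
    offsets_ppm : array-like
        Saturation offsets in ppm relative to water.
    exchange_rate : float
        Solute-to-water exchange rate k_b in 1/s (must be positive).
    pool_fraction : float
        Solute pool fraction relative to water, in (0, 0.1]; 0 is accepted
        and degenerates to the one-pool water solution.
    pool_offset_ppm : float
        Chemical shift of the solute pool (ppm from water).
    t1_water, t2_water, t1_solute, t2_solute : float
        Longitudinal/transverse relaxation times in seconds.
    b1_ut : float
        CW saturation amplitude in microtesla (B1,rms).
    b0_t : float
        Static field in tesla (sets the Hz-per-ppm scale).

    Returns
    -------
    ndarray of Z = Mz_water / M0_water at each offset.
    """
    if exchange_rate <= 0:
        raise ValueError("exchange_rate must be positive")
    if not 0.0 <= pool_fraction <= 0.1:
        raise ValueError("pool_fraction must be in [0, 0.1]")
    for name, t in (("t1_water", t1_water), ("t2_water", t2_water),
                    ("t1_solute", t1_solute), ("t2_solute", t2_solute)):
        if t <= 0:
            raise ValueError(f"{name} must be positive")
    if b1_ut < 0:
        raise ValueError("b1 must be non-negative")

    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    hz_per_ppm = GAMMA_HZ_PER_T * b0_t * 1e-6
    w1 = 2.0 * np.pi * GAMMA_HZ_PER_T * b1_ut * 1e-6  # rad/s

    f = pool_fraction
    kb = exchange_rate            # b -> a
    ka = f * kb                   # a -> b (detailed balance)
    r1a, r2a = 1.0 / t1_water, 1.0 / t2_water
    r1b, r2b = 1.0 / t1_solute, 1.0 / t2_solute
    m0a, m0b = 1.0, f

    z = np.empty_like(offsets_ppm)
    for i, dppm in enumerate(offsets_ppm):
        da = 2.0 * np.pi * hz_per_ppm * (0.0 - dppm)            # water offset in RF frame
        db = 2.0 * np.pi * hz_per_ppm * (pool_offset_ppm - dppm)
        # state [Mxa, Mya, Mza, Mxb, Myb, Mzb]; dM/dt = A M + c, steady state M = -A^-1 c
        A = np.array([
            [-r2a - ka, da, 0.0, kb, 0.0, 0.0],
            [-da, -r2a - ka, w1, 0.0, kb, 0.0],
            [0.0, -w1, -r1a - ka, 0.0, 0.0, kb],
            [ka, 0.0, 0.0, -r2b - kb, db, 0.0],
            [0.0, ka, 0.0, -db, -r2b - kb, w1],
            [0.0, 0.0, ka, 0.0, -w1, -r1b - kb],
        ])
        c = np.array([0.0, 0.0, r1a * m0a, 0.0, 0.0, r1b * m0b])
        m = np.linalg.solve(A, -c)
        z[i] = m[2] / m0a
    return z
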