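"""Biphasic (hormetic) dose-response analysis of MTT viability data.

Cell viability vs drug concentration is modelled with a modified Hill
equation combining a stimulatory and an inhibitory sigmoid:

    V(C) = V0 + Smax C^hs / (EC50^hs + C^hs) - Imax C^hi / (IC50^hi + C^hi)

V0 is the no-drug baseline (100% of control), Smax/EC50/hs describe the
low-dose stimulation (hormesis), Imax/IC50/hi the inhibition.  Receptor
occupancy follows the single-site law: unbound fraction = Ki / (Ki + C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: 2-fold serial dilution ladder, 1.6 to 400 nM (9 points)
DEFAULT_CONCENTRATIONS = tuple(400.0 / 2.0 ** k for k in range(8, -1, -1))


@dataclass(frozen=True)
class HillParameters:
    """Parameters of the biphasic modified Hill curve (viability in %)."""

    v0: float = 100.0     # baseline viability, % of control
    smax: float = 0.0     # stimulation magnitude, %
    ec50: float = 1.0     # half-maximal stimulatory concentration, nM
    hs: float = 1.0       # stimulation slope
    imax: float = 0.0     # inhibition magnitude, %
    ic50: float = 10.0    # half-maximal inhibitory concentration, nM
    hi: float = 1.0       # inhibition slope

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.ic50 <= 0:
            raise ValueError("EC50 and IC50 must be positive")
        if self.hs <= 0 or self.hi <= 0:
            raise ValueError("slopes must be positive")
        if not 0.0 <= self.imax <= self.v0 + self.smax:
            raise ValueError("Imax must lie in [0, V0 + Smax]")


@dataclass
class DoseResponseDataset:
    """Replicate-structured viability table for one cell line / timepoint."""

    table: pd.DataFrame           # columns: concentration_nM, replicate, viability_pct
    timepoint_h: float = 48.0
    label: str = ""

    def __post_init__(self) -> None:
        required = {"concentration_nM", "replicate", "viability_pct"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if (self.table["concentration_nM"] <= 0).any():
            raise ValueError("concentrations must be positive")
        if (self.table["viability_pct"] < 0).any():
            raise ValueError("viabilities must be non-negative")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.table["concentration_nM"].unique())


def hill_model(concentration, p: HillParameters):
    """Viability (%) at the given concentration(s) in nM."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    stim = np.where(c > 0, p.smax * c ** p.hs / (p.ec50 ** p.hs + c ** p.hs), 0.0)
    inhib = np.where(c > 0, p.imax * c ** p.hi / (p.ic50 ** p.hi + c ** p.hi), 0.0)
    out = p.v0 + stim - inhib
    return out if out.ndim else float(out)


def unbound_fraction(concentration, ki: float):
    """Percent of binding sites left unbound: 100 Ki / (Ki + C)."""
    if ki <= 0:
        raise ValueError("Ki must be positive")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = 100.0 * ki / (ki + c)
    return out if out.ndim else float(out)


def viability_from_absorbance(absorbance: pd.DataFrame,
                              control_mask=None) -> DoseResponseDataset:
    """Convert an absorbance plate table to % viability of control.

    ``absorbance`` needs columns ``concentration_nM``, ``replicate`` and
    ``absorbance``; control wells are rows where ``control_mask`` is True
    (default: column ``is_control``).  Viability = 100 x absorbance /
    mean(control absorbance).
    """
    if control_mask is None:
        if "is_control" not in absorbance.columns:
            raise ValueError("provide control_mask or an is_control column")
        control_mask = absorbance["is_control"].astype(bool)
    control_mean = float(absorbance.loc[control_mask, "absorbance"].mean())
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise ValueError("control absorbance mean must be positive")
    wells = absorbance.loc[~control_mask].copy()
    wells["viability_pct"] = 100.0 * wells["absorbance"] / control_mean
    return DoseResponseDataset(
        table=wells[["concentration_nM", "replicate", "viability_pct"]].reset_index(drop=True))


def simulate_mtt_plate(truth: HillParameters, concentrations=None, *,
                       replicates: int = 12, noise_sigma: float = 5.0,
                       seed: int = 0, timepoint_h: float = 48.0,
                       label: str = "") -> DoseResponseDataset:
    """Simulate an MTT viability plate from a known dose-response truth.

    Default ladder is the 2-fold dilution series 1.6-400 nM (9 points);
    each replicate's viability is the truth curve plus Gaussian noise of
    ``noise_sigma`` (% viability), floored at 0.
    """
    if concentrations is None:
        concentrations = DEFAULT_CONCENTRATIONS
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list must be non-empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        clean = hill_model(conc, truth)
        noisy = np.clip(clean + rng.normal(0.0, noise_sigma, size=conc.size), 0.0, None)
        for c, v in zip(conc, noisy):
            rows.append({"concentration_nM": c, "replicate": rep, "viability_pct": v})
    return DoseResponseDataset(pd.DataFrame(rows), timepoint_h=timepoint_h, label=label)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

# fit parameterisation: [v0, smax, log10 ec50, hs, imax_frac, log10 gap, hi]
# with imax = imax_frac * (v0 + smax) (so 0 <= Imax <= V0 + Smax and the
# saturating-dose viability stays non-negative) and ic50 = ec50 * 10^gap with
# gap >= 0 (hormesis: the stimulatory half-point precedes the inhibitory one).
# Both constraints remove the degenerate mode in which enormous, mutually
# cancelling stimulation and inhibition terms overfit plate noise.

def _unpack(x: np.ndarray, ic50_cap: float = np.inf) -> HillParameters:
    v0, smax = float(x[0]), float(x[1])
    ec50 = float(10 ** x[2])
    return HillParameters(v0=v0, smax=smax, ec50=ec50,
                          hs=float(x[3]), imax=float(x[4]) * (v0 + smax),
                          ic50=float(min(ec50 * 10 ** x[5], ic50_cap)),
                          hi=float(x[6]))


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    # floor the RSS at a negligible per-point value so that two essentially
    # perfect fits compare on parameter count alone
    return n * np.log(max(rss, n * 1e-10) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class HillFit:
    """Result of a dose-response fit."""

    params: HillParameters
    params_sd: dict[str, float]
    residual_rms: float
    converged: bool
    biphasic_supported: bool       # AICc prefers the biphasic over the monophasic model
    aicc_biphasic: float
    aicc_monophasic: float


def fit_hill(data: DoseResponseDataset, *,
             v0_bounds: tuple[float, float] = (99.0, 101.0)) -> HillFit:
    """Fit the modified Hill model by bounded NLS on log10 concentration.

    Viability is expressed as percent of control, so the baseline V0 is
    anchored near 100 by default (``v0_bounds``); widen the bounds to fit
    data normalised differently.  Both monophasic (inhibition-only) and
    biphasic initialisations are tried over a grid of (EC50, IC50) starts;
    EC50/IC50 are bounded within [min(C)/10, max(C) x 10] and slopes within
    (0.3, 6).  An AICc comparison between the best biphasic and monophasic
    fits is reported, never silently applied.
    """
    conc = data.table["concentration_nM"].to_numpy(dtype=float)
    via = data.table["viability_pct"].to_numpy(dtype=float)
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")

    cmin, cmax = conc.min(), conc.max()
    ic50_cap = cmax * 10
    lo = np.array([v0_bounds[0], 0.0, np.log10(cmin / 10), 0.3, 0.0, 0.0, 0.3])
    hi = np.array([v0_bounds[1], 60.0, np.log10(cmax * 10), 6.0, 1.0, 4.0, 6.0])

    def resid(x):
        return hill_model(conc, _unpack(x, ic50_cap)) - via

    smax0 = float(np.clip(np.max(via) - 100.0, 5.0, 55.0))
    # multi-start grid over the (EC50, gap) plane: the stimulation and
    # inhibition terms overlap, so single-start fits fall into trade-off
    # valleys; the grid makes the search effectively global.
    log_range = np.log10(cmax) - np.log10(cmin)
    ec_grid = np.log10(cmin) + log_range * np.array([0.0, 0.3, 0.6])
    gap_grid = np.array([0.3, 0.8, 1.5])
    starts = [np.array([100.0, smax0, lec, 1.5, 0.7, gap, 1.5])
              for lec in ec_grid for gap in gap_grid]
    mono_starts = [np.array([100.0, 0.0, lic - 0.3, 1.0, 0.6, 0.3, 1.0])
                   for lic in np.log10(cmin) + log_range * np.array([0.2, 0.45, 0.7, 0.95])]

    best_bi, best_mono = None, None
    for mono, group in ((False, starts), (True, mono_starts)):
        lo_i, hi_i = lo.copy(), hi.copy()
        if mono:
            hi_i[1] = 1e-6  # freeze Smax ~ 0
        for x0 in group:
            try:
                sol = least_squares(resid, np.clip(x0, lo_i + 1e-12, hi_i - 1e-12),
                                    bounds=(lo_i, hi_i), xtol=1e-12, ftol=1e-12,
                                    gtol=1e-12, max_nfev=5000)
            except Exception:  # pragma: no cover
                continue
            if mono:
                if best_mono is None or sol.cost < best_mono.cost:
                    best_mono = sol
            else:
                if best_bi is None or sol.cost < best_bi.cost:
                    best_bi = sol

    if best_bi is None and best_mono is None:
        return HillFit(HillParameters(), {}, np.nan, False, False, np.inf, np.inf)

    n = conc.size
    aicc_bi = _aicc(2 * best_bi.cost, n, 7) if best_bi is not None else np.inf
    aicc_mono = _aicc(2 * best_mono.cost, n, 5) if best_mono is not None else np.inf
    # report the better-fitting curve; on a tie (e.g. flat data, where the
    # stimulation and inhibition terms can cancel exactly) prefer the
    # monophasic solution so degenerate Smax/Imax pairs do not appear
    if best_bi is None:
        sol = best_mono
    elif best_mono is not None and best_mono.cost <= best_bi.cost * (1 + 1e-6) + 1e-9:
        sol = best_mono
    else:
        sol = best_bi

    params = _unpack(sol.x, ic50_cap)
    names = ["v0", "smax", "log10_ec50", "hs", "imax_frac", "log10_gap", "hi"]
    sd: dict[str, float] = {}
    try:
        dof = max(n - sol.x.size, 1)
        s2 = 2 * sol.cost / dof
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        for nm, v in zip(names, np.sqrt(np.clip(np.diag(cov), 0.0, None))):
            sd[nm] = float(v)
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    return HillFit(
        params=params,
        params_sd=sd,
        residual_rms=float(np.sqrt(2 * sol.cost / n)),
        converged=bool(sol.status > 0),
        biphasic_supported=bool(aicc_bi < aicc_mono),
        aicc_biphasic=float(aicc_bi),
        aicc_monophasic=float(aicc_mono),
    )
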