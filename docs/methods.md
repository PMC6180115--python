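# Methods

This note documents the models implemented in `cestpipe`, the defaults and
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## Z-spectrum model and estimation

**Model.** The normalised Z-spectrum Z(f) = S(f)/S0 is modelled as unity
minus a sum of five amplitude/FWHM Lorentzian lines, all displaced by one
global B0 shift δ:

Z(f) = 1 − Σᵢ Aᵢ / (1 + ((f − δ − cᵢ)/(wᵢ/2))²), clipped at 0 from below.

The pools and their nominal centers are: water 0 ppm (direct saturation),
hydroxyl +1.2 ppm, amine +2.4 ppm (the amine region can also contain
guanidinium contributions), amide +3.5 ppm, and one combined NOE/MT line
upfield of water. NOE and MT are deliberately a single broad component:
fitting them separately destabilises the model at typical sampling and
noise, while their combined area is robust. The parameterisation is
phenomenological; amplitudes are specific to the saturation power
(B1,rms = 3 µT in the emulated protocol), and no attempt is made to
separate exchange rate from pool size (that requires a full
Bloch–McConnell analysis, which this package uses only as a simulation
oracle). The closed-form line integral (π/2)·A·w serves as the per-pool
"peak area" summary.

**Priors and bounds** (per-pixel MAP estimation):

| parameter | prior / bounds | default rationale |
|---|---|---|
| fine-peak centers (OH, NH₂, NH) | Gaussian, mean at nominal, sd 0.2 ppm; box ±0.5 ppm | keeps peaks identifiable, matches observed ≤0.1 ppm field drift |
| water center | fixed at 0 | degenerate with δ otherwise |
| NOE/MT center | uniform in [−5, −1] ppm | broad composite line |
| amplitudes | [0, 1] | fractions of the normalised signal |
| FWHM | box: fine peaks [0.2, 3], water [0.5, 6], NOE/MT [2, 12] ppm; log-normal prior, median at nominal width, log-sd 0.5 | see below |
| B0 shift δ | uniform in [−0.3, 0.3] ppm | generous vs the 0.1 ppm drift bound |

The log-normal width priors are a deliberate addition beyond plain box
bounds. At 1% Rician noise the per-pixel amplitude–width trade-off is
nearly unidentified (width posterior sd ≈ 0.6 ppm), and because area =
(π/2)·A·w is a *product*, the correlated errors biased amide/amine area
estimates by 8–9% even though A and w were individually near-unbiased.
The weak width prior regularises the trade-off and brings the area bias
under 3% without affecting noiseless recovery (see reweighting below).

**Estimation.** Bounded nonlinear least squares (trust-region reflective,
analytic Jacobian) on the stacked residual: data misfit scaled by an
assumed noise level, Gaussian center-prior terms, the width-prior terms,
and a hinge penalty that activates when the amine–amide center gap drops
below 0.5 ppm (such pixels are additionally flagged `coalesced`). The
first start is data-informed (water amplitude from the on-resonance dip);
up to four deterministic jittered restarts run only if the fit fails or
the residual is implausible. After convergence the assumed noise scale is
replaced by the empirical residual RMS and the fit repeated until the two
agree (at most 3 rounds, scale clipped to [1e−5, 0.05]). This empirical
reweighting makes high-SNR spectra converge to the likelihood optimum —
noiseless round trips recover all parameters to <1e−3 — while noisy
spectra retain the stabilising priors. Standard errors come from the
Gauss–Newton covariance at the optimum; full posterior sampling (emcee)
is available behind `sample_posterior` for uncertainty maps but is not
the default path. Non-converged pixels are NaN in the exported maps and
counted in the run log; ROI medians ignore NaN.

**Water handling.** The water peak is always fitted, never excised;
removal of the water line in published Z-spectrum figures is cosmetic.
Note the hydroxyl pool (+1.2 ppm) sits on the water shoulder; its
estimates are intrinsically less reliable than amide/amine, and the
round-trip tests quantify this only under the model's own assumptions.

## Relaxometry

ADC: per-pixel fit of S(b) = S0·e^(−b·ADC) with ADC ≥ 0, seeded by
log-linear regression; default b-values 150–1070 s/mm² (6 evenly spaced —
the exact ladder is configurable). T2: S(TE) = S0·e^(−TE/T2), T2 > 0.
T1: three-parameter magnitude fit S(TI) = |A − B·e^(−TI/T1*)| with
polarity restoration (every plausible sign flip around the signal minimum
is fitted; lowest residual wins), then the Look-Locker correction
T1 = T1*·(B/A − 1); pixels with B/A ≤ 1 are uncorrectable and become NaN.
All three agree with log-linear/closed-form oracles to 1e−6 on noiseless
data; mean ADC bias at 1% Rician noise is <2% over ≥500 pixels.

## Dose response

Viability (% of control) versus concentration is fitted with the biphasic
modified Hill form V(C) = V0 + Smax·C^hs/(EC50^hs + C^hs) −
Imax·C^hi/(IC50^hi + C^hi), on log10 concentration, with three structural
constraints motivated by what the quantities mean:

* V0 ∈ [99, 101]% — viability is normalised to control, so the no-drug
  baseline is 100 by construction (widen `v0_bounds` for other data);
* Imax = fraction × (V0 + Smax), fraction ∈ [0, 1] — viability cannot go
  negative at saturating dose;
* IC50 = EC50 × 10^gap, gap ≥ 0 — hormesis means stimulation precedes
  inhibition.

Without these, roughly a third of noisy fits fall into a degenerate mode
in which enormous, mutually cancelling stimulation and inhibition terms
overfit plate noise (Smax at its bound, EC50 ≈ IC50), corrupting IC50 by
up to 140%. Slopes are bounded (0.3, 6); Smax at 60% (hormetic stimulation
beyond ~50% of control is not biologically plausible). A 3×3 grid of
(EC50, gap) starts plus four monophasic starts makes the search
effectively global — multistart solutions match truth-started refits. An
AICc comparison between the best biphasic and monophasic fits is reported
(`biphasic_supported`), never silently applied; on exact ties the simpler
monophasic solution is returned so flat plates yield Smax ≈ Imax ≈ 0.

Identifiability caveat: when EC50 and IC50 lie within one dilution step of
each other (the sensitive line's 48-h condition), the per-plate maximum
likelihood IC50 has ~20% spread at 5% noise with 12 replicates, with a
left-skewed distribution. Replicate determinations should be summarised by
the geometric mean, the standard convention for potency estimates; the
acceptance script does exactly that over 41 simulated plates.

Receptor occupancy is the single-site law: unbound % = 100·Ki/(Ki + C),
with Ki = 0.93 nM for the emulated inhibitor.

## Cohort statistics

Parametric maps are reduced to ROI medians (robust to fitting outliers),
converted to percent change from the pre-dose baseline, and analysed with:
a two-way (dose × timepoint) ANOVA (statsmodels, type-II); between-group
contrasts (each treated dose vs vehicle at matched timepoints, Welch
t-test); within-group contrasts (each post-dose timepoint vs baseline,
paired t-test); and Spearman's rho between dose and group-mean parameter
change (average ranks for ties; exact permutation p for n ≤ 9, else the
t-approximation). Group means are used for the dose correlation because
four dose levels are the natural unit of a dose-escalation design. No
multiple-testing correction is applied — contrasts are reported with raw
p-values and the nominal α = 0.05 is a reporting threshold, never a data
filter. Tumor volume uses the caliper formula V = w²l/2 (warns, but
proceeds, if width exceeds length).

## Synthetic data: what it emulates, what it does not

The generator reproduces the *acquisition geometry and effect structure*
of a two-line colorectal xenograft dose-response study: Z-spectra sampled
−6..6 ppm at 0.12 ppm (101 offsets) with the reference at 8000 ppm at
B1,rms 3 µT; b-values 150–1070 s/mm²; a 2-fold MTT dilution ladder
1.6–400 nM (9 points, 12 replicates); dose groups vehicle/8/9.5/11 mg/kg
with timepoints 0/24/72 h (a 48-h MRI session is sometimes named in such
protocols; the cohort reports effects at 24/72 h, which the simulator
follows, with timepoints configurable).

Phantoms are centred ellipses (~30% grid coverage) with smooth low-order
ramps on all truth maps (±15% on amplitudes, ±10% on ADC/T1/T2, a
±0.08 ppm B0 tilt) and defaults: water A=0.8/w=2.0, hydroxyl 0.03/1.0,
amine 0.04/1.2, amide 0.05/1.0, NOE/MT 0.10/5.0 at −3.0 ppm;
ADC 1.0e−3 mm²/s, T1 1800 ms, T2 40 ms — typical values for subcutaneous
colorectal xenografts at high field. Noise is Rician (magnitude MRI),
scale expressed as a fraction of the per-pixel reference signal, default
1% — the plausible high-SNR preclinical regime. Treatment effects are
multiplicative: amide/amine multipliers 1 + slope·dose at 72 h (slope
0.04/0.035 per mg/kg for the sensitive line, ~0.004 for the resistant
line; half strength at 24 h), an explicit per-dose ADC ratio table whose
72-h sensitive-line entries (1.08/1.415/1.221) mirror reported
treated-to-baseline ADC changes, and volume growth inhibited at the two
highest doses but mildly stimulated at 8 mg/kg (hormesis). MTT viability
is simulated directly as truth curve + Gaussian noise (% viability);
absorbance itself is not modelled because analysis reduces it to % of
control immediately.

A continuous-wave steady-state two-pool Bloch–McConnell solver provides a
*physics-based* cross-check: spectra it generates are not Lorentzian sums,
and the five-pool fit must still localise the exchange peak within
0.3 ppm of the simulated pool offset for slow–intermediate exchange.

What passing tests therefore show: the estimation chain inverts its own
forward models accurately, is calibrated under the stated noise model,
and localises peaks on physically generated two-pool spectra. What they
do not show: performance on real tumors — no spatial noise correlation,
no motion, no B1 inhomogeneity, no multi-compartment diffusion, no
partial-volume effects, and effect sizes are inputs, not discoveries.
In-vivo effect sizes from animal studies are used only as simulation
inputs, never as claims the package reproduces from data.

## Problem sizes and determinism

Default demo/experiment sizes were chosen so that every simulation is a
desk-scale computation: 16×16 grids (≈68 tumor pixels) for pipeline-level
cohort runs (20 subjects × 2 timepoints completes in ~2 minutes on one
CPU), 48×48 for single-map noise-calibration runs, 41 plates for IC50
summaries, and 200 record-level replicates for type-I-error calibration.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config + seed reproduces
bit-identical outputs, and per-subject seeds are derived deterministically
from the base seed.

## Known limitations

* MTRasym-style asymmetry analysis is intentionally out of scope.
* Exchange-rate/pH separation requires the full quantitative exchange
  model; the two-pool solver here is a simulation oracle, not a fitter.
* Hydroxyl-peak quantities inherit water-coalescence uncertainty.
* The per-pixel fit is deterministic MAP; posterior sampling is available
  but slow and intended for spot checks, not whole-image maps.
* Single slice, square grids, no DICOM/vendor-raw ingestion.
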