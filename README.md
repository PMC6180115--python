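# cestpipe

Quantitative-MRI analysis of tumor response to proteasome inhibition:
multi-pool Lorentzian decomposition of CEST Z-spectra, ADC/T1/T2
relaxometry, biphasic (hormetic) dose-response fitting, and cohort-level
biomarker statistics — with a synthetic-phantom module so that every stage
is testable by parameter recovery.

## Who this is for

Preclinical imaging groups evaluating drug response in xenograft models
with chemical exchange saturation transfer (CEST) MRI. Proteasome
inhibitors disrupt protein homeostasis; the resulting accumulation of
mobile proteins and peptides raises the amide (+3.5 ppm) and amine
(+2.4 ppm) exchange signals in the Z-spectrum, making CEST a candidate
noninvasive biomarker of response, alongside the apparent diffusion
coefficient (ADC), T1 and T2.

## The model

A Z-spectrum is the normalised water signal versus saturation offset,
Z(f) = S(f)/S0. It is decomposed into five Lorentzian absorption lines —
water (0 ppm), hydroxyl (+1.2), amine (+2.4), amide (+3.5) and one
combined NOE/MT line upfield of water — plus a global B0 shift δ:

    Z(f) = 1 − Σᵢ Aᵢ / (1 + ((f − δ − cᵢ) / (wᵢ/2))²)

Per pixel, all amplitudes Aᵢ, widths wᵢ (FWHM), fine-peak centers cᵢ and δ
are estimated by maximum a posteriori (bounded nonlinear least squares with
Gaussian center priors), and each pool is summarised by its peak area
(π/2)·Aᵢ·wᵢ. Companion biomarkers use the standard forms: monoexponential
diffusion decay S(b) = S0·e^(−b·ADC), Look-Locker inversion recovery with
correction T1 = T1*·(B/A − 1), and multi-echo decay S(TE) = S0·e^(−TE/T2).
In-vitro viability is fitted with a biphasic modified Hill equation

    V(C) = V0 + Smax·C^hs/(EC50^hs + C^hs) − Imax·C^hi/(IC50^hi + C^hi)

yielding the half-maximal stimulatory (EC50) and inhibitory (IC50)
concentrations, and receptor occupancy follows the single-site law
(unbound fraction = Ki/(Ki + C)).

## Worked example

```python
from cestpipe import (AcquisitionConfig, fit_image, make_phantom,
                      simulate_cest_series, roi_median)

cfg = AcquisitionConfig(grid_size=16, noise_sigma=0.01, seed=1)
truth = make_phantom(cfg)                    # elliptical digital tumor
grid = simulate_cest_series(truth, cfg)      # 101 offsets, −6..6 ppm + S0
maps = fit_image(grid, n_starts=1, seed=1)   # per-pixel five-pool MAP fit
print(f"amide center : {roi_median(maps['amide_center']):.3f} ppm")
print(f"amide area   : {roi_median(maps['amide_area']):.4f}")
print(f"B0 shift     : {roi_median(maps['b0_shift']):.4f} ppm")
```

prints

```
amide center : 3.505 ppm
amide area   : 0.0748
B0 shift     : -0.0076 ppm
```

i.e. at 1% Rician noise the fit localises the amide pool at its true
position (3.5 ppm, recovered within 0.005 ppm), estimates the ROI-median
amide area within ~5% of the generating truth (π/2·0.05·1.0 ≈ 0.0785), and
returns a B0-shift median consistent with the ±0.08 ppm field tilt built
into the phantom (whose median is 0).

The same round-trip logic runs end to end from the command line:

```sh
cestpipe run-demo --seed 1 --out demo/       # cohort → fit → stats report
cestpipe simulate-phantom --seed 1 --out sim/
cestpipe fit-cest --input sim/cest.nii.gz --seed 1 --out maps/
```

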