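"""Biphasic Hill model, MTT plate simulation, fitting and occupancy analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cestpipe.dose_response import (
    DEFAULT_CONCENTRATIONS,
    HillParameters,
    fit_hill,
    hill_model,
    simulate_mtt_plate,
    unbound_fraction,
    viability_from_absorbance,
)

BIPHASIC = HillParameters(v0=100, smax=30, ec50=3, hs=1.5, imax=90, ic50=12.6, hi=1.5)


class TestHillModel:
    def test_no_drug_limit_is_baseline(self):
        assert hill_model(0.0, BIPHASIC) == pytest.approx(100.0)

    def test_half_inhibition_without_stimulation(self):
        p = HillParameters(v0=100, smax=0, ec50=3, hs=1, imax=60, ic50=20, hi=2)
        assert hill_model(20.0, p) == pytest.approx(100 - 30)

    def test_hormetic_shape(self):
        c = np.logspace(-1, 3, 200)
        v = hill_model(c, BIPHASIC)
        assert v.max() > 100.0          # stimulation above baseline at low dose
        assert v[-1] < 50.0             # inhibition below half at high dose
        assert c[np.argmax(v)] < 20.0

    @settings(max_examples=40, derandomize=True)
    @given(c1=st.floats(0.01, 500), c2=st.floats(0.01, 500))
    def test_monotone_without_stimulation(self, c1, c2):
        p = HillParameters(v0=100, smax=0, ec50=3, hs=1, imax=80, ic50=15, hi=1.2)
        lo, hi = sorted((c1, c2))
        assert hill_model(lo, p) >= hill_model(hi, p) - 1e-9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HillParameters(ic50=-1.0)
        with pytest.raises(ValueError):
            HillParameters(v0=100, smax=0, imax=150)


class TestUnboundFraction:
    def test_limits_and_half_occupancy(self):
        assert unbound_fraction(0.0, 0.93) == pytest.approx(100.0)
        assert unbound_fraction(0.93, 0.93) == pytest.approx(50.0)
        assert unbound_fraction(400.0, 0.93) < 0.25

    @settings(max_examples=40, derandomize=True)
    @given(c=st.floats(0, 1e4), ki=st.floats(1e-3, 1e3))
    def test_unbound_plus_occupied_is_total(self, c, ki):
        unbound = unbound_fraction(c, ki)
        occupied = 100.0 * c / (ki + c)
        assert unbound + occupied == pytest.approx(100.0, abs=1e-9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            unbound_fraction(-1.0, 0.93)


class TestViabilityFromAbsorbance:
    def test_control_ratio(self):
        table = pd.DataFrame({
            "concentration_nM": [np.nan, np.nan, 10.0],
            "replicate": [0, 1, 0],
            "absorbance": [0.8, 1.2, 0.5],
            "is_control": [True, True, False],
        })
        data = viability_from_absorbance(table)
        assert data.table["viability_pct"].iloc[0] == pytest.approx(50.0)

    def test_zero_control_aborts(self):
        table = pd.DataFrame({
            "concentration_nM": [np.nan, 10.0],
            "replicate": [0, 0],
            "absorbance": [0.0, 0.5],
            "is_control": [True, False],
        })
        with pytest.raises(ValueError, match="control"):
            viability_from_absorbance(table)


class TestSimulatePlate:
    def test_default_ladder_is_two_fold_nine_points(self):
        conc = np.asarray(DEFAULT_CONCENTRATIONS)
        assert conc.size == 9
        assert conc.max() == pytest.approx(400.0)
        assert conc.min() == pytest.approx(1.5625)
        assert np.allclose(conc[1:] / conc[:-1], 2.0)

    def test_noiseless_low_dose_approaches_baseline(self):
        plate = simulate_mtt_plate(BIPHASIC, concentrations=[1e-4, 1.0, 10.0, 100.0],
                                   replicates=1, noise_sigma=0.0)
        low = plate.table.sort_values("concentration_nM")["viability_pct"].iloc[0]
        assert low == pytest.approx(100.0, abs=0.5)

    def test_stimulation_pushes_curve_above_baseline(self):
        plate = simulate_mtt_plate(BIPHASIC, replicates=1, noise_sigma=0.0)
        assert plate.table["viability_pct"].max() > 100.0

    def test_seeded_replicates_are_reproducible(self):
        a = simulate_mtt_plate(BIPHASIC, replicates=12, noise_sigma=5.0, seed=4)
        b = simulate_mtt_plate(BIPHASIC, replicates=12, noise_sigma=5.0, seed=4)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError):
            simulate_mtt_plate(BIPHASIC, concentrations=[], replicates=1)


class TestFitHill:
    def test_noiseless_round_trip_within_one_percent(self):
        plate = simulate_mtt_plate(BIPHASIC, replicates=1, noise_sigma=0.0)
        fit = fit_hill(plate)
        assert fit.converged and fit.biphasic_supported
        p = fit.params
        for got, want in [(p.smax, 30), (p.ec50, 3), (p.hs, 1.5),
                          (p.imax, 90), (p.ic50, 12.6), (p.hi, 1.5)]:
            assert got == pytest.approx(want, rel=1e-2)

    def test_flat_plate_gives_null_magnitudes(self):
        plate = simulate_mtt_plate(HillParameters(), replicates=3, noise_sigma=0.0)
        fit = fit_hill(plate)
        assert fit.params.smax == pytest.approx(0.0, abs=0.1)
        assert fit.params.imax == pytest.approx(0.0, abs=0.1)
        assert not fit.biphasic_supported

    def test_noisy_ic50_median_error_below_fifteen_percent(self):
        """Across random biphasic truths at 5% noise / 12 replicates the
        median relative IC50 error stays below 15%."""
        rng = np.random.default_rng(123)
        errs = []
        for i in range(15):
            truth = HillParameters(
                v0=100.0, smax=rng.uniform(10, 40), ec50=rng.uniform(1.0, 5.0),
                hs=rng.uniform(1.0, 2.5), imax=rng.uniform(60, 95),
                ic50=10 ** rng.uniform(np.log10(5), np.log10(100)),
                hi=rng.uniform(1.0, 2.5))
            plate = simulate_mtt_plate(truth, replicates=12, noise_sigma=5.0,
                                       seed=900 + i)
            errs.append(abs(fit_hill(plate).params.ic50 - truth.ic50) / truth.ic50)
        assert np.median(errs) < 0.15

    def test_noiseless_random_truths_recover_both_potencies(self):
        """EC50 and IC50 of random biphasic truths are recovered within 1%
        from noiseless plates."""
        rng = np.random.default_rng(77)
        for i in range(10):
            truth = HillParameters(
                v0=100.0, smax=rng.uniform(15, 40), ec50=rng.uniform(1.5, 5.0),
                hs=rng.uniform(1.0, 2.0), imax=rng.uniform(60, 95),
                ic50=10 ** rng.uniform(np.log10(8), np.log10(90)),
                hi=rng.uniform(1.0, 2.0))
            plate = simulate_mtt_plate(truth, replicates=1, noise_sigma=0.0)
            p = fit_hill(plate).params
            assert p.ec50 == pytest.approx(truth.ec50, rel=1e-2)
            assert p.ic50 == pytest.approx(truth.ic50, rel=1e-2)

    def test_too_few_concentrations_rejected(self):
        plate = simulate_mtt_plate(BIPHASIC, concentrations=[1.0, 10.0, 100.0],
                                   replicates=2, noise_sigma=0.0)
        with pytest.raises(ValueError, match="concentrations"):
            fit_hill(plate)
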