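"""Tissue/component dielectric models: limits, passivity, derivatives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tmmkit import (
    ColeColeModel,
    DebyeModel,
    DielectricSpectrum,
    FrequencyGrid,
    SalineModel,
    TissueBlend,
    ValidationError,
    blend_tissues,
    list_tissues,
    load_tissue,
    load_tx100,
)
from tmmkit.tissue_dielectrics import EPS0

from conftest import ALL_TISSUES

GHZ = 1e9


class TestColeCole:
    def test_static_limit_single_pole(self):
        """Debye special case: at f -> 0, eps' -> eps_inf + delta_eps, loss -> 0."""
        m = ColeColeModel(eps_inf=4.0, poles=((30.0, 1e-11, 0.0),), sigma_static=0.0)
        e = m.eval(np.array([1.0]))[0]  # 1 Hz
        assert e.real == pytest.approx(34.0, abs=1e-6)
        assert -e.imag == pytest.approx(0.0, abs=1e-6)

    def test_conductivity_pass_through(self):
        """With no poles, sigma_eff equals sigma_static exactly at any f."""
        m = ColeColeModel(eps_inf=12.0, poles=(), sigma_static=0.2)
        spec = m.evaluate(FrequencyGrid.single(GHZ))
        assert spec.sigma_eff[0] == pytest.approx(0.2, rel=1e-12)
        assert spec.eps_real[0] == pytest.approx(12.0)

    def test_alpha_zero_equals_debye_sum(self, rng):
        """Cole-Cole with all alpha=0 is an exact sum of Debye relaxations."""
        f = np.geomspace(1e8, 1e10, 31)
        for _ in range(10):
            n_poles = rng.integers(1, 4)
            poles = [
                (float(rng.uniform(1, 100)), float(10 ** rng.uniform(-12, -8)), 0.0)
                for _ in range(n_poles)
            ]
            sigma = float(rng.uniform(0, 2))
            cc = ColeColeModel(eps_inf=4.0, poles=tuple(poles), sigma_static=sigma)
            w = 2 * np.pi * f
            expected = 4.0 + sigma / (1j * w * EPS0)
            for d, tau, _ in poles:
                expected = expected + d / (1.0 + 1j * w * tau)
            np.testing.assert_allclose(cc.eval(f), expected, rtol=1e-13)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(eps_inf=0.5, poles=(), sigma_static=0.0), "eps_inf"),
            (dict(eps_inf=4.0, poles=((-1.0, 1e-11, 0.0),), sigma_static=0.0), "delta_eps"),
            (dict(eps_inf=4.0, poles=((1.0, 0.0, 0.0),), sigma_static=0.0), "tau"),
            (dict(eps_inf=4.0, poles=((1.0, 1e-11, 1.0),), sigma_static=0.0), "alpha"),
            (dict(eps_inf=4.0, poles=(), sigma_static=-0.1), "sigma_static"),
        ],
    )
    def test_validation_names_field(self, kwargs, msg):
        with pytest.raises(ValidationError, match=msg):
            ColeColeModel(**kwargs)


class TestDebye:
    def test_static_limit(self):
        m = DebyeModel(eps_static=7.4, eps_inf=2.4, tau=2e-10)
        assert m.eval(np.array([1.0]))[0].real == pytest.approx(7.4, abs=1e-9)

    def test_loss_peak_at_inverse_tau(self):
        """At f = 1/(2 pi tau) the relaxation loss is (eps_s - eps_inf)/2."""
        tau = 2e-10
        m = DebyeModel(eps_static=7.4, eps_inf=2.4, tau=tau)
        f_peak = 1.0 / (2 * np.pi * tau)
        e = m.eval(np.array([f_peak]))[0]
        assert -e.imag == pytest.approx((7.4 - 2.4) / 2, rel=1e-12)

    def test_degenerate_pole_constant_spectrum(self):
        m = DebyeModel(eps_static=5.0, eps_inf=5.0, tau=1e-10, sigma_static=0.1)
        spec = m.evaluate(FrequencyGrid(0.5e9, 3e9, 11))
        np.testing.assert_allclose(spec.eps_real, 5.0, rtol=1e-14)
        np.testing.assert_allclose(spec.sigma_eff, 0.1, rtol=1e-12)

    def test_validation(self):
        with pytest.raises(ValidationError, match="eps_static"):
            DebyeModel(eps_static=2.0, eps_inf=3.0, tau=1e-10)


class TestSaline:
    def test_pure_water_25C_1GHz(self):
        """S=0 reduces to pure water: eps' in the 77-80 range at 25 C.

        Frozen regression anchor: the implemented parametric model gives
        78.158 (value computed from this model and frozen).
        """
        spec = SalineModel(0.0, 25.0).evaluate(FrequencyGrid.single(GHZ))
        assert 77.0 <= spec.eps_real[0] <= 80.0
        assert spec.eps_real[0] == pytest.approx(78.158, abs=1e-2)

    def test_conductivity_increases_with_salinity(self):
        sigmas = [
            SalineModel(s, 25.0).evaluate(FrequencyGrid.single(GHZ)).sigma_eff[0]
            for s in np.linspace(0.0, 20.0, 21)
        ]
        assert np.all(np.diff(sigmas) > 0)

    @pytest.mark.parametrize("s", [0.5, 2.0, 8.0, 13.9, 25.0, 60.0])
    def test_salinity_derivative_matches_central_difference(self, s):
        f = FrequencyGrid().frequencies
        d = SalineModel(s, 25.0).eval_salinity_derivative(f)
        h = s * 1e-4
        fd = (SalineModel(s + h, 25.0).eval(f) - SalineModel(s - h, 25.0).eval(f)) / (2 * h)
        np.testing.assert_allclose(d, fd, rtol=1e-6)

    def test_derivative_imag_nonzero_for_salted_water(self):
        d = SalineModel(10.0, 25.0).eval_salinity_derivative(np.array([GHZ]))[0]
        assert abs(d.imag) > 0.1  # ionic conductivity depends on S

    def test_derivative_continuity_in_salinity(self):
        """No jumps: derivative at nearby S values varies smoothly."""
        f = np.array([GHZ])
        svals = np.linspace(1.0, 30.0, 60)
        d = np.array([SalineModel(s, 25.0).eval_salinity_derivative(f)[0] for s in svals])
        steps = np.abs(np.diff(d))
        assert steps.max() < 0.05 * np.abs(d).max()

    @pytest.mark.parametrize("kwargs", [dict(nacl_concentration=-1.0),
                                        dict(nacl_concentration=500.0),
                                        dict(temperature=-10.0),
                                        dict(temperature=80.0)])
    def test_out_of_window_errors_state_window(self, kwargs):
        with pytest.raises(ValidationError, match="window"):
            SalineModel(**{"nacl_concentration": 10.0, "temperature": 25.0, **kwargs})


class TestBlend:
    def test_degenerate_blend_is_first_model(self):
        white = load_tissue("brain_white_matter")
        grey = load_tissue("brain_grey_matter")
        b = blend_tissues([white, grey], [1.0, 0.0])
        f = FrequencyGrid().frequencies
        np.testing.assert_allclose(b.eval(f), white.eval(f), rtol=1e-14)

    def test_blend_of_equal_models_is_that_model(self):
        m = load_tissue("muscle")
        b = blend_tissues([m, m], [0.5, 0.5])
        f = FrequencyGrid().frequencies
        np.testing.assert_allclose(b.eval(f), m.eval(f), rtol=1e-14)

    def test_brain_blend_matches_printed_reference(self):
        """75% white / 25% grey gives eps' ~ 42 at 1 GHz (recipe table)."""
        brain = load_tissue("brain")
        assert isinstance(brain, TissueBlend)
        e = brain.eval(np.array([GHZ]))[0]
        assert e.real == pytest.approx(42.0, abs=2.0)

    def test_bad_weight_sum_rejected(self):
        models = [load_tissue("csf"), load_tissue("blood")]
        with pytest.raises(ValidationError, match="sum to 1"):
            blend_tissues(models, [0.6, 0.5])


class TestFixtureProperties:
    @pytest.mark.parametrize("name", ALL_TISSUES)
    def test_passivity_100MHz_to_10GHz(self, name):
        """Every vendored tissue has loss >= 0 across the wide band."""
        spec = load_tissue(name).evaluate(FrequencyGrid(1e8, 1e10, 101))
        assert np.all(spec.eps_imag >= 0)
        assert np.all(spec.eps_real >= 1)

    @pytest.mark.parametrize("name", ALL_TISSUES)
    def test_sigma_eff_nondecreasing_on_design_band(self, name):
        spec = load_tissue(name).evaluate(FrequencyGrid(0.5e9, 3e9, 51))
        assert np.all(np.diff(spec.sigma_eff) >= 0)

    def test_tx100_fixture_loads(self):
        tx = load_tx100()
        spec = tx.evaluate(FrequencyGrid.single(GHZ))
        assert 2.0 < spec.eps_real[0] < 8.0
        assert spec.eps_imag[0] >= 0

    def test_library_lists_ten_tissues(self):
        assert set(ALL_TISSUES) <= set(list_tissues())

    def test_unknown_tissue_lists_library(self):
        with pytest.raises(KeyError, match="csf"):
            load_tissue("unobtainium")


class TestSpectrumContainer:
    def test_sigma_view_consistent(self):
        spec = SalineModel(10.0, 25.0).evaluate(FrequencyGrid())
        manual = 2 * np.pi * spec.frequencies * EPS0 * spec.eps_imag
        np.testing.assert_allclose(spec.sigma_eff, manual, rtol=1e-14)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        spec = load_tissue("csf").evaluate(FrequencyGrid(n_points=5))
        path = tmp_path / "spec.csv"
        spec.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "frequency_Hz", "eps_real", "eps_imag", "sigma_S_per_m"
        ]
        np.testing.assert_allclose(df["eps_real"], spec.eps_real, rtol=1e-6)

    def test_decreasing_frequencies_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            DielectricSpectrum(np.array([2e9, 1e9]), np.array([10 + 0j, 10 + 0j]))

    @given(st.floats(0.6e9, 2.9e9))
    def test_grid_single_contains_frequency(self, f):
        g = FrequencyGrid.single(f)
        assert g.frequencies[0] == pytest.approx(f)
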