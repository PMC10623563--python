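"""Calibration, loading quantification, Laurdan GP and CMC breakpoint."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luvkit.fluorometry import (
    LaurdanSpectrum,
    PrepSpec,
    absorbance_to_conc,
    cmc_breakpoint,
    degree_of_labeling,
    fit_calibration,
    laurdan_gp,
    loading_percentages,
    quantify_loaded,
)
from luvkit.synth import NoiseModel, gen_calibration, gen_cmc, gen_laurdan


class TestCalibration:
    def test_exact_line(self):
        c = np.array([0.0, 1.0, 2.0, 3.0])
        cal = fit_calibration(c, 2.0 * c + 1.0)
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(1.0)
        assert cal.r_squared == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        c = np.linspace(0, 50e-9, 8)
        y = 3e9 * c + 0.2 + rng.normal(0, 0.05, 8)
        perm = rng.permutation(8)
        a = fit_calibration(c, y)
        b = fit_calibration(c[perm], y[perm])
        assert a.slope == pytest.approx(b.slope)
        assert a.intercept == pytest.approx(b.intercept)

    def test_symmetric_noise_on_duplicated_points_keeps_slope(self):
        """+/-eps noise applied symmetrically to duplicated abscissas
        cancels in the OLS slope (analytic normal-equations property)."""
        c = np.repeat(np.linspace(1e-9, 40e-9, 5), 2)
        y0 = 2e9 * c + 0.1
        eps = 0.05
        y = y0 + np.tile([eps, -eps], 5)
        cal = fit_calibration(c, y)
        assert cal.slope == pytest.approx(2e9, rel=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_calibration(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_roundtrip_with_generator(self):
        c, y = gen_calibration(slope=3.3e9, intercept=0.7)
        cal = fit_calibration(c, y)
        assert cal.slope == pytest.approx(3.3e9)
        assert cal.intercept == pytest.approx(0.7)


class TestQuantifyLoaded:
    def setup_method(self):
        c, y = gen_calibration(slope=2e9, intercept=0.5)
        self.cal = fit_calibration(c, y)

    def test_blank_gives_zero(self):
        assert quantify_loaded(0.5, self.cal, DOL=2.0) == 0.0

    def test_unit_labeling_is_plain_inverse(self):
        i = 2e9 * 10e-9 + 0.5
        assert quantify_loaded(i, self.cal, DOL=1.0) == pytest.approx(10e-9)

    def test_forward_simulation_round_trip(self):
        c_true, dol = 7.5e-9, 3.2
        intensity = 2e9 * (c_true * dol) + 0.5  # dye conc = protein * DOL
        assert quantify_loaded(intensity, self.cal, DOL=dol) == pytest.approx(c_true)

    def test_negative_dye_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            quantify_loaded(0.1, self.cal, DOL=1.0)


class TestLoadingPercentages:
    reference_prep = PrepSpec(
        lipid_film_mass=3.0,
        hydration_volume=0.5,
        hydration_drug_conc=0.2,
        final_volume=5.0,
        final_lipid_conc=0.2,
        final_drug_conc=0.09e-3,
        drug_MW=23.6,
    )

    def test_reference_preparation_dl_le(self):
        rep = loading_percentages(self.reference_prep)
        assert rep.DL_percent == pytest.approx(0.045, abs=5e-4)
        assert rep.LE_percent == pytest.approx(0.45, abs=5e-3)

    def test_reference_preparation_molar(self):
        rep = loading_percentages(self.reference_prep)
        assert rep.loaded_conc_molar * 1e9 == pytest.approx(3.8, abs=0.05)

    def test_full_retention_gives_le_100(self):
        prep = PrepSpec(
            lipid_film_mass=3.0,
            hydration_volume=0.5,
            hydration_drug_conc=0.2,
            final_volume=5.0,
            final_lipid_conc=0.2,
            final_drug_conc=0.2 * 0.5 / 5.0,
        )
        assert loading_percentages(prep).LE_percent == pytest.approx(100.0)

    def test_unit_rescaling_identity(self):
        """Expressing masses in ug instead of mg (x1000 on both
        concentrations) leaves DL% and LE% unchanged."""
        p = self.reference_prep
        scaled = PrepSpec(
            lipid_film_mass=p.lipid_film_mass * 1e3,
            hydration_volume=p.hydration_volume,
            hydration_drug_conc=p.hydration_drug_conc * 1e3,
            final_volume=p.final_volume,
            final_lipid_conc=p.final_lipid_conc * 1e3,
            final_drug_conc=p.final_drug_conc * 1e3,
        )
        a, b = loading_percentages(p), loading_percentages(scaled)
        assert a.DL_percent == pytest.approx(b.DL_percent, rel=1e-12)
        assert a.LE_percent == pytest.approx(b.LE_percent, rel=1e-12)

    def test_mass_balance_violation_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            PrepSpec(
                lipid_film_mass=3.0,
                hydration_volume=0.5,
                hydration_drug_conc=0.2,
                final_volume=5.0,
                final_lipid_conc=0.2,
                final_drug_conc=0.05,  # 0.25 mg retained > 0.1 mg offered
            )


class TestLaurdanGP:
    def test_equal_edges_give_zero(self):
        spec = gen_laurdan(0.0)
        assert laurdan_gp(spec) == pytest.approx(0.0, abs=1e-12)

    def test_apolar_extreme(self):
        wl = np.arange(400.0, 551.0)
        inten = np.where(wl == 435.0, 1.0, 0.0)
        assert laurdan_gp(LaurdanSpectrum(wl, inten)) == 1.0

    def test_direct_arithmetic_anchor(self):
        """I435 = 0.634, I500 = 0.366 -> GP = 0.268 (the ordered-bilayer
        magnitude scale)."""
        wl = np.array([434.0, 435.0, 436.0, 499.0, 500.0, 501.0])
        inten = np.array([0.6, 0.634, 0.66, 0.37, 0.366, 0.36])
        assert laurdan_gp(LaurdanSpectrum(wl, inten)) == pytest.approx(0.268)

    def test_zero_spectrum_rejected(self):
        wl = np.array([435.0, 500.0])
        with pytest.raises(ValueError, match="undefined"):
            laurdan_gp(LaurdanSpectrum(wl, np.zeros(2)))

    def test_missing_wavelength_rejected(self):
        spec = LaurdanSpectrum(np.array([435.0, 480.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="cover"):
            laurdan_gp(spec)

    @given(st.floats(-0.95, 0.95))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_generator_round_trip_and_bounds(self, gp_target):
        spec = gen_laurdan(gp_target)
        gp = laurdan_gp(spec)
        assert gp == pytest.approx(gp_target, abs=1e-9)
        assert -1.0 <= gp <= 1.0


class TestCMC:
    def test_exact_breakpoint_recovered(self):
        c, y = gen_cmc(break_conc=0.215)
        res = cmc_breakpoint(c, y)
        assert res.detected
        assert res.cmc_mg_per_mL == pytest.approx(0.215, abs=1e-6)

    def test_molar_conversion(self):
        c, y = gen_cmc(break_conc=0.215)
        res = cmc_breakpoint(c, y, MW_kDa=23.6)
        assert res.cmc_molar * 1e6 == pytest.approx(9.1, abs=0.05)

    def test_straight_line_yields_no_cmc(self):
        c = np.linspace(0.0, 0.5, 12)
        res = cmc_breakpoint(c, 2.0 * c + 1.0)
        assert not res.detected
        assert res.cmc_mg_per_mL is None

    def test_noisy_breakpoint_close(self):
        c, y = gen_cmc(
            break_conc=0.215,
            noise=NoiseModel(kind="gaussian-absolute", scale=0.05, seed=2),
            concentrations=np.linspace(0.0, 0.5, 24),
        )
        res = cmc_breakpoint(c, y)
        assert res.detected
        assert res.cmc_mg_per_mL == pytest.approx(0.215, abs=0.03)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 6"):
            cmc_breakpoint(np.linspace(0, 1, 5), np.linspace(0, 1, 5))


class TestAbsorbanceAndDOL:
    @pytest.mark.parametrize(
        "A,expected", [(0.81, 1.0), (0.0, 0.0), (0.405, 0.5)]
    )
    def test_beer_lambert(self, A, expected):
        assert absorbance_to_conc(A, path_cm=1.0) == pytest.approx(expected)

    def test_degree_of_labeling_forward(self):
        # c_dye = 0.5/239000 M; c_prot = (0.3 - 0.03*0.5)/epsP
        eps_dye, eps_prot, cf = 239000.0, 26600.0, 0.03
        dol = degree_of_labeling(0.5, 0.3, eps_dye, eps_prot, correction_factor=cf)
        expected = (0.5 / eps_dye) / ((0.3 - cf * 0.5) / eps_prot)
        assert dol == pytest.approx(expected)

    def test_overcorrected_a280_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            degree_of_labeling(1.0, 0.1, 239000.0, 26600.0, correction_factor=0.5)
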