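"""Closed-form scattering amplitudes against independent quadrature
oracles, plus their structural invariants."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from luvkit import (
    GaussianShellProfile,
    HollowSphereModel,
    ScatteringCurve,
    gaussian_shell_amplitude,
    hollow_sphere_pq,
    saxs_intensity,
    shell_radius_of_gyration,
)
from luvkit.models import ClosedFormAccuracyWarning


def quadrature_amplitude(profile: GaussianShellProfile, q: float) -> float:
    """Independent oracle: adaptive radial integration of
    F(q) = (4 pi / q) Int rho(r) r sin(qr) dr over the physical domain."""
    lo = max(0.0, profile.R - 30.0)
    hi = profile.R + 30.0
    val, _ = quad(
        lambda r: profile.density(r) * r * np.sin(q * r), lo, hi, limit=400
    )
    return 4.0 * np.pi * val / q


def quadrature_shell_pq(model: HollowSphereModel, q: float) -> float:
    """Oracle: quadrature of the uniform-shell density, normalized."""
    amp, _ = quad(
        lambda r: r * np.sin(q * r), model.R_inner, model.R_outer, limit=400
    )
    amp *= 4.0 * np.pi / q
    amp0 = 4.0 / 3.0 * np.pi * (model.R_outer**3 - model.R_inner**3)
    return (amp / amp0) ** 2


class TestGaussianShellAmplitude:
    def test_zero_contrast_gives_zero_amplitude(self):
        profile = GaussianShellProfile(
            R=46.0, components=((0.0, 0.0, 1.0), (0.0, -2.0, 0.5), (0.0, 2.0, 0.5))
        )
        q = np.linspace(0.1, 5.0, 50)
        assert np.allclose(gaussian_shell_amplitude(profile, q), 0.0)

    @pytest.mark.parametrize("q_val", [0.1, 0.3, 1.0, 2.0, 5.0])
    def test_matches_quadrature_oracle(self, lip0_profile, q_val):
        closed = gaussian_shell_amplitude(lip0_profile, np.array([q_val]))[0]
        oracle = quadrature_amplitude(lip0_profile, q_val)
        assert abs(closed - oracle) < 1e-3 * max(abs(oracle), 1.0)

    def test_quadrature_agreement_across_full_window(self, lipcas_profile):
        q = np.logspace(np.log10(0.005), np.log10(5.0), 40)
        closed = gaussian_shell_amplitude(lipcas_profile, q)
        oracle = np.array([quadrature_amplitude(lipcas_profile, qi) for qi in q])
        scale = np.max(np.abs(oracle))
        assert np.all(np.abs(closed - oracle) < 1e-3 * scale)

    def test_linearity_in_contrast(self, lip0_profile):
        q = np.linspace(0.1, 5.0, 100)
        doubled = GaussianShellProfile(
            R=lip0_profile.R,
            components=tuple(
                (2 * rho, eps, sig) for rho, eps, sig in lip0_profile.components
            ),
        )
        assert np.allclose(
            gaussian_shell_amplitude(doubled, q),
            2.0 * gaussian_shell_amplitude(lip0_profile, q),
        )

    def test_rejects_nonpositive_q(self, lip0_profile):
        with pytest.raises(ValueError, match="positive"):
            gaussian_shell_amplitude(lip0_profile, np.array([0.0, 1.0]))

    def test_wide_component_warns(self):
        wide = GaussianShellProfile(R=10.0, components=((1.0, 0.0, 5.0),))
        with pytest.warns(ClosedFormAccuracyWarning):
            gaussian_shell_amplitude(wide, np.array([1.0]))


class TestSaxsIntensity:
    def test_scale_linearity(self, lip0_profile):
        q = np.linspace(0.1, 5.0, 200)
        s = 0.37
        assert np.allclose(
            saxs_intensity(lip0_profile, q, scale=2 * s),
            2.0 * saxs_intensity(lip0_profile, q, scale=s),
        )

    def test_nonnegative_everywhere(self, lipcas_profile):
        q = np.linspace(0.1, 5.0, 500)
        assert np.all(saxs_intensity(lipcas_profile, q) >= 0)

    def test_minima_coincide_with_amplitude_sign_changes(self, lip0_profile):
        """The nodes of I(q) sit where F(q) crosses zero (root-bracketing
        oracle on the amplitude)."""
        q = np.linspace(0.1, 5.0, 4000)
        I = saxs_intensity(lip0_profile, q)
        F = gaussian_shell_amplitude(lip0_profile, q)
        # interior local minima of I
        interior = np.flatnonzero((I[1:-1] < I[:-2]) & (I[1:-1] < I[2:])) + 1
        sign_changes = np.flatnonzero(np.sign(F[:-1]) * np.sign(F[1:]) < 0)
        roots = [
            brentq(
                lambda x: gaussian_shell_amplitude(lip0_profile, np.array([x]))[0],
                q[i],
                q[i + 1],
            )
            for i in sign_changes
        ]
        dq = q[1] - q[0]
        assert len(interior) == len(roots)
        for qi, root in zip(q[interior], roots):
            assert abs(qi - root) <= 2 * dq

    def test_rejects_bad_scale_and_low_q(self, lip0_profile):
        with pytest.raises(ValueError, match="scale"):
            saxs_intensity(lip0_profile, np.array([1.0]), scale=0.0)
        with pytest.raises(ValueError, match="0.1"):
            saxs_intensity(lip0_profile, np.array([0.05]))

    def test_independent_route_through_quadrature(self, lip0_profile):
        """|F|^2/q^2 computed from the quadrature amplitude agrees with
        the closed-form intensity to < 1% over the working window."""
        q = np.logspace(np.log10(0.1), np.log10(5.0), 30)
        I_closed = saxs_intensity(lip0_profile, q)
        I_oracle = np.array(
            [quadrature_amplitude(lip0_profile, qi) ** 2 / qi**2 for qi in q]
        )
        scale = np.max(I_oracle)
        assert np.all(np.abs(I_closed - I_oracle) <= 0.01 * scale)

    def test_thicker_bilayer_shifts_first_minimum_to_lower_q(self):
        """The first intensity node scales inversely with the bilayer
        thickness d (fixture grid of d values at fixed R)."""
        q = np.linspace(0.3, 5.0, 3000)
        first_minima = []
        for d in (3.0, 3.5, 3.9, 4.4, 5.0):
            prof = GaussianShellProfile(
                R=46.0,
                components=(
                    (1.0, 0.0, 1.0),
                    (-1.8, -d / 2, 0.45),
                    (-1.8, d / 2, 0.50),
                ),
            )
            I = saxs_intensity(prof, q)
            interior = np.flatnonzero((I[1:-1] < I[:-2]) & (I[1:-1] < I[2:])) + 1
            first_minima.append(q[interior[0]])
        assert all(a > b for a, b in zip(first_minima, first_minima[1:]))


class TestHollowSphere:
    def test_normalized_at_zero(self, lip0_shell, lipcas_shell):
        for model in (lip0_shell, lipcas_shell):
            assert hollow_sphere_pq(model, np.array([0.0]))[0] == pytest.approx(1.0)

    def test_matches_quadrature(self, lip0_shell):
        q = np.logspace(np.log10(0.002), np.log10(0.5), 30)
        closed = hollow_sphere_pq(lip0_shell, q)
        oracle = np.array([quadrature_shell_pq(lip0_shell, qi) for qi in q])
        assert np.allclose(closed, oracle, rtol=1e-6, atol=1e-12)

    def test_solid_sphere_limit_first_zero(self):
        """As t -> 2 R_mid the shell fills in; the first node of the
        solid-sphere amplitude sits at qR = 4.493 (tan x = x root)."""
        x_root = brentq(lambda x: np.tan(x) - x, np.pi + 0.01, 1.5 * np.pi)
        R_mid = 25.0
        model = HollowSphereModel(R_mid=R_mid, t=2 * R_mid - 1e-9)
        R_out = model.R_outer
        q = np.linspace(3.5 / R_out, 5.5 / R_out, 2000)
        P = hollow_sphere_pq(model, q)
        q_min = q[np.argmin(P)]
        assert q_min * R_out == pytest.approx(x_root, rel=1e-3)
        assert x_root == pytest.approx(4.493, abs=5e-4)

    def test_radius_of_gyration_closed_form_and_monte_carlo(self, lip0_shell):
        rg = shell_radius_of_gyration(lip0_shell)
        assert rg == pytest.approx(41.58, abs=0.01)
        # Monte-Carlo oracle: uniform points in the shell volume
        rng = np.random.default_rng(42)
        u = rng.uniform(lip0_shell.R_inner**3, lip0_shell.R_outer**3, 200_000)
        r = u ** (1.0 / 3.0)
        assert rg == pytest.approx(np.sqrt(np.mean(r**2)), rel=2e-3)

    def test_thin_shell_limit_is_mid_radius(self):
        model = HollowSphereModel(R_mid=41.5, t=1e-6)
        assert shell_radius_of_gyration(model) == pytest.approx(41.5, rel=1e-9)

    def test_rg_monotone_in_radius(self):
        rgs = [
            shell_radius_of_gyration(HollowSphereModel(R_mid=R, t=4.0))
            for R in np.linspace(10, 100, 12)
        ]
        assert all(a < b for a, b in zip(rgs, rgs[1:]))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            HollowSphereModel(R_mid=1.0, t=4.0)
        with pytest.raises(ValueError):
            HollowSphereModel(R_mid=40.0, t=0.0)


class TestScatteringCurve:
    def test_unit_conversion_on_ingestion(self):
        q_um = np.array([5.0, 10.0, 25.0])
        c = ScatteringCurve(q=q_um, I=np.ones(3), q_unit_in="um^-1")
        assert np.allclose(c.q, q_um * 1e-3)
        assert c.q_unit_in == "nm^-1"

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            ScatteringCurve(q=np.array([1.0, 1.0]), I=np.zeros(2))
        with pytest.raises(ValueError, match="finite"):
            ScatteringCurve(q=np.array([1.0, 2.0]), I=np.array([1.0, np.inf]))
        with pytest.raises(ValueError, match="sigma"):
            ScatteringCurve(
                q=np.array([1.0, 2.0]),
                I=np.ones(2),
                sigma=np.array([1.0, 0.0]),
            )
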