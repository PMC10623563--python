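"""Synthetic-data generators for every pipeline input.

Each generator is a deterministic function of (truth parameters, seed)
and closes an exact round trip with its estimator at zero noise, so the
whole pipeline is testable without instrument data.

Two canonical vesicle fixtures are provided, mirroring the best-fit
geometries of a 50 nm-extruded POPC:POPS:cholesterol preparation
without (``LIP0``) and with (``LIPCAS``) an amphiphilic protein cargo:
SAXS Gaussian-shell radii 46/52 nm with a 3.9 nm head-to-head bilayer,
MALS hollow-sphere radii 41.5/46.5 nm with the 4 nm shell.  The
reference geometry pins only R and d; the head/core contrasts and widths are set
at literature-typical PC-bilayer values (head sigma ~0.45-0.5 nm, core
sigma 1 nm, head contrast opposite-signed to the core at ~1.8x
magnitude under the rho_core = +1 normalization), with a slightly
stronger outer head for the protein-decorated fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .dls import CorrelationTrace, SizeDistribution, radius_to_gamma
from .fluorometry import LaurdanSpectrum
from .mals import RayleighCurve
from .models import (
    GaussianShellProfile,
    HollowSphereModel,
    ScatteringCurve,
    hollow_sphere_pq,
    saxs_intensity,
)

# -- canonical fixtures ------------------------------------------------

LIP0_SAXS = GaussianShellProfile(
    R=46.0,
    components=((1.0, 0.0, 1.0), (-1.8, -1.95, 0.45), (-1.8, 1.95, 0.50)),
)
LIPCAS_SAXS = GaussianShellProfile(
    R=52.0,
    components=((1.0, 0.0, 1.0), (-1.8, -1.95, 0.45), (-2.1, 1.95, 0.55)),
)
LIP0_MALS = HollowSphereModel(R_mid=41.5, t=4.0)
LIPCAS_MALS = HollowSphereModel(R_mid=46.5, t=4.0)

FIXTURES = {
    "lip0": {"saxs": LIP0_SAXS, "mals": LIP0_MALS},
    "lipcas": {"saxs": LIPCAS_SAXS, "mals": LIPCAS_MALS},
}


@dataclass(frozen=True)
class NoiseModel:
    """Seeded noise specification for the generators.

    kinds
    -----
    gaussian-relative : sigma_i = scale * |model_i|
    gaussian-absolute : sigma_i = scale
    poisson-like      : sigma_i = scale * sqrt(|model_i|) (Gaussian
                        approximation to counting noise)
    """

    kind: str = "gaussian-relative"
    scale: float = 0.0
    seed: int = 0

    _KINDS = ("gaussian-relative", "gaussian-absolute", "poisson-like")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be nonnegative")

    def sigma(self, model: NDArray[np.float64]) -> NDArray[np.float64]:
        if self.kind == "gaussian-relative":
            return self.scale * np.abs(model)
        if self.kind == "gaussian-absolute":
            return np.full_like(model, self.scale)
        return self.scale * np.sqrt(np.abs(model))

    def apply(
        self, model: NDArray[np.float64]
    ) -> tuple[NDArray[np.float64], NDArray[np.float64] | None]:
        """Return (noisy values, per-point sigma); sigma is None at
        zero noise so noiseless curves compare exactly."""
        if self.scale == 0:
            return model.copy(), None
        rng = np.random.default_rng(self.seed)
        s = self.sigma(model)
        return model + rng.normal(0.0, 1.0, model.shape) * s, s


NO_NOISE = NoiseModel(scale=0.0)


def default_saxs_grid(n: int = 300) -> NDArray[np.float64]:
    """Log-spaced q grid over the SAXS working window 0.1-5 nm^-1."""
    return np.logspace(np.log10(0.1), np.log10(5.0), n)


def default_mals_grid(n: int = 40) -> NDArray[np.float64]:
    """Log-spaced q grid over the MALS instrument range 5-25 um^-1."""
    return np.logspace(np.log10(5.0), np.log10(25.0), n)


def gen_saxs(
    profile: GaussianShellProfile,
    q_grid: ArrayLike | None = None,
    scale: float = 1.0,
    noise: NoiseModel = NO_NOISE,
) -> ScatteringCurve:
    """Synthetic background-subtracted SAXS curve from the
    Gaussian-shell model."""
    q = default_saxs_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    model = saxs_intensity(profile, q, scale=scale, allow_low_q=True)
    I, sigma = noise.apply(model)
    return ScatteringCurve(q=q, I=I, sigma=sigma, technique="SAXS")


def gen_mals(
    model: HollowSphereModel,
    q_grid: ArrayLike | None = None,
    amplitude: float = 1e-4,
    noise: NoiseModel = NO_NOISE,
) -> RayleighCurve:
    """Synthetic Rayleigh-ratio curve (q in um^-1) from the
    hollow-sphere model."""
    q_um = default_mals_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    curve = amplitude * hollow_sphere_pq(model, q_um * 1e-3)
    R_theta, sigma = noise.apply(curve)
    return RayleighCurve(q=q_um, R_theta=np.clip(R_theta, 0.0, None), sigma=sigma)


def gen_dls(
    dist: SizeDistribution,
    beta: float = 0.9,
    tau_grid: ArrayLike | None = None,
    noise: NoiseModel = NO_NOISE,
    q: float = 22.3,
    wavelength: float = 532.0,
    T: float = 293.15,
    eta: float = 1.002e-3,
) -> CorrelationTrace:
    """Synthetic intensity autocorrelation from an intensity-weighted
    size distribution: g1 = sum_i w_i exp(-Gamma(R_i) tau),
    g2 - 1 = beta g1^2 + noise."""
    if dist.basis != "intensity":
        raise ValueError("gen_dls expects an intensity-weighted distribution")
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    if tau_grid is None:
        tau_grid = np.logspace(-6, 0, 200)
    tau = np.asarray(tau_grid, dtype=float)
    meta = CorrelationTrace(
        tau=np.array([1e-6, 1.0]), g2m1=np.zeros(2), q=q,
        wavelength=wavelength, T=T, eta=eta,
    )
    gamma = radius_to_gamma(dist.radii, meta)
    g1 = np.exp(-np.outer(tau, gamma)) @ dist.weights
    g2m1, _ = noise.apply(beta * g1**2)
    return CorrelationTrace(
        tau=tau, g2m1=g2m1, q=q, wavelength=wavelength, T=T, eta=eta
    )


def lognormal_distribution(
    median: float = 45.0,
    sigma_log: float = 0.15,
    radius_grid: ArrayLike | None = None,
    basis: str = "intensity",
) -> SizeDistribution:
    """Log-normal radius distribution on a grid (default 100 log-spaced
    radii over 5-500 nm), the canonical model of an extruded vesicle
    population."""
    r = (
        np.logspace(np.log10(5.0), np.log10(500.0), 100)
        if radius_grid is None
        else np.asarray(radius_grid, dtype=float)
    )
    w = np.exp(-((np.log(r) - np.log(median)) ** 2) / (2 * sigma_log**2)) / r
    return SizeDistribution(radii=r, weights=w, basis=basis)


def gen_calibration(
    slope: float,
    intercept: float = 0.0,
    concentrations: ArrayLike | None = None,
    noise: NoiseModel = NO_NOISE,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Linear fluorophore calibration table (conc mol/L, intensity a.u.)."""
    c = (
        np.linspace(0.0, 50e-9, 8)
        if concentrations is None
        else np.asarray(concentrations, dtype=float)
    )
    y, _ = noise.apply(slope * c + intercept)
    return c, y


def gen_laurdan(
    gp: float,
    wavelengths: ArrayLike | None = None,
    width: float = 35.0,
    total_edge_intensity: float = 1.0,
    noise: NoiseModel = NO_NOISE,
) -> LaurdanSpectrum:
    """Two-band Laurdan emission spectrum with a prescribed generalized
    polarization.

    The spectrum is a sum of Gaussian bands centered on the blue
    (435 nm) and red (500 nm) edges; the band amplitudes are solved
    from the 2x2 linear system fixing I(435) and I(500) to the values
    implied by the target GP, so ``laurdan_gp`` recovers ``gp`` exactly
    at zero noise.
    """
    if not -1 < gp < 1:
        raise ValueError("target GP must lie strictly inside (-1, 1)")
    wl = (
        np.arange(400.0, 551.0)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    I435 = total_edge_intensity * (1.0 + gp) / 2.0
    I500 = total_edge_intensity * (1.0 - gp) / 2.0
    cross = np.exp(-((500.0 - 435.0) ** 2) / (2 * width**2))
    # [1, cross; cross, 1] [A_blue, A_red]^T = [I435, I500]^T
    det = 1.0 - cross**2
    A_blue = (I435 - cross * I500) / det
    A_red = (I500 - cross * I435) / det
    spec = A_blue * np.exp(-((wl - 435.0) ** 2) / (2 * width**2)) + A_red * np.exp(
        -((wl - 500.0) ** 2) / (2 * width**2)
    )
    noisy, _ = noise.apply(spec)
    return LaurdanSpectrum(wavelengths=wl, intensities=np.clip(noisy, 0.0, None))


def gen_cmc(
    break_conc: float = 0.215,
    slope_below: float = 1.0,
    slope_above: float = 20.0,
    intercept: float = 0.5,
    concentrations: ArrayLike | None = None,
    noise: NoiseModel = NO_NOISE,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Piecewise-linear ANS titration table (conc mg/mL, fluorescence).

    Below the break the probe reports monomers (shallow slope); above
    it micelles form and the apolar probe lights up (steep slope).
    """
    c = (
        np.linspace(0.0, 0.5, 12)
        if concentrations is None
        else np.asarray(concentrations, dtype=float)
    )
    y = intercept + slope_below * np.minimum(c - break_conc, 0.0) + slope_above * np.maximum(
        c - break_conc, 0.0
    )
    noisy, _ = noise.apply(y)
    return c, noisy
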