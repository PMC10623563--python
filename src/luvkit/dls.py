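"""Regularized inversion of DLS autocorrelation data.

The measured intensity autocorrelation g2(tau) - 1 is reduced to the
field correlation g1(tau) through the Siegert relation, then inverted
into a decay-rate spectrum by smoothing-constrained (Tikhonov,
second-difference) non-negative least squares:

    min_w  || K w - g1 ||^2 + lambda || L2 w ||^2,   w >= 0,
    K_ij = exp(-Gamma_j tau_i)

Decay rates map to hydrodynamic radii via Stokes-Einstein,
Gamma = D q^2, D = kB T / (6 pi eta R_h).  Intensity-weighted spectra
can be reweighted to mass or number distributions using the thin-shell
vesicle mass scaling m(R) ~ R^2 and the hollow-sphere form factor at
the measurement q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.constants import Boltzmann as KB
from scipy.optimize import nnls

from .models import HollowSphereModel, hollow_sphere_pq

VALID_BASES = ("intensity", "number", "mass")


@dataclass
class CorrelationTrace:
    """DLS intensity autocorrelation g2(tau)-1 plus instrument constants.

    Defaults: q = 22.3 um^-1 (90-degree geometry at 532 nm in water),
    T = 293.15 K, eta = 1.002 mPa s (water at 20 C).
    """

    tau: NDArray[np.float64]
    g2m1: NDArray[np.float64]
    q: float = 22.3  # um^-1
    wavelength: float = 532.0  # nm
    T: float = 293.15  # K
    eta: float = 1.002e-3  # Pa s

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2m1 = np.asarray(self.g2m1, dtype=float)
        if self.tau.shape != self.g2m1.shape:
            raise ValueError("tau and g2m1 must have the same shape")
        if not np.all(self.tau > 0) or not np.all(np.diff(self.tau) > 0):
            raise ValueError("lag times must be positive and strictly increasing")
        if self.q <= 0 or self.T <= 0 or self.eta <= 0:
            raise ValueError("instrument constants must be positive")

    @property
    def q_m(self) -> float:
        """Scattering vector in m^-1."""
        return self.q * 1e6


@dataclass
class SizeDistribution:
    """Radius grid (nm) + normalized nonnegative weights with an
    explicit weighting basis (intensity | number | mass)."""

    radii: NDArray[np.float64]
    weights: NDArray[np.float64]
    basis: str = "intensity"

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.radii.shape != self.weights.shape:
            raise ValueError("radii and weights must have the same shape")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.basis not in VALID_BASES:
            raise ValueError(f"basis must be one of {VALID_BASES}, got {self.basis!r}")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must not be all zero")
        self.weights = self.weights / total

    def median_radius(self) -> float:
        """Weighted median of the radius grid."""
        cdf = np.cumsum(self.weights)
        return float(np.interp(0.5, cdf, self.radii))

    def mean_radius(self) -> float:
        return float(np.dot(self.weights, self.radii))


def estimate_beta(trace: CorrelationTrace, n_points: int = 3) -> float:
    """Coherence factor from the short-lag plateau of g2-1."""
    beta = float(np.mean(trace.g2m1[:n_points]))
    if not 0 < beta <= 1.05:
        raise ValueError(
            f"estimated coherence factor {beta:.3g} outside (0, 1]; "
            "supply beta explicitly"
        )
    return min(beta, 1.0)


def siegert_to_g1(
    trace: CorrelationTrace,
    beta: float | None = None,
    noise_tolerance: float = 0.01,
) -> NDArray[np.float64]:
    """Field correlation g1(tau) = sqrt((g2(tau)-1)/beta).

    ``beta`` (0 < beta <= 1) is the instrumental coherence factor,
    estimated from the short-lag plateau if not supplied.  Values of
    g2-1 slightly below zero are baseline noise and are clipped; values
    below -noise_tolerance*beta trigger a warning first.
    """
    if beta is None:
        beta = estimate_beta(trace)
    if not 0 < beta <= 1:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    ratio = trace.g2m1 / beta
    if np.any(ratio < -noise_tolerance):
        warnings.warn(
            "g2-1 values below the noise tolerance were clipped to zero",
            UserWarning,
            stacklevel=2,
        )
    return np.sqrt(np.clip(ratio, 0.0, None))


def radius_to_gamma(R_h: ArrayLike, trace: CorrelationTrace) -> NDArray[np.float64]:
    """Decay rate Gamma = D q^2 (s^-1) of a sphere of hydrodynamic
    radius R_h (nm) via Stokes-Einstein."""
    R_m = np.asarray(R_h, dtype=float) * 1e-9
    D = KB * trace.T / (6.0 * np.pi * trace.eta * R_m)
    return D * trace.q_m**2


def gamma_to_radius(gamma: ArrayLike, trace: CorrelationTrace) -> NDArray[np.float64]:
    """Hydrodynamic radius (nm) of the sphere decaying at rate Gamma
    (s^-1): D = Gamma/q^2, R_h = kB T / (6 pi eta D)."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("decay rates must be positive")
    D = gamma / trace.q_m**2
    return KB * trace.T / (6.0 * np.pi * trace.eta * D) * 1e9


def second_difference_matrix(n: int) -> NDArray[np.float64]:
    """(n-2) x n second-difference (discrete curvature) operator."""
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


@dataclass
class InversionResult:
    """Decay-rate spectrum from the regularized inversion."""

    gamma_grid: NDArray[np.float64]
    weights: NDArray[np.float64]
    lambda_reg: float
    residual_norm: float
    flags: list[str]


def _solve_tikhonov_nnls(
    K: NDArray[np.float64],
    g1: NDArray[np.float64],
    L: NDArray[np.float64],
    lam: float,
) -> tuple[NDArray[np.float64], float]:
    A = np.vstack([K, np.sqrt(lam) * L]) if lam > 0 else K
    b = np.concatenate([g1, np.zeros(L.shape[0])]) if lam > 0 else g1
    w, _ = nnls(A, b)
    res = float(np.linalg.norm(K @ w - g1))
    return w, res


def select_lambda_lcurve(
    K: NDArray[np.float64],
    g1: NDArray[np.float64],
    L: NDArray[np.float64],
    lambdas: NDArray[np.float64] | None = None,
) -> float:
    """L-curve corner selection of the smoothing weight.

    The corner of the (log residual-norm, log seminorm) curve is taken
    as the point farthest from the chord joining its endpoints (the
    triangle method), a robust discrete approximation to the point of
    maximum curvature.
    """
    if lambdas is None:
        lambdas = np.logspace(-6, 2, 25)
    rho, eta_n = [], []
    for lam in lambdas:
        w, res = _solve_tikhonov_nnls(K, g1, L, lam)
        rho.append(max(res, 1e-15))
        eta_n.append(max(float(np.linalg.norm(L @ w)), 1e-15))
    x, y = np.log(rho), np.log(eta_n)
    p0, p1 = np.array([x[0], y[0]]), np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return float(lambdas[len(lambdas) // 2])
    # signed perpendicular distance of each point from the chord
    d = ((x - p0[0]) * chord[1] - (y - p0[1]) * chord[0]) / norm
    return float(lambdas[int(np.argmax(np.abs(d)))])


def regularized_invert(
    g1: ArrayLike,
    tau: ArrayLike,
    gamma_grid: ArrayLike | None = None,
    lambda_reg: float | str = "auto",
) -> InversionResult:
    """Smoothing-constrained NNLS inversion of g1 into a decay-rate
    spectrum.

    Parameters
    ----------
    g1 : field correlation values.
    tau : lag times, s.
    gamma_grid : decay rates, s^-1; defaults to 100 log-spaced points
        spanning the reciprocal lag range with half a decade of margin.
    lambda_reg : smoothing weight; "auto" selects it by L-curve corner.
        lambda_reg = 0 is permitted but the bare exponential kernel is
        severely ill-conditioned (a warning is emitted).

    Returns
    -------
    InversionResult with weights normalized to unit sum (an all-zero
    NNLS solution is returned un-normalized and flagged "all_zero").
    """
    g1 = np.asarray(g1, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if g1.shape != tau.shape:
        raise ValueError("g1 and tau must have the same shape")
    if gamma_grid is None:
        lo, hi = 1.0 / tau[-1], 1.0 / tau[0]
        gamma_grid = np.logspace(np.log10(lo) - 0.5, np.log10(hi) + 0.5, 100)
    else:
        gamma_grid = np.asarray(gamma_grid, dtype=float)
        if np.any(gamma_grid <= 0) or not np.all(np.diff(gamma_grid) > 0):
            raise ValueError("gamma_grid must be positive and increasing")

    K = np.exp(-np.outer(tau, gamma_grid))
    L = second_difference_matrix(len(gamma_grid))

    flags: list[str] = []
    if isinstance(lambda_reg, str):
        if lambda_reg != "auto":
            raise ValueError(f"lambda_reg must be a number or 'auto', got {lambda_reg!r}")
        lam = select_lambda_lcurve(K, g1, L)
    else:
        lam = float(lambda_reg)
        if lam < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if lam == 0:
            warnings.warn(
                "unregularized exponential kernel is ill-conditioned; "
                "the spectrum may be spiky and unstable",
                UserWarning,
                stacklevel=2,
            )
    w, res = _solve_tikhonov_nnls(K, g1, L, lam)
    total = w.sum()
    if total <= 0:
        flags.append("all_zero")
        warnings.warn("inversion returned the all-zero spectrum", UserWarning, stacklevel=2)
    else:
        w = w / total
    return InversionResult(
        gamma_grid=gamma_grid, weights=w, lambda_reg=lam, residual_norm=res, flags=flags
    )


def noise_floor_cutoff(trace: CorrelationTrace, k: float = 3.0) -> int:
    """Index of the first lag where g2-1 sinks into the baseline noise.

    The square root in the Siegert relation is concave, so sqrt of a
    noisy near-zero correlation is biased; dropping lags where
    g2-1 < k * (tail standard deviation) removes the biased region.
    The tail level is estimated from the last tenth of the lags.
    """
    n = trace.g2m1.size
    tail = trace.g2m1[-max(n // 10, 2):]
    floor = k * max(float(np.std(tail)), 1e-12)
    below = trace.g2m1 <= floor
    return int(np.argmax(below)) if below.any() else n


def invert_trace(
    trace: CorrelationTrace,
    beta: float | None = None,
    radius_grid: ArrayLike | None = None,
    lambda_reg: float | str = "auto",
    truncate_noise_floor: bool = True,
) -> SizeDistribution:
    """Full chain: Siegert -> regularized inversion -> hydrodynamic
    radii (intensity-weighted).

    ``radius_grid`` defaults to 100 log-spaced radii over 5-500 nm,
    bracketing the 50 nm extrusion scale by an order of magnitude
    either way.  By default lags beyond the baseline-noise floor are
    excluded before the Siegert square root (see
    :func:`noise_floor_cutoff`); they carry no decay information and
    bias the inversion toward fast rates.
    """
    if truncate_noise_floor:
        cut = max(noise_floor_cutoff(trace), 8)
        trace = CorrelationTrace(
            tau=trace.tau[:cut], g2m1=trace.g2m1[:cut], q=trace.q,
            wavelength=trace.wavelength, T=trace.T, eta=trace.eta,
        )
    g1 = siegert_to_g1(trace, beta=beta)
    if radius_grid is None:
        radius_grid = np.logspace(np.log10(5.0), np.log10(500.0), 100)
    else:
        radius_grid = np.asarray(radius_grid, dtype=float)
    # large radius <-> slow decay: gamma grid is reversed radius grid
    gamma = radius_to_gamma(radius_grid[::-1], trace)
    inv = regularized_invert(g1, trace.tau, gamma_grid=gamma, lambda_reg=lambda_reg)
    return SizeDistribution(
        radii=radius_grid, weights=inv.weights[::-1], basis="intensity"
    )


def _per_particle_factors(
    radii: NDArray[np.float64], q_nm: float, shell_thickness: float
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """(mass, intensity, P) per particle up to constants: thin-shell
    vesicle mass m ~ R^2, scattered intensity ~ m^2 P(q, R)."""
    mass = radii**2
    P = np.array(
        [
            hollow_sphere_pq(
                HollowSphereModel(
                    R_mid=max(r, shell_thickness / 2 + 1e-6), t=shell_thickness
                ),
                np.array([q_nm]),
            )[0]
            for r in radii
        ]
    )
    return mass, mass**2 * P, P


def reweight(
    dist: SizeDistribution,
    target_basis: str,
    q: float = 0.0223,
    shell_thickness: float = 4.0,
    pq_floor: float = 1e-12,
) -> SizeDistribution:
    """Convert a size distribution between intensity, mass and number
    weighting.

    A vesicle is a thin shell of fixed thickness, so its mass scales as
    R^2 (not R^3); its scattered intensity per particle scales as
    mass^2 * P(q, R) with P the hollow-sphere form factor at the
    measurement q.  Intensity -> mass therefore divides by m(R)*P(q,R).
    Grid points where P(q, R) ~ 0 (form-factor nodes) carry no intensity
    information and are excluded with a warning.

    Parameters
    ----------
    q : measurement momentum transfer, nm^-1 (22.3 um^-1 = 0.0223 nm^-1).
    """
    if target_basis not in VALID_BASES:
        raise ValueError(f"target basis must be one of {VALID_BASES}")
    if target_basis == dist.basis:
        return replace(dist)
    mass, intensity, P = _per_particle_factors(dist.radii, q, shell_thickness)

    per_particle = {"number": np.ones_like(mass), "mass": mass, "intensity": intensity}
    src, dst = per_particle[dist.basis], per_particle[target_basis]
    # converting OUT of the intensity basis divides by P(q, R): bins at
    # form-factor nodes carry no intensity information and are dropped
    bad = (P < pq_floor) if dist.basis == "intensity" else np.zeros_like(P, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(bad, 0.0, dst / np.where(bad, 1.0, src))
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} grid radii excluded from reweighting "
            "(form factor ~ 0 at the measurement q)",
            UserWarning,
            stacklevel=2,
        )
    w = dist.weights * factor
    return SizeDistribution(radii=dist.radii, weights=w, basis=target_basis)
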