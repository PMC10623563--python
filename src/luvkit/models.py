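"""Closed-form scattering models shared by the SAXS and MALS stages.

Two particle models are provided:

* a **Gaussian-shell vesicle**, in which the radial electron-density
  contrast of the bilayer is a sum of Gaussians placed on a sphere of
  radius ``R`` (one for the hydrophobic core, one per polar head-group
  layer), used against SAXS data where the bilayer dominates;
* a **uniform hollow sphere** (spherical shell of constant contrast),
  used against multi-angle static light scattering, where only the
  overall vesicle envelope is resolved.

Both have analytic form factors; the Gaussian-shell amplitude uses the
extended-domain closed form of the radial Fourier integral, valid when
the Gaussian widths are small compared to the vesicle radius (sigma << R),
which holds for ~0.3-1 nm bilayer features on ~45 nm vesicles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray


class ClosedFormAccuracyWarning(UserWarning):
    """A Gaussian component is wide enough that the extended-domain
    closed form (which ignores the r < 0 half-line) starts to degrade."""


@dataclass(frozen=True)
class GaussianShellProfile:
    """Radial electron-density contrast of a spherical vesicle bilayer.

    The density relative to the bulk solvent is

        rho(r) = sum_k rho_k * exp(-(r - R - eps_k)^2 / (2 sigma_k^2))

    with component 1 the hydrophobic core (by convention fixed at
    ``eps_1 = 0``, ``rho_1 = 1`` during fitting), component 2 the internal
    polar heads (``eps_2 < 0``) and component 3 the external polar heads
    (``eps_3 > 0``).  The bilayer thickness is the head-to-head distance
    ``d = eps_3 - eps_2``.

    Parameters
    ----------
    R : float
        Mid-bilayer vesicle radius, nm.
    components : tuple of (rho, eps, sigma)
        Relative contrast (dimensionless), position relative to R (nm)
        and Gaussian width (nm) of each component.  Three components is
        the canonical minimal bilayer model; any number is accepted.
    """

    R: float
    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"vesicle radius must be positive, got R={self.R}")
        if len(self.components) < 1:
            raise ValueError("at least one Gaussian component is required")
        for k, (_, _, sigma) in enumerate(self.components, start=1):
            if sigma <= 0:
                raise ValueError(f"sigma_{k} must be positive, got {sigma}")

    @property
    def d(self) -> float:
        """Bilayer thickness d = eps_3 - eps_2 (head-group peak distance), nm."""
        if len(self.components) < 3:
            raise ValueError("bilayer thickness needs head-group components 2 and 3")
        return self.components[2][1] - self.components[1][1]

    def density(self, r: ArrayLike) -> NDArray[np.float64]:
        """Evaluate rho(r) on a radial grid (nm)."""
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for rho_k, eps_k, sigma_k in self.components:
            out += rho_k * np.exp(-((r - self.R - eps_k) ** 2) / (2.0 * sigma_k**2))
        return out

    def density_across_bilayer(self, eps: ArrayLike) -> NDArray[np.float64]:
        """Evaluate rho on a grid of positions measured from the bilayer
        center (eps = r - R), the natural axis for plotting the profile."""
        eps = np.asarray(eps, dtype=float)
        return self.density(eps + self.R)


@dataclass(frozen=True)
class HollowSphereModel:
    """Uniform spherical shell between R_mid - t/2 and R_mid + t/2.

    ``t`` defaults to 4 nm, the bilayer thickness scale, and is held
    fixed during MALS fitting (light scattering does not resolve it).
    """

    R_mid: float
    t: float = 4.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError(f"shell thickness must be positive, got t={self.t}")
        if self.R_mid <= self.t / 2.0:
            raise ValueError(
                f"R_mid={self.R_mid} must exceed t/2={self.t / 2.0} "
                "(inner radius must be positive)"
            )

    @property
    def R_inner(self) -> float:
        return self.R_mid - self.t / 2.0

    @property
    def R_outer(self) -> float:
        return self.R_mid + self.t / 2.0


@dataclass
class ScatteringCurve:
    """A 1-D scattering curve (q, I, optional sigma).

    q is stored internally in nm^-1 regardless of the unit it was read
    in (MALS instruments report um^-1; 1 um^-1 = 1e-3 nm^-1).
    """

    q: NDArray[np.float64]
    I: NDArray[np.float64]
    sigma: NDArray[np.float64] | None = None
    technique: str = "SAXS"
    q_unit_in: str = "nm^-1"

    _CONVERSION = {"nm^-1": 1.0, "um^-1": 1e-3, "µm^-1": 1e-3, "μm^-1": 1e-3}

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q_unit_in not in self._CONVERSION:
            raise ValueError(
                f"unknown q unit {self.q_unit_in!r}; expected one of "
                f"{sorted(set(self._CONVERSION))}"
            )
        factor = self._CONVERSION[self.q_unit_in]
        if factor != 1.0:
            self.q = self.q * factor
            self.q_unit_in = "nm^-1"
        if self.q.shape != self.I.shape:
            raise ValueError("q and I must have the same shape")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in shape")
            if not np.all(self.sigma > 0):
                raise ValueError("sigma must be positive where present")
        if self.technique not in ("SAXS", "MALS"):
            raise ValueError(f"technique must be SAXS or MALS, got {self.technique!r}")

    def restrict(self, qmin: float, qmax: float) -> "ScatteringCurve":
        """Return the sub-curve with qmin <= q <= qmax (q in nm^-1)."""
        mask = (self.q >= qmin) & (self.q <= qmax)
        if not mask.any():
            raise ValueError(f"no points in q window [{qmin}, {qmax}] nm^-1")
        return ScatteringCurve(
            q=self.q[mask],
            I=self.I[mask],
            sigma=None if self.sigma is None else self.sigma[mask],
            technique=self.technique,
        )


def gaussian_shell_amplitude(
    profile: GaussianShellProfile, q: ArrayLike
) -> NDArray[np.float64]:
    """Scattering amplitude F(q) of a Gaussian-shell vesicle.

    F(q) is the radial Fourier transform of the spherically symmetric
    density, F(q) = (4 pi / q) * Int r sin(qr) rho(r) dr.  With the
    integral extended to the whole real line (legitimate for
    sigma_k << R) each Gaussian contributes in closed form:

        F_k(q) = (4 pi / q) rho_k sqrt(2 pi) sigma_k exp(-q^2 sigma_k^2 / 2)
                 * [ c_k sin(q c_k) + q sigma_k^2 cos(q c_k) ],   c_k = R + eps_k

    Parameters
    ----------
    profile : GaussianShellProfile
    q : array, nm^-1, strictly positive

    Returns
    -------
    F(q), arbitrary units (nm^2 x relative contrast).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be strictly positive for the amplitude")
    wide = [sigma for _, _, sigma in profile.components if sigma > profile.R / 3.0]
    if wide:
        warnings.warn(
            f"Gaussian width(s) {wide} exceed R/3 = {profile.R / 3.0:.3g} nm; "
            "the extended-domain closed form degrades for such wide shells",
            ClosedFormAccuracyWarning,
            stacklevel=2,
        )
    out = np.zeros_like(q)
    for rho_k, eps_k, sigma_k in profile.components:
        c = profile.R + eps_k
        out += (
            rho_k
            * np.sqrt(2.0 * np.pi)
            * sigma_k
            * np.exp(-(q**2) * sigma_k**2 / 2.0)
            * (c * np.sin(q * c) + q * sigma_k**2 * np.cos(q * c))
        )
    return 4.0 * np.pi * out / q


def saxs_intensity(
    profile: GaussianShellProfile,
    q: ArrayLike,
    scale: float = 1.0,
    *,
    allow_low_q: bool = False,
) -> NDArray[np.float64]:
    """Thin-shell SAXS intensity I(q) = scale * |F(q)|^2 / q^2.

    The 1/q^2 prefactor is the standard flat-bilayer (thin-shell)
    factor; the model is meaningful for q above ~1/R, and the working
    window used throughout is 0.1-5 nm^-1.  The zeros of F(q) produce
    the nodes seen in vesicle SAXS data.

    Parameters
    ----------
    scale : positive float
        Overall prefactor absorbing particle number density and
        instrumental scaling.
    allow_low_q : bool
        Permit q < 0.1 nm^-1 (outside the stated validity range).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    q = np.asarray(q, dtype=float)
    if not allow_low_q and np.any(q < 0.1):
        raise ValueError(
            "q below 0.1 nm^-1 is outside the thin-shell validity range; "
            "pass allow_low_q=True to override"
        )
    F = gaussian_shell_amplitude(profile, q)
    return scale * F**2 / q**2


def _sphere_amplitude(q: NDArray[np.float64], R: float) -> NDArray[np.float64]:
    """Unnormalized amplitude of a uniform solid sphere, V * 3 j1(qR)/(qR)."""
    x = q * R
    V = 4.0 / 3.0 * np.pi * R**3
    with np.errstate(invalid="ignore", divide="ignore"):
        shape = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    # series 1 - x^2/10 + ... for the q -> 0 limit
    small = np.abs(x) < 1e-4
    if np.isscalar(shape):  # pragma: no cover - array inputs only
        shape = np.asarray(shape)
    shape = np.where(small, 1.0 - x**2 / 10.0, shape)
    return V * shape


def hollow_sphere_amplitude(
    model: HollowSphereModel, q: ArrayLike
) -> NDArray[np.float64]:
    """Amplitude of the uniform shell: difference of two solid spheres."""
    q = np.asarray(q, dtype=float)
    return model.contrast * (
        _sphere_amplitude(q, model.R_outer) - _sphere_amplitude(q, model.R_inner)
    )


def hollow_sphere_pq(model: HollowSphereModel, q: ArrayLike) -> NDArray[np.float64]:
    """Normalized form factor P(q) of a uniform spherical shell, P(0) = 1."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be nonnegative")
    A = hollow_sphere_amplitude(model, q)
    A0 = model.contrast * (
        4.0 / 3.0 * np.pi * (model.R_outer**3 - model.R_inner**3)
    )
    return (A / A0) ** 2


def shell_radius_of_gyration(model: HollowSphereModel) -> float:
    """Radius of gyration of the uniform shell.

    Rg^2 = (3/5) (R_o^5 - R_i^5) / (R_o^3 - R_i^3); for a vanishingly
    thin shell Rg -> R_mid.
    """
    Ro, Ri = model.R_outer, model.R_inner
    return float(np.sqrt(0.6 * (Ro**5 - Ri**5) / (Ro**3 - Ri**3)))
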