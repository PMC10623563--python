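"""Multi-angle static light scattering: Rayleigh-ratio normalization and
hollow-sphere fitting.

Raw MALS intensities are converted to absolute Rayleigh ratios using a
toluene reference (R_tol = 28e-6 cm^-1 at 532 nm) after solvent
background subtraction.  The angular decay of the Rayleigh ratio over
q = 5-25 um^-1 resolves the overall vesicle envelope, modeled as a
uniform spherical shell of fixed thickness (4 nm, the bilayer scale,
consistent with the SAXS result); the free parameters are the mid-shell
radius and an overall amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from numpy.typing import ArrayLike, NDArray

from .models import HollowSphereModel, hollow_sphere_pq, shell_radius_of_gyration
from .saxs import FitResult

#: Rayleigh ratio of toluene at 532 nm, cm^-1
R_TOLUENE = 28e-6


@dataclass
class RayleighCurve:
    """Absolute excess scattering R_theta(q) in cm^-1, q in um^-1."""

    q: NDArray[np.float64]
    R_theta: NDArray[np.float64]
    sigma: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.R_theta = np.asarray(self.R_theta, dtype=float)
        if self.q.shape != self.R_theta.shape:
            raise ValueError("q and R_theta must have the same shape")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.R_theta < 0):
            raise ValueError("Rayleigh ratio must be nonnegative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in shape")
            if not np.all(self.sigma > 0):
                raise ValueError("sigma must be positive where present")

    @property
    def q_nm(self) -> NDArray[np.float64]:
        """q converted to nm^-1 (1 um^-1 = 1e-3 nm^-1)."""
        return self.q * 1e-3


def to_rayleigh(
    I_sample: ArrayLike,
    I_solvent: ArrayLike,
    I_toluene: float | ArrayLike,
    q: ArrayLike,
    R_tol: float = R_TOLUENE,
) -> RayleighCurve:
    """Normalize detector counts to the absolute Rayleigh ratio.

    R_theta(q) = (I_sample - I_solvent) / I_toluene * R_tol

    Negative background-corrected intensities (possible in the noise
    floor) are clipped to zero with a warning.

    Parameters
    ----------
    I_sample, I_solvent : arrays on the same q grid, detector counts.
    I_toluene : scalar or array, toluene reference counts (> 0).
    q : array, um^-1.
    R_tol : toluene Rayleigh ratio, cm^-1.
    """
    I_sample = np.asarray(I_sample, dtype=float)
    I_solvent = np.asarray(I_solvent, dtype=float)
    I_tol = np.asarray(I_toluene, dtype=float)
    if I_sample.shape != I_solvent.shape:
        raise ValueError("sample and solvent arrays must share the q grid")
    if np.any(I_tol <= 0):
        raise ValueError("toluene reference intensity must be positive")
    excess = I_sample - I_solvent
    if np.any(excess < 0):
        warnings.warn(
            f"{int(np.sum(excess < 0))} negative background-corrected "
            "intensities clipped to zero",
            UserWarning,
            stacklevel=2,
        )
        excess = np.clip(excess, 0.0, None)
    return RayleighCurve(q=np.asarray(q, dtype=float), R_theta=excess / I_tol * R_tol)


def fit_mals(
    curve: RayleighCurve,
    t_fixed: float = 4.0,
    init_R: float = 30.0,
    qmin: float = 5.0,
    qmax: float = 25.0,
) -> FitResult:
    """Fit R_theta(q) = A * P_shell(q; R_mid, t) with t held fixed.

    The amplitude A is a nuisance parameter absorbing concentration and
    contrast; the recovered radius is invariant under rescaling of the
    input.  The shell radius of gyration of the fitted model is reported
    alongside (params key "Rg").

    Parameters
    ----------
    curve : RayleighCurve with q in um^-1.
    t_fixed : shell thickness, nm (not a free parameter).
    init_R : starting mid-shell radius, nm.
    qmin, qmax : fitting window in um^-1 (instrument range).
    """
    mask = (curve.q >= qmin) & (curve.q <= qmax)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 points in q window [{qmin}, {qmax}] um^-1")
    q_nm = curve.q_nm[mask]
    # normalize the working level so the recovered radius is exactly
    # invariant under rescaling of the input amplitude
    y_scale = float(np.max(curve.R_theta[mask]))
    if y_scale <= 0:
        raise ValueError("Rayleigh curve is identically zero in the fit window")
    y = curve.R_theta[mask] / y_scale
    w = None if curve.sigma is None else y_scale / curve.sigma[mask]

    # flat curve carries no size information
    if np.std(y) < 1e-6 * max(np.mean(np.abs(y)), 1e-300):
        return FitResult(
            params={"R_mid": np.nan, "amplitude": float(np.mean(y)), "t": t_fixed},
            uncertainties={"R_mid": np.nan, "amplitude": np.nan},
            chi2_reduced=np.nan,
            converged=False,
            flags=["non_identifiable"],
        )

    def pq(R_mid: float) -> NDArray[np.float64]:
        return hollow_sphere_pq(HollowSphereModel(R_mid=R_mid, t=t_fixed), q_nm)

    def amp_profiled(R_mid: float) -> float:
        p = pq(R_mid)
        if w is not None:
            num, den = float(np.sum(y * p * w**2)), float(np.sum(p**2 * w**2))
        else:
            num, den = float(np.dot(y, p)), float(np.dot(p, p))
        return num / den if den > 0 else float(np.mean(y))

    params = lmfit.Parameters()
    params.add("R_mid", value=init_R, min=t_fixed / 2 + 0.1, max=2000.0)
    params.add("amplitude", value=amp_profiled(init_R), min=0.0)

    def residual(p: lmfit.Parameters) -> NDArray[np.float64]:
        r = p["amplitude"].value * pq(p["R_mid"].value) - y
        return r * w if w is not None else r

    res = lmfit.minimize(residual, params, method="least_squares")
    values = {
        "R_mid": float(res.params["R_mid"].value),
        "amplitude": float(res.params["amplitude"].value) * y_scale,
        "t": t_fixed,
    }
    stderr = {
        n: float(res.params[n].stderr) if res.params[n].stderr is not None else np.nan
        for n in ("R_mid", "amplitude")
    }
    stderr["amplitude"] *= y_scale
    values["Rg"] = shell_radius_of_gyration(
        HollowSphereModel(R_mid=values["R_mid"], t=t_fixed)
    )
    dof = max(int(mask.sum()) - 2, 1)
    return FitResult(
        params=values,
        uncertainties=stderr,
        chi2_reduced=float(np.sum(np.asarray(res.residual) ** 2)) / dof,
        converged=bool(res.success),
        flags=[] if res.success else ["not_converged"],
    )
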