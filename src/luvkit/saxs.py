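"""Fit the Gaussian-shell bilayer model to vesicle SAXS curves.

The working q-window is 0.1-5 nm^-1, where the scattering of a dilute
unilamellar vesicle suspension is dominated by the bilayer and is well
described by I(q) = scale * |F(q)|^2 / q^2 with F the amplitude of a
sum-of-Gaussians electron-density profile (see :mod:`luvkit.models`).
The hydrophobic-core Gaussian is pinned at eps_1 = 0, rho_1 = 1, which
fixes the contrast normalization; the free parameters are the vesicle
radius R, the head-group contrasts and positions (rho_2, eps_2, rho_3,
eps_3), the three widths, and an overall scale.  The bilayer thickness
is reported as the head-to-head distance d = eps_3 - eps_2.

The least-squares surface has permutation/sign quasi-symmetries, so the
fit is a seeded multi-start: the initial guess is perturbed and the best
of ``n_restarts`` local optimizations is kept, canonicalized so that
eps_2 < 0 < eps_3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from numpy.typing import ArrayLike, NDArray

from .models import GaussianShellProfile, ScatteringCurve, saxs_intensity

PARAM_NAMES = (
    "R",
    "rho_2",
    "rho_3",
    "eps_2",
    "eps_3",
    "sigma_1",
    "sigma_2",
    "sigma_3",
    "scale",
)

#: physics-informed default starting point: ~45 nm extruded vesicle,
#: ~4 nm bilayer, 0.5 nm head-group widths, 1 nm core width, head
#: contrast opposite in sign to the (fixed, +1) core contrast.
DEFAULT_INIT = GaussianShellProfile(
    R=45.0,
    components=((1.0, 0.0, 1.0), (-2.0, -2.0, 0.5), (-2.0, 2.0, 0.5)),
)

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "R": (10.0, 200.0),
    "rho_2": (-10.0, 10.0),
    "rho_3": (-10.0, 10.0),
    "eps_2": (-5.0, -0.3),
    "eps_3": (0.3, 5.0),
    "sigma_1": (0.05, 3.0),
    "sigma_2": (0.05, 3.0),
    "sigma_3": (0.05, 3.0),
    "scale": (1e-30, np.inf),
}


@dataclass
class FitResult:
    """Outcome of a SAXS (or MALS) least-squares fit.

    ``params``/``uncertainties`` are name -> value maps; ``d`` is the
    head-to-head bilayer thickness derived from the fitted eps's.
    ``flags`` collects non-fatal diagnostics ("multimodal",
    "at_boundary", "not_converged").
    """

    params: dict[str, float]
    uncertainties: dict[str, float]
    chi2_reduced: float
    converged: bool
    n_restarts_used: int = 1
    flags: list[str] = field(default_factory=list)

    @property
    def d(self) -> float:
        return self.params["eps_3"] - self.params["eps_2"]

    @property
    def d_stderr(self) -> float:
        # independent-error propagation; correlations are available from
        # the full covariance but rarely change the flagging decision
        return float(
            np.hypot(
                self.uncertainties.get("eps_2", 0.0),
                self.uncertainties.get("eps_3", 0.0),
            )
        )

    def profile(self) -> GaussianShellProfile:
        """Reconstruct the fitted electron-density profile."""
        p = self.params
        return GaussianShellProfile(
            R=p["R"],
            components=(
                (1.0, 0.0, p["sigma_1"]),
                (p["rho_2"], p["eps_2"], p["sigma_2"]),
                (p["rho_3"], p["eps_3"], p["sigma_3"]),
            ),
        )


def _profile_to_init(init: GaussianShellProfile, scale: float) -> dict[str, float]:
    (_, _, s1), (r2, e2, s2), (r3, e3, s3) = init.components[:3]
    return {
        "R": init.R,
        "rho_2": r2,
        "rho_3": r3,
        "eps_2": e2,
        "eps_3": e3,
        "sigma_1": s1,
        "sigma_2": s2,
        "sigma_3": s3,
        "scale": scale,
    }


def _model(params: lmfit.Parameters, q: NDArray[np.float64]) -> NDArray[np.float64]:
    v = params.valuesdict()
    profile = GaussianShellProfile(
        R=v["R"],
        components=(
            (1.0, 0.0, v["sigma_1"]),
            (v["rho_2"], v["eps_2"], v["sigma_2"]),
            (v["rho_3"], v["eps_3"], v["sigma_3"]),
        ),
    )
    return saxs_intensity(profile, q, scale=v["scale"], allow_low_q=True)


def _estimate_scale(
    init: GaussianShellProfile, q: NDArray[np.float64], I: NDArray[np.float64]
) -> float:
    """Least-squares optimal prefactor for the initial profile."""
    m = saxs_intensity(init, q, scale=1.0, allow_low_q=True)
    denom = float(np.dot(m, m))
    s = float(np.dot(I, m)) / denom if denom > 0 else 1.0
    return s if s > 0 else 1.0


def fit_saxs(
    curve: ScatteringCurve,
    init: GaussianShellProfile | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 8,
    seed: int | None = None,
    qmin: float = 0.1,
    qmax: float = 5.0,
    perturbation: float = 0.2,
) -> FitResult:
    """Weighted multi-start least-squares fit of the Gaussian-shell model.

    Parameters
    ----------
    curve : ScatteringCurve
        Background-subtracted SAXS data (technique must be "SAXS").
        Weights are 1/sigma^2 when the curve carries uncertainties,
        otherwise the fit is unweighted.
    init : GaussianShellProfile, optional
        Starting geometry; defaults to a generic extruded-vesicle guess.
    bounds : dict, optional
        Per-parameter (lo, hi) overrides of the default boxes.
    n_restarts : int
        Number of local optimizations; the first starts at ``init``,
        the rest at multiplicative +/-``perturbation`` perturbations.
    seed : int, optional
        Seeds the perturbation draws (reproducible restarts).

    Returns
    -------
    FitResult
        Best restart, canonicalized so eps_2 < 0 < eps_3.  A fit that
        never converged is returned flagged, not raised.
    """
    if curve.technique != "SAXS":
        raise ValueError(f"expected a SAXS curve, got technique={curve.technique!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    sub = curve.restrict(qmin, qmax)
    q, I = sub.q, sub.I
    if sub.sigma is not None:
        weights = 1.0 / sub.sigma
    else:
        # without uncertainties, weight relatively: the curve spans many
        # decades and absolute residuals would let the low-q plateau
        # drown the high-q bilayer oscillations that carry d; the floor
        # keeps form-factor nodes from dominating
        weights = 1.0 / np.maximum(np.abs(I), 1e-6 * np.max(np.abs(I)))

    init = init or DEFAULT_INIT
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    init_vals = _profile_to_init(init, _estimate_scale(init, q, I))
    # the generic bilayer guess doubles as a dispersed anchor start:
    # perturbed user inits alone can miss the global basin
    anchor_vals = _profile_to_init(DEFAULT_INIT, _estimate_scale(DEFAULT_INIT, q, I))

    rng = np.random.default_rng(seed)
    n_free = len(PARAM_NAMES)

    def residual(params: lmfit.Parameters) -> NDArray[np.float64]:
        r = _model(params, q) - I
        return r * weights if weights is not None else r

    best: lmfit.minimizer.MinimizerResult | None = None
    restart_d: list[tuple[float, float]] = []  # (cost, d) per converged restart
    for k in range(n_restarts):
        base = init_vals if k % 2 == 0 else anchor_vals
        start = dict(base)
        if k > 1:
            for name in PARAM_NAMES:
                start[name] *= 1.0 + rng.uniform(-perturbation, perturbation)
            # re-profile the prefactor for the perturbed geometry: the
            # optimum scale is a linear subproblem and a poor value
            # strands the optimizer in the low-q-dominated plateau
            trial = GaussianShellProfile(
                R=max(start["R"], 1e-3),
                components=(
                    (1.0, 0.0, max(start["sigma_1"], 1e-3)),
                    (start["rho_2"], start["eps_2"], max(start["sigma_2"], 1e-3)),
                    (start["rho_3"], start["eps_3"], max(start["sigma_3"], 1e-3)),
                ),
            )
            start["scale"] = _estimate_scale(trial, q, I)
        params = lmfit.Parameters()
        for name in PARAM_NAMES:
            lo, hi = box[name]
            params.add(name, value=float(np.clip(start[name], lo, hi)), min=lo, max=hi)
        try:
            # Jacobian-based variable scaling is essential: the intensity
            # spans many decades over the q window and the parameters mix
            # nm-scale geometry with an arbitrary-units prefactor
            res = lmfit.minimize(
                residual,
                params,
                method="least_squares",
                x_scale="jac",
                max_nfev=50000,
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
            )
        except Exception:  # a pathological start may blow up; skip it
            continue
        if res.success:
            cost = float(np.sum(np.asarray(res.residual) ** 2))
            d_k = res.params["eps_3"].value - res.params["eps_2"].value
            restart_d.append((cost, d_k))
            if best is None or cost < float(np.sum(np.asarray(best.residual) ** 2)):
                best = res

    if best is None:
        return FitResult(
            params=dict(init_vals),
            uncertainties={n: np.nan for n in PARAM_NAMES},
            chi2_reduced=np.nan,
            converged=False,
            n_restarts_used=n_restarts,
            flags=["not_converged"],
        )

    values = {n: float(best.params[n].value) for n in PARAM_NAMES}
    stderr = {
        n: float(best.params[n].stderr) if best.params[n].stderr is not None else np.nan
        for n in PARAM_NAMES
    }
    values, stderr = _canonicalize(values, stderr)

    dof = max(len(q) - n_free, 1)
    chi2_red = float(np.sum(np.asarray(best.residual) ** 2)) / dof

    flags: list[str] = []
    for name in PARAM_NAMES:
        lo, hi = box[name]
        span = hi - lo
        if np.isfinite(span) and span > 0:
            if (values[name] - lo) < 1e-8 * span or (hi - values[name]) < 1e-8 * span:
                flags.append("at_boundary")
                warnings.warn(
                    f"parameter {name} pinned at its bound [{lo}, {hi}]",
                    UserWarning,
                    stacklevel=2,
                )
                break

    result = FitResult(
        params=values,
        uncertainties=stderr,
        chi2_reduced=chi2_red,
        converged=True,
        n_restarts_used=n_restarts,
        flags=flags,
    )

    # identifiability guard: equivalent-cost minima must agree on d
    best_cost = float(np.sum(np.asarray(best.residual) ** 2))
    tol_cost = best_cost * 1.001 + 1e-12
    d_equiv = [d for c, d in restart_d if c <= tol_cost]
    if len(d_equiv) >= 2:
        spread = max(d_equiv) - min(d_equiv)
        if spread > max(result.d_stderr, 1e-3 * abs(result.d)):
            result.flags.append("multimodal")
    return result


def electron_density_profile(
    result: FitResult, r_grid: ArrayLike
) -> NDArray[np.float64]:
    """Evaluate the fitted electron-density contrast rho(eps) across the
    bilayer, with eps measured from the bilayer center (eps = r - R).

    Leaflet asymmetry is preserved exactly as fitted; the contrast is
    relative to the bulk solvent, so rho -> 0 far from the bilayer.
    """
    if not result.converged:
        raise ValueError("cannot evaluate the profile of a non-converged fit")
    return result.profile().density_across_bilayer(np.asarray(r_grid, dtype=float))


def _canonicalize(
    values: dict[str, float], stderr: dict[str, float]
) -> tuple[dict[str, float], dict[str, float]]:
    """Order the head-group components so eps_2 < 0 < eps_3 (label swap
    leaves the model invariant)."""
    if values["eps_2"] > values["eps_3"]:
        for a, b in (("rho_2", "rho_3"), ("eps_2", "eps_3"), ("sigma_2", "sigma_3")):
            values[a], values[b] = values[b], values[a]
            stderr[a], stderr[b] = stderr[b], stderr[a]
    return values, stderr
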