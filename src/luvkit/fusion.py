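"""Sew MALS and SAXS branches into a single whole-liposome form factor.

The two techniques probe disjoint q ranges (MALS 5-25 um^-1, SAXS
0.1-5 nm^-1), so the relative scale cannot come from a data overlap.
Instead it is anchored through the fitted models: the Gaussian-shell
SAXS model, itself normalized to the hollow-sphere level of the MALS
branch inside a low-q bridge window, provides the reference against
which the SAXS data are rescaled by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .mals import RayleighCurve
from .models import (
    GaussianShellProfile,
    HollowSphereModel,
    ScatteringCurve,
    hollow_sphere_pq,
    saxs_intensity,
)


@dataclass
class CompositeFormFactor:
    """Whole-liposome P(q): merged MALS + scaled-SAXS branches with
    per-point provenance."""

    q: NDArray[np.float64]  # nm^-1, strictly increasing
    P: NDArray[np.float64]
    source: NDArray[np.str_]  # "MALS" | "SAXS" per point
    saxs_scale: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("merged q must be strictly increasing")
        if np.any(self.P <= 0):
            raise ValueError("composite form factor must be positive")


def sew(
    mals_pf: RayleighCurve,
    saxs_curve: ScatteringCurve,
    shell_profile: GaussianShellProfile,
    hollow_model: HollowSphereModel,
    mals_amplitude: float | None = None,
    bridge_window: tuple[float, float] = (0.1, 0.3),
) -> CompositeFormFactor:
    """Combine a MALS form factor and a SAXS curve into one P(q).

    Steps:

    1. normalize the MALS branch to P(q -> 0) = 1 (dividing by
       ``mals_amplitude``, the fitted hollow-sphere amplitude; defaults
       to the forward-extrapolated model value);
    2. inside ``bridge_window`` (nm^-1), scale the Gaussian-shell SAXS
       model onto the hollow-sphere model continued from the MALS
       branch — this puts the bilayer model on the absolute level of
       the normalized form factor;
    3. rescale the SAXS data onto that bridged model by least squares:
       saxs_scale = argmin_a sum (a I_saxs - P_model)^2.

    A non-positive optimal scale indicates a sign error in the inputs
    and is rejected.
    """
    lo, hi = bridge_window
    if not 0 < lo < hi:
        raise ValueError("bridge window must satisfy 0 < lo < hi (nm^-1)")
    in_window = (saxs_curve.q >= lo) & (saxs_curve.q <= hi)
    if in_window.sum() < 2:
        raise ValueError(
            f"need >= 2 SAXS points inside the bridge window [{lo}, {hi}] nm^-1"
        )
    qw = saxs_curve.q[in_window]

    # hollow-sphere model continued into the bridge window, on the
    # normalized (P(0)=1) scale of the MALS branch
    p_hollow_w = hollow_sphere_pq(hollow_model, qw)

    # Gaussian-shell model normalized onto that level
    i_gs_w = saxs_intensity(shell_profile, qw, scale=1.0)
    denom = float(np.dot(i_gs_w, i_gs_w))
    s_gs = float(np.dot(i_gs_w, p_hollow_w)) / denom
    p_model_w = s_gs * i_gs_w

    # least-squares rescaling of the SAXS data onto the bridged model
    I_w = saxs_curve.I[in_window]
    saxs_scale = float(np.dot(I_w, p_model_w)) / float(np.dot(I_w, I_w))
    if saxs_scale <= 0:
        raise ValueError(
            f"optimal SAXS scale {saxs_scale:.3g} is non-positive; "
            "check the sign/level of the inputs"
        )

    if mals_amplitude is None:
        mals_amplitude = float(
            np.max(mals_pf.R_theta) / np.max(hollow_sphere_pq(hollow_model, mals_pf.q_nm))
        )
    q_mals = mals_pf.q_nm
    p_mals = mals_pf.R_theta / mals_amplitude

    q_all = np.concatenate([q_mals, saxs_curve.q])
    p_all = np.concatenate([p_mals, saxs_scale * saxs_curve.I])
    src_all = np.concatenate(
        [np.full(q_mals.shape, "MALS"), np.full(saxs_curve.q.shape, "SAXS")]
    )
    order = np.argsort(q_all, kind="stable")
    return CompositeFormFactor(
        q=q_all[order], P=p_all[order], source=src_all[order], saxs_scale=saxs_scale
    )
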