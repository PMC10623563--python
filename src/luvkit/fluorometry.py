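"""Fluorescence- and absorbance-derived quantities for proteo-liposome
characterization.

Covers the loading-quantification chain (dye calibration line ->
labeled-protein concentration -> drug loading DL% and loading efficacy
LE% from the preparation mass balance), the Laurdan generalized
polarization (membrane surface hydration/order), the ANS-titration
critical micelle concentration breakpoint, and A280 protein
concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import stats
from scipy.optimize import minimize_scalar

#: extinction coefficient of alpha_s1-casein at 280 nm, mg^-1 mL cm^-1
EPSILON_280 = 0.81
#: molecular weight of alpha_s1-casein, kDa
CASEIN_MW_KDA = 23.6


@dataclass(frozen=True)
class FluorescenceCalibration:
    """Linear fluorophore calibration: intensity = slope*conc + intercept."""

    concentrations: NDArray[np.float64]  # mol/L
    intensities: NDArray[np.float64]  # a.u.
    slope: float
    intercept: float
    r_squared: float
    lambda_em: float = 650.0  # nm (Alexa Fluor 647 assay)

    def invert(self, intensity: float) -> float:
        """Concentration (mol/L) back-calculated from an intensity."""
        return (intensity - self.intercept) / self.slope


@dataclass(frozen=True)
class PrepSpec:
    """Mass balance of a proteo-liposome preparation.

    The lipid film (``lipid_film_mass`` mg) is hydrated with
    ``hydration_volume`` mL of drug (protein) solution at
    ``hydration_drug_conc`` mg/mL; after extrusion/purification the
    final ``final_volume`` mL preparation carries ``final_lipid_conc``
    and ``final_drug_conc`` mg/mL.  ``drug_MW`` is in kDa.
    """

    lipid_film_mass: float
    hydration_volume: float
    hydration_drug_conc: float
    final_volume: float
    final_lipid_conc: float
    final_drug_conc: float
    drug_MW: float = CASEIN_MW_KDA

    def __post_init__(self) -> None:
        for name in (
            "lipid_film_mass",
            "hydration_volume",
            "hydration_drug_conc",
            "final_volume",
            "final_lipid_conc",
            "final_drug_conc",
            "drug_MW",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        offered = self.hydration_drug_conc * self.hydration_volume
        retained = self.final_drug_conc * self.final_volume
        if retained > offered * (1 + 1e-9):
            raise ValueError(
                f"final drug mass {retained:.4g} mg exceeds the "
                f"{offered:.4g} mg offered at hydration"
            )


@dataclass
class LaurdanSpectrum:
    """Laurdan emission spectrum (wavelengths nm, intensities a.u.)."""

    wavelengths: NDArray[np.float64]
    intensities: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must match in shape")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    def intensity_at(self, wavelength: float, tol: float = 1.0) -> float:
        """Nearest-grid intensity within +/- tol nm."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > tol:
            raise ValueError(
                f"spectrum does not cover {wavelength} nm within +/-{tol} nm"
            )
        return float(self.intensities[i])


@dataclass(frozen=True)
class LoadingReport:
    """Encapsulation metrics of a preparation."""

    loaded_conc_mg_per_mL: float
    loaded_conc_molar: float  # mol/L
    DL_percent: float
    LE_percent: float

    def __post_init__(self) -> None:
        if self.DL_percent < 0:
            raise ValueError("DL% must be nonnegative")
        if not 0 <= self.LE_percent <= 100:
            raise ValueError("LE% must lie in [0, 100]")


@dataclass(frozen=True)
class CMCResult:
    """Two-segment breakpoint analysis of a probe-fluorescence titration."""

    detected: bool
    cmc_mg_per_mL: float | None
    cmc_molar: float | None  # mol/L
    slopes: tuple[float, float] | None
    p_value: float


def fit_calibration(
    concentrations: ArrayLike,
    intensities: ArrayLike,
    lambda_em: float = 650.0,
) -> FluorescenceCalibration:
    """Ordinary least-squares calibration line through (conc, intensity).

    Requires >= 3 points with at least two distinct concentrations.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if c.shape != y.shape or c.size < 3:
        raise ValueError("need >= 3 matched (concentration, intensity) points")
    if np.unique(c).size < 2:
        raise ValueError("calibration requires at least two distinct concentrations")
    fit = stats.linregress(c, y)
    if fit.slope <= 0:
        raise ValueError(f"calibration slope must be positive, got {fit.slope:.3g}")
    return FluorescenceCalibration(
        concentrations=c,
        intensities=y,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        lambda_em=lambda_em,
    )


def quantify_loaded(
    intensity_at_650: float,
    calib: FluorescenceCalibration,
    DOL: float,
) -> float:
    """Protein concentration (mol/L) from the dye emission of the
    purified proteo-liposomes.

    The calibration inverts to the *dye* concentration; dividing by the
    degree of labeling (mean dyes per protein) gives the protein.
    Intensities outside the calibration range are extrapolations and
    only warned about.
    """
    if DOL <= 0:
        raise ValueError("degree of labeling must be positive")
    if not (
        calib.intensities.min() <= intensity_at_650 <= calib.intensities.max()
    ):
        warnings.warn(
            "intensity outside the calibration range; extrapolating",
            UserWarning,
            stacklevel=2,
        )
    c_dye = calib.invert(intensity_at_650)
    # round-off on a blank can produce a -1e-24-scale value; only a
    # genuinely negative back-calculation is an error
    tol = 1e-9 * float(np.max(np.abs(calib.concentrations)))
    if c_dye < -tol:
        raise ValueError(
            f"back-calculated dye concentration {c_dye:.3g} M is negative"
        )
    return max(c_dye, 0.0) / DOL


def degree_of_labeling(
    A_dye: float,
    A280: float,
    epsilon_dye: float,
    epsilon_protein: float,
    correction_factor: float = 0.0,
    path_cm: float = 1.0,
) -> float:
    """Spectrophotometric degree of labeling (dyes per protein).

    DOL = (A_dye / eps_dye) / ((A280 - CF * A_dye) / eps_protein); the
    kit-specific extinction coefficients and the dye's 280 nm
    correction factor CF are supplied by the labeling-kit datasheet.
    """
    if min(A_dye, A280, epsilon_dye, epsilon_protein, path_cm) <= 0:
        raise ValueError("absorbances, extinctions and path must be positive")
    c_dye = A_dye / (epsilon_dye * path_cm)
    c_prot = (A280 - correction_factor * A_dye) / (epsilon_protein * path_cm)
    if c_prot <= 0:
        raise ValueError("corrected A280 implies non-positive protein concentration")
    return c_dye / c_prot


def loading_percentages(prep: PrepSpec, dl_denominator: str = "lipid") -> LoadingReport:
    """Drug loading and loading efficacy from the preparation mass
    balance.

    DL% = 100 * final_drug_conc / final_lipid_conc (drug per carrier
    lipid mass; ``dl_denominator="total"`` uses drug/(drug+lipid)
    instead).  LE% = 100 * drug mass retained / drug mass offered at
    hydration.  The molar loaded concentration uses ``drug_MW`` (kDa).
    """
    if dl_denominator not in ("lipid", "total"):
        raise ValueError("dl_denominator must be 'lipid' or 'total'")
    denom = prep.final_lipid_conc
    if dl_denominator == "total":
        denom = prep.final_lipid_conc + prep.final_drug_conc
    DL = 100.0 * prep.final_drug_conc / denom
    LE = (
        100.0
        * (prep.final_drug_conc * prep.final_volume)
        / (prep.hydration_drug_conc * prep.hydration_volume)
    )
    # mg/mL = g/L; MW kDa = 1000*MW g/mol
    molar = prep.final_drug_conc / (prep.drug_MW * 1000.0)
    return LoadingReport(
        loaded_conc_mg_per_mL=prep.final_drug_conc,
        loaded_conc_molar=molar,
        DL_percent=DL,
        LE_percent=LE,
    )


def laurdan_gp(spectrum: LaurdanSpectrum) -> float:
    """Laurdan generalized polarization GP = (I435 - I500)/(I435 + I500).

    The blue (435 nm) and red (500 nm) emission edges report the
    polarity of the probe environment; GP is bounded in [-1, 1], higher
    meaning a less hydrated (more ordered) bilayer surface.
    """
    I_blue = spectrum.intensity_at(435.0)
    I_red = spectrum.intensity_at(500.0)
    total = I_blue + I_red
    if total == 0:
        raise ValueError("I435 + I500 = 0; GP undefined")
    return (I_blue - I_red) / total


def _piecewise_rss(
    x: NDArray[np.float64], y: NDArray[np.float64], x0: float
) -> tuple[float, NDArray[np.float64]]:
    """RSS of the continuous two-segment line with hinge at x0; linear
    least squares in (a, b1, b2) for y = a + b1*min(x-x0,0) + b2*max(x-x0,0)."""
    X = np.column_stack(
        [np.ones_like(x), np.minimum(x - x0, 0.0), np.maximum(x - x0, 0.0)]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((X @ coef - y) ** 2))
    return rss, coef


def cmc_breakpoint(
    concentrations: ArrayLike,
    fluorescence: ArrayLike,
    MW_kDa: float = CASEIN_MW_KDA,
    alpha: float = 0.05,
) -> CMCResult:
    """Critical micelle concentration from a probe-fluorescence
    titration.

    Fits a continuous two-segment piecewise-linear model by exhaustive
    search over candidate breakpoints (every interior inter-point
    interval) with local refinement, then tests the slope change
    against a single straight line with an F-test (2 extra parameters).
    If the test is not significant at ``alpha`` no CMC is reported.

    Returns the breakpoint abscissa in mg/mL and mol/L.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.shape != y.shape or x.size < 6:
        raise ValueError("need >= 6 titration points spanning the break")
    order = np.argsort(x)
    x, y = x[order], y[order]

    # exhaustive candidate search: one trial breakpoint per interior interval
    best_rss, best_x0, best_coef = np.inf, None, None
    interior = range(1, x.size - 2)
    for i in interior:
        lo, hi = x[i], x[i + 1]
        if hi <= lo:
            continue
        res = minimize_scalar(
            lambda x0: _piecewise_rss(x, y, x0)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        rss, coef = _piecewise_rss(x, y, float(res.x))
        if rss < best_rss:
            best_rss, best_x0, best_coef = rss, float(res.x), coef

    # single-line null model
    X1 = np.column_stack([np.ones_like(x), x])
    coef1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(np.sum((X1 @ coef1 - y) ** 2))

    n = x.size
    dof2 = n - 4  # a, b1, b2, x0
    if best_x0 is None or dof2 <= 0:
        raise ValueError("too few points for the breakpoint F-test")
    y_scatter = float(np.sum((y - y.mean()) ** 2))
    if rss1 <= 1e-12 * max(y_scatter, 1e-300):
        p_value = 1.0  # a single line is already exact: no break
    elif best_rss <= 1e-12 * max(rss1, 1.0):
        p_value = 0.0
    else:
        F = ((rss1 - best_rss) / 2.0) / (best_rss / dof2)
        p_value = float(stats.f.sf(max(F, 0.0), 2, dof2))

    if p_value >= alpha:
        return CMCResult(
            detected=False, cmc_mg_per_mL=None, cmc_molar=None, slopes=None,
            p_value=p_value,
        )
    return CMCResult(
        detected=True,
        cmc_mg_per_mL=best_x0,
        cmc_molar=best_x0 / (MW_kDa * 1000.0),
        slopes=(float(best_coef[1]), float(best_coef[2])),
        p_value=p_value,
    )


def absorbance_to_conc(
    A280: float, path_cm: float = 1.0, epsilon: float = EPSILON_280
) -> float:
    """Beer-Lambert protein concentration (mg/mL) from A280."""
    if A280 < 0:
        raise ValueError("absorbance must be nonnegative")
    if path_cm <= 0 or epsilon <= 0:
        raise ValueError("path length and extinction coefficient must be positive")
    return A280 / (epsilon * path_cm)
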