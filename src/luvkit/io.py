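"""Readers/writers for curve files and the pipeline configuration.

Curves travel as plain two/three-column ASCII or CSV (columns:
abscissa, value, optional uncertainty; '#' comment lines skipped).
The declared q unit is converted on read so everything downstream
works in nm^-1 (SAXS) or um^-1 (MALS/DLS instrument conventions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from numpy.typing import NDArray

from .dls import CorrelationTrace
from .mals import RayleighCurve
from .models import ScatteringCurve


class CurveParseError(ValueError):
    """Raised when a curve file cannot be parsed (carries the line number)."""


def _load_columns(path: str | Path) -> NDArray[np.float64]:
    """Parse a 2-3 column numeric file; commas or whitespace delimit."""
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise CurveParseError(
                    f"{path}: non-numeric payload on line {lineno}: {raw.rstrip()!r}"
                ) from exc
            if width is None:
                width = len(values)
                if width < 2:
                    raise CurveParseError(
                        f"{path}: need >= 2 numeric columns (line {lineno})"
                    )
            elif len(values) != width:
                raise CurveParseError(
                    f"{path}: inconsistent column count on line {lineno}"
                )
            rows.append(values)
    if not rows:
        raise CurveParseError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def _dedupe(data: NDArray[np.float64], path: str | Path) -> NDArray[np.float64]:
    """Stable-sort on the abscissa; merge duplicated abscissas by
    averaging the remaining columns (with a warning)."""
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    x = data[:, 0]
    if np.unique(x).size != x.size:
        warnings.warn(
            f"{path}: duplicated abscissa rows merged by averaging",
            UserWarning,
            stacklevel=3,
        )
        uniq, inverse = np.unique(x, return_inverse=True)
        merged = np.zeros((uniq.size, data.shape[1]))
        merged[:, 0] = uniq
        counts = np.bincount(inverse)
        for col in range(1, data.shape[1]):
            merged[:, col] = np.bincount(inverse, weights=data[:, col]) / counts
        data = merged
    return data


def read_curve(
    path: str | Path,
    kind: str = "saxs",
    q_unit: str | None = None,
    **metadata: Any,
) -> ScatteringCurve | RayleighCurve | CorrelationTrace:
    """Read a curve file as the requested kind.

    kind = "saxs" -> ScatteringCurve (q_unit default nm^-1)
    kind = "mals" -> RayleighCurve   (q_unit default um^-1)
    kind = "dls"  -> CorrelationTrace (columns tau s, g2-1; extra
                     instrument constants pass through **metadata)
    """
    data = _dedupe(_load_columns(path), path)
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    if kind == "saxs":
        return ScatteringCurve(
            q=data[:, 0],
            I=data[:, 1],
            sigma=sigma,
            technique="SAXS",
            q_unit_in=q_unit or "nm^-1",
        )
    if kind == "mals":
        q = data[:, 0]
        if (q_unit or "um^-1") in ("nm^-1",):
            q = q * 1e3  # RayleighCurve stores um^-1
        return RayleighCurve(q=q, R_theta=data[:, 1], sigma=sigma)
    if kind == "dls":
        return CorrelationTrace(tau=data[:, 0], g2m1=data[:, 1], **metadata)
    raise ValueError(f"unknown curve kind {kind!r}; expected saxs|mals|dls")


def write_curve(
    path: str | Path,
    curve: ScatteringCurve | RayleighCurve | CorrelationTrace,
    header: str | None = None,
) -> None:
    """Write a curve in the same 2-3 column format the readers accept."""
    if isinstance(curve, ScatteringCurve):
        cols = [curve.q, curve.I] + ([curve.sigma] if curve.sigma is not None else [])
        default_header = "q[nm^-1] I[a.u.]" + (" sigma" if curve.sigma is not None else "")
    elif isinstance(curve, RayleighCurve):
        cols = [curve.q, curve.R_theta] + (
            [curve.sigma] if curve.sigma is not None else []
        )
        default_header = "q[um^-1] R_theta[cm^-1]" + (
            " sigma" if curve.sigma is not None else ""
        )
    elif isinstance(curve, CorrelationTrace):
        cols = [curve.tau, curve.g2m1]
        default_header = "tau[s] g2-1"
    else:
        raise TypeError(f"cannot write object of type {type(curve).__name__}")
    np.savetxt(
        path,
        np.column_stack(cols),
        header=header if header is not None else default_header,
        fmt="%.10g",
    )


# -- configuration -----------------------------------------------------

_KNOWN_STAGE_KEYS: dict[str, set[str]] = {
    "saxs": {"input", "fixture", "qmin", "qmax", "restarts", "q_unit", "noise_scale"},
    "mals": {"input", "fixture", "thickness", "init_R", "qmin", "qmax", "q_unit",
             "noise_scale"},
    "dls": {"input", "fixture", "beta", "lambda_reg", "basis", "q", "wavelength",
            "T", "eta", "median", "sigma_log", "noise_scale"},
    "fusion": {"bridge_qmin", "bridge_qmax"},
    "loading": {
        "lipid_film_mass", "hydration_volume", "hydration_drug_conc",
        "final_volume", "final_lipid_conc", "final_drug_conc", "drug_MW",
    },
}
_TOP_LEVEL_KEYS = {"seed", "stages"} | set(_KNOWN_STAGE_KEYS)


@dataclass
class PipelineConfig:
    """Validated per-stage parameter blocks for the pipeline driver.

    Unknown keys are rejected so silent typos cannot change a run;
    seeds are mandatory because the SAXS stage is multi-start.
    """

    seed: int
    stages: list[str] = field(default_factory=list)
    blocks: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _TOP_LEVEL_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must declare a seed")
        stages = list(raw.get("stages", []))
        for stage in stages:
            if stage not in _KNOWN_STAGE_KEYS:
                raise ValueError(f"unknown stage {stage!r}")
        blocks: dict[str, dict[str, Any]] = {}
        for stage, allowed in _KNOWN_STAGE_KEYS.items():
            block = dict(raw.get(stage, {}))
            bad = set(block) - allowed
            if bad:
                raise ValueError(f"unknown keys in {stage!r} block: {sorted(bad)}")
            if stage in ("saxs", "mals") and "input" in block and "q_unit" not in block:
                raise ValueError(
                    f"{stage!r} block reads a file and must declare its q_unit"
                )
            blocks[stage] = block
        return cls(seed=int(raw["seed"]), stages=stages, blocks=blocks)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)
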