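"""Pipeline driver: run the requested stages in dependency order and
emit a machine-readable report.

Each stage either reads an instrument file named in its config block
or, for fully synthetic runs, generates its input from a named fixture
("lip0" / "lipcas").  The fusion stage requires the SAXS and MALS fits
as upstream products.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from . import dls as dls_mod
from . import fusion as fusion_mod
from . import mals as mals_mod
from . import saxs as saxs_mod
from . import synth
from .fluorometry import PrepSpec, loading_percentages
from .io import PipelineConfig, read_curve
from .models import GaussianShellProfile, HollowSphereModel

#: execution order; fusion depends on saxs and mals
_STAGE_ORDER = ("saxs", "mals", "dls", "fusion", "loading")


class DependencyError(RuntimeError):
    """A stage's upstream product is missing."""


def _saxs_input(block: dict[str, Any], seed: int):
    if "input" in block:
        return read_curve(block["input"], kind="saxs", q_unit=block.get("q_unit"))
    fixture = synth.FIXTURES[block.get("fixture", "lip0")]["saxs"]
    noise = synth.NoiseModel(scale=block.get("noise_scale", 0.0), seed=seed)
    return synth.gen_saxs(fixture, noise=noise)


def _mals_input(block: dict[str, Any], seed: int):
    if "input" in block:
        return read_curve(block["input"], kind="mals", q_unit=block.get("q_unit"))
    fixture = synth.FIXTURES[block.get("fixture", "lip0")]["mals"]
    noise = synth.NoiseModel(scale=block.get("noise_scale", 0.0), seed=seed)
    return synth.gen_mals(fixture, noise=noise)


def _dls_input(block: dict[str, Any], seed: int):
    meta = {
        k: block[k] for k in ("q", "wavelength", "T", "eta") if k in block
    }
    if "input" in block:
        return read_curve(block["input"], kind="dls", **meta)
    dist = synth.lognormal_distribution(
        median=block.get("median", 45.0), sigma_log=block.get("sigma_log", 0.15)
    )
    noise = synth.NoiseModel(
        kind="gaussian-absolute", scale=block.get("noise_scale", 0.0), seed=seed
    )
    return synth.gen_dls(dist, beta=block.get("beta", 0.9), noise=noise, **meta)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> dict[str, Any]:
    """Execute the configured stages; return (and optionally write) the
    report bundle.

    The report is a plain dict (JSON-serializable); with ``outdir`` a
    ``report.json`` plus per-stage CSV tables are written.  The
    ``converged`` flag at top level is False if any fit failed.
    """
    report: dict[str, Any] = {"seed": config.seed, "stages": {}, "converged": True}
    products: dict[str, Any] = {}

    stages = [s for s in _STAGE_ORDER if s in config.stages]
    for stage in stages:
        block = config.blocks.get(stage, {})
        if stage == "saxs":
            curve = _saxs_input(block, config.seed)
            fit = saxs_mod.fit_saxs(
                curve,
                n_restarts=block.get("restarts", 8),
                seed=config.seed,
                qmin=block.get("qmin", 0.1),
                qmax=block.get("qmax", 5.0),
            )
            products["saxs_fit"] = fit
            products["saxs_curve"] = curve
            report["stages"]["saxs"] = {
                "params": fit.params,
                "uncertainties": fit.uncertainties,
                "d_nm": fit.d,
                "R_nm": fit.params["R"],
                "chi2_reduced": fit.chi2_reduced,
                "converged": fit.converged,
                "flags": fit.flags,
            }
            report["converged"] &= fit.converged
        elif stage == "mals":
            curve = _mals_input(block, config.seed)
            fit = mals_mod.fit_mals(
                curve,
                t_fixed=block.get("thickness", 4.0),
                init_R=block.get("init_R", 30.0),
                qmin=block.get("qmin", 5.0),
                qmax=block.get("qmax", 25.0),
            )
            products["mals_fit"] = fit
            products["mals_curve"] = curve
            report["stages"]["mals"] = {
                "params": fit.params,
                "uncertainties": fit.uncertainties,
                "R_nm": fit.params["R_mid"],
                "Rg_nm": fit.params.get("Rg"),
                "chi2_reduced": fit.chi2_reduced,
                "converged": fit.converged,
                "flags": fit.flags,
            }
            report["converged"] &= fit.converged
        elif stage == "dls":
            trace = _dls_input(block, config.seed)
            dist = dls_mod.invert_trace(
                trace,
                beta=block.get("beta"),
                lambda_reg=block.get("lambda_reg", "auto"),
            )
            basis = block.get("basis", "mass")
            if basis != "intensity":
                dist = dls_mod.reweight(dist, basis, q=trace.q * 1e-3)
            products["dls_dist"] = dist
            report["stages"]["dls"] = {
                "basis": dist.basis,
                "median_radius_nm": dist.median_radius(),
                "mean_radius_nm": dist.mean_radius(),
                "radii_nm": dist.radii.tolist(),
                "weights": dist.weights.tolist(),
            }
        elif stage == "fusion":
            for need in ("saxs_fit", "mals_fit"):
                if need not in products:
                    raise DependencyError(
                        f"fusion requires the {need.split('_')[0]} stage upstream"
                    )
            saxs_fit = products["saxs_fit"]
            mals_fit = products["mals_fit"]
            hollow = HollowSphereModel(
                R_mid=mals_fit.params["R_mid"], t=mals_fit.params["t"]
            )
            composite = fusion_mod.sew(
                products["mals_curve"],
                products["saxs_curve"],
                saxs_fit.profile(),
                hollow,
                mals_amplitude=mals_fit.params["amplitude"],
                bridge_window=(
                    block.get("bridge_qmin", 0.1),
                    block.get("bridge_qmax", 0.3),
                ),
            )
            products["composite"] = composite
            report["stages"]["fusion"] = {
                "saxs_scale": composite.saxs_scale,
                "n_points": int(composite.q.size),
                "q_nm": composite.q.tolist(),
                "P": composite.P.tolist(),
                "source": composite.source.tolist(),
            }
        elif stage == "loading":
            prep = PrepSpec(**block)
            rep = loading_percentages(prep)
            report["stages"]["loading"] = {
                "DL_percent": rep.DL_percent,
                "LE_percent": rep.LE_percent,
                "loaded_conc_mg_per_mL": rep.loaded_conc_mg_per_mL,
                "loaded_conc_nM": rep.loaded_conc_molar * 1e9,
            }

    report["converged"] = bool(report["converged"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        if "dls_dist" in products:
            d = products["dls_dist"]
            np.savetxt(
                outdir / "size_distribution.csv",
                np.column_stack([d.radii, d.weights]),
                header=f"radius[nm] weight[{d.basis}]",
                delimiter=",",
            )
        if "composite" in products:
            c = products["composite"]
            with open(outdir / "composite_pq.csv", "w") as fh:
                fh.write("q[nm^-1],P,source\n")
                for qi, pi, si in zip(c.q, c.P, c.source):
                    fh.write(f"{qi:.10g},{pi:.10g},{si}\n")
    return report
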