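"""Run configuration and pipeline orchestration.

A single structured-text (YAML) configuration file holds every tunable of
every stage; each stage writes CSV outputs plus a machine-readable JSON
manifest recording inputs, seeds and package versions, so any run can be
reproduced from its output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import GeneratorConfig, generate_cohort, write_cohort_csv
from .domain import DomainSpec, build_domain
from .gci import error_measures
from .metrics import characterize_curve, transient_metrics, vpd_sweep
from .morphometry import (
    AneurysmMorphometry,
    AneurysmShape,
    CoilSpec,
    aneurysm_volume,
    morphometric_indices,
    packing_metrics,
)
from .reference import GRID_TRIPLETS
from .rheology import BloodModel, DEFAULT_WIRE_DIAMETER_M, ergun_coefficients
from .solver import ProjectionSolver, default_waveform
from .stats import empirical_roc, group_comparison_table, logistic_fit
from .vtkio import write_vtk

logger = logging.getLogger("porocoil")

STAGES = ("morphometry", "sweep", "transient", "gci", "cohort")

DEFAULT_CONFIG: dict[str, Any] = {
    "stages": list(STAGES),
    "seed": 0,
    "blood": {
        "density_rho": 1050.0,
        "eta0": 0.035,
        "n_index": 0.6,
    },
    "porous": {"wire_diameter_m": DEFAULT_WIRE_DIAMETER_M},
    "domain": {
        "parent_diameter": 3.0e-3,
        "parent_length": 24.0e-3,
        "dome_radius": 2.5e-3,
        "neck_width": 3.0e-3,
        "grid_spacing": 3.0e-3 / 16,
    },
    "sweep": {
        "vpd_values": [0, 5, 10, 15, 20, 25, 30],
        "inflow_velocity": 0.35,
        "tol": 2.0e-6,
        "max_iter": 8000,
        "rfv_threshold": 0.01,
        "write_vtk": False,
    },
    "waveform": {
        "mean_velocity": 0.35,
        "period": 0.8,
        "t_peak_fraction": 0.22,
        "peak_to_mean": 2.0,
        "n_cycles": 5,
        "vpd_pct": 10.0,
        "samples_per_cycle": 24,
    },
    "morphometry": {
        "height_H": 6.0,
        "width_S": 5.0,
        "depth_D": 5.0,
        "neck_N": 3.5,
        "parent_P": 3.2,
        "hmax": 6.5,
        "shape": "spherical",
        "coils": [
            {"wire_diameter_inch": 0.010, "length_mm": 150.0, "is_first_coil": True},
            {"wire_diameter_inch": 0.010, "length_mm": 100.0},
        ],
    },
    "cohort": {
        "n_recan": 11,
        "n_no_recan": 55,
        "correlation_pd_vpd": 0.6,
        "predictor": "first_vpd_pct",
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    raw: dict[str, Any]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: Optional[dict] = None) -> "RunConfig":
        cfg = _merge(DEFAULT_CONFIG, user or {})
        unknown = [s for s in cfg["stages"] if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages in config: {unknown}")
        return cls(raw=cfg)

    def __getitem__(self, key):
        return self.raw[key]

    def blood_model(self) -> BloodModel:
        b = self.raw["blood"]
        return BloodModel(
            density_rho=b["density_rho"], eta0=b["eta0"], n_index=b["n_index"]
        )

    def domain_spec(self) -> DomainSpec:
        d = self.raw["domain"]
        return DomainSpec(
            parent_diameter=d["parent_diameter"],
            parent_length=d["parent_length"],
            dome_radius=d["dome_radius"],
            neck_width=d["neck_width"],
            grid_spacing=d["grid_spacing"],
        )


def run_pipeline(config: RunConfig, outdir, seed: Optional[int] = None) -> dict:
    """Execute the requested stages in dependency order.

    Returns the manifest (also written to ``manifest.json``).  A stage
    failure is recorded in the manifest and later independent stages still
    run; the function raises only if every requested stage failed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config["seed"])
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "config": config.raw,
        "stages": {},
        "outputs": [],
    }
    handlers = {
        "morphometry": _stage_morphometry,
        "sweep": _stage_sweep,
        "transient": _stage_transient,
        "gci": _stage_gci,
        "cohort": _stage_cohort,
    }
    requested = [s for s in STAGES if s in config["stages"]]
    n_fail = 0
    for stage in requested:
        try:
            outputs = handlers[stage](config, outdir, seed)
            manifest["stages"][stage] = {"status": "ok"}
            manifest["outputs"].extend(outputs)
            logger.info("stage %s: ok (%d outputs)", stage, len(outputs))
        except Exception as exc:  # recorded, pipeline continues
            n_fail += 1
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            logger.error("stage %s failed: %s", stage, exc)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if requested and n_fail == len(requested):
        raise RuntimeError("every requested pipeline stage failed; see manifest.json")
    return manifest


# ------------------------------------------------------------------ stages


def _stage_morphometry(config: RunConfig, outdir: Path, seed: int) -> list[str]:
    m = config["morphometry"]
    morph = AneurysmMorphometry(
        height_H=m["height_H"],
        width_S=m["width_S"],
        depth_D=m["depth_D"],
        neck_N=m["neck_N"],
        parent_P=m["parent_P"],
        hmax=m["hmax"],
        shape=AneurysmShape(m["shape"]),
        bilobed_components=(
            tuple(tuple(c) for c in m["bilobed_components"])
            if m.get("bilobed_components")
            else None
        ),
    )
    coils = [
        CoilSpec(
            wire_diameter_inch=c["wire_diameter_inch"],
            length_mm=c["length_mm"],
            is_first_coil=bool(c.get("is_first_coil", False)),
        )
        for c in m["coils"]
    ]
    vol = aneurysm_volume(morph)
    packing = packing_metrics(vol, coils)
    idx = morphometric_indices(morph)
    row = pd.DataFrame(
        [
            {
                "aneurysm_volume_mm3": vol,
                "total_coil_volume_mm3": packing.total_coil_volume_mm3,
                "first_coil_volume_mm3": packing.first_coil_volume_mm3,
                "packing_density_pct": packing.packing_density_pct,
                "first_vpd_pct": packing.first_vpd_pct,
                "aspect_ratio_AR": idx.aspect_ratio_AR,
                "size_ratio_SR": idx.size_ratio_SR,
                "neck_parent_ratio": idx.neck_parent_ratio,
            }
        ]
    )
    path = outdir / "morphometry.csv"
    row.to_csv(path, index=False)
    return [str(path)]


def _stage_sweep(config: RunConfig, outdir: Path, seed: int) -> list[str]:
    sw = config["sweep"]
    domain = build_domain(config.domain_spec())
    blood = config.blood_model()
    table, rows, fields = vpd_sweep(
        domain,
        blood,
        sw["vpd_values"],
        inflow_velocity=sw["inflow_velocity"],
        tol=sw["tol"],
        max_iter=sw["max_iter"],
        threshold=sw["rfv_threshold"],
    )
    outputs = []
    path = outdir / "sweep.csv"
    table.to_csv(path, index=False)
    outputs.append(str(path))
    if len(table) >= 5:  # curve shapes need enough sweep points
        desc_rows = []
        for col in ("wss_aneurysm", "rfv_av_pct", "pressure_aneurysm", "neck_velocity"):
            d = characterize_curve(table, col)
            desc_rows.append(asdict(d))
        dpath = outdir / "sweep_curve_shapes.csv"
        pd.DataFrame(desc_rows).to_csv(dpath, index=False)
        outputs.append(str(dpath))
    if sw.get("write_vtk"):
        for row, f in zip(rows, fields):
            vpath = outdir / f"field_vpd{row.vpd_pct:04.1f}.vtk"
            write_vtk(vpath, f, domain)
            outputs.append(str(vpath))
    return outputs


def _stage_transient(config: RunConfig, outdir: Path, seed: int) -> list[str]:
    wf_cfg = config["waveform"]
    domain = build_domain(config.domain_spec())
    blood = config.blood_model()
    waveform = default_waveform(
        wf_cfg["mean_velocity"],
        period=wf_cfg["period"],
        t_peak_fraction=wf_cfg["t_peak_fraction"],
        peak_to_mean=wf_cfg["peak_to_mean"],
        n_cycles=wf_cfg["n_cycles"],
    )
    porous = ergun_coefficients(wf_cfg["vpd_pct"], blood)
    solver = ProjectionSolver(domain, blood, porous)
    result = solver.solve_transient(
        waveform, samples_per_cycle=wf_cfg["samples_per_cycle"]
    )
    tm = transient_metrics(result, domain, blood, region="dome")
    summary = pd.DataFrame(
        [
            {
                "vpd_pct": wf_cfg["vpd_pct"],
                "tawss_avg": tm.tawss_avg,
                "osi_avg": tm.osi_avg,
                "osi_max": float(tm.osi_field.max()),
                "rfv_av_cycle_avg": tm.rfv_av_cycle_avg,
                "cycle_periodicity_rel": result.cycle_periodicity_rel,
            }
        ]
    )
    path = outdir / "transient_summary.csv"
    summary.to_csv(path, index=False)
    spath = outdir / "transient_rfv_series.csv"
    pd.DataFrame(tm.rfv_av_series, columns=["time_s", "rfv_av_pct"]).to_csv(
        spath, index=False
    )
    return [str(path), str(spath)]


def _stage_gci(config: RunConfig, outdir: Path, seed: int) -> list[str]:
    rows = []
    for name, triplet in GRID_TRIPLETS.items():
        rep = error_measures(triplet)
        rows.append({"probe": name, **asdict(rep)})
    path = outdir / "gci.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [str(path)]


def _stage_cohort(config: RunConfig, outdir: Path, seed: int) -> list[str]:
    c = config["cohort"]
    gen = GeneratorConfig(
        n_recan=c["n_recan"],
        n_no_recan=c["n_no_recan"],
        correlation_pd_vpd=c["correlation_pd_vpd"],
        seed=seed,
    )
    frame = generate_cohort(gen)
    outputs = []
    cpath = outdir / "cohort.csv"
    write_cohort_csv(frame, cpath, seed=seed)
    outputs.append(str(cpath))

    variables = [v.name for v in gen.variables]
    table = group_comparison_table(frame, "group", "recanalization", variables)
    tpath = outdir / "cohort_tests.csv"
    table.to_csv(tpath, index=False)
    outputs.append(str(tpath))

    labels = (frame["group"] == "recanalization").astype(int).to_numpy()
    roc = empirical_roc(frame[c["predictor"]].to_numpy(), labels, seed=seed)
    roc_points = pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    )
    rpath = outdir / "roc_points.csv"
    roc_points.to_csv(rpath, index=False)
    outputs.append(str(rpath))

    fit = logistic_fit(frame[[c["predictor"]]], labels)
    term = fit.term(c["predictor"])
    summary = pd.DataFrame(
        [
            {
                "predictor": c["predictor"],
                "auc": roc.auc,
                "auc_ci_low": roc.auc_ci[0],
                "auc_ci_high": roc.auc_ci[1],
                "youden_cutoff": roc.youden_cutoff,
                "sens_at_cutoff": roc.sens_at_cutoff,
                "spec_at_cutoff": roc.spec_at_cutoff,
                "direction": roc.direction,
                "odds_ratio": term.odds_ratio,
                "or_ci_low": term.or_ci[0],
                "or_ci_high": term.or_ci[1],
                "p_value": term.p_value,
                "seed": seed,
            }
        ]
    )
    spath = outdir / "cohort_summary.csv"
    summary.to_csv(spath, index=False)
    outputs.append(str(spath))
    return outputs
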