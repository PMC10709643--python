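"""End-to-end pipeline: raw or synthetic inputs -> thermo/kinetics/structure report.

The analysis sequence is the one the individual modules implement:
monomer:tetramer ratios -> K_D(T) -> ΔG°(T) -> constant-ΔC°p fit -> ΔH°/ΔS°;
time courses -> relaxation times -> rate constants; chromatograms -> peak
areas; structures -> hydrogen bonds, swap report, framework RMSD.  Stages run
in dependency order, each failure is contained and reported per stage, and a
run writes its resolved configuration beside the outputs so it can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import equilibrium, kinetics, sec, structure, synthetic, thermo

__all__ = ["ConfigSpec", "SyntheticConfig", "ReportBundle", "load_config", "run_pipeline"]


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 7
    delta_cp: float = 0.78  # kcal/mol/K
    t_h_C: float = 1.0
    t_s_C: float = 29.0
    temperatures_C: list[float] = Field(
        default_factory=lambda: list(synthetic.DEFAULT_TEMPERATURES_C)
    )
    concentrations_uM: list[float] = Field(
        default_factory=lambda: list(synthetic.DEFAULT_CONCENTRATIONS_UM)
    )
    ratio_noise_sd: float = 0.03
    timecourse_noise_sd: float = 0.01
    chromatogram_noise_sd: float = 0.002

    def ground_truth(self) -> synthetic.GroundTruth:
        return synthetic.GroundTruth(
            thermo=thermo.ThermoParams(
                delta_cp=self.delta_cp,
                t_h=equilibrium.celsius_to_kelvin(self.t_h_C),
                t_s=equilibrium.celsius_to_kelvin(self.t_s_C),
            ),
            ratio_noise_sd=self.ratio_noise_sd,
            timecourse_noise_sd=self.timecourse_noise_sd,
            chromatogram_noise_sd=self.chromatogram_noise_sd,
            seed=self.seed,
        )


class ConfigSpec(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    synthetic: Optional[SyntheticConfig] = None
    equilibrium_table: Optional[str] = None  # CSV: temperature_C, c_total_uM, f_mono, f_tet
    timecourses: dict[str, str] = Field(default_factory=dict)  # temperature_C -> CSV path
    chromatograms: list[str] = Field(default_factory=list)
    structure_path: Optional[str] = None
    structure_protomers: tuple[str, str] = ("A", "B")
    structure_dimer_groups: Optional[tuple[list[str], list[str]]] = None  # e.g. ([A,B],[C,D])

    run_thermo: bool = True
    run_kinetics: bool = True
    run_peaks: bool = True
    run_structure: bool = True

    output_dir: str = "tetraswap_out"
    seed: int = 0


@dataclass
class ReportBundle:
    stages: dict = field(default_factory=dict)  # name -> {"status": ..., ...}
    provenance: dict = field(default_factory=dict)

    @property
    def failed(self) -> list[str]:
        return [k for k, v in self.stages.items() if v.get("status") == "error"]

    def to_dict(self) -> dict:
        return {"stages": self.stages, "provenance": self.provenance}


def load_config(path: str | Path) -> ConfigSpec:
    """Load YAML or JSON configuration with schema validation."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return ConfigSpec(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round_floats(obj: Any, ndigits: int = 12) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _thermo_stage(config: ConfigSpec, truth: synthetic.GroundTruth | None, outdir: Path) -> dict:
    if config.equilibrium_table is not None:
        table = equilibrium.read_equilibrium_table(config.equilibrium_table)
        source = config.equilibrium_table
    elif truth is not None:
        syn = config.synthetic
        table = synthetic.generate_equilibrium_dataset(
            truth,
            temperatures=[equilibrium.celsius_to_kelvin(t) for t in syn.temperatures_C],
            concentrations=[c * 1e-6 for c in syn.concentrations_uM],
        )
        source = "synthetic"
    else:
        raise FileNotFoundError("thermo stage needs equilibrium_table or a synthetic block")

    kd_rows = []
    for _, row in table.iterrows():
        t_K = equilibrium.celsius_to_kelvin(row["temperature_C"])
        k = equilibrium.kd_from_ratio(row["f_mono"], row["c_total_uM"] * 1e-6, t_K)
        kd_rows.append(
            {
                "temperature_C": row["temperature_C"],
                "c_total_uM": row["c_total_uM"],
                "kd_M3": k.value,
                "delta_g_kcal_mol": thermo.delta_g_from_k(k),
            }
        )
    kd_table = pd.DataFrame(kd_rows)
    kd_table.to_csv(outdir / "kd_table.csv", index=False)

    # one ΔG° point per temperature: mean over concentrations
    points = [
        thermo.ThermoPoint(
            temperature=equilibrium.celsius_to_kelvin(t_C), delta_g=float(g["delta_g_kcal_mol"].mean())
        )
        for t_C, g in kd_table.groupby("temperature_C")
    ]
    fit = thermo.fit_thermo(points)
    thermo.write_fit_json(fit, outdir / "thermo_fit.json")
    t_lo = min(p.temperature for p in points)
    t_hi = max(p.temperature for p in points)
    return {
        "status": "ok" if fit.success else "error",
        "source": source,
        "n_measurements": int(len(kd_table)),
        "delta_cp_kcal_mol_K": fit.params.delta_cp,
        "t_h_C": equilibrium.kelvin_to_celsius(fit.params.t_h),
        "t_s_C": equilibrium.kelvin_to_celsius(fit.params.t_s),
        "rss": fit.rss,
        "delta_h_range_kcal_mol": [
            float(thermo.delta_h(fit.params, t_lo)),
            float(thermo.delta_h(fit.params, t_hi)),
        ],
        "delta_s_range_kcal_mol_K": [
            float(thermo.delta_s(fit.params, t_lo)),
            float(thermo.delta_s(fit.params, t_hi)),
        ],
        "kd_by_temperature_M3": {
            f"{t_C:g}": float(
                thermo.k_from_delta_g(
                    float(thermo.delta_g_model(fit.params, equilibrium.celsius_to_kelvin(t_C))),
                    equilibrium.celsius_to_kelvin(t_C),
                ).value
            )
            for t_C in sorted(kd_table["temperature_C"].unique())
        },
    }


def _kinetics_stage(config: ConfigSpec, truth: synthetic.GroundTruth | None, outdir: Path) -> dict:
    courses: dict[float, kinetics.TimeCourse] = {}
    if config.timecourses:
        for t_C, path in config.timecourses.items():
            df = pd.read_csv(path, comment="#")
            courses[equilibrium.celsius_to_kelvin(float(t_C))] = kinetics.TimeCourse(
                times=df["time_h"].to_numpy(float), f_tet=df["f_tet"].to_numpy(float)
            )
    elif truth is not None:
        syn = config.synthetic
        courses = synthetic.generate_timecourses(
            truth, temperatures=[equilibrium.celsius_to_kelvin(t) for t in syn.temperatures_C]
        )
    else:
        raise FileNotFoundError("kinetics stage needs timecourses or a synthetic block")

    rows = []
    for t_K in sorted(courses):
        fit = kinetics.fit_relaxation(courses[t_K])
        row = {
            "temperature_C": equilibrium.kelvin_to_celsius(t_K),
            "tau_h": fit.tau,
            "inverse_tau_per_h": 1.0 / fit.tau,
            "f0": fit.f0,
            "f_eq": fit.f_eq,
            "rms_residual": fit.rms_residual,
        }
        if truth is not None:
            c_obs = truth.c_stock / truth.dilution_factor
            rates = kinetics.k_off_from_tau(fit.tau, truth.kd(t_K), c_obs)
            row["k_off_per_h"] = rates.k_off
            row["k_on_per_M3_h"] = rates.k_on
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "kinetics.csv", index=False)
    return {
        "status": "ok",
        "n_timecourses": len(rows),
        "tau_h_by_temperature": {f"{r['temperature_C']:g}": r["tau_h"] for r in rows},
    }


def _peaks_stage(config: ConfigSpec, truth: synthetic.GroundTruth | None, outdir: Path) -> dict:
    chroms: list[tuple[str, sec.Chromatogram]] = []
    if config.chromatograms:
        for path in config.chromatograms:
            chroms.append((path, sec.read_chromatogram(path)))
    elif truth is not None:
        f25 = equilibrium.solve_speciation(
            truth.kd(equilibrium.celsius_to_kelvin(25.0)), truth.c_stock
        ).f_mono
        chrom, _ = synthetic.generate_chromatogram(truth, f25, artifact="chromatogram-300uM")
        chroms.append(("synthetic-300uM-25C", chrom))
    else:
        raise FileNotFoundError("peaks stage needs chromatograms or a synthetic block")

    results = {}
    for i, (name, chrom) in enumerate(chroms):
        fit = sec.fit_peaks(chrom, n_peaks=2)
        sec.write_peak_fit(chrom, fit, outdir / f"peak_fit_{i}.csv")
        results[name] = {
            "f_mono": fit.f_mono,
            "f_tet": 1.0 - fit.f_mono,
            "centers_mL": [p.center for p in fit.peaks],
            "rms_residual": fit.rms_residual,
        }
    return {"status": "ok", "fits": results}


def _structure_stage(config: ConfigSpec, truth: synthetic.GroundTruth | None, outdir: Path) -> dict:
    out: dict = {"status": "ok"}
    if config.structure_path is not None:
        model = structure.read_structure(config.structure_path)
        ca, cb = config.structure_protomers
        hbonds = structure.find_hbonds(model, ca, cb)
        out["interprotomer_hbonds"] = {
            "count": len(hbonds),
            "bonds": [hb.label() for hb in hbonds],
        }
        swap = structure.detect_swap(model, (ca, cb))
        out["swap"] = {
            "swapped_segments": swap.swapped_segments,
            "hinge_segments": swap.hinge_segments,
        }
        if config.structure_dimer_groups is not None:
            ga, gb = config.structure_dimer_groups
            rep = structure.interface_report(model, ga, gb)
            out["dimer_interface"] = {
                "hbond_count": rep.n_hbonds,
                "bonds": [hb.label() for hb in rep.hydrogen_bonds],
                "hydrophobic_cluster": list(rep.hydrophobic_cluster),
            }
    elif truth is not None:
        toys = synthetic.generate_toy_structures(truth)
        ladder_bonds = structure.find_hbonds(toys.beta_ladder, "A", "B")
        swap = structure.detect_swap(toys.swapped, ("A", "B"))
        no_swap = structure.detect_swap(toys.unswapped, ("A", "B"))
        out["toy"] = {
            "beta_ladder_hbonds": len(ladder_bonds),
            "declared_hbonds": len(toys.declared_bonds),
            "swapped_segments": swap.swapped_segments,
            "declared_swap_range": list(toys.swap_range),
            "unswapped_segments": no_swap.swapped_segments,
        }
    else:
        raise FileNotFoundError("structure stage needs structure_path or a synthetic block")
    (outdir / "structure_report.json").write_text(
        json.dumps(_round_floats(out), indent=2, sort_keys=True)
    )
    return out


def run_pipeline(config: ConfigSpec) -> ReportBundle:
    """Execute all enabled stages; contain per-stage failures.

    Writes the resolved config, per-stage tables and a consolidated
    ``report.json`` under ``config.output_dir``.  Deterministic under a fixed
    configuration: numeric report sections are byte-identical across reruns.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=True)
    )
    truth = config.synthetic.ground_truth() if config.synthetic is not None else None

    bundle = ReportBundle()
    stages = {
        "thermo": (config.run_thermo, _thermo_stage),
        "kinetics": (config.run_kinetics, _kinetics_stage),
        "peaks": (config.run_peaks, _peaks_stage),
        "structure": (config.run_structure, _structure_stage),
    }
    for name, (enabled, fn) in stages.items():
        if not enabled:
            bundle.stages[name] = {"status": "skipped"}
            continue
        try:
            bundle.stages[name] = fn(config, truth, outdir)
        except Exception as exc:  # contained per stage, reported in the bundle
            bundle.stages[name] = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}

    digests = {}
    for p in [config.equilibrium_table, config.structure_path, *config.chromatograms,
              *config.timecourses.values()]:
        if p and Path(p).exists():
            digests[p] = _sha256(Path(p))
    try:
        ver = pkg_version("tetraswap")
    except PackageNotFoundError:
        ver = "unknown"
    bundle.provenance = {
        "package_version": ver,
        "seed": config.seed,
        "synthetic_seed": config.synthetic.seed if config.synthetic else None,
        "input_digests": digests,
    }
    (outdir / "report.json").write_text(
        json.dumps(_round_floats(bundle.to_dict()), indent=2, sort_keys=True)
    )
    return bundle
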