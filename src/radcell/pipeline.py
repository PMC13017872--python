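"""End-to-end orchestration: plan -> speciate -> simulate/ingest -> fit ->
RBE -> images -> report.

Each stage writes plain files (CSV/JSON/TIFF) into the output directory;
rerunning with the same configuration and seed reproduces them exactly
(the report isolates its timestamp in a single field so everything else
is byte-identical).  A stage failure leaves the outputs of earlier stages
on disk and is reported with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__, clonogenic, dosimetry, imaging, speciation, synthetic

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("radcell")

ALL_STAGES = ("plan", "speciate", "simulate", "fit", "rbe", "imaging")


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.  All values have defaults that
    reproduce the study design with synthetic data."""

    outdir: str = "radcell_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # dosimetry
    half_life_days: float = dosimetry.AG111.half_life_days
    s_medium: float = dosimetry.S_MEDIUM_CALIBRATED
    s_cytoplasm: float = dosimetry.S_CYTOPLASM_TO_NUCLEUS
    cytoplasm_volume_um3: float = dosimetry.DEFAULT_CYTOPLASM_VOLUME_UM3
    doses_gy: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    exposure_days: tuple[float, ...] = (4.0, 6.0)
    # speciation
    total_ag: float = speciation.ADMINISTERED_SOLUTION.total_ag
    total_cl: float = speciation.ADMINISTERED_SOLUTION.total_cl
    # clonogenic simulation / fitting
    colony_csv: str | None = None   # ingest instead of simulating when set
    arm_alpha_beta: dict = field(default_factory=lambda: {
        4.0: (0.4, 0.03), 6.0: (0.5, 0.04)})
    cells_seeded: int = 1000
    pe0: float = 0.5
    replicates: int = 3
    rbe_reference_alpha_beta: tuple[float, float] = (0.12, 0.06)
    rbe_endpoints: tuple[float, ...] = (0.1,)
    # imaging simulation
    n_nuclei: int = 40
    foci_per_nucleus: int = 7
    mn_frequency: float = 0.10

    @property
    def physics(self) -> dosimetry.RadionuclidePhysics:
        return dosimetry.RadionuclidePhysics("nuclide", self.half_life_days)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("stages", "doses_gy", "exposure_days", "rbe_endpoints",
                "rbe_reference_alpha_beta"):
        if key in data:
            data[key] = tuple(data[key])
    if "arm_alpha_beta" in data:
        data["arm_alpha_beta"] = {float(k): tuple(v)
                                  for k, v in data["arm_alpha_beta"].items()}
    return RunConfig(**data)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the
    analysis report (also written to ``<outdir>/report.json`` with a
    markdown summary)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": "radcell",
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "config": dataclasses.asdict(config),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        "assumptions": {
            "cytoplasm_volume_um3": config.cytoplasm_volume_um3,
        },
    }

    plans: list[dosimetry.ExposurePlan] = []
    tables = None
    fits: dict[str, clonogenic.LQFit] = {}

    stage = "none"
    try:
        if "plan" in config.stages:
            stage = "plan"
            plans = [dosimetry.plan_exposure(config.doses_gy, t,
                                             config.s_medium, config.physics)
                     for t in config.exposure_days]
            report["exposure_plans"] = []
            for plan in plans:
                path = out / f"plan_{plan.exposure_days:g}d.csv"
                plan.to_csv(path)
                report["exposure_plans"].append({
                    "exposure_days": plan.exposure_days,
                    "doses_Gy": list(plan.target_doses_gy),
                    "activity_kBq_per_mL": list(plan.activity_kbq_per_ml),
                    "activity_kBq_per_mL_rounded": [
                        round(a) for a in plan.activity_kbq_per_ml],
                    "file": path.name,
                })
            excess = dosimetry.internalization_excess(
                dosimetry.SValueSet(config.s_medium, config.s_cytoplasm),
                dosimetry.CellGeometry(config.cytoplasm_volume_um3),
                exposure_days=max(config.exposure_days, default=4.0),
                physics=config.physics)
            report["internalization_excess_fraction"] = excess
            log.info("plan: %d exposure arms, internalization excess %.3g",
                     len(plans), excess)

        if "speciate" in config.stages:
            stage = "speciate"
            result = speciation.speciate(
                speciation.SolutionComposition(config.total_ag, config.total_cl))
            report["speciation"] = result.as_dict()
            (out / "speciation.json").write_text(
                json.dumps(result.as_dict(), indent=2))
            log.info("speciate: AgCl2- fraction %.3f, saturated=%s",
                     result.fraction_agcl2, result.saturated)

        if "simulate" in config.stages or "fit" in config.stages:
            stage = "simulate"
            if config.colony_csv is not None:
                records = clonogenic.read_colony_csv(config.colony_csv)
                tables = {}
                for t in sorted({r.exposure_days for r in records}):
                    tables[t] = [r for r in records if r.exposure_days == t]
                log.info("ingest: %d dishes from %s", len(records),
                         config.colony_csv)
            else:
                base = synthetic.ClonogenicSimConfig(
                    doses_gy=tuple(config.doses_gy),
                    cells_seeded=config.cells_seeded, pe0=config.pe0,
                    replicates=config.replicates)
                _, tables = synthetic.generate_exposure_dataset(
                    doses_gy=config.doses_gy,
                    exposure_days=config.exposure_days,
                    arm_params=config.arm_alpha_beta,
                    s_medium=config.s_medium, physics=config.physics,
                    base_config=base, seed=config.seed)
                for t, recs in tables.items():
                    clonogenic.records_to_frame(recs).to_csv(
                        out / f"colonies_{t:g}d.csv", index=False)
                log.info("simulate: %d arms", len(tables))

        if "fit" in config.stages and tables:
            stage = "fit"
            report["lq_fits"] = {}
            for t, recs in tables.items():
                fit = clonogenic.fit_lq_from_records(recs)
                fits[f"{t:g}d"] = fit
                report["lq_fits"][f"{t:g}d"] = fit.as_dict()
                log.info("fit %gd: alpha=%.3f beta=%.3f", t, fit.alpha, fit.beta)
            (out / "lq_fits.json").write_text(json.dumps(
                report["lq_fits"], indent=2))

        if "rbe" in config.stages and fits:
            stage = "rbe"
            ref = config.rbe_reference_alpha_beta
            report["rbe"] = {}
            for name, fit in fits.items():
                for sf in config.rbe_endpoints:
                    report["rbe"][f"{name}_sf{sf:g}"] = clonogenic.rbe(
                        (fit.alpha, fit.beta), ref, sf)
            log.info("rbe: %s", report["rbe"])

        if "imaging" in config.stages:
            stage = "imaging"
            cfg = synthetic.ImageSimConfig(
                n_nuclei=config.n_nuclei,
                foci_per_nucleus=config.foci_per_nucleus,
                mn_frequency=config.mn_frequency, seed=config.seed)
            dapi, focus, truth = synthetic.generate_image_pair(cfg)
            tifffile.imwrite(out / "synthetic_dapi.tif",
                             dapi.astype(np.float32))
            tifffile.imwrite(out / "synthetic_foci.tif",
                             focus.astype(np.float32))
            labels, nuclei = imaging.segment_nuclei(dapi)
            foci = imaging.detect_foci(focus, labels, nuclei)
            mn = imaging.detect_micronuclei(dapi, labels, nuclei)
            groups = {g: 0 for g in imaging.FOCI_GROUPS}
            for rec in foci:
                groups[rec.group] += 1
            report["imaging"] = {
                "n_nuclei_detected": len(nuclei),
                "n_nuclei_planted": int(cfg.n_nuclei),
                "mean_foci_per_nucleus": (
                    float(np.mean([r.n_foci for r in foci])) if foci else 0.0),
                "planted_foci_per_nucleus": cfg.foci_per_nucleus,
                "foci_group_counts": groups,
                "mn_frequency": mn.frequency,
                "mn_frequency_se": mn.se,
                "planted_mn_frequency": cfg.mn_frequency,
            }
            log.info("imaging: %d nuclei, %.2f foci/nucleus, MN freq %.3f",
                     len(nuclei), report["imaging"]["mean_foci_per_nucleus"],
                     mn.frequency)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "report.md").write_text(_markdown_summary(report))
    return report


def _markdown_summary(report: dict) -> str:
    lines = ["# radcell analysis report", ""]
    prov = report["provenance"]
    lines += [f"- package: radcell {prov['version']}",
              f"- seed: {prov['seed']}",
              f"- config hash: {prov['config_hash']}", ""]
    if "exposure_plans" in report:
        lines.append("## Exposure plans")
        for plan in report["exposure_plans"]:
            rounded = plan["activity_kBq_per_mL_rounded"]
            lines.append(f"- {plan['exposure_days']:g} d: doses "
                         f"{plan['doses_Gy']} Gy -> {rounded} kBq/mL")
        if "internalization_excess_fraction" in report:
            pct = 100 * report["internalization_excess_fraction"]
            lines.append(f"- cytoplasmic-internalization dose excess: "
                         f"{pct:.2f}% (assumed cytoplasm volume "
                         f"{report['assumptions']['cytoplasm_volume_um3']:g} um^3)")
        lines.append("")
    if "speciation" in report:
        s = report["speciation"]
        lines += ["## Ag-Cl speciation",
                  f"- AgCl2-: {100 * s['fraction_agcl2']:.0f}%, AgCl: "
                  f"{100 * s['fraction_agcl']:.0f}%, free Ag+: "
                  f"{100 * s['fraction_free_ag']:.2g}%",
                  f"- saturated: {s['saturated']}", ""]
    if "lq_fits" in report:
        lines.append("## Linear-quadratic fits")
        for name, fit in report["lq_fits"].items():
            lines.append(
                f"- {name}: alpha = {fit['alpha_per_Gy']:.3f} +/- "
                f"{fit['alpha_se']:.3f} Gy^-1, beta = {fit['beta_per_Gy2']:.3f} "
                f"+/- {fit['beta_se']:.3f} Gy^-2")
        lines.append("")
    if "rbe" in report:
        lines.append("## RBE")
        for key, val in report["rbe"].items():
            lines.append(f"- {key}: {val:.2f}")
        lines.append("")
    if "imaging" in report:
        im = report["imaging"]
        lines += ["## Imaging",
                  f"- nuclei detected: {im['n_nuclei_detected']} of "
                  f"{im['n_nuclei_planted']} planted",
                  f"- mean foci/nucleus: {im['mean_foci_per_nucleus']:.2f} "
                  f"(planted {im['planted_foci_per_nucleus']})",
                  f"- micronucleus frequency: {100 * im['mn_frequency']:.1f}% "
                  f"+/- {100 * im['mn_frequency_se']:.1f}% "
                  f"(planted {100 * im['planted_mn_frequency']:.0f}%)", ""]
    return "\n".join(lines)
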