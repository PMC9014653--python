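"""Pipeline orchestration: simulate -> qc -> reduce -> modules -> associate,
with a manifest, per-stage logging, and a summary report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brain, networks, preprocess, sexdiff
from .synthetic import ModuleSpec, SimulationConfig, generate_cohort, read_fixtures, write_fixtures

log = logging.getLogger("metabsex")

__all__ = ["PipelineConfig", "run_pipeline", "summarize"]

STAGES = ("simulate", "qc", "reduce", "modules", "associate")


@dataclass
class PipelineConfig:
    """All stage parameters, with defaults matching the reference protocol."""

    seed: int = 0
    platform: str = "targeted"
    # simulate
    n_participants: int = 800
    sex_ratio: float = 0.5
    n_metabolites: int = 60
    module_sizes: tuple = (20, 15)
    module_rho: tuple = (0.8, 0.7)
    module_effects_f: tuple = (0.0, 0.0)
    module_effects_m: tuple = (0.0, 0.0)
    n_plates: int = 4
    plate_effect_sd: float = 0.10
    lod_quantile: float = 0.02
    replicate_fraction: float = 0.10
    replicate_noise_sd: float = 0.05
    diagnosis_probs: tuple = (0.4, 0.4, 0.2)
    # qc
    metabolite_missing_max: float = 0.20
    participant_missing_max: float = 0.40
    cv_max: float = 0.20
    icc_min: float = 0.65
    winsor_limit: float = 3.0
    mahalanobis_alpha: float = 0.001
    manual_exclusions: tuple = ()
    # reduce
    n_components: int = 5
    variance_target: float = 0.95
    score_outlier_alpha: float = 0.001
    # modules
    beta: float = 10.0
    min_cluster_size: int = 5
    merge_r: float = 0.9
    # associate
    overall_alpha: float = 1e-5
    nominal_alpha: float = 0.05
    include_metabolites: bool = True

    def validate(self) -> None:
        checks = {
            "n_participants": self.n_participants > 0,
            "sex_ratio": 0 <= self.sex_ratio <= 1,
            "metabolite_missing_max": 0 < self.metabolite_missing_max <= 1,
            "participant_missing_max": 0 < self.participant_missing_max <= 1,
            "cv_max": self.cv_max >= 0,
            "icc_min": 0 <= self.icc_min <= 1,
            "winsor_limit": self.winsor_limit > 0,
            "mahalanobis_alpha": 0 < self.mahalanobis_alpha <= 1,
            "n_components": self.n_components >= 1,
            "variance_target": 0 <= self.variance_target <= 1,
            "beta": self.beta >= 1,
            "min_cluster_size": self.min_cluster_size >= 1,
            "merge_r": 0 < self.merge_r <= 1,
            "overall_alpha": 0 < self.overall_alpha < 1,
            "nominal_alpha": 0 < self.nominal_alpha < 1,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid pipeline configuration field(s): {bad}")
        if len({len(self.module_sizes), len(self.module_rho), len(self.module_effects_f), len(self.module_effects_m)}) != 1:
            raise ValueError("module_sizes, module_rho and module_effects_* must have equal length")

    def simulation_config(self) -> SimulationConfig:
        spec = tuple(
            ModuleSpec(size=s, rho=r, effect_f=ef, effect_m=em)
            for s, r, ef, em in zip(
                self.module_sizes, self.module_rho, self.module_effects_f, self.module_effects_m
            )
        )
        return SimulationConfig(
            n_participants=self.n_participants,
            sex_ratio=self.sex_ratio,
            n_metabolites=self.n_metabolites,
            module_spec=spec,
            n_plates=self.n_plates,
            plate_effect_sd=self.plate_effect_sd,
            lod_quantile=self.lod_quantile,
            replicate_fraction=self.replicate_fraction,
            replicate_noise_sd=self.replicate_noise_sd,
            diagnosis_probs=tuple(self.diagnosis_probs),
            platform=self.platform,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def run_pipeline(config: PipelineConfig, outdir, stages=STAGES) -> Path:
    """Execute the requested stages in order; each stage reads the previous
    stage's files from ``outdir``.  Writes a manifest with the dimension
    trajectory and parameter echo.  Raises on the first failing stage."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "config": dataclasses.asdict(config)}
    for k, v in manifest["config"].items():
        if isinstance(v, tuple):
            manifest["config"][k] = list(v)

    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            log.info("stage %s", stage)
            entry = {"stage": stage}
            if stage == "simulate":
                cohort = generate_cohort(config.simulation_config())
                write_fixtures(cohort, outdir / "fixtures")
                entry["n_participants"] = int(cohort.covariates.shape[0])
                entry["n_records"] = int(cohort.raw.n_records)
                entry["n_metabolites"] = int(cohort.raw.n_metabolites)
            elif stage == "qc":
                cohort = read_fixtures(outdir / "fixtures")
                clean, report = preprocess.run_qc(
                    cohort.raw,
                    metabolite_missing_max=config.metabolite_missing_max,
                    participant_missing_max=config.participant_missing_max,
                    cv_max=config.cv_max,
                    icc_min=config.icc_min,
                    winsor_limit=config.winsor_limit,
                    mahalanobis_alpha=config.mahalanobis_alpha,
                    manual_exclusions=config.manual_exclusions,
                    medications=cohort.medications if cohort.medications.shape[1] else None,
                )
                clean.matrix.to_csv(outdir / "clean_matrix.tsv", sep="\t")
                with open(outdir / "qc_report.json", "w") as fh:
                    json.dump(report.to_dict(), fh, indent=1)
                entry["n_participants"] = int(clean.matrix.shape[0])
                entry["n_metabolites"] = int(clean.matrix.shape[1])
            elif stage == "reduce":
                cohort = read_fixtures(outdir / "fixtures")
                clean_idx = pd.read_csv(outdir / "clean_matrix.tsv", sep="\t", index_col=0).index
                keep = cohort.brain.index.intersection(clean_idx)
                vols = brain.normalize_volumes(cohort.brain.loc[keep])
                dx3 = brain.consolidate_diagnosis(cohort.covariates.loc[keep, "diagnosis"])
                model = brain.fit_plsda(vols, dx3, n_components=config.n_components)
                sel = brain.select_components(model, config.variance_target)
                flagged = brain.score_outlier_screen(model, sel, alpha=config.score_outlier_alpha)
                scores = model.scores.drop(index=flagged).iloc[:, sel]
                scores.to_csv(outdir / "scores.tsv", sep="\t")
                vip = brain.vip_scores(model)
                with open(outdir / "model.json", "w") as fh:
                    json.dump(
                        {
                            "predictors": model.predictors,
                            "classes": model.classes,
                            "x_weights": model.x_weights.tolist(),
                            "x_loadings": model.x_loadings.tolist(),
                            "y_loadings": model.y_loadings.tolist(),
                            "x_variance": model.x_variance.tolist(),
                            "y_variance": model.y_variance.tolist(),
                            "vip": vip.to_dict(),
                            "selected_components": [int(s) for s in sel],
                            "score_outliers": list(map(str, flagged)),
                        },
                        fh,
                        indent=1,
                    )
                entry["n_participants"] = int(scores.shape[0])
                entry["n_components"] = int(scores.shape[1])
            elif stage == "modules":
                clean = pd.read_csv(outdir / "clean_matrix.tsv", sep="\t", index_col=0)
                net = networks.build_network(clean, beta=config.beta)
                part = networks.cluster_modules(net, min_cluster_size=config.min_cluster_size)
                eig = networks.compute_eigen(clean, part)
                if len(part.modules()) >= 2:
                    part, eig = networks.merge_close_modules(clean, part, eig, merge_r=config.merge_r)
                mods = pd.DataFrame(
                    {"module_label": part.labels, "module_membership": eig.membership}
                )
                mods.index.name = "metabolite_id"
                mods.to_csv(outdir / "modules.tsv", sep="\t")
                eig.eigens.to_csv(outdir / "eigens.tsv", sep="\t")
                entry["n_modules"] = int(len(part.modules()))
                entry["n_unassigned"] = int((part.labels == networks.GREY).sum())
            elif stage == "associate":
                clean = pd.read_csv(outdir / "clean_matrix.tsv", sep="\t", index_col=0)
                eigens = pd.read_csv(outdir / "eigens.tsv", sep="\t", index_col=0)
                scores = pd.read_csv(outdir / "scores.tsv", sep="\t", index_col=0)
                cohort = read_fixtures(outdir / "fixtures")
                keep = clean.index.intersection(scores.index)
                results, plan = sexdiff.run_association_study(
                    clean.loc[keep],
                    eigens.loc[keep],
                    scores.loc[keep],
                    cohort.covariates.loc[keep],
                    overall_alpha=config.overall_alpha,
                    nominal_alpha=config.nominal_alpha,
                    include_metabolites=config.include_metabolites,
                )
                results.to_csv(outdir / "associations.tsv", sep="\t", index=False)
                with open(outdir / "plan.json", "w") as fh:
                    json.dump(plan.to_dict(), fh, indent=1)
                report = summarize(results)
                with open(outdir / "report.json", "w") as fh:
                    json.dump(report, fh, indent=1)
                (outdir / "report.txt").write_text(format_report(report))
                entry["n_associations"] = int(len(results))
            manifest["stages"].append(entry)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def summarize(results: pd.DataFrame) -> dict:
    """Counts per classification category per unit type per component, plus the
    list of screen-flagged associations."""
    if len(results) == 0:
        return {"n_associations": 0, "categories": {}, "winkler_significant": []}
    cats = {}
    grouped = results.groupby(["unit_type", "component", "arnold_category"]).size()
    for (unit_type, component, cat), n in grouped.items():
        cats.setdefault(unit_type, {}).setdefault(str(component), {})[cat] = int(n)
    winkler = results.loc[
        results.get("winkler_any", pd.Series(False, index=results.index)).astype(bool),
        ["unit", "unit_type", "component"],
    ]
    return {
        "n_associations": int(len(results)),
        "categories": cats,
        "category_totals": {k: int(v) for k, v in results["arnold_category"].value_counts().items()},
        "winkler_significant": winkler.to_dict(orient="records"),
    }


def format_report(report: dict) -> str:
    lines = [f"associations: {report['n_associations']}"]
    for cat, n in sorted(report.get("category_totals", {}).items()):
        lines.append(f"  {cat}: {n}")
    lines.append(f"screen-flagged: {len(report.get('winkler_significant', []))}")
    for rec in report.get("winkler_significant", []):
        lines.append(f"  {rec['unit_type']} {rec['unit']} x {rec['component']}")
    return "\n".join(lines) + "\n"
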