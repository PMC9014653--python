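"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the downstream pipeline assumes: block
correlated metabolite panels built from latent factors, multiplicative plate
effects, left-censoring at per-plate detection limits, duplicate replicates,
diagnosis-linked brain atrophy (with ventricular enlargement), and per-sex
metabolite/brain-axis effects.  Every injected signal is stored in the truth
record so recovery can be tested.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import BELOW_QUANT_TAG, RawMetaboliteData

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "inject_outliers",
    "write_fixtures",
    "read_fixtures",
    "ConfigError",
]

SEGMENTS = ("ventricles", "hippocampus", "entorhinal", "fusiform", "midtemporal", "wholebrain")

#: baseline segment/ICV ratios (rough adult magnitudes, mm^3 / mm^3)
_BASE_RATIO = np.array([0.025, 0.005, 0.0025, 0.012, 0.014, 0.70])
#: direction of the per-level diagnosis shift (ventricles enlarge, rest atrophy)
_ATROPHY_DIR = np.array([-2.0, 1.0, 1.0, 0.6, 0.6, 0.3])

DIAGNOSIS6 = ("CN", "SMC", "EMCI", "MCI", "LMCI", "AD")


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class ModuleSpec:
    """One planted metabolite module.

    ``effect_f`` / ``effect_m`` are the per-sex loadings of the module's
    latent factor on the disease-severity brain axis (the axis that drives
    atrophy and that the first brain component recovers downstream).
    """

    size: int
    rho: float
    effect_f: float = 0.0
    effect_m: float = 0.0


@dataclass
class SimulationConfig:
    n_participants: int = 1000
    sex_ratio: float = 0.5  # fraction female
    n_metabolites: int = 60
    module_spec: tuple[ModuleSpec, ...] = (ModuleSpec(20, 0.8), ModuleSpec(15, 0.7))
    n_plates: int = 4
    plate_effect_sd: float = 0.10  # multiplicative, log scale
    lod_quantile: float = 0.02
    replicate_fraction: float = 0.10
    replicate_noise_sd: float = 0.05
    diagnosis_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # CN, MCI, AD
    atrophy_effects: np.ndarray | None = None  # (3 levels x 6 segments), log-ratio units
    nonfasting_fraction: float = 0.0
    contaminated_fraction: float = 0.0  # NMR: records with a non-censoring QC tag
    n_medications: int = 0
    medication_prevalence: float = 0.25
    medication_effects: tuple[tuple[int, int, float], ...] = ()  # (med idx, metabolite idx, z-shift)
    brain_noise_sd: float = 0.08  # per-segment log-ratio noise
    severity_noise_sd: float = 0.3  # noise on the latent brain axis
    platform: str = "targeted"
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise ConfigError("sex_ratio must be in [0, 1]")
        if self.n_metabolites <= 0:
            raise ConfigError("n_metabolites must be positive")
        for i, spec in enumerate(self.module_spec):
            if spec.size <= 0:
                raise ConfigError(f"module_spec[{i}].size must be positive")
            if not 0 <= spec.rho < 1:
                raise ConfigError(f"module_spec[{i}].rho must be in [0, 1)")
        if sum(s.size for s in self.module_spec) > self.n_metabolites:
            raise ConfigError("sum of module sizes exceeds n_metabolites")
        if self.n_plates <= 0:
            raise ConfigError("n_plates must be positive")
        if self.plate_effect_sd < 0:
            raise ConfigError("plate_effect_sd must be >= 0")
        if not 0 <= self.lod_quantile < 1:
            raise ConfigError("lod_quantile must be in [0, 1)")
        if not 0 <= self.replicate_fraction <= 1:
            raise ConfigError("replicate_fraction must be in [0, 1]")
        if self.replicate_noise_sd < 0:
            raise ConfigError("replicate_noise_sd must be >= 0")
        probs = np.asarray(self.diagnosis_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ConfigError("diagnosis_probs must be a 3-vector summing to 1")
        if self.platform not in ("targeted", "nmr"):
            raise ConfigError(f"platform must be 'targeted' or 'nmr', got {self.platform!r}")
        if self.atrophy_effects is not None:
            arr = np.asarray(self.atrophy_effects, dtype=float)
            if arr.shape not in ((3, 6), (6,)):
                raise ConfigError("atrophy_effects must have shape (3, 6) or (6,)")

    def resolved_atrophy(self) -> np.ndarray:
        if self.atrophy_effects is None:
            return np.outer([0.0, 0.15, 0.30], _ATROPHY_DIR)
        arr = np.asarray(self.atrophy_effects, dtype=float)
        if arr.shape == (6,):
            return np.outer([0.0, 1.0, 2.0], arr)
        return arr


@dataclass
class SyntheticCohort:
    covariates: pd.DataFrame  # participant: age, sex, education, apoe4, diagnosis, fasting
    brain: pd.DataFrame  # participant: 6 segments + icv (mm^3)
    raw: RawMetaboliteData
    medications: pd.DataFrame
    truth: dict
    config: SimulationConfig

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            covariates=self.covariates.copy(),
            brain=self.brain.copy(),
            raw=self.raw.copy(),
            medications=self.medications.copy(),
            truth=json.loads(json.dumps(self.truth)),
            config=self.config,
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    # fixed-offset sub-streams from a single cohort seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a cohort; deterministic given ``config.seed``."""
    config.validate()
    n = config.n_participants
    pids = [f"P{i:05d}" for i in range(n)]

    # --- covariates -------------------------------------------------------
    rng = _rng(config.seed, 0)
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    age = np.clip(rng.normal(73.0, 7.0, n), 55, 95).round(1)
    education = np.clip(rng.normal(16.0, 2.7, n), 6, 20).round(0)
    apoe4 = rng.choice([0, 1, 2], size=n, p=[0.55, 0.35, 0.10])
    dx3 = rng.choice([0, 1, 2], size=n, p=np.asarray(config.diagnosis_probs, dtype=float))
    # split consolidated groups into the six clinical labels
    six = np.empty(n, dtype=object)
    u = rng.random(n)
    six[dx3 == 0] = np.where(u[dx3 == 0] < 0.7, "CN", "SMC")
    mci_lab = np.array(["EMCI", "MCI", "LMCI"], dtype=object)
    six[dx3 == 1] = mci_lab[(u[dx3 == 1] * 3).astype(int).clip(0, 2)]
    six[dx3 == 2] = "AD"
    fasting = rng.random(n) >= config.nonfasting_fraction

    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "education": education,
            "apoe4": apoe4,
            "diagnosis": six,
            "fasting": fasting,
        },
        index=pd.Index(pids, name="participant_id"),
    )

    # --- latent brain axis and volumes -----------------------------------
    rng_b = _rng(config.seed, 1)
    sev_raw = dx3 + config.severity_noise_sd * rng_b.normal(size=n)
    severity = (sev_raw - sev_raw.mean()) / max(sev_raw.std(), 1e-12)

    atrophy = config.resolved_atrophy()  # (3, 6)
    # continuous severity drives the same per-segment pattern as the level means
    per_unit = (atrophy[2] - atrophy[0]) / 2.0
    level_scale = sev_raw  # in diagnosis-level units
    shift = np.outer(level_scale, per_unit)
    noise = config.brain_noise_sd * rng_b.normal(size=(n, 6))
    icv = rng_b.normal(1.5e6, 1.2e5, size=n).clip(1.0e6, 2.0e6)
    ratios = _BASE_RATIO * np.exp(-shift + noise)
    brain = pd.DataFrame(ratios * icv[:, None], index=covariates.index, columns=SEGMENTS)
    brain["icv"] = icv

    # --- metabolite latent structure --------------------------------------
    rng_m = _rng(config.seed, 2)
    labels = np.zeros(config.n_metabolites, dtype=int)  # 0 = noise/unassigned
    z = rng_m.normal(size=(n, config.n_metabolites))
    pos = 0
    is_f = sex == "F"
    truth_modules = []
    for mi, spec in enumerate(config.module_spec, start=1):
        cols = np.arange(pos, pos + spec.size)
        pos += spec.size
        labels[cols] = mi
        effect = np.where(is_f, spec.effect_f, spec.effect_m)
        if np.any(np.abs(effect) >= 1):
            raise ConfigError(f"module_spec[{mi - 1}] per-sex effects must have |effect| < 1")
        resid = np.sqrt(1.0 - effect**2)
        latent = effect * severity + resid * rng_m.normal(size=n)
        eps = rng_m.normal(size=(n, spec.size))
        z[:, cols] = np.sqrt(spec.rho) * latent[:, None] + np.sqrt(1 - spec.rho) * eps
        truth_modules.append(
            {
                "module": mi,
                "metabolites": [f"M{c:04d}" for c in cols],
                "rho": spec.rho,
                "effect_f": spec.effect_f,
                "effect_m": spec.effect_m,
            }
        )

    # --- medications -------------------------------------------------------
    rng_med = _rng(config.seed, 3)
    med_cols = [f"med_{j:02d}" for j in range(config.n_medications)]
    meds = pd.DataFrame(
        (rng_med.random((n, config.n_medications)) < config.medication_prevalence).astype(int),
        index=covariates.index,
        columns=med_cols,
    )
    for med_idx, met_idx, eff in config.medication_effects:
        z[:, met_idx] += eff * meds.iloc[:, med_idx].to_numpy()

    # --- assay layer: replicates, plates, scale, censoring ----------------
    rng_a = _rng(config.seed, 4)
    met_ids = [f"M{j:04d}" for j in range(config.n_metabolites)]
    scale = np.exp(rng_a.uniform(np.log(1.0), np.log(100.0), size=config.n_metabolites))

    n_rep = int(np.floor(config.replicate_fraction * n))
    rep_participants = sorted(rng_a.choice(n, size=n_rep, replace=False).tolist())

    record_rows = []  # (record_id, participant_idx, replicate_no)
    for i in range(n):
        record_rows.append((f"{pids[i]}-r1", i, 1))
    for i in rep_participants:
        record_rows.append((f"{pids[i]}-r2", i, 2))
    record_ids = [r[0] for r in record_rows]
    part_idx = np.array([r[1] for r in record_rows])
    rep_no = np.array([r[2] for r in record_rows])

    z_rec = z[part_idx].copy()
    dup = rep_no == 2
    z_rec[dup] += config.replicate_noise_sd * rng_a.normal(size=(dup.sum(), config.n_metabolites))
    # baseline replicate also gets measurement noise so duplicate pairs differ
    base_of_dup = np.isin(part_idx, rep_participants) & (rep_no == 1)
    z_rec[base_of_dup] += config.replicate_noise_sd * rng_a.normal(
        size=(base_of_dup.sum(), config.n_metabolites)
    )

    plates = np.array([f"plate_{k}" for k in range(config.n_plates)])
    plate_of_rec = plates[rng_a.integers(config.n_plates, size=len(record_ids))]
    plate_fx = np.exp(rng_a.normal(0.0, config.plate_effect_sd, size=(config.n_plates, config.n_metabolites)))
    plate_pos = {p: k for k, p in enumerate(plates)}
    fx = plate_fx[[plate_pos[p] for p in plate_of_rec]]

    conc = np.exp(z_rec) * scale[None, :] * fx

    values = pd.DataFrame(conc, index=pd.Index(record_ids, name="record_id"), columns=met_ids)
    plate_of = pd.Series(plate_of_rec, index=values.index, name="plate_id")
    replicate_group = pd.Series([pids[i] for i in part_idx], index=values.index, name="participant_id")

    # per-(metabolite, plate) LOD at the configured empirical quantile
    lod = pd.DataFrame(0.0, index=met_ids, columns=list(plates))
    if config.lod_quantile > 0:
        for p in plates:
            rows = values.index[plate_of == p]
            if len(rows) == 0:
                continue
            lod[p] = values.loc[rows].quantile(config.lod_quantile, axis=0)
        censored = values.copy()
        for p in plates:
            rows = values.index[plate_of == p]
            sub = censored.loc[rows]
            censored.loc[rows] = sub.where(sub.to_numpy() >= lod[p].to_numpy()[None, :])
        values = censored

    qc_tags = None
    if config.platform == "nmr":
        qc_tags = pd.DataFrame(None, index=values.index, columns=values.columns, dtype=object)
        miss = values.isna()
        qc_tags = qc_tags.where(~miss, BELOW_QUANT_TAG)
        if config.contaminated_fraction > 0:
            n_bad = int(np.floor(config.contaminated_fraction * len(values)))
            bad_rows = rng_a.choice(len(values), size=n_bad, replace=False)
            bad_col = rng_a.integers(values.shape[1], size=n_bad)
            for r, c in zip(bad_rows, bad_col):
                values.iloc[r, c] = np.nan
                qc_tags.iloc[r, c] = "low ethanol"

    raw = RawMetaboliteData(
        values=values,
        plate_of=plate_of,
        replicate_group=replicate_group,
        lod=lod if config.platform == "targeted" else None,
        qc_tags=qc_tags,
        fasting=covariates["fasting"],
        platform=config.platform,
    )

    truth = {
        "module_labels": {met_ids[j]: int(labels[j]) for j in range(config.n_metabolites)},
        "modules": truth_modules,
        "outliers": [],
        "replicated_participants": [pids[i] for i in rep_participants],
        "seed": config.seed,
    }
    return SyntheticCohort(
        covariates=covariates, brain=brain, raw=raw, medications=meds, truth=truth, config=config
    )


def inject_outliers(
    cohort: SyntheticCohort, n_outliers: int, magnitude: float, seed: int | None = None
) -> SyntheticCohort:
    """Shift ``n_outliers`` random participants by ``magnitude`` (z-units) along
    a random multivariate direction in metabolite space; indices are recorded
    in the truth record.  Returns a new cohort; the input is unmodified."""
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    n = cohort.covariates.shape[0]
    if n_outliers >= n:
        raise ValueError("n_outliers must be smaller than the cohort size")
    out = cohort.copy()
    if n_outliers == 0:
        return out
    rng = _rng(cohort.config.seed if seed is None else seed, 9)
    pids = list(cohort.covariates.index)
    chosen = sorted(rng.choice(n, size=n_outliers, replace=False).tolist())
    p = out.raw.n_metabolites
    for i in chosen:
        d = rng.normal(size=p)
        d /= np.linalg.norm(d)
        recs = out.raw.values.index[out.raw.replicate_group == pids[i]]
        # shift on the latent log scale: multiply concentrations by exp(mag * d)
        out.raw.values.loc[recs] = out.raw.values.loc[recs] * np.exp(magnitude * d)[None, :]
    out.truth["outliers"] = [pids[i] for i in chosen]
    return out


# ---------------------------------------------------------------------------
# fixture I/O (tab-delimited, missing = empty field)
# ---------------------------------------------------------------------------

def write_fixtures(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as TSV fixtures plus a truth JSON; round-trips through
    :func:`read_fixtures`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    long = cohort.raw.values.stack(future_stack=True).rename("value").reset_index()
    long.columns = ["record_id", "metabolite_id", "value"]
    long["participant_id"] = cohort.raw.replicate_group.loc[long["record_id"]].to_numpy()
    long["plate_id"] = cohort.raw.plate_of.loc[long["record_id"]].to_numpy()
    long["replicate_no"] = [int(r.rsplit("-r", 1)[1]) for r in long["record_id"]]
    cols = ["participant_id", "metabolite_id", "plate_id", "replicate_no", "value"]
    if cohort.raw.qc_tags is not None:
        tags = cohort.raw.qc_tags.stack(future_stack=True).rename("qc_tag").reset_index(drop=True)
        long["qc_tag"] = tags
        cols.append("qc_tag")
    paths["metabolites"] = directory / "metabolites.tsv"
    long[cols].to_csv(paths["metabolites"], sep="\t", index=False)

    paths["lod"] = directory / "lod.tsv"
    if cohort.raw.lod is not None:
        lod_long = cohort.raw.lod.stack(future_stack=True).rename("lod").reset_index()
        lod_long.columns = ["metabolite_id", "plate_id", "lod"]
        lod_long.to_csv(paths["lod"], sep="\t", index=False)
    else:
        pd.DataFrame(columns=["metabolite_id", "plate_id", "lod"]).to_csv(
            paths["lod"], sep="\t", index=False
        )

    paths["covariates"] = directory / "covariates.tsv"
    cohort.covariates.to_csv(paths["covariates"], sep="\t")
    paths["brain"] = directory / "brain.tsv"
    cohort.brain.to_csv(paths["brain"], sep="\t")
    paths["medications"] = directory / "medications.tsv"
    cohort.medications.to_csv(paths["medications"], sep="\t")

    paths["truth"] = directory / "truth.json"
    truth = dict(cohort.truth)
    truth["platform"] = cohort.config.platform
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def read_fixtures(directory: str | Path) -> SyntheticCohort:
    """Read fixtures written by :func:`write_fixtures`."""
    directory = Path(directory)
    covariates = pd.read_csv(directory / "covariates.tsv", sep="\t", index_col="participant_id")
    brain = pd.read_csv(directory / "brain.tsv", sep="\t", index_col="participant_id")
    medications = pd.read_csv(directory / "medications.tsv", sep="\t", index_col="participant_id")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    platform = truth.pop("platform", "targeted")

    long = pd.read_csv(directory / "metabolites.tsv", sep="\t")
    long["record_id"] = long["participant_id"] + "-r" + long["replicate_no"].astype(str)
    values = long.pivot(index="record_id", columns="metabolite_id", values="value")
    meta = long.drop_duplicates("record_id").set_index("record_id")
    # preserve generation order: participants then replicate number
    order = meta.sort_values(["replicate_no", "participant_id"]).index
    order = sorted(values.index, key=lambda r: (int(r.rsplit("-r", 1)[1]), r))
    values = values.loc[order]
    meta = meta.loc[order]
    values.index.name = "record_id"
    values.columns.name = None

    qc_tags = None
    if "qc_tag" in long.columns and long["qc_tag"].notna().any():
        qc_tags = long.pivot(index="record_id", columns="metabolite_id", values="qc_tag")
        qc_tags = qc_tags.loc[order].astype(object).where(lambda df: df.notna(), None)
        qc_tags.index.name = "record_id"
        qc_tags.columns.name = None

    lod_long = pd.read_csv(directory / "lod.tsv", sep="\t")
    lod = None
    if len(lod_long):
        lod = lod_long.pivot(index="metabolite_id", columns="plate_id", values="lod")
        lod = lod.reindex(values.columns)
        lod.index.name = None
        lod.columns.name = None

    raw = RawMetaboliteData(
        values=values,
        plate_of=meta["plate_id"],
        replicate_group=meta["participant_id"],
        lod=lod if platform == "targeted" else None,
        qc_tags=qc_tags,
        fasting=covariates["fasting"] if "fasting" in covariates else None,
        platform=platform,
    )
    config = SimulationConfig(
        n_participants=covariates.shape[0],
        n_metabolites=values.shape[1],
        platform=platform,
        seed=int(truth.get("seed", 0)),
    )
    return SyntheticCohort(
        covariates=covariates, brain=brain, raw=raw, medications=medications, truth=truth, config=config
    )
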