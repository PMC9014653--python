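"""Metabolomics quality control and normalization.

Implements the record-level QC protocol for two platform styles:

* ``targeted`` -- plate-based assays with per-(metabolite, plate) limits of
  detection (LOD) and duplicate/triplicate replicates.
* ``nmr`` -- plate-free high-throughput assays where missing cells carry QC
  tags and censoring is imputed from the observed minimum.

The protocol, in order: missingness filtering, cross-plate mean
normalization, replicate-based CV/ICC filtering, fasting/QC-tag participant
filtering, replicate averaging, manual exclusions, left-censored imputation,
log2 + z-score + winsorizing transform, Mahalanobis outlier screening, and
medication residualization.  Every removal is recorded in a :class:`QCReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RawMetaboliteData",
    "CleanMetaboliteData",
    "QCReport",
    "BELOW_QUANT_TAG",
    "filter_by_missingness",
    "crossplate_normalize",
    "replicate_quality",
    "collapse_replicates",
    "filter_participants_by_flags",
    "impute_left_censored",
    "transform_concentrations",
    "mahalanobis_screen",
    "residualize_medications",
    "run_qc",
]

#: canonical QC tag marking left-censoring (kept through participant filtering)
BELOW_QUANT_TAG = "below limit of quantification"


@dataclass
class RawMetaboliteData:
    """Record-level metabolite concentrations with assay metadata.

    ``values`` is records x metabolites (NaN = missing).  A *record* is one
    assay run; ``replicate_group`` maps each record to its biological
    participant, so replicates share a group.  ``lod`` is metabolite x plate
    (required for the targeted platform).  ``qc_tags`` mirrors ``values`` with
    string tags on missing cells (NMR platform).  ``fasting`` is indexed by
    participant.
    """

    values: pd.DataFrame
    plate_of: pd.Series
    replicate_group: pd.Series
    lod: pd.DataFrame | None = None
    qc_tags: pd.DataFrame | None = None
    fasting: pd.Series | None = None
    platform: str = "targeted"

    def __post_init__(self) -> None:
        if self.platform not in ("targeted", "nmr"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if not self.values.index.equals(self.plate_of.index):
            raise ValueError("plate_of index must match values index")
        if not self.values.index.equals(self.replicate_group.index):
            raise ValueError("replicate_group index must match values index")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ValueError("concentration values must be >= 0")
        if self.platform == "targeted":
            if self.lod is None:
                raise ValueError("targeted platform requires an LOD table")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "RawMetaboliteData":
        return RawMetaboliteData(
            values=self.values.copy(),
            plate_of=self.plate_of.copy(),
            replicate_group=self.replicate_group.copy(),
            lod=None if self.lod is None else self.lod.copy(),
            qc_tags=None if self.qc_tags is None else self.qc_tags.copy(),
            fasting=None if self.fasting is None else self.fasting.copy(),
            platform=self.platform,
        )

    def _subset(self, records=None, metabolites=None) -> "RawMetaboliteData":
        out = self.copy()
        if metabolites is not None:
            out.values = out.values.loc[:, metabolites]
            if out.lod is not None:
                out.lod = out.lod.loc[out.lod.index.intersection(metabolites)]
            if out.qc_tags is not None:
                out.qc_tags = out.qc_tags.loc[:, metabolites]
        if records is not None:
            out.values = out.values.loc[records]
            out.plate_of = out.plate_of.loc[records]
            out.replicate_group = out.replicate_group.loc[records]
            if out.qc_tags is not None:
                out.qc_tags = out.qc_tags.loc[records]
        return out


@dataclass
class CleanMetaboliteData:
    """Participants x metabolites matrix of transformed values plus provenance."""

    matrix: pd.DataFrame
    provenance: list = field(default_factory=list)

    def copy(self) -> "CleanMetaboliteData":
        return CleanMetaboliteData(self.matrix.copy(), list(self.provenance))


@dataclass
class QCReport:
    """Ledger of removals and imputations across the QC pipeline."""

    removed_metabolites: list = field(default_factory=list)  # (id, reason)
    removed_participants: list = field(default_factory=list)  # (id, reason)
    imputation_log: list = field(default_factory=list)  # (record, metabolite, value, rule)
    steps: list = field(default_factory=list)  # dicts: name, n_records, n_metabolites

    def log_step(self, name: str, data) -> None:
        if isinstance(data, RawMetaboliteData):
            n_rec, n_met = data.values.shape
        else:
            n_rec, n_met = data.matrix.shape
        self.steps.append({"step": name, "n_records": int(n_rec), "n_metabolites": int(n_met)})

    def metabolites_removed_for(self, reason: str) -> list:
        return [m for m, r in self.removed_metabolites if r == reason]

    def participants_removed_for(self, reason: str) -> list:
        return [p for p, r in self.removed_participants if r == reason]

    def to_dict(self) -> dict:
        return {
            "removed_metabolites": [list(x) for x in self.removed_metabolites],
            "removed_participants": [list(x) for x in self.removed_participants],
            "imputation_log": [list(x) for x in self.imputation_log],
            "steps": self.steps,
        }


# ---------------------------------------------------------------------------
# individual QC operations
# ---------------------------------------------------------------------------

def filter_by_missingness(
    data: RawMetaboliteData,
    metabolite_thresh: float = 0.20,
    participant_thresh: float = 0.40,
    report: QCReport | None = None,
) -> tuple[RawMetaboliteData, QCReport]:
    """Drop metabolites with missingness >= ``metabolite_thresh`` (inclusive),
    then participants with missingness > ``participant_thresh`` (exclusive).

    The metabolite pass runs first so that a very incomplete metabolite does
    not drag participants over their threshold.
    """
    for name, t in (("metabolite_thresh", metabolite_thresh), ("participant_thresh", participant_thresh)):
        if not 0 < t <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {t}")
    report = report if report is not None else QCReport()

    met_missing = data.values.isna().mean(axis=0)
    bad_mets = met_missing.index[met_missing >= metabolite_thresh]
    for m in bad_mets:
        report.removed_metabolites.append((m, "missingness"))
    keep_mets = data.values.columns.difference(bad_mets, sort=False)
    data = data._subset(metabolites=keep_mets)

    rec_missing = data.values.isna().mean(axis=1)
    bad_recs = rec_missing.index[rec_missing > participant_thresh]
    bad_participants = sorted(set(data.replicate_group.loc[bad_recs]))
    for p in bad_participants:
        report.removed_participants.append((p, "missingness"))
    keep_recs = data.values.index[~data.replicate_group.isin(bad_participants)]
    data = data._subset(records=keep_recs)

    if data.values.size == 0:
        raise ValueError("matrix is empty after missingness filtering")
    report.log_step("filter_by_missingness", data)
    return data, report


def crossplate_normalize(data: RawMetaboliteData) -> RawMetaboliteData:
    """Multiplicatively rescale each metabolite so every plate's mean equals
    the metabolite's grand mean.

    A plate whose values for a metabolite are all missing is left unscaled
    (with a warning).  With a single plate this is the identity, and the
    operation is idempotent.
    """
    plates = data.plate_of.unique()
    if len(plates) < 2:
        return data.copy()
    out = data.copy()
    vals = out.values
    grand = vals.mean(axis=0)  # per metabolite, over non-missing
    for plate in plates:
        rows = data.plate_of.index[data.plate_of == plate]
        plate_mean = vals.loc[rows].mean(axis=0)
        empty = plate_mean.isna()
        if empty.any():
            warnings.warn(
                f"plate {plate!r}: {int(empty.sum())} metabolite(s) all-missing; left unscaled",
                stacklevel=2,
            )
        nonpos = plate_mean <= 0
        if nonpos.any():
            raise ValueError("plate means must be positive for multiplicative normalization")
        scale = grand / plate_mean
        scale[empty] = 1.0
        vals.loc[rows] = vals.loc[rows] * scale
    out.values = vals
    return out


def replicate_quality(
    data: RawMetaboliteData,
    cv_max: float = 0.20,
    icc_min: float = 0.65,
    report: QCReport | None = None,
) -> tuple[RawMetaboliteData, pd.Series, pd.Series, QCReport]:
    """Per-metabolite CV and ICC from replicate groups; filter failing analytes.

    CV is the mean over replicate groups of (group SD / group mean).  ICC is
    the one-way random-effects estimator from the replicate-group ANOVA,
    (MSB - MSW) / (MSB + (kbar - 1) * MSW) with kbar the mean group size.
    Metabolites with CV > cv_max or ICC < icc_min are removed (strict
    inequalities, matching the protocol wording).
    """
    report = report if report is not None else QCReport()
    group_sizes = data.replicate_group.value_counts()
    rep_groups = group_sizes.index[group_sizes >= 2]
    if len(rep_groups) == 0:
        warnings.warn("no replicate groups with >= 2 records; CV/ICC filtering skipped", stacklevel=2)
        cv = pd.Series(np.nan, index=data.values.columns)
        icc = pd.Series(np.nan, index=data.values.columns)
        report.log_step("replicate_quality", data)
        return data.copy(), cv, icc, report

    in_reps = data.replicate_group.isin(rep_groups)
    sub = data.values.loc[in_reps]
    groups = data.replicate_group.loc[in_reps]

    gmean = sub.groupby(groups).mean()
    gsd = sub.groupby(groups).std(ddof=1)
    gcount = sub.groupby(groups).count()
    with np.errstate(divide="ignore", invalid="ignore"):
        gcv = gsd / gmean
    gcv = gcv.where(gcount >= 2)
    cv = gcv.mean(axis=0)

    icc = pd.Series(np.nan, index=data.values.columns)
    for met in data.values.columns:
        icc[met] = _oneway_icc(sub[met], groups)

    fail_cv = cv.index[cv > cv_max]
    fail_icc = icc.index[icc < icc_min]
    for m in fail_cv:
        report.removed_metabolites.append((m, "cv"))
    for m in fail_icc.difference(fail_cv):
        report.removed_metabolites.append((m, "icc"))
    keep = data.values.columns.difference(fail_cv.union(fail_icc), sort=False)
    out = data._subset(metabolites=keep)
    report.log_step("replicate_quality", out)
    return out, cv, icc, report


def _oneway_icc(values: pd.Series, groups: pd.Series) -> float:
    """One-way random-effects ICC from an unbalanced replicate ANOVA."""
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    counts = df.groupby("g")["v"].count()
    counts = counts[counts >= 2]
    df = df[df["g"].isin(counts.index)]
    g = len(counts)
    n = len(df)
    if g < 2 or n <= g:
        return np.nan
    grand = df["v"].mean()
    means = df.groupby("g")["v"].mean()
    ssb = float((counts * (means - grand) ** 2).sum())
    ssw = float(((df["v"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    kbar = n / g
    denom = msb + (kbar - 1) * msw
    if denom <= 0:
        return np.nan
    return (msb - msw) / denom


def collapse_replicates(data: RawMetaboliteData) -> RawMetaboliteData:
    """Average replicate records into one record per biological participant.

    The mean is taken over non-missing replicate values; a cell stays missing
    only when every replicate is missing.  Plate assignment and QC tags are
    taken from the first record of each group (in record order).
    """
    groups = data.replicate_group
    order = pd.unique(groups)
    vals = data.values.groupby(groups).mean().reindex(order)
    first = pd.Series(data.values.index, index=data.values.index).groupby(groups).first().reindex(order)
    plate = data.plate_of.loc[first].set_axis(order)
    tags = None
    if data.qc_tags is not None:
        # keep the first non-null tag per cell within each group
        tags = data.qc_tags.groupby(groups).first().reindex(order)
    return RawMetaboliteData(
        values=vals,
        plate_of=plate,
        replicate_group=pd.Series(order, index=order),
        lod=None if data.lod is None else data.lod.copy(),
        qc_tags=tags,
        fasting=None if data.fasting is None else data.fasting.copy(),
        platform=data.platform,
    )


def filter_participants_by_flags(
    data: RawMetaboliteData, report: QCReport | None = None
) -> tuple[RawMetaboliteData, QCReport]:
    """Remove non-fasting participants and, on the NMR platform, participants
    whose missing cells carry any QC tag other than the below-quantification
    tag (tagged missingness indicates contamination, e.g. "low ethanol")."""
    report = report if report is not None else QCReport()
    bad: dict[str, str] = {}

    if data.fasting is not None:
        fasting = data.fasting.reindex(data.replicate_group.unique()).fillna(True)
        for p, ok in fasting.items():
            if not ok:
                bad[p] = "non-fasting"

    if data.platform == "nmr" and data.qc_tags is not None:
        missing = data.values.isna()
        tagged = data.qc_tags.notna() & (data.qc_tags != BELOW_QUANT_TAG)
        flagged_records = (missing & tagged).any(axis=1)
        for rec in data.values.index[flagged_records]:
            p = data.replicate_group.loc[rec]
            bad.setdefault(p, "qc-tag")

    for p, reason in bad.items():
        report.removed_participants.append((p, reason))
    keep = data.values.index[~data.replicate_group.isin(bad)]
    out = data._subset(records=keep)
    report.log_step("filter_participants_by_flags", out)
    return out, report


def impute_left_censored(
    data: RawMetaboliteData, report: QCReport | None = None
) -> tuple[RawMetaboliteData, QCReport]:
    """Impute remaining (left-censored) missing values.

    Targeted platform: half the LOD of that metabolite on that record's
    plate.  NMR platform: half the minimum observed value of that metabolite.
    Every imputed cell is recorded in the report's imputation log.
    """
    report = report if report is not None else QCReport()
    out = data.copy()
    vals = out.values
    missing = vals.isna()
    if data.platform == "targeted":
        lod = data.lod
        for met in vals.columns[missing.any(axis=0)]:
            recs = vals.index[missing[met]]
            for rec in recs:
                plate = data.plate_of.loc[rec]
                if lod is None or met not in lod.index or plate not in lod.columns or pd.isna(lod.loc[met, plate]):
                    raise ValueError(f"missing LOD entry for metabolite {met!r} on plate {plate!r}")
                fill = float(lod.loc[met, plate]) / 2.0
                vals.loc[rec, met] = fill
                report.imputation_log.append((rec, met, fill, "half-lod"))
    else:
        for met in vals.columns[missing.any(axis=0)]:
            observed = vals[met].dropna()
            if observed.empty:
                raise ValueError(f"metabolite {met!r} has no observed values to impute from")
            fill = float(observed.min()) / 2.0
            for rec in vals.index[missing[met]]:
                vals.loc[rec, met] = fill
                report.imputation_log.append((rec, met, fill, "half-min"))
    out.values = vals
    report.log_step("impute_left_censored", out)
    return out, report


def transform_concentrations(
    data: RawMetaboliteData | pd.DataFrame,
    winsor_limit: float | None = 3.0,
) -> CleanMetaboliteData:
    """Add 1, log2-transform, z-score per metabolite, then winsorize.

    The constant guards against zero concentrations (half-LOD imputations can
    be 0 when the LOD itself is 0).  The z-score uses the population SD; with
    ``winsor_limit=None`` the clamping step is skipped.
    """
    vals = data.values if isinstance(data, RawMetaboliteData) else data
    if vals.isna().any().any():
        raise ValueError("transform requires a complete matrix (impute first)")
    if (vals.to_numpy(dtype=float) < 0).any():
        raise ValueError("transform requires non-negative concentrations")
    logged = np.log2(vals.astype(float) + 1.0)
    sd = logged.std(axis=0, ddof=0)
    zero_var = sd.index[sd == 0]
    if len(zero_var):
        raise ValueError(f"zero-variance metabolite column(s): {list(zero_var)}")
    z = (logged - logged.mean(axis=0)) / sd
    provenance = [
        {"step": "add_constant", "constant": 1.0},
        {"step": "log2"},
        {"step": "zscore"},
    ]
    if winsor_limit is not None:
        if winsor_limit <= 0:
            raise ValueError("winsor_limit must be positive")
        z = z.clip(lower=-winsor_limit, upper=winsor_limit)
        provenance.append({"step": "winsorize", "limit": float(winsor_limit)})
    return CleanMetaboliteData(matrix=z, provenance=provenance)


def mahalanobis_screen(matrix, alpha: float = 0.001):
    """Flag multivariate outliers by squared Mahalanobis distance.

    D2_i = (x_i - xbar)' S^{-1} (x_i - xbar) with the sample mean and sample
    covariance; a row is flagged when the upper-tail chi-square probability of
    D2_i at p degrees of freedom is below ``alpha``.  Returns the flagged row
    index (for DataFrames) or a boolean mask (for arrays).
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows than columns for a stable covariance (n={n}, p={p})")
    Xc = X - X.mean(axis=0)
    S = np.cov(Xc, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    eigvals = np.linalg.eigvalsh(S)
    data_scale = float(np.mean(X**2)) + 1e-300  # identical rows => variance ~ eps^2
    if eigvals[-1] <= 1e-24 * data_scale or eigvals[0] <= 1e-12 * eigvals[-1]:
        raise ValueError(
            "sample covariance is singular; reduce dimensionality before screening"
        )
    L = np.linalg.cholesky(S)
    sol = np.linalg.solve(L, Xc.T)
    d2 = (sol**2).sum(axis=0)
    flagged = stats.chi2.sf(d2, df=p) < alpha
    if is_frame:
        return matrix.index[flagged]
    return flagged


def residualize_medications(
    clean: CleanMetaboliteData,
    medications: pd.DataFrame,
    alpha_keep: float = 0.05,
) -> CleanMetaboliteData:
    """Replace each metabolite by residuals of a backward-selected medication model.

    Per metabolite: start from all medication indicators, iteratively drop the
    predictor with the largest P until every remaining P < ``alpha_keep``.  If
    nothing survives the column passes through unchanged.  Duplicate
    medication columns are dropped with a warning.
    """
    if medications.shape[1] == 0:
        return clean.copy()
    meds = medications.loc[clean.matrix.index].astype(float)

    # drop exact duplicates / constant columns that would make the design singular
    keep_cols = []
    seen: list[np.ndarray] = []
    for c in meds.columns:
        col = meds[c].to_numpy()
        if col.std() == 0 or any(np.array_equal(col, s) for s in seen):
            warnings.warn(f"dropping collinear/constant medication column {c!r}", stacklevel=2)
            continue
        keep_cols.append(c)
        seen.append(col)
    meds = meds[keep_cols]
    if meds.shape[1] == 0:
        return clean.copy()

    out = clean.matrix.copy()
    M = meds.to_numpy()
    for met in out.columns:
        y = out[met].to_numpy(dtype=float)
        active = list(range(M.shape[1]))
        while active:
            X = np.column_stack([np.ones(len(y)), M[:, active]])
            beta, se, pvals = _ols_fit(X, y)
            med_p = pvals[1:]
            worst = int(np.argmax(med_p))
            if med_p[worst] >= alpha_keep:
                active.pop(worst)
            else:
                break
        if active:
            X = np.column_stack([np.ones(len(y)), M[:, active]])
            beta, _, _ = _ols_fit(X, y)
            out[met] = y - X @ beta
    result = clean.copy()
    result.matrix = out
    result.provenance.append({"step": "residualize_medications", "alpha_keep": float(alpha_keep)})
    return result


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS coefficients, standard errors and two-sided t-test P-values."""
    n, k = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - k
    if df <= 0:
        raise ValueError("not enough observations for OLS")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=df)
    return beta, se, pvals


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def run_qc(
    data: RawMetaboliteData,
    *,
    metabolite_missing_max: float = 0.20,
    participant_missing_max: float = 0.40,
    cv_max: float = 0.20,
    icc_min: float = 0.65,
    winsor_limit: float | None = 3.0,
    mahalanobis_alpha: float = 0.001,
    manual_exclusions: Sequence[str] = (),
    medications: pd.DataFrame | None = None,
    medication_alpha: float = 0.05,
) -> tuple[CleanMetaboliteData, QCReport]:
    """Run the full QC protocol for the data's platform; returns the clean
    participants x metabolites matrix and the QC report."""
    report = QCReport()
    report.log_step("input", data)

    data, report = filter_by_missingness(
        data, metabolite_missing_max, participant_missing_max, report
    )
    if data.platform == "targeted" and data.plate_of.nunique() > 1:
        data = crossplate_normalize(data)
        report.log_step("crossplate_normalize", data)
    if (data.replicate_group.value_counts() >= 2).any():
        data, _cv, _icc, report = replicate_quality(data, cv_max, icc_min, report)
    data, report = filter_participants_by_flags(data, report)
    data = collapse_replicates(data)
    report.log_step("collapse_replicates", data)

    excl = [m for m in manual_exclusions if m in data.values.columns]
    if excl:
        for m in excl:
            report.removed_metabolites.append((m, "manual"))
        data = data._subset(metabolites=data.values.columns.difference(excl, sort=False))
        report.log_step("manual_exclusions", data)

    data, report = impute_left_censored(data, report)
    clean = transform_concentrations(data, winsor_limit=winsor_limit)
    report.log_step("transform_concentrations", clean)

    if clean.matrix.shape[0] > clean.matrix.shape[1]:
        flagged = mahalanobis_screen(clean.matrix, alpha=mahalanobis_alpha)
        for p in flagged:
            report.removed_participants.append((p, "outlier"))
        clean.matrix = clean.matrix.drop(index=flagged)
        clean.provenance.append({"step": "mahalanobis_screen", "alpha": mahalanobis_alpha, "n_flagged": int(len(flagged))})
    else:
        warnings.warn("skipping Mahalanobis screen: fewer participants than metabolites", stacklevel=2)
    report.log_step("mahalanobis_screen", clean)

    if medications is not None and medications.shape[1] > 0:
        meds = medications.reindex(clean.matrix.index)
        clean = residualize_medications(clean, meds, alpha_keep=medication_alpha)
        report.log_step("residualize_medications", clean)

    return clean, report
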