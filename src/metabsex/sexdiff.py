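"""Sex-stratified association of metabolites/modules with brain components,
the two sex-difference detection frameworks, and multiple-testing machinery.

Two frameworks are implemented:

* a two-fold screen: the heterogeneity test over all associations, and again
  over the subset with a strong overall (inverse-variance-combined)
  association;
* a classification of each association as homogeneous, heterogeneous,
  sex-specific, or none, driven by per-sex and pooled significance plus the
  heterogeneity test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestingPlan",
    "stratified_regression",
    "z_diff_test",
    "z_overall_test",
    "winkler_screen",
    "arnold_classify",
    "effective_tests",
    "run_association_study",
]

COVARIATE_COLS = ("age", "education", "apoe4")


@dataclass
class TestingPlan:
    """Significance levels for the association study.

    Module-level Bonferroni alpha is 0.05/(M*C); single-metabolite alpha is
    0.05/(I*C) with I the effective number of independent tests.
    """

    n_modules: int
    n_components: int
    effective_tests: float
    overall_alpha: float = 1e-5
    nominal_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.effective_tests < 1:
            raise ValueError("effective_tests must be >= 1")
        for name in ("overall_alpha", "nominal_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @property
    def module_alpha(self) -> float:
        return self.nominal_alpha / (self.n_modules * self.n_components)

    @property
    def metabolite_alpha(self) -> float:
        return self.nominal_alpha / (self.effective_tests * self.n_components)

    def bonferroni_alpha(self, unit_type: str) -> float:
        return self.module_alpha if unit_type == "module" else self.metabolite_alpha

    def to_dict(self) -> dict:
        return {
            "n_modules": self.n_modules,
            "n_components": self.n_components,
            "effective_tests": self.effective_tests,
            "overall_alpha": self.overall_alpha,
            "nominal_alpha": self.nominal_alpha,
            "module_alpha": self.module_alpha,
            "metabolite_alpha": self.metabolite_alpha,
        }


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with t-distribution P-values; raises on rank deficiency."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"not enough observations (n={n}) for {k} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValueError("rank-deficient design matrix (collinear columns)")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=df)
    return beta, se, pvals, df


def _design(components: pd.DataFrame, covariates: pd.DataFrame, extra: pd.Series | None = None):
    cols = [np.ones(len(components))]
    names = ["const"]
    for c in components.columns:
        cols.append(components[c].to_numpy(dtype=float))
        names.append(str(c))
    for c in COVARIATE_COLS:
        if c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    if extra is not None:
        cols.append(extra.to_numpy(dtype=float))
        names.append(str(extra.name))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns for the error message
        bad = []
        kept = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(names[j])
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    return X, names


def stratified_regression(
    outcome: pd.Series,
    components: pd.DataFrame,
    covariates: pd.DataFrame,
    sex: pd.Series,
) -> pd.DataFrame:
    """Per-sex and pooled OLS of the outcome on all brain components jointly
    plus age, education, and APOE-e4 allele count; the pooled model adds sex.

    Returns one row per component with beta_f/se_f/p_f, beta_m/se_m/p_m,
    beta_all/se_all/p_all, and per-stratum sample sizes.
    """
    idx = outcome.index
    for tbl, name in ((components, "components"), (covariates, "covariates"), (sex, "sex")):
        if not idx.equals(tbl.index):
            raise ValueError(f"{name} index must match the outcome index")
    is_f = sex.astype(str).str.upper().isin(["F", "FEMALE", "1"])
    strata = {"f": idx[is_f], "m": idx[~is_f]}
    if any(len(v) == 0 for v in strata.values()):
        raise ValueError("both sex strata must be non-empty")

    comp_names = [str(c) for c in components.columns]
    out = {}
    for tag, rows in strata.items():
        X, names = _design(components.loc[rows], covariates.loc[rows])
        beta, se, p, _ = _ols(X, outcome.loc[rows].to_numpy(dtype=float))
        for j, name in enumerate(names):
            if name in comp_names:
                out.setdefault(name, {})[f"beta_{tag}"] = beta[j]
                out[name][f"se_{tag}"] = se[j]
                out[name][f"p_{tag}"] = p[j]
                out[name][f"n_{tag}"] = len(rows)

    sex_num = (~is_f).astype(float).rename("sex_male")
    X, names = _design(components, covariates, extra=sex_num)
    beta, se, p, _ = _ols(X, outcome.to_numpy(dtype=float))
    for j, name in enumerate(names):
        if name in comp_names:
            out[name]["beta_all"] = beta[j]
            out[name]["se_all"] = se[j]
            out[name]["p_all"] = p[j]
            out[name]["n_all"] = len(idx)

    res = pd.DataFrame.from_dict(out, orient="index").loc[comp_names]
    res.index.name = "component"
    return res


def z_diff_test(beta_f, se_f, beta_m, se_m):
    """Heterogeneity test Z = (beta_f - beta_m) / sqrt(se_f^2 + se_m^2), with a
    two-sided standard-normal P-value.  Accepts scalars or arrays."""
    beta_f, se_f, beta_m, se_m = map(np.asarray, (beta_f, se_f, beta_m, se_m))
    if (se_f <= 0).any() or (se_m <= 0).any():
        raise ValueError("standard errors must be positive")
    z = (beta_f - beta_m) / np.sqrt(se_f**2 + se_m**2)
    p = 2 * stats.norm.sf(np.abs(z))
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def z_overall_test(beta_f, se_f, beta_m, se_m):
    """Inverse-variance-weighted combined association
    Z = (beta_f/se_f^2 + beta_m/se_m^2) / sqrt(1/se_f^2 + 1/se_m^2)."""
    beta_f, se_f, beta_m, se_m = map(np.asarray, (beta_f, se_f, beta_m, se_m))
    if (se_f <= 0).any() or (se_m <= 0).any():
        raise ValueError("standard errors must be positive")
    wf, wm = 1.0 / se_f**2, 1.0 / se_m**2
    z = (beta_f * wf + beta_m * wm) / np.sqrt(wf + wm)
    p = 2 * stats.norm.sf(np.abs(z))
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def winkler_screen(results: pd.DataFrame, plan: TestingPlan) -> pd.DataFrame:
    """Two-fold sex-difference screen over a family of associations.

    Screen 1 applies the heterogeneity test Bonferroni-corrected over all
    N associations.  Screen 2 restricts to associations with overall P below
    ``plan.overall_alpha`` and corrects over that subset only.  An association
    is flagged if it passes either screen.
    """
    cols = ["winkler_screen1", "winkler_passes_filter", "winkler_screen2", "winkler_any"]
    if len(results) == 0:
        return pd.DataFrame(columns=cols, dtype=bool)
    n_all = len(results)
    screen1 = results["p_diff"] < plan.nominal_alpha / n_all
    passes = results["p_overall"] < plan.overall_alpha
    n_filt = int(passes.sum())
    if n_filt > 0:
        screen2 = passes & (results["p_diff"] < plan.nominal_alpha / n_filt)
    else:
        screen2 = pd.Series(False, index=results.index)
    out = pd.DataFrame(
        {
            "winkler_screen1": screen1,
            "winkler_passes_filter": passes,
            "winkler_screen2": screen2,
            "winkler_any": screen1 | screen2,
        }
    )
    return out


def arnold_classify(
    p_all: float,
    p_f: float,
    p_m: float,
    p_diff: float,
    alpha_bonf: float,
    nominal_alpha: float = 0.05,
) -> str:
    """Classify one association as homogeneous / heterogeneous / sex-specific
    / none.

    Selection requires any of: (a) pooled-cohort Bonferroni significance,
    (b) Bonferroni significance in one sex, or (c) nominal significance in
    one sex together with a nominally significant sex-difference test.
    Selected associations are sex-specific when exactly one stratum is
    Bonferroni significant and the sex-difference P is below the nominal
    level, otherwise heterogeneous (P_diff < nominal) or homogeneous.
    """
    sel_a = p_all < alpha_bonf
    sel_b = min(p_f, p_m) < alpha_bonf
    sel_c = (min(p_f, p_m) < nominal_alpha) and (p_diff < nominal_alpha)
    if not (sel_a or sel_b or sel_c):
        return "none"
    one_sex_bonf = (p_f < alpha_bonf) != (p_m < alpha_bonf)
    if one_sex_bonf and p_diff < nominal_alpha:
        return "sex-specific"
    if p_diff < nominal_alpha:
        return "heterogeneous"
    return "homogeneous"


def effective_tests(correlation: pd.DataFrame | np.ndarray) -> float:
    """Effective number of independent tests from the eigenvalues of a
    correlation matrix: I = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]."""
    C = correlation.to_numpy(dtype=float) if isinstance(correlation, pd.DataFrame) else np.asarray(correlation, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(C)
    lam = np.clip(lam, 0.0, None)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def run_association_study(
    clean_matrix: pd.DataFrame,
    eigens: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    sex: pd.Series | None = None,
    overall_alpha: float = 1e-5,
    nominal_alpha: float = 0.05,
    include_metabolites: bool = True,
) -> tuple[pd.DataFrame, TestingPlan]:
    """Full association study: modules x components and metabolites x
    components, with both detection frameworks attached.

    All inputs must be aligned on the same participants; ``sex`` defaults to
    the covariates' ``sex`` column.
    """
    if sex is None:
        if "sex" not in covariates.columns:
            raise ValueError("sex column required in covariates (or pass sex=)")
        sex = covariates["sex"]
    idx = clean_matrix.index
    for name, tbl in (("eigens", eigens), ("scores", scores), ("covariates", covariates)):
        if not idx.equals(tbl.index):
            missing = idx.symmetric_difference(tbl.index)
            raise ValueError(
                f"participant misalignment between clean matrix and {name}: "
                f"{list(missing[:10])}{'...' if len(missing) > 10 else ''}"
            )

    plan = TestingPlan(
        n_modules=max(eigens.shape[1], 1),
        n_components=scores.shape[1],
        effective_tests=effective_tests(clean_matrix.corr()) if include_metabolites and clean_matrix.shape[1] else 1.0,
        overall_alpha=overall_alpha,
        nominal_alpha=nominal_alpha,
    )

    units: list[tuple[str, str, pd.Series]] = []
    for mod in eigens.columns:
        units.append((str(mod), "module", eigens[mod]))
    if include_metabolites:
        for met in clean_matrix.columns:
            units.append((str(met), "metabolite", clean_matrix[met]))

    rows = []
    for unit, unit_type, outcome in units:
        res = stratified_regression(outcome, scores, covariates, sex)
        res = res.reset_index()
        res.insert(0, "unit", unit)
        res.insert(1, "unit_type", unit_type)
        rows.append(res)
    results = pd.concat(rows, ignore_index=True)

    zd, pd_ = z_diff_test(
        results["beta_f"].to_numpy(), results["se_f"].to_numpy(),
        results["beta_m"].to_numpy(), results["se_m"].to_numpy(),
    )
    zo, po = z_overall_test(
        results["beta_f"].to_numpy(), results["se_f"].to_numpy(),
        results["beta_m"].to_numpy(), results["se_m"].to_numpy(),
    )
    results["z_diff"], results["p_diff"] = zd, pd_
    results["z_overall"], results["p_overall"] = zo, po

    # Winkler screens run within each unit-type family (separate Bonferroni
    # denominators, mirroring the separate module vs metabolite alpha plans)
    for c in ("winkler_screen1", "winkler_passes_filter", "winkler_screen2", "winkler_any"):
        results[c] = False
    for unit_type in results["unit_type"].unique():
        mask = results["unit_type"] == unit_type
        flags = winkler_screen(results.loc[mask], plan)
        results.loc[mask, flags.columns] = flags

    results["arnold_category"] = [
        arnold_classify(
            r.p_all, r.p_f, r.p_m, r.p_diff,
            alpha_bonf=plan.bonferroni_alpha(r.unit_type),
            nominal_alpha=plan.nominal_alpha,
        )
        for r in results.itertuples()
    ]
    return results, plan
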