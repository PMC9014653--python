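"""Brain volume phenotypes: diagnosis consolidation, ICV normalization, and
PLS-DA reduction of the six segment volumes against diagnosis groups."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import mahalanobis_screen

__all__ = [
    "SEGMENTS",
    "DIAGNOSIS_MAP",
    "consolidate_diagnosis",
    "normalize_volumes",
    "PLSDAModel",
    "fit_plsda",
    "vip_scores",
    "select_components",
    "score_outlier_screen",
]

SEGMENTS = ("ventricles", "hippocampus", "entorhinal", "fusiform", "midtemporal", "wholebrain")

DIAGNOSIS_MAP = {"CN": "CN", "SMC": "CN", "MCI": "MCI", "EMCI": "MCI", "LMCI": "MCI", "AD": "AD"}


def consolidate_diagnosis(labels6) -> pd.Series:
    """Map the six clinical labels onto {CN, MCI, AD}.

    CN and SMC collapse to CN; MCI, EMCI and LMCI collapse to MCI.
    """
    s = pd.Series(labels6)
    unknown = sorted(set(s.unique()) - set(DIAGNOSIS_MAP))
    if unknown:
        raise ValueError(f"unknown diagnosis label(s): {unknown}")
    return s.map(DIAGNOSIS_MAP)


def normalize_volumes(volumes: pd.DataFrame) -> pd.DataFrame:
    """Divide each segment volume by ICV; the ventricle ratio (non-normal) is
    replaced by its natural log.  Column order follows :data:`SEGMENTS`."""
    missing = [c for c in SEGMENTS + ("icv",) if c not in volumes.columns]
    if missing:
        raise ValueError(f"volume table lacks column(s): {missing}")
    icv = volumes["icv"].astype(float)
    if (icv <= 0).any():
        raise ValueError("ICV must be positive for all participants")
    out = volumes.loc[:, list(SEGMENTS)].astype(float).div(icv, axis=0)
    if (out["ventricles"] <= 0).any():
        raise ValueError("nonpositive ventricle/ICV ratio cannot be log-transformed")
    out["ventricles"] = np.log(out["ventricles"])
    return out


@dataclass
class PLSDAModel:
    """Fitted PLS2 discriminant model (NIPALS with X deflation).

    Weights/loadings are predictors x components; scores are participants x
    components.  ``x_variance`` / ``y_variance`` hold the per-component
    fraction of centered-and-scaled X (resp. centered Y) sum of squares.
    """

    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: pd.DataFrame
    x_variance: np.ndarray
    y_variance: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    predictors: list
    classes: list

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]


def fit_plsda(
    X: pd.DataFrame,
    y,
    n_components: int = 5,
    *,
    scale: bool = True,
    deflate_y: bool = False,
) -> PLSDAModel:
    """Fit PLS2 of autoscaled predictors against a centered one-hot class matrix.

    Per component the X-weight vector is the dominant singular direction of
    X'Y, scores t = Xw, and X is deflated by its rank-one reconstruction
    t p'.  Scores are therefore mutually orthogonal and the per-component
    X-variance fractions sum to 1 at full rank.  Deterministic: the sign of
    each weight vector is fixed by its largest-magnitude coordinate.
    """
    X = pd.DataFrame(X)
    y = pd.Series(y, index=X.index)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("PLS-DA requires at least two classes")
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n <= n_components:
        raise ValueError(f"fewer participants ({n}) than requested components + 1")

    Xv = X.to_numpy(dtype=float)
    x_mean = Xv.mean(axis=0)
    x_std = Xv.std(axis=0, ddof=1) if scale else np.ones(p)
    if (x_std == 0).any():
        bad = [X.columns[j] for j in np.flatnonzero(x_std == 0)]
        raise ValueError(f"constant predictor column(s): {bad}")
    Xd = (Xv - x_mean) / x_std

    Y = pd.get_dummies(y).loc[:, classes].to_numpy(dtype=float)
    Yd = Y - Y.mean(axis=0)

    rank = np.linalg.matrix_rank(Xd)
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank(X)={rank}; truncating", stacklevel=2
        )
        n_components = rank

    ssx = float((Xd**2).sum())
    ssy = float((Yd**2).sum())
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Yd.shape[1], n_components))
    T = np.zeros((n, n_components))
    xve = np.zeros(n_components)
    yve = np.zeros(n_components)

    Xa, Ya = Xd.copy(), Yd.copy()
    for a in range(n_components):
        M = Xa.T @ Ya
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        w = U[:, 0]
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            warnings.warn("degenerate component; stopping early", stacklevel=2)
            W, P, Q, T = W[:, :a], P[:, :a], Q[:, :a], T[:, :a]
            xve, yve = xve[:a], yve[:a]
            n_components = a
            break
        pvec = Xa.T @ t / tt
        qvec = Ya.T @ t / tt
        Xa = Xa - np.outer(t, pvec)
        if deflate_y:
            Ya = Ya - np.outer(t, qvec)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, qvec, t
        xve[a] = tt * float(pvec @ pvec) / ssx
        yve[a] = tt * float(qvec @ qvec) / ssy if ssy > 0 else 0.0

    scores = pd.DataFrame(
        T, index=X.index, columns=[f"component_{a + 1}" for a in range(n_components)]
    )
    return PLSDAModel(
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=scores,
        x_variance=xve,
        y_variance=yve,
        x_mean=x_mean,
        x_std=x_std,
        predictors=list(X.columns),
        classes=classes,
    )


def vip_scores(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a); the mean
    squared VIP equals 1 by construction.
    """
    ssy = model.y_variance
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no Y-variance; VIP undefined")
    W = model.x_weights
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = W.shape[0]
    vip = np.sqrt(p * (wn**2 @ ssy) / total)
    return pd.Series(vip, index=model.predictors, name="vip")


def select_components(model: PLSDAModel, variance_target: float = 0.95) -> list[int]:
    """Smallest leading prefix of components whose cumulative X-variance
    reaches ``variance_target``; all components (with a warning) if the target
    is unreachable.  Returns 0-based component indices."""
    cum = np.cumsum(model.x_variance)
    reached = np.flatnonzero(cum >= variance_target - 1e-12)
    if len(reached) == 0:
        warnings.warn(
            f"variance target {variance_target} unreachable with "
            f"{model.n_components} components (cumulative {cum[-1]:.3f}); using all",
            stacklevel=2,
        )
        return list(range(model.n_components))
    return list(range(int(reached[0]) + 1))


def score_outlier_screen(model: PLSDAModel, components: list[int] | None = None, alpha: float = 0.001):
    """Mahalanobis outlier screen on the (selected) PLS score columns."""
    cols = model.scores.columns if components is None else model.scores.columns[components]
    return mahalanobis_screen(model.scores.loc[:, cols], alpha=alpha)
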