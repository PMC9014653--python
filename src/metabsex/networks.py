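"""Weighted correlation networks over metabolites: soft-thresholded adjacency,
topological overlap, branch-cut module detection, eigen-metabolites, module
membership, and eigen-correlation module merging."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

__all__ = [
    "CorrelationNetwork",
    "ModulePartition",
    "EigenMetabolites",
    "build_network",
    "topological_overlap",
    "pick_soft_threshold",
    "cluster_modules",
    "compute_eigen",
    "merge_close_modules",
    "MODULE_COLORS",
]

# WGCNA-style color labels, assigned to modules in decreasing size order
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
GREY = "grey"


@dataclass
class CorrelationNetwork:
    similarity: pd.DataFrame  # |correlation|
    adjacency: pd.DataFrame  # similarity ** beta
    tom: pd.DataFrame
    beta: float

    @property
    def metabolites(self) -> pd.Index:
        return self.similarity.index


@dataclass
class ModulePartition:
    labels: pd.Series  # metabolite -> color label; GREY = unassigned
    min_cluster_size: int
    merge_history: list = field(default_factory=list)

    def modules(self) -> list[str]:
        """Assigned module labels, largest first (GREY excluded)."""
        counts = self.labels[self.labels != GREY].value_counts()
        return list(counts.index)

    def members(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


@dataclass
class EigenMetabolites:
    eigens: pd.DataFrame  # participants x module
    membership: pd.Series  # metabolite -> correlation with own-module eigen (NaN for grey)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij),
    with k_i the connectivity excluding the diagonal, and unit diagonal."""
    A = np.asarray(adjacency, dtype=float)
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=0)
    numer = A0 @ A0 + A0
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(clean, beta: float = 10, signed: bool = False) -> CorrelationNetwork:
    """Similarity = |Pearson correlation| (or (1+r)/2 when ``signed``),
    adjacency = similarity ** beta with unit diagonal, plus the TOM."""
    matrix = clean.matrix if hasattr(clean, "matrix") else pd.DataFrame(clean)
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 metabolites to build a network")
    if beta < 1:
        raise ValueError("soft-threshold power beta must be >= 1")
    sd = matrix.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant metabolite column(s): {bad}")
    corr = matrix.corr()
    S = (1 + corr) / 2 if signed else corr.abs()
    A = S**beta
    np.fill_diagonal(A.values, 1.0)
    tom = pd.DataFrame(topological_overlap(A.to_numpy()), index=S.index, columns=S.columns)
    return CorrelationNetwork(similarity=S, adjacency=A, tom=tom, beta=float(beta))


def pick_soft_threshold(
    clean, candidate_powers=(1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20), n_bins: int = 10
) -> pd.DataFrame:
    """Scale-free-topology fit per candidate power.

    For each power, connectivities k are binned on log10 scale and
    log10 p(k) is regressed on log10 k; R^2 is negated when the slope is
    positive (scale-free topology requires a decreasing degree distribution).
    """
    matrix = clean.matrix if hasattr(clean, "matrix") else pd.DataFrame(clean)
    if matrix.shape[1] < 20:
        raise ValueError("need at least 20 metabolites for a degree distribution")
    S = matrix.corr().abs().to_numpy()
    np.fill_diagonal(S, 0.0)
    rows = []
    for power in candidate_powers:
        A0 = S**power
        k = A0.sum(axis=0)
        rows.append({"power": power, "r_squared": _scale_free_r2(k, n_bins), "mean_k": float(k.mean())})
    return pd.DataFrame(rows)


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if len(k) < 10 or np.ptp(k) < 1e-12:
        return np.nan
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    kmean = np.array([k[which == b].mean() if freq[b] else np.nan for b in range(n_bins)])
    ok = (freq > 0) & (kmean > 0)
    if ok.sum() < 3:
        return np.nan
    x = np.log10(kmean[ok])
    ylog = np.log10(freq[ok] / freq.sum())
    if np.ptp(x) < 1e-12:
        return np.nan
    slope, intercept = np.polyfit(x, ylog, 1)
    fitted = slope * x + intercept
    ss_res = float(((ylog - fitted) ** 2).sum())
    ss_tot = float(((ylog - ylog.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if np.isfinite(r2) and slope > 0:
        r2 = -r2
    return r2


def pick_power(table: pd.DataFrame, r2_min: float = 0.8) -> float | None:
    """Smallest candidate power whose scale-free fit R^2 reaches ``r2_min``."""
    ok = table[table["r_squared"] >= r2_min]
    return None if ok.empty else float(ok["power"].iloc[0])


def cluster_modules(
    network: CorrelationNetwork,
    min_cluster_size: int = 5,
    cut_height: float = 0.99,
    split_gap: float = 0.15,
    static: bool = False,
) -> ModulePartition:
    """Average-linkage clustering on 1 - TOM with a top-down branch cut.

    Branches are first separated at ``cut_height`` (1 - TOM dissimilarities
    lie in [0, 1], so 0.99 severs only essentially-unconnected branches);
    unless ``static``, each branch is further decomposed at
    merges whose height gap to their sub-branches is large, provided both
    sub-branches satisfy ``min_cluster_size``.  Clusters smaller than
    ``min_cluster_size`` become unassigned (grey).  Deterministic.
    """
    n = network.tom.shape[0]
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    if min_cluster_size > n:
        warnings.warn(
            f"min_cluster_size={min_cluster_size} exceeds n_metabolites={n}; "
            "every metabolite will be unassigned",
            stacklevel=2,
        )
    d = 1.0 - network.tom.to_numpy()
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    root = to_tree(Z)

    def _branch_leaves(node, min_size, gap_frac, static_cut):
        # recursive branch decomposition below the static cut
        if static_cut or node.is_leaf():
            return [node.pre_order(lambda x: x.id)]
        left, right = node.left, node.right
        gap_ok = node.dist > 0 and (node.dist - max(left.dist, right.dist)) >= gap_frac * node.dist
        if gap_ok and left.get_count() >= min_size and right.get_count() >= min_size:
            return _branch_leaves(left, min_size, gap_frac, static_cut) + _branch_leaves(
                right, min_size, gap_frac, static_cut
            )
        return [node.pre_order(lambda x: x.id)]

    flat: list[list[int]] = []

    def collect(node):
        if node.is_leaf() or node.dist <= cut_height:
            flat.extend(_branch_leaves(node, min_cluster_size, split_gap, static))
        else:
            collect(node.left)
            collect(node.right)

    collect(root)

    clusters = [c for c in flat if len(c) >= min_cluster_size]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    ids = network.metabolites
    labels = pd.Series(GREY, index=ids, name="module")
    for rank, members in enumerate(clusters):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        labels.iloc[members] = color
    return ModulePartition(labels=labels, min_cluster_size=min_cluster_size)


def compute_eigen(clean, partition: ModulePartition) -> EigenMetabolites:
    """Per-module eigen-metabolite (unit-variance first principal component of
    the standardized member columns, sign-aligned with the module mean
    profile) and per-metabolite module membership correlations."""
    matrix = clean.matrix if hasattr(clean, "matrix") else pd.DataFrame(clean)
    eigens = {}
    mm = pd.Series(np.nan, index=partition.labels.index, name="module_membership")
    for label in partition.modules():
        members = partition.members(label)
        sub = matrix.loc[:, members].to_numpy(dtype=float)
        sub = sub - sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise ValueError(f"constant member column in module {label!r}")
        sub = sub / sd
        if sub.shape[1] == 1:
            warnings.warn(f"module {label!r} has a single member; eigen equals that column", stacklevel=2)
            e = sub[:, 0]
        else:
            U, s, Vt = np.linalg.svd(sub, full_matrices=False)
            e = U[:, 0] * s[0]
        e = (e - e.mean()) / e.std(ddof=0)
        mean_profile = sub.mean(axis=1)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        eigens[label] = e
        for met in members:
            mm[met] = float(np.corrcoef(matrix[met].to_numpy(dtype=float), e)[0, 1])
    eig_df = pd.DataFrame(eigens, index=matrix.index)
    return EigenMetabolites(eigens=eig_df, membership=mm)


def merge_close_modules(
    clean,
    partition: ModulePartition,
    eigens: EigenMetabolites | None = None,
    merge_r: float = 0.9,
) -> tuple[ModulePartition, EigenMetabolites]:
    """Iteratively merge the module pair with the highest eigen-metabolite
    correlation while it strictly exceeds ``merge_r``, recomputing eigens after
    each merge.  Ties break on the lexicographically smallest label pair; the
    merged module keeps the larger module's label."""
    if eigens is None:
        eigens = compute_eigen(clean, partition)
    labels = partition.labels.copy()
    history = list(partition.merge_history)
    while True:
        current = ModulePartition(labels, partition.min_cluster_size, history)
        mods = current.modules()
        if len(mods) < 2:
            break
        E = eigens.eigens.loc[:, mods]
        C = E.corr().to_numpy()
        np.fill_diagonal(C, -np.inf)
        best = np.unravel_index(np.argmax(C), C.shape)
        best_r = C[best]
        if not best_r > merge_r:
            break
        # deterministic tie-break: smallest (sorted) label pair among maxima
        ties = np.argwhere(np.isclose(C, best_r, rtol=0, atol=1e-15))
        pairs = sorted({tuple(sorted((mods[i], mods[j]))) for i, j in ties})
        a, b = pairs[0]
        sizes = labels.value_counts()
        keep, absorb = (a, b) if sizes[a] >= sizes[b] else (b, a)
        labels[labels == absorb] = keep
        history.append({"kept": keep, "absorbed": absorb, "eigen_r": float(best_r)})
        eigens = compute_eigen(clean, ModulePartition(labels, partition.min_cluster_size))
    out = ModulePartition(labels, partition.min_cluster_size, history)
    eigens = compute_eigen(clean, out)
    return out, eigens
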