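"""Unsigned weighted co-expression network analysis.

Builds the powered absolute-correlation network, measures scale-free fit
to choose the soft-thresholding power, converts the adjacency to
topological overlap, clusters the overlap dissimilarity into modules, and
computes the trait statistics: module eigengenes E(q), gene significance
GS_i = |cor(x_i, T)|, and module membership kME_i(q) = cor(x_i, E(q)).

Genes below the minimum module size land in the catch-all "grey" module.
Module colors are assigned by decreasing module size from a fixed palette,
so labels are deterministic for a given input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .config import NetworkParams

#: color labels handed out by decreasing module size; grey is reserved for
#: unassigned genes.
MODULE_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)

GREY = "grey"


@dataclass
class ExpressionData:
    """Expression values (samples x genes) with a binary sample trait."""

    values: pd.DataFrame
    trait: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape[0] < 4:
            raise ValueError("need at least 4 samples")
        if self.values.columns.duplicated().any():
            raise ValueError("gene ids must be unique")
        self.trait = self.trait.reindex(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ModulePartition:
    """Gene -> module assignment plus per-gene and per-module statistics."""

    labels: pd.Series
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    gs: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)
    module_significance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def modules(self) -> list[str]:
        """Non-grey module labels ordered by decreasing size."""
        counts = self.labels[self.labels != GREY].value_counts()
        return list(counts.index)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _correlation(values: pd.DataFrame) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    tol = 1e-13 * np.maximum(1.0, np.abs(x).max(axis=0))
    if np.any(sd <= tol):
        bad = values.columns[np.where(sd <= tol)[0][0]]
        raise ValueError(f"gene '{bad}' has zero variance")
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x, rowvar=False)
    return np.clip(c, -1.0, 1.0)


def filter_genes_by_pcc(expr: ExpressionData, tau: float) -> ExpressionData:
    """Keep genes that have at least one partner with |PCC| >= tau.

    A pre-filter that discards genes unconnected to the rest of the
    network before the expensive steps; gene order is preserved.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    corr = np.abs(_correlation(expr.values))
    np.fill_diagonal(corr, 0.0)
    keep = corr.max(axis=1) >= tau
    if keep.sum() < 2:
        raise ValueError("filter too strict: fewer than 2 genes retained")
    values = expr.values.loc[:, keep]
    return ExpressionData(values=values, trait=expr.trait)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of the log-log degree-distribution fit.

    Connectivities are cut into ``n_bins`` equal-count bins; within each
    bin the empirical density (bin count / (N * bin width)) is regressed on
    the mean connectivity, both on log10 scales. The R^2 is negated when
    the slope is positive, following the scale-free topology convention
    that only decreasing degree distributions count as scale-free.
    """
    k = np.asarray(k, dtype=float)
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 4:
        return float("nan"), float("nan")
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    log_k, log_p = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        width = edges[b + 1] - edges[b]
        if mask.sum() == 0 or width <= 0:
            continue
        mean_k = k[mask].mean()
        density = mask.sum() / (len(k) * width)
        if mean_k <= 0 or density <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_p.append(np.log10(density))
    if len(log_k) < 3:
        return float("nan"), float("nan")
    fit = linregress(log_k, log_p)
    r2 = fit.rvalue**2
    signed = r2 if fit.slope <= 0 else -r2
    return float(signed), float(fit.slope)


def pick_soft_threshold(
    expr: ExpressionData, params: NetworkParams | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by the scale-free topology criterion.

    For each integer power in the search interval, the connectivity
    k_i = sum_j |cor(x_i, x_j)|^p is computed and its distribution tested
    for a power law. Returns the smallest power whose signed R^2 reaches
    ``r2_min`` while the mean connectivity stays above
    ``min_mean_connectivity`` (a fit achieved only on a near-empty network
    says nothing about topology). If none qualifies, the data is simply not
    scale-free at any usable power; picking the R^2-maximizing power would
    then favor degenerate near-empty networks (connectivity shrinks to
    zero as the power grows, so any residual network fits a line), so the
    fallback is instead the conventional sample-size-based default for
    unsigned networks (6 for >= 40 samples, 7 for 30-39, 8 for 20-29,
    9 below 20), clipped to the search interval, with a warning. The fit
    table has one row per power.
    """
    params = params or NetworkParams()
    corr = np.abs(_correlation(expr.values))
    np.fill_diagonal(corr, 0.0)
    lo, hi = params.power_search_interval
    rows = []
    for power in range(lo, hi + 1):
        k = (corr**power).sum(axis=1)
        signed_r2, slope = _scale_free_fit(k)
        rows.append(
            {
                "power": power,
                "signed_r2": signed_r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    qualifying = table[
        (table["signed_r2"] >= params.r2_min)
        & (table["mean_k"] >= params.min_mean_connectivity)
    ]
    if len(qualifying):
        beta = int(qualifying["power"].iloc[0])
    else:
        if table["signed_r2"].isna().all():
            raise ValueError("scale-free fit undefined for every power")
        m = expr.values.shape[0]
        default = 6 if m >= 40 else 7 if m >= 30 else 8 if m >= 20 else 9
        beta = int(np.clip(default, lo, hi))
        warnings.warn(
            f"no power reached signed R^2 >= {params.r2_min}; "
            f"falling back to the sample-size default power {beta}",
            stacklevel=2,
        )
    return beta, table


def adjacency(expr: ExpressionData, beta: float) -> pd.DataFrame:
    """Unsigned weighted adjacency a_ij = |cor(x_i, x_j)|^beta, a_ii = 0."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    corr = np.abs(_correlation(expr.values))
    adj = corr**beta
    np.fill_diagonal(adj, 0.0)
    genes = expr.gene_ids
    return pd.DataFrame(adj, index=genes, columns=genes)


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap: shared-neighbor similarity on top of adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with TOM_ii = 1.
    """
    a = adj.to_numpy(dtype=float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of a is zero, so u = i, j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def detect_modules(
    tom: pd.DataFrame, params: NetworkParams | None = None
) -> ModulePartition:
    """Cluster 1 - TOM by average linkage and cut at a fixed height.

    Clusters smaller than ``min_module_size`` are relabeled grey;
    surviving clusters receive palette colors ordered by decreasing size
    (ties broken by first gene position, so labels are deterministic).
    """
    params = params or NetworkParams()
    if params.min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = list(tom.index)
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=params.cut_height, criterion="distance")
    labels = pd.Series(GREY, index=genes, dtype=object)
    clusters: dict[int, list[int]] = {}
    for pos, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(pos)
    eligible = [
        (len(members), min(members), cid)
        for cid, members in clusters.items()
        if len(members) >= params.min_module_size
    ]
    eligible.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, cid) in enumerate(eligible):
        color = (
            MODULE_PALETTE[rank]
            if rank < len(MODULE_PALETTE)
            else f"module{rank + 1}"
        )
        for pos in clusters[cid]:
            labels.iloc[pos] = color
    return ModulePartition(labels=labels)


def module_eigengene(expr: ExpressionData, genes: list[str]) -> pd.Series:
    """First principal component of the standardized module submatrix.

    The eigengene has unit norm and its sign is flipped so the mean
    correlation of member genes with it is non-negative.
    """
    if len(genes) < 2:
        raise ValueError("module must have at least 2 genes")
    sub = expr.values[genes].to_numpy(dtype=float)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    if np.any(sd == 0):
        warnings.warn("module contains constant genes; treated as zero profiles", stacklevel=2)
        sd = np.where(sd == 0, 1.0, sd)
    std = (sub - mean) / sd
    u, s, _ = np.linalg.svd(std, full_matrices=False)
    if len(s) > 1 and np.isclose(s[0], s[1]):
        warnings.warn("degenerate leading spectrum; returning the first direction", stacklevel=2)
    e = u[:, 0]
    centered = std - std.mean(axis=0)
    e_c = e - e.mean()
    denom = np.linalg.norm(centered, axis=0) * np.linalg.norm(e_c)
    denom = np.where(denom == 0, 1.0, denom)
    cors = (centered.T @ e_c) / denom
    if cors.mean() < 0:
        e = -e
    return pd.Series(e, index=expr.sample_ids)


def gene_significance(expr: ExpressionData) -> pd.Series:
    """GS_i = |cor(x_i, T)| against the binary sample trait."""
    t = expr.trait.to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("trait has no contrast")
    x = expr.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    tc = t - t.mean()
    denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(tc)
    if np.any(denom == 0):
        raise ValueError("zero-variance gene encountered in gene significance")
    gs = np.abs(xc.T @ tc) / denom
    return pd.Series(np.clip(gs, 0.0, 1.0), index=expr.gene_ids, name="GS")


def module_significance(partition: ModulePartition, gs: pd.Series) -> pd.Series:
    """Mean gene significance over each module's members."""
    out = {}
    for module in partition.modules():
        out[module] = float(gs[partition.members(module)].mean())
    return pd.Series(out, name="module_significance").sort_values(ascending=False)


def module_membership(expr: ExpressionData, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME matrix: correlation of every gene with every module eigengene."""
    x = expr.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    e = eigengenes.to_numpy(dtype=float)
    ec = e - e.mean(axis=0)
    en = np.linalg.norm(ec, axis=0)
    denom = np.outer(xn, en)
    denom = np.where(denom == 0, 1.0, denom)
    kme = (xc.T @ ec) / denom
    return pd.DataFrame(
        np.clip(kme, -1.0, 1.0), index=expr.gene_ids, columns=eigengenes.columns
    )


def identify_hubs(
    partition: ModulePartition, top_k: int
) -> dict[str, list[str]]:
    """Top intra-modular hub genes per module.

    Members are ranked by own-module kME descending, ties broken by GS
    descending then lexicographic gene id.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    hubs: dict[str, list[str]] = {}
    for module in partition.modules():
        members = partition.members(module)
        ranked = sorted(
            members,
            key=lambda g: (-partition.kme.loc[g, module], -partition.gs[g], g),
        )
        hubs[module] = ranked[:top_k]
    return hubs


def analyze(
    expr: ExpressionData, params: NetworkParams | None = None
) -> tuple[ModulePartition, int, pd.DataFrame, pd.DataFrame]:
    """Full co-expression stage: filter, soft power, TOM, modules, statistics.

    Returns the completed partition, the chosen power, the soft-threshold
    fit table, and the adjacency matrix of the retained genes.
    """
    params = params or NetworkParams()
    filtered = filter_genes_by_pcc(expr, params.pcc_filter_tau)
    if params.beta is None:
        beta, fit_table = pick_soft_threshold(filtered, params)
    else:
        beta, fit_table = params.beta, pd.DataFrame()
    adj = adjacency(filtered, beta)
    tom = tom_similarity(adj)
    partition = detect_modules(tom, params)
    eig = {}
    for module in partition.modules():
        eig[module] = module_eigengene(filtered, partition.members(module))
    partition.eigengenes = pd.DataFrame(eig)
    partition.gs = gene_significance(filtered)
    if len(partition.eigengenes.columns):
        partition.kme = module_membership(filtered, partition.eigengenes)
    partition.module_significance = module_significance(partition, partition.gs)
    return partition, beta, fit_table, adj
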