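"""Weighted co-expression network construction and module analysis.

Implements biweight midcorrelation (bicor), soft-threshold selection by
scale-free fit, module detection via topological overlap and average-
linkage clustering with a static height cut, module eigengenes (first
principal components), module membership (kME), hub selection, and
module-trait correlation with Student p-values.

bicor standardizes by median and MAD and applies Tukey biweights
``(1 - u^2)^2`` with ``u = (x - median) / (9 * MAD)``, which makes the
correlation robust to the outliers and heavy tails typical of log
RNA-seq abundances. A vector whose MAD is zero falls back to Pearson
standardization (mean centring, unit weights) with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


@dataclass
class NetworkConfig:
    """Network construction parameters.

    ``beta`` is the soft-threshold power on |correlation| (non-integer
    values such as the 10.2 used for the TCGA-LUAD reference network are
    accepted); ``scale_free_target`` the signed R^2 a candidate power
    must reach; modules smaller than ``min_module_size`` are left
    unassigned (label 0, "grey"); modules whose eigengenes correlate
    above ``merge_me_cor`` are merged. ``cut_height`` fixes the static
    dendrogram cut as a fraction of the maximum merge height; when None
    (default) the cut height is chosen adaptively as the highest cut
    yielding the largest number of clusters of at least
    ``min_module_size``."""

    beta: float = 5.0
    candidate_powers: tuple[float, ...] = DEFAULT_POWERS
    scale_free_target: float = 0.8
    min_module_size: int = 100
    cut_height: float | None = None
    merge_me_cor: float = 0.75
    cor_method: str = "bicor"
    signed: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.scale_free_target <= 1:
            raise ValueError("scale_free_target must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class ModuleAssignment:
    """Per-gene module labels; 0 means unassigned (grey). Labels are
    numbered by module size, M1 largest."""

    gene_ids: list[str]
    labels: np.ndarray

    def members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    @property
    def module_labels(self) -> list[int]:
        labs = sorted(set(self.labels.tolist()) - {0})
        return labs

    def sizes(self) -> dict[int, int]:
        return {l: int((self.labels == l).sum()) for l in self.module_labels}


@dataclass
class EigengeneMatrix:
    """Sample x module eigengene scores (unit variance, sign-oriented so
    mean member kME is positive) plus per-module variance explained."""

    data: pd.DataFrame  # samples x modules, columns "M1", "M2", ...
    variance_explained: dict[str, float] = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ModuleTraitCorr:
    """Module x trait bicor, Student p, and per-cell sample counts."""

    bicor: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.DataFrame


def _bicor_prepare(X: np.ndarray) -> np.ndarray:
    """Weight-standardize each row of X for bicor: returns rows scaled to
    unit Euclidean norm so that bicor = dot product of prepared rows."""
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    fallback = (mad == 0).ravel()
    if fallback.any():
        warnings.warn(
            f"bicor: {int(fallback.sum())} vector(s) with zero MAD fall back to "
            "Pearson standardization",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    out = (X - med) * w
    if fallback.any():
        Xf = X[fallback]
        out[fallback] = Xf - Xf.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = out / norm
    out[norm.ravel() == 0] = np.nan
    return out


def bicor_matrix(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Biweight midcorrelation between the rows of X (and of Y, if given).

    Complete data only; use :func:`bicor` for pairwise-complete handling
    of vectors with missing values."""
    gx = _bicor_prepare(X)
    gy = gx if Y is None else _bicor_prepare(Y)
    r = gx @ gy.T
    return np.clip(r, -1.0, 1.0)


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two sample vectors (pairwise-complete:
    positions missing in either vector are dropped first)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("bicor needs >= 3 complete observations")
    return float(bicor_matrix(np.vstack([x[ok], y[ok]]))[0, 1])


def correlation_student_p(r: float | np.ndarray, n: int | np.ndarray) -> float | np.ndarray:
    """Two-sided Student p for a correlation: t = r*sqrt((n-2)/(1-r^2))
    on n-2 degrees of freedom. |r| = 1 returns p = 0."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 3):
        raise ValueError("need n >= 3 for a correlation p-value")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    if p.ndim == 0:
        return float(p)
    return p


def _adjacency(cor: np.ndarray, beta: float, signed: bool) -> np.ndarray:
    if signed:
        return ((1.0 + cor) / 2.0) ** beta
    return np.abs(cor) ** beta


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit: R^2 of log10 p(k) on log10 k over
    occupancy-weighted bins, reported positive when the slope is negative
    (the direction a scale-free degree distribution has)."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    occupied = counts > 0
    mean_k = np.array(
        [k[which == b].mean() if counts[b] else np.nan for b in range(n_bins)]
    )
    x = np.log10(mean_k[occupied])
    y = np.log10(counts[occupied] / k.size)
    w = counts[occupied].astype(float)
    if x.size < 3 or np.ptp(x) == 0:
        return 0.0
    wm_x, wm_y = np.average(x, weights=w), np.average(y, weights=w)
    cov = np.average((x - wm_x) * (y - wm_y), weights=w)
    var_x = np.average((x - wm_x) ** 2, weights=w)
    var_y = np.average((y - wm_y) ** 2, weights=w)
    if var_x == 0 or var_y == 0:
        return 0.0
    slope = cov / var_x
    r2 = cov**2 / (var_x * var_y)
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    expr: ExpressionMatrix, config: NetworkConfig | None = None
) -> tuple[float, pd.DataFrame]:
    """Evaluate candidate soft-threshold powers and return the smallest
    one whose signed scale-free fit reaches the target (plus the full fit
    table with mean connectivity per power). If no power reaches the
    target the best-fitting power is returned with a warning."""
    config = config or NetworkConfig()
    if expr.n_genes < 50:
        raise ValueError("soft-threshold selection needs >= 50 genes")
    cor = _correlation(expr.values, config.cor_method)
    rows = []
    for power in config.candidate_powers:
        a = _adjacency(cor, power, config.signed)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append(
            {
                "power": power,
                "fit": scale_free_fit(k),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    reaching = table[table["fit"] >= config.scale_free_target]
    if len(reaching):
        beta = float(reaching.iloc[0]["power"])
    else:
        beta = float(table.loc[table["fit"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached scale-free fit {config.scale_free_target}; "
            f"using best fit at power {beta}",
            stacklevel=2,
        )
    return beta, table


def _correlation(values: np.ndarray, method: str) -> np.ndarray:
    if method == "bicor":
        return bicor_matrix(values)
    if method == "pearson":
        return np.clip(np.corrcoef(values), -1.0, 1.0)
    raise ValueError(f"unknown correlation method {method!r}")


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with unit diagonal."""
    a = np.array(adjacency, dtype=float)
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    expr: ExpressionMatrix, config: NetworkConfig | None = None
) -> ModuleAssignment:
    """Detect co-expression modules.

    Pipeline: |bicor|^beta adjacency -> topological overlap -> 1-TOM
    distance -> average-linkage hierarchical clustering -> static cut at
    ``cut_height`` x (max merge height) -> clusters below
    ``min_module_size`` set to grey -> modules with eigengene correlation
    above ``merge_me_cor`` merged to a fixpoint -> labels renumbered by
    size (M1 largest)."""
    config = config or NetworkConfig()
    cor = _correlation(expr.values, config.cor_method)
    if np.isnan(cor).any():
        warnings.warn(
            "constant gene(s) produce undefined correlations; treated as 0",
            stacklevel=2,
        )
        cor = np.nan_to_num(cor, nan=0.0)
    adj = _adjacency(cor, config.beta, config.signed)
    tom = topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # guard vs roundoff asymmetry
    Z = average(squareform(dist, checks=False))
    labels = _static_cut(Z, config.cut_height, config.min_module_size)
    # drop undersized clusters
    for lab, size in zip(*np.unique(labels, return_counts=True)):
        if size < config.min_module_size:
            labels[labels == lab] = 0
    if (labels == 0).all():
        warnings.warn("all genes are unassigned (grey)", stacklevel=2)
        return ModuleAssignment(gene_ids=expr.gene_ids, labels=labels)
    labels = _split_bipolar_modules(expr, labels, config.min_module_size)
    labels = _rescue_grey_genes(expr, labels)
    labels = _merge_close_modules(expr, labels, config.merge_me_cor)
    return ModuleAssignment(gene_ids=expr.gene_ids, labels=_renumber_by_size(labels))


def _static_cut(
    Z: np.ndarray, cut_height: float | None, min_module_size: int
) -> np.ndarray:
    """Flat clusters from a static dendrogram cut.

    With an explicit ``cut_height`` the tree is cut at that fraction of
    the maximum merge height. Otherwise candidate heights spanning the
    merge range are scanned and the highest cut producing the maximum
    number of clusters of size >= min_module_size is used — deterministic
    and robust to how far below the background-merge ceiling the real
    modules attach."""
    hmax = Z[:, 2].max()
    if cut_height is not None:
        return np.asarray(fcluster(Z, t=cut_height * hmax, criterion="distance"), dtype=int)
    hmin = Z[:, 2].min()
    best_labels, best_count, = None, -1
    for frac in np.linspace(0.999, 0.5, 100):
        t = hmin + frac * (hmax - hmin)
        labs = fcluster(Z, t=t, criterion="distance")
        _, counts = np.unique(labs, return_counts=True)
        n_big = int((counts >= min_module_size).sum())
        if n_big > best_count:  # first (highest) cut wins ties
            best_count, best_labels = n_big, labs
    return np.asarray(best_labels, dtype=int)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    labs, counts = np.unique(labels[labels != 0], return_counts=True)
    order = labs[np.lexsort((labs, -counts))]
    mapping = {int(old): new for new, old in enumerate(order, start=1)}
    out = np.zeros_like(labels)
    for old, new in mapping.items():
        out[labels == old] = new
    return out


def _split_bipolar_modules(
    expr: ExpressionMatrix, labels: np.ndarray, min_module_size: int,
    min_minor_frac: float = 0.1,
) -> np.ndarray:
    """Split modules that contain two anti-correlated gene sets.

    An unsigned network can cluster opposing co-expression groups into
    one module; such a module is bipolar — a substantial fraction of its
    members correlate negatively with its own eigengene. When the minor
    sign group exceeds ``min_minor_frac`` of the module, the module is
    split by kME sign; resulting groups below ``min_module_size`` go
    grey."""
    labels = labels.copy()
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    next_label = labels.max() + 1
    for lab in sorted(set(labels.tolist()) - {0}):
        idx = np.flatnonzero(labels == lab)
        assignment = ModuleAssignment(
            gene_ids=expr.gene_ids, labels=np.where(labels == lab, lab, 0)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            me = module_eigengenes(expr, assignment).data.iloc[:, 0].to_numpy()
            kme = bicor_matrix(expr.values[idx], me[None, :])[:, 0]
        neg = kme < 0
        minor = min(neg.sum(), (~neg).sum())
        if minor < min_minor_frac * idx.size:
            continue
        for group in (neg, ~neg):
            gidx = idx[group]
            if gidx.size >= min_module_size:
                labels[gidx] = next_label
                next_label += 1
            else:
                labels[gidx] = 0
    return labels


def _rescue_grey_genes(
    expr: ExpressionMatrix, labels: np.ndarray, min_kme: float = 0.3
) -> np.ndarray:
    """kME-based membership curation: an unassigned gene joins the module
    whose eigengene it correlates with most, provided that correlation
    reaches ``min_kme``. One pass against the pre-rescue eigengenes."""
    grey = np.flatnonzero(labels == 0)
    labs = sorted(set(labels.tolist()) - {0})
    if grey.size == 0 or not labs:
        return labels
    assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        me = module_eigengenes(expr, assignment)
        kme = bicor_matrix(expr.values[grey], me.data.to_numpy().T)
    best = np.argmax(kme, axis=1)
    best_val = kme[np.arange(grey.size), best]
    labels = labels.copy()
    joined = best_val >= min_kme
    labels[grey[joined]] = np.asarray(labs)[best[joined]]
    return labels


def _merge_close_modules(
    expr: ExpressionMatrix, labels: np.ndarray, merge_me_cor: float
) -> np.ndarray:
    """Iteratively merge the most correlated eigengene pair until no pair
    exceeds the merge threshold."""
    labels = labels.copy()
    while True:
        labs = sorted(set(labels.tolist()) - {0})
        if len(labs) < 2:
            return labels
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=labels)
        me = module_eigengenes(expr, assignment)
        cor = np.corrcoef(me.data.to_numpy().T)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= merge_me_cor:
            return labels
        keep, absorb = labs[min(i, j)], labs[max(i, j)]
        labels[labels == absorb] = keep


def module_eigengenes(
    expr: ExpressionMatrix, assignment: ModuleAssignment
) -> EigengeneMatrix:
    """First principal component of each module's standardized expression.

    Eigengenes have unit variance and are sign-oriented so the mean
    correlation of member genes with their eigengene is positive.
    Zero-variance genes are dropped from the computation with a warning."""
    labs = assignment.module_labels
    if not labs:
        raise ValueError("no modules to compute eigengenes for")
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    cols, var_exp = {}, {}
    vals = expr.values
    for lab in labs:
        idx = [gene_index[g] for g in assignment.members(lab)]
        X = vals[idx]
        sd = X.std(axis=1, ddof=1)
        if (sd == 0).any():
            warnings.warn(
                f"module M{lab}: {(sd == 0).sum()} zero-variance gene(s) dropped "
                "from eigengene computation",
                stacklevel=2,
            )
            X = X[sd > 0]
            sd = sd[sd > 0]
        Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        me = Vt[0]
        me = me / me.std(ddof=1)
        if np.mean([np.corrcoef(row, me)[0, 1] for row in Xs]) < 0:
            me = -me
        cols[f"M{lab}"] = me
        var_exp[f"M{lab}"] = float(s[0] ** 2 / (s**2).sum())
    data = pd.DataFrame(cols, index=expr.sample_ids)
    return EigengeneMatrix(data=data, variance_explained=var_exp)


def kme_table(
    expr: ExpressionMatrix, eigengenes: EigengeneMatrix, cor_method: str = "bicor"
) -> pd.DataFrame:
    """Module membership: correlation of every gene with every module
    eigengene (genes x modules)."""
    me = eigengenes.data.to_numpy().T  # modules x samples
    if cor_method == "bicor":
        r = bicor_matrix(expr.values, me)
    elif cor_method == "pearson":
        X = expr.values - expr.values.mean(axis=1, keepdims=True)
        M = me - me.mean(axis=1, keepdims=True)
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        M /= np.linalg.norm(M, axis=1, keepdims=True)
        r = np.clip(X @ M.T, -1, 1)
    else:
        raise ValueError(f"unknown correlation method {cor_method!r}")
    return pd.DataFrame(r, index=expr.gene_ids, columns=eigengenes.module_names)


def hub_genes(
    kme: pd.DataFrame, assignment: ModuleAssignment, top_frac: float = 0.1
) -> dict[int, list[str]]:
    """Top ``ceil(top_frac * module size)`` members of each module by
    own-module kME, ties broken by gene ID (deterministic)."""
    hubs: dict[int, list[str]] = {}
    for lab in assignment.module_labels:
        members = assignment.members(lab)
        scores = kme.loc[members, f"M{lab}"]
        n_top = ceil(top_frac * len(members))
        ranked = sorted(members, key=lambda g: (-scores[g], g))
        hubs[lab] = ranked[:n_top]
    return hubs


def module_trait_correlation(
    eigengenes: EigengeneMatrix, traits: pd.DataFrame
) -> ModuleTraitCorr:
    """Pairwise-complete bicor of each module eigengene with each numeric
    trait, with Student p-values and the per-cell sample count."""
    modules = eigengenes.module_names
    trait_names = list(traits.columns)
    shared = eigengenes.data.index.intersection(traits.index)
    me = eigengenes.data.loc[shared]
    tr = traits.loc[shared]
    r = pd.DataFrame(np.nan, index=modules, columns=trait_names)
    p = pd.DataFrame(np.nan, index=modules, columns=trait_names)
    n = pd.DataFrame(0, index=modules, columns=trait_names)
    for t in trait_names:
        tv = tr[t].to_numpy(dtype=float)
        ok = np.isfinite(tv)
        for m in modules:
            mv = me[m].to_numpy(dtype=float)
            use = ok & np.isfinite(mv)
            n.loc[m, t] = int(use.sum())
            if use.sum() < 3 or np.ptp(tv[use]) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rv = bicor(mv[use], tv[use])
            if np.isfinite(rv):
                r.loc[m, t] = rv
                p.loc[m, t] = correlation_student_p(rv, int(use.sum()))
    return ModuleTraitCorr(bicor=r, p=p, n_used=n)


def module_overlap_fisher(
    labels_a: dict[str, int] | pd.Series, labels_b: dict[str, int] | pd.Series
) -> pd.DataFrame:
    """One-tailed Fisher (hypergeometric upper tail) overlap p-values
    between the modules of two labelings of the same gene universe,
    BH-adjusted across all module pairs. Returns the adjusted matrix."""
    from statsmodels.stats.multitest import multipletests

    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if set(a.index) != set(b.index):
        raise ValueError("labelings must share the same gene universe")
    b = b.loc[a.index]
    universe = len(a)
    labs_a = sorted(set(a) - {0})
    labs_b = sorted(set(b) - {0})
    raw = np.empty((len(labs_a), len(labs_b)))
    for i, la in enumerate(labs_a):
        in_a = a == la
        for j, lb in enumerate(labs_b):
            in_b = b == lb
            overlap = int((in_a & in_b).sum())
            raw[i, j] = stats.hypergeom.sf(
                overlap - 1, universe, int(in_a.sum()), int(in_b.sum())
            )
    adj = multipletests(raw.ravel(), method="fdr_bh")[1].reshape(raw.shape)
    return pd.DataFrame(
        adj, index=[f"A{l}" for l in labs_a], columns=[f"B{l}" for l in labs_b]
    )


def plot_module_trait_heatmap(corr: ModuleTraitCorr, path: str, p_max: float = 0.05):
    """Module x trait bicor heatmap with Student p overlays on
    significant cells."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = corr.bicor
    fig, ax = plt.subplots(
        figsize=(max(6, 0.6 * r.shape[1]), max(4, 0.4 * r.shape[0]))
    )
    im = ax.imshow(r.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(r.shape[0]), r.index, fontsize=7)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            pv = corr.p.iat[i, j]
            if np.isfinite(pv) and pv <= p_max:
                ax.text(j, i, f"{pv:.1g}", ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, label="bicor")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
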