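"""Stage-wise differential expression on log2 expression.

Per-gene one-way ANOVA across pathologic stages, Tukey HSD pairwise
contrasts (studentized-range adjusted), Welch two-group t-tests for
binary groupings (stage 1 vs rest, OS event groups), Benjamini-Hochberg
FDR across genes, and DEG calling at adjusted p < 0.05 and |L2FC| > 0.5
(both strict). L2FC is the difference of group means of log2 values
(group 2 minus group 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

#: Default DEG thresholds.
P_THRESHOLD = 0.05
L2FC_THRESHOLD = 0.5


@dataclass
class DegThresholds:
    p: float = P_THRESHOLD
    l2fc: float = L2FC_THRESHOLD
    use_raw_p: bool = False  # threshold raw p instead of BH-adjusted
    inclusive: bool = False  # <= / >= instead of strict < / >


def _group_arrays(values: np.ndarray, groups: np.ndarray) -> tuple[list[np.ndarray], list]:
    """Split a gene x sample matrix by group label, dropping labels with
    fewer than 2 samples (with a warning) and missing labels."""
    groups = np.asarray(groups, dtype=float)
    ok = np.isfinite(groups)
    out, labels = [], []
    for g in np.unique(groups[ok]):
        idx = np.flatnonzero(groups == g)
        if idx.size < 2:
            warnings.warn(f"group {g!r} has < 2 samples; dropped", stacklevel=3)
            continue
        out.append(values[:, idx])
        labels.append(g)
    return out, labels


def stage_anova(
    expr: ExpressionMatrix, stages: Sequence[float]
) -> pd.DataFrame:
    """Classical one-way F test per gene of equal mean expression across
    stage groups. Genes with zero within-group variance get a null
    record."""
    arrays, labels = _group_arrays(expr.values, np.asarray(stages, dtype=float))
    if len(arrays) < 2:
        raise ValueError("need >= 2 stage groups with >= 2 samples each")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays, axis=1)
    return pd.DataFrame({"F": f, "p": p}, index=expr.gene_ids)


def tukey_pairwise(
    expr: ExpressionMatrix, stages: Sequence[float]
) -> dict[tuple[float, float], pd.DataFrame]:
    """Tukey HSD adjusted p-values for every stage pair, per gene.

    Uses the studentized range distribution with the pooled within-group
    MSE of the one-way ANOVA, vectorised across genes. Returns a mapping
    (stage_a, stage_b) -> per-gene table with the mean difference
    (b - a) and adjusted p."""
    arrays, labels = _group_arrays(expr.values, np.asarray(stages, dtype=float))
    k = len(arrays)
    if k < 2:
        raise ValueError("need >= 2 stage groups with >= 2 samples each")
    ns = np.array([a.shape[1] for a in arrays])
    means = np.column_stack([a.mean(axis=1) for a in arrays])  # genes x k
    sse = sum(((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for a in arrays)
    df = int(ns.sum() - k)
    mse = sse / df
    out = {}
    for i, j in combinations(range(k), 2):
        diff = means[:, j] - means[:, i]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.abs(diff) / se
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.studentized_range.sf(q, k, df)
        p = np.where(np.isfinite(q), np.clip(p, 0.0, 1.0), np.nan)
        out[(labels[i], labels[j])] = pd.DataFrame(
            {"diff": diff, "p_adj": p}, index=expr.gene_ids
        )
    return out


def group_ttest(
    values: np.ndarray, binary_groups: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t test (two-sided) along the sample axis.

    ``values`` may be a vector or a gene x sample matrix; group 1 minus
    group 0 orientation for the t statistic."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    groups = np.asarray(binary_groups, dtype=float)
    a = values[:, groups == 1]
    b = values[:, groups == 0]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t, p = np.atleast_1d(t), np.atleast_1d(p)
    if t.size == 1:
        return float(t[0]), float(p[0])
    return t, p


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at
    1). NaN entries are passed through untouched."""
    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_degs(
    l2fc: Sequence[float],
    p: Sequence[float],
    gene_ids: Sequence[str],
    comparison: str = "",
    thresholds: DegThresholds | None = None,
) -> pd.DataFrame:
    """Flag differentially expressed genes.

    A gene is a DEG when its (BH-adjusted, by default) p-value beats the
    p threshold and |L2FC| exceeds the fold-change threshold — both
    strict inequalities by default. Direction follows the sign of L2FC."""
    th = thresholds or DegThresholds()
    l2fc = np.asarray(l2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    fdr = p if th.use_raw_p else bh_adjust(p)
    if th.inclusive:
        is_deg = (fdr <= th.p) & (np.abs(l2fc) >= th.l2fc)
    else:
        is_deg = (fdr < th.p) & (np.abs(l2fc) > th.l2fc)
    is_deg &= np.isfinite(fdr) & np.isfinite(l2fc)
    return pd.DataFrame(
        {
            "gene": list(gene_ids),
            "comparison": comparison,
            "l2fc": l2fc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(l2fc >= 0, "up", "down"),
            "is_deg": is_deg,
        }
    ).set_index("gene")


def run_stage_comparisons(
    expr: ExpressionMatrix,
    stages: Sequence[float],
    thresholds: DegThresholds | None = None,
) -> dict[str, pd.DataFrame]:
    """The two headline comparisons: stage 1 vs stage 2 (one-way ANOVA on
    the two groups) and stage 1 vs all later stages (Welch t). Both share
    the L2FC convention (later-stage mean minus stage-1 mean) and BH-FDR
    DEG calling."""
    stages = np.asarray(stages, dtype=float)
    vals = expr.values
    out = {}

    pair_mask = np.isin(stages, (1.0, 2.0))
    sub = vals[:, pair_mask]
    sub_stages = stages[pair_mask]
    anova = stage_anova(
        ExpressionMatrix(
            expr.data.loc[:, pair_mask], scale=expr.scale
        ),
        sub_stages,
    )
    l2fc = sub[:, sub_stages == 2].mean(axis=1) - sub[:, sub_stages == 1].mean(axis=1)
    out["stage1-vs-2"] = call_degs(
        l2fc, anova["p"].to_numpy(), expr.gene_ids, "stage1-vs-2", thresholds
    )

    binary = np.where(stages > 1, 1.0, 0.0)
    binary[~np.isfinite(stages)] = np.nan
    ok = np.isfinite(binary)
    t, p = group_ttest(vals[:, ok], binary[ok])
    l2fc = vals[:, ok][:, binary[ok] == 1].mean(axis=1) - vals[:, ok][
        :, binary[ok] == 0
    ].mean(axis=1)
    out["stage1-vs-rest"] = call_degs(
        l2fc, np.atleast_1d(p), expr.gene_ids, "stage1-vs-rest", thresholds
    )
    return out


def deg_summary(degs: pd.DataFrame, module_of: dict[str, int] | None = None) -> pd.DataFrame:
    """Up/down DEG counts, optionally per module."""
    d = degs[degs["is_deg"]].copy()
    if module_of is not None:
        d["module"] = [module_of.get(g, 0) for g in d.index]
        return d.groupby(["module", "direction"]).size().unstack(fill_value=0)
    return d.groupby("direction").size().to_frame("count").T


def volcano_plot(
    degs: pd.DataFrame, path: str, l2fc_line: float = 0.58, fdr_line: float = 0.05
) -> None:
    """L2FC vs -log10 FDR with cut lines (the plotted fold-change line
    defaults to log2(1.5) ~ 0.58; the calling threshold is separate)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        y = -np.log10(degs["fdr"].to_numpy(dtype=float))
    ax.scatter(degs["l2fc"], y, s=4, c=np.where(degs["is_deg"], "crimson", "grey"))
    for x in (-l2fc_line, l2fc_line):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.axhline(-np.log10(fdr_line), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 FDR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
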