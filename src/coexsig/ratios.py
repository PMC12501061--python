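"""Exhaustive combinatorial sum-ratio prognostic scoring ranked by
time-point ROC AUC.

The discovery engine: candidate numerator genes (high expression predicts
high survival) and denominator genes (the inverse) are combined in all
1:1, 2:2, 3:3 and 4:4 sum ratios; each combination's per-sample score is
evaluated against fixed-horizon binary survival outcomes at five time
points (12 months, 18 months, 3, 5 and 10 years) by ROC AUC with DeLong
confidence intervals, and combinations are ranked by mean AUC over
configurable time-point subsets. Candidates come either from hub/DEG
nomination (network + differential expression) or from survival-time
correlation.

Scores enter the ROC through a single-covariate logistic fit; since the
fitted probabilities are a monotone transform of the score (orientation
chosen by the fit), the reported AUC is the score's concordance oriented
to be >= 0.5, which the vectorised search computes directly from ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SignatureDef
from .network import bicor
from .survival import SurvivalData

DEFAULT_TIMEPOINTS = (365, 548, 1095, 1825, 3650)
DEFAULT_RANK_SUBSETS = {
    "all": (365, 548, 1095, 1825, 3650),
    "excl-10y": (365, 548, 1095, 1825),
    "excl-5y-10y": (365, 548, 1095),
}
DENOMINATOR_GUARD = 1e-9


@dataclass
class RatioSearchConfig:
    """Ratio enumeration and ranking parameters."""

    timepoints_days: tuple[int, ...] = DEFAULT_TIMEPOINTS
    max_side_size: int = 4
    rank_subsets: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_RANK_SUBSETS)
    )
    top_k_for_frequency: int = 100
    frequency_threshold: float = 0.2

    def __post_init__(self) -> None:
        tp = tuple(self.timepoints_days)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints_days must be strictly increasing")
        if self.max_side_size < 1:
            raise ValueError("max_side_size must be >= 1")


def cluster3_normalize(expr: ExpressionMatrix, tol: float = 1e-12) -> ExpressionMatrix:
    """Three-step normalization: (1) log2(x+1); (2) per-sample median
    centring; (3) per-gene scaling to unit variance.

    Step 3 scales rather than centres: the sum-ratio statistic needs
    sign-stable "normalized abundances" — centring every gene at zero
    would make denominator sums straddle zero and turn the ratio into an
    uninformative heavy-tailed variable, so gene-level baselines are
    deliberately preserved. Steps 2-3 are iterated to a joint fixpoint so
    both invariants (sample medians 0, gene variances 1) hold
    simultaneously and re-application is a no-op; the recipe is recorded
    in ``data.attrs['normalization']``."""
    if expr.scale != "raw":
        raise ValueError("three-step normalization expects raw-scale input")
    vals = np.log2(expr.values + 1.0)
    if np.ptp(vals) == 0:
        warnings.warn("constant expression matrix normalizes to all zeros", stacklevel=2)
    for _ in range(200):
        sample_med = np.median(vals, axis=0, keepdims=True)
        vals = vals - sample_med
        gene_sd = vals.std(axis=1, ddof=1, keepdims=True)
        safe = np.where(gene_sd > 0, gene_sd, 1.0)
        vals = vals / safe
        if np.abs(sample_med).max() < tol and np.abs(safe - 1.0).max() < tol:
            break
    out = ExpressionMatrix(
        pd.DataFrame(vals, index=expr.gene_ids, columns=expr.sample_ids),
        scale="normalized",
    )
    out.data.attrs["normalization"] = (
        "log2(x+1); per-sample median centring; per-gene unit-variance "
        "scaling (steps 2-3 iterated to fixpoint)"
    )
    return out


def ratio_score(norm: ExpressionMatrix, sig: SignatureDef) -> np.ndarray:
    """Per-sample sum-ratio score: sum of numerator-gene values over sum
    of denominator-gene values. Samples whose denominator sum is within
    the guard of zero get a null (NaN) score; the invert flag negates."""
    missing = [g for g in sig.genes if g not in norm.data.index]
    if missing:
        raise KeyError(f"signature {sig.name!r}: genes missing from matrix: {missing}")
    num = norm.data.loc[sig.numerator_genes].to_numpy(dtype=float).sum(axis=0)
    den = norm.data.loc[sig.denominator_genes].to_numpy(dtype=float).sum(axis=0)
    guarded = np.abs(den) < DENOMINATOR_GUARD
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / den
    score[guarded] = np.nan
    if guarded.any():
        warnings.warn(
            f"{int(guarded.sum())} sample(s) excluded: denominator sum within "
            f"{DENOMINATOR_GUARD} of zero",
            stacklevel=2,
        )
    return -score if sig.invert else score


def binarize_outcome(surv: SurvivalData, t_days: float) -> np.ndarray:
    """Fixed-horizon binary outcome at time t: 1 = died by t, 0 =
    survived past t (censoring after t is irrelevant), NaN = censored
    before t (excluded)."""
    if t_days <= 0:
        raise ValueError("t_days must be > 0")
    died = (surv.event == 1) & (surv.time <= t_days)
    survived = surv.time >= t_days
    return np.where(died, 1.0, np.where(survived, 0.0, np.nan))


@dataclass
class LogisticFit:
    probs: np.ndarray
    intercept: float
    coef: float
    converged: bool
    separated: bool


def fit_logistic(
    score: Sequence[float],
    binary_outcome: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Single-covariate logistic regression by IRLS (binomial family,
    logit link). Perfect separation is flagged; fitted probabilities are
    still returned."""
    x = np.asarray(score, dtype=float)
    y = np.asarray(binary_outcome, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = separated = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-10:
            separated = True
            break
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            separated = True
            break
        beta += step
        if np.abs(step).max() < tol:
            converged = True
            break
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    if not separated and (np.abs(beta[1]) * (x.std() + 1e-300) > 30):
        separated = True
    if separated:
        warnings.warn("logistic fit: perfect or quasi-perfect separation", stacklevel=2)
    probs = np.full(len(ok), np.nan)
    probs[ok] = mu
    return LogisticFit(
        probs=probs,
        intercept=float(beta[0]),
        coef=float(beta[1]),
        converged=converged,
        separated=separated,
    )


def roc_auc(score: Sequence[float], binary_outcome: Sequence[float]) -> float:
    """Mann-Whitney concordance AUC: (#concordant + 0.5 #ties) /
    (n1 * n0). NaN scores or outcomes are excluded."""
    x = np.asarray(score, dtype=float)
    y = np.asarray(binary_outcome, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = stats.rankdata(x)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_variance(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    pos = x[y == 1]
    neg = x[y == 0]
    n1, n0 = len(pos), len(neg)
    ranks_all = stats.rankdata(x)
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks_all[y == 1] - ranks_pos) / n0  # placement of each positive
    v01 = 1.0 - (ranks_all[y == 0] - ranks_neg) / n1  # placement of each negative
    auc = float(v10.mean())
    var = 0.0
    if n1 > 1:
        var += v10.var(ddof=1) / n1
    if n0 > 1:
        var += v01.var(ddof=1) / n0
    return auc, float(var)


def auc_ci(
    score: Sequence[float], binary_outcome: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """DeLong normal-approximation CI for the AUC (truncated to [0, 1])
    and the two-sided p-value against AUC = 0.5. A degenerate variance
    yields the widest interval [0, 1] with p = NaN."""
    x = np.asarray(score, dtype=float)
    y = np.asarray(binary_outcome, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("need at least one positive and one negative")
    auc, var = _delong_variance(x, y)
    if var <= 0:
        warnings.warn("degenerate DeLong variance; widest CI returned", stacklevel=2)
        return 0.0, 1.0, float("nan")
    se = np.sqrt(var)
    zc = stats.norm.ppf(0.5 + level / 2.0)
    low = max(0.0, auc - zc * se)
    high = min(1.0, auc + zc * se)
    p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    return float(low), float(high), float(p)


def count_combinations(n_num: int, n_den: int, max_side_size: int = 4) -> int:
    """Closed-form count of equal-sized pairings: sum_k C(n,k)*C(m,k)."""
    return sum(
        comb(n_num, k) * comb(n_den, k) for k in range(1, max_side_size + 1)
    )


def enumerate_combinations(
    num_candidates: Sequence[str],
    den_candidates: Sequence[str],
    max_side_size: int = 4,
) -> Iterator[SignatureDef]:
    """All unordered k-subsets of each side for k = 1..max_side_size,
    paired only at equal k, in deterministic lexical order. Sides must be
    disjoint; a k larger than a side is skipped."""
    num = sorted(set(num_candidates))
    den = sorted(set(den_candidates))
    if set(num) & set(den):
        raise ValueError("candidate lists must be disjoint")
    for k in range(1, max_side_size + 1):
        if k > len(num) or k > len(den):
            continue
        for nc in combinations(num, k):
            for dc in combinations(den, k):
                yield SignatureDef(
                    name="+".join(nc) + "/" + "+".join(dc),
                    numerator_genes=list(nc),
                    denominator_genes=list(dc),
                )


def _subset_sums(values: np.ndarray, subsets: list[tuple[int, ...]]) -> np.ndarray:
    out = np.empty((len(subsets), values.shape[1]))
    for i, sub in enumerate(subsets):
        out[i] = values[list(sub)].sum(axis=0)
    return out


def _roc_metrics_block(
    scores: np.ndarray, y: np.ndarray, full: bool
) -> dict[str, np.ndarray]:
    """Vectorised per-row ROC metrics for a block of score rows against a
    single binary outcome vector (NaN = excluded sample).

    Rows are oriented the way a logistic fit would orient them, so the
    reported AUC is max(concordance, 1 - concordance); CI/p (DeLong) and
    the Youden-threshold confusion metrics follow that orientation."""
    nrow = scores.shape[0]
    valid_y = np.isfinite(y)
    res = {
        k: np.full(nrow, np.nan)
        for k in ("auc", "ci_low", "ci_high", "p", "accuracy", "sensitivity", "specificity")
    }
    res["n_used"] = np.zeros(nrow)
    res["n_events"] = np.zeros(nrow)
    if valid_y.sum() == 0 or len(np.unique(y[valid_y])) < 2:
        return res

    s = np.where(valid_y[None, :], scores, np.nan)
    valid = np.isfinite(s)
    pos = (y == 1) & valid_y
    neg = (y == 0) & valid_y
    n1 = (valid & pos[None, :]).sum(axis=1).astype(float)
    n0 = (valid & neg[None, :]).sum(axis=1).astype(float)
    res["n_used"] = n1 + n0
    res["n_events"] = n1
    usable = (n1 > 0) & (n0 > 0)

    ranks = stats.rankdata(s, axis=1, nan_policy="omit")
    pos_rank_sum = np.nansum(np.where(pos[None, :], ranks, 0.0), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        auc_raw = (pos_rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    flip = auc_raw < 0.5
    auc = np.where(flip, 1.0 - auc_raw, auc_raw)
    res["auc"] = np.where(usable, auc, np.nan)
    if not full:
        return res

    # DeLong variance from placement values, vectorised over rows.
    s_pos = np.where(pos[None, :], s, np.nan)
    s_neg = np.where(neg[None, :], s, np.nan)
    ranks_pos = stats.rankdata(s_pos, axis=1, nan_policy="omit")
    ranks_neg = stats.rankdata(s_neg, axis=1, nan_policy="omit")
    with np.errstate(divide="ignore", invalid="ignore"):
        v10 = (ranks - ranks_pos) / n0[:, None]
        v01 = 1.0 - (ranks - ranks_neg) / n1[:, None]
    v10 = np.where(flip[:, None], 1.0 - v10, v10)
    v01 = np.where(flip[:, None], 1.0 - v01, v01)

    def _nanvar_ddof1(a: np.ndarray, counts: np.ndarray) -> np.ndarray:
        mean = np.nanmean(a, axis=1)
        ss = np.nansum((a - mean[:, None]) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(counts > 1, ss / np.maximum(counts - 1, 1), 0.0)

    var = np.zeros(nrow)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = _nanvar_ddof1(v10, n1) / n1 + _nanvar_ddof1(v01, n0) / n0
    se = np.sqrt(var)
    zc = stats.norm.ppf(0.975)
    with np.errstate(invalid="ignore"):
        res["ci_low"] = np.where(usable, np.clip(auc - zc * se, 0.0, 1.0), np.nan)
        res["ci_high"] = np.where(usable, np.clip(auc + zc * se, 0.0, 1.0), np.nan)
        p = 2.0 * stats.norm.sf(np.abs(auc - 0.5) / np.where(se > 0, se, np.nan))
    res["p"] = np.where(usable, p, np.nan)

    # Youden-optimal confusion metrics on the oriented score.
    oriented = np.where(flip[:, None], -s, s)
    oriented_f = np.where(np.isfinite(oriented), oriented, -np.inf)
    order = np.argsort(-oriented_f, axis=1, kind="stable")
    pos_sorted = np.take_along_axis(
        np.broadcast_to(pos & valid_y, oriented.shape).copy(), order, axis=1
    )
    neg_sorted = np.take_along_axis(
        np.broadcast_to(neg & valid_y, oriented.shape).copy(), order, axis=1
    )
    finite_sorted = np.take_along_axis(np.isfinite(oriented), order, axis=1)
    tp = np.cumsum(pos_sorted & finite_sorted, axis=1).astype(float)
    fp = np.cumsum(neg_sorted & finite_sorted, axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpr = tp / n1[:, None]
        fpr = fp / n0[:, None]
    youden = tpr - fpr
    best = np.argmax(youden, axis=1)
    rows = np.arange(nrow)
    sens = tpr[rows, best]
    spec = 1.0 - fpr[rows, best]
    acc = (tp[rows, best] + (n0 - fp[rows, best])) / np.maximum(n1 + n0, 1)
    res["sensitivity"] = np.where(usable, sens, np.nan)
    res["specificity"] = np.where(usable, spec, np.nan)
    res["accuracy"] = np.where(usable, acc, np.nan)
    return res


def evaluate_all_ratios(
    norm: ExpressionMatrix,
    surv: SurvivalData,
    num_candidates: Sequence[str],
    den_candidates: Sequence[str],
    config: RatioSearchConfig | None = None,
    full_metrics: bool = True,
    chunk_size: int = 2048,
) -> pd.DataFrame:
    """Evaluate every equal-sized sum-ratio combination at every time
    point.

    For each combination x time point the per-sample score is binarized
    against the fixed-horizon outcome and summarised as the logistic-
    oriented ROC AUC; with ``full_metrics`` the DeLong CI and p and the
    Youden-threshold accuracy/sensitivity/specificity are added. Mean
    AUCs over the configured rank subsets are appended. Fully
    deterministic given the inputs. Time points where only one outcome
    class exists give null cells; means are taken over the rest."""
    config = config or RatioSearchConfig()
    missing = [
        g
        for g in list(num_candidates) + list(den_candidates)
        if g not in norm.data.index
    ]
    if missing:
        raise KeyError(f"candidate genes missing from matrix: {missing}")
    if len(surv) != norm.n_samples:
        raise ValueError("survival data and matrix differ in sample count")

    num = sorted(set(num_candidates))
    den = sorted(set(den_candidates))
    if set(num) & set(den):
        raise ValueError("candidate lists must be disjoint")
    gene_row = {g: i for i, g in enumerate(norm.data.index)}
    vals = norm.values

    outcomes = {t: binarize_outcome(surv, t) for t in config.timepoints_days}

    frames = []
    for k in range(1, config.max_side_size + 1):
        if k > len(num) or k > len(den):
            continue
        num_subsets = list(combinations([gene_row[g] for g in num], k))
        den_subsets = list(combinations([gene_row[g] for g in den], k))
        num_names = ["+".join(c) for c in combinations(num, k)]
        den_names = ["+".join(c) for c in combinations(den, k)]
        num_sums = _subset_sums(vals, num_subsets)
        den_sums = _subset_sums(vals, den_subsets)
        den_guard = np.abs(den_sums) < DENOMINATOR_GUARD

        n_pairs = len(num_subsets) * len(den_subsets)
        pair_idx = 0
        while pair_idx < n_pairs:
            block = min(chunk_size, n_pairs - pair_idx)
            ii = (np.arange(pair_idx, pair_idx + block) // len(den_subsets)).astype(int)
            jj = (np.arange(pair_idx, pair_idx + block) % len(den_subsets)).astype(int)
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = num_sums[ii] / den_sums[jj]
            scores[den_guard[jj]] = np.nan
            rec: dict[str, np.ndarray] = {}
            for t in config.timepoints_days:
                m = _roc_metrics_block(scores, outcomes[t], full=full_metrics)
                for key, arr in m.items():
                    if full_metrics or key in ("auc", "n_used", "n_events"):
                        rec[f"{key}_{t}"] = arr
            df = pd.DataFrame(rec)
            df.insert(0, "k", k)
            df.insert(
                0,
                "signature",
                [f"{num_names[i]}/{den_names[j]}" for i, j in zip(ii, jj)],
            )
            df.insert(1, "numerator", [num_names[i] for i in ii])
            df.insert(2, "denominator", [den_names[j] for j in jj])
            frames.append(df)
            pair_idx += block

    if not frames:
        raise ValueError("no combinations to evaluate (sides too small?)")
    out = pd.concat(frames, ignore_index=True)
    for name, subset in config.rank_subsets.items():
        cols = [f"auc_{t}" for t in subset if f"auc_{t}" in out.columns]
        out[f"mean_auc_{name}"] = out[cols].mean(axis=1)
    return out


def evaluate_signatures(
    norm: ExpressionMatrix,
    surv: SurvivalData,
    signatures: Sequence[SignatureDef],
    config: RatioSearchConfig | None = None,
    full_metrics: bool = True,
) -> pd.DataFrame:
    """Per-timepoint ROC evaluation of an explicit list of signatures
    (same metrics and columns as :func:`evaluate_all_ratios`)."""
    config = config or RatioSearchConfig()
    if len(surv) != norm.n_samples:
        raise ValueError("survival data and matrix differ in sample count")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = np.vstack([ratio_score(norm, sig) for sig in signatures])
    rec: dict[str, np.ndarray] = {}
    for t in config.timepoints_days:
        m = _roc_metrics_block(scores, binarize_outcome(surv, t), full=full_metrics)
        for key, arr in m.items():
            if full_metrics or key in ("auc", "n_used", "n_events"):
                rec[f"{key}_{t}"] = arr
    out = pd.DataFrame(rec)
    out.insert(0, "signature", [sig.name for sig in signatures])
    out.insert(1, "numerator", ["+".join(sig.numerator_genes) for sig in signatures])
    out.insert(2, "denominator", ["+".join(sig.denominator_genes) for sig in signatures])
    out.insert(3, "k", [len(sig.numerator_genes) for sig in signatures])
    for name, subset in config.rank_subsets.items():
        cols = [f"auc_{t}" for t in subset if f"auc_{t}" in out.columns]
        out[f"mean_auc_{name}"] = out[cols].mean(axis=1)
    return out


def rank_by_mean_auc(evals: pd.DataFrame, subset_name: str = "all") -> pd.DataFrame:
    """Sort descending by the named subset's mean AUC; ties broken by the
    full-subset mean, then signature name."""
    col = f"mean_auc_{subset_name}"
    if col not in evals.columns:
        raise KeyError(f"unknown rank subset {subset_name!r}")
    if not len(evals):
        raise ValueError("empty evaluation table")
    tiebreak = "mean_auc_all" if "mean_auc_all" in evals.columns else col
    out = evals.sort_values(
        [col, tiebreak, "signature"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def top_gene_frequency(
    ranked: pd.DataFrame, config: RatioSearchConfig | None = None
) -> pd.DataFrame:
    """Per-gene frequency among the top-k ranked signatures, reported per
    side; genes above the frequency threshold are flagged for the next
    nomination round."""
    config = config or RatioSearchConfig()
    k = config.top_k_for_frequency
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} evaluations available (< top_k={k}); using all",
            stacklevel=2,
        )
        k = len(ranked)
    top = ranked.head(k)
    rows = []
    for side, col in (("num", "numerator"), ("den", "denominator")):
        counts: dict[str, int] = {}
        for cell in top[col]:
            for g in str(cell).split("+"):
                counts[g] = counts.get(g, 0) + 1
        for g, c in counts.items():
            rows.append(
                {
                    "gene": g,
                    "side": side,
                    "count": c,
                    "frequency": c / k,
                    "selected": c / k > config.frequency_threshold,
                }
            )
    return (
        pd.DataFrame(rows, columns=["gene", "side", "count", "frequency", "selected"])
        .sort_values(["side", "frequency", "gene"], ascending=[True, False, True])
        .reset_index(drop=True)
    )


def select_survival_correlated(
    norm: ExpressionMatrix,
    surv: SurvivalData,
    top_n_per_direction: int,
    uncensored_only: bool = False,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Nominate candidates by bicor of each gene with survival time:
    the ``top_n`` most positively correlated genes become numerator
    candidates, the most negative become denominator candidates.

    All samples are used by default — censored times understate true
    survival but keep the correlation's sign, and the doubled sample
    size stabilizes the ranking; ``uncensored_only`` restricts to
    observed deaths."""
    if top_n_per_direction > norm.n_genes:
        raise ValueError("top_n_per_direction exceeds gene count")
    mask = surv.event == 1 if uncensored_only else np.ones(len(surv), dtype=bool)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 usable samples for survival correlation")
    times = surv.time[mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from .network import bicor_matrix

        r = bicor_matrix(norm.values[:, mask], times[None, :])[:, 0]
    table = pd.DataFrame(
        {"gene": norm.gene_ids, "bicor_os_time": r, "n_used": int(mask.sum())}
    ).sort_values("bicor_os_time", ascending=False, kind="stable")
    numerator = table.head(top_n_per_direction)["gene"].tolist()
    denominator = table.tail(top_n_per_direction)["gene"].tolist()[::-1]
    return numerator, denominator, table.reset_index(drop=True)
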