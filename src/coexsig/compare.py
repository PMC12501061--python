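"""Comparison of prognostic signatures.

Scores arbitrary sum-ratio signatures on a normalized matrix (tolerating
partially missing gene lists), correlates the scores to module eigengenes
and to quantitative survival-time traits with bicor + Student p,
correlates signatures to each other with Pearson, and compares AUCs of
two signatures with the paired DeLong test (placement-value covariance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SignatureDef
from .network import EigengeneMatrix, bicor, correlation_student_p
from .ratios import ratio_score

#: A signature is skipped when more than this fraction of either side is
#: absent from the expression matrix.
MAX_MISSING_FRAC = 0.5


@dataclass
class SignatureComparison:
    scores: pd.DataFrame  # samples x signatures
    module_bicor: pd.DataFrame | None = None
    module_p: pd.DataFrame | None = None
    survival_bicor: pd.DataFrame | None = None
    survival_p: pd.DataFrame | None = None
    pearson_r: pd.DataFrame | None = None
    pearson_p: pd.DataFrame | None = None


def score_signatures(
    norm: ExpressionMatrix, signatures: Sequence[SignatureDef]
) -> pd.DataFrame:
    """Per-sample ratio score for each signature (samples x signatures).

    Genes absent from the matrix are dropped per side with a logged
    fraction; a signature loses its column (with a warning) when more
    than half of either side is missing."""
    cols = {}
    present = set(norm.data.index)
    for sig in signatures:
        num = [g for g in sig.numerator_genes if g in present]
        den = [g for g in sig.denominator_genes if g in present]
        frac_num = 1 - len(num) / len(sig.numerator_genes)
        frac_den = 1 - len(den) / len(sig.denominator_genes)
        if frac_num > MAX_MISSING_FRAC or frac_den > MAX_MISSING_FRAC or not num or not den:
            warnings.warn(
                f"signature {sig.name!r} skipped: {frac_num:.0%} of numerator / "
                f"{frac_den:.0%} of denominator genes missing",
                stacklevel=2,
            )
            continue
        if frac_num > 0 or frac_den > 0:
            warnings.warn(
                f"signature {sig.name!r}: dropped {frac_num:.0%} numerator / "
                f"{frac_den:.0%} denominator genes missing from matrix",
                stacklevel=2,
            )
        reduced = SignatureDef(
            name=sig.name, numerator_genes=num, denominator_genes=den, invert=sig.invert
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cols[sig.name] = ratio_score(norm, reduced)
    return pd.DataFrame(cols, index=norm.sample_ids)


def _bicor_with_p(
    scores: pd.DataFrame, targets: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete bicor + Student p of every score column against
    every target column."""
    shared = scores.index.intersection(targets.index)
    s, t = scores.loc[shared], targets.loc[shared]
    r = pd.DataFrame(np.nan, index=scores.columns, columns=targets.columns)
    p = pd.DataFrame(np.nan, index=scores.columns, columns=targets.columns)
    for sig in scores.columns:
        sv = s[sig].to_numpy(dtype=float)
        for col in targets.columns:
            tv = t[col].to_numpy(dtype=float)
            ok = np.isfinite(sv) & np.isfinite(tv)
            if ok.sum() < 3 or np.ptp(sv[ok]) == 0 or np.ptp(tv[ok]) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rv = bicor(sv[ok], tv[ok])
            if np.isfinite(rv):
                r.loc[sig, col] = rv
                p.loc[sig, col] = correlation_student_p(rv, int(ok.sum()))
    return r, p


def signature_module_bicor(
    scores: pd.DataFrame, eigengenes: EigengeneMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """bicor + Student p of each signature score against each module
    eigengene."""
    return _bicor_with_p(scores, eigengenes.data)


def signature_survival_bicor(
    scores: pd.DataFrame,
    traits: pd.DataFrame,
    survival_traits: Sequence[str] = ("OS.time",),
    events: pd.Series | None = None,
    uncensored_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """bicor + Student p of signature scores against quantitative
    survival-time traits, restricted to uncensored samples (those with an
    observed event) by default."""
    cols = [c for c in survival_traits if c in traits.columns]
    target = traits[cols]
    if uncensored_only:
        if events is None:
            if "OS" not in traits.columns:
                raise ValueError("need event indicators (OS) for uncensored-only mode")
            events = traits["OS"]
        keep = events.loc[target.index] == 1
        target = target.loc[keep[keep].index]
    return _bicor_with_p(scores, target)


def signature_pearson(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signature x signature Pearson correlation (pairwise-complete) with
    Student p; symmetric with unit diagonal."""
    names = list(scores.columns)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            x = scores[a].to_numpy(dtype=float)
            y = scores[b].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(x[ok], y[ok])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def delong_paired_test(
    score_a: Sequence[float],
    score_b: Sequence[float],
    binary_outcome: Sequence[float],
) -> tuple[float, float, float]:
    """Paired DeLong test of two AUCs on the same samples.

    Returns (auc_a, auc_b, two-sided p). The variance of the AUC
    difference uses the placement-value covariance structure; identical
    or monotone-equivalent scores give p = 1."""
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    y = np.asarray(binary_outcome, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(y)
    a, b, y = a[ok], b[ok], y[ok]
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both outcome classes")

    def placements(x: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        ranks_all = stats.rankdata(x)
        v10 = (ranks_all[y == 1] - stats.rankdata(x[y == 1])) / n0
        v01 = 1.0 - (ranks_all[y == 0] - stats.rankdata(x[y == 0])) / n1
        return float(v10.mean()), v10, v01

    auc_a, v10_a, v01_a = placements(a)
    auc_b, v10_b, v01_b = placements(b)
    if np.array_equal(stats.rankdata(a), stats.rankdata(b)):
        return auc_a, auc_b, 1.0

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (
        s10[0, 0] / n1
        + s10[1, 1] / n1
        - 2 * s10[0, 1] / n1
        + s01[0, 0] / n0
        + s01[1, 1] / n0
        - 2 * s01[0, 1] / n0
    )
    if var <= 0:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(p)


def plot_signature_heatmap(
    r: pd.DataFrame, p: pd.DataFrame, path: str, p_max: float = 0.05, scale: float = 1.0
) -> None:
    """Signature x target bicor heatmap with p-value overlays on cells
    significant at ``p_max``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(5, 0.5 * r.shape[1]), max(3, 0.5 * r.shape[0])))
    im = ax.imshow(
        r.to_numpy(dtype=float), cmap="RdBu_r", vmin=-scale, vmax=scale, aspect="auto"
    )
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(r.shape[0]), r.index, fontsize=7)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            pv = p.iat[i, j]
            if np.isfinite(pv) and pv <= p_max:
                ax.text(j, i, f"{pv:.1g}", ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, label="bicor")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
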