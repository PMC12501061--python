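"""Kaplan-Meier curves, median-split grouping and univariate Cox models.

The Cox model is fit by Newton iteration on the partial likelihood with
Breslow handling of tied event times; inference (p-value and 95% CI on
the hazard ratio) is by the Wald statistic from the observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io import ClinicalTable


@dataclass
class SurvivalData:
    """Right-censored survival outcomes: time in days, event 1 = death."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not np.isfinite(self.time).all() or (self.time < 0).any():
            raise ValueError("survival times must be finite and non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("events must be coded 0/1")

    @classmethod
    def from_clinical(cls, clinical: ClinicalTable) -> "SurvivalData":
        df = clinical.data
        return cls(
            sample_ids=list(df.index),
            time=df["os_time_days"].to_numpy(dtype=float),
            event=df["os_event"].to_numpy(dtype=int),
        )

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class CoxResult:
    """Univariate Cox fit: hazard ratio with Wald 95% CI and p-value."""

    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    n: int
    n_events: int
    beta: float
    se: float
    converged: bool = True
    separation: bool = False


def median_split(score: Sequence[float]) -> np.ndarray:
    """Binary high/low grouping at the median; ties at the median go to
    the low group (1 = high). Deterministic in the input order."""
    score = np.asarray(score, dtype=float)
    if score.size < 4:
        raise ValueError("median split needs >= 4 samples")
    if np.ptp(score[np.isfinite(score)]) == 0:
        raise ValueError("cannot median-split a constant score")
    med = np.nanmedian(score)
    return (score > med).astype(int)


def km_estimate(
    surv: SurvivalData, groups: Sequence[int] | None = None
) -> dict[int, pd.DataFrame]:
    """Product-limit survival estimates, one step function per group
    (group ``0`` holds everyone when no grouping is given). Each entry is
    a table of (time, survival)."""
    groups = np.zeros(len(surv), dtype=int) if groups is None else np.asarray(groups)
    out: dict[int, pd.DataFrame] = {}
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask])
        sf = kmf.survival_function_
        out[int(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def _breslow_stats(beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray):
    """Log partial likelihood, score and information under Breslow ties.

    Arrays must be sorted by descending time so that risk sets are prefix
    cumulative sums."""
    eta = beta * x
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    # index of the last row sharing each row's time (risk set boundary)
    last = np.searchsorted(-t, -t, side="right") - 1
    ev = e == 1
    r0, r1, r2 = s0[last[ev]], s1[last[ev]], s2[last[ev]]
    loglik = float(np.sum(eta[ev]) - np.sum(np.log(r0)))
    score = float(np.sum(x[ev] - r1 / r0))
    info = float(np.sum(r2 / r0 - (r1 / r0) ** 2))
    return loglik, score, info


def cox_univariate(
    covariate: Sequence[float],
    surv: SurvivalData,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit.

    Newton iteration on the Breslow partial likelihood (convergence on
    the coefficient to ``tol``); HR = exp(beta) with Wald p and 95% CI
    from the observed information. A monotone likelihood (perfect
    separation) is flagged and reported with an infinite CI."""
    x = np.asarray(covariate, dtype=float)
    if x.shape[0] != len(surv):
        raise ValueError("covariate and survival data differ in length")
    n_events = int(surv.event.sum())
    if n_events < 2:
        raise ValueError("need >= 2 events to fit a Cox model")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")

    order = np.argsort(-surv.time, kind="stable")
    t, e, xs = surv.time[order], surv.event[order], x[order]
    sd = xs.std()

    beta, converged, separation = 0.0, False, False
    for _ in range(max_iter):
        _, score, info = _breslow_stats(beta, t, e, xs)
        if info <= 1e-12:
            separation = True
            break
        step = score / info
        step = np.clip(step, -5.0 / sd, 5.0 / sd)  # damp early overshoot
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) * sd > 50:
            separation = True
            break

    _, _, info = _breslow_stats(beta, t, e, xs)
    if separation or info <= 1e-12:
        warnings.warn("monotone partial likelihood (perfect separation)", stacklevel=2)
        return CoxResult(
            hr=float(np.exp(beta)),
            ci_low=0.0,
            ci_high=np.inf,
            wald_p=np.nan,
            n=len(surv),
            n_events=n_events,
            beta=float(beta),
            se=np.inf,
            converged=False,
            separation=True,
        )
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    zc = stats.norm.ppf(0.975)
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zc * se)),
        ci_high=float(np.exp(beta + zc * se)),
        wald_p=float(p),
        n=len(surv),
        n_events=n_events,
        beta=float(beta),
        se=float(se),
        converged=converged,
    )


def median_split_cox(score: Sequence[float], surv: SurvivalData) -> CoxResult:
    """HR of the high-score group vs the low-score group under a median
    split (the Fig.-4-style analysis on eigengenes or single genes)."""
    groups = median_split(score)
    return cox_univariate(groups.astype(float), surv)


def km_plot(
    surv: SurvivalData,
    groups: Sequence[int],
    path: str,
    labels: dict[int, str] | None = None,
    annotate: CoxResult | None = None,
) -> None:
    """Kaplan-Meier plot per group with optional HR/CI/p annotation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = km_estimate(surv, groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, df in curves.items():
        name = (labels or {}).get(g, f"group {g}")
        ax.step(df["time"], df["survival"], where="post", label=name)
    if annotate is not None:
        ax.text(
            0.05,
            0.05,
            f"HR={annotate.hr:.2f} ({annotate.ci_low:.2f}-{annotate.ci_high:.2f})\n"
            f"Wald p={annotate.wald_p:.2g}",
            transform=ax.transAxes,
            fontsize=8,
        )
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
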