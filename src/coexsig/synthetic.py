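"""Synthetic expression + clinical data with the structure the analysis assumes.

The generator emulates the data regime of a bulk RNA-seq tumour cohort in
which two anti-correlated co-expressed gene blocks (an M6-like protective
block and an M3-like hazardous block) sit in a background of unstructured
genes. Each sample carries a malignancy factor pair ``(f1, f2)`` with a
negative correlation and an equally anti-correlated co-regulation pair
``(u1, u2)``; block genes load on their block's factors, pathologic stage
is an ordinal draw shifted along the ``f2 - f1`` contrast, and overall
survival is exponential with log-hazard ``h1*f1 + h2*f2`` (``h1 < 0``:
high block-1 expression is protective). Expression is exponentiated to an
FPKM-like dynamic range and zero-inflated at a global low-abundance
threshold, so the whole preprocessing path (zero filter, log2, outlier
removal, covariate regression) is exercised.

Ground truth (block labels, latent factors, hazard coefficients, and the
planted 4+4 signature formed by the full-loading core genes of each block)
is returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix, SignatureDef, write_clinical, write_expression

#: Marginal stage distribution at stage_effect=0 (stage 1..4), matching a
#: predominantly early-stage adenocarcinoma cohort.
STAGE_MARGINAL = (0.53, 0.25, 0.17, 0.05)

_SUBSTAGE = {1: ("IA", "IB"), 2: ("IIA", "IIB"), 3: ("IIIA", "IIIB"), 4: ("IV", "IV")}


@dataclass
class SimulationParams:
    """Parameters of the synthetic cohort.

    The first two ``module_sizes`` are the planted anti-correlated blocks
    (block 1 = protective / M6-like, block 2 = hazardous / M3-like);
    remaining genes are unstructured background. ``within_module_cor`` is
    the target mean pairwise correlation inside a block and
    ``block_anticor`` the target |correlation| between the two latent
    factors. ``stage_effect`` shifts the ordinal stage draw along the
    standardized block contrast ``f2 - f1`` (latent units on a
    standard-logistic noise scale), so both blocks are differentially
    expressed across stages, in opposite directions.
    ``hazard_coefs`` are log-hazard weights per factor unit;
    ``baseline_hazard`` and ``censor_rate`` are per-day exponential rates;
    follow-up is administratively capped at ``followup_cap_days``.
    ``signal_scale`` is the amplitude of the factor-plus-noise signal on
    the log2 scale (log2 FPKM sd of a typical variable gene).
    """

    n_samples: int = 300
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (150, 150)
    within_module_cor: float = 0.35
    block_anticor: float = 0.7
    stage_effect: float = 2.0
    hazard_coefs: tuple[float, float] = (-1.0, 1.0)
    baseline_hazard: float = 5.5e-4
    censor_rate: float = 4.0e-4
    followup_cap_days: float = 3650.0
    zero_inflation: float = 0.3
    signal_scale: float = 1.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.module_sizes) < 2 or any(s < 1 for s in self.module_sizes):
            raise ValueError("module_sizes needs >= 2 positive block sizes")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes must sum to <= n_genes")
        if not 0 < self.within_module_cor < 1:
            raise ValueError("within_module_cor must be in (0, 1)")
        if not 0 < self.block_anticor < 1:
            raise ValueError("block_anticor must be in (0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.followup_cap_days <= 0:
            raise ValueError("followup_cap_days must be > 0")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.signal_scale <= 0:
            raise ValueError("signal_scale must be > 0")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    gene_block_labels: np.ndarray  # per-gene block id, 0 = background
    latent_factors: np.ndarray  # n_samples x n_blocks malignancy factors
    true_hazard_coefs: tuple[float, float]
    planted_signature: SignatureDef = field(default=None)  # type: ignore[assignment]
    loadings: np.ndarray = field(default=None)  # type: ignore[assignment]
    coreg_factors: np.ndarray = field(default=None)  # type: ignore[assignment]


def _draw_factor_pair(rng: np.random.Generator, params: SimulationParams) -> np.ndarray:
    """A pair of standard-normal factors with corr = -block_anticor; any
    further blocks get independent factors."""
    n_blocks = len(params.module_sizes)
    f = rng.standard_normal((params.n_samples, n_blocks))
    rho = -params.block_anticor
    f[:, 1] = rho * f[:, 0] + np.sqrt(1 - rho**2) * f[:, 1]
    return f


def generate_dataset(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Generate an FPKM-like expression matrix, a clinical table and the
    planted ground truth. Identical params (including seed) reproduce
    bit-identical outputs."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, g = params.n_samples, params.n_genes

    factors = _draw_factor_pair(rng, params)  # malignancy axis (drives outcomes)
    coreg = _draw_factor_pair(rng, params)  # co-regulation axis (tightness only)

    labels = np.zeros(g, dtype=int)
    start = 0
    for b, size in enumerate(params.module_sizes, start=1):
        labels[start : start + size] = b
        start += size

    # Factor model on the log2 scale:
    #   signal = scale * (lambda*f_b + mu*u_b + noise)
    # where f is the malignancy factor (stage and hazard depend on it)
    # and u an equally anti-correlated co-regulation factor that carries
    # module coherence but no outcome information — real modules cohere
    # through shared regulation of which only part tracks the disease
    # axis. Each block has a 4-gene core (the planted signature: full
    # malignancy loading, ordinary gene-level noise — the top-kME hubs a
    # module carries in practice); peripheral members load mostly on the
    # co-regulation axis (lambda in [0.25, 0.5], mu in [0.45, 0.75]),
    # with noise set so the mean pairwise within-block correlation hits
    # within_module_cor.
    r = params.within_module_cor
    n_core = 4
    core_mu = 0.55
    loadings = np.zeros(g)
    signal = np.empty((g, n))
    mean_cross = 0.375**2 + 0.6**2  # E[lam]E[lam'] + E[mu]E[mu']
    mean_var = (0.5**3 - 0.25**3) / (3 * 0.25) + (0.75**3 - 0.45**3) / (3 * 0.3)
    noise_sd = np.sqrt(max(mean_cross / r - mean_var, 0.04))
    bg_sd = np.sqrt(mean_var + noise_sd**2)
    for b in range(1, len(params.module_sizes) + 1):
        idx = np.flatnonzero(labels == b)
        lam = rng.uniform(0.25, 0.5, idx.size)
        mu = rng.uniform(0.45, 0.75, idx.size)
        sd = np.full(idx.size, noise_sd)
        if idx.size >= n_core:
            lam[:n_core] = 1.0
            mu[:n_core] = core_mu
        loadings[idx] = lam
        signal[idx] = (
            lam[:, None] * factors[:, b - 1][None, :]
            + mu[:, None] * coreg[:, b - 1][None, :]
            + sd[:, None] * rng.standard_normal((idx.size, n))
        )
    bg = np.flatnonzero(labels == 0)
    signal[bg] = bg_sd * rng.standard_normal((bg.size, n))

    # Module members are detectably expressed (co-expression presupposes
    # signal above the noise floor) and block cores are abundant, several
    # log2 units above the typical sample median — the regime in which
    # sums of normalized abundances stay sign-stable. Background genes
    # span the full FPKM dynamic range (2^1..2^12) including barely
    # expressed transcripts.
    baseline = 1.0 + 11.0 * rng.beta(1.2, 3.0, g)  # right-skewed: most genes low
    baseline[labels > 0] = 4.0 + 8.0 * rng.beta(1.5, 2.0, int((labels > 0).sum()))
    core_mask = loadings == 1.0
    baseline[core_mask] = rng.uniform(8.0, 12.0, int(core_mask.sum()))
    log2_expr = baseline[:, None] + params.signal_scale * signal
    fpkm = np.maximum(np.exp2(log2_expr) - 1.0, 0.0)
    if params.zero_inflation > 0:
        # Zeros arise from a global low-abundance detection floor: the
        # bottom zero_inflation quantile of all FPKM entries reads 0, so
        # lowly expressed transcripts are mostly zero (the input regime
        # of the >= 50%-zero filter) while well-expressed genes are not.
        thresh = np.quantile(fpkm, params.zero_inflation)
        fpkm = np.where(fpkm <= thresh, 0.0, fpkm)

    # Ordinal stage shifted along the block eigengenes (cumulative-logit
    # draw on the standardized block contrast f2 - f1), so the hazardous
    # block rises and the protective block falls with advancing stage —
    # the antagonistic pattern the analysis is built to detect.
    cuts = stats.logistic.ppf(np.cumsum(STAGE_MARGINAL)[:-1])
    contrast = factors[:, 1] - factors[:, 0]
    contrast = contrast / np.sqrt(2.0 * (1.0 + params.block_anticor))
    latent = params.stage_effect * contrast + rng.logistic(size=n)
    stage = 1 + (latent[:, None] > cuts[None, :]).sum(axis=1)

    # Exponential survival with log-hazard h1*f1 + h2*f2; independent
    # exponential censoring capped at the follow-up horizon.
    h1, h2 = params.hazard_coefs
    hazard = params.baseline_hazard * np.exp(h1 * factors[:, 0] + h2 * factors[:, 1])
    t_death = rng.exponential(1.0 / hazard)
    if params.censor_rate > 0:
        t_censor = rng.exponential(1.0 / params.censor_rate, n)
    else:
        t_censor = np.full(n, np.inf)
    t_censor = np.minimum(t_censor, params.followup_cap_days)
    os_time = np.minimum(t_death, t_censor)
    os_event = (t_death <= t_censor).astype(int)

    age = np.clip(rng.normal(65.0, 10.0, n), 30.0, 90.0).round(1)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    sub_pick = rng.integers(0, 2, n)
    substage = [_SUBSTAGE[int(s)][int(k)] for s, k in zip(stage, sub_pick)]
    t_stage = stage.copy()
    n_stage = np.clip(stage - 1, 0, 2)
    m_stage = (stage == 4).astype(int)

    gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids), scale="raw"
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "stage": stage.astype(float),
                "substage": substage,
                "os_time_days": os_time,
                "os_event": os_event,
                "age": age,
                "sex": sex,
                "t_stage": t_stage.astype(float),
                "n_stage": n_stage.astype(float),
                "m_stage": m_stage.astype(float),
            },
            index=sample_ids,
        )
    )

    # Planted 4+4 signature: the core genes of each block. Block 1 is
    # protective (h1 < 0 by default) so its genes form the numerator.
    def _core(block: int) -> list[str]:
        idx = np.flatnonzero(labels == block)
        order = idx[np.argsort(-loadings[idx], kind="stable")][:4]
        return [gene_ids[i] for i in sorted(order)]

    planted = SignatureDef(
        name="planted-4x4", numerator_genes=_core(1), denominator_genes=_core(2)
    )
    truth = GroundTruth(
        gene_block_labels=labels,
        latent_factors=factors,
        true_hazard_coefs=(h1, h2),
        planted_signature=planted,
        loadings=loadings,
        coreg_factors=coreg,
    )
    return expr, clinical, truth


def write_dataset(
    out_prefix: str | Path,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write the standard expression and clinical TSVs (plus the ground
    truth, if given) under ``<out_prefix>.*``."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_prefix.with_suffix(".expression.tsv"),
        "clinical": out_prefix.with_suffix(".clinical.tsv"),
    }
    write_expression(paths["expression"], expr)
    write_clinical(paths["clinical"], clinical)
    if truth is not None:
        paths["truth"] = out_prefix.with_suffix(".truth.tsv")
        pd.DataFrame(
            {"gene_id": expr.gene_ids, "block": truth.gene_block_labels, "loading": truth.loadings}
        ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
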