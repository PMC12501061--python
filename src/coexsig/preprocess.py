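"""Expression cleaning: zero filtering, log2 transform, connectivity-based
outlier removal, covariate regression, and numeric trait encoding.

The intended order — zero filter and clinical cleaning on the raw scale,
then log2, then outlier removal and covariate regression — is enforced by
the scale tags on :class:`~coexsig.io.ExpressionMatrix`.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_missing_transcripts(
    expr: ExpressionMatrix, max_zero_frac: float = 0.5
) -> ExpressionMatrix:
    """Drop transcripts with >= ``max_zero_frac`` zero FPKM values (the
    threshold is inclusive). Row order of survivors is preserved."""
    if expr.scale != "raw":
        raise ValueError("zero filtering applies to raw-scale FPKM values")
    zero_frac = (expr.values == 0).mean(axis=1)
    keep = zero_frac < max_zero_frac
    if not keep.any():
        raise ValueError("zero filter removed every transcript")
    logger.info("zero filter: removed %d of %d transcripts", (~keep).sum(), expr.n_genes)
    return ExpressionMatrix(expr.data.loc[keep], scale="raw")


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); tags the matrix as log2 scale."""
    if expr.scale != "raw":
        raise ValueError("log2 transform expects raw-scale input")
    vals = expr.values
    if (vals < 0).any():
        raise ValueError("negative values in raw expression")
    out = np.log2(vals + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids), scale="log2"
    )


def remove_outlier_samples(
    expr: ExpressionMatrix, z_thresh: float = 3.0, upper_only: bool = False
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove samples whose standardized inter-sample connectivity is an
    outlier, in a single pass.

    Connectivity of sample i is the sum of its Pearson correlations to all
    other samples (computed on the log2 matrix); samples with
    ``|z| > z_thresh`` (or ``z > z_thresh`` with ``upper_only``) are
    removed. If the connectivity spread is zero nothing is removed.
    """
    if expr.scale != "log2":
        raise ValueError("outlier removal expects log2-scale input")
    if expr.n_samples < 4:
        raise ValueError("need >= 4 samples for outlier detection")
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(expr.values.T)
    cor = np.nan_to_num(cor, nan=0.0)
    k = cor.sum(axis=1) - 1.0  # exclude self-correlation
    sd = k.std(ddof=1)
    if sd == 0:
        warnings.warn("connectivity spread is zero; no outliers removed", stacklevel=2)
        return expr, []
    z = (k - k.mean()) / sd
    flag = z > z_thresh if upper_only else np.abs(z) > z_thresh
    removed = [s for s, f in zip(expr.sample_ids, flag) if f]
    kept = [s for s, f in zip(expr.sample_ids, flag) if not f]
    logger.info("outlier removal: removed %d samples %s", len(removed), removed)
    return expr.subset_samples(kept), removed


def clean_clinical_samples(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    required: Sequence[str] = ("stage", "age", "sex", "t_stage"),
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Keep only samples present in both tables with complete stage, age,
    sex and t-stage annotations; aligns sample order."""
    shared = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise ValueError("expression and clinical tables share no samples")
    sub = clinical.data.loc[shared]
    complete = sub[list(required)].notna().all(axis=1)
    keep = sub.index[complete].tolist()
    if not keep:
        raise ValueError("no samples with complete clinical annotations")
    logger.info(
        "clinical cleaning: kept %d of %d expression samples", len(keep), expr.n_samples
    )
    return expr.subset_samples(keep), clinical.subset(keep)


def regress_covariates(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    covariates: Sequence[str] = ("age", "sex"),
) -> ExpressionMatrix:
    """Regress nuisance covariates out of every gene by OLS, returning
    residuals + gene mean (scale tag preserved).

    Categorical covariates (sex) are coded numerically; constant
    covariates are dropped with a warning."""
    if expr.scale != "log2":
        raise ValueError("covariate regression expects log2-scale input")
    cols = []
    for cov in covariates:
        v = clinical.data.loc[expr.sample_ids, cov]
        if v.dtype == object:
            v = pd.Categorical(v).codes.astype(float)
        v = np.asarray(v, dtype=float)
        if np.nanstd(v) == 0:
            warnings.warn(f"covariate {cov!r} is constant; dropped", stacklevel=2)
            continue
        cols.append(v)
    if not cols:
        return expr
    X = np.column_stack([np.ones(expr.n_samples)] + cols)
    Y = expr.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T + expr.values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids), scale=expr.scale
    )


def encode_traits(clinical: ClinicalTable) -> pd.DataFrame:
    """Encode the clinical table as the numeric trait matrix used for
    module-trait correlation.

    Emits binary per-stage indicators, the 3.5-collapsed codings (stages 3
    and 4 merged into one category, and the early-vs-late binary), the
    TNM indicator columns, demographics, and the survival pair OS /
    OS.time. Missing source values propagate as nulls."""
    df = clinical.data
    traits = pd.DataFrame(index=df.index)
    stage = df["stage"]
    for s in (1, 2, 3, 4):
        traits[f"Stage {s}"] = (stage == s).astype(float).where(stage.notna())
    traits["Pathologic stage"] = stage
    traits["Pathologic stage 3.5"] = stage.where(stage < 3, 3.5)
    traits["Stage 3.5"] = (stage >= 3).astype(float).where(stage.notna())
    t = df["t_stage"]
    for s in (1, 2, 3, 4):
        traits[f"Stage T{s}"] = (t == s).astype(float).where(t.notna())
    traits["Pathologic T"] = t
    traits["Pathologic T 3.5"] = t.where(t < 3, 3.5)
    traits["Stage T3.5"] = (t >= 3).astype(float).where(t.notna())
    n = df["n_stage"]
    for s in (0, 1, 2):
        traits[f"Stage N{s}"] = (n == s).astype(float).where(n.notna())
    traits["Pathologic N"] = n
    m = df["m_stage"]
    traits["Pathologic M"] = m
    traits["Age"] = df["age"]
    sex = df["sex"]
    traits["Sex"] = sex.map(
        lambda v: np.nan if v is None or pd.isna(v) else float(str(v).lower().startswith("m"))
    )
    traits["OS"] = df["os_event"].astype(float)
    traits["OS.time"] = df["os_time_days"].astype(float)
    return traits


def run_preprocessing(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    max_zero_frac: float = 0.5,
    pseudocount: float = 1.0,
    z_thresh: float = 3.0,
    covariates: Sequence[str] = ("age", "sex"),
) -> tuple[ExpressionMatrix, ClinicalTable, pd.DataFrame]:
    """The full cleaning path: zero filter -> clinical cleaning -> log2 ->
    outlier removal -> covariate regression -> trait encoding."""
    expr = filter_missing_transcripts(expr, max_zero_frac=max_zero_frac)
    expr, clinical = clean_clinical_samples(expr, clinical)
    expr = log2_transform(expr, pseudocount=pseudocount)
    expr, removed = remove_outlier_samples(expr, z_thresh=z_thresh)
    if removed:
        clinical = clinical.subset(expr.sample_ids)
    expr = regress_covariates(expr, clinical, covariates=covariates)
    traits = encode_traits(clinical)
    return expr, clinical, traits
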