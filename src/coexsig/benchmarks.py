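"""Self-validation benchmarks: parameter recovery on synthetic cohorts and
statistical calibration of the inferential machinery.

Each routine builds its own inputs from a seed, runs the relevant part of
the pipeline, and returns the measured quantity, so results are
reproducible and independent of any external data.
"""

from __future__ import annotations

import tempfile
import warnings
from dataclasses import replace

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import compare, diffexpr, network, preprocess, ratios, survival
from .io import ExpressionMatrix
from .pipeline import RunConfig, run_full_pipeline
from .synthetic import SimulationParams, generate_dataset


def module_recovery(seed: int = 1) -> dict:
    """Run preprocessing + network detection on a default synthetic cohort
    and score module recovery against the planted blocks.

    Returns the adjusted Rand index over all genes and the bicor between
    the two detected module eigengenes (negative when the anti-correlated
    structure is recovered)."""
    import pandas as pd

    params = SimulationParams(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr, clinical, truth = generate_dataset(params)
        raw = preprocess.filter_missing_transcripts(expr)
        raw, clinical = preprocess.clean_clinical_samples(raw, clinical)
        log2 = preprocess.log2_transform(raw)
        log2, removed = preprocess.remove_outlier_samples(log2)
        if removed:
            clinical = clinical.subset(log2.sample_ids)
        log2 = preprocess.regress_covariates(log2, clinical)
        assignment = network.detect_modules(log2)
        me = network.module_eigengenes(log2, assignment)
    planted = pd.Series(truth.gene_block_labels, index=expr.gene_ids)
    ari = adjusted_rand_score(planted.loc[log2.gene_ids].to_numpy(), assignment.labels)
    me_bicor = np.nan
    if me.data.shape[1] >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            me_bicor = network.bicor(
                me.data.iloc[:, 0].to_numpy(), me.data.iloc[:, 1].to_numpy()
            )
    return {
        "ari": float(ari),
        "me_bicor": float(me_bicor),
        "n_modules": len(assignment.module_labels),
        "n_genes": log2.n_genes,
        "n_samples": log2.n_samples,
    }


def planted_signature_recovery(seeds=range(1, 11)) -> dict:
    """Run the full discovery pipeline once per seed and check whether a
    top-10 ranked ratio shares at least 6 of the 8 planted signature
    genes."""
    import pandas as pd

    overlaps = []
    for seed in seeds:
        with tempfile.TemporaryDirectory() as tmp, warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = RunConfig(out_dir=tmp, seed=int(seed))
            run_full_pipeline(cfg)
            ranked = pd.read_csv(f"{tmp}/ratios_ranked.tsv", sep="\t", comment="#")
        _, _, truth = generate_dataset(
            replace(RunConfig().simulation, seed=int(seed))
        )
        planted = set(truth.planted_signature.genes)
        best = 0
        for _, row in ranked.head(10).iterrows():
            genes = set(str(row["numerator"]).split("+")) | set(
                str(row["denominator"]).split("+")
            )
            best = max(best, len(genes & planted))
        overlaps.append(best)
    overlaps = np.asarray(overlaps)
    return {
        "success_fraction": float((overlaps >= 6).mean()),
        "overlaps": overlaps.tolist(),
        "n_runs": len(overlaps),
    }


def cox_recovery(seed: int = 1, n: int = 500, true_beta: float = 1.0) -> dict:
    """Fit the univariate Cox model on exponential survival with a known
    log-hazard ratio and report the estimate."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    t = rng.exponential(1.0 / (1e-3 * np.exp(true_beta * x)))
    surv = survival.SurvivalData(
        sample_ids=[f"S{i}" for i in range(n)], time=t, event=np.ones(n, dtype=int)
    )
    res = survival.cox_univariate(x, surv)
    return {"beta_hat": res.beta, "true_beta": true_beta, "n": n,
            "abs_error": abs(res.beta - true_beta)}


def deg_recovery(seed: int = 1, n_genes: int = 2000, n_true: int = 100,
                 n_per_group: int = 100) -> dict:
    """Plant |L2FC| = 1 shifts in a subset of genes and measure recall and
    observed false discovery proportion of the DEG caller."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_genes, 2 * n_per_group))
    x[:n_true, n_per_group:] += 1.0
    em = ExpressionMatrix(
        pd.DataFrame(x, index=[f"G{i}" for i in range(n_genes)],
                     columns=[f"S{i}" for i in range(2 * n_per_group)]),
        scale="log2",
    )
    stages = np.repeat([1.0, 2.0], n_per_group)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = diffexpr.run_stage_comparisons(em, stages)["stage1-vs-2"]
    called = set(table.index[table["is_deg"]])
    truth = {f"G{i}" for i in range(n_true)}
    return {
        "recall": len(called & truth) / n_true,
        "observed_fdr": len(called - truth) / max(len(called), 1),
        "n_called": len(called),
    }


def delong_type1_error(reps: int = 500, n: int = 200, seed: int = 0) -> dict:
    """Type-I error of the paired DeLong test on two equally informative
    noisy copies of one marker."""
    rejections = used = 0
    for rep in range(reps):
        rng = np.random.default_rng(seed * 1_000_003 + rep)
        marker = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-marker))).astype(float)
        if y.sum() in (0, n):
            continue
        a = marker + rng.standard_normal(n)
        b = marker + rng.standard_normal(n)
        _, _, p = compare.delong_paired_test(a, b, y)
        used += 1
        rejections += p < 0.05
    return {"type1_error": rejections / used, "n_reps": used}


def auc_ci_coverage(reps: int = 1000, n: int = 100, true_auc: float = 0.7,
                    seed: int = 0) -> dict:
    """Coverage of the 95% DeLong CI under a binormal model with known
    AUC."""
    delta = np.sqrt(2.0) * stats.norm.ppf(true_auc)
    covered = 0
    for rep in range(reps):
        rng = np.random.default_rng(seed * 2_000_003 + rep)
        neg = rng.standard_normal(n // 2)
        pos = rng.standard_normal(n // 2) + delta
        x = np.concatenate([pos, neg])
        y = np.repeat([1.0, 0.0], n // 2)
        low, high, _ = ratios.auc_ci(x, y)
        covered += low <= true_auc <= high
    return {"coverage": covered / reps, "true_auc": true_auc, "n_reps": reps}


def anova_null_uniformity(n_genes: int = 2000, seed: int = 0) -> dict:
    """Kolmogorov-Smirnov test of one-way ANOVA p-values against U(0,1)
    on pure-noise genes across four unbalanced stage groups."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_genes, 100))
    em = ExpressionMatrix(
        pd.DataFrame(x, index=[f"G{i}" for i in range(n_genes)],
                     columns=[f"S{i}" for i in range(100)]),
        scale="log2",
    )
    stages = np.concatenate([np.full(40, 1.0), np.full(30, 2.0),
                             np.full(20, 3.0), np.full(10, 4.0)])
    table = diffexpr.stage_anova(em, stages)
    ks = stats.kstest(table["p"].to_numpy(), "uniform")
    return {"ks_p": float(ks.pvalue), "n_genes": n_genes}
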