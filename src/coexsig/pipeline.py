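"""End-to-end orchestration with reproducible run manifests.

Sequences the full analysis: (optional) simulation -> preprocessing ->
network construction -> stage-wise differential expression -> hub/DEG
candidate nomination from the most anti-correlated trait-significant
module pair -> exhaustive ratio search -> survival analysis of the top
signature -> signature correlation summaries. Every output file carries
the config hash and seed in a header comment; the manifest lists each
artifact with its checksum, so identical config + seed reproduce
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, diffexpr, network, preprocess, ratios, survival
from .io import ExpressionMatrix, SignatureDef, read_clinical, read_expression
from .synthetic import SimulationParams, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; serializable so its hash can stamp
    every output."""

    out_dir: str = "coexsig_run"
    expression_path: str | None = None  # None => simulate
    clinical_path: str | None = None
    seed: int = 0
    simulation: SimulationParams = field(default_factory=SimulationParams)
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    ratio: ratios.RatioSearchConfig = field(default_factory=ratios.RatioSearchConfig)
    pick_beta: bool = False  # scan candidate powers instead of config beta
    max_candidates_per_side: int = 10
    rank_subset: str = "all"
    top_k_full_metrics: int = 100
    significance_p: float = 0.05
    staging_traits: tuple[str, ...] = ("Pathologic stage", "Stage 1", "Stage 3.5")
    survival_traits: tuple[str, ...] = ("OS", "OS.time")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ratio"]["rank_subsets"] = {
            k: list(v) for k, v in d["ratio"]["rank_subsets"].items()
        }
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # analysis identity, not artifact placement
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write_tsv(path: Path, df: pd.DataFrame, header: str, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pick_module_pair(
    me: network.EigengeneMatrix,
    mt: network.ModuleTraitCorr,
    staging_traits: tuple[str, ...],
    survival_traits: tuple[str, ...],
    significance_p: float,
) -> tuple[str, str]:
    """Most anti-correlated eigengene pair among trait-significant
    modules; first element is the protective (numerator) module."""
    p = mt.p
    stage_cols = [c for c in staging_traits if c in p.columns]
    surv_cols = [c for c in survival_traits if c in p.columns]
    significant = [
        m
        for m in p.index
        if len(stage_cols)
        and len(surv_cols)
        and p.loc[m, stage_cols].min() <= significance_p
        and p.loc[m, surv_cols].min() <= significance_p
    ]
    if len(significant) < 2:
        raise RuntimeError("fewer than two trait-significant modules; cannot nominate")
    sub = me.data[significant]
    cor = np.corrcoef(sub.to_numpy().T)
    np.fill_diagonal(cor, np.inf)
    i, j = np.unravel_index(np.argmin(cor), cor.shape)
    a, b = significant[i], significant[j]
    # protective module: negative correlation to the death event
    os_col = "OS" if "OS" in mt.bicor.columns else surv_cols[0]
    ra = mt.bicor.loc[a, os_col]
    rb = mt.bicor.loc[b, os_col]
    return (a, b) if (np.isnan(ra) or ra <= rb) else (b, a)


def run_full_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns the manifest dict (also written to
    ``<out_dir>/manifest.json``)."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"coexsig {__version__} config={config.config_hash()} seed={config.seed}"
    artifacts: dict[str, Path] = {}
    summary: dict = {}

    # ------------------------------------------------------------------ data
    if config.expression_path is None:
        params = SimulationParams(**{**asdict(config.simulation), "seed": config.seed})
        expr, clinical, truth = generate_dataset(params)
        summary["simulated"] = True
    else:
        expr = read_expression(config.expression_path, scale="raw")
        clinical = read_clinical(config.clinical_path)
        truth = None
        summary["simulated"] = False

    # ------------------------------------------------------------ preprocess
    expr_raw = preprocess.filter_missing_transcripts(expr)
    expr_raw, clinical = preprocess.clean_clinical_samples(expr_raw, clinical)
    expr_pp = preprocess.log2_transform(expr_raw)
    expr_pp, removed = preprocess.remove_outlier_samples(expr_pp)
    if removed:
        clinical = clinical.subset(expr_pp.sample_ids)
        expr_raw = expr_raw.subset_samples(expr_pp.sample_ids)
    expr_pp = preprocess.regress_covariates(expr_pp, clinical)
    traits = preprocess.encode_traits(clinical)
    summary["n_genes"] = expr_pp.n_genes
    summary["n_samples"] = expr_pp.n_samples
    _write_tsv(out / "expression_preprocessed.tsv", expr_pp.data, tag, "gene_id")
    artifacts["expression_preprocessed"] = out / "expression_preprocessed.tsv"

    # --------------------------------------------------------------- network
    net_cfg = config.network
    if config.pick_beta:
        beta, fit_table = network.pick_soft_threshold(expr_pp, net_cfg)
        net_cfg = network.NetworkConfig(**{**asdict(net_cfg), "beta": beta})
        _write_tsv(out / "soft_threshold.tsv", fit_table, tag, "row")
        artifacts["soft_threshold"] = out / "soft_threshold.tsv"
    assignment = network.detect_modules(expr_pp, net_cfg)
    me = network.module_eigengenes(expr_pp, assignment)
    kme = network.kme_table(expr_pp, me, cor_method=net_cfg.cor_method)
    hubs = network.hub_genes(kme, assignment)
    mt = network.module_trait_correlation(me, traits)
    summary["n_modules"] = len(assignment.module_labels)
    summary["module_sizes"] = assignment.sizes()
    labels_df = pd.DataFrame(
        {"module": assignment.labels}, index=assignment.gene_ids
    )
    _write_tsv(out / "module_labels.tsv", labels_df, tag, "gene_id")
    _write_tsv(out / "eigengenes.tsv", me.data, tag, "sample_id")
    _write_tsv(out / "kme.tsv", kme, tag, "gene_id")
    _write_tsv(out / "module_trait_bicor.tsv", mt.bicor, tag, "module")
    _write_tsv(out / "module_trait_p.tsv", mt.p, tag, "module")
    for name in ("module_labels", "eigengenes", "kme", "module_trait_bicor", "module_trait_p"):
        artifacts[name] = out / f"{name}.tsv"

    # ---------------------------------------------------- differential expr
    stages = clinical.data["stage"].to_numpy(dtype=float)
    deg_tables = diffexpr.run_stage_comparisons(expr_pp, stages)
    for name, table in deg_tables.items():
        path = out / f"degs_{name.replace('-', '_')}.tsv"
        _write_tsv(path, table, tag, "gene")
        artifacts[f"degs_{name}"] = path
    summary["n_degs_stage1_vs_2"] = int(deg_tables["stage1-vs-2"]["is_deg"].sum())
    summary["n_degs_stage1_vs_rest"] = int(deg_tables["stage1-vs-rest"]["is_deg"].sum())

    # ------------------------------------------------------------ nomination
    surv = survival.SurvivalData.from_clinical(clinical)
    norm = ratios.cluster3_normalize(expr_raw)
    num_mod, den_mod = _pick_module_pair(
        me, mt, config.staging_traits, config.survival_traits, config.significance_p
    )
    deg_set = set(deg_tables["stage1-vs-2"].index[deg_tables["stage1-vs-2"]["is_deg"]])
    # survival-time correlation table for round-2 style top-up nomination
    _, _, os_corr = ratios.select_survival_correlated(norm, surv, 1)
    os_corr = os_corr.set_index("gene")["bicor_os_time"]

    def _pool(mod: str, protective: bool) -> list[str]:
        """Round 1: the module's hub genes that are stage1-vs-2 DEGs,
        ranked by own-module kME. If that leaves the side short, round-2
        nomination tops it up with the module members most correlated to
        survival time in the protective (positive) or hazardous
        (negative) direction."""
        lab = int(mod[1:])
        pool = [g for g in hubs[lab] if g in deg_set]
        pool.sort(key=lambda g: (-abs(kme.loc[g, mod]), g))
        pool = pool[: config.max_candidates_per_side]
        if len(pool) < config.max_candidates_per_side:
            members = [g for g in assignment.members(lab) if g not in pool]
            members = [g for g in members if g in os_corr.index]
            members.sort(key=lambda g: ((-1 if protective else 1) * os_corr[g], g))
            pool += members[: config.max_candidates_per_side - len(pool)]
        return pool

    num_candidates = _pool(num_mod, protective=True)
    den_candidates = _pool(den_mod, protective=False)
    summary["module_pair"] = {"numerator": num_mod, "denominator": den_mod}
    summary["candidates"] = {"numerator": num_candidates, "denominator": den_candidates}
    if not num_candidates or not den_candidates:
        raise RuntimeError("candidate nomination produced an empty pool")

    # ----------------------------------------------------------- ratio search
    evals = ratios.evaluate_all_ratios(
        norm, surv, num_candidates, den_candidates, config.ratio, full_metrics=False
    )
    ranked = ratios.rank_by_mean_auc(evals, config.rank_subset)
    summary["n_combinations"] = len(evals)
    # full per-timepoint metrics (DeLong CI/p, Youden confusion) for the
    # top block only; the exhaustive scan keeps the cheap AUC-only path
    top_names = ranked.head(config.top_k_full_metrics)
    top_sigs = [
        SignatureDef(
            name=str(r["signature"]),
            numerator_genes=str(r["numerator"]).split("+"),
            denominator_genes=str(r["denominator"]).split("+"),
        )
        for _, r in top_names.iterrows()
    ]
    top_full = ratios.evaluate_signatures(norm, surv, top_sigs, config.ratio)
    freq = ratios.top_gene_frequency(ranked, config.ratio)
    _write_tsv(out / "ratios_ranked.tsv", ranked.head(1000), tag, "row")
    _write_tsv(out / "ratios_top_full_metrics.tsv", top_full, tag, "row")
    _write_tsv(out / "gene_frequency_top.tsv", freq, tag, "row")
    for name in ("ratios_ranked", "ratios_top_full_metrics", "gene_frequency_top"):
        artifacts[name] = out / f"{name}.tsv"
    best = ranked.iloc[0]
    top_sig = SignatureDef(
        name=str(best["signature"]),
        numerator_genes=str(best["numerator"]).split("+"),
        denominator_genes=str(best["denominator"]).split("+"),
    )
    summary["top_signature"] = {
        "signature": top_sig.name,
        "mean_auc": float(best[f"mean_auc_{config.rank_subset}"]),
    }

    # ------------------------------------------------- survival of top ratio
    # Orient the score so larger values predict longer survival (the
    # ROC evaluation is orientation-free; the KM/Cox summary is not).
    score = ratios.ratio_score(norm, top_sig)
    y18 = ratios.binarize_outcome(surv, 548)
    ok18 = np.isfinite(score) & np.isfinite(y18)
    if len(np.unique(y18[ok18])) == 2 and ratios.roc_auc(score[ok18], y18[ok18]) > 0.5:
        score = -score
    ok = np.isfinite(score)
    surv_ok = survival.SurvivalData(
        sample_ids=[s for s, m in zip(surv.sample_ids, ok) if m],
        time=surv.time[ok],
        event=surv.event[ok],
    )
    cox = survival.median_split_cox(score[ok], surv_ok)
    summary["top_signature_cox"] = {
        "hr": cox.hr,
        "ci": [cox.ci_low, cox.ci_high],
        "wald_p": cox.wald_p,
        "n": cox.n,
        "n_events": cox.n_events,
    }

    # --------------------------------------------------- signature comparison
    sigs = [top_sig]
    if truth is not None:
        sigs.append(truth.planted_signature)
    scores = compare.score_signatures(norm, sigs)
    mod_r, mod_p = compare.signature_module_bicor(scores, me)
    surv_r, surv_p = compare.signature_survival_bicor(scores, traits)
    _write_tsv(out / "signature_module_bicor.tsv", mod_r, tag, "signature")
    _write_tsv(out / "signature_survival_bicor.tsv", surv_r, tag, "signature")
    artifacts["signature_module_bicor"] = out / "signature_module_bicor.tsv"
    artifacts["signature_survival_bicor"] = out / "signature_survival_bicor.tsv"

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "summary": summary,
        "artifacts": {
            name: {"path": str(path), "sha256": _checksum(path)}
            for name, path in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
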