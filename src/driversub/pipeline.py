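"""End-to-end pipeline orchestration.

Stage order: hypermutator filter -> domain burden -> stratification genes
-> tumor/normal differential analysis -> DDG assembly -> binarize /
propagate / z-score / SNF / consensus / silhouette -> characterization ->
classifier panel + training. Every stage parameter has the analysis
default; all randomness flows from one global seed expanded into
per-stage streams, and a run manifest records parameters, seeds and
per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import characterization as charac
from . import classifier as clf_mod
from . import ddg as ddg_mod
from . import domain_burden as burden
from . import fusion
from . import io as dio
from .synthetic import SyntheticCohort, SyntheticCohortConfig, generate_cohort, truth_ari
from .types import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with their analysis defaults."""

    # inputs: either a synthetic cohort config or a directory of input files
    synthetic: Optional[SyntheticCohortConfig] = None
    input_dir: Optional[str] = None
    out_dir: str = "driversub_out"
    seed: int = 0
    # domain burden
    n_perm: int = 9999
    burden_alpha: float = 0.05
    entropy_cutoff: float = 0.5
    tmb_cutoff: float = 30.0
    coding_megabases: float = 38.0
    # differential / evidence thresholds
    de_fc_cut: float = 1.0
    de_p_cut: float = 0.05
    dmp_delta_cut: float = 0.2
    cnv_gain_level: float = 1.0
    cnv_loss_level: float = -1.0
    cnv_frac: float = 0.2
    rho_cut: float = 0.2
    ddg_combine: str = "union"
    # subtype model
    alpha: float = 0.7
    tol: float = 1e-6
    quantile_normalize: bool = False
    snf_k: int = 20
    snf_mu: float = 0.5
    snf_t: int = 20
    max_k: int = 6
    reps: int = 5000
    p_item: float = 0.8
    # classifier
    panel_p_cut: float = 1e-3
    panel_fc_cut: float = 1.0
    l1_ratio: float = 0.5
    train_frac: float = 0.7

    @classmethod
    def demo(cls, seed: int = 0, out_dir: str = "driversub_out", **overrides) -> "PipelineConfig":
        """Synthetic-cohort profile with consensus reps reduced to 500."""
        params = dict(
            synthetic=SyntheticCohortConfig(seed=seed),
            seed=seed,
            out_dir=out_dir,
            reps=500,
        )
        params.update(overrides)
        return cls(**params)


_BOUNDS = {
    "alpha": (0.0, True, 1.0, False),  # 0 <= alpha < 1
    "p_item": (0.0, False, 1.0, True),
    "train_frac": (0.0, False, 1.0, False),
    "de_p_cut": (0.0, False, 1.0, True),
    "burden_alpha": (0.0, False, 1.0, True),
    "l1_ratio": (0.0, True, 1.0, True),
}


def validate_config(config) -> PipelineConfig:
    """Normalize a PipelineConfig or mapping; aggregate all violations."""
    if isinstance(config, PipelineConfig):
        cfg = config
    else:
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = sorted(set(config) - known)
        errors = [f"unknown key {k!r}" for k in unknown]
        if errors:
            raise ValueError("; ".join(errors))
        params = dict(config)
        if isinstance(params.get("synthetic"), dict):
            params["synthetic"] = SyntheticCohortConfig(**params["synthetic"])
        cfg = PipelineConfig(**params)
    errors = []
    for name, (lo, lo_inc, hi, hi_inc) in _BOUNDS.items():
        v = getattr(cfg, name)
        ok_lo = v >= lo if lo_inc else v > lo
        ok_hi = v <= hi if hi_inc else v < hi
        if not (ok_lo and ok_hi):
            lo_b = "[" if lo_inc else "("
            hi_b = "]" if hi_inc else ")"
            errors.append(f"{name}={v} outside {lo_b}{lo}, {hi}{hi_b}")
    if cfg.n_perm < 1:
        errors.append("n_perm must be >= 1")
    if cfg.reps < 1:
        errors.append("reps must be >= 1")
    if cfg.max_k < 2:
        errors.append("max_k must be >= 2")
    if cfg.ddg_combine not in ("union", "intersection"):
        errors.append("ddg_combine must be 'union' or 'intersection'")
    if cfg.synthetic is None and cfg.input_dir is None:
        errors.append("either synthetic config or input_dir is required")
    if cfg.input_dir is not None and not os.path.isdir(cfg.input_dir):
        errors.append(f"input_dir does not exist: {cfg.input_dir}")
    if errors:
        raise ValueError("; ".join(errors))
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        return generate_cohort(cfg.synthetic)
    d = cfg.input_dir
    for fname in ("mutations.maf.tsv", "expression_tumor.tsv", "network.tsv"):
        if not os.path.exists(os.path.join(d, fname)):
            raise FileNotFoundError(os.path.join(d, fname))
    raise NotImplementedError(
        "file-based cohorts are loaded with driversub.io readers; assemble a "
        "SyntheticCohort-like bundle and call run_pipeline_on_cohort"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    cfg = validate_config(config)
    cohort = _load_inputs(cfg)
    return run_pipeline_on_cohort(cohort, cfg)


def run_pipeline_on_cohort(cohort: SyntheticCohort, cfg: PipelineConfig) -> dict:
    """Execute every stage on an in-memory cohort; returns the manifest
    (with ``_objects`` holding the in-memory stage outputs)."""
    seed_seq = np.random.SeedSequence(cfg.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("burden", "consensus", "classifier"), seed_seq.spawn(3)
        )
    }
    manifest: dict = {
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("synthetic",)
        },
        "stage_seeds": stage_seeds,
        "counts": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if cfg.synthetic is not None:
        manifest["parameters"]["synthetic"] = dataclasses.asdict(cfg.synthetic)

    # --- stage 1: hypermutator filter ------------------------------------
    mutations, retained_samples, excluded = burden.filter_hypermutators(
        cohort.mutations, tmb_cutoff=cfg.tmb_cutoff, coding_megabases=cfg.coding_megabases
    )
    samples = [s for s in cohort.sample_ids if s not in set(excluded)]
    manifest["counts"]["samples_retained"] = len(samples)
    manifest["counts"]["hypermutators_excluded"] = len(excluded)

    # --- stage 2: domain burden -> stratification genes -------------------
    results = burden.analyze_domain_burden(
        mutations,
        cohort.domains,
        cohort.protein_lengths,
        n_perm=cfg.n_perm,
        seed=stage_seeds["burden"],
        alpha=cfg.burden_alpha,
        entropy_cutoff=cfg.entropy_cutoff,
    )
    strat_genes = sorted(
        burden.select_stratification_genes(
            results, entropy_cutoff=cfg.entropy_cutoff, alpha=cfg.burden_alpha
        )
    )
    manifest["counts"]["domains_tested"] = len(results)
    manifest["counts"]["significant_high_entropy_domains"] = sum(
        1 for r in results if r.significant and r.high_entropy
    )
    manifest["counts"]["stratification_genes"] = len(strat_genes)
    if not strat_genes:
        raise RuntimeError("stage domain_burden: no stratification genes found")

    # --- stage 3: differential analysis + DDGs ----------------------------
    expr_t = cohort.expression_tumor.restrict_samples(samples)
    de = ddg_mod.differential_expression(
        expr_t, cohort.expression_normal, fc_cut=cfg.de_fc_cut, p_cut=cfg.de_p_cut
    )
    dmps = ddg_mod.call_dmps(
        cohort.methylation.restrict_samples(samples),
        cohort.methylation_normal,
        delta_cutoff=cfg.dmp_delta_cut,
        p_cut=cfg.de_p_cut,
    )
    dmi = ddg_mod.differential_expression(
        cohort.mirna.restrict_samples(samples),
        cohort.mirna_normal,
        fc_cut=cfg.de_fc_cut,
        p_cut=cfg.de_p_cut,
    )
    cnv_flags = ddg_mod.classify_cnv_groups(
        cohort.cnv_gene.restrict_samples(samples),
        gain_level=cfg.cnv_gain_level,
        loss_level=cfg.cnv_loss_level,
        frac=cfg.cnv_frac,
    )
    ddgs = ddg_mod.assemble_ddgs(
        de,
        cohort.families,
        expr_t,
        dmps=dmps,
        probe_annotation=cohort.probe_annotation,
        beta_tumor=cohort.methylation.restrict_samples(samples),
        dmi=dmi,
        mirna_tumor=cohort.mirna.restrict_samples(samples),
        mirna_targets=cohort.mirna_targets,
        cnv_flags=cnv_flags,
        cnv_gene=cohort.cnv_gene.restrict_samples(samples),
        rho_cut=cfg.rho_cut,
        p_cut=cfg.de_p_cut,
        combine=cfg.ddg_combine,
    )
    manifest["counts"]["degs"] = sum(1 for r in de if r.is_deg)
    manifest["counts"]["ddgs"] = len(ddgs)

    # --- stage 4: subtype model -------------------------------------------
    f0 = fusion.binarize_mutations(mutations, strat_genes, samples)
    expr_features = sorted(ddgs) if len(ddgs) >= 2 else sorted(
        {r.gene_id for r in de if r.is_deg}
    )
    if len(expr_features) < 2:
        raise RuntimeError("stage subtype_model: fewer than 2 expression features")
    assignment, fused, per_k, smoothed = fusion.discover_subtypes(
        f0,
        expr_t.data.loc[expr_features],
        cohort.network,
        alpha=cfg.alpha,
        tol=cfg.tol,
        k_neighbors=cfg.snf_k,
        mu=cfg.snf_mu,
        t_iter=cfg.snf_t,
        max_k=cfg.max_k,
        reps=cfg.reps,
        p_item=cfg.p_item,
        seed=stage_seeds["consensus"],
        quantile_normalize=cfg.quantile_normalize,
    )
    manifest["counts"]["expression_features"] = len(expr_features)
    manifest["chosen_k"] = assignment.chosen_k
    manifest["mean_silhouette_per_k"] = {
        str(k): v for k, v in assignment.mean_silhouette_per_k.items()
    }
    manifest["propagation_iterations"] = smoothed.iterations
    manifest["propagation_final_step_norm"] = smoothed.final_step_norm
    if cohort.truth is not None:
        manifest["truth_ari"] = truth_ari(assignment.labels, cohort.truth.labels)

    # --- stage 5: characterization ----------------------------------------
    cin = charac.cin_table(cohort.cnv_arm.restrict_samples(samples))
    cin_by = charac.compare_continuous_by_subtype(
        cin.set_index("sample_id")["cin_ratio"], assignment.labels
    )
    assoc = charac.mutation_association(assignment.labels, f0)
    stat, p, medians = charac.logrank_compare(cohort.survival, assignment.labels)
    manifest["characterization"] = {
        "cin_comparison": cin_by,
        "logrank_statistic": stat,
        "logrank_p": p,
        "km_medians_months": medians,
        "n_associations_tested": len(assoc),
    }

    # --- stage 6: classifier ----------------------------------------------
    selection, clf, metrics, held_out = clf_mod.build_panel_and_classifier(
        expr_t,
        assignment.labels,
        p_cut=cfg.panel_p_cut,
        fc_cut=cfg.panel_fc_cut,
        l1_ratio=cfg.l1_ratio,
        train_frac=cfg.train_frac,
        seed=stage_seeds["classifier"],
    )
    manifest["counts"]["panel_candidates"] = len(selection["candidate_genes"])
    manifest["counts"]["panel_interval_pass"] = len(selection["interval_pass_genes"])
    manifest["counts"]["panel_genes"] = len(selection["panel_genes"])
    manifest["classifier_metrics"] = metrics.as_dict()

    # --- outputs ----------------------------------------------------------
    assignments_df = pd.DataFrame(
        {
            "sample_id": assignment.labels.index,
            "subtype": assignment.labels.to_numpy(),
            "silhouette": assignment.silhouette.to_numpy(),
        }
    )
    panel_json = {
        "panel_genes": selection["panel_genes"],
        "intervals": clf.intervals,
        "model": type(clf.model).__name__,
        "model_params": {
            k: v for k, v in clf.model.get_params().items() if isinstance(v, (int, float, str, bool))
        },
    }
    dio.write_results(
        cfg.out_dir,
        assignments=assignments_df,
        domain_table=burden.burden_results_table(results),
        ddg_table=ddg_mod.ddg_table(ddgs),
        panel=panel_json,
        metrics=manifest["classifier_metrics"],
        manifest=manifest,
        extra_tables={
            "cin_ratio.tsv": cin,
            "mutation_association.tsv": charac.association_table(assoc),
        },
    )
    manifest["_objects"] = {
        "assignment": assignment,
        "fused": fused,
        "per_k": per_k,
        "smoothed": smoothed,
        "burden_results": results,
        "stratification_genes": strat_genes,
        "ddgs": ddgs,
        "selection": selection,
        "classifier": clf,
        "metrics": metrics,
        "held_out": held_out,
        "cohort": cohort,
    }
    return manifest
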