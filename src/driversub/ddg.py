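"""Driver-dysregulated genes (DDGs).

A DDG is a family-member gene that is differentially expressed between
tumor and normal tissue *and* whose dysregulation is supported by at least
one correlated regulatory layer: a differentially methylated probe (DMP)
annotated to it, a differentially expressed miRNA (DMi) targeting it, or a
recurrent copy-number gain/loss. Expression differences use the
Mann-Whitney U test with Benjamini-Hochberg correction; the evidence link
is a Spearman correlation with |rho| > 0.2 and BH-adjusted p < 0.05,
corrected within each evidence batch (methylation pairs together, miRNA
pairs together, CNV pairs together).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GeneFamily, OmicsMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

FC_CUT = 1.0
P_CUT = 0.05
MIN_MEAN_EXPR = 1.0
DELTA_BETA_CUT = 0.2
CNV_GAIN_LEVEL = 1.0
CNV_LOSS_LEVEL = -1.0
CNV_FRAC = 0.2
RHO_CUT = 0.2

_REGION_EVIDENCE = {
    "promoter": "promoter_meth",
    "gene_body": "body_meth",
    "distal_enhancer": "enhancer_meth",
}


@dataclass
class DiffExprResult:
    gene_id: str
    log2fc: float
    p_value: float
    p_adjusted: float
    mean_tumor: float
    mean_normal: float
    is_deg: bool


@dataclass
class DdgEvidence:
    gene_id: str
    evidence_type: str
    regulator_id: str
    rho: float
    p_adjusted: float

    def __post_init__(self) -> None:
        assert abs(self.rho) > RHO_CUT and self.p_adjusted < P_CUT, (
            "evidence row violates its own threshold invariant"
        )


def _mwu_pvalues(t: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney U p-values (normal approximation with
    tie and continuity correction); constant rows get p = 1."""
    combined = np.concatenate([t, n], axis=1)
    constant = combined.max(axis=1) == combined.min(axis=1)
    p = np.ones(t.shape[0])
    active = ~constant
    if active.any():
        res = stats.mannwhitneyu(
            t[active], n[active], axis=1, alternative="two-sided", method="asymptotic"
        )
        p[active] = res.pvalue
    return p


def differential_expression(
    tumor: OmicsMatrix,
    normal: OmicsMatrix,
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
    min_mean: float = MIN_MEAN_EXPR,
) -> list[DiffExprResult]:
    """Tumor-vs-normal differential expression on a shared feature universe.

    ``log2fc = log2((mean_tumor + 1) / (mean_normal + 1))``; a feature is a
    DEG iff |log2fc| > fc_cut, BH-adjusted p < p_cut and at least one group
    mean is >= ``min_mean``.
    """
    if tumor.data.shape[1] < 2 or normal.data.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    shared = [g for g in tumor.feature_ids if g in set(normal.feature_ids)]
    if not shared:
        raise ValueError("no shared features between tumor and normal matrices")
    t = tumor.data.loc[shared].to_numpy(dtype=float)
    n = normal.data.loc[shared].to_numpy(dtype=float)
    mean_t = t.mean(axis=1)
    mean_n = n.mean(axis=1)
    log2fc = np.log2((mean_t + 1.0) / (mean_n + 1.0))
    p = _mwu_pvalues(t, n)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    results = []
    for i, g in enumerate(shared):
        is_deg = (
            abs(log2fc[i]) > fc_cut
            and p_adj[i] < p_cut
            and max(mean_t[i], mean_n[i]) >= min_mean
        )
        results.append(
            DiffExprResult(
                g,
                float(log2fc[i]),
                float(p[i]),
                float(p_adj[i]),
                float(mean_t[i]),
                float(mean_n[i]),
                bool(is_deg),
            )
        )
    return results


def call_dmps(
    beta_tumor: OmicsMatrix,
    beta_normal: OmicsMatrix,
    delta_cutoff: float = DELTA_BETA_CUT,
    p_cut: float = P_CUT,
) -> pd.DataFrame:
    """Differentially methylated probes: |delta beta| > cutoff and BH p < p_cut."""
    if beta_tumor.data.shape[1] < 2 or beta_normal.data.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    shared = [p for p in beta_tumor.feature_ids if p in set(beta_normal.feature_ids)]
    t = beta_tumor.data.loc[shared].to_numpy(dtype=float)
    n = beta_normal.data.loc[shared].to_numpy(dtype=float)
    delta = t.mean(axis=1) - n.mean(axis=1)
    p = _mwu_pvalues(t, n)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "probe_id": shared,
            "delta_beta": delta,
            "p_value": p,
            "p_adjusted": p_adj,
            "is_dmp": (np.abs(delta) > delta_cutoff) & (p_adj < p_cut),
        }
    )


def classify_cnv_groups(
    cnv_gene: OmicsMatrix,
    gain_level: float = CNV_GAIN_LEVEL,
    loss_level: float = CNV_LOSS_LEVEL,
    frac: float = CNV_FRAC,
) -> pd.DataFrame:
    """Flag genes with a copy-number gain/loss ratio strictly above ``frac``.

    Gain: fraction of samples with score > gain_level exceeds ``frac``;
    loss analogously with score < loss_level. A gene can carry both flags.
    """
    vals = cnv_gene.values
    gain_ratio = (vals > gain_level).mean(axis=1)
    loss_ratio = (vals < loss_level).mean(axis=1)
    return pd.DataFrame(
        {
            "gene_id": cnv_gene.feature_ids,
            "gain_ratio": gain_ratio,
            "loss_ratio": loss_ratio,
            "gain": gain_ratio > frac,
            "loss": loss_ratio > frac,
        }
    )


def correlate_regulator_target(regulator_values, target_expression):
    """Spearman correlation (average-rank ties, two-sided t-approximation p).

    Returns ``(rho, p)`` or ``None`` when either vector is constant.
    """
    x = np.asarray(regulator_values, dtype=float)
    y = np.asarray(target_expression, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("paired vectors of length >= 5 required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector in correlation pair; skipped")
        return None
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _evidence_batch(pairs, rho_cut: float, p_cut: float):
    """BH-correct a batch of (meta, rho, p) tuples; yield passing evidence."""
    if not pairs:
        return []
    pvals = [p for (_, _, p) in pairs]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for (meta, rho, _), pa in zip(pairs, p_adj):
        if abs(rho) > rho_cut and pa < p_cut:
            out.append((meta, rho, float(pa)))
    return out


def assemble_ddgs(
    diff_expr: Sequence[DiffExprResult],
    families: Sequence[GeneFamily],
    expression_tumor: OmicsMatrix,
    dmps: Optional[pd.DataFrame] = None,
    probe_annotation: Optional[Sequence[ProbeAnnotation]] = None,
    beta_tumor: Optional[OmicsMatrix] = None,
    dmi: Optional[Sequence[DiffExprResult]] = None,
    mirna_tumor: Optional[OmicsMatrix] = None,
    mirna_targets: Optional[Mapping[str, Iterable[str]]] = None,
    cnv_flags: Optional[pd.DataFrame] = None,
    cnv_gene: Optional[OmicsMatrix] = None,
    rho_cut: float = RHO_CUT,
    p_cut: float = P_CUT,
    combine: str = "union",
) -> dict[str, list[DdgEvidence]]:
    """Integrate evidence layers into the DDG set.

    Candidates are family-member DEGs; a candidate becomes a DDG when at
    least one evidence link passes (``combine='union'``, the default) or
    when every supplied layer yields one (``combine='intersection'``).
    Returns ``{gene_id: [DdgEvidence, ...]}`` for the DDGs only.
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    family_genes = set().union(*(f.member_gene_ids for f in families)) if families else set()
    degs = {r.gene_id for r in diff_expr if r.is_deg}
    candidates = sorted(degs & family_genes)
    expr = expression_tumor.data
    samples = list(expr.columns)

    per_layer: dict[str, dict[str, list[DdgEvidence]]] = {}

    # (a) methylation: DMPs annotated to a candidate
    if dmps is not None and probe_annotation is not None and beta_tumor is not None:
        ann = {p.probe_id: p for p in probe_annotation}
        dmp_ids = set(dmps.loc[dmps["is_dmp"], "probe_id"])
        pairs = []
        for probe in sorted(dmp_ids):
            a = ann.get(probe)
            if a is None or a.target_gene_id not in candidates:
                continue
            if probe not in beta_tumor.data.index:
                continue
            res = correlate_regulator_target(
                beta_tumor.data.loc[probe, samples].to_numpy(),
                expr.loc[a.target_gene_id, samples].to_numpy(),
            )
            if res is None:
                continue
            rho, p = res
            pairs.append(((a.target_gene_id, _REGION_EVIDENCE[a.region], probe), rho, p))
        layer: dict[str, list[DdgEvidence]] = {}
        for (gene, etype, probe), rho, pa in _evidence_batch(pairs, rho_cut, p_cut):
            layer.setdefault(gene, []).append(DdgEvidence(gene, etype, probe, rho, pa))
        per_layer["methylation"] = layer

    # (b) miRNA: differentially expressed miRNAs targeting a candidate
    if dmi is not None and mirna_tumor is not None and mirna_targets is not None:
        dmi_ids = {r.gene_id for r in dmi if r.is_deg}
        pairs = []
        for mir in sorted(dmi_ids):
            if mir not in mirna_tumor.data.index:
                continue
            for gene in sorted(set(mirna_targets.get(mir, ())) & set(candidates)):
                res = correlate_regulator_target(
                    mirna_tumor.data.loc[mir, samples].to_numpy(),
                    expr.loc[gene, samples].to_numpy(),
                )
                if res is None:
                    continue
                rho, p = res
                pairs.append(((gene, "mirna", mir), rho, p))
        layer = {}
        for (gene, etype, mir), rho, pa in _evidence_batch(pairs, rho_cut, p_cut):
            layer.setdefault(gene, []).append(DdgEvidence(gene, etype, mir, rho, pa))
        per_layer["mirna"] = layer

    # (c) CNV: gain/loss-flagged candidates whose score tracks expression
    if cnv_flags is not None and cnv_gene is not None:
        flagged = cnv_flags.loc[cnv_flags["gain"] | cnv_flags["loss"]]
        pairs = []
        for row in flagged.itertuples(index=False):
            gene = row.gene_id
            if gene not in candidates or gene not in cnv_gene.data.index:
                continue
            res = correlate_regulator_target(
                cnv_gene.data.loc[gene, samples].to_numpy(),
                expr.loc[gene, samples].to_numpy(),
            )
            if res is None:
                continue
            rho, p = res
            etype = "cnv_gain" if row.gain else "cnv_loss"
            pairs.append(((gene, etype, gene), rho, p))
        layer = {}
        for (gene, etype, reg), rho, pa in _evidence_batch(pairs, rho_cut, p_cut):
            layer.setdefault(gene, []).append(DdgEvidence(gene, etype, reg, rho, pa))
        per_layer["cnv"] = layer

    ddgs: dict[str, list[DdgEvidence]] = {}
    for gene in candidates:
        rows = [ev for layer in per_layer.values() for ev in layer.get(gene, [])]
        if not rows:
            continue
        if combine == "intersection" and not all(
            gene in layer for layer in per_layer.values()
        ):
            continue
        ddgs[gene] = rows
    return ddgs


def ddg_table(ddgs: Mapping[str, Sequence[DdgEvidence]]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g,
            "evidence_type": ev.evidence_type,
            "regulator_id": ev.regulator_id,
            "rho": ev.rho,
            "p_adjusted": ev.p_adjusted,
        }
        for g in sorted(ddgs)
        for ev in ddgs[g]
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "evidence_type", "regulator_id", "rho", "p_adjusted"]
    )
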