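"""Readers, writers and preprocessing filters for the pipeline's text formats.

All tabular formats are tab-separated text: MAF-like mutation tables,
feature x sample omics matrices, network edge lists, probe annotations and
clinical tables. Matrices round-trip exactly (values written at full
precision).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    POINT_CLASSES,
    GeneNetwork,
    MutationRecord,
    OmicsMatrix,
    ProbeAnnotation,
    SurvivalRecord,
)

logger = logging.getLogger(__name__)

#: default column names for MAF-like input; override per dialect
DEFAULT_MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "protein_pos": "Protein_position",
    "ref_aa": "Reference_AA",
    "alt_aa": "Alternate_AA",
    "variant_class": "Variant_Classification",
}

#: MAF Variant_Classification spellings -> controlled vocabulary
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Silent": "silent",
    "Splice_Site": "splice",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
}


class FormatError(ValueError):
    """Malformed input file."""


@dataclasses.dataclass(frozen=True)
class RejectedRecord:
    row: int
    reason: str
    detail: str = ""


def _canonical_class(raw: str) -> str:
    raw = str(raw).strip()
    if raw in MAF_CLASS_MAP:
        return MAF_CLASS_MAP[raw]
    low = raw.lower()
    from .types import VARIANT_CLASSES

    return low if low in VARIANT_CLASSES else "other"


def read_mutations(
    path,
    protein_lengths: Mapping[str, int],
    column_map: Optional[Mapping[str, str]] = None,
    protein_sequences: Optional[Mapping[str, str]] = None,
):
    """Read and sanitize a MAF-like somatic mutation table.

    Only single amino-acid substitutions are retained; records with a
    protein position beyond the protein length, or (when reference
    sequences are supplied) a reference amino acid disagreeing with the
    sequence, are dropped. Every rejection is logged with a reason code and
    ``len(records) + len(rejections)`` equals the number of input rows.

    Returns ``(records, rejections)``.
    """
    cols = dict(DEFAULT_MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[MutationRecord] = []
    rejections: list[RejectedRecord] = []
    seen = set()
    for row_idx, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        gene = str(rowd[cols["gene"]])
        sample = str(rowd[cols["sample"]])
        vclass = _canonical_class(rowd[cols["variant_class"]])
        if vclass not in POINT_CLASSES:
            rejections.append(RejectedRecord(row_idx, "non_point", vclass))
            continue
        try:
            pos = int(float(rowd[cols["protein_pos"]]))
            if pos < 1:
                raise ValueError
        except (TypeError, ValueError):
            rejections.append(
                RejectedRecord(row_idx, "invalid_position", str(rowd[cols["protein_pos"]]))
            )
            continue
        if gene not in protein_lengths:
            rejections.append(RejectedRecord(row_idx, "no_reference_length", gene))
            continue
        if pos > protein_lengths[gene]:
            rejections.append(
                RejectedRecord(row_idx, "position_exceeds_length", f"{gene}:{pos}")
            )
            continue
        ref_aa = str(rowd[cols["ref_aa"]]).strip()
        alt_aa = str(rowd[cols["alt_aa"]]).strip()
        if protein_sequences is not None and gene in protein_sequences:
            seq = protein_sequences[gene]
            if pos <= len(seq) and seq[pos - 1] != ref_aa:
                rejections.append(
                    RejectedRecord(row_idx, "ref_aa_mismatch", f"{gene}:{ref_aa}{pos}")
                )
                continue
        key = (sample, gene, pos, alt_aa)
        if key in seen:
            rejections.append(RejectedRecord(row_idx, "duplicate", f"{key}"))
            continue
        seen.add(key)
        records.append(
            MutationRecord(sample, gene, pos, ref_aa, alt_aa, vclass)
        )
    for reason in sorted({r.reason for r in rejections}):
        n = sum(1 for r in rejections if r.reason == reason)
        logger.info("read_mutations: rejected %d record(s): %s", n, reason)
    return records, rejections


def read_omics_matrix(path, layer: str) -> OmicsMatrix:
    """Read a tab-separated feature x sample matrix (first column = feature ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate feature id {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(layer, df)


def write_omics_matrix(m: OmicsMatrix, path) -> None:
    df = m.data.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def _pairwise_feature_distances(x: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Euclidean distances between feature rows over pairwise-complete samples."""
    xz = np.where(obs, x, 0.0)
    s = obs.astype(float)
    cross = xz @ xz.T
    sq = (xz**2) @ s.T
    d2 = sq + sq.T - 2.0 * cross
    shared = s @ s.T
    d = np.sqrt(np.clip(d2, 0.0, None))
    d[shared == 0] = np.inf
    return d


def filter_and_impute(
    m: OmicsMatrix, max_missing_frac: float = 0.3, knn_k: int = 15
) -> OmicsMatrix:
    """Apply the missingness filter and KNN imputation, or the TPM zero filter.

    For methylation/miRNA layers, features missing in strictly more than
    ``max_missing_frac`` of samples are removed and remaining missing cells
    are imputed as the mean of the ``knn_k`` nearest features (Euclidean
    distance over pairwise-complete samples, ties broken by feature order)
    observed at that sample. For ``mrna_tpm``, genes with values <= 0 in
    strictly more than ``max_missing_frac`` of samples are removed.
    Idempotent: a matrix without missing values passes through unchanged
    apart from the filter.
    """
    df = m.data
    n_samples = df.shape[1]
    if m.layer == "mrna_tpm":
        frac_nonpos = (df.to_numpy(dtype=float) <= 0).mean(axis=1)
        kept = df.loc[frac_nonpos <= max_missing_frac]
        if kept.empty:
            raise ValueError("all features removed by the TPM filter")
        return OmicsMatrix(m.layer, kept.copy())
    if m.layer not in ("methylation_beta", "mirna"):
        return m

    vals = df.to_numpy(dtype=float)
    miss_frac = np.isnan(vals).mean(axis=1)
    keep = miss_frac <= max_missing_frac
    if not keep.any():
        raise ValueError("all features removed by the missingness filter")
    df = df.loc[keep]
    x = df.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    if obs.all():
        return OmicsMatrix(m.layer, df.copy())

    dist = _pairwise_feature_distances(x, obs)
    np.fill_diagonal(dist, np.inf)
    out = x.copy()
    n_feat = x.shape[0]
    for i in range(n_feat):
        missing_cols = np.flatnonzero(~obs[i])
        for s in missing_cols:
            candidates = np.flatnonzero(obs[:, s] & np.isfinite(dist[i]))
            if candidates.size == 0:
                # no feature observed here shares samples with i; fall back to
                # the per-sample mean of observed features
                donors = np.flatnonzero(obs[:, s])
                out[i, s] = x[donors, s].mean() if donors.size else np.nan
                continue
            k = min(knn_k, candidates.size)
            if k < knn_k:
                logger.warning(
                    "filter_and_impute: only %d neighbors available (k=%d requested)",
                    k,
                    knn_k,
                )
            order = np.lexsort((candidates, dist[i, candidates]))
            nearest = candidates[order[:k]]
            out[i, s] = x[nearest, s].mean()
    imputed = pd.DataFrame(out, index=df.index, columns=df.columns)
    if imputed.isna().any().any():
        raise ValueError("imputation left missing values (empty sample column?)")
    return OmicsMatrix(m.layer, imputed)


def read_network(path) -> GeneNetwork:
    """Read an edge-list TSV (gene_a, gene_b[, weight])."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise FormatError("network edge list needs at least two columns")
    cols = list(df.columns)
    edges = []
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        w = float(row[2]) if len(cols) > 2 else 1.0
        edges.append((a, b, w))
    return GeneNetwork.from_edges(edges)


def write_network(net: GeneNetwork, path) -> None:
    rows = [
        {"gene_a": u, "gene_b": v, "weight": d.get("weight", 1.0)}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_probe_annotation(path) -> list[ProbeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"probe_id", "region", "target_gene_id"}
    if not needed <= set(df.columns):
        raise FormatError(f"probe annotation needs columns {sorted(needed)}")
    return [
        ProbeAnnotation(r.probe_id, r.region, r.target_gene_id)
        for r in df.itertuples(index=False)
    ]


def read_clinical(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "time_months", "event"}
    if not needed <= set(df.columns):
        raise FormatError(f"clinical table needs columns {sorted(needed)}")
    extra = [c for c in df.columns if c not in needed]
    records = []
    for r in df.itertuples(index=False):
        rowd = r._asdict()
        cov = tuple((c, rowd[c]) for c in extra)
        records.append(
            SurvivalRecord(
                str(rowd["sample_id"]),
                float(rowd["time_months"]),
                int(rowd["event"]),
                cov,
            )
        )
    return records


def write_results(
    out_dir,
    assignments: Optional[pd.DataFrame] = None,
    domain_table: Optional[pd.DataFrame] = None,
    ddg_table: Optional[pd.DataFrame] = None,
    panel: Optional[dict] = None,
    metrics: Optional[dict] = None,
    manifest: Optional[dict] = None,
    extra_tables: Optional[Mapping[str, pd.DataFrame]] = None,
) -> list:
    """Write pipeline outputs; returns the list of files written."""
    os.makedirs(out_dir, exist_ok=True)
    written = []

    def _table(df: pd.DataFrame, name: str) -> None:
        p = os.path.join(out_dir, name)
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        written.append(p)

    if assignments is not None:
        _table(assignments, "subtype_assignments.tsv")
    if domain_table is not None:
        _table(domain_table, "domain_burden.tsv")
    if ddg_table is not None:
        _table(ddg_table, "ddg_evidence.tsv")
    for name, obj in (("classifier_panel.json", panel), ("classifier_metrics.json", metrics), ("run_manifest.json", manifest)):
        if obj is not None:
            p = os.path.join(out_dir, name)
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=str)
            written.append(p)
    if extra_tables:
        for name, df in extra_tables.items():
            _table(df, name)
    return written
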