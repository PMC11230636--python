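"""The subtype-recognition model.

Stages: (1) binarize non-silent mutations over the stratification genes;
(2) smooth the binary patient x gene matrix by network propagation
``F_{t+1} = alpha * F_t A + (1 - alpha) * F_0`` over the row-stochastic
normalized gene-interaction network until the Frobenius norm of a step
falls below tolerance (alpha = 0.7, tol = 1e-6 by default); (3) z-score the
log2(x+1)-transformed expression of the driver-dysregulated genes; (4) fuse
the two layers into a sample similarity matrix W by similarity network
fusion (K = 20 neighbors, kernel bandwidth mu = 0.5, T = 20 diffusion
rounds); (5) consensus-cluster W (subsampled hierarchical clustering with
Spearman distance between W rows); (6) pick the cluster count k by mean
silhouette and name the clusters CLASS A, CLASS B, ... by descending size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from scipy.stats import rankdata

from .types import GeneNetwork, MutationRecord, NONSILENT_CLASSES

logger = logging.getLogger(__name__)

ALPHA = 0.7
PROP_TOL = 1e-6
SNF_K = 20
SNF_MU = 0.5
SNF_T = 20
MAX_K = 6
CONSENSUS_REPS = 5000
P_ITEM = 0.8


def binarize_mutations(
    mutations: Sequence[MutationRecord],
    gene_subset: Sequence[str],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Sample x gene 0/1 matrix: 1 iff the sample has >= 1 non-silent
    mutation in the gene. All-zero rows are permitted but logged."""
    genes = list(dict.fromkeys(gene_subset))
    if not genes:
        raise ValueError("gene_subset is empty")
    samples = list(sample_ids)
    f0 = pd.DataFrame(0, index=samples, columns=genes, dtype=float)
    gene_set = set(genes)
    sample_set = set(samples)
    for m in mutations:
        if (
            m.variant_class in NONSILENT_CLASSES
            and m.gene_id in gene_set
            and m.sample_id in sample_set
        ):
            f0.loc[m.sample_id, m.gene_id] = 1.0
    n_empty = int((f0.sum(axis=1) == 0).sum())
    if n_empty:
        logger.info("binarize_mutations: %d sample(s) with all-zero rows", n_empty)
    return f0


def normalize_network(net: GeneNetwork, gene_order: Sequence[str]) -> np.ndarray:
    """Row-stochastic adjacency over ``gene_order``.

    ``A[i, j] = w(i, j) / weighted_degree(i)``; a gene absent from the
    network or isolated keeps its mass (self-indicator row), so every row
    sums to exactly 1 and propagation conserves per-patient mass.
    """
    genes = list(gene_order)
    if not genes:
        raise ValueError("empty gene order")
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    a = np.zeros((n, n))
    dropped = [g for g in genes if g not in net.nodes]
    if dropped:
        logger.info("normalize_network: %d gene(s) absent from the network", len(dropped))
    for u, v, d in net.graph.edges(data=True):
        if u in idx and v in idx:
            w = d.get("weight", 1.0)
            a[idx[u], idx[v]] += w
            a[idx[v], idx[u]] += w
    deg = a.sum(axis=1)
    isolated = deg == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(isolated[:, None], 0.0, a / np.where(deg == 0, 1.0, deg)[:, None])
    a[isolated, :] = 0.0
    a[np.flatnonzero(isolated), np.flatnonzero(isolated)] = 1.0
    return a


@dataclass
class SmoothedProfile:
    data: pd.DataFrame  # samples x genes
    alpha: float
    iterations: int
    final_step_norm: float

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def propagate(
    f0: pd.DataFrame,
    a: np.ndarray,
    alpha: float = ALPHA,
    tol: float = PROP_TOL,
    max_iter: int = 1000,
    quantile_normalize: bool = False,
) -> SmoothedProfile:
    """Network propagation of the binary mutation matrix.

    Iterates ``F <- alpha * F A + (1 - alpha) * F0`` from ``F = F0`` until
    the Frobenius norm of the step is below ``tol``. The fixed point equals
    the closed form ``(1 - alpha) * F0 (I - alpha A)^{-1}``; per-patient row
    sums are conserved because A is row-stochastic. ``quantile_normalize``
    optionally rank-normalizes each patient profile to the mean sorted
    profile afterwards.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    f_prev = f0.to_numpy(dtype=float)
    f0_term = (1.0 - alpha) * f_prev
    step_norm = math.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        f_next = alpha * (f_prev @ a) + f0_term
        step_norm = float(np.linalg.norm(f_next - f_prev, "fro"))
        f_prev = f_next
        if step_norm < tol:
            break
    else:
        raise RuntimeError(
            f"propagation failed to converge in {max_iter} iterations "
            f"(final step norm {step_norm:.3e})"
        )
    out = f_prev
    if quantile_normalize:
        order = np.argsort(out, axis=1)
        ref = np.sort(out, axis=1).mean(axis=0)
        qn = np.empty_like(out)
        rows = np.arange(out.shape[0])[:, None]
        qn[rows, order] = ref[None, :]
        out = qn
    return SmoothedProfile(
        pd.DataFrame(out, index=f0.index, columns=f0.columns),
        alpha=alpha,
        iterations=iterations,
        final_step_norm=step_norm,
    )


def zscore_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) transform then per-gene z-score (population sd) across samples.

    Zero-variance genes become all-zero rows (logged)."""
    y = np.log2(expr.to_numpy(dtype=float) + 1.0)
    mean = y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, ddof=0, keepdims=True)
    degenerate = sd[:, 0] == 0
    if degenerate.any():
        logger.warning("zscore_expression: %d zero-variance gene(s)", int(degenerate.sum()))
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (y - mean) / sd_safe
    z[degenerate, :] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


# --------------------------- similarity network fusion ---------------------


def _affinity_kernel(x: np.ndarray, k: int, mu: float) -> np.ndarray:
    """Scaled-exponential affinity with K-neighbor local bandwidth scaling."""
    d = cdist(x, x, metric="euclidean")
    d_sorted = np.sort(d, axis=1)
    # mean distance to the K nearest other samples (column 0 is self)
    t = d_sorted[:, 1 : k + 1].mean(axis=1)
    eps = (t[:, None] + t[None, :] + d) / 3.0
    eps = np.where(eps <= 0, np.finfo(float).tiny ** 0.5, eps)
    w = np.exp(-(d**2) / (2.0 * (mu * eps) ** 2))
    return (w + w.T) / 2.0


def _full_kernel(w: np.ndarray) -> np.ndarray:
    """Row-normalized full kernel: off-diagonal mass 1/2, diagonal 1/2."""
    p = w.copy().astype(float)
    np.fill_diagonal(p, 0.0)
    rs = p.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    p = p / (2.0 * rs)
    np.fill_diagonal(p, 0.5)
    return p


def _local_kernel(w: np.ndarray, k: int) -> np.ndarray:
    """K-NN sparsified, row-normalized kernel (self included among neighbors)."""
    n = w.shape[0]
    s = np.zeros_like(w)
    order = np.argsort(w, axis=1)[:, ::-1]
    for i in range(n):
        nbrs = order[i, : k + 1]  # self plus K nearest
        s[i, nbrs] = w[i, nbrs]
    rs = s.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return s / rs


@dataclass
class FusedSimilarity:
    sample_ids: list
    w: np.ndarray
    k: int
    mu: float
    t: int

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def snf_fuse(
    layers: Sequence[pd.DataFrame],
    k: int = SNF_K,
    mu: float = SNF_MU,
    t: int = SNF_T,
) -> FusedSimilarity:
    """Similarity network fusion of sample x feature layers.

    Each layer becomes a sample-sample affinity kernel (Euclidean distances,
    scaled-exponential kernel with bandwidth ``mu`` and K-neighbor local
    scaling); ``t`` rounds of cross-layer diffusion propagate each layer's
    local (K-NN) kernel over the average of the other layers' full kernels;
    W is the symmetrized average of the diffused layers. With a single
    layer the diffusion runs on the layer itself.
    """
    if not layers:
        raise ValueError("at least one layer required")
    samples = list(layers[0].index)
    for lay in layers[1:]:
        if list(lay.index) != samples:
            raise ValueError("layers must share the same ordered sample universe")
    n = len(samples)
    if k >= n:
        logger.warning("snf_fuse: K=%d >= n=%d; reducing to n-1", k, n)
        k = n - 1
    kernels = [_affinity_kernel(lay.to_numpy(dtype=float), k, mu) for lay in layers]
    ps = [_full_kernel(w) for w in kernels]
    ss = [_local_kernel(w, k) for w in kernels]
    m = len(ps)
    for _ in range(t):
        if m == 1:
            avg = [ps[0]]
        else:
            total = np.sum(ps, axis=0)
            avg = [(total - ps[v]) / (m - 1) for v in range(m)]
        nxt = [ss[v] @ avg[v] @ ss[v].T for v in range(m)]
        ps = [_full_kernel((p + p.T) / 2.0) for p in nxt]
    w = np.mean(ps, axis=0)
    w = (w + w.T) / 2.0
    return FusedSimilarity(samples, w, k=k, mu=mu, t=t)


# ------------------------------ consensus clustering -----------------------


@dataclass
class ConsensusMatrix:
    sample_ids: list
    m: np.ndarray
    k: int
    reps: int
    labels: np.ndarray  # 1..k cluster labels from the consensus matrix
    n_never_cosampled: int = 0


def _spearman_distance(rows: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation between rows (average-rank ties)."""
    ranks = rankdata(rows, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    norms[norms == 0] = 1.0
    corr = (ranks @ ranks.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def consensus_cluster(
    fused: FusedSimilarity,
    max_k: int = MAX_K,
    reps: int = CONSENSUS_REPS,
    p_item: float = P_ITEM,
    seed: int = 0,
) -> dict[int, ConsensusMatrix]:
    """Subsampled consensus clustering of the fused similarity matrix.

    Per repetition, ``ceil(p_item * n)`` samples are drawn without
    replacement; each is represented by its W row restricted to the
    subsample; pairwise distance is 1 - Spearman correlation; average-
    linkage hierarchical clustering is cut at each k in 2..max_k. The
    consensus M(i, j) is the co-clustered count over the co-sampled count
    (0 for never co-sampled pairs, logged); final labels per k come from
    average-linkage clustering of 1 - M.
    """
    n = fused.n
    if not 2 <= max_k < n:
        raise ValueError(f"need 2 <= max_k < n (max_k={max_k}, n={n})")
    if not 0 < p_item <= 1:
        raise ValueError("p_item must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    m_sub = math.ceil(p_item * n)
    ks = range(2, max_k + 1)
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sample = np.zeros((n, n))
    w = fused.w
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m_sub, replace=False))
        rows = w[np.ix_(idx, idx)]
        d = _spearman_distance(rows)
        z = linkage(squareform(d, checks=False), method="average")
        co_sample[np.ix_(idx, idx)] += 1.0
        for k in ks:
            lab = fcluster(z, k, criterion="maxclust")
            for c in np.unique(lab):
                members = idx[lab == c]
                co_cluster[k][np.ix_(members, members)] += 1.0
    never = int(np.sum((co_sample == 0) & ~np.eye(n, dtype=bool)) // 2)
    if never:
        logger.warning("consensus_cluster: %d pair(s) never co-sampled", never)
    out = {}
    for k in ks:
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(co_sample > 0, co_cluster[k] / np.where(co_sample == 0, 1.0, co_sample), 0.0)
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2.0
        z = linkage(squareform(np.clip(1.0 - m, 0.0, None), checks=False), method="average")
        labels = fcluster(z, k, criterion="maxclust")
        out[k] = ConsensusMatrix(fused.sample_ids, m, k, reps, labels, never)
    return out


# --------------------------------- silhouette ------------------------------


def silhouette_samples_from_distance(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette ``(b - a) / max(a, b)`` on a distance matrix.

    ``a(i)`` is the mean distance to the other members of i's cluster,
    ``b(i)`` the smallest mean distance to any other cluster. Members of
    singleton clusters get silhouette 0.
    """
    labels = np.asarray(labels)
    n = d.shape[0]
    uniq = np.unique(labels)
    sil = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    for i in range(n):
        c = labels[i]
        if sizes[c] <= 1:
            sil[i] = 0.0
            continue
        a = d[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(
            d[i, masks[o]].mean() for o in uniq if o != c
        )
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return sil


@dataclass
class SubtypeAssignment:
    labels: pd.Series  # sample_id -> "CLASS A", "CLASS B", ...
    silhouette: pd.Series  # per-sample silhouette at the chosen k
    mean_silhouette_per_k: dict
    chosen_k: int

    @property
    def mean_silhouette(self) -> float:
        return self.mean_silhouette_per_k[self.chosen_k]


def silhouette_and_choose_k(
    per_k: Mapping[int, ConsensusMatrix], fused: FusedSimilarity
) -> SubtypeAssignment:
    """Pick k by mean silhouette on the similarity-derived distance matrix.

    The distance is ``D = max(W) - W`` with zero diagonal. Clusters are
    renamed CLASS A, CLASS B, ... by descending size (ties by first
    occurrence). Any k whose clustering degenerates (fewer than k
    nonempty clusters) is skipped with a warning.
    """
    w = fused.w.copy()
    np.fill_diagonal(w, 0.0)  # self-similarity carries no between-sample information
    d = w.max() - w
    np.fill_diagonal(d, 0.0)
    mean_sil: dict[int, float] = {}
    per_sample: dict[int, np.ndarray] = {}
    for k, cm in sorted(per_k.items()):
        if len(np.unique(cm.labels)) < k:
            logger.warning("k=%d produced an empty cluster; skipped", k)
            continue
        sil = silhouette_samples_from_distance(d, cm.labels)
        mean_sil[k] = float(sil.mean())
        per_sample[k] = sil
    if not mean_sil:
        raise ValueError("no valid clustering at any k")
    chosen = max(mean_sil, key=lambda k: (mean_sil[k], -k))
    cm = per_k[chosen]
    raw = cm.labels
    order = sorted(
        np.unique(raw), key=lambda c: (-int((raw == c).sum()), int(np.argmax(raw == c)))
    )
    name_map = {c: f"CLASS {chr(ord('A') + i)}" for i, c in enumerate(order)}
    labels = pd.Series([name_map[c] for c in raw], index=fused.sample_ids, name="subtype")
    sil = pd.Series(per_sample[chosen], index=fused.sample_ids, name="silhouette")
    return SubtypeAssignment(labels, sil, mean_sil, chosen)


def discover_subtypes(
    f0: pd.DataFrame,
    expr_tpm: pd.DataFrame,
    network: GeneNetwork,
    alpha: float = ALPHA,
    tol: float = PROP_TOL,
    k_neighbors: int = SNF_K,
    mu: float = SNF_MU,
    t_iter: int = SNF_T,
    max_k: int = MAX_K,
    reps: int = CONSENSUS_REPS,
    p_item: float = P_ITEM,
    seed: int = 0,
    quantile_normalize: bool = False,
):
    """Full subtype model: propagate, z-score, fuse, consensus, silhouette.

    ``f0``: sample x stratification-gene binary matrix; ``expr_tpm``:
    feature x sample TPM matrix restricted to the DDGs (samples must match
    ``f0.index``). Returns ``(assignment, fused, per_k, smoothed)``.
    """
    if list(expr_tpm.columns) != list(f0.index):
        expr_tpm = expr_tpm.loc[:, list(f0.index)]
    a = normalize_network(network, list(f0.columns))
    smoothed = propagate(f0, a, alpha=alpha, tol=tol, quantile_normalize=quantile_normalize)
    z = zscore_expression(expr_tpm)
    fused = snf_fuse([smoothed.data, z.T], k=k_neighbors, mu=mu, t=t_iter)
    per_k = consensus_cluster(fused, max_k=max_k, reps=reps, p_item=p_item, seed=seed)
    assignment = silhouette_and_choose_k(per_k, fused)
    return assignment, fused, per_k, smoothed
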