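"""Protein-domain mutation burden: permutation test, dispersion entropy and
stratification-gene selection.

The burden test asks whether a domain shared by the members of a gene family
accumulates more mutations than expected when every residue of each protein
is equally likely to mutate. The dispersion of a domain's mutations across
its family carriers is scored with a normalized Shannon entropy
``S = -sum(P_i ln P_i) / ln n`` (``P_i`` = gene *i*'s share of the domain's
mutations, ``n`` = number of carrier genes): S -> 1 for uniformly dispersed
mutations, S -> 0 when a single carrier absorbs them all. Stratification
genes are family genes mutated inside a domain that is both significant
after Benjamini-Hochberg correction and high-entropy.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import DomainInstance, MutationRecord, NONSILENT_CLASSES

logger = logging.getLogger(__name__)

CODING_MEGABASES = 38.0
TMB_CUTOFF = 30.0


def compute_tmb(mutations: Iterable[MutationRecord], coding_megabases: float = CODING_MEGABASES) -> float:
    """Tumor mutational burden: non-silent coding mutations per megabase."""
    n = sum(1 for m in mutations if m.variant_class in NONSILENT_CLASSES)
    return n / coding_megabases


def filter_hypermutators(
    mutations: Sequence[MutationRecord],
    tmb_cutoff: float = TMB_CUTOFF,
    coding_megabases: float = CODING_MEGABASES,
):
    """Drop samples whose TMB strictly exceeds the cutoff.

    Returns ``(retained_mutations, retained_samples, excluded_samples)``.
    A sample at exactly the cutoff is retained.
    """
    by_sample: dict[str, list] = defaultdict(list)
    for m in mutations:
        by_sample[m.sample_id].append(m)
    excluded = sorted(
        s for s, ms in by_sample.items() if compute_tmb(ms, coding_megabases) > tmb_cutoff
    )
    excluded_set = set(excluded)
    retained = [m for m in mutations if m.sample_id not in excluded_set]
    retained_samples = sorted(set(by_sample) - excluded_set)
    if excluded:
        logger.info("filter_hypermutators: excluded %d sample(s)", len(excluded))
    return retained, retained_samples, excluded


def map_mutations_to_domains(
    mutations: Iterable[MutationRecord],
    domains: Iterable[DomainInstance],
    nonsilent_only: bool = True,
):
    """Count mutations inside each (domain, gene) instance.

    A mutation at position ``p`` is in-domain iff ``start_aa <= p <= end_aa``.
    A mutation falling into overlapping instances of *different* domains
    counts once per domain; multiple instances of the same domain on the
    same gene count it once. Returns ``{domain_id: Counter{gene: count}}``.
    """
    by_gene: dict[str, list[DomainInstance]] = defaultdict(list)
    known_genes = set()
    for d in domains:
        by_gene[d.gene_id].append(d)
        known_genes.add(d.gene_id)
    counts: dict[str, Counter] = defaultdict(Counter)
    for m in mutations:
        if nonsilent_only and m.variant_class not in NONSILENT_CLASSES:
            continue
        hit_domains = {
            d.domain_id for d in by_gene.get(m.gene_id, ()) if d.contains(m.protein_pos)
        }
        for did in hit_domains:
            counts[did][m.gene_id] += 1
    return dict(counts)


def _domain_coverage(instances: Sequence[DomainInstance]) -> int:
    """Residues covered by the union of a gene's instances of one domain."""
    ivs = sorted((d.start_aa, d.end_aa) for d in instances)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e + 1:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + cur_e - cur_s + 1


def permutation_test_domain(
    observed_in_domain: int,
    gene_total_mutations: Mapping[str, int],
    gene_domain_instances: Mapping[str, Sequence[DomainInstance]],
    protein_lengths: Mapping[str, int],
    n_perm: int = 9999,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> float:
    """Permutation p-value for a domain's total in-domain mutation count.

    Under the null each gene's observed mutations are re-placed independently
    and uniformly over its residues; the permuted statistic is the family's
    total in-domain count. Because placements are independent and uniform,
    each gene's permuted in-domain count is drawn exactly as
    ``Binomial(m_g, covered_g / L_g)``. p = (#{permuted >= observed} + 1) /
    (n_perm + 1), so p >= 1/(n_perm + 1) and the test is conservative at
    ties.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    totals, probs = [], []
    for gene, instances in gene_domain_instances.items():
        length = protein_lengths[gene]
        if length <= 0:
            raise ValueError(f"protein length for {gene} must be positive")
        m = int(gene_total_mutations.get(gene, 0))
        if m == 0:
            continue
        totals.append(m)
        probs.append(_domain_coverage(instances) / length)
    if not totals:
        logger.warning("permutation_test_domain: no mutations in family; p = 1")
        return 1.0
    totals_a = np.asarray(totals)
    probs_a = np.asarray(probs)
    permuted = rng.binomial(totals_a[None, :], probs_a[None, :], size=(n_perm, len(totals))).sum(axis=1)
    n_ge = int(np.count_nonzero(permuted >= observed_in_domain))
    return (n_ge + 1) / (n_perm + 1)


def domain_entropy(per_gene_in_domain_counts: Mapping[str, float]) -> float:
    """Normalized Shannon entropy of a domain's mutation shares.

    ``n`` counts every carrier gene, including those with zero in-domain
    mutations (0 * ln 0 = 0). Returns NaN when the total count is zero and
    0.0 for single-carrier domains (no family-dispersion evidence).
    """
    counts = np.asarray(list(per_gene_in_domain_counts.values()), dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("counts must be a nonempty set of nonnegative numbers")
    total = counts.sum()
    if total == 0:
        return float("nan")
    n = counts.size
    if n == 1:
        return 0.0
    p = counts / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(n) + 0.0)


@dataclass
class DomainBurdenResult:
    domain_id: str
    n_family_genes_with_domain: int
    observed_in_domain_mutations: int
    per_gene_in_domain_counts: dict
    p_value: float
    p_adjusted: float = float("nan")
    entropy_S: float = float("nan")
    significant: bool = False
    high_entropy: bool = False


def analyze_domain_burden(
    mutations: Sequence[MutationRecord],
    domains: Sequence[DomainInstance],
    protein_lengths: Mapping[str, int],
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
    entropy_cutoff: float = 0.5,
) -> list[DomainBurdenResult]:
    """Run the burden permutation test and entropy scoring for every domain."""
    known = set(protein_lengths)
    usable = [d for d in domains if d.gene_id in known]
    for d in domains:
        if d.gene_id not in known:
            logger.warning("domain %s on unknown gene %s skipped", d.domain_id, d.gene_id)

    per_domain_gene_instances: dict[str, dict[str, list]] = defaultdict(lambda: defaultdict(list))
    for d in usable:
        per_domain_gene_instances[d.domain_id][d.gene_id].append(d)

    gene_totals = Counter(
        m.gene_id for m in mutations if m.variant_class in NONSILENT_CLASSES
    )
    in_domain = map_mutations_to_domains(mutations, usable)

    rng = np.random.default_rng(seed)
    results = []
    for did in sorted(per_domain_gene_instances):
        carriers = per_domain_gene_instances[did]
        per_gene = {g: int(in_domain.get(did, Counter()).get(g, 0)) for g in sorted(carriers)}
        observed = sum(per_gene.values())
        p = permutation_test_domain(
            observed, gene_totals, carriers, protein_lengths, n_perm=n_perm, rng=rng
        )
        results.append(
            DomainBurdenResult(
                domain_id=did,
                n_family_genes_with_domain=len(carriers),
                observed_in_domain_mutations=observed,
                per_gene_in_domain_counts=per_gene,
                p_value=p,
                entropy_S=domain_entropy(per_gene),
            )
        )
    if results:
        _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, pa in zip(results, p_adj):
            r.p_adjusted = float(pa)
            r.significant = r.p_adjusted < alpha
            r.high_entropy = bool(r.entropy_S > entropy_cutoff)
    return results


def select_stratification_genes(
    results: Iterable[DomainBurdenResult],
    entropy_cutoff: float = 0.5,
    alpha: float = 0.05,
) -> set:
    """Family genes with >= 1 mutation in a significant, high-entropy domain."""
    genes = set()
    for r in results:
        if r.p_adjusted < alpha and r.entropy_S > entropy_cutoff:
            genes.update(g for g, c in r.per_gene_in_domain_counts.items() if c >= 1)
    return genes


def burden_results_table(results: Sequence[DomainBurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain_id": r.domain_id,
                "n_carrier_genes": r.n_family_genes_with_domain,
                "observed_in_domain": r.observed_in_domain_mutations,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "entropy_S": r.entropy_S,
                "significant": r.significant,
                "high_entropy": r.high_entropy,
            }
            for r in results
        ]
    )
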