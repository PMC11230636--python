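"""Synthetic multi-omics cohort with planted two-subtype ground truth.

The generator emulates the statistical structure the subtyping analysis
assumes: gene families whose members share a protein domain, subtype-skewed
domain-localized mutations (dispersed across family members so the planted
hotspots are high-entropy, plus one low-entropy decoy concentrated in a
single member), subtype-differential expression, promoter-methylation /
miRNA / gene-level-CNV features correlated with expression, arm-level copy
number with subtype-specific instability, and exponential survival with a
subtype hazard difference. Everything is reproducible from ``config.seed``.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io as dio
from .types import (
    DomainInstance,
    GeneFamily,
    GeneNetwork,
    MutationRecord,
    OmicsMatrix,
    ProbeAnnotation,
    SurvivalRecord,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

#: GISTIC-style arm labels: p and q for 22 autosomes, minus the p arms of
#: the acrocentric chromosomes 13, 14, 15, 21 and 22 (39 arms).
ARM_NAMES = tuple(
    f"{c}{a}"
    for c in range(1, 23)
    for a in ("p", "q")
    if not (a == "p" and c in (13, 14, 15, 21, 22))
)

PROTEIN_LENGTH = 500
DOMAIN_START, DOMAIN_END = 101, 200
DECOY_START, DECOY_END = 301, 400
ARM_BACKGROUND_PROB = 0.1  # arm-alteration probability in subtype A


@dataclass
class SyntheticCohortConfig:
    """Study conditions for the synthetic cohort (defaults = test conditions)."""

    n_samples: int = 120
    subtype_fraction_B: float = 0.5
    n_families: int = 10
    members_per_family: int = 6
    n_background_genes: int = 140
    n_hotspot_domains: int = 3
    domain_mutation_rate_in_hotspot: float = 1.5
    background_mutation_rate: float = 0.02
    n_planted_degs: int = 30
    deg_log2fc: float = 2.0
    expression_noise_sd: float = 0.5
    meth_effect_delta_beta: float = 0.3
    mirna_target_rho: float = -0.8
    cnv_arm_instability_prob_B: float = 0.5
    hazard_ratio_B: float = 2.0
    median_survival_A_months: float = 20.0
    censoring_rate: float = 0.3
    network_within_family_p: float = 0.8
    network_background_p: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        for name in (
            "subtype_fraction_B",
            "cnv_arm_instability_prob_B",
            "censoring_rate",
            "network_within_family_p",
            "network_background_p",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                errors.append(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.subtype_fraction_B < 1:
            errors.append("subtype_fraction_B must lie in (0, 1)")
        for name in ("domain_mutation_rate_in_hotspot", "background_mutation_rate"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be nonnegative")
        if self.n_hotspot_domains > self.n_families:
            errors.append("n_hotspot_domains cannot exceed n_families")
        n_family_genes = self.n_families * self.members_per_family
        if self.n_planted_degs > n_family_genes:
            errors.append(
                f"n_planted_degs ({self.n_planted_degs}) exceeds family genes "
                f"({n_family_genes})"
            )
        if errors:
            raise ValueError("; ".join(errors))

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SyntheticCohortConfig":
        """A cohort with every planted effect switched off."""
        params = dict(
            deg_log2fc=0.0,
            domain_mutation_rate_in_hotspot=0.0,
            meth_effect_delta_beta=0.0,
            mirna_target_rho=0.0,
            cnv_arm_instability_prob_B=ARM_BACKGROUND_PROB,
            hazard_ratio_B=1.0,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class CohortTruth:
    labels: pd.Series  # sample_id -> "A" / "B"
    planted_degs: list
    hotspot_domain_ids: list
    decoy_domain_id: str
    meth_genes: list
    mirna_genes: list
    cnv_genes: list


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    mutations: list
    domains: list
    families: list
    protein_lengths: dict
    expression_tumor: OmicsMatrix
    expression_normal: OmicsMatrix
    methylation: OmicsMatrix
    methylation_normal: OmicsMatrix
    mirna: OmicsMatrix
    mirna_normal: OmicsMatrix
    cnv_gene: OmicsMatrix
    cnv_arm: OmicsMatrix
    mirna_targets: dict
    probe_annotation: list
    network: GeneNetwork
    survival: list
    truth: CohortTruth

    @property
    def sample_ids(self) -> list:
        return list(self.truth.labels.index)

    def to_directory(self, out_dir) -> None:
        """Emit the cohort in the pipeline's tab-separated text formats."""
        os.makedirs(out_dir, exist_ok=True)
        mut = pd.DataFrame(
            {
                "Tumor_Sample_Barcode": [m.sample_id for m in self.mutations],
                "Hugo_Symbol": [m.gene_id for m in self.mutations],
                "Protein_position": [m.protein_pos for m in self.mutations],
                "Reference_AA": [m.ref_aa for m in self.mutations],
                "Alternate_AA": [m.alt_aa for m in self.mutations],
                "Variant_Classification": [m.variant_class for m in self.mutations],
            }
        )
        mut.to_csv(os.path.join(out_dir, "mutations.maf.tsv"), sep="\t", index=False)
        dom = pd.DataFrame(
            [
                {
                    "gene_id": d.gene_id,
                    "domain_id": d.domain_id,
                    "start_aa": d.start_aa,
                    "end_aa": d.end_aa,
                    "e_value": d.e_value,
                }
                for d in self.domains
            ]
        )
        dom.to_csv(os.path.join(out_dir, "domains.tsv"), sep="\t", index=False)
        fam = pd.DataFrame(
            [
                {"family_id": f.family_id, "gene_id": g}
                for f in self.families
                for g in sorted(f.member_gene_ids)
            ]
        )
        fam.to_csv(os.path.join(out_dir, "families.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {
                "gene_id": list(self.protein_lengths),
                "length": list(self.protein_lengths.values()),
            }
        ).to_csv(os.path.join(out_dir, "protein_lengths.tsv"), sep="\t", index=False)
        matrices = {
            "expression_tumor.tsv": self.expression_tumor,
            "expression_normal.tsv": self.expression_normal,
            "methylation_tumor.tsv": self.methylation,
            "methylation_normal.tsv": self.methylation_normal,
            "mirna_tumor.tsv": self.mirna,
            "mirna_normal.tsv": self.mirna_normal,
            "cnv_gene.tsv": self.cnv_gene,
            "cnv_arm.tsv": self.cnv_arm,
        }
        for name, m in matrices.items():
            dio.write_omics_matrix(m, os.path.join(out_dir, name))
        pd.DataFrame(
            [
                {"mirna_id": m, "gene_id": g}
                for m, genes in self.mirna_targets.items()
                for g in sorted(genes)
            ]
        ).to_csv(os.path.join(out_dir, "mirna_targets.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                {"probe_id": p.probe_id, "region": p.region, "target_gene_id": p.target_gene_id}
                for p in self.probe_annotation
            ]
        ).to_csv(os.path.join(out_dir, "probe_annotation.tsv"), sep="\t", index=False)
        dio.write_network(self.network, os.path.join(out_dir, "network.tsv"))
        pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.survival],
                "time_months": [s.time for s in self.survival],
                "event": [s.event for s in self.survival],
            }
        ).to_csv(os.path.join(out_dir, "clinical.tsv"), sep="\t", index=False)
        self.truth.labels.rename("subtype").rename_axis("sample_id").to_csv(
            os.path.join(out_dir, "truth_labels.tsv"), sep="\t"
        )


def _family_gene_ids(cfg: SyntheticCohortConfig) -> list:
    return [
        f"FAM{f + 1:02d}_M{m + 1}"
        for f in range(cfg.n_families)
        for m in range(cfg.members_per_family)
    ]


#: fixed stream for gene-level parameters (baseline expression, which genes
#: carry planted effects): these are properties of the simulated disease
#: process, shared by every cohort drawn from it, so classifiers trained on
#: one seeded cohort transfer to another.
_STRUCTURE_SEED = 715517


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    struct_rng = np.random.default_rng(_STRUCTURE_SEED)

    samples = [f"T{i + 1:03d}" for i in range(cfg.n_samples)]
    n_b = int(round(cfg.n_samples * cfg.subtype_fraction_B))
    labels = np.array(["A"] * cfg.n_samples, dtype=object)
    b_idx = rng.choice(cfg.n_samples, size=n_b, replace=False)
    labels[b_idx] = "B"
    labels = pd.Series(labels, index=samples, name="subtype")
    is_b = (labels == "B").to_numpy()

    family_genes = _family_gene_ids(cfg)
    background_genes = [f"BG{i + 1:03d}" for i in range(cfg.n_background_genes)]
    genes = family_genes + background_genes
    protein_lengths = {g: PROTEIN_LENGTH for g in genes}

    families = [
        GeneFamily(
            f"FAM{f + 1:02d}",
            frozenset(
                family_genes[f * cfg.members_per_family : (f + 1) * cfg.members_per_family]
            ),
        )
        for f in range(cfg.n_families)
    ]

    # one shared domain per family; the first n_hotspot families are hotspots
    domains: list[DomainInstance] = []
    for f, fam in enumerate(families):
        did = f"DOM_F{f + 1:02d}"
        for g in sorted(fam.member_gene_ids):
            domains.append(DomainInstance(g, did, DOMAIN_START, DOMAIN_END, 1e-8))
    hotspot_ids = [f"DOM_F{f + 1:02d}" for f in range(cfg.n_hotspot_domains)]
    # low-entropy decoy: shared by the last family, mutations land in one member
    decoy_family = families[-1]
    decoy_members = sorted(decoy_family.member_gene_ids)
    decoy_id = "DOM_DECOY"
    for g in decoy_members:
        domains.append(DomainInstance(g, decoy_id, DECOY_START, DECOY_END, 1e-8))

    # ---- mutations -------------------------------------------------------
    mutations: list[MutationRecord] = []

    def _add_mutation(sample: str, gene: str, pos: int) -> None:
        ref, alt = rng.choice(len(AA), size=2, replace=False)
        mutations.append(
            MutationRecord(sample, gene, int(pos), AA[ref], AA[alt], "missense")
        )

    domain_len = DOMAIN_END - DOMAIN_START + 1
    for si, s in enumerate(samples):
        n_bg = rng.poisson(cfg.background_mutation_rate, size=len(genes))
        for gi in np.flatnonzero(n_bg):
            for _ in range(int(n_bg[gi])):
                _add_mutation(s, genes[gi], rng.integers(1, PROTEIN_LENGTH + 1))
        if is_b[si]:
            for f in range(cfg.n_hotspot_domains):
                members = sorted(families[f].member_gene_ids)
                for _ in range(int(rng.poisson(cfg.domain_mutation_rate_in_hotspot))):
                    g = members[rng.integers(len(members))]
                    _add_mutation(s, g, DOMAIN_START + rng.integers(domain_len))
        # subtype-neutral decoy burden, all in one member
        for _ in range(int(rng.poisson(cfg.domain_mutation_rate_in_hotspot))):
            _add_mutation(
                s, decoy_members[0], DECOY_START + rng.integers(DECOY_END - DECOY_START + 1)
            )

    # ---- expression ------------------------------------------------------
    n_normal = max(20, cfg.n_samples // 2)
    normals = [f"N{i + 1:03d}" for i in range(n_normal)]
    baseline = struct_rng.uniform(2.0, 8.0, size=len(genes))
    planted_degs = list(
        struct_rng.choice(family_genes, size=cfg.n_planted_degs, replace=False)
    )
    deg_set = set(planted_degs)
    effect = np.array([cfg.deg_log2fc if g in deg_set else 0.0 for g in genes])

    log_t = (
        baseline[:, None]
        + effect[:, None] * is_b[None, :].astype(float)
        + rng.normal(0.0, cfg.expression_noise_sd, size=(len(genes), cfg.n_samples))
    )
    log_n = baseline[:, None] + rng.normal(
        0.0, cfg.expression_noise_sd, size=(len(genes), n_normal)
    )
    expr_t = OmicsMatrix(
        "mrna_tpm",
        pd.DataFrame(np.clip(2.0**log_t - 1.0, 0.0, None), index=genes, columns=samples),
    )
    expr_n = OmicsMatrix(
        "mrna_tpm",
        pd.DataFrame(np.clip(2.0**log_n - 1.0, 0.0, None), index=genes, columns=normals),
    )

    # evidence subsets (disjoint thirds of the planted DEGs)
    third = len(planted_degs) // 3
    meth_genes = planted_degs[:third]
    mirna_genes = planted_degs[third : 2 * third]
    cnv_genes = planted_degs[2 * third :]

    gene_pos = {g: i for i, g in enumerate(genes)}

    # ---- methylation (one promoter probe per family gene) ----------------
    probes = [f"PRB_{g}" for g in family_genes]
    probe_annotation = [ProbeAnnotation(f"PRB_{g}", "promoter", g) for g in family_genes]
    beta_t = np.empty((len(probes), cfg.n_samples))
    beta_n = np.empty((len(probes), n_normal))
    for pi, g in enumerate(family_genes):
        if g in meth_genes and cfg.meth_effect_delta_beta > 0:
            dev = log_t[gene_pos[g]] - log_t[gene_pos[g]].mean()
            beta_t[pi] = (
                0.65
                - cfg.meth_effect_delta_beta
                - 0.1 * dev
                + rng.normal(0.0, 0.03, cfg.n_samples)
            )
            beta_n[pi] = 0.65 + rng.normal(0.0, 0.03, n_normal)
        else:
            beta_t[pi] = 0.5 + rng.normal(0.0, 0.05, cfg.n_samples)
            beta_n[pi] = 0.5 + rng.normal(0.0, 0.05, n_normal)
    meth_t = OmicsMatrix(
        "methylation_beta",
        pd.DataFrame(np.clip(beta_t, 0.0, 1.0), index=probes, columns=samples),
    )
    meth_n = OmicsMatrix(
        "methylation_beta",
        pd.DataFrame(np.clip(beta_n, 0.0, 1.0), index=probes, columns=normals),
    )

    # ---- miRNA (one regulator per planted miRNA gene + background) -------
    mirna_ids = [f"mir-{i + 1:03d}" for i in range(max(len(mirna_genes), 1) + 10)]
    mirna_targets: dict[str, set] = {m: set() for m in mirna_ids}
    mlog_t = np.empty((len(mirna_ids), cfg.n_samples))
    mlog_n = np.empty((len(mirna_ids), n_normal))
    for mi, m in enumerate(mirna_ids):
        if mi < len(mirna_genes) and cfg.mirna_target_rho != 0:
            g = mirna_genes[mi]
            mirna_targets[m].add(g)
            dev = log_t[gene_pos[g]] - log_t[gene_pos[g]].mean()
            # miRNA low in tumor (de-repressed target), anti-correlated within tumors
            mlog_t[mi] = 5.0 + cfg.mirna_target_rho * dev + rng.normal(0.0, 0.3, cfg.n_samples)
            mlog_n[mi] = 7.0 + rng.normal(0.0, 0.3, n_normal)
        else:
            base = struct_rng.uniform(3.0, 6.0)
            mlog_t[mi] = base + rng.normal(0.0, 0.3, cfg.n_samples)
            mlog_n[mi] = base + rng.normal(0.0, 0.3, n_normal)
            # decoy target links exercise the evidence filter
            mirna_targets[m].add(family_genes[mi % len(family_genes)])
    mirna_t = OmicsMatrix(
        "mirna",
        pd.DataFrame(np.clip(2.0**mlog_t - 1.0, 0.0, None), index=mirna_ids, columns=samples),
    )
    mirna_n = OmicsMatrix(
        "mirna",
        pd.DataFrame(np.clip(2.0**mlog_n - 1.0, 0.0, None), index=mirna_ids, columns=normals),
    )

    # ---- gene-level CNV --------------------------------------------------
    cnv = rng.normal(0.0, 0.2, size=(len(genes), cfg.n_samples))
    for g in cnv_genes:
        gi = gene_pos[g]
        cnv[gi] = (log_t[gi] - baseline[gi]) - 0.7 + rng.normal(0.0, 0.2, cfg.n_samples)
    cnv_gene_m = OmicsMatrix("cnv_gene", pd.DataFrame(cnv, index=genes, columns=samples))

    # ---- arm-level CNV ---------------------------------------------------
    arm_prob = np.where(is_b, cfg.cnv_arm_instability_prob_B, ARM_BACKGROUND_PROB)
    altered = rng.random((len(ARM_NAMES), cfg.n_samples)) < arm_prob[None, :]
    magnitude = rng.uniform(0.15, 0.5, size=altered.shape) * rng.choice(
        [-1.0, 1.0], size=altered.shape
    )
    quiet = rng.uniform(-0.05, 0.05, size=altered.shape)
    arm_scores = np.where(altered, magnitude, quiet)
    cnv_arm_m = OmicsMatrix(
        "cnv_arm", pd.DataFrame(arm_scores, index=list(ARM_NAMES), columns=samples)
    )

    # ---- network ---------------------------------------------------------
    edges = []
    for fam in families:
        members = sorted(fam.member_gene_ids)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < cfg.network_within_family_p:
                    edges.append((members[i], members[j], 1.0))
    fam_sets = {g: f.family_id for f in families for g in f.member_gene_ids}
    n_genes = len(genes)
    # background edges via sparse Bernoulli sampling over all pairs
    n_pairs = n_genes * (n_genes - 1) // 2
    n_bg_edges = rng.binomial(n_pairs, cfg.network_background_p)
    if n_bg_edges:
        chosen = rng.choice(n_pairs, size=n_bg_edges, replace=False)
        for c in chosen:
            i = int((1 + np.sqrt(1 + 8 * c)) // 2)
            j = int(c - i * (i - 1) // 2)
            a, b = genes[i], genes[j]
            if fam_sets.get(a) is not None and fam_sets.get(a) == fam_sets.get(b):
                continue
            edges.append((a, b, 1.0))
    network = GeneNetwork.from_edges(edges)
    for g in genes:
        network.graph.add_node(g)

    # ---- survival --------------------------------------------------------
    lam_a = np.log(2.0) / cfg.median_survival_A_months
    lam = np.where(is_b, cfg.hazard_ratio_B * lam_a, lam_a)
    event_t = rng.exponential(1.0 / lam)
    if cfg.censoring_rate > 0:
        lam_c = lam_a * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        censor_t = rng.exponential(1.0 / lam_c, size=cfg.n_samples)
    else:
        censor_t = np.full(cfg.n_samples, np.inf)
    obs_t = np.minimum(event_t, censor_t)
    events = (event_t <= censor_t).astype(int)
    survival = [
        SurvivalRecord(s, float(obs_t[i]), int(events[i]))
        for i, s in enumerate(samples)
    ]

    truth = CohortTruth(
        labels=labels,
        planted_degs=planted_degs,
        hotspot_domain_ids=hotspot_ids,
        decoy_domain_id=decoy_id,
        meth_genes=meth_genes,
        mirna_genes=mirna_genes,
        cnv_genes=cnv_genes,
    )
    return SyntheticCohort(
        config=cfg,
        mutations=mutations,
        domains=domains,
        families=families,
        protein_lengths=protein_lengths,
        expression_tumor=expr_t,
        expression_normal=expr_n,
        methylation=meth_t,
        methylation_normal=meth_n,
        mirna=mirna_t,
        mirna_normal=mirna_n,
        cnv_gene=cnv_gene_m,
        cnv_arm=cnv_arm_m,
        mirna_targets={m: s for m, s in mirna_targets.items() if s},
        probe_annotation=probe_annotation,
        network=network,
        survival=survival,
        truth=truth,
    )


def truth_ari(predicted_labels, truth_labels) -> float:
    """Adjusted Rand index between a predicted and the planted partition."""
    pred = pd.Series(predicted_labels)
    truth = pd.Series(truth_labels)
    if len(pred) != len(truth):
        raise ValueError(
            f"label vectors differ in length ({len(pred)} vs {len(truth)})"
        )
    if isinstance(pred.index[0], str) and isinstance(truth.index[0], str):
        common = truth.index
        pred = pred.loc[common]
        truth = truth.loc[common]
    return float(adjusted_rand_score(truth.to_numpy(), pred.to_numpy()))


def config_to_dict(cfg: SyntheticCohortConfig) -> dict:
    return asdict(cfg)
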