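"""Shared domain types for the subtyping pipeline.

Conventions used throughout the package:

* protein coordinates are 1-based, closed intervals ``[start_aa, end_aa]``;
  a mutation at position ``p`` lies in a domain iff ``start_aa <= p <= end_aa``;
* omics matrices are features x samples;
* expression values are TPM (nonnegative), methylation values are beta
  fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "splice", "frameshift", "inframe_indel", "silent", "other"}
)
#: variant classes that are single amino-acid substitutions
POINT_CLASSES = frozenset({"missense", "nonsense", "silent"})
#: variant classes counted as non-silent coding mutations
NONSILENT_CLASSES = frozenset({"missense", "nonsense"})

OMICS_LAYERS = frozenset(
    {"mrna_tpm", "mirna", "methylation_beta", "cnv_gene", "cnv_arm"}
)
PROBE_REGIONS = frozenset({"promoter", "gene_body", "distal_enhancer"})


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic point mutation in protein coordinates."""

    sample_id: str
    gene_id: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    variant_class: str

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")

    @property
    def is_nonsilent(self) -> bool:
        return self.variant_class in NONSILENT_CLASSES


@dataclass(frozen=True)
class DomainInstance:
    """One occurrence of a protein domain on a gene product."""

    gene_id: str
    domain_id: str
    start_aa: int
    end_aa: int
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError(
                f"invalid domain interval [{self.start_aa}, {self.end_aa}]"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be nonnegative")

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1

    def contains(self, pos: int) -> bool:
        return self.start_aa <= pos <= self.end_aa


@dataclass
class GeneFamily:
    family_id: str
    member_gene_ids: frozenset
    seed_driver_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.member_gene_ids = frozenset(self.member_gene_ids)
        self.seed_driver_ids = frozenset(self.seed_driver_ids)
        if not self.member_gene_ids:
            raise ValueError(f"family {self.family_id} has no members")
        if not self.seed_driver_ids <= self.member_gene_ids:
            raise ValueError(
                f"family {self.family_id}: seed drivers must be members"
            )


@dataclass
class OmicsMatrix:
    """A feature x sample real matrix tagged with its omics layer."""

    layer: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in OMICS_LAYERS:
            raise ValueError(f"unknown omics layer {self.layer!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if self.layer == "methylation_beta":
            with np.errstate(invalid="ignore"):
                bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                raise ValueError("methylation beta values must lie in [0, 1]")
        elif self.layer in ("mrna_tpm", "mirna"):
            with np.errstate(invalid="ignore"):
                bad = vals < 0
            if np.any(bad & ~np.isnan(vals)):
                raise ValueError(f"{self.layer} values must be nonnegative")

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def restrict_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    region: str
    target_gene_id: str

    def __post_init__(self) -> None:
        if self.region not in PROBE_REGIONS:
            raise ValueError(f"unknown probe region {self.region!r}")


@dataclass
class GeneNetwork:
    """Undirected weighted gene-interaction network (no self-loops)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            w = d.get("weight", 1.0)
            if w <= 0:
                raise ValueError(f"edge ({u}, {v}) has nonpositive weight {w}")

    @classmethod
    def from_edges(cls, edges) -> "GeneNetwork":
        g = nx.Graph()
        for edge in edges:
            if len(edge) == 2:
                a, b = edge
                w = 1.0
            else:
                a, b, w = edge
            g.add_edge(a, b, weight=float(w))
        return cls(g)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be nonnegative")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")
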