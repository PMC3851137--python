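"""Domain types shared by all pipeline stages.

All identifier spaces (probesets, genes, phenotypes, drugs, samples,
perturbation instances) are opaque strings; nothing here assumes Entrez or
Affymetrix formats.  Types validate their own invariants at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "ProbesetGeneMap",
    "OrthologyMap",
    "AntiCoexNetwork",
    "CAGC",
    "GeneSetCollection",
    "PhenotypeSimilarity",
    "DrugTargetTable",
    "PerturbationRankMatrix",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen = pd.Index(list(ids))
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression, probesets x samples.

    ``values`` rows are probesets, columns are samples.  Missing values are
    permitted; correlation downstream uses pairwise-complete samples.
    """

    dataset_id: str
    species: str
    values: pd.DataFrame
    min_samples: int = 4

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probeset IDs")
        _check_unique(self.values.columns, "sample IDs")
        self.values = self.values.astype(float)

    @property
    def probesets(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def zero_variance_probesets(self) -> list[str]:
        """Probesets whose observed values are constant (or all missing).

        These carry no correlation signal and are excluded from network
        construction.
        """
        v = self.values
        std = v.std(axis=1, ddof=0)
        flagged = std.isna() | (std == 0.0)
        return list(v.index[flagged])

    def check_usable(self) -> None:
        if self.n_samples < self.min_samples:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: {self.n_samples} samples < "
                f"required minimum {self.min_samples}; refusing to build networks"
            )


@dataclass
class ProbesetGeneMap:
    """Set of (probeset, gene) pairs; a probeset may map to no gene."""

    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = set(self.pairs)
        self._by_probeset: dict[str, set[str]] = {}
        for ps, g in self.pairs:
            self._by_probeset.setdefault(ps, set()).add(g)

    def genes_of(self, probeset: str) -> set[str]:
        return self._by_probeset.get(probeset, set())

    def genes(self) -> set[str]:
        return {g for _, g in self.pairs}

    def probesets_of(self, gene: str) -> set[str]:
        return {ps for ps, g in self.pairs if g == gene}


@dataclass
class OrthologyMap:
    """Cross-species gene pairs with a one-to-one flag.

    Only pairs flagged one-to-one take part in conservation; the flag is
    validated (a one-to-one A gene appears in exactly one pair, ditto B).
    """

    pairs: list[tuple[str, str, bool]]

    def __post_init__(self) -> None:
        a_count: dict[str, int] = {}
        b_count: dict[str, int] = {}
        for a, b, _ in self.pairs:
            a_count[a] = a_count.get(a, 0) + 1
            b_count[b] = b_count.get(b, 0) + 1
        self.one_to_one: dict[str, str] = {}
        for a, b, flag in self.pairs:
            if flag:
                if a_count[a] != 1 or b_count[b] != 1:
                    raise ValidationError(
                        f"pair ({a}, {b}) flagged one-to-one but one endpoint "
                        "occurs in multiple pairs"
                    )
                self.one_to_one[a] = b

    def ortholog(self, gene_a: str) -> str | None:
        """One-to-one B-species ortholog of an A-species gene, if any."""
        return self.one_to_one.get(gene_a)


@dataclass
class AntiCoexNetwork:
    """Undirected anti-coexpression network at probeset or gene level.

    The node set derives from the edge set: a node with no edge is not in
    the network.  ``species_scope`` is a species label or "conserved".
    """

    graph: nx.Graph
    level: str  # "probeset" | "gene"
    species_scope: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in ("probeset", "gene"):
            raise ValidationError(f"bad network level {self.level!r}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loops not allowed: {loops[:3]}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        level: str,
        species_scope: str,
        provenance: list[str] | None = None,
    ) -> "AntiCoexNetwork":
        g = nx.Graph()
        g.add_edges_from((u, v) for u, v in edges if u != v)
        return cls(g, level, species_scope, list(provenance or []))

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CAGC:
    """A centre gene and its neighbour set in the merged conserved network."""

    centre: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if self.centre in self.members:
            raise ValidationError(
                f"centre {self.centre!r} may not be a member of its own cluster"
            )

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets (GO-like annotation or phenotype-gene associations)."""

    sets: dict[str, frozenset[str]]
    kind: str  # "annotation" | "phenotype_association"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {sid!r} is empty")
            self.sets[sid] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, sid: str) -> frozenset[str]:
        return self.sets[sid]

    def items(self):
        return self.sets.items()

    def sets_containing(self, gene: str) -> set[str]:
        return {sid for sid, genes in self.sets.items() if gene in genes}


@dataclass
class PhenotypeSimilarity:
    """Square symmetric table of phenotype-phenotype similarity in [0, 1]."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.scores
        if list(s.index) != list(s.columns):
            raise ValidationError("similarity matrix index and columns differ")
        vals = s.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("similarity matrix contains missing values")
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("similarity scores must lie in [0, 1]")
        if not np.allclose(vals, vals.T):
            raise ValidationError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(vals), 1.0):
            raise ValidationError("similarity matrix diagonal must be 1")
        self.scores = s.astype(float)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.scores.index)

    def __contains__(self, pheno: str) -> bool:
        return pheno in self.scores.index

    def similar_to(self, pheno: str, threshold: float) -> set[str]:
        """Phenotypes P' with s(pheno, P') >= threshold (closed bound)."""
        row = self.scores.loc[pheno]
        return set(row.index[row.to_numpy() >= threshold])

    def score(self, p1: str, p2: str) -> float:
        return float(self.scores.at[p1, p2])


@dataclass
class DrugTargetTable:
    """(drug, target gene, action) triples; (drug, target) pairs unique."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        _check_unique([(d, t) for d, t, _ in self.rows], "(drug, target) pairs")

    @property
    def drugs(self) -> set[str]:
        return {d for d, _, _ in self.rows}

    @property
    def targets(self) -> set[str]:
        return {t for _, t, _ in self.rows}

    def targets_of(self, drug: str) -> set[str]:
        return {t for d, t, _ in self.rows if d == drug}

    def drugs_targeting(self, gene: str) -> set[str]:
        return {d for d, t, _ in self.rows if t == gene}

    def action(self, drug: str, target: str) -> str | None:
        for d, t, a in self.rows:
            if d == drug and t == target:
                return a
        return None


@dataclass
class PerturbationRankMatrix:
    """Probesets x instances rank matrix for drug-treatment experiments.

    Within each instance the probeset ranks are a permutation of 1..N;
    higher rank means higher case-vs-control fold change.  ``instances``
    maps instance ID -> metadata (at least a ``drug`` key).
    """

    ranks: pd.DataFrame
    instances: dict[str, Mapping[str, str]]

    def __post_init__(self) -> None:
        _check_unique(self.ranks.index, "probeset IDs")
        _check_unique(self.ranks.columns, "instance IDs")
        missing = set(self.ranks.columns) - set(self.instances)
        if missing:
            raise ValidationError(f"instances without metadata: {sorted(missing)[:5]}")
        n = self.ranks.shape[0]
        expect = np.arange(1, n + 1)
        vals = self.ranks.to_numpy()
        for j, inst in enumerate(self.ranks.columns):
            col = np.sort(vals[:, j])
            if not np.array_equal(col, expect):
                raise ValidationError(
                    f"instance {inst!r}: ranks are not a permutation of 1..{n}"
                )
        self.ranks = self.ranks.astype(int)

    @property
    def probesets(self) -> list[str]:
        return list(self.ranks.index)

    def instance_ranks(self, instance: str) -> pd.Series:
        if instance not in self.ranks.columns:
            raise KeyError(f"unknown perturbation instance {instance!r}")
        return self.ranks[instance]

    def instances_of_drug(self, drug: str) -> list[str]:
        return [i for i in self.ranks.columns if self.instances[i].get("drug") == drug]
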