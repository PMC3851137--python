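"""Anti-coexpression network construction and conserved-cluster extraction.

The method: for every probeset pair compute the Pearson correlation; draw a
directed edge p1 -> p2 when p1 is among the most anti-correlated fraction
(default 1%) of probesets for p2; keep only reciprocal edges (undirected
single-species anti-coexpression network, SAN); collapse probesets to genes;
intersect two species' gene networks through one-to-one orthology into a
conserved network (CAGN); merge any number of conserved networks by edge
union; and read off, for each gene, its conserved anti-coexpressed gene
cluster (CAGC) = its neighbour set in the merged network.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    CAGC,
    AntiCoexNetwork,
    ExpressionMatrix,
    OrthologyMap,
    ProbesetGeneMap,
    ValidationError,
)

__all__ = [
    "correlation_matrix",
    "directed_anticorr_edges",
    "reciprocal_undirected",
    "collapse_to_genes",
    "build_san",
    "build_conserved_network",
    "merge_networks",
    "extract_cagc",
    "extract_all_cagcs",
]


def correlation_matrix(
    expr: ExpressionMatrix, min_overlap: int = 4
) -> pd.DataFrame:
    """Pearson correlation of every probeset profile with every other.

    Zero-variance probesets are excluded before computing.  With missing
    values, correlations use pairwise-complete samples; pairs with fewer
    than ``min_overlap`` complete sample pairs are recorded as NaN and are
    ineligible for edges downstream.  Diagonal is set to exactly 1.
    """
    expr.check_usable()
    flagged = set(expr.zero_variance_probesets())
    values = expr.values.loc[[p for p in expr.probesets if p not in flagged]]
    if values.shape[0] < 2:
        raise ValidationError(
            f"dataset {expr.dataset_id!r}: fewer than two non-constant probesets"
        )
    mat = values.to_numpy(dtype=float)
    if not np.isnan(mat).any():
        # complete data: one BLAS call
        corr = np.corrcoef(mat)
    else:
        corr = (
            values.T.corr(method="pearson", min_periods=min_overlap).to_numpy()
        )
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def anticorr_fraction_k(n_probesets: int, fraction: float) -> int:
    """Edges admitted per column: k = max(1, floor(fraction * (N - 1)))."""
    return max(1, math.floor(fraction * (n_probesets - 1)))


def directed_anticorr_edges(
    corr: pd.DataFrame, fraction: float = 0.01
) -> set[tuple[str, str]]:
    """Ordered edges (p1 -> p2): p1 among the k most anti-correlated with p2.

    Only strictly negative, defined correlations are eligible.  Ties at the
    k-th most-negative value break lexicographically by probeset ID, so a
    given matrix always yields the same edge set.
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    ids = np.asarray(corr.index, dtype=object)
    n = len(ids)
    k = anticorr_fraction_k(n, fraction)
    vals = corr.to_numpy(dtype=float)
    # lexicographic tie-break: rank of each ID in sorted ID order
    id_rank = np.empty(n, dtype=np.int64)
    id_rank[np.argsort(ids, kind="stable")] = np.arange(n)
    edges: set[tuple[str, str]] = set()
    rows = np.arange(n)
    for j in range(n):
        col = vals[:, j]
        eligible = rows[(rows != j) & np.isfinite(col) & (col < 0.0)]
        if eligible.size == 0:
            continue
        order = eligible[np.lexsort((id_rank[eligible], col[eligible]))]
        for i in order[:k]:
            edges.add((ids[i], ids[j]))
    return edges


def reciprocal_undirected(
    directed: set[tuple[str, str]],
    species_scope: str = "unknown",
    provenance: Iterable[str] = (),
) -> AntiCoexNetwork:
    """Keep {p1, p2} only when both p1->p2 and p2->p1 are present."""
    undirected = {(a, b) for a, b in directed if (b, a) in directed and a < b}
    return AntiCoexNetwork.from_edges(
        undirected, level="probeset", species_scope=species_scope,
        provenance=list(provenance),
    )


def collapse_to_genes(net: AntiCoexNetwork, psmap: ProbesetGeneMap) -> AntiCoexNetwork:
    """Gene edge {G1, G2} when at least one probeset edge spans their probesets.

    Probeset edges internal to a single gene's probesets are dropped
    (no self-loops); probesets that map to no gene contribute nothing.
    """
    if net.level != "probeset":
        raise ValidationError("collapse_to_genes expects a probeset-level network")
    gene_edges: set[tuple[str, str]] = set()
    for p1, p2 in net.graph.edges:
        for g1 in psmap.genes_of(p1):
            for g2 in psmap.genes_of(p2):
                if g1 != g2:
                    gene_edges.add((g1, g2) if g1 < g2 else (g2, g1))
    return AntiCoexNetwork.from_edges(
        gene_edges, level="gene", species_scope=net.species_scope,
        provenance=net.provenance,
    )


def build_san(
    expr: ExpressionMatrix,
    psmap: ProbesetGeneMap,
    fraction: float = 0.01,
    min_overlap: int = 4,
) -> AntiCoexNetwork:
    """Full single-species pipeline: correlate -> rank -> reciprocate -> collapse."""
    corr = correlation_matrix(expr, min_overlap=min_overlap)
    directed = directed_anticorr_edges(corr, fraction=fraction)
    probeset_net = reciprocal_undirected(
        directed, species_scope=expr.species, provenance=[expr.dataset_id]
    )
    return collapse_to_genes(probeset_net, psmap)


def build_conserved_network(
    net_a: AntiCoexNetwork,
    net_b: AntiCoexNetwork,
    orth: OrthologyMap,
) -> AntiCoexNetwork:
    """Conserved network in species-A gene IDs.

    An A-species edge {G1, G2} survives iff (1) it is in ``net_a``, (2) both
    genes have a one-to-one ortholog, and (3) the orthologs are connected
    in ``net_b``.
    """
    if net_a.level != "gene" or net_b.level != "gene":
        raise ValidationError("conservation requires gene-level networks")
    kept: set[tuple[str, str]] = set()
    b_graph = net_b.graph
    for g1, g2 in net_a.graph.edges:
        m1 = orth.ortholog(g1)
        m2 = orth.ortholog(g2)
        if m1 is None or m2 is None:
            continue
        if b_graph.has_edge(m1, m2):
            kept.add((g1, g2) if g1 < g2 else (g2, g1))
    return AntiCoexNetwork.from_edges(
        kept, level="gene", species_scope="conserved",
        provenance=net_a.provenance + net_b.provenance,
    )


def merge_networks(nets: Sequence[AntiCoexNetwork]) -> AntiCoexNetwork:
    """Union of node and edge sets; provenance concatenated, deduplicated."""
    if not nets:
        raise ValidationError("merge_networks needs at least one network")
    levels = {n.level for n in nets}
    if levels != {"gene"}:
        raise ValidationError(f"can only merge gene-level networks, got {levels}")
    scopes = {n.species_scope for n in nets}
    if len(scopes) > 1:
        raise ValidationError(
            f"refusing to merge networks from mixed ID spaces: {sorted(scopes)}"
        )
    edges: set[tuple[str, str]] = set()
    provenance: list[str] = []
    for n in nets:
        for u, v in n.graph.edges:
            edges.add((u, v) if u < v else (v, u))
        for p in n.provenance:
            if p not in provenance:
                provenance.append(p)
    return AntiCoexNetwork.from_edges(
        edges, level="gene", species_scope=scopes.pop(), provenance=provenance
    )


def extract_cagc(net: AntiCoexNetwork, gene: str) -> CAGC:
    """Cluster of ``gene``: its neighbour set in the merged network.

    The centre itself is not a member.  A gene absent from the network
    (equivalently: with no edges) has no cluster and raises ``KeyError``.
    """
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} is not in the network")
    return CAGC(centre=gene, members=frozenset(net.graph.neighbors(gene)))


def extract_all_cagcs(net: AntiCoexNetwork, genes: Iterable[str] | None = None) -> list[CAGC]:
    """Clusters for every network gene (or a given subset thereof, ignoring
    genes not in the network)."""
    if genes is None:
        pool = sorted(net.graph.nodes)
    else:
        pool = sorted(g for g in set(genes) if g in net.graph)
    return [extract_cagc(net, g) for g in pool]
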