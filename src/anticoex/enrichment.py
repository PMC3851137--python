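"""Functional-coherence validation of clusters.

Each cluster is scored against an annotation collection with one-sided
Fisher exact (hypergeometric upper-tail) tests; its *functional index* is
the p-value of its most significant set.  The distribution of indices over
all clusters of the real network is compared with the distributions from
node-label-permuted networks by a two-sample Kolmogorov-Smirnov test: a
left-shifted real distribution means clusters are functionally coherent
beyond what topology alone explains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .types import CAGC, AntiCoexNetwork, GeneSetCollection, PhenotypeSimilarity, ValidationError

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "FunctionalIndex",
    "functional_index",
    "functional_indices",
    "permuted_network",
    "IndexDistributionReport",
    "index_distribution_test",
    "ConcordanceReport",
    "centre_keyword_concordance",
    "CentreSimilarityResult",
    "centre_phenotype_similarity",
]


@dataclass
class EnrichmentResult:
    centre: str
    set_id: str
    p_value: float
    overlap: int
    cluster_size: int
    set_size: int
    universe_size: int

    def __post_init__(self) -> None:
        if self.overlap > min(self.cluster_size, self.set_size):
            raise ValidationError("overlap exceeds cluster or set size")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


def fisher_enrichment(
    cluster_genes: Iterable[str],
    annot_genes: Iterable[str],
    universe: Iterable[str],
    centre: str = "",
    set_id: str = "",
) -> EnrichmentResult:
    """One-sided over-representation test of a cluster against one gene set.

    The annotation set is intersected with the universe first; the p-value
    is the hypergeometric upper tail P(X >= observed overlap).
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    cluster = set(cluster_genes)
    if not cluster <= uni:
        raise ValidationError("cluster genes must be a subset of the universe")
    annot = set(annot_genes) & uni
    overlap = len(cluster & annot)
    p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(annot), len(cluster)))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return EnrichmentResult(
        centre=centre,
        set_id=set_id,
        p_value=p,
        overlap=overlap,
        cluster_size=len(cluster),
        set_size=len(annot),
        universe_size=len(uni),
    )


@dataclass
class FunctionalIndex:
    """Minimum enrichment p-value of one cluster, with the argmin set ID(s)."""

    centre: str
    value: float
    best_set_ids: list[str] = field(default_factory=list)


def _pvalue_matrix(
    clusters: Sequence[CAGC], sets: GeneSetCollection, uni_sorted: list[str]
) -> tuple[list[str], np.ndarray]:
    """Hypergeometric upper tails for every (cluster, set) pair at once.

    Clusters and sets become boolean membership matrices over the universe,
    so all overlaps come from one integer matrix product.
    """
    pos = {g: i for i, g in enumerate(uni_sorted)}
    n_uni = len(uni_sorted)
    cmat = np.zeros((len(clusters), n_uni), dtype=np.uint8)
    for i, c in enumerate(clusters):
        for g in c.members:
            j = pos.get(g)
            if j is not None:
                cmat[i, j] = 1
    ids = list(sets.sets)
    smat = np.zeros((len(ids), n_uni), dtype=np.uint8)
    for i, sid in enumerate(ids):
        for g in sets.sets[sid]:
            j = pos.get(g)
            if j is not None:
                smat[i, j] = 1
    overlap = cmat.astype(np.int64) @ smat.T.astype(np.int64)
    set_sizes = smat.sum(axis=1).astype(np.int64)
    cluster_sizes = cmat.sum(axis=1).astype(np.int64)
    p = stats.hypergeom.sf(
        overlap - 1, n_uni, set_sizes[None, :], cluster_sizes[:, None]
    )
    return ids, np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def functional_index(
    cluster: CAGC, sets: GeneSetCollection, universe: Iterable[str]
) -> FunctionalIndex:
    """Index = min over all sets of the one-sided enrichment p-value."""
    return functional_indices([cluster], sets, universe)[0]


def functional_indices(
    clusters: Sequence[CAGC], sets: GeneSetCollection, universe: Iterable[str]
) -> list[FunctionalIndex]:
    if len(sets) == 0:
        raise ValidationError("empty gene-set collection")
    uni_sorted = sorted(set(universe))
    if not uni_sorted:
        raise ValidationError("empty universe")
    ids, p = _pvalue_matrix(clusters, sets, uni_sorted)
    uni = set(uni_sorted)
    if all(len(sets.sets[s] & uni) == 0 for s in ids):
        warnings.warn("no annotation set overlaps the universe; index = 1")
        return [FunctionalIndex(c.centre, 1.0, []) for c in clusters]
    out = []
    for i, c in enumerate(clusters):
        best = float(p[i].min())
        argmin = [ids[j] for j in np.flatnonzero(p[i] == best)]
        out.append(FunctionalIndex(c.centre, best, argmin))
    return out


def permuted_network(net: AntiCoexNetwork, seed: int) -> AntiCoexNetwork:
    """Same topology with node (gene) labels permuted uniformly at random.

    Degree sequence and edge count are preserved by construction.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(net.graph.nodes)
    perm = rng.permutation(len(nodes))
    mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
    g = nx.relabel_nodes(net.graph, mapping, copy=True)
    return AntiCoexNetwork(
        g, level=net.level, species_scope=net.species_scope,
        provenance=net.provenance + [f"label-permuted(seed={seed})"],
    )


@dataclass
class IndexDistributionReport:
    ks_statistic: float
    p_value: float
    n_real: int
    n_permuted_total: int
    replicate_means: list[float]
    band_mean: float
    band_std: float


def index_distribution_test(
    real_indices: Sequence[float],
    permuted_indices: Sequence[Sequence[float]],
) -> IndexDistributionReport:
    """Two-sample KS of real indices vs all permutation-replicate indices pooled,
    plus the per-replicate mean and its spread (the grey-band summary)."""
    real = np.asarray(real_indices, dtype=float)
    if real.size == 0 or len(permuted_indices) == 0:
        raise ValidationError("need non-empty real and permuted index lists")
    reps = [np.asarray(r, dtype=float) for r in permuted_indices]
    if any(r.size == 0 for r in reps):
        raise ValidationError("empty permutation replicate")
    pooled = np.concatenate(reps)
    ks = stats.ks_2samp(real, pooled, alternative="two-sided", method="auto")
    rep_means = [float(r.mean()) for r in reps]
    return IndexDistributionReport(
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        n_real=int(real.size),
        n_permuted_total=int(pooled.size),
        replicate_means=rep_means,
        band_mean=float(np.mean(rep_means)),
        band_std=float(np.std(rep_means)),
    )


@dataclass
class ConcordanceReport:
    """Centre-keyword concordance among clusters with a significant set."""

    fraction: float | None
    n_clusters_significant: int
    n_concordant: int
    applicable: bool


def centre_keyword_concordance(
    results: Sequence[EnrichmentResult],
    annot: GeneSetCollection,
    alpha: float = 0.05,
) -> ConcordanceReport:
    """Among clusters with >=1 Bonferroni-significant set, the fraction whose
    centre gene is itself annotated to a significant set.

    Bonferroni divisor = number of sets tested for that cluster.
    """
    by_centre: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_centre.setdefault(r.centre, []).append(r)
    n_sig = 0
    n_conc = 0
    for centre, rows in by_centre.items():
        cutoff = alpha / len(rows)
        significant = [r.set_id for r in rows if r.p_value <= cutoff]
        if not significant:
            continue
        n_sig += 1
        if any(centre in annot.sets[s] for s in significant if s in annot.sets):
            n_conc += 1
    if n_sig == 0:
        return ConcordanceReport(None, 0, 0, applicable=False)
    return ConcordanceReport(n_conc / n_sig, n_sig, n_conc, applicable=True)


@dataclass
class CentreSimilarityResult:
    max_score: float | None
    reached_threshold: bool | None
    applicable: bool
    threshold: float = 0.4


def centre_phenotype_similarity(
    centre_phenos: Iterable[str],
    member_phenos: Iterable[str],
    sim: PhenotypeSimilarity,
    threshold: float = 0.4,
) -> CentreSimilarityResult:
    """Max similarity between any centre phenotype and any member phenotype.

    Reaching the threshold means s >= threshold (closed bound).  A centre
    with no phenotype is reported as not applicable.
    """
    cp = list(centre_phenos)
    mp = list(member_phenos)
    if not cp:
        return CentreSimilarityResult(None, None, applicable=False, threshold=threshold)
    if not mp:
        return CentreSimilarityResult(None, None, applicable=False, threshold=threshold)
    for p in cp + mp:
        if p not in sim:
            raise ValidationError(f"phenotype {p!r} missing from similarity matrix")
    best = max(sim.score(a, b) for a in cp for b in mp)
    return CentreSimilarityResult(
        best, best >= threshold, applicable=True, threshold=threshold
    )
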