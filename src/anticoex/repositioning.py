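"""Drug-target to disease-phenotype association through cluster overlap.

A *pheno-cluster* of phenotype P is the set of genes associated to P or to
any phenotype whose similarity to P is at least a threshold (default 0.4,
the value below which text-mining similarity stops being biologically
meaningful).  Each drug-target-centred cluster is tested against each
pheno-cluster with a one-sided Fisher exact test; overlaps with
p < 1e-4 become candidate drug-disease associations, with Benjamini-
Hochberg q-values reported over the whole test family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import fisher_enrichment
from .types import (
    CAGC,
    DrugTargetTable,
    GeneSetCollection,
    PhenotypeSimilarity,
    ValidationError,
)

__all__ = [
    "PhenoCluster",
    "build_phenoclusters",
    "DrugDiseaseAssociation",
    "associate",
    "rank_report",
]


@dataclass
class PhenoCluster:
    phenotype: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError(f"pheno-cluster {self.phenotype!r} has no genes")


def build_phenoclusters(
    sim: PhenotypeSimilarity,
    pheno_genes: GeneSetCollection,
    threshold: float = 0.4,
) -> list[PhenoCluster]:
    """One cluster per phenotype with associated genes.

    Inclusion uses the closed bound s >= threshold; since s(P, P) = 1 the
    phenotype's own genes are always included.  A phenotype absent from the
    similarity matrix is treated as similar only to itself (with a warning).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"similarity threshold must be in [0, 1], got {threshold}")
    clusters: list[PhenoCluster] = []
    for pheno, own_genes in pheno_genes.items():
        if pheno in sim:
            similar = sim.similar_to(pheno, threshold)
        else:
            warnings.warn(
                f"phenotype {pheno!r} missing from similarity matrix; "
                "treated as similar only to itself"
            )
            similar = {pheno}
        genes: set[str] = set(own_genes)
        for other in similar:
            if other in pheno_genes.sets:
                genes |= pheno_genes.sets[other]
        clusters.append(PhenoCluster(pheno, frozenset(genes)))
    return clusters


@dataclass
class DrugDiseaseAssociation:
    drug: str
    target: str
    phenotype: str
    p_value: float
    q_value: float
    overlap_genes: frozenset[str]
    action: str = "unknown"


def associate(
    clusters: Sequence[CAGC],
    phenos: Sequence[PhenoCluster],
    drugs: DrugTargetTable,
    universe: Iterable[str],
    p_threshold: float = 1e-4,
) -> list[DrugDiseaseAssociation]:
    """Candidate drug-disease associations from cluster x pheno-cluster overlap.

    Only clusters centred on a declared drug target are tested.  The primary
    filter is the p-value cut; BH q-values over the full test family are
    reported alongside.  One association row is emitted per drug hitting a
    passing target.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    if not drugs.rows:
        warnings.warn("empty drug-target table; no associations possible")
        return []
    targets = drugs.targets
    tested: list[tuple[CAGC, PhenoCluster, float, frozenset[str]]] = []
    for cluster in clusters:
        if cluster.centre not in targets:
            continue
        cluster_uni = set(cluster.members) & uni
        for pc in phenos:
            res = fisher_enrichment(
                cluster_uni, pc.genes, uni,
                centre=cluster.centre, set_id=pc.phenotype,
            )
            overlap = frozenset(cluster_uni & pc.genes & uni)
            tested.append((cluster, pc, res.p_value, overlap))
    if not tested:
        return []
    pvals = [t[2] for t in tested]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out: list[DrugDiseaseAssociation] = []
    for (cluster, pc, p, overlap), q in zip(tested, qvals):
        if p >= p_threshold:
            continue
        for drug in sorted(drugs.drugs_targeting(cluster.centre)):
            out.append(
                DrugDiseaseAssociation(
                    drug=drug,
                    target=cluster.centre,
                    phenotype=pc.phenotype,
                    p_value=float(p),
                    q_value=float(q),
                    overlap_genes=overlap,
                    action=drugs.action(drug, cluster.centre) or "unknown",
                )
            )
    out.sort(key=lambda a: (a.target, a.p_value, a.phenotype, a.drug))
    return out


def rank_report(
    assocs: Sequence[DrugDiseaseAssociation],
    phenotype_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-target table of associated phenotypes, ascending by p-value."""
    names = phenotype_names or {}
    rows = [
        {
            "target": a.target,
            "drug": a.drug,
            "phenotype": a.phenotype,
            "phenotype_name": names.get(a.phenotype, ""),
            "p_value": a.p_value,
            "q_value": a.q_value,
            "overlap_genes": ",".join(sorted(a.overlap_genes)),
        }
        for a in assocs
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "target", "drug", "phenotype", "phenotype_name",
            "p_value", "q_value", "overlap_genes",
        ],
    )
    if not df.empty:
        df = df.sort_values(["target", "p_value", "phenotype", "drug"]).reset_index(drop=True)
    return df
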