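"""Direction-of-effect validation against drug-perturbation rank matrices.

Each perturbation instance ranks all probesets by case-vs-control fold
change (1 = most down, N = most up).  Probeset ranks collapse to gene ranks
by taking each gene's maximum-ranked probeset.  For every cluster whose
centre is a target of the instance's drug, cluster-gene ranks are compared
with all other gene ranks by a two-sided Mann-Whitney U test; the direction
call (up/down) compares the cluster median rank with the background median.
If inhibiting the centre releases its anti-correlated cluster, significant
instances should be overwhelmingly "up".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    CAGC,
    DrugTargetTable,
    PerturbationRankMatrix,
    ProbesetGeneMap,
    ValidationError,
)

__all__ = [
    "gene_rank",
    "InstanceTestResult",
    "test_cluster_shift",
    "run_validation",
    "ValidationSummary",
]

# below this group size the Mann-Whitney null is enumerated exactly;
# above it the normal approximation with tie correction is used
EXACT_ENUMERATION_MAX = 8


def gene_rank(
    ranks: PerturbationRankMatrix,
    psmap: ProbesetGeneMap,
    instance: str,
) -> pd.Series:
    """Per-gene rank for one instance: the maximum rank among its probesets.

    Probesets mapping to no gene are dropped, so some ranks are lost and
    the gene-rank distribution is skewed upward relative to probeset ranks.
    """
    col = ranks.instance_ranks(instance)
    rows = [(g, r) for ps, r in col.items() for g in psmap.genes_of(ps)]
    if not rows:
        return pd.Series(dtype=int)
    df = pd.DataFrame(rows, columns=["gene", "rank"])
    return df.groupby("gene")["rank"].max().astype(int)


@dataclass
class InstanceTestResult:
    instance: str
    drug: str
    target: str
    u_statistic: float
    p_value: float
    q_value: float | None
    cluster_median: float
    background_median: float
    direction: str  # "up" | "down" | "tie"
    n_cluster: int
    n_background: int
    testable: bool = True


def _mannwhitney_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    method = "exact" if min(x.size, y.size) <= EXACT_ENUMERATION_MAX else "asymptotic"
    if method == "exact" and (np.unique(np.concatenate([x, y])).size < x.size + y.size):
        method = "asymptotic"  # exact null assumes no ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def test_cluster_shift(
    gene_ranks: Mapping[str, int] | pd.Series,
    cluster: CAGC,
    instance: str = "",
    drug: str = "",
) -> InstanceTestResult:
    """Two-sided Mann-Whitney of cluster-gene ranks vs all other gene ranks.

    The centre gene is excluded from both groups so its own perturbation
    response cannot drive the call.
    """
    gr = pd.Series(gene_ranks, dtype=float)
    gr = gr.drop(cluster.centre, errors="ignore")
    in_cluster = gr.index.isin(cluster.members)
    x = gr[in_cluster].to_numpy()
    y = gr[~in_cluster].to_numpy()
    if x.size == 0 or y.size == 0:
        return InstanceTestResult(
            instance=instance, drug=drug, target=cluster.centre,
            u_statistic=float("nan"), p_value=1.0, q_value=None,
            cluster_median=float("nan"), background_median=float("nan"),
            direction="tie", n_cluster=int(x.size), n_background=int(y.size),
            testable=False,
        )
    u, p = _mannwhitney_two_sided(x, y)
    med_x = float(np.median(x))
    med_y = float(np.median(y))
    if med_x > med_y:
        direction = "up"
    elif med_x < med_y:
        direction = "down"
    else:
        direction = "tie"
    return InstanceTestResult(
        instance=instance, drug=drug, target=cluster.centre,
        u_statistic=u, p_value=p, q_value=None,
        cluster_median=med_x, background_median=med_y,
        direction=direction, n_cluster=int(x.size), n_background=int(y.size),
    )


@dataclass
class ValidationSummary:
    n_tests: int
    n_significant: int
    n_up: int
    n_down: int
    n_tie: int
    fdr: float


def run_validation(
    ranks: PerturbationRankMatrix,
    psmap: ProbesetGeneMap,
    clusters: Sequence[CAGC],
    drugs: DrugTargetTable,
    fdr: float = 0.05,
) -> tuple[list[InstanceTestResult], ValidationSummary]:
    """One test per (target-centred cluster x instance of a drug hitting it).

    For a drug with N target-centred clusters and M instances this yields
    N x M tests.  BH correction runs over all tests in the run; the summary
    tallies significant calls by direction.
    """
    by_centre = {c.centre: c for c in clusters}
    pairs: list[tuple[str, str, CAGC]] = []  # (instance, drug, cluster)
    for drug in sorted(drugs.drugs):
        instances = ranks.instances_of_drug(drug)
        targets = sorted(drugs.targets_of(drug))
        for target in targets:
            cluster = by_centre.get(target)
            if cluster is None:
                continue
            for inst in instances:
                pairs.append((inst, drug, cluster))
    if not pairs:
        warnings.warn("no drug links any perturbation instance to a cluster centre")
        return [], ValidationSummary(0, 0, 0, 0, 0, fdr)
    # gene ranks are instance-specific; compute once per instance
    rank_cache: dict[str, pd.Series] = {}
    results: list[InstanceTestResult] = []
    for inst, drug, cluster in pairs:
        if inst not in rank_cache:
            rank_cache[inst] = gene_rank(ranks, psmap, inst)
        results.append(test_cluster_shift(rank_cache[inst], cluster, instance=inst, drug=drug))
    testable = [r for r in results if r.testable]
    if testable:
        _, qvals, _, _ = multipletests([r.p_value for r in testable], method="fdr_bh")
        for r, q in zip(testable, qvals):
            r.q_value = float(q)
    sig = [r for r in testable if r.q_value is not None and r.q_value < fdr]
    summary = ValidationSummary(
        n_tests=len(results),
        n_significant=len(sig),
        n_up=sum(r.direction == "up" for r in sig),
        n_down=sum(r.direction == "down" for r in sig),
        n_tie=sum(r.direction == "tie" for r in sig),
        fdr=fdr,
    )
    return results, summary


def results_table(results: Sequence[InstanceTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "instance": r.instance,
                "drug": r.drug,
                "target": r.target,
                "U": r.u_statistic,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "cluster_median": r.cluster_median,
                "background_median": r.background_median,
                "direction": r.direction,
                "n_cluster": r.n_cluster,
                "n_background": r.n_background,
            }
            for r in results
        ],
        columns=[
            "instance", "drug", "target", "U", "p_value", "q_value",
            "cluster_median", "background_median", "direction",
            "n_cluster", "n_background",
        ],
    )
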