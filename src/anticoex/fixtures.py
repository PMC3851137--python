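"""Seeded synthetic inputs with the statistical structure the method assumes.

The generator emulates the shape of the real study inputs — two-species
expression compendia on a microarray-like platform, one-to-one orthology,
phenotype-gene associations with a text-mining-style similarity matrix,
drug-target annotations and drug-perturbation rank matrices — with planted
ground truth: anti-correlated conserved modules around centre genes,
phenotype families aligned with modules, and drug instances that upregulate
their target's module.  Every generator is bit-reproducible under a fixed
seed, and the truth record suffices to score every downstream stage.

The expression model is latent-factor: each module has one latent profile z
per (dataset pair, species); the centre gene follows +z, each member gene
follows rho * z (rho < 0), and every probeset adds independent Gaussian
probe noise sigma.  Background genes follow their own latent profile.
Several dataset pairs share one platform (probeset-gene maps, orthology),
mirroring a compendium of tissue-specific datasets merged into a single
conserved network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AntiCoexNetwork,
    DrugTargetTable,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologyMap,
    PerturbationRankMatrix,
    PhenotypeSimilarity,
    ProbesetGeneMap,
    ValidationError,
)

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "make_expression_pair",
    "make_pheno_world",
    "make_annotation_sets",
    "make_perturbation_matrix",
    "make_bundle",
    "make_enrichment_world",
    "write_fixture_bundle",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic world.

    Defaults emulate the real study conditions at desk scale: a Plus-2-like
    platform (~2.7 probesets per gene, ~10% of probesets unmapped), 40
    samples per dataset, six tissue-like dataset pairs merged into one
    conserved network, three planted modules of ten genes anti-correlated
    (rho = -1) with their centres under probe noise sigma = 0.2, phenotype
    families aligned with modules, and perturbation instances planting
    module probesets in the top rank decile.
    """

    seed: int = 0
    n_genes: int = 300
    mean_extra_probesets: float = 1.7  # probesets per gene = 1 + Poisson(this)
    unmapped_fraction: float = 0.1
    n_samples_per_species: int = 40
    n_dataset_pairs: int = 6
    n_modules: int = 3
    module_size: int = 10
    rho: float = -1.0
    noise_sigma: float = 0.2
    one_to_one_fraction: float = 1.0
    pheno_family_size: int = 3
    n_decoy_phenotypes: int = 3
    genes_per_phenotype: tuple[int, int] = (4, 7)
    n_drugs: int = 6  # n_modules planted inhibitors, rest decoys
    instances_per_drug: int = 4
    effect_quantile: float = 0.9

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_samples_per_species, self.n_dataset_pairs,
            self.n_modules, self.module_size, self.pheno_family_size,
            self.n_drugs, self.instances_per_drug,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all fixture counts must be positive")
        if not (-1.0 <= self.rho < 0.0):
            raise ValidationError(f"rho must lie in [-1, 0), got {self.rho}")
        for frac in (self.one_to_one_fraction, self.unmapped_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"fractions must lie in [0, 1], got {frac}")
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be non-negative")
        if self.n_modules * self.module_size >= self.n_genes:
            raise ValidationError(
                f"{self.n_modules} modules x {self.module_size} genes do not fit "
                f"in {self.n_genes} genes with background left over"
            )
        if self.n_drugs < self.n_modules:
            raise ValidationError("need at least one drug per planted module")


@dataclass
class _Platform:
    """Shared across dataset pairs: gene IDs, probe maps, orthology, modules."""

    genes_a: list[str]
    genes_b: list[str]
    probesets_a: dict[str, list[str]]  # gene -> probesets
    probesets_b: dict[str, list[str]]
    unmapped_a: list[str]
    unmapped_b: list[str]
    orthology: OrthologyMap
    modules: list[dict[str, Any]]  # centre_a/centre_b/members_a/members_b
    background_a: list[str]

    def psmap_a(self) -> ProbesetGeneMap:
        return ProbesetGeneMap({(p, g) for g, ps in self.probesets_a.items() for p in ps})

    def psmap_b(self) -> ProbesetGeneMap:
        return ProbesetGeneMap({(p, g) for g, ps in self.probesets_b.items() for p in ps})

    def all_probesets_a(self) -> list[str]:
        return [p for g in self.genes_a for p in self.probesets_a[g]] + self.unmapped_a


def _build_platform(spec: FixtureSpec) -> _Platform:
    rng = np.random.default_rng([spec.seed, 0])
    genes_a = [f"HG{i:04d}" for i in range(spec.n_genes)]
    genes_b = [f"MG{i:04d}" for i in range(spec.n_genes)]

    def probe_names(prefix: str, genes: list[str]) -> dict[str, list[str]]:
        out = {}
        for g in genes:
            n_ps = 1 + int(rng.poisson(spec.mean_extra_probesets))
            out[g] = [f"{prefix}_{g[2:]}_{j}_at" for j in range(n_ps)]
        return out

    ps_a = probe_names("A", genes_a)
    ps_b = probe_names("B", genes_b)
    n_mapped_a = sum(len(v) for v in ps_a.values())
    n_mapped_b = sum(len(v) for v in ps_b.values())
    n_unm_a = int(round(spec.unmapped_fraction * n_mapped_a))
    n_unm_b = int(round(spec.unmapped_fraction * n_mapped_b))
    unmapped_a = [f"A_unm{i:04d}_at" for i in range(n_unm_a)]
    unmapped_b = [f"B_unm{i:04d}_at" for i in range(n_unm_b)]

    flags = rng.random(spec.n_genes) < spec.one_to_one_fraction
    orth = OrthologyMap(
        [(genes_a[i], genes_b[i], bool(flags[i])) for i in range(spec.n_genes)]
    )

    perm = rng.permutation(spec.n_genes)
    modules = []
    used: set[int] = set()
    pos = 0
    for m in range(spec.n_modules):
        centre_idx = int(perm[pos]); pos += 1
        member_idx = [int(perm[pos + j]) for j in range(spec.module_size)]
        pos += spec.module_size
        used.add(centre_idx)
        used.update(member_idx)
        modules.append(
            {
                "centre_a": genes_a[centre_idx],
                "centre_b": genes_b[centre_idx],
                "members_a": [genes_a[i] for i in member_idx],
                "members_b": [genes_b[i] for i in member_idx],
            }
        )
    background_a = [genes_a[i] for i in range(spec.n_genes) if i not in used]
    return _Platform(
        genes_a, genes_b, ps_a, ps_b, unmapped_a, unmapped_b, orth,
        modules, background_a,
    )


def _species_matrix(
    spec: FixtureSpec,
    platform: _Platform,
    species: str,
    pair_index: int,
) -> ExpressionMatrix:
    rng = np.random.default_rng([spec.seed, 10 + pair_index, 0 if species == "human" else 1])
    n = spec.n_samples_per_species
    genes = platform.genes_a if species == "human" else platform.genes_b
    psmap = platform.probesets_a if species == "human" else platform.probesets_b
    unmapped = platform.unmapped_a if species == "human" else platform.unmapped_b
    key = "centre_a" if species == "human" else "centre_b"
    mkey = "members_a" if species == "human" else "members_b"

    profile: dict[str, np.ndarray] = {}
    for mod in platform.modules:
        z = rng.standard_normal(n)
        profile[mod[key]] = z
        for g in mod[mkey]:
            profile[g] = spec.rho * z
    rows: list[np.ndarray] = []
    index: list[str] = []
    for g in genes:
        base = profile.get(g)
        if base is None:
            base = rng.standard_normal(n)
        for ps in psmap[g]:
            rows.append(base + spec.noise_sigma * rng.standard_normal(n))
            index.append(ps)
    for ps in unmapped:
        rows.append(rng.standard_normal(n))
        index.append(ps)
    samples = [f"{species[:2]}{pair_index:02d}_s{j:03d}" for j in range(n)]
    values = pd.DataFrame(np.asarray(rows), index=index, columns=samples)
    return ExpressionMatrix(
        dataset_id=f"{species}_pair{pair_index:02d}", species=species, values=values
    )


def make_expression_pair(
    spec: FixtureSpec, pair_index: int = 0, platform: _Platform | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologyMap, ProbesetGeneMap, ProbesetGeneMap, dict]:
    """One two-species dataset pair plus maps, orthology and the truth record."""
    platform = platform or _build_platform(spec)
    expr_a = _species_matrix(spec, platform, "human", pair_index)
    expr_b = _species_matrix(spec, platform, "mouse", pair_index)
    truth = {
        "modules": platform.modules,
        "background_a": platform.background_a,
        "one_to_one_a": sorted(platform.orthology.one_to_one),
    }
    return expr_a, expr_b, platform.orthology, platform.psmap_a(), platform.psmap_b(), truth


def make_pheno_world(
    spec: FixtureSpec, truth: dict
) -> tuple[PhenotypeSimilarity, GeneSetCollection]:
    """Phenotype families aligned with planted modules, plus decoy phenotypes.

    Within-family similarity is drawn in [0.45, 0.85] (>= the 0.4 cut),
    between-family similarity in [0.02, 0.35] (< the cut).  Aligned
    phenotypes draw their genes from the planted module members.
    """
    rng = np.random.default_rng([spec.seed, 2])
    phenos: list[str] = []
    families: dict[str, list[str]] = {}
    sets: dict[str, frozenset[str]] = {}
    lo, hi = spec.genes_per_phenotype
    for m, mod in enumerate(truth["modules"]):
        fam = [f"PH{m}{i:02d}" for i in range(spec.pheno_family_size)]
        families[f"module_{m}"] = fam
        for p in fam:
            size = int(rng.integers(lo, hi + 1))
            size = min(size, len(mod["members_a"]))
            genes = rng.choice(mod["members_a"], size=size, replace=False)
            sets[p] = frozenset(genes.tolist())
        phenos.extend(fam)
    background = truth["background_a"]
    for i in range(spec.n_decoy_phenotypes):
        p = f"PHD{i:02d}"
        size = min(int(rng.integers(lo, hi + 1)), len(background))
        genes = rng.choice(background, size=size, replace=False)
        sets[p] = frozenset(genes.tolist())
        phenos.append(p)
        families[f"decoy_{i}"] = [p]

    n = len(phenos)
    fam_of = {p: fam for fam, members in families.items() for p in members}
    scores = np.empty((n, n))
    for i in range(n):
        scores[i, i] = 1.0
        for j in range(i + 1, n):
            if fam_of[phenos[i]] == fam_of[phenos[j]]:
                s = rng.uniform(0.45, 0.85)
            else:
                s = rng.uniform(0.02, 0.35)
            scores[i, j] = scores[j, i] = s
    sim = PhenotypeSimilarity(pd.DataFrame(scores, index=phenos, columns=phenos))
    coll = GeneSetCollection(sets, kind="phenotype_association")
    truth["phenotype_families"] = families
    truth["aligned_phenotypes"] = {
        f"module_{m}": families[f"module_{m}"] for m in range(spec.n_modules)
    }
    return sim, coll


def make_annotation_sets(spec: FixtureSpec, truth: dict) -> GeneSetCollection:
    """GO-like annotation: per module one set covering module plus centre and
    one centre-free set, plus random background sets."""
    rng = np.random.default_rng([spec.seed, 3])
    background = truth["background_a"]
    sets: dict[str, frozenset[str]] = {}
    for m, mod in enumerate(truth["modules"]):
        extras = rng.choice(background, size=4, replace=False).tolist()
        sets[f"KW{m:02d}_with_centre"] = frozenset(
            mod["members_a"] + [mod["centre_a"]] + extras
        )
        sub = rng.choice(mod["members_a"], size=max(3, spec.module_size // 2), replace=False)
        extras2 = rng.choice(background, size=4, replace=False).tolist()
        sets[f"KW{m:02d}_no_centre"] = frozenset(sub.tolist() + extras2)
    for i in range(12):
        size = int(rng.integers(8, 25))
        sets[f"KWR{i:02d}"] = frozenset(
            rng.choice(background, size=min(size, len(background)), replace=False).tolist()
        )
    return GeneSetCollection(sets, kind="annotation")


def make_perturbation_matrix(
    spec: FixtureSpec, truth: dict
) -> tuple[PerturbationRankMatrix, DrugTargetTable]:
    """Rank matrix with planted drug effects plus a drug-target table.

    Instances of a planted drug redraw the probesets of its module's member
    genes above the effect quantile before rank transformation, so those
    probesets land in the top ranks.  Decoy drugs target background genes
    and their instances carry no signal.
    """
    rng = np.random.default_rng([spec.seed, 4])
    # species-A platform probesets, rebuilt deterministically from the spec
    platform = _build_platform(spec)
    probesets = platform.all_probesets_a()
    ps_index = {p: i for i, p in enumerate(probesets)}
    n = len(probesets)

    drug_rows: list[tuple[str, str, str]] = []
    planted_drugs: dict[str, int] = {}
    for m, mod in enumerate(truth["modules"]):
        d = f"drug_m{m}"
        drug_rows.append((d, mod["centre_a"], "inhibitor"))
        planted_drugs[d] = m
    background = truth["background_a"]
    n_decoys = spec.n_drugs - spec.n_modules
    decoy_targets = rng.choice(background, size=n_decoys, replace=False)
    for i in range(n_decoys):
        drug_rows.append((f"drug_d{i}", str(decoy_targets[i]), "unknown"))
    drugs = DrugTargetTable(drug_rows)

    cells = ["PC3", "MCF7", "HL60"]
    concs = ["1e-05 M", "1e-06 M", "1e-07 M"]
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, dict[str, str]] = {}
    idx = 0
    for d, _, _ in drug_rows:
        for r in range(spec.instances_per_drug):
            inst = f"inst{idx:04d}"
            idx += 1
            vals = rng.uniform(0.0, 1.0, size=n)
            if d in planted_drugs:
                mod = truth["modules"][planted_drugs[d]]
                for g in mod["members_a"]:
                    for ps in platform.probesets_a[g]:
                        vals[ps_index[ps]] = rng.uniform(spec.effect_quantile, 1.0)
            cols[inst] = stats.rankdata(vals, method="ordinal").astype(int)
            meta[inst] = {
                "instance": inst,
                "drug": d,
                "concentration": concs[r % len(concs)],
                "cell_line": cells[r % len(cells)],
                "duration": "6h",
            }
    ranks = pd.DataFrame(cols, index=probesets)
    truth["planted_drugs"] = {d: truth["modules"][m]["centre_a"] for d, m in planted_drugs.items()}
    truth["decoy_drugs"] = sorted(d for d, _, _ in drug_rows if d not in planted_drugs)
    return PerturbationRankMatrix(ranks, meta), drugs


@dataclass
class FixtureBundle:
    """Everything one pipeline run needs, plus the planted ground truth."""

    spec: FixtureSpec
    expression_pairs: list[tuple[ExpressionMatrix, ExpressionMatrix]]
    orthology: OrthologyMap
    psmap_a: ProbesetGeneMap
    psmap_b: ProbesetGeneMap
    similarity: PhenotypeSimilarity
    pheno_genes: GeneSetCollection
    annotation: GeneSetCollection
    rank_matrix: PerturbationRankMatrix
    drug_targets: DrugTargetTable
    truth: dict = field(default_factory=dict)


def make_bundle(spec: FixtureSpec) -> FixtureBundle:
    """Generate the full input bundle for one pipeline run."""
    platform = _build_platform(spec)
    pairs = []
    truth: dict = {
        "modules": platform.modules,
        "background_a": platform.background_a,
        "one_to_one_a": sorted(platform.orthology.one_to_one),
    }
    for d in range(spec.n_dataset_pairs):
        expr_a = _species_matrix(spec, platform, "human", d)
        expr_b = _species_matrix(spec, platform, "mouse", d)
        pairs.append((expr_a, expr_b))
    sim, pheno_genes = make_pheno_world(spec, truth)
    annotation = make_annotation_sets(spec, truth)
    ranks, drugs = make_perturbation_matrix(spec, truth)
    return FixtureBundle(
        spec=spec,
        expression_pairs=pairs,
        orthology=platform.orthology,
        psmap_a=platform.psmap_a(),
        psmap_b=platform.psmap_b(),
        similarity=sim,
        pheno_genes=pheno_genes,
        annotation=annotation,
        rank_matrix=ranks,
        drug_targets=drugs,
        truth=truth,
    )


def make_enrichment_world(
    n_clusters: int = 200,
    degree: int = 8,
    extras_per_set: int = 10,
    seed: int = 0,
    aligned: bool = True,
) -> tuple[AntiCoexNetwork, GeneSetCollection, list[str]]:
    """A regular gene network with one neighbourhood-aligned set per gene.

    A random ``degree``-regular graph over ``n_clusters`` genes: every gene
    is a cluster centre of the same size, matching the fact that label
    permutation preserves the degree sequence.  When ``aligned``, each
    annotation set contains one gene's neighbourhood plus random extras;
    with ``aligned=False`` the sets' gene labels are scrambled by a global
    permutation, destroying the alignment while keeping every set size —
    the matched null for the validation machinery.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    if (n_clusters * degree) % 2:
        raise ValidationError("n_clusters * degree must be even for a regular graph")
    graph = nx.random_regular_graph(degree, n_clusters, seed=int(rng.integers(2**31)))
    genes = [f"G{i:05d}" for i in range(n_clusters)]
    edges = [(genes[u], genes[v]) for u, v in graph.edges]
    net = AntiCoexNetwork.from_edges(edges, level="gene", species_scope="conserved")
    universe = sorted(net.nodes)
    sets: dict[str, frozenset[str]] = {}
    for i, g in enumerate(universe):
        neigh = [genes[v] for v in graph.neighbors(int(g[1:]))]
        extras = rng.choice(universe, size=extras_per_set, replace=False).tolist()
        sets[f"SET{i:04d}"] = frozenset(neigh + extras)
    if not aligned:
        perm = rng.permutation(len(universe))
        relabel = {universe[i]: universe[perm[i]] for i in range(len(universe))}
        sets = {
            sid: frozenset(relabel[g] for g in genes_)
            for sid, genes_ in sets.items()
        }
    return net, GeneSetCollection(sets, kind="annotation"), universe


def write_fixture_bundle(spec: FixtureSpec, outdir: str | Path) -> FixtureBundle:
    """Generate a bundle and write it as the TSV/GMT input files plus truth JSON."""
    from . import io as aio  # local import to avoid cycle

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = make_bundle(spec)
    for i, (ea, eb) in enumerate(bundle.expression_pairs):
        for e in (ea, eb):
            df = e.values.copy()
            df.insert(0, "probeset", df.index)
            aio.write_tsv(df, out / f"expr_{e.dataset_id}.tsv")
    for name, psmap in (("a", bundle.psmap_a), ("b", bundle.psmap_b)):
        rows = sorted(psmap.pairs)
        aio.write_tsv(
            pd.DataFrame(rows, columns=["probeset", "gene"]),
            out / f"probeset_gene_map_{name}.tsv",
        )
    aio.write_tsv(
        pd.DataFrame(
            [(a, b, int(f)) for a, b, f in bundle.orthology.pairs],
            columns=["gene_a", "gene_b", "one_to_one"],
        ),
        out / "orthology.tsv",
    )
    sim = bundle.similarity.scores.copy()
    sim.insert(0, "phenotype", sim.index)
    aio.write_tsv(sim, out / "phenotype_similarity.tsv")
    aio.write_gene_sets(bundle.pheno_genes, out / "phenotype_genes.gmt")
    aio.write_gene_sets(bundle.annotation, out / "annotation.gmt")
    ranks = bundle.rank_matrix.ranks.copy()
    ranks.insert(0, "probeset", ranks.index)
    aio.write_tsv(ranks, out / "perturbation_ranks.tsv")
    meta_cols = ["instance", "drug", "concentration", "cell_line", "duration"]
    aio.write_tsv(
        pd.DataFrame(
            [[m.get(c, "") for c in meta_cols] for m in bundle.rank_matrix.instances.values()],
            columns=meta_cols,
        ),
        out / "perturbation_instances.tsv",
    )
    aio.write_tsv(
        pd.DataFrame(bundle.drug_targets.rows, columns=["drug", "target", "action"]),
        out / "drug_targets.tsv",
    )
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump({"spec": asdict(bundle.spec), "truth": bundle.truth}, fh, indent=1)
    return bundle
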