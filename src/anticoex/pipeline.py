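"""End-to-end pipeline runner with config, logging and provenance.

Stages, in order: build-san -> conserve -> merge -> clusters -> enrich ->
phenoclusters -> associate -> validate-perturbation.  A YAML config names
every input file and threshold; one master seed fans out deterministically
to per-stage seeds.  Every output file carries a header comment with the
tool version, the config hash and the master seed, so two runs with the
same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, enrichment, io as aio, network, perturbation, repositioning
from .types import ValidationError

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]

log = logging.getLogger("anticoex")

STAGES = [
    "build-san",
    "conserve",
    "merge",
    "clusters",
    "enrich",
    "phenoclusters",
    "associate",
    "validate-perturbation",
]


def derive_seed(master: int, *context: int) -> int:
    """Deterministic child seed < 2**31 from a master seed and context ints."""
    ss = np.random.SeedSequence([int(master), *[int(c) for c in context]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    expression_pairs: list[dict[str, str]]  # dataset_id, species_a/b, path_a/b
    psmap_a: str
    psmap_b: str
    orthology: str
    annotation: str
    phenotype_genes: str
    phenotype_similarity: str
    drug_targets: str
    rank_matrix: str
    rank_metadata: str
    fraction: float = 0.01
    min_overlap: int = 4
    min_samples: int = 4
    sim_threshold: float = 0.4
    p_threshold: float = 1e-4
    fdr: float = 0.05
    n_permutations: int = 100
    seed: int = 0
    outdir: str = "anticoex_out"
    config_hash: str = field(default="", repr=False)

    def validate(self) -> None:
        if not (0.0 < self.fraction < 1.0):
            raise ValidationError(f"fraction must be in (0, 1), got {self.fraction}")
        if not (0.0 <= self.sim_threshold <= 1.0):
            raise ValidationError("sim_threshold must be in [0, 1]")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValidationError("p_threshold must be in (0, 1]")
        if not self.expression_pairs:
            raise ValidationError("config names no expression pairs")
        paths = [self.psmap_a, self.psmap_b, self.orthology, self.annotation,
                 self.phenotype_genes, self.phenotype_similarity,
                 self.drug_targets, self.rank_matrix, self.rank_metadata]
        for pair in self.expression_pairs:
            paths.extend([pair["path_a"], pair["path_b"]])
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(raw)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "config_hash"}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.config_hash = hashlib.sha256(raw.encode()).hexdigest()[:16]
        # resolve relative paths against the config file's directory
        base = Path(path).parent
        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)
        for f in ("psmap_a", "psmap_b", "orthology", "annotation",
                  "phenotype_genes", "phenotype_similarity", "drug_targets",
                  "rank_matrix", "rank_metadata"):
            setattr(cfg, f, resolve(getattr(cfg, f)))
        for pair in cfg.expression_pairs:
            pair["path_a"] = resolve(pair["path_a"])
            pair["path_b"] = resolve(pair["path_b"])
        return cfg


def _header(cfg: PipelineConfig, stage: str) -> str:
    return (
        f"anticoex v{__version__}\n"
        f"config_hash={cfg.config_hash or 'none'}\n"
        f"seed={cfg.seed}\n"
        f"stage={stage}"
    )


def _stage_done(out: Path, files: list[Path]) -> bool:
    return all(f.exists() for f in files)


def run_pipeline(
    config: PipelineConfig | str | Path, resume: bool = False
) -> Path:
    """Execute every stage in order; returns the output directory.

    With ``resume=True`` a stage whose outputs already exist is skipped, so
    an interrupted run restarts from the last completed stage.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    cfg = config
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out, resume)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, out: Path, resume: bool) -> Path:
    t_start = time.time()
    log.info("anticoex v%s run start: seed=%d config=%s", __version__, cfg.seed, cfg.config_hash)

    psmap_a = aio.read_probeset_gene_map(cfg.psmap_a)
    psmap_b = aio.read_probeset_gene_map(cfg.psmap_b)
    orth = aio.read_orthology(cfg.orthology)

    # --- build-san + conserve ------------------------------------------------
    san_files: list[tuple[Path, Path]] = []
    conserved_files: list[Path] = []
    for pair in cfg.expression_pairs:
        did = pair["dataset_id"]
        f_a = out / f"san_{did}_a.tsv"
        f_b = out / f"san_{did}_b.tsv"
        f_c = out / f"conserved_{did}.tsv"
        san_files.append((f_a, f_b))
        conserved_files.append(f_c)
        if resume and _stage_done(out, [f_a, f_b, f_c]):
            log.info("skip pair %s (resume)", did)
            continue
        t0 = time.time()
        expr_a, rep_a = aio.read_expression_matrix(
            pair["path_a"], did, pair.get("species_a", "A"), min_samples=cfg.min_samples
        )
        expr_b, rep_b = aio.read_expression_matrix(
            pair["path_b"], did, pair.get("species_b", "B"), min_samples=cfg.min_samples
        )
        for rep, name in ((rep_a, "A"), (rep_b, "B")):
            if rep.flagged:
                log.info("pair %s species %s: %d zero-variance probesets excluded",
                         did, name, len(rep.flagged))
        san_a = network.build_san(expr_a, psmap_a, cfg.fraction, cfg.min_overlap)
        san_b = network.build_san(expr_b, psmap_b, cfg.fraction, cfg.min_overlap)
        conserved = network.build_conserved_network(san_a, san_b, orth)
        aio.write_network(san_a, f_a, header=_header(cfg, "build-san"))
        aio.write_network(san_b, f_b, header=_header(cfg, "build-san"))
        aio.write_network(conserved, f_c, header=_header(cfg, "conserve"))
        log.info("pair %s: SAN %d/%d edges, conserved %d edges (%.1fs)",
                 did, san_a.n_edges(), san_b.n_edges(), conserved.n_edges(),
                 time.time() - t0)

    # --- merge ---------------------------------------------------------------
    f_merged = out / "merged_network.tsv"
    if resume and f_merged.exists():
        merged = aio.read_network(f_merged)
    else:
        merged = network.merge_networks([aio.read_network(f) for f in conserved_files])
        aio.write_network(merged, f_merged, header=_header(cfg, "merge"))
    log.info("merged network: %d genes, %d edges", len(merged.nodes), merged.n_edges())

    # --- clusters ------------------------------------------------------------
    f_clusters = out / "clusters.gmt"
    if resume and f_clusters.exists():
        clusters = aio.read_clusters(f_clusters)
    else:
        clusters = network.extract_all_cagcs(merged)
        aio.write_clusters(clusters, f_clusters, header=_header(cfg, "clusters"))
    log.info("extracted %d clusters", len(clusters))
    universe = sorted(merged.nodes)

    # --- enrich --------------------------------------------------------------
    f_enrich = out / "functional_indices.tsv"
    f_kstest = out / "index_distribution_test.tsv"
    if not (resume and _stage_done(out, [f_enrich, f_kstest])):
        annot, rep = aio.read_gene_sets(cfg.annotation, kind="annotation")
        if rep.dropped:
            log.info("annotation: %d empty sets dropped", len(rep.dropped))
        real = enrichment.functional_indices(clusters, annot, universe)
        perm_indices: list[list[float]] = []
        for i in range(cfg.n_permutations):
            pnet = enrichment.permuted_network(merged, derive_seed(cfg.seed, 1, i))
            pclusters = network.extract_all_cagcs(pnet)
            perm = enrichment.functional_indices(pclusters, annot, universe)
            perm_indices.append([fi.value for fi in perm])
        report = enrichment.index_distribution_test(
            [fi.value for fi in real], perm_indices
        )
        rows = [{"network": "real", "centre": fi.centre, "functional_index": fi.value,
                 "best_sets": ",".join(fi.best_set_ids)} for fi in real]
        aio.write_tsv(pd.DataFrame(rows), f_enrich, header=_header(cfg, "enrich"))
        aio.write_tsv(
            pd.DataFrame([{
                "ks_statistic": report.ks_statistic,
                "p_value": report.p_value,
                "n_real": report.n_real,
                "n_permuted_total": report.n_permuted_total,
                "replicate_band_mean": report.band_mean,
                "replicate_band_std": report.band_std,
            }]),
            f_kstest, header=_header(cfg, "enrich"),
        )
        log.info("enrichment: KS=%.4f p=%.3g over %d real vs %d permuted indices",
                 report.ks_statistic, report.p_value, report.n_real,
                 report.n_permuted_total)

    # --- phenoclusters -------------------------------------------------------
    f_pheno = out / "phenoclusters.gmt"
    sim = aio.read_phenotype_similarity(cfg.phenotype_similarity)
    pheno_genes, _ = aio.read_gene_sets(cfg.phenotype_genes, kind="phenotype_association")
    phenos = repositioning.build_phenoclusters(sim, pheno_genes, cfg.sim_threshold)
    if not (resume and f_pheno.exists()):
        from .types import GeneSetCollection
        coll = GeneSetCollection(
            {pc.phenotype: pc.genes for pc in phenos}, kind="phenotype_association"
        )
        aio.write_gene_sets(coll, f_pheno, header=_header(cfg, "phenoclusters"))
    log.info("built %d pheno-clusters (threshold %.2f)", len(phenos), cfg.sim_threshold)

    # --- associate -----------------------------------------------------------
    f_assoc = out / "associations.tsv"
    drugs = aio.read_drug_targets(cfg.drug_targets)
    if not (resume and f_assoc.exists()):
        assocs = repositioning.associate(
            clusters, phenos, drugs, universe, p_threshold=cfg.p_threshold
        )
        table = repositioning.rank_report(assocs)
        aio.write_tsv(table, f_assoc, header=_header(cfg, "associate"))
        log.info("associate: %d candidate drug-disease associations", len(assocs))

    # --- validate-perturbation -----------------------------------------------
    f_pert = out / "perturbation_results.tsv"
    f_pert_sum = out / "perturbation_summary.tsv"
    if not (resume and _stage_done(out, [f_pert, f_pert_sum])):
        ranks = aio.read_rank_matrix(cfg.rank_matrix, cfg.rank_metadata)
        results, summary = perturbation.run_validation(
            ranks, psmap_a, clusters, drugs, fdr=cfg.fdr
        )
        aio.write_tsv(perturbation.results_table(results), f_pert,
                      header=_header(cfg, "validate-perturbation"))
        aio.write_tsv(
            pd.DataFrame([{
                "n_tests": summary.n_tests,
                "n_significant": summary.n_significant,
                "n_up": summary.n_up,
                "n_down": summary.n_down,
                "n_tie": summary.n_tie,
                "fdr": summary.fdr,
            }]),
            f_pert_sum, header=_header(cfg, "validate-perturbation"),
        )
        log.info("perturbation: %d tests, %d significant (%d up / %d down / %d tie)",
                 summary.n_tests, summary.n_significant, summary.n_up,
                 summary.n_down, summary.n_tie)

    log.info("run complete in %.1fs -> %s", time.time() - t_start, out)
    return out


def write_config(cfg_dict: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=False)
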