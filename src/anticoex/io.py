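"""Readers and writers for the TSV/GMT dialects used by the pipeline.

Dialect: tab-separated, UTF-8, lines starting with '#' are comments and are
ignored on read.  All readers validate domain-type invariants and raise
:class:`~anticoex.types.ValidationError` with the offending location.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    CAGC,
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
    "ReadReport",
    "read_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "write_clusters",
    "read_probeset_gene_map",
    "read_orthology",
    "read_drug_targets",
    "read_phenotype_similarity",
    "read_rank_matrix",
    "write_network",
    "read_network",
    "write_tsv",
]


@dataclass
class ReadReport:
    """Side notes produced while reading a file (nothing fatal)."""

    flagged: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append((lineno, line))
    return out


def read_expression_matrix(
    path: str | Path,
    dataset_id: str,
    species: str,
    min_samples: int = 4,
) -> tuple[ExpressionMatrix, ReadReport]:
    """Read a probesets x samples TSV (header = sample IDs, col 0 = probeset).

    Returns the matrix plus a report listing zero-variance probesets; those
    probesets stay in the matrix but are excluded from correlation.
    """
    lines = _data_lines(path)
    if not lines:
        raise ValidationError(f"{path}: empty expression file")
    header = lines[0][1].split("\t")
    samples = header[1:]
    if not samples:
        raise ValidationError(f"{path}: header has no sample columns")
    probesets: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        probesets.append(fields[0])
        vals = []
        for col, cell in zip(samples, fields[1:]):
            if cell in ("", "NA", "nan", "NaN"):
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: malformed numeric cell {cell!r} "
                    f"(probeset {fields[0]!r}, sample {col!r})"
                ) from None
        rows.append(vals)
    if pd.Index(probesets).has_duplicates:
        dup = pd.Index(probesets)
        names = dup[dup.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate probeset IDs {names[:5]}")
    values = pd.DataFrame(rows, index=probesets, columns=samples)
    expr = ExpressionMatrix(dataset_id, species, values, min_samples=min_samples)
    report = ReadReport(flagged=expr.zero_variance_probesets())
    return expr, report


def read_gene_sets(path: str | Path, kind: str) -> tuple[GeneSetCollection, ReadReport]:
    """Read a GMT-dialect file: set ID, description, then member genes."""
    lines = _data_lines(path)
    if not lines:
        raise ValidationError(f"{path}: empty gene-set file")
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    report = ReadReport()
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValidationError(
                f"{path}:{lineno}: gene-set line needs at least ID and description"
            )
        sid, desc, *genes = fields
        genes = [g for g in genes if g]
        if sid in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate set ID {sid!r}")
        if not genes:
            report.dropped.append(sid)
            continue
        sets[sid] = frozenset(genes)
        descriptions[sid] = desc
    return GeneSetCollection(sets, kind, descriptions), report


def write_gene_sets(
    sets: GeneSetCollection, path: str | Path, header: str | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for sid in sets.sets:
            desc = sets.descriptions.get(sid, ".") or "."
            members = "\t".join(sorted(sets.sets[sid]))
            fh.write(f"{sid}\t{desc}\t{members}\n")


def write_clusters(
    clusters: Sequence[CAGC], path: str | Path, header: str | None = None
) -> None:
    """Serialize clusters as GMT: set ID = centre gene, members = neighbours.

    Round-trips through :func:`read_gene_sets` (member sets identical).
    """
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for c in clusters:
            fh.write(f"{c.centre}\t.\t" + "\t".join(sorted(c.members)) + "\n")


def read_clusters(path: str | Path) -> list[CAGC]:
    coll, _ = read_gene_sets(path, kind="annotation")
    return [CAGC(centre=sid, members=genes) for sid, genes in coll.items()]


def read_probeset_gene_map(path: str | Path) -> ProbesetGeneMap:
    """Two-column TSV probeset<TAB>gene; an empty gene field = unmapped."""
    pairs: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 1:
            continue
        ps = fields[0]
        gene = fields[1] if len(fields) > 1 else ""
        if gene:
            pairs.add((ps, gene))
    return ProbesetGeneMap(pairs)


def read_orthology(path: str | Path) -> OrthologyMap:
    """TSV gene_a<TAB>gene_b<TAB>one_to_one(1/0)."""
    rows: list[tuple[str, str, bool]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: orthology rows need gene_a, gene_b, one_to_one"
            )
        rows.append((fields[0], fields[1], fields[2] in ("1", "true", "True")))
    return OrthologyMap(rows)


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    """TSV drug<TAB>target_gene<TAB>action (action optional, default unknown)."""
    rows: list[tuple[str, str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: need drug and target columns")
        action = fields[2] if len(fields) > 2 and fields[2] else "unknown"
        rows.append((fields[0], fields[1], action))
    return DrugTargetTable(rows)


def read_phenotype_similarity(path: str | Path) -> PhenotypeSimilarity:
    """Square TSV with phenotype IDs on both the header row and first column."""
    lines = _data_lines(path)
    if not lines:
        raise ValidationError(f"{path}: empty similarity file")
    buf = _io.StringIO("\n".join(line for _, line in lines))
    df = pd.read_csv(buf, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return PhenotypeSimilarity(df)


def read_rank_matrix(
    matrix_path: str | Path, metadata_path: str | Path
) -> PerturbationRankMatrix:
    """Rank matrix TSV (probesets x instances) plus instance-metadata TSV.

    Metadata columns: instance, drug, then free-form extras (concentration,
    cell_line, duration, ...).
    """
    lines = _data_lines(matrix_path)
    if not lines:
        raise ValidationError(f"{matrix_path}: empty rank matrix")
    buf = _io.StringIO("\n".join(line for _, line in lines))
    ranks = pd.read_csv(buf, sep="\t", index_col=0)
    ranks.index = ranks.index.astype(str)
    ranks.columns = ranks.columns.astype(str)

    meta_lines = _data_lines(metadata_path)
    if not meta_lines:
        raise ValidationError(f"{metadata_path}: empty instance metadata")
    header = meta_lines[0][1].split("\t")
    if "instance" not in header or "drug" not in header:
        raise ValidationError(
            f"{metadata_path}: metadata needs 'instance' and 'drug' columns"
        )
    instances: dict[str, dict[str, str]] = {}
    for lineno, line in meta_lines[1:]:
        fields = line.split("\t")
        row = dict(zip(header, fields))
        instances[row["instance"]] = row
    return PerturbationRankMatrix(ranks, instances)


def write_network(net: AntiCoexNetwork, path: str | Path, header: str | None = None) -> None:
    """Two-column TSV edge list with '#'-prefixed provenance header."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# level={net.level} species_scope={net.species_scope}\n")
        fh.write(f"# provenance={','.join(net.provenance)}\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_network(path: str | Path) -> AntiCoexNetwork:
    level, scope, prov = "gene", "unknown", []
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("level="):
                    for tok in body.split():
                        key, _, val = tok.partition("=")
                        if key == "level":
                            level = val
                        elif key == "species_scope":
                            scope = val
                elif body.startswith("provenance="):
                    val = body.split("=", 1)[1]
                    prov = [p for p in val.split(",") if p]
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"{path}:{lineno}: edge rows need two columns")
            edges.append((fields[0], fields[1]))
    return AntiCoexNetwork.from_edges(edges, level=level, species_scope=scope, provenance=prov)


def write_tsv(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a DataFrame as TSV with an optional '#'-comment header block."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
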