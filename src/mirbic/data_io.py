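"""Readers and writers for the pipeline's external formats.

Formats are deliberately plain: a tab-separated fold-change matrix (header
row of condition IDs, first column of gene symbols), gene-set files with
one symbol per line (``#`` comments ignored), a three-column edge list for
functional interaction networks, and a tab-separated bicluster table that
round-trips losslessly.  Gene symbols are matched case-sensitively after
whitespace trimming.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import Bicluster
from .profile import MirProfile

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Genes x conditions matrix of log2 fold changes.

    Missing values are stored as NaN and treated as neutral (no evidence of
    regulation) by downstream quantization.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("duplicate condition ids")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.condition_ids)
        )


@dataclass(frozen=True)
class TargetSetCollection:
    """Per-source predicted target gene sets for one miRNA."""

    sets: Mapping[str, frozenset[str]]
    min_sources: int = 3

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            genes = frozenset(g.strip() for g in genes)
            if any(not g for g in genes):
                raise ValueError(f"empty gene symbol in source {name!r}")
            clean[str(name)] = genes
        if self.min_sources < 1:
            raise ValueError("min_sources must be positive")
        if self.min_sources > len(clean):
            raise ValueError("min_sources exceeds the number of sources")
        object.__setattr__(self, "sets", clean)


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected weighted gene-gene network above a score threshold."""

    edges: Mapping[tuple[str, str], float]
    score_threshold: float

    def __post_init__(self) -> None:
        for (a, b), score in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError("edge keys must be sorted pairs")
            if not score > self.score_threshold:
                raise ValueError("edge below the score threshold")

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out


def read_fold_change_matrix(path: PathLike, delimiter: str = "\t") -> FoldChangeMatrix:
    """Read a delimited fold-change matrix (condition header, gene label column).

    Non-numeric cells become missing (NaN).  Duplicate gene symbols and
    ragged rows are hard errors naming the offender.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: no data rows") from None
        conditions = [c.strip() for c in header[1:]]
        n_fields = len(header)
        genes: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != n_fields:
                raise ValueError(
                    f"{path}: line {lineno} has {len(rec)} fields, expected {n_fields}"
                )
            gene = rec[0].strip()
            if gene in seen:
                raise ValueError(f"{path}: duplicate gene symbol {gene!r}")
            seen.add(gene)
            genes.append(gene)
            row = []
            for cell in rec[1:]:
                try:
                    row.append(float(cell))
                except ValueError:
                    row.append(float("nan"))
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return FoldChangeMatrix(
        values=np.array(rows, dtype=float),
        gene_ids=tuple(genes),
        condition_ids=tuple(conditions),
    )


def read_gene_set(path: PathLike) -> frozenset[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.add(line)
    return frozenset(out)


def read_target_sets(
    paths: Mapping[str, PathLike], min_sources: int = 3
) -> TargetSetCollection:
    """Load one gene-set file per prediction source."""
    return TargetSetCollection(
        sets={name: read_gene_set(p) for name, p in paths.items()},
        min_sources=min_sources,
    )


def consensus_background(targets: TargetSetCollection) -> frozenset[str]:
    """Genes predicted by at least ``min_sources`` of the source databases.

    This consensus defines the background target set of a miRNA; an empty
    result is returned with a warning (the pipeline for that miRNA then
    halts cleanly).
    """
    counts: dict[str, int] = {}
    for genes in targets.sets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    result = frozenset(g for g, c in counts.items() if c >= targets.min_sources)
    if not result:
        logger.warning(
            "no gene reaches the %d-source consensus; empty background",
            targets.min_sources,
        )
    return result


def read_edge_list(path: PathLike, score_threshold: float = 150.0) -> InteractionNetwork:
    """Read a 3-column (gene, gene, score) edge list.

    Edges are kept when score is strictly above the threshold; pairs are
    stored once (sorted), duplicates keep the maximum score, and self-loops
    are dropped with a logged count.
    """
    edges: dict[tuple[str, str], float] = {}
    n_self = 0
    with Path(path).open(newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields")
            a, b = rec[0].strip(), rec[1].strip()
            score = float(rec[2])
            if a == b:
                n_self += 1
                continue
            if score > score_threshold:
                key = tuple(sorted((a, b)))
                edges[key] = max(edges.get(key, score), score)
    if n_self:
        logger.info("dropped %d self-loop rows", n_self)
    return InteractionNetwork(edges=edges, score_threshold=score_threshold)


_BICLUSTER_COLUMNS = [
    "bicluster_id",
    "direction",
    "fc_threshold",
    "stage",
    "n_conditions",
    "n_genes",
    "density",
    "condition_ids",
    "gene_ids",
]


def write_biclusters(
    biclusters: Sequence[Bicluster], profile: MirProfile, path: PathLike
) -> None:
    """Write biclusters as a tab-separated table resolving indices to IDs."""
    records = []
    for i, b in enumerate(biclusters):
        if b.rows and max(b.rows) >= len(profile.condition_ids):
            raise IndexError(f"bicluster {i}: row index out of range")
        if b.cols and max(b.cols) >= len(profile.gene_ids):
            raise IndexError(f"bicluster {i}: column index out of range")
        records.append(
            {
                "bicluster_id": i,
                "direction": profile.direction,
                "fc_threshold": profile.fc_threshold,
                "stage": b.stage,
                "n_conditions": len(b.rows),
                "n_genes": len(b.cols),
                "density": b.density,
                "condition_ids": ";".join(profile.condition_ids[r] for r in b.rows),
                "gene_ids": ";".join(profile.gene_ids[c] for c in b.cols),
            }
        )
    df = pd.DataFrame.from_records(records, columns=_BICLUSTER_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_biclusters(
    path: PathLike, profile: Optional[MirProfile] = None
) -> Union[pd.DataFrame, list[Bicluster]]:
    """Read a bicluster table; with a profile, resolve IDs back to index sets."""
    df = pd.read_csv(path, sep="\t", dtype={"condition_ids": str, "gene_ids": str})
    missing = set(_BICLUSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if profile is None:
        return df
    cond_index = {c: i for i, c in enumerate(profile.condition_ids)}
    gene_index = {g: i for i, g in enumerate(profile.gene_ids)}
    out = []
    for _, rec in df.iterrows():
        rows = tuple(cond_index[c] for c in str(rec["condition_ids"]).split(";"))
        cols = tuple(gene_index[g] for g in str(rec["gene_ids"]).split(";"))
        out.append(
            Bicluster(
                rows=rows,
                cols=cols,
                stage=str(rec["stage"]),
                density=float(rec["density"]),
            )
        )
    return out
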