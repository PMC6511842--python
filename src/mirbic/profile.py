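"""Quantization of log fold changes and assembly of direction-specific
binary regulation profiles.

A compendium of log2 fold-change contrasts (genes x conditions) is first
quantized to a ternary matrix (up = 1, neutral = 0, down = -1) at a
symmetric threshold, by default log2(1.3).  For one miRNA, conditions in
which the miRNA's sequence-predicted targets (the *background set*) are
over-represented among regulated genes are selected with a one-sided
hypergeometric test (Benjamini-Hochberg FDR across conditions, default 5%),
separately per regulation direction.  The selected conditions x background
genes submatrix, binarized to the chosen direction, is the profile that the
biclustering stages operate on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: log2 threshold corresponding to a 1.3-fold change
DEFAULT_FC_THRESHOLD = math.log2(1.3)
DEFAULT_FDR_CUTOFF = 0.05

_DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class TernaryMatrix:
    """Genes x conditions matrix over {-1, 0, 1} with its quantization threshold."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    fc_threshold: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError("ternary matrix shape does not match id lists")
        if not np.isin(v, (-1, 0, 1)).all():
            raise ValueError("ternary values must be in {-1, 0, 1}")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MirProfile:
    """Binary conditions x genes profile for one miRNA and one direction.

    Rows are the enrichment-selected conditions (with their BH-adjusted
    p-values), columns the background target genes present in the
    compendium; a cell is 1 iff the gene is regulated in the profile's
    direction in that condition.
    """

    values: np.ndarray
    direction: str
    fc_threshold: float
    fdr_cutoff: float
    condition_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    condition_fdr: dict[str, float]

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        v = np.asarray(self.values, dtype=np.uint8)
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("profile values must be binary")
        if v.shape != (len(self.condition_ids), len(self.gene_ids)):
            raise ValueError("profile shape does not match id lists")
        object.__setattr__(self, "values", v)

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0


def quantize(fc, fc_threshold: float = DEFAULT_FC_THRESHOLD) -> TernaryMatrix:
    """Quantize log2 fold changes into up (1) / neutral (0) / down (-1).

    ``fc_threshold`` is on the log2 scale and must be positive; a value at
    exactly the threshold counts as regulated (inclusive boundary).  Missing
    values quantize to neutral.
    """
    if not fc_threshold > 0:
        raise ValueError("fc_threshold must be positive (log2 scale)")
    values = np.asarray(fc.values, dtype=float)
    tern = np.zeros(values.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        tern[values >= fc_threshold] = 1
        tern[values <= -fc_threshold] = -1
    return TernaryMatrix(
        values=tern,
        gene_ids=tuple(fc.gene_ids),
        condition_ids=tuple(fc.condition_ids),
        fc_threshold=float(fc_threshold),
    )


def enriched_conditions(
    tern: TernaryMatrix,
    background: Iterable[str],
    direction: str = "up",
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
) -> tuple[list[str], pd.DataFrame]:
    """Conditions where regulated genes are enriched in the background set.

    Per condition a one-sided hypergeometric upper-tail test is applied:
    universe N = genes in the matrix, K = background genes present, n =
    genes regulated in the given direction in that condition, k = regulated
    background genes; p = P(X >= k).  P-values are Benjamini-Hochberg
    adjusted across all conditions, and conditions with adjusted p strictly
    below ``fdr_cutoff`` are returned in matrix order, together with a
    per-condition table of raw (``pvalue``) and adjusted (``fdr``) values.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    if not (0.0 < fdr_cutoff < 1.0):
        raise ValueError("fdr_cutoff must lie in (0, 1)")
    background = set(background)
    present = background & set(tern.gene_ids)
    if len(present) < len(background):
        logger.info(
            "%d background genes absent from the matrix were ignored",
            len(background) - len(present),
        )
    N = len(tern.gene_ids)
    K = len(present)
    target_value = 1 if direction == "up" else -1
    in_bg = np.fromiter(
        (g in present for g in tern.gene_ids), dtype=bool, count=N
    )
    regulated = tern.values == target_value  # genes x conditions
    n_per_cond = regulated.sum(axis=0)
    k_per_cond = (regulated & in_bg[:, None]).sum(axis=0)
    # P(X >= k); conditions with no regulated genes get p = 1
    pvals = np.where(
        n_per_cond > 0, hypergeom.sf(k_per_cond - 1, N, K, n_per_cond), 1.0
    )
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    stats = pd.DataFrame(
        {"pvalue": pvals, "fdr": adjusted}, index=list(tern.condition_ids)
    )
    selected = [
        c for c, p in zip(tern.condition_ids, adjusted) if p < fdr_cutoff
    ]
    return selected, stats


def build_mir_profile(
    tern: TernaryMatrix,
    background: Iterable[str],
    direction: str = "up",
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
) -> MirProfile:
    """Assemble the binary profile for one miRNA and one direction.

    Rows are the enriched conditions for the direction, columns the
    background genes present in the matrix; a cell is 1 iff the ternary
    value matches the direction (+1 for up, -1 for down).  With no enriched
    conditions an empty profile is returned and downstream stages no-op.
    """
    background = set(background)
    selected, adj = enriched_conditions(tern, background, direction, fdr_cutoff)
    genes = tuple(g for g in tern.gene_ids if g in background)
    if not selected:
        logger.warning("no enriched conditions for direction %r", direction)
        return MirProfile(
            values=np.zeros((0, len(genes)), dtype=np.uint8),
            direction=direction,
            fc_threshold=tern.fc_threshold,
            fdr_cutoff=fdr_cutoff,
            condition_ids=(),
            gene_ids=genes,
            condition_fdr={},
        )
    target_value = 1 if direction == "up" else -1
    cond_index = {c: i for i, c in enumerate(tern.condition_ids)}
    gene_rows = [i for i, g in enumerate(tern.gene_ids) if g in background]
    cond_cols = [cond_index[c] for c in selected]
    sub = tern.values[np.ix_(gene_rows, cond_cols)]
    binary = (sub == target_value).astype(np.uint8).T  # conditions x genes
    return MirProfile(
        values=binary,
        direction=direction,
        fc_threshold=tern.fc_threshold,
        fdr_cutoff=fdr_cutoff,
        condition_ids=tuple(selected),
        gene_ids=genes,
        condition_fdr={c: float(adj.loc[c, "fdr"]) for c in selected},
    )
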