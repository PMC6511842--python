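"""Bicluster discovery in binary profiles: seed enumeration, progressive
extension and redundancy merging.

The pipeline implemented here turns a binary conditions x genes profile into
a small set of dense biclusters in three stages:

1. **Seeds** — inclusion-maximal all-1 submatrices (maximal bicliques) of
   at least a minimum size: either the exact BIMAX divide-and-conquer
   enumeration (uncapped) or, with an iteration cap, a greedy
   maximum-coverage selection of one maximal biclique per iteration.  Real
   profiles are noisy, so individual seeds are fragments of the underlying
   modules.
2. **Progressive extension (PBE)** — each seed is grown by competitively
   adding dense rows and columns and pruning noisy ones, under a
   zero-proportion threshold that is ramped from strict (1%) to permissive
   (10%).  The ramp lets the bicluster absorb noise gradually without being
   captured by it.
3. **Merging** — extended biclusters are clustered by Meet/Min distance
   (average linkage, dendrogram cut 0.5), each cluster is replaced by the
   union of its members, and rows/columns with more than 10% zeros are
   trimmed off one at a time.

All stages are fully deterministic: ties are broken by score, then by the
number of 1s in the full profile, then by rows before columns, then by the
lowest index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: slack for comparing zero fractions (ratios of small integers) to thresholds
_EPS = 1e-9

_STAGES = ("seed", "extended", "merged")


@dataclass(frozen=True)
class Bicluster:
    """A pair of row- and column-index sets over a binary profile.

    ``rows`` and ``cols`` are stored as sorted tuples of unique indices.
    ``density`` is the fraction of 1s in the induced submatrix; seed-stage
    biclusters are all-1 by construction (density exactly 1.0).
    """

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    stage: str = "seed"
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        rows = tuple(sorted(set(int(r) for r in self.rows)))
        cols = tuple(sorted(set(int(c) for c in self.cols)))
        if not rows or not cols:
            raise ValueError("bicluster rows and cols must be non-empty")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)
        if self.stage == "seed" and self.density != 1.0:
            raise ValueError("seed biclusters must have density 1.0")

    @property
    def n_cells(self) -> int:
        return len(self.rows) * len(self.cols)


@dataclass(frozen=True)
class PbeConfig:
    """Tunable parameters of the seed / extend / merge pipeline.

    Defaults correspond to the reference setting for real expression
    profiles: 10 x 10 minimum seeds, at most 20 seeds per profile, a zero
    threshold ramp 0.01..0.10 in steps of 0.01, Meet/Min dendrogram cut at
    0.5 and a 10% trimming threshold.
    """

    min_seed_rows: int = 10
    min_seed_cols: int = 10
    bimax_iterations: int = 20
    zero_thresholds: tuple[float, ...] = tuple(
        round(0.01 * i, 2) for i in range(1, 11)
    )
    merge_cutoff: float = 0.5
    trim_zero_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_seed_rows < 1 or self.min_seed_cols < 1:
            raise ValueError("minimum seed dimensions must be >= 1")
        if self.bimax_iterations < 1:
            raise ValueError("bimax_iterations must be >= 1")
        ts = tuple(float(t) for t in self.zero_thresholds)
        if not ts or any(not (0.0 < t < 1.0) for t in ts):
            raise ValueError("zero thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("zero thresholds must be strictly increasing")
        object.__setattr__(self, "zero_thresholds", ts)
        if not (0.0 < self.merge_cutoff < 1.0):
            raise ValueError("merge_cutoff must lie in (0, 1)")
        if not (0.0 < self.trim_zero_fraction < 1.0):
            raise ValueError("trim_zero_fraction must lie in (0, 1)")


def _as_bool_matrix(profile) -> np.ndarray:
    """Coerce a profile (ndarray or object with ``.values``) to a 2-D bool array."""
    values = getattr(profile, "values", profile)
    M = np.asarray(values)
    if M.ndim != 2:
        raise ValueError("profile must be a 2-D matrix")
    if M.dtype != bool:
        uniq = np.unique(M)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("profile must be binary (0/1)")
        M = M.astype(bool)
    return M


def _density(M: np.ndarray, rows: Sequence[int], cols: Sequence[int]) -> float:
    sub = M[np.ix_(list(rows), list(cols))]
    return float(sub.mean())


# ---------------------------------------------------------------------------
# Seed enumeration (BIMAX)
# ---------------------------------------------------------------------------


def _row_bitmasks(M: np.ndarray) -> list[int]:
    """Column bitmask per row; bit j set iff M[i, j] == 1."""
    row_bits: list[int] = []
    for i in range(M.shape[0]):
        b = 0
        for j in np.flatnonzero(M[i]):
            b |= 1 << int(j)
        row_bits.append(b)
    return row_bits


def _close_leaf(
    row_bits: Sequence[int], n_cols: int, cmask: int
) -> tuple[tuple[int, ...], int]:
    """Close an all-1 column set against the matrix: all rows covering it,
    then all columns those rows share."""
    rows = tuple(i for i, rb in enumerate(row_bits) if rb & cmask == cmask)
    closed = (1 << n_cols) - 1
    for i in rows:
        closed &= row_bits[i]
    return rows, closed


def _enumerate_bicliques(
    row_bits: Sequence[int],
    n_cols: int,
    min_rows: int,
    min_cols: int,
    cap: float,
    node_budget: Optional[int] = None,
) -> list[tuple[tuple[int, ...], int]]:
    """BIMAX divide-and-conquer enumeration of maximal all-1 submatrices.

    A template row splits the column set into its 1-columns (CU) and the
    rest (CV); the CU branch is explored first, and the CV branch carries
    CV as a mandatory column set so no bicluster is reported twice.  Each
    all-1 leaf is closed against the matrix, so every reported
    (rows, colmask) pair is inclusion-maximal.  Depth-first, deterministic;
    stops once ``cap`` bicliques have been reported.
    """
    n_rows = len(row_bits)
    full_cols = (1 << n_cols) - 1
    results: list[tuple[tuple[int, ...], int]] = []
    seen: set[tuple[tuple[int, ...], int]] = set()
    # stack entries: (row index tuple, column bitmask, mandatory column masks)
    stack: list[tuple[tuple[int, ...], int, tuple[int, ...]]] = [
        (tuple(range(n_rows)), full_cols, ())
    ]
    n_nodes = 0
    while stack and len(results) < cap:
        n_nodes += 1
        if node_budget is not None and n_nodes > node_budget:
            logger.debug("biclique search stopped at node budget %d", node_budget)
            break
        G, C, Z = stack.pop()
        # rows with fewer than min_cols ones in scope cannot join a
        # qualifying biclique (closure is taken globally, so this is sound)
        G = tuple(g for g in G if (row_bits[g] & C).bit_count() >= min_cols)
        if len(G) < min_rows or C.bit_count() < min_cols:
            continue
        template = -1
        for g in G:
            if row_bits[g] & C != C:
                template = g
                break
        if template < 0:
            leaf_rows, closed_cols = _close_leaf(row_bits, n_cols, C)
            key = (leaf_rows, closed_cols)
            if (
                key not in seen
                and len(leaf_rows) >= min_rows
                and closed_cols.bit_count() >= min_cols
            ):
                seen.add(key)
                results.append(key)
            continue
        CU = row_bits[template] & C
        CV = C & ~CU
        rows_u = tuple(g for g in G if row_bits[g] & CU)
        rows_v = tuple(g for g in G if row_bits[g] & CV)
        # push the CV branch first so the CU branch is explored first (LIFO)
        if len(rows_v) >= min_rows:
            stack.append((rows_v, C, Z + (CV,)))
        if len(rows_u) >= min_rows and CU.bit_count() >= min_cols:
            if all(z & CU for z in Z):
                stack.append((rows_u, CU, Z))
    return results


def _close_colmask(M: np.ndarray, col_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Close a column mask against M: all rows covering it, then the full
    common column set of those rows.  The result is an inclusion-maximal
    all-1 submatrix containing the input columns."""
    rows = np.flatnonzero(M[:, col_mask].all(axis=1))
    cols = np.flatnonzero(M[rows].all(axis=0))
    return rows, cols


def _best_new_cell_prefix(
    M: np.ndarray,
    covered: np.ndarray,
    col_mask: np.ndarray,
    min_rows: int,
    min_cols: int,
) -> Optional[tuple[int, np.ndarray]]:
    """Best all-1 prefix bicluster inside ``col_mask`` by new-cell count.

    Rows are ordered by their uncovered overlap with the candidate columns;
    walking that order while intersecting supports yields a sequence of
    all-1 biclusters (k rows x shrinking column set).  Returns the
    (new-cell count, column mask) of the prefix covering the most cells not
    yet in ``covered``, or None if no prefix reaches the minimum size.
    """
    n_rows = M.shape[0]
    overlap = (M[:, col_mask] & ~covered[:, col_mask]).sum(axis=1)
    order = np.argsort(-overlap, kind="stable")
    current = col_mask.copy()
    members: list[int] = []
    best: Optional[np.ndarray] = None
    best_new = 0
    for i in order:
        shrunk = current & M[i]
        n_cols_left = int(shrunk.sum())
        if n_cols_left < min_cols:
            break
        members.append(int(i))
        current = shrunk
        if len(members) >= min_rows:
            new = int((~covered[np.ix_(members, np.flatnonzero(current))]).sum())
            if new > best_new:
                best_new = new
                best = current.copy()
        if n_rows * n_cols_left <= best_new:
            break  # no longer prefix can beat the best found
    if best is None:
        return None
    return best_new, best


def _search_anchored(
    M: np.ndarray,
    covered: np.ndarray,
    min_rows: int,
    min_cols: int,
    n_anchors: int,
    n_refine: int,
) -> Optional[tuple[int, np.ndarray]]:
    """Best maximal biclique by uncovered cells, anchored on dense rows.

    Anchors are the rows with the most uncovered 1s; each anchor's support
    is refined by repeated best-prefix passes.  If no anchor in the top
    ``n_anchors`` yields new coverage, the remaining rows are swept until
    one does.  Returns (new-cell count, column mask) or None.
    """
    uncovered = (M & ~covered).sum(axis=1)
    order = np.argsort(-uncovered, kind="stable")

    def _refine(anchor: int) -> Optional[tuple[int, np.ndarray]]:
        col_mask = M[anchor].copy()
        if int(col_mask.sum()) < min_cols:
            return None
        best: Optional[tuple[int, np.ndarray]] = None
        prev = -1
        for _ in range(n_refine):
            res = _best_new_cell_prefix(M, covered, col_mask, min_rows, min_cols)
            if res is None or res[0] <= prev:
                break
            prev = res[0]
            col_mask = res[1]
            if best is None or res[0] > best[0]:
                best = res
        return best

    overall: Optional[tuple[int, np.ndarray]] = None
    for a in order[:n_anchors]:
        res = _refine(int(a))
        if res is not None and (overall is None or res[0] > overall[0]):
            overall = res
    if overall is None or overall[0] <= 0:
        for a in order[n_anchors:]:
            res = _refine(int(a))
            if res is not None and res[0] > 0:
                overall = res
                break
    if overall is None or overall[0] <= 0:
        return None
    return overall


def bimax_seeds(
    profile,
    min_rows: int = 10,
    min_cols: int = 10,
    max_seeds: Optional[int] = None,
) -> list[Bicluster]:
    """Extract all-1 seed biclusters (maximal bicliques) from a binary profile.

    With ``max_seeds=None`` this is the exhaustive BIMAX divide-and-conquer
    enumeration of all inclusion-maximal all-1 submatrices of at least
    ``min_rows`` x ``min_cols``.

    With a cap of k ("iterations"), one seed is extracted per iteration:
    the maximal biclique covering the most cells not yet covered by earlier
    seeds, found by an anchored greedy search run on both the profile and
    its transpose.  Seeds may overlap, but each contributes new cells, so k
    iterations produce a diverse set of at most k large seeds spread over
    the dense regions of the profile rather than near-duplicates of the
    first region an exhaustive enumeration would visit.  Extraction stops
    early once no qualifying biclique adds new coverage.  A run capped at k
    is a prefix of a run capped at k' > k.

    Every returned seed is an inclusion-maximal all-1 submatrix of the
    input profile (density exactly 1.0) of at least ``min_rows`` x
    ``min_cols``, and no seed's (rows, cols) pair is a subset of another's.
    """
    M = _as_bool_matrix(profile)
    n_rows, n_cols = M.shape
    if min_rows < 1 or min_cols < 1:
        raise ValueError("min_rows and min_cols must be >= 1")
    if max_seeds is not None and max_seeds < 1:
        return []
    if n_rows < min_rows or n_cols < min_cols:
        return []

    if max_seeds is None:
        row_bits = _row_bitmasks(M)
        leaves = _enumerate_bicliques(
            row_bits, n_cols, min_rows, min_cols, float("inf")
        )
        out = []
        for rows, cmask in leaves:
            cols = tuple(j for j in range(n_cols) if cmask >> j & 1)
            out.append(Bicluster(rows=rows, cols=cols, stage="seed", density=1.0))
        return out

    n_anchors, n_refine = 30, 3
    covered = np.zeros_like(M)
    results: list[Bicluster] = []
    for _ in range(int(max_seeds)):
        row_side = _search_anchored(M, covered, min_rows, min_cols, n_anchors, n_refine)
        col_side = _search_anchored(
            M.T, covered.T, min_cols, min_rows, n_anchors, n_refine
        )
        candidates: list[tuple[int, np.ndarray, np.ndarray]] = []
        if row_side is not None:
            rows, cols = _close_colmask(M, row_side[1])
            candidates.append((row_side[0], rows, cols))
        if col_side is not None:
            cols, rows = _close_colmask(M.T, col_side[1])
            candidates.append((col_side[0], rows, cols))
        if not candidates:
            break
        candidates.sort(key=lambda c: -c[0])
        _, rows, cols = candidates[0]
        new = int((~covered[np.ix_(rows, cols)]).sum())
        if new == 0:
            break
        covered[np.ix_(rows, cols)] = True
        results.append(
            Bicluster(
                rows=tuple(int(i) for i in rows),
                cols=tuple(int(j) for j in cols),
                stage="seed",
                density=1.0,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Progressive extension
# ---------------------------------------------------------------------------


def _best_addition(
    M: np.ndarray,
    in_rows: np.ndarray,
    in_cols: np.ndarray,
    ones_row: np.ndarray,
    ones_col: np.ndarray,
    t: float,
) -> Optional[tuple[int, int]]:
    """Best (axis, index) to add at threshold ``t``, or None.

    Rows and columns compete in one pool.  Order: lowest zero fraction,
    then most 1s in the full profile, then rows before columns, then
    lowest index.
    """
    best = None  # (zf, -ones, axis, index)
    zf_r = 1.0 - M[:, in_cols].mean(axis=1)
    cand_r = np.flatnonzero(~in_rows & (zf_r <= t + _EPS))
    if cand_r.size:
        zf = zf_r[cand_r]
        m = zf.min()
        sel = cand_r[zf == m]
        i = int(sel[np.argmax(ones_row[sel])])
        best = (float(zf_r[i]), -int(ones_row[i]), 0, i)
    zf_c = 1.0 - M[in_rows, :].mean(axis=0)
    cand_c = np.flatnonzero(~in_cols & (zf_c <= t + _EPS))
    if cand_c.size:
        zf = zf_c[cand_c]
        m = zf.min()
        sel = cand_c[zf == m]
        j = int(sel[np.argmax(ones_col[sel])])
        cand = (float(zf_c[j]), -int(ones_col[j]), 1, j)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return best[2], best[3]


def _worst_member(
    M: np.ndarray,
    in_rows: np.ndarray,
    in_cols: np.ndarray,
    ones_row: np.ndarray,
    ones_col: np.ndarray,
    t: float,
) -> Optional[tuple[int, int]]:
    """Worst member (axis, index) with zero fraction above ``t``, or None.

    Order: highest zero fraction, then fewest 1s in the full profile, then
    rows before columns, then lowest index.
    """
    worst = None  # (-zf, ones, axis, index)
    zf_r = 1.0 - M[:, in_cols].mean(axis=1)
    memb_r = np.flatnonzero(in_rows & (zf_r > t + _EPS))
    if memb_r.size:
        zf = zf_r[memb_r]
        m = zf.max()
        sel = memb_r[zf == m]
        i = int(sel[np.argmin(ones_row[sel])])
        worst = (-float(zf_r[i]), int(ones_row[i]), 0, i)
    zf_c = 1.0 - M[in_rows, :].mean(axis=0)
    memb_c = np.flatnonzero(in_cols & (zf_c > t + _EPS))
    if memb_c.size:
        zf = zf_c[memb_c]
        m = zf.max()
        sel = memb_c[zf == m]
        j = int(sel[np.argmin(ones_col[sel])])
        cand = (-float(zf_c[j]), int(ones_col[j]), 1, j)
        if worst is None or cand < worst:
            worst = cand
    if worst is None:
        return None
    return worst[2], worst[3]


def extend_seed(seed: Bicluster, profile, config: Optional[PbeConfig] = None) -> Bicluster:
    """Grow a seed bicluster by the progressive extension schedule.

    For each zero threshold ``t`` (ascending): first repeatedly add the
    single best outside row or column whose zero fraction over the current
    bicluster is at most ``t``; then repeatedly remove the single worst
    member row or column whose zero fraction exceeds ``t``.  At exit every
    row and column of the result has zero fraction at most the final
    threshold.

    If the removal phase would empty the bicluster the original seed is
    returned unchanged.
    """
    config = config or PbeConfig()
    M = _as_bool_matrix(profile)
    n_rows, n_cols = M.shape
    if max(seed.rows) >= n_rows or max(seed.cols) >= n_cols:
        raise IndexError("seed indices out of range for profile")
    ones_row = M.sum(axis=1)
    ones_col = M.sum(axis=0)
    in_rows = np.zeros(n_rows, dtype=bool)
    in_rows[list(seed.rows)] = True
    in_cols = np.zeros(n_cols, dtype=bool)
    in_cols[list(seed.cols)] = True

    for t in config.zero_thresholds:
        # addition phase: best-first greedy with full recomputation
        while True:
            add = _best_addition(M, in_rows, in_cols, ones_row, ones_col, t)
            if add is None:
                break
            axis, idx = add
            (in_rows if axis == 0 else in_cols)[idx] = True
        # removal phase: worst-first, one at a time
        while True:
            rem = _worst_member(M, in_rows, in_cols, ones_row, ones_col, t)
            if rem is None:
                break
            axis, idx = rem
            (in_rows if axis == 0 else in_cols)[idx] = False
            if not in_rows.any() or not in_cols.any():
                logger.warning(
                    "extension removal emptied the bicluster at t=%.3f; "
                    "returning seed unchanged",
                    t,
                )
                return seed

    rows = tuple(int(i) for i in np.flatnonzero(in_rows))
    cols = tuple(int(j) for j in np.flatnonzero(in_cols))
    return Bicluster(
        rows=rows, cols=cols, stage="extended", density=_density(M, rows, cols)
    )


# ---------------------------------------------------------------------------
# Meet/Min distance and merging
# ---------------------------------------------------------------------------


def meet_min_distance(a: Bicluster, b: Bicluster) -> float:
    """Meet/Min distance: 1 - shared cells / cells of the smaller bicluster.

    A bicluster's cell count is rows x columns; the shared cell count is the
    product of the row- and column-intersection sizes.  The distance is 0
    for identical biclusters and 1 for pairs that share no row or no column.
    """
    size_a = a.n_cells
    size_b = b.n_cells
    shared = len(set(a.rows) & set(b.rows)) * len(set(a.cols) & set(b.cols))
    return 1.0 - shared / min(size_a, size_b)


def _trim(
    M: np.ndarray,
    in_rows: np.ndarray,
    in_cols: np.ndarray,
    ones_row: np.ndarray,
    ones_col: np.ndarray,
    threshold: float,
) -> bool:
    """Remove worst offenders in place until all zero fractions <= threshold.

    Returns False if trimming emptied the bicluster.
    """
    while True:
        rem = _worst_member(M, in_rows, in_cols, ones_row, ones_col, threshold)
        if rem is None:
            return True
        axis, idx = rem
        (in_rows if axis == 0 else in_cols)[idx] = False
        if not in_rows.any() or not in_cols.any():
            return False


def merge_biclusters(
    extended: Sequence[Bicluster], profile, config: Optional[PbeConfig] = None
) -> list[Bicluster]:
    """Merge redundant extended biclusters and trim noisy rows/columns.

    Average-linkage hierarchical clustering on pairwise Meet/Min distances,
    dendrogram cut strictly below ``config.merge_cutoff``; each cluster
    becomes the union of its members' rows x union of columns, after which
    rows or columns whose zero fraction exceeds ``config.trim_zero_fraction``
    are removed one at a time (worst first).  Clusters trimmed to emptiness
    are dropped; identical results are deduplicated.
    """
    config = config or PbeConfig()
    M = _as_bool_matrix(profile)
    if not extended:
        return []
    n = len(extended)
    if n == 1:
        labels = np.ones(1, dtype=int)
    else:
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = meet_min_distance(extended[i], extended[j])
        link = linkage(squareform(D, checks=False), method="average")
        # join below the cutoff (strict)
        labels = fcluster(link, t=config.merge_cutoff - _EPS, criterion="distance")

    ones_row = M.sum(axis=1)
    ones_col = M.sum(axis=0)
    merged: list[Bicluster] = []
    seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    for lab in np.unique(labels):
        members = [extended[i] for i in np.flatnonzero(labels == lab)]
        row_union = sorted(set().union(*(set(b.rows) for b in members)))
        col_union = sorted(set().union(*(set(b.cols) for b in members)))
        in_rows = np.zeros(M.shape[0], dtype=bool)
        in_rows[row_union] = True
        in_cols = np.zeros(M.shape[1], dtype=bool)
        in_cols[col_union] = True
        if not _trim(M, in_rows, in_cols, ones_row, ones_col, config.trim_zero_fraction):
            logger.warning("merged bicluster trimmed to emptiness; dropped")
            continue
        rows = tuple(int(i) for i in np.flatnonzero(in_rows))
        cols = tuple(int(j) for j in np.flatnonzero(in_cols))
        key = (rows, cols)
        if key in seen:
            continue
        seen.add(key)
        merged.append(
            Bicluster(rows=rows, cols=cols, stage="merged", density=_density(M, rows, cols))
        )
    return merged


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pbe(
    profile,
    config: Optional[PbeConfig] = None,
    seeds: Optional[Sequence[Bicluster]] = None,
) -> list[Bicluster]:
    """Seed -> extend -> merge pipeline over one binary profile.

    ``profile`` may be a binary ndarray or any object with a binary
    ``.values`` matrix.  Precomputed seeds may be supplied to skip the
    enumeration stage.  Output biclusters are sorted by descending cell
    count, then descending density, then first row index, and every output
    row and column has zero fraction at most ``config.trim_zero_fraction``.
    """
    config = config or PbeConfig()
    values = getattr(profile, "values", profile)
    M = np.asarray(values)
    if M.size == 0:
        return []
    M = _as_bool_matrix(M)
    if seeds is None:
        seeds = bimax_seeds(
            M,
            min_rows=config.min_seed_rows,
            min_cols=config.min_seed_cols,
            max_seeds=config.bimax_iterations,
        )
    if not seeds:
        return []
    extended = [extend_seed(s, M, config) for s in seeds]
    merged = merge_biclusters(extended, M, config)
    merged.sort(key=lambda b: (-b.n_cells, -b.density, b.rows[0]))
    return merged
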