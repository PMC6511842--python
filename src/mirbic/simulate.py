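"""Synthetic binary profiles with planted noisy biclusters, and the
element-level precision/sensitivity benchmark run over them.

The generator emulates the shape of real binary regulation profiles: a
700 x 300 matrix at 20% background density containing seven planted
biclusters whose row and column sizes are drawn uniformly from [20, 80],
each carrying 1-3% internal zeros (noise), with any two planted biclusters
overlapping in fewer than 20% of the smaller one's cells.  Ground truth is
the set of cells covered by any planted bicluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .core import Bicluster, PbeConfig, bimax_seeds, run_pbe

logger = logging.getLogger(__name__)

#: rejection-sampling attempts per planted bicluster before giving up
_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the planted-bicluster benchmark.

    Defaults reflect the average size and density of real profiles:
    700 rows x 300 columns, 20% background density, 7 planted biclusters
    sized uniformly in [20, 80] per dimension with 1-3% internal zeros,
    pairwise cell overlap below 20% of the smaller bicluster, 50 replicates.
    """

    n_rows: int = 700
    n_cols: int = 300
    background_density: float = 0.20
    n_biclusters: int = 7
    size_min: int = 20
    size_max: int = 80
    noise_min: float = 0.01
    noise_max: float = 0.03
    max_overlap_fraction: float = 0.20
    n_replicates: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_density < 1.0):
            raise ValueError("background_density must lie in [0, 1)")
        if not (0.0 <= self.noise_min <= self.noise_max < 1.0):
            raise ValueError("need 0 <= noise_min <= noise_max < 1")
        if not (0.0 < self.max_overlap_fraction < 1.0):
            raise ValueError("max_overlap_fraction must lie in (0, 1)")
        if self.size_max > min(self.n_rows, self.n_cols):
            raise ValueError("size_max exceeds matrix dimensions")
        if self.size_min < 1 or self.size_min > self.size_max:
            raise ValueError("need 1 <= size_min <= size_max")
        if self.n_biclusters < 0 or self.n_replicates < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class SimulatedProfile:
    """A binary matrix plus the ground truth of its planted biclusters."""

    matrix: np.ndarray
    truth_mask: np.ndarray
    planted: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-replicate element-level precision and sensitivity, with medians."""

    precision: tuple[float, ...]
    sensitivity: tuple[float, ...]
    median_precision: float
    median_sensitivity: float
    n_failed: int = 0


def generate_profile(config: SimulationConfig, replicate_seed: int) -> SimulatedProfile:
    """Generate one profile with planted noisy biclusters.

    Planted biclusters are random row/column index subsets placed by
    rejection sampling under the pairwise overlap bound.  Background cells
    are i.i.d. Bernoulli(background_density).  Each planted bicluster is
    filled with 1s and a fraction of its cells, drawn uniformly from
    [noise_min, noise_max], is flipped to 0; where biclusters overlap the
    last-placed one's noise takes precedence, and each bicluster's realized
    zero fraction is kept inside [noise_min, noise_max].
    """
    rng = np.random.default_rng(replicate_seed)
    n_rows, n_cols = config.n_rows, config.n_cols

    # place rectangles by rejection sampling under the overlap bound
    planted: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(config.n_biclusters):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            nr = int(rng.integers(config.size_min, config.size_max + 1))
            nc = int(rng.integers(config.size_min, config.size_max + 1))
            rows = np.sort(rng.choice(n_rows, size=nr, replace=False))
            cols = np.sort(rng.choice(n_cols, size=nc, replace=False))
            ok = True
            for prows, pcols in planted:
                shared = len(np.intersect1d(rows, prows, assume_unique=True)) * len(
                    np.intersect1d(cols, pcols, assume_unique=True)
                )
                bound = config.max_overlap_fraction * min(
                    nr * nc, len(prows) * len(pcols)
                )
                if shared >= bound:
                    ok = False
                    break
            if ok:
                planted.append((rows, cols))
                break
        else:
            raise RuntimeError(
                "could not place planted biclusters under the overlap bound; "
                "use smaller sizes or fewer biclusters"
            )

    matrix = rng.random((n_rows, n_cols)) < config.background_density
    truth_mask = np.zeros((n_rows, n_cols), dtype=bool)
    for rows, cols in planted:
        truth_mask[np.ix_(rows, cols)] = True

    # per-bicluster noise fractions, drawn in placement order
    noise_fracs = rng.uniform(config.noise_min, config.noise_max, len(planted))

    # fill in reverse placement order so the last-placed bicluster's noise
    # draw owns the overlap cells; earlier biclusters adjust only their
    # exclusive cells, which also pins every realized zero fraction inside
    # [noise_min, noise_max]
    claimed = np.zeros((n_rows, n_cols), dtype=bool)
    for idx in range(len(planted) - 1, -1, -1):
        rows, cols = planted[idx]
        cells = len(rows) * len(cols)
        lo = math.ceil(config.noise_min * cells)
        hi = math.floor(config.noise_max * cells)
        target = int(np.clip(round(noise_fracs[idx] * cells), lo, hi))
        sub_claimed = claimed[np.ix_(rows, cols)]
        z_later = int((~matrix[np.ix_(rows, cols)] & sub_claimed).sum())
        free_r, free_c = np.nonzero(~sub_claimed)
        n_free = free_r.size
        need = target - z_later
        if need < 0 or need > n_free:
            need = int(np.clip(need, 0, n_free))
            if not (lo <= z_later + need <= hi):
                raise RuntimeError(
                    "planted-bicluster noise became infeasible under the "
                    "overlap pattern; re-seed or use smaller overlaps"
                )
        sub = matrix[np.ix_(rows, cols)]
        sub[free_r, free_c] = True
        if need:
            pick = rng.choice(n_free, size=need, replace=False)
            sub[free_r[pick], free_c[pick]] = False
        matrix[np.ix_(rows, cols)] = sub
        claimed[np.ix_(rows, cols)] = True

    planted_idx = tuple(
        (tuple(int(r) for r in rows), tuple(int(c) for c in cols))
        for rows, cols in planted
    )
    return SimulatedProfile(matrix=matrix, truth_mask=truth_mask, planted=planted_idx)


def element_precision_sensitivity(
    predicted: Sequence[Bicluster], truth: SimulatedProfile
) -> tuple[float, float]:
    """Element-level precision and sensitivity of predicted biclusters.

    Precision is the fraction of predicted cells that are true (inside some
    planted bicluster); sensitivity is the fraction of true cells covered by
    the predictions.  An empty prediction scores precision 1, sensitivity 0.
    """
    mask = np.zeros_like(truth.truth_mask, dtype=bool)
    for b in predicted:
        if (b.rows and max(b.rows) >= mask.shape[0]) or (
            b.cols and max(b.cols) >= mask.shape[1]
        ):
            raise IndexError("predicted bicluster indices out of range")
        mask[np.ix_(list(b.rows), list(b.cols))] = True
    n_pred = int(mask.sum())
    n_truth = int(truth.truth_mask.sum())
    hit = int((mask & truth.truth_mask).sum())
    precision = 1.0 if n_pred == 0 else hit / n_pred
    sensitivity = 0.0 if n_truth == 0 else hit / n_truth
    return precision, sensitivity


def pbe_algorithm(config: Optional[PbeConfig] = None) -> Callable[[np.ndarray], list[Bicluster]]:
    """Full seed/extend/merge pipeline as a benchmark algorithm."""
    cfg = config or PbeConfig()

    def _run(matrix: np.ndarray) -> list[Bicluster]:
        return run_pbe(matrix, cfg)

    return _run


def bimax_only_algorithm(
    min_rows: int = 10, min_cols: int = 10, max_seeds: int = 20
) -> Callable[[np.ndarray], list[Bicluster]]:
    """Seed enumeration alone (no extension/merge) as a benchmark algorithm."""

    def _run(matrix: np.ndarray) -> list[Bicluster]:
        return bimax_seeds(matrix, min_rows=min_rows, min_cols=min_cols, max_seeds=max_seeds)

    return _run


def run_benchmark(
    config: SimulationConfig,
    algorithm: Callable[[np.ndarray], list[Bicluster]],
) -> BenchmarkResult:
    """Run ``algorithm`` over independently generated replicate profiles.

    Replicate seeds are derived deterministically as ``rng_seed + index``.
    A replicate on which the algorithm raises is excluded from the metric
    lists and counted in ``n_failed``.
    """
    if config.n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    precisions: list[float] = []
    sensitivities: list[float] = []
    n_failed = 0
    for i in range(config.n_replicates):
        prof = generate_profile(config, config.rng_seed + i)
        try:
            predicted = algorithm(prof.matrix)
        except Exception:
            logger.exception("algorithm failed on replicate %d; excluded", i)
            n_failed += 1
            continue
        p, s = element_precision_sensitivity(predicted, prof)
        precisions.append(p)
        sensitivities.append(s)
    if not precisions:
        raise RuntimeError("algorithm failed on every replicate")
    return BenchmarkResult(
        precision=tuple(precisions),
        sensitivity=tuple(sensitivities),
        median_precision=float(np.median(precisions)),
        median_sensitivity=float(np.median(sensitivities)),
        n_failed=n_failed,
    )
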