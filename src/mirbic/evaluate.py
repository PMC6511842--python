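"""Accuracy metrics against gold-standard target sets, network-degree
filtering, and ranked condition-proportion pooling.

Predicted targets of a miRNA are judged within its sequence-predicted
background set: gold positives (GP) are targets with strong experimental
evidence, gold negatives (GN) those with none.  Sensitivity and specificity
are complemented by the *gain in certainty* (sensitivity + specificity - 1),
which is zero for the trivial predictor that calls the whole background.
Predictions can be sharpened by keeping only genes with at least k
functional interactions among the predicted set, and bicluster targets can
be pooled in order of how specific their conditions are to a keyword
(e.g. a cancer type), tracing a TPR/FPR curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .core import Bicluster
from .data_io import InteractionNetwork
from .profile import MirProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldStandard:
    """Disjoint gold-positive and gold-negative gene sets within a background."""

    background: frozenset[str]
    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        background = frozenset(self.background)
        gp = frozenset(self.positives)
        gn = frozenset(self.negatives)
        if not gp <= background:
            raise ValueError("positives must be a subset of the background")
        if not gn <= background:
            raise ValueError("negatives must be a subset of the background")
        if gp & gn:
            raise ValueError("positives and negatives must be disjoint")
        object.__setattr__(self, "background", background)
        object.__setattr__(self, "positives", gp)
        object.__setattr__(self, "negatives", gn)


@dataclass(frozen=True)
class EvalMetrics:
    """Sensitivity, specificity and their gain over the background predictor."""

    sensitivity: float
    specificity: float

    @property
    def gain(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def eligible_mirna(
    gs: GoldStandard, min_gp: int = 30, min_gp_fraction: float = 0.05
) -> bool:
    """Whether a miRNA has enough validated positives to be evaluated.

    True iff it has strictly more than ``min_gp`` gold positives and their
    fraction of the background set is at least ``min_gp_fraction``.
    """
    if not gs.background:
        raise ValueError("background must be non-empty")
    n_gp = len(gs.positives)
    return n_gp > min_gp and n_gp / len(gs.background) >= min_gp_fraction


def score_predictions(predicted: Iterable[str], gs: GoldStandard) -> EvalMetrics:
    """Sensitivity, specificity and gain of a predicted target set.

    Genes outside the background are discarded with a warning.  Sensitivity
    is the GP fraction recovered, specificity the GN fraction excluded;
    predicting the whole background scores gain 0.
    """
    if not gs.positives or not gs.negatives:
        raise ValueError("gold standard must have non-empty GP and GN sets")
    predicted = set(predicted)
    outside = predicted - gs.background
    if outside:
        logger.warning(
            "%d predicted genes outside the background were discarded", len(outside)
        )
        predicted &= gs.background
    sensitivity = len(predicted & gs.positives) / len(gs.positives)
    specificity = len(gs.negatives - predicted) / len(gs.negatives)
    return EvalMetrics(sensitivity=sensitivity, specificity=specificity)


def network_degree_filter(
    predicted: Iterable[str], network: InteractionNetwork, k: int
) -> frozenset[str]:
    """Keep predicted genes with >= k interactions among the predicted set.

    The degree is computed on the subgraph induced by the predicted genes;
    k = 0 returns the input unchanged.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    predicted = frozenset(predicted)
    if k == 0:
        return predicted
    graph = nx.Graph()
    graph.add_nodes_from(predicted)
    for (a, b), score in network.edges.items():
        if a in predicted and b in predicted:
            graph.add_edge(a, b, weight=score)
    return frozenset(g for g in predicted if graph.degree[g] >= k)


def condition_fraction(
    bicluster: Bicluster,
    profile: MirProfile,
    condition_labels: Mapping[str, str],
    keyword: str,
) -> float:
    """Fraction of a bicluster's conditions whose label matches the keyword
    (case-insensitive substring)."""
    keyword = keyword.lower()
    labels = []
    for r in bicluster.rows:
        cond = profile.condition_ids[r]
        if cond not in condition_labels:
            raise KeyError(f"no label for condition {cond!r}")
        labels.append(condition_labels[cond])
    hits = sum(keyword in lab.lower() for lab in labels)
    return hits / len(labels)


def pooled_condition_curve(
    biclusters: Sequence[tuple[Bicluster, MirProfile]],
    condition_labels: Mapping[str, str],
    keyword: str,
    gs: GoldStandard,
    min_fraction: float = 0.30,
) -> list[tuple[float, float]]:
    """TPR/FPR trace of pooling bicluster targets by condition specificity.

    Each entry pairs a bicluster with the profile it was discovered in (up-
    and down-direction biclusters may be mixed).  Biclusters whose fraction
    of keyword-matching condition rows is below ``min_fraction`` are
    dropped; the rest are sorted by that fraction (descending; ties favour
    the larger bicluster, then input order) and their gene sets are
    cumulatively pooled.  After each pooling step the pool's TPR
    (|pool ∩ GP| / |GP|) and FPR (|pool ∩ GN| / |GN|) are emitted, so both
    coordinates are non-decreasing along the curve.
    """
    if not gs.positives or not gs.negatives:
        raise ValueError("gold standard must have non-empty GP and GN sets")
    scored = []
    for order, (b, prof) in enumerate(biclusters):
        frac = condition_fraction(b, prof, condition_labels, keyword)
        if frac >= min_fraction:
            scored.append((-frac, -b.n_cells, order, b, prof))
    scored.sort(key=lambda t: t[:3])
    pool: set[str] = set()
    curve: list[tuple[float, float]] = []
    for _, _, _, b, prof in scored:
        pool.update(prof.gene_ids[c] for c in b.cols)
        tpr = len(pool & gs.positives) / len(gs.positives)
        fpr = len(pool & gs.negatives) / len(gs.negatives)
        curve.append((tpr, fpr))
    return curve
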