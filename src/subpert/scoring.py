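"""Degree-weighted Liptak-Stouffer perturbation score for sub-pathways.

For a subgraph Q with edge set I' of a pathway, each gene g carries the
degree d_Q(g) = number of edges of I' incident on g, and the score is

    z(Q) = sum_g d_Q(g) * z(g) / sqrt(sum_g d_Q(g)^2).

When the per-gene z-scores are iid standard normal, z(Q) is again standard
normal for any fixed Q, so scores of differently-shaped subgraphs are on a
common scale.  The score depends only on the edge subset: genes of degree 0
contribute nothing, so a subgraph is represented canonically by its edges,
and z of the empty edge set is defined as 0 (the null expectation).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

from .diffexpr import GeneScoreMap
from .exceptions import MissingScoreError
from .io import Edge, Pathway

ScoreSource = Union[GeneScoreMap, Mapping[str, float]]


@dataclass(frozen=True)
class ScoredSubgraph:
    """An edge subset of a pathway together with its perturbation score.

    The node set is implied by the edges; degree-0 genes carry zero weight
    and are not stored.
    """

    parent_name: str
    edges: frozenset[Edge]
    score: float

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def __len__(self) -> int:
        return len(self.edges)


def _z_lookup(scores: ScoreSource, gene: str) -> float:
    if isinstance(scores, GeneScoreMap):
        return scores.z(gene)
    try:
        return float(scores[gene])
    except KeyError:
        raise MissingScoreError(gene) from None


def subgraph_degrees(edges: Iterable[Edge]) -> dict[str, int]:
    """Per-gene edge counts d_Q(g); the degree sum is twice the edge count."""
    deg: Counter[str] = Counter()
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return dict(deg)


def perturbation_score(edges: Iterable[Edge], scores: ScoreSource) -> float:
    """z(Q) for the given edge set; 0.0 for the empty set.

    ``scores`` is a :class:`GeneScoreMap` or a plain gene -> z mapping.
    Raises :class:`MissingScoreError` if an endpoint is unscored (restrict
    the pathway to measured genes first).
    """
    deg = subgraph_degrees(edges)
    if not deg:
        return 0.0
    num = 0.0
    den = 0
    for g, d in deg.items():
        num += d * _z_lookup(scores, g)
        den += d * d
    return num / math.sqrt(den)


def full_pathway_score(pathway: Pathway, scores: ScoreSource) -> float:
    """z(P) of the complete (measured) pathway edge set."""
    return perturbation_score(pathway.interactions, scores)
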