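"""Synthetic pathways and case/control expression with a planted perturbed
sub-pathway.

The generator emulates the statistical shape of a curated-pathway x
case-control-microarray study: a random simple interaction graph, Gaussian
expression noise, and a connected subset of interactions whose endpoint
genes receive a mean shift (in within-group standard-deviation units) in
the case class.  Defaults describe a moderately sized pathway (60 genes,
100 interactions), a quarter of the interactions planted, a 2.5-SD shift
and 15 samples per class.  Genes, not edges, carry the perturbation,
because expression is a node-level signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import Edge, ExpressionMatrix, Pathway, PhenotypeLabels, canonical_edge

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``effect_size`` is the case-class mean shift of perturbed genes in units
    of ``background_sd``; ``n_background_genes`` adds measured genes outside
    the pathway (useful as extra universe members for permutation tests).
    """

    n_genes: int = 60
    n_edges: int = 100
    planted_edge_fraction: float = 0.25
    effect_size: float = 2.5
    n_case: int = 15
    n_control: int = 15
    background_sd: float = 1.0
    n_background_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigurationError("need at least 2 genes")
        max_edges = self.n_genes * (self.n_genes - 1) // 2
        if not 1 <= self.n_edges <= max_edges:
            raise ConfigurationError(
                f"n_edges must be in [1, {max_edges}] for {self.n_genes} genes"
            )
        if not 0.0 < self.planted_edge_fraction <= 1.0:
            raise ConfigurationError("planted_edge_fraction must be in (0, 1]")
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigurationError("need >=2 samples per class")
        if self.background_sd <= 0:
            raise ConfigurationError("background_sd must be positive")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_pathway(config: SyntheticConfig) -> Pathway:
    """Uniform random simple graph with exactly ``n_edges`` interactions on
    ``n_genes`` labeled genes; deterministic per seed."""
    g = nx.gnm_random_graph(config.n_genes, config.n_edges, seed=config.seed)
    edges = frozenset(canonical_edge(_gene_name(u), _gene_name(v)) for u, v in g.edges)
    genes = frozenset(_gene_name(i) for i in range(config.n_genes))
    return Pathway(name=f"synthetic-{config.seed}", genes=genes, interactions=edges)


def plant_perturbation(
    pathway: Pathway, config: SyntheticConfig, rng: np.random.Generator
) -> frozenset[Edge]:
    """Choose ceil(fraction * |I|) interactions by randomized breadth-first
    growth from a random seed interaction.

    Growth prefers interactions adjacent to the already-planted node set so
    the planted sub-pathway is connected where the graph allows; if the
    reachable component is exhausted, arbitrary remaining interactions are
    added.
    """
    edges = pathway.sorted_interactions()
    target = math.ceil(config.planted_edge_fraction * len(edges))
    first = edges[int(rng.integers(len(edges)))]
    planted: set[Edge] = {first}
    frontier_nodes: set[str] = set(first)
    remaining = [e for e in edges if e != first]
    while len(planted) < target:
        adjacent = [e for e in remaining if e[0] in frontier_nodes or e[1] in frontier_nodes]
        pool = adjacent if adjacent else remaining
        pick = pool[int(rng.integers(len(pool)))]
        planted.add(pick)
        frontier_nodes.update(pick)
        remaining.remove(pick)
    return frozenset(planted)


def generate_expression(
    pathway: Pathway,
    planted: frozenset[Edge],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, PhenotypeLabels]:
    """Gaussian case/control expression with a mean shift on planted genes.

    Control samples are N(0, sd) for every gene; case samples are
    N(effect_size * sd, sd) for genes incident to a planted interaction and
    N(0, sd) otherwise.  Background genes (outside the pathway) are always
    unshifted.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    perturbed = {g for e in planted for g in e}
    genes = sorted(pathway.genes) + [
        f"BG{i:04d}" for i in range(config.n_background_genes)
    ]
    samples = [f"case_{i:03d}" for i in range(config.n_case)] + [
        f"ctrl_{i:03d}" for i in range(config.n_control)
    ]
    sd = config.background_sd
    values = rng.normal(0.0, sd, size=(len(genes), len(samples)))
    shift = config.effect_size * sd
    for gi, g in enumerate(genes):
        if g in perturbed:
            values[gi, : config.n_case] += shift
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    labels = PhenotypeLabels(
        assignments={
            s: (CASE if s.startswith("case") else CONTROL) for s in samples
        }
    )
    return expr, labels


@dataclass(frozen=True)
class SyntheticDataset:
    """One generated study: pathway, planted truth, expression and labels."""

    config: SyntheticConfig
    pathway: Pathway
    planted: frozenset[Edge]
    expression: ExpressionMatrix
    labels: PhenotypeLabels


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate pathway, planted sub-pathway and expression in one call,
    all driven by ``config.seed``."""
    pathway = generate_pathway(config)
    rng = np.random.default_rng(config.seed)
    planted = plant_perturbation(pathway, config, rng)
    expr, labels = generate_expression(pathway, planted, config, rng)
    return SyntheticDataset(
        config=config, pathway=pathway, planted=planted,
        expression=expr, labels=labels,
    )
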