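"""Permutation significance of perturbed sub-pathways and FDR control.

The perturbation score of the best sub-pathway cannot be referred to the
standard normal because the search maximises over subgraphs and because
gene z-scores need not be independent.  Significance is therefore assessed
against a graph-isomorphic null: the pathway's genes are replaced by genes
drawn uniformly without replacement from a user-defined *universe* (default:
all measured genes), preserving the interaction structure exactly, and the
same annealing search is run on each relabeled pathway.  The empirical
p-value is the fraction of null trials whose best score strictly exceeds the
observed best score (a pseudocount variant ``(count+1)/(k+1)`` avoids exact
zeros).  Benjamini-Hochberg step-up adjustment controls the FDR across the
pathway x condition family.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffexpr import GeneScoreMap, compute_gene_scores
from .exceptions import ConfigurationError
from .io import ExpressionMatrix, Pathway, PhenotypeLabels, canonical_edge
import pandas as pd

from .search import AnnealParams, anneal_max_subgraph


@dataclass(frozen=True)
class Universe:
    """Gene pool from which null relabelings are drawn.

    Every member must carry a differential-expression score, and the pool
    must be at least as large as any pathway tested against it.
    """

    gene_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_scores(cls, scores: GeneScoreMap) -> "Universe":
        return cls(gene_ids=frozenset(scores.scores.keys()))


@dataclass(frozen=True)
class NullDistribution:
    """k best-subgraph scores from isomorphic relabelings of one pathway."""

    scores: tuple[float, ...]
    k: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.scores) != self.k:
            raise ConfigurationError("null length disagrees with k")


def relabel_pathway(
    pathway: Pathway, universe: Universe, rng: np.random.Generator
) -> Pathway:
    """Isomorphic relabeling: map the pathway's genes bijectively onto
    distinct genes drawn uniformly without replacement from the universe.

    Edge structure (and hence the degree multiset) is preserved exactly.
    """
    pool = sorted(universe.gene_ids)
    originals = sorted(pathway.genes)
    if len(pool) < len(originals):
        raise ConfigurationError(
            f"universe has {len(pool)} genes; pathway needs {len(originals)}"
        )
    picks = rng.choice(len(pool), size=len(originals), replace=False)
    mapping = {g: pool[int(i)] for g, i in zip(originals, picks)}
    edges = frozenset(
        canonical_edge(mapping[u], mapping[v]) for u, v in pathway.interactions
    )
    return Pathway(
        name=pathway.name,
        genes=frozenset(mapping.values()),
        interactions=edges,
    )


def build_null(
    pathway: Pathway,
    scores: GeneScoreMap,
    universe: Universe,
    k: int,
    params: AnnealParams,
    seed: int,
) -> NullDistribution:
    """k relabel-and-anneal trials with the same annealing parameters as the
    observed pathway; per-trial RNG streams derive deterministically from
    ``seed`` and the trial index."""
    missing = [g for g in universe.gene_ids if g not in scores]
    if missing:
        raise ConfigurationError(
            f"{len(missing)} universe gene(s) lack scores, e.g. {sorted(missing)[:3]}"
        )
    vals = []
    for i in range(k):
        rng = np.random.default_rng([seed, i])
        relabeled = relabel_pathway(pathway, universe, rng)
        sub_seed = int(rng.integers(2**31))
        best = anneal_max_subgraph(relabeled, scores, replace(params, seed=sub_seed))
        vals.append(best.score)
    return NullDistribution(scores=tuple(vals), k=k, seed=seed)


def empirical_pvalue(
    observed: float, null: NullDistribution, pseudocount: bool = False
) -> float:
    """Fraction of null scores strictly exceeding the observed score.

    With ``pseudocount=True`` returns (count+1)/(k+1), bounding the p-value
    away from zero at finite k.
    """
    count = int(np.sum(np.asarray(null.scores) > observed))
    if pseudocount:
        return (count + 1) / (null.k + 1)
    return count / null.k


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def null_calibration_pvalues(
    pathway: Pathway,
    universe: Universe,
    k: int,
    n_trials: int,
    seed: int,
    *,
    n_case: int = 10,
    n_control: int = 10,
    params: AnnealParams | None = None,
    pseudocount: bool = False,
) -> np.ndarray:
    """Empirical p-values from the full pipeline on global-null data.

    Each trial draws fresh iid N(0,1) expression for every universe gene in
    both classes (no true case/control difference), scores the observed
    pathway's best subgraph, builds a k-trial null and records the empirical
    p-value.  Under this exchangeable null the p-values should be
    approximately uniform.
    """
    if params is None:
        params = AnnealParams()
    if not pathway.genes <= universe.gene_ids:
        raise ConfigurationError("pathway genes must be contained in the universe")
    genes = sorted(universe.gene_ids)
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_control)
    ]
    labels = PhenotypeLabels(
        assignments={s: ("case" if s.startswith("case") else "control") for s in samples}
    )
    pvals = np.empty(n_trials)
    for t in range(n_trials):
        rng = np.random.default_rng([seed, t])
        expr = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(len(genes), len(samples))),
                index=genes,
                columns=samples,
            )
        )
        gene_scores = compute_gene_scores(expr, labels, "case", "control")
        obs_seed = int(rng.integers(2**31))
        observed = anneal_max_subgraph(
            pathway, gene_scores, replace(params, seed=obs_seed)
        )
        null = build_null(
            pathway, gene_scores, universe, k, params,
            seed=int(rng.integers(2**31)),
        )
        pvals[t] = empirical_pvalue(observed.score, null, pseudocount=pseudocount)
    return pvals


def null_calibration_check(
    pathway: Pathway,
    universe: Universe,
    k: int,
    n_trials: int,
    seed: int,
    **kwargs,
) -> float:
    """Kolmogorov-Smirnov distance of global-null empirical p-values from
    the uniform distribution (smaller is better calibrated)."""
    pvals = null_calibration_pvalues(pathway, universe, k, n_trials, seed, **kwargs)
    return float(stats.kstest(pvals, "uniform").statistic)
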