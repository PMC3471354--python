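"""Screen orchestration: many pathways x conditions, leave-one-out
robustness, and the union of perturbed interactions per pathway.

``run_screen`` ties the modules together: per pathway x contrast it scores
genes, restricts the pathway to measured genes, computes the full-pathway
score, anneals for the best sub-pathway, builds the relabeling null, and
finally applies one joint Benjamini-Hochberg correction across every
retained pair.  Per-pair seeds derive from the master seed and a stable
hash of (pathway, condition), so adding a pathway never changes another
pair's result.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .diffexpr import GeneScoreMap, compute_gene_scores
from .exceptions import (
    ConfigurationError,
    EmptyPathwayError,
    InsufficientSamplesError,
    SubpertError,
)
from .io import (
    Edge,
    ExpressionMatrix,
    Pathway,
    PhenotypeLabels,
    ScreenResult,
    load_universe,
    restrict_to_measured,
)
from .scoring import full_pathway_score
from .search import AnnealParams, anneal_max_subgraph
from .significance import Universe, bh_adjust, build_null, empirical_pvalue

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Screen-level knobs: contrast(s), annealing schedule, permutation
    count, FDR level and optional universe file.

    ``contrasts`` lists (case, control) label pairs; when None, the single
    (case_label, control_label) pair is used.  BH correction spans all
    pathway x contrast pairs jointly unless ``bh_per_condition``.
    """

    case_label: str
    control_label: str
    anneal: AnnealParams = field(default_factory=AnnealParams)
    k_permutations: int = 200
    alpha: float = 0.05
    universe_path: str | None = None
    output_dir: str | None = None
    contrasts: tuple[tuple[str, str], ...] | None = None
    pseudocount: bool = False
    bh_per_condition: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.k_permutations < 1:
            raise ConfigurationError("k_permutations must be >= 1")

    def contrast_list(self) -> list[tuple[str, str]]:
        if self.contrasts is not None:
            return list(self.contrasts)
        return [(self.case_label, self.control_label)]


@dataclass(frozen=True)
class RobustnessRecord:
    """Leave-one-out robustness of one pathway x condition pair:
    the fraction of single-case-sample-removed reruns whose significance
    status at alpha matches the full-data status."""

    pathway_name: str
    condition: str
    significant_full: bool
    agreement_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.agreement_fraction <= 1.0:
            raise ValueError("agreement_fraction must lie in [0, 1]")


def pair_seed(master_seed: int, pathway_name: str, condition: str) -> int:
    """Stable per-pair seed below 2^31."""
    h = zlib.crc32(f"{pathway_name}|{condition}".encode())
    return (master_seed * 1000003 + h) % (2**31)


def _analyse_pair(
    pathway: Pathway,
    expr: ExpressionMatrix,
    gene_scores: GeneScoreMap,
    universe: Universe,
    config: ScreenConfig,
    condition: str,
) -> ScreenResult:
    """One pathway x condition analysis up to the raw empirical p-value
    (p_adjusted is filled in by the caller after BH)."""
    measured = restrict_to_measured(pathway, expr)
    seed = pair_seed(config.seed, pathway.name, condition)
    params = replace(config.anneal, seed=seed)
    z_full = full_pathway_score(measured, gene_scores)
    best = anneal_max_subgraph(measured, gene_scores, params)
    null = build_null(
        measured, gene_scores, universe, config.k_permutations, config.anneal,
        seed=seed + 1,
    )
    p_emp = empirical_pvalue(best.score, null, pseudocount=config.pseudocount)
    return ScreenResult(
        pathway_name=pathway.name,
        condition=condition,
        z_best=best.score,
        z_full=z_full,
        p_empirical=p_emp,
        p_adjusted=float("nan"),
        best_edges=best.edges,
        k_permutations=config.k_permutations,
        seed=seed,
    )


def _resolve_universe(config: ScreenConfig, gene_scores: GeneScoreMap) -> Universe:
    if config.universe_path is None:
        return Universe.from_scores(gene_scores)
    genes = load_universe(config.universe_path)
    unscored = {g for g in genes if g not in gene_scores}
    if unscored:
        log.warning(
            "universe: dropping %d gene(s) without expression", len(unscored)
        )
        genes = genes - unscored
    if not genes:
        raise ConfigurationError("universe has no measured genes")
    return Universe(gene_ids=frozenset(genes))


def run_screen(
    pathways: Sequence[Pathway],
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    config: ScreenConfig,
) -> list[ScreenResult]:
    """Screen every pathway against every contrast.

    Pairs whose pathway loses all interactions after restriction to
    measured genes are skipped (logged) and excluded from the BH family.
    Raises :class:`SubpertError` if every pair is skipped.
    """
    results: list[ScreenResult] = []
    families: list[list[int]] = []  # index groups for BH
    for case_label, control_label in config.contrast_list():
        gene_scores = compute_gene_scores(expr, labels, case_label, control_label)
        universe = _resolve_universe(config, gene_scores)
        condition = case_label
        family: list[int] = []
        for pathway in pathways:
            try:
                res = _analyse_pair(
                    pathway, expr, gene_scores, universe, config, condition
                )
            except (EmptyPathwayError, ConfigurationError) as exc:
                log.warning("skipping %s x %s: %s", pathway.name, condition, exc)
                continue
            family.append(len(results))
            results.append(res)
            log.info(
                "%s x %s: z_full=%.3f z_best=%.3f p=%.4g",
                pathway.name, condition, res.z_full, res.z_best, res.p_empirical,
            )
        families.append(family)
    if not results:
        raise SubpertError("screen produced no results: every pair was skipped")

    groups = families if config.bh_per_condition else [list(range(len(results)))]
    for group in groups:
        if not group:
            continue
        adjusted = bh_adjust([results[i].p_empirical for i in group])
        for i, p_adj in zip(group, adjusted):
            results[i] = replace(results[i], p_adjusted=float(p_adj))
    return results


def leave_one_out_robustness(
    pathway: Pathway,
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    config: ScreenConfig,
) -> RobustnessRecord:
    """Leave-one-out stability of one pair's significance call.

    Each case sample is removed in turn and the full pair analysis
    (gene scores, annealing, permutation null, raw empirical p-value) is
    recomputed; the record reports the fraction of reruns whose
    significance status at ``config.alpha`` matches the full-data status.
    Only case samples are removed.
    """
    case_label, control_label = config.contrast_list()[0]
    assignments = labels.resolve(expr.sample_ids)
    case_ids = [s for s in expr.sample_ids if assignments.get(s) == case_label]
    if len(case_ids) < 3:
        raise InsufficientSamplesError(
            f"leave-one-out needs >=3 case samples, got {len(case_ids)}"
        )

    def _status(e: ExpressionMatrix) -> bool:
        gs = compute_gene_scores(e, labels, case_label, control_label)
        uni = _resolve_universe(config, gs)
        res = _analyse_pair(pathway, e, gs, uni, config, case_label)
        return res.p_empirical <= config.alpha

    significant_full = _status(expr)
    matches = sum(
        _status(expr.drop_samples([sid])) == significant_full for sid in case_ids
    )
    return RobustnessRecord(
        pathway_name=pathway.name,
        condition=case_label,
        significant_full=significant_full,
        agreement_fraction=matches / len(case_ids),
    )


def perturbed_interaction_union(
    results: Sequence[ScreenResult],
    pathway: Pathway,
    p_threshold: float,
) -> tuple[int, float]:
    """Union of best-sub-pathway interactions over all significant
    conditions of one pathway.

    Returns ``(count, fraction)`` where fraction is the union size over the
    pathway's measured interaction count (in [0, 1]).  Non-decreasing in
    ``p_threshold``.
    """
    for r in results:
        if r.pathway_name != pathway.name:
            raise ConfigurationError(
                f"result for {r.pathway_name!r} does not match pathway {pathway.name!r}"
            )
    union: set[Edge] = set()
    for r in results:
        if r.p_adjusted <= p_threshold:
            union |= r.best_edges
    count = len(union)
    fraction = count / len(pathway.interactions) if pathway.interactions else 0.0
    return count, fraction
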