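"""Per-gene differential expression: Welch t-test p-values and z-scores.

Each gene's case/control expression is compared with the two-sided Welch
(unequal-variance) t-test; the p-value is mapped to a z-score through the
upper-tail standard-normal quantile, z(g) = Phi^-1(1 - p(g)).  No
significance cut-off is applied: every measured gene keeps its score, since
perturbation may only be visible at the level of gene sets.

p-values are clamped to [EPS, 1 - EPS] before the quantile transform so that
z is always finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, InsufficientSamplesError, MissingScoreError
from .io import ExpressionMatrix, PhenotypeLabels

log = logging.getLogger(__name__)

#: p-value clamp bound; keeps Phi^-1 finite without disturbing any
#: realistically attainable p-value.
EPS = 1e-15


class GeneScore(NamedTuple):
    p_value: float
    z: float


@dataclass(frozen=True)
class GeneScoreMap:
    """Per-gene (p-value, z-score) pairs for one case/control contrast."""

    scores: Mapping[str, GeneScore]
    case_label: str
    control_label: str
    n_case: int
    n_control: int

    def __contains__(self, gene: str) -> bool:
        return gene in self.scores

    def __len__(self) -> int:
        return len(self.scores)

    def z(self, gene: str) -> float:
        try:
            return self.scores[gene].z
        except KeyError:
            raise MissingScoreError(gene) from None

    def p(self, gene: str) -> float:
        try:
            return self.scores[gene].p_value
        except KeyError:
            raise MissingScoreError(gene) from None

    def z_map(self) -> dict[str, float]:
        return {g: s.z for g, s in self.scores.items()}


def welch_t_pvalue(case_values, control_values) -> float:
    """Two-sided Welch t-test p-value with Welch-Satterthwaite df.

    Degenerate rule: if both groups have zero variance the p-value is 1 for
    equal means and ``EPS`` (the clamp floor) otherwise.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientSamplesError(
            f"need >=2 values per group, got {a.size} and {b.size}"
        )
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else EPS
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def pvalue_to_zscore(p: float) -> float:
    """Upper-tail normal quantile z = Phi^-1(1 - p), clamped to stay finite.

    Monotone decreasing in p; p > 0.5 yields negative z.
    """
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    return float(stats.norm.isf(np.clip(p, EPS, 1.0 - EPS)))


def compute_gene_scores(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    case_label: str,
    control_label: str,
) -> GeneScoreMap:
    """Welch-test every gene in ``expr`` for the given contrast.

    Vectorised across genes.  Raises :class:`ConfigurationError` when either
    class has fewer than two samples.
    """
    assignments = labels.resolve(expr.sample_ids)
    case_ids = [s for s in expr.sample_ids if assignments.get(s) == case_label]
    ctrl_ids = [s for s in expr.sample_ids if assignments.get(s) == control_label]
    if len(case_ids) < 2:
        raise ConfigurationError(
            f"class {case_label!r} has {len(case_ids)} sample(s); need >=2"
        )
    if len(ctrl_ids) < 2:
        raise ConfigurationError(
            f"class {control_label!r} has {len(ctrl_ids)} sample(s); need >=2"
        )

    case = expr.data[case_ids].to_numpy(dtype=float)
    ctrl = expr.data[ctrl_ids].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)

    # degenerate rows: both groups constant
    flat = (case.var(axis=1, ddof=1) == 0.0) & (ctrl.var(axis=1, ddof=1) == 0.0)
    if flat.any():
        same = np.isclose(case.mean(axis=1), ctrl.mean(axis=1), rtol=0, atol=0)
        p[flat & same] = 1.0
        p[flat & ~same] = EPS
        log.info("%d gene(s) constant in both groups", int(flat.sum()))

    p = np.clip(p, EPS, 1.0 - EPS)
    z = stats.norm.isf(p)
    scores = {
        gene: GeneScore(float(pv), float(zv))
        for gene, pv, zv in zip(expr.gene_ids, p, z)
    }
    return GeneScoreMap(
        scores=scores,
        case_label=case_label,
        control_label=control_label,
        n_case=len(case_ids),
        n_control=len(ctrl_ids),
    )
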