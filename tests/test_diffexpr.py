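import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from subpert import (
    ConfigurationError,
    ExpressionMatrix,
    InsufficientSamplesError,
    PhenotypeLabels,
    compute_gene_scores,
    pvalue_to_zscore,
    welch_t_pvalue,
)
from subpert.diffexpr import EPS


def _welch_oracle(a, b):
    """Independent Welch p-value: t statistic and Welch-Satterthwaite df by
    hand, two-sided tail by numerical integration of the t density."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))

    def pdf(x):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return 2 * tail


class TestWelch:
    def test_identical_groups_give_p_one(self):
        assert welch_t_pvalue([1, 2, 3], [1, 2, 3]) == 1.0

    def test_matches_numerical_integration_oracle(self):
        # t = 4/sqrt(2/3) ~ 4.899 with Welch df = 4 -> p ~ 0.0080
        p = welch_t_pvalue([5, 6, 7], [1, 2, 3])
        assert p == pytest.approx(_welch_oracle([5, 6, 7], [1, 2, 3]), rel=1e-8)
        assert p == pytest.approx(0.0080, abs=5e-4)

    @pytest.mark.parametrize(
        "case, control, expected",
        [([0, 0], [0, 0], 1.0), ([1, 1], [1, 1], 1.0), ([2, 2], [0, 0], EPS)],
    )
    def test_degenerate_zero_variance(self, case, control, expected):
        assert welch_t_pvalue(case, control) == expected

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientSamplesError):
            welch_t_pvalue([1.0], [1, 2, 3])

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(1, 2, size=9)
        assert welch_t_pvalue(a, b) == pytest.approx(welch_t_pvalue(b, a), rel=1e-12)


class TestPvalueToZscore:
    def test_median_maps_to_zero(self):
        assert pvalue_to_zscore(0.5) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p, z", [(0.05, 1.6449), (0.975, -1.9600)])
    def test_against_bisection_oracle(self, p, z):
        # oracle: bisect Phi(x) = 1 - p using the error function directly
        lo, hi = -10.0, 10.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if 0.5 * (1 + math.erf(mid / math.sqrt(2))) < 1 - p:
                lo = mid
            else:
                hi = mid
        assert pvalue_to_zscore(p) == pytest.approx((lo + hi) / 2, abs=1e-9)
        assert pvalue_to_zscore(p) == pytest.approx(z, abs=1e-4)

    def test_monotone_decreasing(self):
        ps = np.linspace(0.01, 0.99, 25)
        zs = [pvalue_to_zscore(p) for p in ps]
        assert all(a > b for a, b in zip(zs, zs[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            pvalue_to_zscore(1.5)

    def test_extremes_stay_finite(self):
        assert math.isfinite(pvalue_to_zscore(0.0))
        assert math.isfinite(pvalue_to_zscore(1.0))


class TestComputeGeneScores:
    def test_basic_map(self, small_expression):
        expr, labels = small_expression
        gsm = compute_gene_scores(expr, labels, "tumor", "normal")
        assert len(gsm) == 3
        assert gsm.n_case == 3 and gsm.n_control == 3
        assert all(math.isfinite(gsm.z(g)) for g in expr.gene_ids)
        # the shifted gene must be by far the most significant
        assert gsm.p("g1") < min(gsm.p("g2"), gsm.p("g3"))
        # z = Phi^-1(1 - p) consistency for every entry
        for g in expr.gene_ids:
            assert gsm.z(g) == pytest.approx(float(stats.norm.isf(gsm.p(g))), rel=1e-9)

    def test_missing_class_is_configuration_error(self, small_expression):
        expr, labels = small_expression
        with pytest.raises(ConfigurationError):
            compute_gene_scores(expr, labels, "absent", "normal")

    def test_constant_gene_keeps_finite_z(self):
        data = pd.DataFrame(
            [[1.0] * 6, [0, 1, 2, 3, 4, 5]],
            index=["flat", "var"],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = PhenotypeLabels(
            assignments={f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        )
        gsm = compute_gene_scores(ExpressionMatrix(data), labels, "a", "b")
        assert gsm.p("flat") == 1.0 - EPS  # clamped from p = 1
        assert math.isfinite(gsm.z("flat"))

    def test_label_swap_preserves_pvalues(self, small_expression):
        expr, labels = small_expression
        ab = compute_gene_scores(expr, labels, "tumor", "normal")
        ba = compute_gene_scores(expr, labels, "normal", "tumor")
        for g in expr.gene_ids:
            assert ab.p(g) == pytest.approx(ba.p(g), rel=1e-12)

    def test_global_null_pvalues_uniform(self):
        """With both groups drawn iid from one normal, per-gene p-values are
        uniform on (0,1) (KS at alpha = 0.01, 5000 genes, fixed seed)."""
        rng = np.random.default_rng(2024)
        n_genes = 5000
        data = pd.DataFrame(
            rng.normal(size=(n_genes, 12)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(12)],
        )
        labels = PhenotypeLabels(
            assignments={f"s{i}": ("a" if i < 6 else "b") for i in range(12)}
        )
        gsm = compute_gene_scores(ExpressionMatrix(data), labels, "a", "b")
        ps = [gsm.p(g) for g in data.index]
        assert stats.kstest(ps, "uniform").pvalue > 0.01
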