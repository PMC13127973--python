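"""Association statistics against independent textbook-formula oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from textmarkers import (correlation_matrix, holm_bonferroni, moderated_regression,
                         pearson_ci, welch_t)

# frozen fixture vectors (n = 20)
FX = [2.1, 3.4, 1.9, 4.2, 5.5, 2.8, 3.3, 4.9, 1.2, 3.7,
      2.6, 4.4, 5.1, 2.2, 3.9, 1.8, 4.7, 3.1, 2.4, 5.0]
FY = [1.0, 2.9, 2.2, 3.8, 4.9, 2.1, 3.5, 4.1, 1.9, 2.8,
      3.1, 4.8, 4.2, 2.0, 3.3, 2.5, 4.0, 2.7, 2.9, 4.6]

GX = [4.1, 5.2, 3.8, 6.0, 4.9, 5.5, 4.4, 5.8, 4.0, 5.1]
GY = [3.2, 4.1, 2.9, 3.8, 3.5, 4.4, 3.0, 3.9, 3.3, 4.2]


def pearson_oracle(x, y, alpha=0.05):
    """Direct textbook formulas: product-moment r, t-test p, Fisher-z CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    z = 0.5 * math.log((1 + r) / (1 - r))
    half = sps.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    lo, hi = math.tanh(z - half), math.tanh(z + half)
    return r, p, lo, hi


def welch_oracle(x, y):
    """Direct Welch/Satterthwaite/pooled-d formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), df)
    sp = math.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    d = (x.mean() - y.mean()) / sp
    return t, df, p, d


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])
        x, y = x - x.mean(), y - y.mean()
        assert pearson_ci(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self):
        res = pearson_ci(FX, FY)
        r, p, lo, hi = pearson_oracle(FX, FY)
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.ci_low == pytest.approx(lo, abs=1e-10)
        assert res.ci_high == pytest.approx(hi, abs=1e-10)
        assert res.ci_low <= res.r <= res.ci_high

    def test_pairwise_deletion(self):
        x = FX + [float("nan")]
        y = FY + [3.0]
        assert pearson_ci(x, y).n == 20

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_ci([1.0] * 10, FY[:10])

    def test_fisher_ci_coverage_under_null(self, rng):
        """~95% of null 95% CIs cover zero (2000 simulated datasets)."""
        covered = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            res = pearson_ci(x, y)
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered / n_sim == pytest.approx(0.95, abs=0.02)


class TestWelch:
    def test_identical_groups_null(self):
        res = welch_t(GX, GX)
        assert res.t == pytest.approx(0.0) and res.d == pytest.approx(0.0)

    def test_antisymmetry_under_group_swap(self):
        a, b = welch_t(GX, GY), welch_t(GY, GX)
        assert a.t == pytest.approx(-b.t)
        assert a.d == pytest.approx(-b.d)
        assert a.p == pytest.approx(b.p)

    def test_matches_direct_formula_oracle(self):
        res = welch_t(GX, GY)
        t, df, p, d = welch_oracle(GX, GY)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.d == pytest.approx(d, abs=1e-10)

    def test_scale_invariance_of_t(self):
        res1 = welch_t(GX, GY)
        res2 = welch_t([2 * v for v in GX], [2 * v for v in GY])
        assert res1.t == pytest.approx(res2.t)
        assert res1.d == pytest.approx(res2.d)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_t([1.0], GY)


class TestCorrelationMatrix:
    def test_independent_variables_near_zero(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)})
        matrix = correlation_matrix(df, ["a", "b"])
        assert abs(matrix.get("a", "b").r) < 0.05

    def test_symmetric_under_reordering(self):
        df = pd.DataFrame({"a": FX, "b": FY, "c": list(reversed(FX))})
        m1 = correlation_matrix(df, ["a", "b", "c"])
        m2 = correlation_matrix(df, ["c", "b", "a"])
        assert m1.get("a", "b").r == pytest.approx(m2.get("a", "b").r)

    def test_constant_variable_marked_unavailable(self):
        df = pd.DataFrame({"a": FX, "b": [1.0] * len(FX)})
        matrix = correlation_matrix(df, ["a", "b"])
        assert matrix.get("a", "b") is None
        assert matrix.formatted.loc["b", "a"] == "NA"

    def test_per_cell_n_varies_with_missingness(self):
        df = pd.DataFrame({"a": FX, "b": FY, "c": [float("nan")] * 3 + FX[3:]})
        matrix = correlation_matrix(df, ["a", "b", "c"])
        assert matrix.get("a", "b").n == 20
        assert matrix.get("a", "c").n == 17

    def test_star_thresholds(self):
        from textmarkers.stats import _stars
        assert [_stars(p) for p in (0.04, 0.009, 0.0009, 0.2)] == ["*", "**", "***", ""]

    def test_holm_adjustment_monotone(self):
        adj = holm_bonferroni([0.01, 0.04, 0.03, 0.5])
        assert all(a >= p for a, p in zip(adj, [0.01, 0.04, 0.03, 0.5]))
        assert max(adj) <= 1.0


class TestModeration:
    def test_no_planted_interaction_ci_covers_zero(self, rng):
        n = 2000
        x, m = rng.normal(size=n), rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        fit = moderated_regression(y, x, m)
        inter = fit.interaction
        assert inter["ci_low"] <= 0.0 <= inter["ci_high"]
        assert abs(inter["beta"]) < 0.08

    def test_planted_interaction_recovered(self, rng):
        n = 2000
        x, m = rng.normal(size=n), rng.normal(size=n)
        y = 0.2 * x + 0.3 * (x * m) + rng.normal(size=n)
        fit = moderated_regression(y, x, m)
        assert fit.interaction["p"] < 0.001
        assert fit.interaction["beta"] == pytest.approx(0.3, abs=0.1)

    def test_interaction_symmetric_in_x_and_m(self, rng):
        n = 500
        x, m = rng.normal(size=n), rng.normal(size=n)
        y = x + 0.5 * m + 0.2 * x * m + rng.normal(size=n)
        a = moderated_regression(y, x, m)
        b = moderated_regression(y, m, x)
        assert a.interaction["beta"] == pytest.approx(b.interaction["beta"], abs=1e-10)

    def test_listwise_deletion(self, rng):
        x = np.append(rng.normal(size=50), np.nan)
        m = rng.normal(size=51)
        y = rng.normal(size=51)
        assert moderated_regression(y, x, m).n == 50

    def test_collinear_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            moderated_regression(x, x, x)
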