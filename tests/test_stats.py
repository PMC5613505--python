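"""Correlation, regression and t statistics against definitional oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emoeeg.features import FeatureTable
from emoeeg.reference import FZ_APEN_BETA_SUMMARY
from emoeeg.stats import (
    StatsError,
    SubjectMetadata,
    correlation_grid,
    pearson_with_p,
    significance_stars,
    simple_regression,
    t_from_summary,
    t_independent,
    ttest_grid,
)


def _pearson_oracle(x, y):
    """r from the definitional sums, p via the exact t transform."""
    from scipy import stats as sps

    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    r = (n * (x * y).sum() - sx * sy) / math.sqrt(
        (n * (x**2).sum() - sx**2) * (n * (y**2).sum() - sy**2)
    )
    t = r * math.sqrt((n - 2) / (1 - r**2))
    return r, 2 * sps.t.sf(abs(t), n - 2)


def _grid_table(rng, subjects):
    cols = pd.MultiIndex.from_product(
        [["Fz"], ["ApEn"], ["HVLA", "LVLA", "LVHA"],
         ["theta", "alpha", "beta1", "beta2", "beta3"], [1, 2, 3]],
        names=["electrode", "method", "emotion", "band", "section"],
    )
    idx = pd.Index(subjects, name="subject_id")
    return FeatureTable(
        pd.DataFrame(rng.uniform(0.4, 0.7, (len(subjects), len(cols))),
                     index=idx, columns=cols)
    )


def _metadata(subjects):
    out = []
    for i, s in enumerate(subjects):
        group = "moderately_ill" if i % 2 == 0 else "markedly_ill"
        total = 70.0 + i
        out.append(SubjectMetadata(s, group, 0.25 * total, 0.25 * total, 0.5 * total, total))
    return out


class TestPearson:
    def test_perfect_linear_relation(self, rng):
        x = rng.standard_normal(20)
        res = pearson_with_p(x, 2 * x + 1)
        assert res.value == pytest.approx(1.0, abs=1e-12)
        assert res.p < 1e-12
        assert res.df == 18

    def test_orthogonal_residuals_give_zero(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        y -= y.mean() + np.dot(y - y.mean(), x - x.mean()) / np.dot(
            x - x.mean(), x - x.mean()
        ) * (x - x.mean())
        assert abs(pearson_with_p(x, y).value) < 1e-12

    def test_matches_definitional_oracle(self, rng):
        x, y = rng.standard_normal((2, 10))
        res = pearson_with_p(x, y)
        r, p = _pearson_oracle(x, y)
        assert res.value == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, rel=1e-10)

    @given(seed=st.integers(0, 2**31 - 1), a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_affine_invariance(self, seed, a, b):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal((2, 15))
        assert pearson_with_p(a * x + b, y).value == pytest.approx(
            pearson_with_p(x, y).value, abs=1e-9
        )

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            pearson_with_p(np.ones(10), np.arange(10.0))


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = simple_regression(x, 3 * x)
        assert res.value == pytest.approx(3.0, abs=1e-12)
        assert res.extras["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_slope_zero(self, rng):
        x = rng.standard_normal(10)
        x -= x.mean()
        assert simple_regression(x, np.full(10, 4.2)).value == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        x, y = rng.standard_normal((2, 25))
        res = simple_regression(x, y)
        A = np.vstack([x, np.ones_like(x)]).T
        slope, intercept = np.linalg.lstsq(A, y, rcond=None)[0]
        assert res.value == pytest.approx(slope, abs=1e-10)
        assert res.extras["intercept"] == pytest.approx(intercept, abs=1e-10)

    def test_slope_p_equals_pearson_p(self, rng):
        x, y = rng.standard_normal((2, 18))
        assert simple_regression(x, y).p == pytest.approx(pearson_with_p(x, y).p, rel=1e-10)


class TestTIndependent:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        res = t_independent(g, g)
        assert res.value == 0.0 and res.p == 1.0

    def test_zero_variance_unequal_means_diverges(self):
        res = t_independent([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert math.isinf(res.value) and res.value < 0
        assert res.p == 0.0

    def test_matches_definitional_oracle_17_vs_17(self, rng):
        a, b = rng.standard_normal((2, 17))
        b += 0.5
        res = t_independent(a, b)
        sp2 = (16 * a.var(ddof=1) + 16 * b.var(ddof=1)) / 32
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (2 / 17))
        assert res.value == pytest.approx(t, abs=1e-12)
        assert res.df == 32

    def test_welch_variant_matches_scipy(self, rng):
        from scipy import stats as sps

        a = rng.standard_normal(10)
        b = 2.0 * rng.standard_normal(20) + 0.3
        res = t_independent(a, b, pooled=False)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.value == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_tiny_groups_rejected(self):
        with pytest.raises(StatsError, match="at least 2"):
            t_independent([1.0], [2.0, 3.0])


class TestTFromSummary:
    def test_published_summary_cell_reproduces_printed_t(self):
        """β2/LVHA/section-3 published cell: recomputing t from the printed
        3-decimal group summaries gives −4.278 vs the printed −4.276."""
        res = t_from_summary(0.537, 0.066, 17, 0.607, 0.014, 17)
        assert res.value == pytest.approx(-4.278, abs=0.01)
        assert res.value == pytest.approx(-4.276, abs=0.05)
        assert res.df == 32
        assert res.stars == "***"

    def test_equal_means_give_zero(self):
        assert t_from_summary(0.5, 0.1, 10, 0.5, 0.2, 12).value == 0.0

    def test_matches_scipy_from_stats(self):
        from scipy import stats as sps

        res = t_from_summary(0.540, 0.067, 17, 0.609, 0.008, 17)
        ref = sps.ttest_ind_from_stats(0.540, 0.067, 17, 0.609, 0.008, 17)
        assert res.value == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_summary_route_equals_raw_route(self, seed):
        """t_from_summary ∘ summaries ≡ t_independent on the raw data."""
        r = np.random.default_rng(seed)
        a = r.standard_normal(17) * r.uniform(0.5, 2) + r.uniform(-1, 1)
        b = r.standard_normal(17) * r.uniform(0.5, 2) + r.uniform(-1, 1)
        raw = t_independent(a, b)
        summ = t_from_summary(
            a.mean(), a.std(ddof=1), 17, b.mean(), b.std(ddof=1), 17
        )
        assert summ.value == pytest.approx(raw.value, abs=1e-10)
        assert summ.p == pytest.approx(raw.p, abs=1e-10)

    def test_moment_matched_raw_data_equivalence(self):
        """Construct raw vectors with exactly the printed moments; the raw
        and summary routes agree to 1e-10."""
        mean_a, sd_a, mean_b, sd_b = 0.540, 0.067, 0.609, 0.008
        base = np.arange(17, dtype=float)

        def with_moments(mean, sd):
            z = (base - base.mean()) / base.std(ddof=1)
            return mean + sd * z

        a, b = with_moments(mean_a, sd_a), with_moments(mean_b, sd_b)
        raw = t_independent(a, b)
        summ = t_from_summary(mean_a, sd_a, 17, mean_b, sd_b, 17)
        assert raw.value == pytest.approx(summ.value, abs=1e-10)

    def test_every_published_cell_within_rounding_uncertainty(self):
        """All 27 published cells: |recomputed − printed| bounded by the
        worst-case t-shift from ±0.0005 rounding of each summary."""
        import itertools

        for cell, s in FZ_APEN_BETA_SUMMARY.items():
            recomputed = t_from_summary(
                s.mean_moderate, s.sd_moderate, 17, s.mean_marked, s.sd_marked, 17
            ).value
            shifts = [
                t_from_summary(
                    s.mean_moderate + dm1, max(s.sd_moderate + ds1, 1e-9), 17,
                    s.mean_marked + dm2, max(s.sd_marked + ds2, 1e-9), 17,
                ).value
                for dm1, ds1, dm2, ds2 in itertools.product(*[[-5e-4, 5e-4]] * 4)
            ]
            bound = max(abs(v - recomputed) for v in shifts)
            assert abs(recomputed - s.t_published) <= bound + 5e-4, cell


class TestGrids:
    def test_correlation_grid_shape_and_columns(self, rng):
        subjects = [f"p{i}" for i in range(12)]
        grid = correlation_grid(_grid_table(rng, subjects), _metadata(subjects))
        assert grid.shape == (45, 3)
        assert set(grid.columns) == {"r", "p", "stars"}
        assert grid["p"].between(0, 1).all()

    def test_missing_metadata_is_explicit(self, rng):
        subjects = [f"p{i}" for i in range(6)]
        with pytest.raises(StatsError, match="p5"):
            correlation_grid(_grid_table(rng, subjects), _metadata(subjects[:-1]))

    def test_null_grid_type_one_error_near_five_percent(self):
        """Independent features and PANSS: ~5% of grid cells reach p < .05.

        4500 cells from 100 independently seeded tables; per-table cell
        dependence is absent here because every feature is iid noise."""
        hits = total = 0
        subjects = [f"p{i}" for i in range(20)]
        meta = _metadata(subjects)
        for seed in range(100):
            r = np.random.default_rng(seed)
            grid = correlation_grid(_grid_table(r, subjects), meta)
            hits += int((grid["p"] < 0.05).sum())
            total += len(grid)
        rate = hits / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) <= 3.3 * se

    def test_ttest_grid_beta_cells(self, rng):
        subjects = [f"p{i}" for i in range(12)]
        table = _grid_table(rng, subjects)
        meta = _metadata(subjects)
        grid = ttest_grid(table, meta)
        assert grid.shape == (27, 7)
        cell = table.select_cell("Fz", "ApEn", "HVLA")[("beta2", 1)]
        mods = [m.subject_id for m in meta if m.group == "moderately_ill"]
        assert grid.loc[("beta2", "HVLA", 1), "mean_moderate"] == pytest.approx(
            cell.loc[mods].mean()
        )

    def test_bh_adjustment_is_monotone_extra(self, rng):
        subjects = [f"p{i}" for i in range(12)]
        grid = correlation_grid(
            _grid_table(rng, subjects), _metadata(subjects), bh_adjust=True
        )
        assert (grid["p_bh"] >= grid["p"] - 1e-15).all()


@pytest.mark.parametrize(
    "p,stars", [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "")]
)
def test_significance_star_thresholds(p, stars):
    assert significance_stars(p) == stars
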