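"""Selection tests: ellipse geometry, wedge oracle, top-τ cut, weak filter."""

import numpy as np
import pytest
from scipy import stats

from bcrange import (
    ConfidenceEllipse,
    DegenerateGroupError,
    FeatureTable,
    SelectionParams,
    ellipse_angular_range,
    fit_biplot,
    fit_group_ellipse,
    logistic_slope_pvalue,
    magnitude_top_fraction,
    select_features,
    weak_filter,
    wedge_membership,
)
from bcrange.selection import TWO_PI


def circle_ellipse(center, radius=1.0):
    """Circle of given radius as a ConfidenceEllipse (S = I, r² = radius²)."""
    return ConfidenceEllipse(
        center=np.asarray(center, float),
        covariance=np.eye(2),
        coverage=0.95,
        radius_sq=radius**2,
    )


class TestFitGroupEllipse:
    def test_default_radius_is_chi2_95(self, rng):
        pts = rng.standard_normal((50, 2))
        e = fit_group_ellipse(pts, np.ones(50, bool), coverage=0.95)
        assert e.radius_sq == pytest.approx(stats.chi2.ppf(0.95, 2))
        assert e.radius_sq == pytest.approx(5.99146, abs=1e-4)

    def test_center_and_covariance_unbiased(self, rng):
        pts = rng.standard_normal((200, 2)) * [2.0, 0.5] + [4.0, -1.0]
        e = fit_group_ellipse(pts, np.ones(200, bool))
        assert np.allclose(e.center, pts.mean(axis=0))
        assert np.allclose(e.covariance, np.cov(pts, rowvar=False, ddof=1))

    def test_too_small_group(self, rng):
        with pytest.raises(DegenerateGroupError):
            fit_group_ellipse(rng.standard_normal((5, 2)),
                              np.array([1, 1, 0, 0, 0], bool))

    def test_collinear_scores_degenerate(self):
        pts = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(DegenerateGroupError):
            fit_group_ellipse(pts, np.ones(6, bool))

    def test_scale_invariance_of_wedge(self, rng):
        pts = rng.standard_normal((60, 2)) + [6.0, 2.0]
        mask = np.ones(60, bool)
        r1 = ellipse_angular_range(fit_group_ellipse(pts, mask))
        r2 = ellipse_angular_range(fit_group_ellipse(1000.0 * pts, mask))
        (s1, w1), (s2, w2) = r1.intervals[0], r2.intervals[0]
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert w1 == pytest.approx(w2, abs=1e-9)


class TestAngularRange:
    def test_unit_circle_at_distance_two(self):
        # tangent lines from the origin to a unit circle at (2, 0) make
        # half-angle asin(1/2) = 30 degrees
        rng_ = ellipse_angular_range(circle_ellipse([2.0, 0.0]))
        assert not rng_.full_circle
        (start, width), = rng_.intervals
        assert np.degrees(width) == pytest.approx(60.0, abs=1e-6)
        assert np.degrees(start) == pytest.approx(330.0, abs=1e-6)
        assert rng_.contains(np.radians([0.0, 29.9, 330.1])).all()
        assert not rng_.contains(np.radians([30.5, 180.0, 329.5])).any()

    def test_origin_inside_gives_full_circle(self):
        with pytest.warns(UserWarning, match="full-circle"):
            rng_ = ellipse_angular_range(circle_ellipse([0.3, 0.1]))
        assert rng_.full_circle
        assert rng_.contains(np.linspace(0, TWO_PI, 17)).all()

    def test_wraparound_membership(self):
        # circle centered just below the +x axis: wedge straddles angle 0
        rng_ = ellipse_angular_range(circle_ellipse([3.0, -0.5], radius=1.0))
        assert rng_.contains(np.array([0.0])).all()
        assert rng_.contains(np.array([TWO_PI - 0.05])).all()
        assert not rng_.contains(np.array([np.pi])).any()

    @pytest.mark.parametrize("seed", range(8))
    def test_boundary_sweep_oracle(self, seed):
        # the wedge must exactly cover the angles spanned by the ellipse
        # boundary, for arbitrary exterior ellipses
        rng = np.random.default_rng(seed)
        L = rng.standard_normal((2, 2))
        S = L @ L.T + 0.05 * np.eye(2)
        c = rng.normal(0, 4, size=2)
        r_sq = 2.0
        if c @ np.linalg.inv(S) @ c <= r_sq:  # origin inside: skip geometry
            c = c * 10.0
        e = ConfidenceEllipse(center=c, covariance=S, coverage=0.95,
                              radius_sq=r_sq)
        rng_ = ellipse_angular_range(e)
        (start, width), = rng_.intervals
        theta = np.linspace(0, TWO_PI, 200_001)
        chol = np.linalg.cholesky(S)
        boundary = c + np.sqrt(r_sq) * (
            chol @ np.vstack([np.cos(theta), np.sin(theta)])
        ).T
        angles = np.arctan2(boundary[:, 1], boundary[:, 0])
        theta_c = np.arctan2(c[1], c[0])
        rel = np.mod(angles - theta_c + np.pi, TWO_PI) - np.pi
        observed_width = rel.max() - rel.min()
        observed_start = np.mod(theta_c + rel.min(), TWO_PI)
        assert width == pytest.approx(observed_width, abs=2e-3)
        assert np.mod(start - observed_start + np.pi, TWO_PI) - np.pi == (
            pytest.approx(0.0, abs=2e-3)
        )
        assert rng_.contains(np.mod(angles, TWO_PI)).all()


class TestWedgeMembership:
    def test_zero_arrow_excluded(self):
        rng_ = ellipse_angular_range(circle_ellipse([2.0, 0.0]))
        a_pred = np.array([1.0, 0.0, 1.0])
        a_ortho = np.array([0.0, 0.0, 5.0])  # angle ~79 degrees: outside
        got = wedge_membership(a_pred, a_ortho, rng_)
        assert got.tolist() == [True, False, False]


class TestTopFraction:
    def test_hand_example(self):
        m = np.arange(1.0, 11.0)  # magnitudes 1..10
        members = np.ones(10, bool)
        got = magnitude_top_fraction(m, np.zeros(10), members, tau=0.2)
        assert set(np.flatnonzero(got)) == {8, 9}

    def test_budget_spent_inside_wedge(self):
        m = np.arange(1.0, 11.0)
        members = np.zeros(10, bool)
        members[:5] = True  # wedge only covers magnitudes 1..5
        got = magnitude_top_fraction(m, np.zeros(10), members, tau=0.2)
        assert set(np.flatnonzero(got)) == {3, 4}

    def test_tau_one_keeps_all_members(self):
        members = np.array([True, False, True, True])
        got = magnitude_top_fraction(
            np.ones(4), np.ones(4), members, tau=1.0
        )
        assert np.array_equal(got, members)

    def test_ties_break_to_lower_index(self):
        m = np.array([5.0, 5.0, 5.0, 1.0])
        got = magnitude_top_fraction(m, np.zeros(4), np.ones(4, bool), tau=0.5)
        assert set(np.flatnonzero(got)) == {0, 1}

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            magnitude_top_fraction(np.ones(3), np.ones(3), np.ones(3, bool), 0.0)


class TestLogisticFilter:
    def test_constant_predictor_p_one(self):
        y = np.array([0.0, 1.0] * 10)
        assert logistic_slope_pvalue(np.full(20, 3.0), y) == 1.0

    def test_complete_separation_p_zero(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = np.concatenate([np.linspace(0, 1, 10), np.linspace(2, 3, 10)])
        assert logistic_slope_pvalue(x, y) == 0.0

    def test_matches_statsmodels_on_regular_data(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal(80)
        y = (rng.random(80) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        ours = logistic_slope_pvalue(x, y)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert ours == pytest.approx(float(fit.pvalues[1]), rel=1e-8)

    def test_weak_filter_keeps_separator_drops_null(self, rng):
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([
            y + 0.01 * rng.standard_normal(n),  # near-perfect separator
            np.full(n, 2.0),                    # constant: p = 1
        ])
        table = FeatureTable(
            X=X, sample_ids=[str(i) for i in range(n)],
            feature_ids=["a", "b"], labels=y,
        )
        kept, removed = weak_filter(table, {0, 1}, filter_alpha=0.10)
        assert kept == {0}
        assert [j for j, _ in removed] == [1]
        assert removed[0][1] == 1.0

    def test_pvalue_cache_is_trusted(self, small_table):
        cache = {0: 0.99, 1: 0.0}
        kept, removed = weak_filter(small_table, {0, 1}, 0.10, cache)
        assert kept == {1}
        assert removed == [(0, 0.99)]


class TestSelectFeatures:
    @pytest.fixture(scope="class")
    def sim(self):
        from bcrange import SimulationDesign, Structure, generate_dataset

        design = SimulationDesign(
            structure=Structure.TWO_LAYER, n_features=1000, seed=17
        )
        table, truth = generate_dataset(design)
        model = fit_biplot(table, autoscale=True)
        return table, truth, model

    def test_subset_chain(self, sim):
        table, _, model = sim
        result = select_features(model, table, SelectionParams(tau=0.05))
        for sel in result.per_group.values():
            assert sel.selected <= sel.top_candidates <= sel.wedge_members
            dropped = {j for j, _ in sel.filtered_out}
            assert sel.selected | dropped == sel.top_candidates
        assert result.union_selected == set().union(
            *(s.selected for s in result.per_group.values())
        )

    def test_tau_monotone(self, sim):
        table, _, model = sim
        cache = {}
        r_small = select_features(model, table, SelectionParams(tau=0.02),
                                  pvalue_cache=cache)
        r_large = select_features(model, table, SelectionParams(tau=0.10),
                                  pvalue_cache=cache)
        for label in r_small.per_group:
            assert (r_small.per_group[label].top_candidates
                    <= r_large.per_group[label].top_candidates)
        assert r_small.union_selected <= r_large.union_selected

    def test_recovers_strong_variables(self, sim):
        table, truth, model = sim
        result = select_features(model, table, SelectionParams(tau=0.05))
        assert set(range(8)) <= result.union_selected

    def test_budget_bound(self, sim):
        table, _, model = sim
        result = select_features(model, table, SelectionParams(tau=0.05))
        k = int(np.ceil(0.05 * table.n_features))
        for sel in result.per_group.values():
            assert len(sel.top_candidates) <= k

    def test_degenerate_group_contributes_nothing(self, rng):
        n = 12
        y = np.array([0] * 3 + [1] * 9)
        X = rng.standard_normal((n, 6))
        X[:3] = X[3]  # group 0 collapses to one point in score space
        X[:, 0] += 2.0 * y
        table = FeatureTable(
            X=X, sample_ids=[str(i) for i in range(n)],
            feature_ids=[str(j) for j in range(6)], labels=y,
        )
        model = fit_biplot(table)
        with pytest.warns(UserWarning, match="degenerate"):
            result = select_features(model, table)
        assert result.per_group[0].selected == set()
        assert result.per_group[0].ellipse is None

    def test_union_filtered_excludes_selected(self, sim):
        table, _, model = sim
        result = select_features(model, table, SelectionParams(tau=0.10))
        assert not (result.union_filtered() & result.union_selected)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            SelectionParams(tau=0.0)
        with pytest.raises(ValueError):
            SelectionParams(coverage=1.0)
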