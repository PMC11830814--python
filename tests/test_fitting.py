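"""Weighted least squares, model selection and baseline anchoring."""

import numpy as np
import pytest

from lactodb import add_baseline_anchor, default_registry, fit_weighted, weighted_r2
from lactodb.fitting import (
    CANDIDATE_SETS,
    ShapeConflictError,
    UnderdeterminedError,
    build_candidates,
    default_candidate,
    polynomial_candidate,
    select_model,
)


def make_points(ts, xs, ns):
    return np.column_stack([ts, xs, ns]).astype(float)


def segment_grid(seg, k_geom=12, k_lin=15):
    """Noise-free sampling of one registry segment, dense near its left edge."""
    lo, hi = seg.t_lo, seg.t_hi
    ts = np.unique(
        np.concatenate([lo + np.geomspace(1e-3, (hi - lo) * 0.99, k_geom), np.linspace(lo, hi, k_lin)])
    )
    return make_points(ts, np.asarray(seg(ts), dtype=float), np.full(ts.size, 10.0))


class TestFitWeighted:
    def test_exact_line_interpolation(self):
        ts = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
        pts = make_points(ts, 1.549 - 0.024 * ts, np.ones(5))
        fit = fit_weighted(pts, default_candidate("linear", pts))
        assert fit.coefficients["intercept"] == pytest.approx(1.549, abs=1e-8)
        assert fit.coefficients["slope"] == pytest.approx(-0.024, abs=1e-8)
        assert fit.weighted_r2 == pytest.approx(1.0)

    def test_quadratic_recovery_with_study_weights(self, registry):
        """Noise-free milk-fat quadratic with uneven study-size weights."""
        seg = registry["milk_fat"].segments[0]
        ts = np.linspace(0.0, 12.0, 10)
        ns = np.array([763, 328, 2661, 481, 1005, 2417, 88, 191, 560, 165], dtype=float)
        pts = make_points(ts, np.asarray(seg(ts)), ns)
        fit = fit_weighted(pts, polynomial_candidate(2))
        assert fit.coefficients["c0"] == pytest.approx(3.69, rel=1e-6)
        assert fit.coefficients["c1"] / fit.coefficients["c0"] == pytest.approx(0.012083, rel=1e-6)
        assert fit.coefficients["c2"] / fit.coefficients["c0"] == pytest.approx(0.000171, rel=1e-6)

    def test_heavy_point_dominates_constant_fit(self):
        pts = make_points([1.0, 5.0], [10.0, 20.0], [1000.0, 1.0])
        fit = fit_weighted(pts, default_candidate("constant", pts))
        expected = (1000 * 10 + 1 * 20) / 1001  # closed-form weighted mean
        assert fit.coefficients["value"] == pytest.approx(expected, rel=1e-12)
        assert abs(fit.coefficients["value"] - 10.0) / 10.0 < 0.002

    def test_replication_equals_weighting(self):
        rng = np.random.default_rng(5)
        ts = np.linspace(0, 12, 8)
        xs = 2.0 + 0.3 * ts + rng.normal(0, 0.2, 8)
        ks = np.array([1, 3, 2, 5, 1, 4, 2, 3])
        weighted = fit_weighted(make_points(ts, xs, ks), polynomial_candidate(1))
        replicated_pts = make_points(np.repeat(ts, ks), np.repeat(xs, ks), np.ones(ks.sum()))
        replicated = fit_weighted(replicated_pts, polynomial_candidate(1))
        for k in weighted.coefficients:
            assert weighted.coefficients[k] == pytest.approx(replicated.coefficients[k], rel=1e-10)

    def test_underdetermined_raises(self):
        pts = make_points([0.0, 1.0], [1.0, 2.0], [1.0, 1.0])
        with pytest.raises(UnderdeterminedError):
            fit_weighted(pts, polynomial_candidate(2))


@pytest.mark.parametrize("param_id", [p.id for p in default_registry()])
def test_noise_free_recovery_of_registry_segments(registry, param_id):
    """Every registry family refits its own noise-free curve to its printed
    coefficients (relative error < 1e-5)."""
    for seg in registry[param_id].segments:
        pts = segment_grid(seg)
        if seg.family == "polynomial":
            cand = polynomial_candidate(len(seg.coefficients) - 1)
        else:
            cand = default_candidate(seg.family, pts)
        fit = fit_weighted(pts, cand, seed=0)
        for k, truth in seg.coefficients.items():
            assert fit.coefficients[k] == pytest.approx(truth, rel=1e-5, abs=1e-8), (
                param_id, seg.family, k)


class TestWeightedR2:
    def test_perfect_fit_is_one(self):
        pts = make_points([0, 1, 2], [1.0, 2.0, 3.0], [1, 1, 1])
        fit = fit_weighted(pts, polynomial_candidate(1))
        assert fit.weighted_r2 == pytest.approx(1.0)

    def test_weighted_mean_constant_is_zero(self):
        pts = make_points([0, 1, 2], [1.0, 2.0, 3.0], [1, 1, 1])
        assert weighted_r2(pts, lambda t: np.full_like(np.asarray(t, float), 2.0)) == pytest.approx(0.0)

    def test_three_point_line_closed_form(self):
        """OLS on {(0,0),(1,1),(2,1)}: slope 1/2, intercept 1/6, r2 = 3/4."""
        pts = make_points([0, 1, 2], [0.0, 1.0, 1.0], [1, 1, 1])
        fit = fit_weighted(pts, polynomial_candidate(1))
        assert fit.coefficients["c1"] == pytest.approx(0.5)
        assert fit.coefficients["c0"] == pytest.approx(1 / 6)
        assert fit.weighted_r2 == pytest.approx(0.75)

    def test_degenerate_inputs_raise(self):
        pts = make_points([0, 1], [2.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            weighted_r2(pts, lambda t: np.asarray(t, float))


class TestSelectModel:
    def test_polynomial_parsimony(self, registry):
        seg = registry["milk_fat"].segments[0]
        ts = np.linspace(0, 12, 9)
        pts = make_points(ts, np.asarray(seg(ts)), np.full(9, 20.0))
        chosen = select_model(pts, [polynomial_candidate(2), polynomial_candidate(3)], "unconstrained")
        assert chosen.family == "polynomial" and len(chosen.coefficients) == 3

    def test_parsimony_walks_whole_chain(self, registry):
        seg = registry["gfr"].segments[0]  # genuinely quartic
        ts = np.linspace(0, 12, 13)
        pts = make_points(ts, np.asarray(seg(ts)), np.full(13, 20.0))
        cands = [polynomial_candidate(d) for d in (2, 3, 4)]
        chosen = select_model(pts, cands, "unconstrained")
        assert len(chosen.coefficients) == 5  # quartic wins: real SS and r2 gains

    def test_shape_exclusion_before_fitting(self, registry):
        seg = registry["milk_volume"].segments[0]
        ts = np.geomspace(0.02, 5.9, 12)
        pts = make_points(ts, np.asarray(seg(ts)), np.full(12, 10.0))
        cands = [default_candidate("linear", pts), default_candidate("hill", pts)]
        chosen = select_model(pts, cands, "monotone_up")
        assert chosen.family == "hill"

    def test_all_excluded_raises(self, registry):
        pts = make_points([0, 1, 2, 3], [1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ShapeConflictError, match="monotone_up"):
            select_model(pts, [default_candidate("linear", pts)], "monotone_up")

    def test_winner_has_lowest_ss_among_survivors(self, registry):
        seg = registry["milk_protein"].segments[0]
        ts = np.linspace(0, 12, 15)
        pts = make_points(ts, np.asarray(seg(ts)), np.full(15, 10.0))
        names = ["mono_exponential", "exp_decay_to_baseline"]
        fits = {n: fit_weighted(pts, default_candidate(n, pts)) for n in names}
        chosen = select_model(pts, build_candidates(names, pts), "decay_to_floor")
        assert chosen.weighted_ss <= min(f.weighted_ss for f in fits.values()) * (1 + 1e-12)
        assert chosen.family == "exp_decay_to_baseline"

    def test_candidate_sets_are_buildable(self, registry):
        seg = registry["haematocrit"].segments[0]
        ts = np.linspace(0.05, 12, 14)
        pts = make_points(ts, np.asarray(seg(ts)), np.full(14, 10.0))
        for name in CANDIDATE_SETS:
            assert build_candidates(CANDIDATE_SETS[name], pts)


class TestBaselineAnchor:
    def test_appends_single_point_untouched_originals(self):
        pts = make_points([0.1, 2.0, 6.0], [31.0, 37.0, 38.5], [500, 300, 200])
        out = add_baseline_anchor(pts, 12.0, 38.74, 1000)
        assert out.shape == (4, 3)
        assert np.array_equal(out[:3], pts)
        assert tuple(out[3]) == (12.0, 38.74, 1000.0)

    def test_anchor_before_last_observation_rejected(self):
        pts = make_points([0.1, 12.0], [31.0, 38.7], [500, 300])
        with pytest.raises(ValueError, match="anchor"):
            add_baseline_anchor(pts, 12.0, 38.74, 1000)

    @pytest.mark.parametrize("pseudo_ns", [(10, 100, 1000)])
    def test_plateau_moves_monotonically_towards_anchor(self, pseudo_ns):
        # early observations far below the anchor; plateau should approach it
        ts = np.array([0.05, 0.2, 0.5, 1.0, 2.0])
        xs = np.array([31.2, 33.0, 36.0, 37.5, 37.8])
        pts = make_points(ts, xs, np.full(5, 50.0))
        anchor_value = 40.0
        gaps = []
        for pn in pseudo_ns:
            aug = add_baseline_anchor(pts, 12.0, anchor_value, pn)
            fit = fit_weighted(aug, default_candidate("offset_hill", aug), seed=0)
            gaps.append(abs(float(fit(12.0)) - anchor_value))
        # heavier pseudo-weights pin the fitted curve ever closer to the anchor
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.05
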