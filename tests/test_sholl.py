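"""Sholl profiles: exact crossing counts, polynomial fits, normalization."""

import numpy as np
import pytest

from ancmorph import (
    DegenerateInputError,
    ParameterError,
    TraceSet,
    fit_profile,
    normalize_profiles,
    path_length,
    sholl_profile,
)
from ancmorph.synthetic import TraceSpec, gen_trace, sholl_profile_dense

from conftest import build_trace, random_rotation


def straight_ray(length, n_nodes=8, name="ray"):
    zs = np.linspace(0, length, n_nodes)
    rows = [(1, 0, 0, 0, -1)] + [
        (i + 2, 0, 0, zs[i + 1], i + 1) for i in range(n_nodes - 1)
    ]
    return build_trace(rows, name=name)


class TestShollProfile:
    def test_straight_ray_crosses_each_inner_sphere_once(self):
        p = sholl_profile(straight_ray(95.0), step=10)
        assert list(p.radii) == [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        assert list(p.counts) == [1] * 9 + [0]

    def test_y_tree_with_nodes_exactly_on_shells(self):
        # bifurcation at radius 50, tips exactly at radius 100:
        # one crossing up to the bifurcation shell, two beyond, none at the
        # tip shell (the distance never exceeds 100)
        trace, _ = gen_trace(TraceSpec(kind="y_tree", bifurcation_radius=50,
                                       tip_radius=100, seed=0))
        p = sholl_profile(trace, step=10)
        assert list(p.counts) == [1, 1, 1, 1, 1, 2, 2, 2, 2, 0]

    def test_matches_dense_resampling_oracle_on_random_trees(self):
        for seed in range(25):
            trace, truth = gen_trace(TraceSpec(kind="random_tree", seed=seed))
            p = sholl_profile(trace, step=10)
            assert np.array_equal(p.counts, truth.counts), f"seed {seed}"

    def test_refinement_consistency_step5_vs_step10(self):
        for seed in (0, 3, 11):
            trace, _ = gen_trace(TraceSpec(kind="random_tree", seed=seed))
            p10 = sholl_profile(trace, step=10)
            p5 = sholl_profile(trace, step=5)
            # step-10 shells are the even shells of the step-5 profile
            assert np.array_equal(p5.counts[1::2][: len(p10.counts)],
                                  p10.counts[: len(p5.counts[1::2])])

    def test_reentrant_edge_counts_two_crossings(self):
        # the chord from (25,−20,0) to (25,20,0) dips to distance 25 at its
        # midpoint and ends at distance √1025 ≈ 32, so it crosses the r=30
        # sphere twice; the radial stem crosses every inner sphere once
        t = build_trace([
            (1, 0, 0, 0, -1), (2, 25, -20, 0, 1), (3, 25, 20, 0, 2),
        ])
        p = sholl_profile(t, step=10)
        assert list(p.counts) == [1, 1, 3, 0]

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(0)
        trace, _ = gen_trace(TraceSpec(kind="random_tree", seed=5))
        base = sholl_profile(trace, step=10)
        for _ in range(5):
            moved = trace.transformed(random_rotation(rng),
                                      rng.normal(scale=50, size=3))
            p = sholl_profile(moved, step=10)
            assert np.array_equal(p.counts, base.counts)

    def test_root_only_trace_all_zero(self):
        p = sholl_profile(build_trace([(1, 0, 0, 0, -1)]), step=10)
        assert p.counts.sum() == 0

    def test_bad_step(self, straight_path):
        with pytest.raises(ParameterError):
            sholl_profile(straight_path, step=0)

    def test_radial_append_monotonicity(self):
        # appending outward-pointing edges never removes crossings
        rows = [(1, 0, 0, 0, -1), (2, 0, 0, 15, 1)]
        prev_total = 0
        for k in range(6):
            rows.append((3 + k, 0, 0, 15 + 10 * (k + 1), 2 + k))
            total = sholl_profile(build_trace(rows), step=10).counts.sum()
            assert total >= prev_total
            prev_total = total


class TestFitProfile:
    def test_constant_counts_give_constant_polynomial(self):
        p = sholl_profile(straight_ray(95.0, n_nodes=20), step=10)
        assert list(p.counts[:9]) == [1] * 9
        fit = fit_profile(p, degree=5)
        assert fit(55.0) == pytest.approx(np.polynomial.polynomial.polyval(
            55.0, fit.coefficients))

    def test_recovers_generating_cubic(self):
        from ancmorph.sholl import ShollProfile
        radii = 10.0 * np.arange(1, 11)
        coeffs = np.array([2.0, 0.3, -0.01, 0.0001])
        counts = np.polynomial.polynomial.polyval(radii, coeffs)
        prof = ShollProfile("c", np.zeros(3), 10.0, radii, counts)
        fit = fit_profile(prof, degree=3)
        assert np.allclose(fit.coefficients, coeffs, atol=1e-8)

    def test_degree_five_on_five_shells_refused(self):
        p = sholl_profile(straight_ray(45.0), step=10)
        assert len(p.radii) == 5
        with pytest.raises(DegenerateInputError):
            fit_profile(p, degree=5)

    def test_least_squares_optimality(self):
        # perturbing the fitted coefficients never lowers the residual
        trace, _ = gen_trace(TraceSpec(kind="random_tree", seed=2))
        p = sholl_profile(trace, step=5)
        fit = fit_profile(p, degree=5)
        resid = np.sum((fit(p.radii) - p.counts) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            delta = rng.normal(scale=1e-4, size=6)
            other = np.polynomial.polynomial.polyval(
                p.radii, fit.coefficients + delta)
            assert np.sum((other - p.counts) ** 2) >= resid - 1e-9


class TestNormalizeProfiles:
    def _two_nerves(self):
        long = straight_ray(100.0, name="long")
        long.reaches_skin = True
        short = straight_ray(50.0, name="short")
        return TraceSet([long, short])

    def test_longest_nerve_last_shell_at_most_one(self):
        ts = self._two_nerves()
        profiles = [sholl_profile(t, step=10) for t in ts]
        normed = normalize_profiles(profiles, ts)
        long_prof = next(p for p in normed if p.trace_name == "long")
        nonzero = long_prof.radii[long_prof.counts > 0]
        assert nonzero.max() <= 1.0 + 1e-12

    def test_second_profile_spans_half(self):
        ts = self._two_nerves()
        normed = normalize_profiles([sholl_profile(t, step=10) for t in ts], ts)
        short_prof = next(p for p in normed if p.trace_name == "short")
        assert short_prof.norm_length == pytest.approx(100.0)
        assert short_prof.radii[short_prof.counts > 0].max() <= 0.5 + 1e-12

    def test_normalize_then_denormalize_restores(self):
        ts = self._two_nerves()
        profiles = [sholl_profile(t, step=10) for t in ts]
        normed = normalize_profiles(profiles, ts)
        for orig, n in zip(profiles, normed):
            assert np.allclose(n.denormalized().radii, orig.radii)

    def test_warns_without_skin_flag_and_uses_longest(self):
        a = straight_ray(80.0, name="a")
        b = straight_ray(40.0, name="b")
        ts = TraceSet([a, b])
        with pytest.warns(UserWarning, match="reaches_skin"):
            normed = normalize_profiles([sholl_profile(a, step=10)], ts)
        assert normed[0].norm_length == pytest.approx(path_length(a))


def test_dense_oracle_is_independent_and_agrees_on_known_ray():
    p = sholl_profile_dense(straight_ray(95.0), step=10)
    assert list(p.counts) == [1] * 9 + [0]
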