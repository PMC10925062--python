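import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretrla.efficiency import (
    ForsterParams,
    NoViableFramesError,
    PairGrid,
    average_dynamic,
    average_dynamic_plus,
    average_static,
    compute_efficiencies,
    forster_radius,
    kappa_squared,
    kish_effective_fraction,
    point_efficiency,
    regime_average,
    reweight_frames,
)

EX = np.array([1.0, 0.0, 0.0])
EY = np.array([0.0, 1.0, 0.0])
EZ = np.array([0.0, 0.0, 1.0])


class TestKappaSquared:
    @pytest.mark.parametrize(
        "mu_d, mu_a, expected",
        [
            (EZ, EZ, 4.0),  # both along the inter-dye axis
            (EX, EX, 1.0),  # parallel, perpendicular to the axis
            (EX, EY, 0.0),  # mutually perpendicular, both off-axis
        ],
    )
    def test_canonical_orientations(self, mu_d, mu_a, expected):
        assert float(kappa_squared(mu_d, mu_a, EZ)) == pytest.approx(expected, abs=1e-14)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            kappa_squared(np.zeros(3), EX, EZ)

    def test_isotropic_average_is_two_thirds(self):
        rng = np.random.default_rng(123)
        n = 200_000
        v = rng.normal(size=(3, n, 3))
        k2 = kappa_squared(v[0], v[1], v[2])
        se = k2.std(ddof=1) / np.sqrt(n)
        assert abs(k2.mean() - 2.0 / 3.0) < 3.0 * se

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounded_in_0_4(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(3, 3))
        k2 = float(kappa_squared(v[0], v[1], v[2]))
        assert 0.0 <= k2 <= 4.0 + 1e-12


class TestForsterRadius:
    def test_doubling_overlap_scales_by_sixth_root_of_two(self):
        r1 = forster_radius(1.0e15, 2 / 3, 0.9, 1.33)
        r2 = forster_radius(2.0e15, 2 / 3, 0.9, 1.33)
        assert r2 / r1 == pytest.approx(2.0 ** (1.0 / 6.0), abs=1e-12)

    def test_zero_kappa_gives_zero_radius(self):
        assert forster_radius(1.0, 0.0, 1.0, 1.0) == 0.0

    def test_unit_inputs_closed_form(self):
        assert forster_radius(1.0, 2 / 3, 1.0, 1.0) == pytest.approx(
            0.02108 * (2.0 / 3.0) ** (1.0 / 6.0), abs=1e-15
        )

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            forster_radius(-1.0, 2 / 3, 1.0, 1.0)


class TestPointEfficiency:
    def test_half_at_forster_radius(self):
        assert point_efficiency(52.0, 2.0 / 3.0, 52.0) == 0.5

    def test_limits(self):
        assert float(point_efficiency(1e-6, 2 / 3, 50.0)) == pytest.approx(1.0)
        assert float(point_efficiency(1e6, 2 / 3, 50.0)) == pytest.approx(0.0)
        assert float(point_efficiency(30.0, 0.0, 50.0)) == 0.0

    def test_reduces_to_isotropic_form(self):
        """At κ²=2/3 the orientation-explicit formula equals R0^6/(r^6+R0^6)."""
        rng = np.random.default_rng(42)
        r = rng.uniform(5.0, 120.0, size=1000)
        r0 = rng.uniform(20.0, 80.0, size=1000)
        e3 = np.array([float(point_efficiency(ri, 2.0 / 3.0, r0i)) for ri, r0i in zip(r, r0)])
        e2 = r0**6 / (r**6 + r0**6)
        np.testing.assert_allclose(e3, e2, atol=1e-14)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=1.0, max_value=200.0),
        st.floats(min_value=1.0, max_value=200.0),
        st.floats(min_value=0.01, max_value=4.0),
    )
    def test_monotone_decreasing_in_distance(self, r, r0, k2):
        e1 = float(point_efficiency(r, k2, r0))
        e2 = float(point_efficiency(r * 1.01, k2, r0))
        assert 0.0 <= e2 < e1 <= 1.0


def _random_grid(rng, n, l, m, with_clash=False):
    r = rng.uniform(20.0, 90.0, size=(n, l, m))
    k2 = rng.uniform(0.0, 4.0, size=(n, l, m))
    wd = rng.dirichlet(np.ones(l), size=n)
    wa = rng.dirichlet(np.ones(m), size=n)
    zd = rng.uniform(0.1, 1.0, size=n)
    za = rng.uniform(0.1, 1.0, size=n)
    if with_clash:
        zd[0] = 0.0
        wd[0] = 0.0
    return PairGrid(r=r, kappa2=k2, w_donor=wd, w_acceptor=wa, z_donor=zd, z_acceptor=za)


def _brute_force(grid, r0):
    """Naive triple-loop references for the three averaging regimes."""
    viable = np.flatnonzero(grid.viable)
    nv = len(viable)
    e_static = 0.0
    k2_mean = 0.0
    for s in viable:
        for i in range(grid.r.shape[1]):
            for j in range(grid.r.shape[2]):
                w = grid.w_donor[s, i] * grid.w_acceptor[s, j]
                r, k2 = grid.r[s, i, j], grid.kappa2[s, i, j]
                if k2 > 0:
                    e_static += w / (1.0 + (2.0 / (3.0 * k2)) * (r / r0) ** 6) / nv
                k2_mean += w * k2 / nv
    e_dynamic = 0.0
    for s in viable:
        for i in range(grid.r.shape[1]):
            for j in range(grid.r.shape[2]):
                w = grid.w_donor[s, i] * grid.w_acceptor[s, j]
                r = grid.r[s, i, j]
                e_dynamic += w / (1.0 + (2.0 / (3.0 * k2_mean)) * (r / r0) ** 6) / nv
    e_plus = 0.0
    for s in viable:
        A = 0.0
        for i in range(grid.r.shape[1]):
            for j in range(grid.r.shape[2]):
                w = grid.w_donor[s, i] * grid.w_acceptor[s, j]
                A += 1.5 * grid.kappa2[s, i, j] * (r0 / grid.r[s, i, j]) ** 6 * w
        e_plus += A / (1.0 + A) / nv
    return e_static, e_dynamic, e_plus, k2_mean


class TestAveragingRegimes:
    def test_single_pair_equals_point_efficiency(self):
        grid = PairGrid(
            r=np.array([[[40.0]]]),
            kappa2=np.array([[[1.2]]]),
            w_donor=np.ones((1, 1)),
            w_acceptor=np.ones((1, 1)),
            z_donor=np.ones(1),
            z_acceptor=np.ones(1),
        )
        params = ForsterParams(mode="fixed", r0=50.0)
        e, _ = average_static(grid, params)
        assert e == pytest.approx(float(point_efficiency(40.0, 1.2, 50.0)), abs=1e-15)

    def test_identical_frames_average_to_single_frame_value(self):
        one = PairGrid(
            r=np.full((1, 2, 2), 45.0),
            kappa2=np.full((1, 2, 2), 0.9),
            w_donor=np.full((1, 2), 0.5),
            w_acceptor=np.full((1, 2), 0.5),
            z_donor=np.ones(1),
            z_acceptor=np.ones(1),
        )
        many = PairGrid(
            r=np.full((6, 2, 2), 45.0),
            kappa2=np.full((6, 2, 2), 0.9),
            w_donor=np.full((6, 2), 0.5),
            w_acceptor=np.full((6, 2), 0.5),
            z_donor=np.ones(6),
            z_acceptor=np.ones(6),
        )
        params = ForsterParams(mode="fixed", r0=50.0)
        assert average_static(many, params)[0] == pytest.approx(
            average_static(one, params)[0], abs=1e-14
        )

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        params = ForsterParams(mode="fixed", r0=55.0)
        for trial in range(10):
            n, l, m = rng.integers(1, 6), rng.integers(1, 7), rng.integers(1, 7)
            grid = _random_grid(rng, int(n), int(l), int(m), with_clash=(trial % 3 == 0 and n > 1))
            ref_s, ref_d, ref_p, ref_k2 = _brute_force(grid, 55.0)
            e_s, _ = average_static(grid, params)
            e_d, _, k2 = average_dynamic(grid, params)
            e_p, _ = average_dynamic_plus(grid, params)
            assert e_s == pytest.approx(ref_s, abs=1e-10)
            assert e_d == pytest.approx(ref_d, abs=1e-10)
            assert e_p == pytest.approx(ref_p, abs=1e-10)
            assert k2 == pytest.approx(ref_k2, abs=1e-10)

    def test_single_rotamer_degeneracy(self):
        """With one rotamer per dye, rate pre-averaging is a no-op: the
        dynamic+ average equals the static one for any frames, and all
        three regimes coincide once the frames are identical (single κ²)."""
        rng = np.random.default_rng(3)
        params = ForsterParams(mode="fixed", r0=60.0)
        hetero = _random_grid(rng, 5, 1, 1)
        res = compute_efficiencies(hetero, params)
        assert res.e_dynamic_plus == pytest.approx(res.e_static, abs=1e-12)
        homo = PairGrid(
            r=np.full((5, 1, 1), 48.0),
            kappa2=np.full((5, 1, 1), 1.3),
            w_donor=np.ones((5, 1)),
            w_acceptor=np.ones((5, 1)),
            z_donor=np.ones(5),
            z_acceptor=np.ones(5),
        )
        res = compute_efficiencies(homo, params)
        assert res.e_dynamic == pytest.approx(res.e_static, abs=1e-12)
        assert res.e_dynamic_plus == pytest.approx(res.e_static, abs=1e-12)
        assert res.kappa2_mean == pytest.approx(1.3, abs=1e-12)

    def test_kappa_dependent_r0_policy(self):
        rng = np.random.default_rng(8)
        grid = _random_grid(rng, 2, 2, 2)
        params = ForsterParams(mode="kappa", j=1e17, quantum_yield=0.9, refractive_index=1.33)
        r0 = params.r0_iso()
        fixed = ForsterParams(mode="fixed", r0=r0)
        assert average_static(grid, params)[0] == pytest.approx(
            average_static(grid, fixed)[0], abs=1e-14
        )

    def test_far_pairs_give_zero_efficiency(self):
        grid = PairGrid(
            r=np.full((2, 1, 1), 1.0e5),
            kappa2=np.full((2, 1, 1), 0.7),
            w_donor=np.ones((2, 1)),
            w_acceptor=np.ones((2, 1)),
            z_donor=np.ones(2),
            z_acceptor=np.ones(2),
        )
        params = ForsterParams(mode="fixed", r0=50.0)
        e, _ = average_dynamic_plus(grid, params)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_no_viable_frames_is_an_error(self):
        rng = np.random.default_rng(1)
        grid = _random_grid(rng, 2, 2, 2)
        grid.z_donor[:] = 0.0
        with pytest.raises(NoViableFramesError):
            compute_efficiencies(grid, ForsterParams(mode="fixed", r0=50.0))

    def test_results_bounded_and_kappa_convex(self):
        rng = np.random.default_rng(17)
        grid = _random_grid(rng, 4, 3, 3)
        res = compute_efficiencies(grid, ForsterParams(mode="fixed", r0=50.0))
        for e in (res.e_static, res.e_dynamic, res.e_dynamic_plus, res.e_mean):
            assert 0.0 <= e <= 1.0
        assert grid.kappa2.min() - 1e-12 <= res.kappa2_mean <= grid.kappa2.max() + 1e-12


class TestRegimeAverage:
    def test_arithmetic_mean(self):
        assert regime_average(0.2, 0.3, 0.4) == pytest.approx(0.3, abs=1e-15)

    def test_identity_when_equal(self):
        assert regime_average(0.7, 0.7, 0.7) == pytest.approx(0.7, abs=1e-15)


class TestReweighting:
    def test_uniform_inputs_give_uniform_weights(self):
        w, eff = reweight_frames(np.full(4, 0.5), np.full(4, 0.5), np.ones(4))
        np.testing.assert_array_equal(w, 0.25)
        assert eff == pytest.approx(1.0, abs=1e-15)

    def test_zero_partition_discards_the_frame(self):
        zd = np.array([1.0, 1.0, 0.0])
        w, _ = reweight_frames(zd, np.ones(3))
        assert w[2] == 0.0
        np.testing.assert_allclose(w[:2], 0.5)

    def test_kish_fraction_half(self):
        assert kish_effective_fraction(np.array([0.5, 0.5, 0.0, 0.0])) == pytest.approx(0.5)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(NoViableFramesError):
            reweight_frames(np.zeros(3), np.ones(3))

    def test_uniform_frame_weights_reproduce_unweighted_bitwise(self):
        rng = np.random.default_rng(21)
        grid = _random_grid(rng, 4, 3, 2)
        params = ForsterParams(mode="fixed", r0=50.0)
        a = compute_efficiencies(grid, params)
        b = compute_efficiencies(grid, params, frame_weights=np.ones(4))
        assert a.e_static == b.e_static
        assert a.e_dynamic == b.e_dynamic
        assert a.e_dynamic_plus == b.e_dynamic_plus
        assert a.kappa2_mean == b.kappa2_mean

    def test_zero_weight_equivalent_to_discarding(self):
        rng = np.random.default_rng(5)
        grid = _random_grid(rng, 3, 2, 2)
        params = ForsterParams(mode="fixed", r0=50.0)
        w = np.array([1.0, 1.0, 0.0])
        full = compute_efficiencies(grid, params, frame_weights=w)
        sub = PairGrid(
            r=grid.r[:2],
            kappa2=grid.kappa2[:2],
            w_donor=grid.w_donor[:2],
            w_acceptor=grid.w_acceptor[:2],
            z_donor=grid.z_donor[:2],
            z_acceptor=grid.z_acceptor[:2],
        )
        ref = compute_efficiencies(sub, params)
        assert full.e_static == pytest.approx(ref.e_static, abs=1e-14)
        assert full.e_dynamic == pytest.approx(ref.e_dynamic, abs=1e-14)


class TestPairGridInvariants:
    def test_swap_transposes_and_preserves_kappa(self):
        rng = np.random.default_rng(30)
        grid = _random_grid(rng, 2, 3, 4)
        sw = grid.transpose()
        np.testing.assert_array_equal(sw.r, grid.r.transpose(0, 2, 1))
        np.testing.assert_array_equal(sw.kappa2, grid.kappa2.transpose(0, 2, 1))
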