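import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sxcalib.errormodels import LOG_HALF_NORMAL_NORM, MM24Params
from sxcalib.mm24 import (
    MM24Calibration,
    PairwiseDifferenceSet,
    build_pair_set,
    cantor_pair,
    fit_mm24,
    initialize_mm24,
    miller_seed,
    mm24_loss_and_gradient,
    normalized_pairwise_differences,
    subsample_pairs,
    _pair_indices_from_linear,
)
from sxcalib.reflections import UnmergedReflectionTable
from sxcalib.simulate import SimulationConfig, simulate_experiment


class TestCantorPairing:
    def test_printed_values(self):
        assert cantor_pair(0, 0) == 0
        assert cantor_pair(1, 2) == 8

    def test_injective_by_exhaustion(self):
        seen = {
            cantor_pair(a, b)
            for a, b in itertools.product(range(301), repeat=2)
        }
        assert len(seen) == 301 * 301

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cantor_pair(-1, 0)


class TestMillerSeed:
    def test_boundaries(self):
        miller_seed(999, 0, 0)
        miller_seed(-999, 0, 0)
        with pytest.raises(ValueError):
            miller_seed(1000, 0, 0)
        with pytest.raises(ValueError):
            miller_seed(-1000, 0, 0)

    def test_unique_on_21_cubed_grid(self):
        rng = range(-10, 11)
        seeds = {
            miller_seed(h, k, l)
            for h, k, l in itertools.product(rng, rng, rng)
        }
        assert len(seeds) == 21**3

    def test_offset_additivity(self):
        assert miller_seed(1, 2, 3, 5) == miller_seed(1, 2, 3, 0) + 5


class TestSubsampling:
    def test_small_group_keeps_all_pairs(self):
        j, k = subsample_pairs(3, 1, 2, 3)
        assert len(j) == 3
        assert set(zip(j.tolist(), k.tolist())) == {(0, 1), (0, 2), (1, 2)}

    def test_large_group_capped_at_100(self):
        j, k = subsample_pairs(300, 1, 2, 3)  # 44850 candidates
        assert len(j) == 100
        assert np.all(j < k)
        assert len(set(zip(j.tolist(), k.tolist()))) == 100

    def test_deterministic_and_offset_sensitive(self):
        a = subsample_pairs(50, 4, -2, 7)
        b = subsample_pairs(50, 4, -2, 7)
        c = subsample_pairs(50, 4, -2, 7, extra_offset=1)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not (
            np.array_equal(a[0], c[0]) and np.array_equal(a[1], c[1])
        )

    @pytest.mark.parametrize("n", [3, 5, 17])
    def test_linear_index_decode_matches_enumeration(self, n):
        pairs = list(itertools.combinations(range(n), 2))
        lin = np.arange(len(pairs))
        j, k = _pair_indices_from_linear(lin, n)
        assert list(zip(j.tolist(), k.tolist())) == pairs


def _two_obs_table(i1, i2, sigma):
    refl = pd.DataFrame(
        {
            "h": [1, 1],
            "k": [0, 0],
            "l": [0, 0],
            "lattice_id": ["a", "b"],
            "intensity": [i1, i2],
            "sigma": [sigma, sigma],
        }
    )
    lat = pd.DataFrame({"lattice_id": ["a", "b"], "cc": [0.5, 0.5]})
    return UnmergedReflectionTable(refl, lat)


class TestOmega:
    def test_equal_intensities_give_zero(self):
        table = _two_obs_table(10.0, 10.0, 1.0)
        pairs = build_pair_set(table)
        om = normalized_pairwise_differences(
            pairs, table, MM24Params(1.0, 0.0, 0.0, 0.0)
        )
        assert om.omega[0] == 0.0

    def test_hand_value(self):
        # I = {4, 6}, sigma' = 1 each: omega = 2/sqrt(2)
        table = _two_obs_table(4.0, 6.0, 1.0)
        pairs = build_pair_set(table)
        om = normalized_pairwise_differences(
            pairs, table, MM24Params(1.0, 0.0, 0.0, 0.0)
        )
        assert om.omega[0] == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_invariant_under_joint_rescale(self, small_sim):
        _, table, _ = small_sim
        p = MM24Params(1.2, 0.01, 0.15, 2.0)
        pairs = build_pair_set(table)
        om1 = normalized_pairwise_differences(pairs, table, p)
        refl = table.reflections.copy()
        refl["intensity"] *= 3.0
        refl["sigma"] *= 3.0
        scaled = UnmergedReflectionTable(refl, table.lattices)
        pairs2 = build_pair_set(scaled)
        om2 = normalized_pairwise_differences(pairs2, scaled, p)
        np.testing.assert_allclose(om2.omega, om1.omega, rtol=1e-10)


class TestLoss:
    def test_closed_form_at_zero_omega_unit_scales(self):
        # two identical observations with sigma chosen so the pair scale
        # s = sqrt(sigma'^2 + sigma'^2) = 1; NLL = -m log sqrt(2/pi)
        table = _two_obs_table(10.0, 10.0, math.sqrt(0.5))
        pairs = build_pair_set(table)
        nll, _ = mm24_loss_and_gradient(
            pairs, table, MM24Params(1.0, 0.0, 0.0, 0.0)
        )
        assert nll == pytest.approx(-1 * LOG_HALF_NORMAL_NORM, rel=1e-12)

    @pytest.mark.parametrize("likelihood", ["half_normal", "half_t"])
    def test_gradient_matches_finite_differences(self, small_sim, likelihood):
        _, table, _ = small_sim
        pairs = build_pair_set(table)
        rng = np.random.default_rng(9)
        for _ in range(8):
            params = MM24Params(
                s_fac=rng.uniform(0.5, 2.0),
                s_add_0=rng.uniform(0.005, 0.1),
                s_add_1=rng.uniform(0.01, 0.5),
                s_add_2=rng.uniform(0.1, 5.0),
                nu=rng.uniform(2.0, 30.0) if likelihood == "half_t" else None,
                likelihood_kind=likelihood,
            )
            _, grad = mm24_loss_and_gradient(pairs, table, params)
            fields = ["s_fac", "s_add_0", "s_add_1", "s_add_2"]
            if likelihood == "half_t":
                fields.append("nu")
            for i, f in enumerate(fields):
                eps = 1e-6 * max(abs(getattr(params, f)), 1e-2)
                up = dataclasses.replace(params, **{f: getattr(params, f) + eps})
                dn = dataclasses.replace(params, **{f: getattr(params, f) - eps})
                fd = (
                    mm24_loss_and_gradient(pairs, table, up)[0]
                    - mm24_loss_and_gradient(pairs, table, dn)[0]
                ) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_half_t_converges_to_half_normal_at_large_nu(self, small_sim):
        _, table, _ = small_sim
        pairs = build_pair_set(table)
        pn = MM24Params(1.2, 0.01, 0.15, 2.0)
        pt = dataclasses.replace(pn, nu=1e7, likelihood_kind="half_t")
        nll_n, _ = mm24_loss_and_gradient(pairs, table, pn)
        nll_t, _ = mm24_loss_and_gradient(pairs, table, pt)
        assert nll_t == pytest.approx(nll_n, abs=1e-4)

    def test_invariant_under_lattice_relabeling_full_pairs(self, hand_table):
        p = MM24Params(1.1, 0.02, 0.1, 1.0)
        pairs = build_pair_set(hand_table, cap=10**6)
        nll1, _ = mm24_loss_and_gradient(pairs, hand_table, p)
        # rename lattices (non order-preserving) and keep cc attached
        mapping = {"a": "z", "b": "m", "c": "a"}
        refl = hand_table.reflections.copy()
        refl["lattice_id"] = refl["lattice_id"].map(mapping)
        lat = hand_table.lattices.copy()
        lat["lattice_id"] = lat["lattice_id"].map(mapping)
        relabeled = UnmergedReflectionTable(refl, lat)
        pairs2 = build_pair_set(relabeled, cap=10**6)
        nll2, _ = mm24_loss_and_gradient(pairs2, relabeled, p)
        assert nll2 == pytest.approx(nll1, rel=1e-12)


class TestInitialization:
    def test_constants_are_0_001(self, small_sim):
        _, table, _ = small_sim
        init = initialize_mm24(table)
        assert init.s_add_0 == 0.001
        assert init.s_add_2 == 0.001

    def test_bin_upper_edge_is_tenth_of_max_mean(self, small_sim):
        _, table, _ = small_sim
        from sxcalib.reflections import miller_group_arrays

        _, _, _, _, means = miller_group_arrays(table)
        # binning is internal; verify via a direct reconstruction
        hi = 0.1 * means.max()
        edges = np.linspace(0.0, hi, 101)
        assert edges[-1] == pytest.approx(0.1 * means.max(), rel=1e-15)

    def test_recovery_with_no_additional_error(self):
        config = SimulationConfig(
            seed=5,
            n_miller=2000,
            mean_multiplicity=15,
            n_lattices=50,
            counting_inflation=0.0,
            true_params=MM24Params(s_fac=1.4, s_add_0=1e-9, s_add_1=0.0, s_add_2=0.0),
        )
        table, _ = simulate_experiment(config)
        init = initialize_mm24(table)
        assert init.s_add_1 <= 0.02
        assert init.s_fac == pytest.approx(1.4, rel=0.15)

    def test_fallback_when_bins_starved(self, hand_table):
        with pytest.warns(UserWarning):
            init = initialize_mm24(hand_table)
        assert init.s_fac == 1.0
        assert init.s_add_1 == 0.05


class TestFitDeterminism:
    def test_bit_identical_refits(self, small_sim):
        _, table, _ = small_sim
        r1 = fit_mm24(table, likelihood="half_normal")
        r2 = fit_mm24(table, likelihood="half_normal")
        assert r1.params == r2.params
        assert r1.final_nll == r2.final_nll

    def test_invariant_under_row_permutation(self, small_sim):
        _, table, _ = small_sim
        refl = table.reflections.sample(frac=1.0, random_state=3)
        permuted = UnmergedReflectionTable(refl, table.lattices)
        r1 = fit_mm24(table, likelihood="half_normal")
        r2 = fit_mm24(permuted, likelihood="half_normal")
        assert r1.params == r2.params

    def test_extra_offset_changes_subsample(self, small_sim):
        _, table, _ = small_sim
        p1 = build_pair_set(table, cap=5)
        p2 = build_pair_set(table, cap=5, extra_offset=17)
        assert not np.array_equal(p1.i_j, p2.i_j)

    def test_scale_equivariance_of_fit(self, small_sim):
        _, table, _ = small_sim
        refl = table.reflections.copy()
        refl["intensity"] *= 10.0
        refl["sigma"] *= 10.0
        scaled = UnmergedReflectionTable(refl, table.lattices)
        r1 = fit_mm24(table, likelihood="half_normal")
        r2 = fit_mm24(scaled, likelihood="half_normal")
        assert r2.params.s_fac == pytest.approx(r1.params.s_fac, rel=1e-6)
        assert r2.params.s_add_1 == pytest.approx(r1.params.s_add_1, rel=1e-4)


class TestFitRecovery:
    def test_self_consistent_omega_spread(self, mm24_halfnormal_fit):
        om = mm24_halfnormal_fit.omega()
        # omega is a folded statistic: its scale is the RMS about zero
        assert 0.95 <= np.sqrt(np.mean(om.omega**2)) <= 1.05

    def test_nu_recovery_with_t_noise(self):
        config = SimulationConfig(seed=6, noise_family="t", nu_true=5.0)
        table, _ = simulate_experiment(config)
        res = fit_mm24(table, likelihood="half_t")
        assert 1.5 < res.params.nu < 50.0

    def test_nu_hits_upper_bound_with_normal_noise(self, recovery_sim):
        _, table, _ = recovery_sim
        res = fit_mm24(table, likelihood="half_t")
        assert res.params.nu == pytest.approx(200.0, rel=1e-6)


class TestPairingProperties:
    """Derandomized property checks of the deterministic seeding."""

    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 10**4), st.integers(0, 10**4))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_cantor_inverse_recovers_arguments(self, k1, k2):
        # invert pi via the triangular root: exact integer arithmetic
        z = cantor_pair(k1, k2)
        w = (math.isqrt(8 * z + 1) - 1) // 2
        t = w * (w + 1) // 2
        assert (w - (z - t), z - t) == (k1, k2)

    @given(
        st.integers(-999, 999),
        st.integers(-999, 999),
        st.integers(-999, 999),
        st.integers(0, 1000),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_seed_nonnegative_and_offset_linear(self, h, k, l, off):
        assert miller_seed(h, k, l) >= 0
        assert miller_seed(h, k, l, off) == miller_seed(h, k, l) + off
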