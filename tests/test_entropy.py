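"""Windowing, truncation and histogram/MIST entropy estimation."""

import math

import numpy as np
import pytest

from entropath.constants import KB_KCAL, ROOM_T
from entropath.entropy import (EstimatorConfig, StructuralWindow,
                               entropy_profile, fixed_edges,
                               induced_columns, marginal_entropies,
                               MoietyDefinition, mist_entropy,
                               pairwise_mutual_information, recenter_torsions,
                               rice_bins, segment_windows, truncate_sparse)
from entropath.entropy import _digitize, _plugin_entropy


class TestSegmentWindows:
    def test_direct_binning(self):
        windows = segment_windows(np.array([-0.25, -0.15, -0.05]), 0.1,
                                  lo=-0.3, hi=0.0)
        assert [w.population for w in windows] == [1, 1, 1]
        # ordered from the TS side (largest dr) downward
        assert windows[0].lo == pytest.approx(-0.1)

    def test_edge_value_goes_to_upper_bin(self):
        windows = segment_windows(np.array([-0.2, -0.1]), 0.1, lo=-0.2, hi=0.0)
        by_lo = {round(w.lo, 10): w.population for w in windows}
        assert by_lo == {-0.2: 1, -0.1: 1}

    def test_counts_match_numpy_histogram(self, rng):
        dr = rng.uniform(-0.6, 0.6, 10_000)
        windows = segment_windows(dr, 0.05, lo=-0.6, hi=0.6)
        ref, edges = np.histogram(dr, bins=24, range=(-0.6, 0.6))
        ours = {round(w.lo, 10): w.population for w in windows}
        for k, count in enumerate(ref):
            if count:
                assert ours[round(edges[k], 10)] == count

    def test_each_configuration_in_exactly_one_window(self, rng):
        dr = rng.uniform(-0.5, 0.5, 2000)
        windows = segment_windows(dr, 0.05)
        seen = np.concatenate([w.members for w in windows])
        assert np.array_equal(np.sort(seen), np.arange(dr.size))


class TestTruncateSparse:
    def test_printed_rule_on_chosen_counts(self):
        windows = [StructuralWindow(-0.1 * (k + 1), -0.1 * k,
                                    np.arange(n))
                   for k, n in enumerate((100, 30, 20))]
        survivors = truncate_sparse(windows)
        assert [w.population for w in survivors] == [100, 30]

    def test_equal_populations_all_survive(self):
        windows = [StructuralWindow(-0.1 * (k + 1), -0.1 * k, np.arange(40))
                   for k in range(5)]
        assert len(truncate_sparse(windows)) == 5

    def test_boundary_is_strict_less_than(self):
        windows = [StructuralWindow(-0.1, 0.0, np.arange(100)),
                   StructuralWindow(-0.2, -0.1, np.arange(25))]
        assert len(truncate_sparse(windows)) == 2

    def test_all_removed_raises(self):
        with pytest.raises(ValueError):
            truncate_sparse([])


class TestMarginalEntropies:
    def test_uniform_differential_entropy_is_zero(self, rng):
        x = rng.uniform(0, 1, (100_000, 1))
        s = marginal_entropies(x, fixed_edges(x, 32))[0]
        assert abs(s) < 0.02

    def test_gaussian_matches_closed_form(self, rng):
        sigma = 0.7
        x = rng.normal(0, sigma, (100_000, 1))
        s = marginal_entropies(x, fixed_edges(x, rice_bins(100_000)))[0]
        truth = 0.5 * math.log(2 * math.pi * math.e * sigma**2)
        assert s == pytest.approx(truth, rel=0.02)

    def test_doubling_scale_adds_ln2(self, rng):
        x = rng.normal(0, 1.0, (50_000, 1))
        s1 = marginal_entropies(x, fixed_edges(x, 32))[0]
        y = 2.0 * x
        s2 = marginal_entropies(y, fixed_edges(y, 32))[0]
        assert s2 - s1 == pytest.approx(math.log(2), abs=0.02)


class TestMutualInformation:
    def test_independent_coordinates_near_zero(self, rng):
        t = rng.normal(0, 1, (100_000, 2))
        mi = pairwise_mutual_information(t, fixed_edges(t, 32), (0, 1))
        assert mi < 0.01

    def test_perfect_correlation_is_maximal(self, rng):
        a = rng.normal(0, 1, 20_000)
        t = np.column_stack([a, a])
        edges = fixed_edges(t, 32)
        mi = pairwise_mutual_information(t, edges, (0, 1))
        s1 = marginal_entropies(t, edges)[0] - math.log(edges[0][1] - edges[0][0])
        assert mi == pytest.approx(s1, rel=0.01)

    def test_bivariate_gaussian_closed_form(self, rng):
        rho = 0.8
        t = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 100_000)
        mi = pairwise_mutual_information(t, fixed_edges(t, rice_bins(100_000)),
                                         (0, 1))
        assert mi == pytest.approx(-0.5 * math.log(1 - rho**2), rel=0.05)


class TestMistEntropy:
    def test_two_variables_equal_joint_histogram_entropy(self, rng):
        rho = 0.6
        t = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 20_000)
        edges = fixed_edges(t, 24)
        s = mist_entropy(t, edges)
        dig0 = _digitize(t[:, 0], edges[0])
        dig1 = _digitize(t[:, 1], edges[1])
        joint = np.bincount(dig0 * 24 + dig1, minlength=24 * 24)
        s2 = _plugin_entropy(joint, t.shape[0], True) \
            + math.log(edges[0][1] - edges[0][0]) \
            + math.log(edges[1][1] - edges[1][0])
        assert s == pytest.approx(s2, abs=1e-12)

    def test_markov_chain_recovered_within_tolerance(self, rng):
        n = 100_000
        a = rng.normal(0, 1, n)
        b = 0.7 * a + rng.normal(0, 0.5, n)
        c = 0.6 * b + rng.normal(0, 0.7, n)
        t = np.column_stack([a, b, c])
        edges = fixed_edges(t, 20)
        s = mist_entropy(t, edges)
        d0 = _digitize(t[:, 0], edges[0])
        d1 = _digitize(t[:, 1], edges[1])
        d2 = _digitize(t[:, 2], edges[2])
        joint = np.bincount((d0 * 20 + d1) * 20 + d2, minlength=20**3)
        s3 = _plugin_entropy(joint, n, True) \
            + sum(math.log(e[1] - e[0]) for e in edges)
        assert s == pytest.approx(s3, rel=0.02)

    def test_independent_coordinates_sum_of_marginals(self, rng):
        t = rng.normal(0, 1, (50_000, 4))
        edges = fixed_edges(t, 24)
        s = mist_entropy(t, edges)
        assert s == pytest.approx(marginal_entropies(t, edges).sum(),
                                  rel=0.01)

    def test_mist_never_exceeds_marginal_sum(self, rng):
        for _ in range(5):
            t = rng.normal(0, 1, (3000, 5))
            t[:, 1] += 0.8 * t[:, 0]
            edges = fixed_edges(t, 16)
            assert mist_entropy(t, edges) \
                <= marginal_entropies(t, edges).sum() + 1e-12


def make_profile_windows(tables):
    """Stack per-window tables into (windows, table, members)."""
    table = np.concatenate(tables, axis=0)
    windows = []
    start = 0
    for k, t in enumerate(tables):
        members = np.arange(start, start + t.shape[0])
        windows.append(StructuralWindow(-0.05 * (k + 1), -0.05 * k, members))
        start += t.shape[0]
    return windows, table


class TestEntropyProfile:
    def test_null_profile_is_flat_within_bootstrap_error(self, rng):
        tables = [rng.normal(0, 0.3, (2000, 4)) for _ in range(5)]
        windows, table = make_profile_windows(tables)
        prof = entropy_profile(windows, table,
                               config=EstimatorConfig(n_bootstrap=30))
        assert np.all(np.abs(prof.minus_t_delta_s)
                      <= 3.0 * np.maximum(prof.standard_errors, 0.005))

    def test_engineered_variance_inflation_gives_minus_rt(self, rng):
        """One coordinate's variance inflated by e^2 in the middle window
        shifts -T dS by about -RT = -0.5925 kcal/mol at 298.15 K."""
        scale = np.array([1.0, 1.0, 1.0, 1.0])
        tables = []
        for k in range(5):
            t = rng.normal(0, 0.2, (4000, 4)) * scale
            if k == 2:
                t[:, 0] *= math.e
            tables.append(t)
        windows, table = make_profile_windows(tables)
        prof = entropy_profile(windows, table,
                               config=EstimatorConfig(n_bootstrap=30))
        expected = -ROOM_T * KB_KCAL
        k_mid = 2
        assert prof.minus_t_delta_s[k_mid] == pytest.approx(
            expected, abs=max(3 * prof.standard_errors[k_mid], 0.03))

    def test_profile_invariant_to_duplication(self, rng):
        tables = [rng.normal(0, 0.3, (500, 3)) for _ in range(3)]
        windows, table = make_profile_windows(tables)
        cfg = EstimatorConfig(n_bootstrap=0, bins=16)
        a = entropy_profile(windows, table, config=cfg)
        dup_windows, dup_table = make_profile_windows(
            [np.concatenate([t, t]) for t in tables])
        b = entropy_profile(dup_windows, dup_table, config=cfg)
        # Miller-Madow term halves, everything else identical
        assert np.allclose(a.minus_t_delta_s, b.minus_t_delta_s, atol=0.02)

    def test_reference_window_is_zero(self, rng):
        tables = [rng.normal(0, 1, (300, 3)) for _ in range(4)]
        windows, table = make_profile_windows(tables)
        prof = entropy_profile(windows, table,
                               config=EstimatorConfig(n_bootstrap=0))
        assert prof.minus_t_delta_s[prof.reference_index] == 0.0

    def test_small_windows_dropped(self, rng):
        tables = [rng.normal(0, 1, (300, 3)), rng.normal(0, 1, (10, 3)),
                  rng.normal(0, 1, (300, 3))]
        windows, table = make_profile_windows(tables)
        prof = entropy_profile(windows, table,
                               config=EstimatorConfig(n_bootstrap=0))
        assert len(prof.centers) == 2


class TestMoietyProfiles:
    def test_full_atom_set_equals_full_profile(self, rng, default_spec):
        from entropath.internal_coordinates import build_scheme
        from entropath.toy_system import build_topology

        topo = build_topology(default_spec)
        scheme = build_scheme(topo.connectivity, root=1)
        tables = [rng.normal(0.5, 0.3, (400, scheme.n_coordinates))
                  for _ in range(3)]
        windows, table = make_profile_windows(tables)
        cfg = EstimatorConfig(n_bootstrap=0, bins=12)
        full = entropy_profile(windows, table, config=cfg)
        moiety = MoietyDefinition.of("all", range(6))
        cols = induced_columns(scheme, moiety)
        assert cols == list(range(scheme.n_coordinates))
        sub = entropy_profile(windows, table, config=cfg, columns=cols)
        assert np.allclose(full.minus_t_delta_s, sub.minus_t_delta_s)

    def test_disjoint_independent_moieties_add(self, rng):
        """For independent column blocks, block MIST entropies sum to the
        total within estimator tolerance."""
        t = rng.normal(0, 1, (30_000, 4))
        edges = fixed_edges(t, 20)
        total = mist_entropy(t, edges)
        left = mist_entropy(t[:, :2], edges[:2])
        right = mist_entropy(t[:, 2:], edges[2:])
        assert total == pytest.approx(left + right, rel=0.01)

    def test_frozen_moiety_zero_profile(self, rng):
        tables = []
        for k in range(3):
            t = rng.normal(0, 1, (400, 3))
            t[:, 2] = 1.234   # frozen coordinate
            tables.append(t)
        windows, table = make_profile_windows(tables)
        prof = entropy_profile(windows, table, columns=[2],
                               config=EstimatorConfig(n_bootstrap=0, bins=8))
        assert np.allclose(prof.minus_t_delta_s, 0.0)


class TestTorsionRecentering:
    def test_wrapped_bimodal_becomes_unimodal(self, rng):
        ang = np.mod(np.pi + rng.normal(0, 0.2, 5000) + np.pi, 2 * np.pi) - np.pi
        table = ang[:, None]
        out = recenter_torsions(table, np.array([True]))
        assert np.std(out) < 0.3   # single lobe after recentring
        edges = fixed_edges(out, 24)
        s = marginal_entropies(out, edges)[0]
        truth = 0.5 * math.log(2 * math.pi * math.e * 0.04)
        assert s == pytest.approx(truth, abs=0.05)
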