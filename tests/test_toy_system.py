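"""Model surface, quasiclassical sampling and the integrator."""

import math

import numpy as np
import pytest

from entropath.constants import KB_KCAL, KCAL_PER_WAVENUMBER, ROOM_T, \
    wavenumber_from_eigenvalue
from entropath.toy_system import (InitialCondition, ModelSurfaceSpec,
                                  generate_ensemble, normal_mode_sample,
                                  propagate, reactive_potential,
                                  saddle_geometry, saddle_normal_modes,
                                  trap_study_spec)
from entropath.toy_system import _kinetic_energy
from entropath.trajectory_io import Outcome


class TestReactivePotential:
    def test_reactant_minimum_has_zero_energy(self, default_spec):
        assert reactive_potential(0.0, 1.0, default_spec) == 0.0

    def test_saddle_is_index_one_by_finite_difference(self, default_spec):
        h = 1e-5
        hess = np.zeros((2, 2))
        pts = [(h, 0.0), (0.0, h)]
        for a in range(2):
            for b in range(2):
                da, db = pts[a], pts[b]
                vpp = reactive_potential(0 + da[0] + db[0], -1 + da[1] + db[1], default_spec)
                vpm = reactive_potential(0 + da[0] - db[0], -1 + da[1] - db[1], default_spec)
                vmp = reactive_potential(0 - da[0] + db[0], -1 - da[1] + db[1], default_spec)
                vmm = reactive_potential(0 - da[0] - db[0], -1 - da[1] - db[1], default_spec)
                hess[a, b] = (vpp - vpm - vmp + vmm) / (4 * h * h)
        eig = np.linalg.eigvalsh(hess)
        assert (eig < 0).sum() == 1

    def test_asymmetry_is_the_only_odd_term(self, default_spec, rng):
        g = 0.7
        spec = ModelSurfaceSpec(asymmetry=g)
        for _ in range(20):
            x, y = rng.uniform(-2, 2), rng.uniform(-2, 2)
            diff = reactive_potential(x, y, spec) - reactive_potential(-x, y, spec)
            assert diff == pytest.approx(2 * g * x, abs=1e-12)

    def test_nonfinite_inputs_rejected(self, default_spec):
        with pytest.raises(ValueError):
            reactive_potential(np.nan, 0.0, default_spec)


class TestNormalModeSample:
    def test_saddle_has_exactly_one_imaginary_mode(self, default_modes):
        (coords, lam, vec), topo = default_modes
        assert int((lam < 0).sum()) == 1
        assert lam.size == 3 * coords.shape[0] - 6

    def test_zero_temperature_gives_exact_zero_point_energy(
            self, default_spec, default_modes):
        modes, _ = default_modes
        _, lam, _ = modes
        ic = normal_mode_sample(default_spec, temperature=0.0, seed=5,
                                modes=modes)
        neg = int(np.argmin(lam))
        for i, lam_i in enumerate(lam):
            if i == neg:
                continue
            zpe = 0.5 * wavenumber_from_eigenvalue(lam_i) * KCAL_PER_WAVENUMBER
            assert ic.mode_energies[i] == pytest.approx(zpe, rel=1e-12)

    def test_thermal_mode_energy_matches_quantum_average(self):
        """10^4 samples of a 1000 cm^-1 mode at 298.15 K agree with the
        closed-form Boltzmann average over quantum numbers to 3 SE."""
        nu = 1000.0
        hnu = nu * KCAL_PER_WAVENUMBER
        kt = KB_KCAL * ROOM_T
        r = math.exp(-hnu / kt)
        expected = hnu * (0.5 + r / (1 - r))
        rng = np.random.default_rng(77)
        n = 10_000
        draws = hnu * (rng.geometric(1 - r, n) - 1 + 0.5)
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_same_seed_is_bitwise_identical(self, default_spec, default_modes):
        modes, _ = default_modes
        a = normal_mode_sample(default_spec, seed=9, modes=modes)
        b = normal_mode_sample(default_spec, seed=9, modes=modes)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert np.array_equal(a.velocities, b.velocities)


class TestPropagate:
    def test_stationary_at_saddle_with_zero_velocity(self, default_spec,
                                                     default_modes):
        _, topo = default_modes
        coords = topo.saddle_coordinates.copy()
        ic = InitialCondition(coords, np.zeros_like(coords),
                              np.zeros(12), seed=0)
        traj = propagate(ic, default_spec, topo, max_steps=200)
        drift = np.linalg.norm(traj.coordinates - coords[None], axis=(-2, -1))
        assert drift.max() < 1e-9

    def test_zero_velocity_at_product_minimum_stays_put(self, default_spec,
                                                        default_modes):
        """A relaxed product-basin geometry with zero velocities remains
        at the minimum to numerical tolerance."""
        from scipy.optimize import minimize

        from entropath.toy_system import gradient, potential_energy

        modes, topo = default_modes
        ic = normal_mode_sample(default_spec, seed=3, modes=modes)
        traj = propagate(ic, default_spec, topo)
        r0 = traj.coordinates[-1]
        res = minimize(
            lambda x: potential_energy(x.reshape(r0.shape), default_spec, topo),
            r0.ravel(),
            jac=lambda x: gradient(x.reshape(r0.shape), default_spec,
                                   topo).ravel(),
            method="BFGS", options={"gtol": 1e-10})
        rmin = res.x.reshape(r0.shape)
        ic0 = InitialCondition(rmin, np.zeros_like(rmin), np.zeros(12), 0)
        still = propagate(ic0, default_spec, topo, max_steps=200)
        wander = np.linalg.norm(still.coordinates - rmin[None], axis=(-2, -1))
        assert wander.max() < 1e-6

    def test_median_secular_drift_small(self, default_spec, default_modes):
        """Median secular drift over 500 steps stays a small fraction of
        the initial kinetic energy on the default surface at dt = 1 fs
        (and well below the trajectory-exclusion tolerance)."""
        modes, topo = default_modes
        rels = []
        for seed in range(10):
            ic = normal_mode_sample(default_spec, seed=seed, modes=modes)
            traj = propagate(ic, default_spec, topo, max_steps=500)
            ke0 = _kinetic_energy(ic.velocities, default_spec.mass)
            rels.append(traj.max_energy_drift / ke0)
        assert np.median(rels) < 2.5e-4

    def test_halving_dt_reduces_energy_error_fourfold(self, default_spec,
                                                      default_modes):
        modes, topo = default_modes
        ic = normal_mode_sample(default_spec, seed=5, modes=modes)
        errs = []
        for dt in (1.0, 0.5):
            traj = propagate(ic, default_spec, topo, dt=dt,
                             max_steps=int(400 / dt))
            et = traj.energies + _kinetic_energy(traj.velocities,
                                                 default_spec.mass)
            errs.append(np.max(np.abs(et - et[traj.ts_frame_index])))
        ratio = errs[0] / errs[1]
        assert 3.0 < ratio < 5.0


class TestGenerateEnsemble:
    def test_symmetric_surface_gives_equal_channels(self, small_ensemble):
        counts = small_ensemble.outcome_counts()
        na, nb = counts["adduct_42"], counts["adduct_64"]
        n = na + nb
        assert abs(na - nb) <= 3 * math.sqrt(n * 0.25) + 1

    def test_reproducible_under_seed(self, default_spec):
        a = generate_ensemble(default_spec, 16, seed=5)
        b = generate_ensemble(default_spec, 16, seed=5)
        assert len(a) == len(b)
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert np.array_equal(ta.coordinates, tb.coordinates)
            assert ta.outcome == tb.outcome

    def test_asymmetry_shifts_channel_ratio_monotonically(self):
        """More negative g favours channel A (lowers the +x channel).

        The bare surface commits nearly ballistically, so the committor
        responds weakly to the tilt; the scan spans most of the viable g
        range (the saddle ceases to exist near |g| = 2.2)."""
        fracs = []
        for g in (0.0, -1.0, -2.0):
            ens = generate_ensemble(ModelSurfaceSpec(asymmetry=g), 400,
                                    seed=88)
            c = ens.outcome_counts()
            fracs.append(c["adduct_42"] / max(c["adduct_42"] + c["adduct_64"], 1))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_shelf_increases_roaming_residence_on_channel_a(self):
        """tau > 0 on channel A increases the mean number of slow
        (|d d2/dt| <= 0.01 A/fs) frames per channel-A trajectory."""
        from entropath.energy import bond_velocity
        from entropath.trajectory_io import bond_length_series

        def residence(ens):
            per = []
            for t in ens.trajectories:
                if t.outcome != Outcome.ADDUCT_42:
                    continue
                d = bond_length_series(t, ens.bond_definitions[2])
                dr = d - ens.tss_bond_lengths[2]
                v = bond_velocity(t, ens.bond_definitions[2])
                m = (dr >= -0.55) & (dr < -0.2)
                per.append(np.sum(m & (np.abs(v) <= 0.01)))
            return np.mean(per)

        base = generate_ensemble(trap_study_spec(0.0), 500, seed=31)
        shelf = generate_ensemble(trap_study_spec(0.45), 500, seed=31)
        assert residence(shelf) > residence(base)

    def test_flagged_trajectories_are_excluded_and_counted(self, small_ensemble):
        meta = small_ensemble.meta
        assert meta["n_flagged_energy_drift"] >= 0
        assert all(not t.energy_drift_exceeded
                   for t in small_ensemble.trajectories)
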