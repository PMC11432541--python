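"""Langevin engine: initialisation, potentials, integration, collapse detection."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from sbsfold import _kernels
from sbsfold.md_engine import (
    SimulationDiverged,
    detect_collapse,
    init_saw,
    place_binders,
    radius_of_gyration,
    run_dynamics,
    system_energy,
    system_forces,
    _system_arrays,
)
from sbsfold.model_core import (
    BinderEnsemble,
    BinderType,
    Conformation,
    PolymerSpec,
    SimulationParams,
)


def _min_image_min_distance(coords, L, exclude_bonded=True):
    wrapped = coords % L
    tree = cKDTree(wrapped, boxsize=L)
    d, idx = tree.query(wrapped, k=3)
    best = np.inf
    n = len(coords)
    for i in range(n):
        for dist, j in zip(d[i, 1:], idx[i, 1:]):
            if exclude_bonded and abs(i - j) == 1:
                continue
            best = min(best, dist)
    return best


class TestInitSaw:
    def test_dimer(self):
        spec = PolymerSpec.homopolymer(2)
        conf = init_saw(spec, SimulationParams(box_edge=10.0), seed=0)
        bond = np.linalg.norm(conf.bead_coords[1] - conf.bead_coords[0])
        assert 0.9 <= bond <= 1.1

    def test_unit_bonds_and_self_avoidance_many_seeds(self):
        spec = PolymerSpec.homopolymer(100)
        params = SimulationParams(box_edge=20.0)
        for seed in range(40):
            conf = init_saw(spec, params, seed)
            bonds = np.linalg.norm(np.diff(conf.bead_coords, axis=0), axis=1)
            assert np.allclose(bonds, 1.0, atol=1e-9)
            assert _min_image_min_distance(conf.bead_coords, 20.0) >= 0.9

    def test_reproducible_per_seed(self):
        spec = PolymerSpec.homopolymer(50)
        params = SimulationParams(box_edge=15.0)
        a = init_saw(spec, params, 7).bead_coords
        b = init_saw(spec, params, 7).bead_coords
        assert np.array_equal(a, b)

    def test_saw_scaling_exponent(self):
        """End-to-end distance scales as N^nu with the SAW exponent ~0.588.

        A large box keeps even the longest chain unconfined, so the walk's
        intrinsic Flory scaling is what is measured."""
        params = SimulationParams(box_edge=300.0)
        sizes = np.array([50, 100, 200, 400])
        mean_r2 = []
        for n in sizes:
            spec = PolymerSpec.homopolymer(int(n))
            r2 = [
                np.sum((c.bead_coords[-1] - c.bead_coords[0]) ** 2)
                for c in (init_saw(spec, params, s) for s in range(24))
            ]
            mean_r2.append(np.mean(r2))
        slope = np.polyfit(np.log(sizes), 0.5 * np.log(mean_r2), 1)[0]
        assert abs(slope - 0.588) < 0.05

    def test_box_too_small_raises(self):
        spec = PolymerSpec.homopolymer(500)
        with pytest.raises(RuntimeError, match="larger box"):
            init_saw(spec, SimulationParams(box_edge=7.0), seed=0)


class TestPlaceBinders:
    def test_zero_binders_noop(self, homopolymer_small):
        spec, params = homopolymer_small
        conf = init_saw(spec, params, 0)
        out = place_binders(conf, BinderEnsemble(), spec, params, 1)
        assert out.n_binders == 0
        assert np.array_equal(out.bead_coords, conf.bead_coords)

    def test_count_resolution_and_min_separation(self, homopolymer_small):
        spec, params = homopolymer_small
        ens = BinderEnsemble.uniform(["A"], 0.05, 2.0)
        conf = place_binders(init_saw(spec, params, 0), ens, spec, params, 1)
        expected = ens.total_count(params.box_edge)
        assert conf.n_binders == expected
        allc = np.vstack([conf.bead_coords, conf.binder_coords])
        tree = cKDTree(allc % params.box_edge, boxsize=params.box_edge)
        pairs = tree.query_pairs(0.999)
        non_bonded = [p for p in pairs if not (max(p) < spec.n_beads and abs(p[0] - p[1]) == 1)]
        # binders never start inside the repulsive core of any particle
        assert all(min(p) < spec.n_beads and max(p) < spec.n_beads for p in non_bonded)

    def test_two_seeds_differ_same_count(self, homopolymer_small):
        spec, params = homopolymer_small
        ens = BinderEnsemble.uniform(["A"], 0.02, 2.0)
        conf = init_saw(spec, params, 0)
        a = place_binders(conf, ens, spec, params, 1)
        b = place_binders(conf, ens, spec, params, 2)
        assert a.n_binders == b.n_binders
        assert not np.array_equal(a.binder_coords, b.binder_coords)

    def test_overpacked_box_raises(self):
        spec = PolymerSpec.homopolymer(5)
        params = SimulationParams(box_edge=5.0)
        ens = BinderEnsemble({"A": BinderType(affinity=1.0, volume_fraction=0.45)})
        with pytest.raises(RuntimeError, match="packing"):
            place_binders(init_saw(spec, params, 0), ens, spec, params, 1)


class TestEnergies:
    def test_wca_zero_at_cutoff(self):
        """Two non-cognate particles at 2^(1/6) sigma: zero energy and force."""
        spec = PolymerSpec.from_lists([["A"], []], ["A"])
        params = SimulationParams(box_edge=20.0)
        r = 2.0 ** (1.0 / 6.0)
        # place a non-cognate binder-like pair: use two inert beads far from bonding
        conf = Conformation(
            bead_coords=np.array([[5.0, 5.0, 5.0], [5.0 + r + 1e-12, 5.0, 5.0]]),
            box_edge=20.0,
        )
        eb = system_energy(conf, spec, BinderEnsemble(), params)
        assert eb.repulsive == pytest.approx(0.0, abs=1e-10)

    def test_attraction_exactly_zero_at_cutoff(self):
        spec = PolymerSpec.homopolymer(2)
        params = SimulationParams(box_edge=20.0)
        ens = BinderEnsemble({"A": BinderType(affinity=3.0, count=1)})
        conf = Conformation(
            bead_coords=np.array([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0]]),
            binder_coords=np.array([[5.0, 5.0 + 1.5, 5.0]]),
            binder_labels=np.array([0]),
            box_edge=20.0,
        )
        eb = system_energy(conf, spec, ens, params)
        assert eb.attractive == pytest.approx(0.0, abs=1e-12)
        # just inside the cutoff the attraction is negative
        conf.binder_coords[0, 1] -= 0.01
        assert system_energy(conf, spec, ens, params).attractive < 0

    def test_bonded_pair_minimum_near_0_97(self):
        """FENE + WCA minimum for an isolated bond sits near 0.97 sigma."""
        params = SimulationParams()

        def u(r):
            fene = -0.5 * params.fene_k * params.fene_r0**2 * np.log(
                1 - (r / params.fene_r0) ** 2
            )
            wca = 4 * (r**-12 - r**-6) + 1 if r < params.r_rep else 0.0
            return fene + wca

        res = minimize_scalar(u, bounds=(0.7, 1.3), method="bounded")
        r_direct = res.x
        assert 0.955 < r_direct < 0.985
        # the engine's energy agrees with the closed-form sum
        spec = PolymerSpec.homopolymer(2)
        conf = Conformation(
            bead_coords=np.array([[5.0, 5.0, 5.0], [5.0 + r_direct, 5.0, 5.0]]),
            box_edge=20.0,
        )
        eb = system_energy(conf, spec, BinderEnsemble(), params)
        assert eb.total == pytest.approx(u(r_direct), rel=1e-12)

    def test_breakdown_additivity(self, tiny_system):
        spec, binders, params, conf = tiny_system
        eb = system_energy(conf, spec, binders, params)
        assert eb.total == pytest.approx(eb.fene + eb.repulsive + eb.attractive)

    def test_overstretched_bond_identified(self):
        spec = PolymerSpec.homopolymer(3)
        conf = Conformation(
            bead_coords=np.array([[5, 5, 5.0], [6, 5, 5.0], [7.7, 5, 5.0]]),
            box_edge=20.0,
        )
        with pytest.raises(SimulationDiverged, match="bond 1-2"):
            system_energy(conf, spec, BinderEnsemble(), SimulationParams())

    def test_minimum_image_translation_invariance(self, tiny_system):
        """Energies are invariant under rigid translation by any lattice vector."""
        spec, binders, params, conf = tiny_system
        e0 = system_energy(conf, spec, binders, params)
        shift = np.array([params.box_edge, -2 * params.box_edge, params.box_edge])
        moved = Conformation(
            bead_coords=conf.bead_coords + shift,
            binder_coords=conf.binder_coords + shift,
            binder_labels=conf.binder_labels,
            box_edge=params.box_edge,
        )
        e1 = system_energy(moved, spec, binders, params)
        assert e1.total == pytest.approx(e0.total, rel=1e-10)


class TestForces:
    def test_forces_are_negative_energy_gradients(self, tiny_system):
        """Central finite differences of the total energy match -F to 1e-4."""
        spec, binders, params, conf = tiny_system
        forces = system_forces(conf, spec, binders, params)
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(12):
            p = int(rng.integers(0, conf.n_beads + conf.n_binders))
            d = int(rng.integers(0, 3))

            def energy_at(delta):
                bc = conf.bead_coords.copy()
                bn = conf.binder_coords.copy()
                if p < conf.n_beads:
                    bc[p, d] += delta
                else:
                    bn[p - conf.n_beads, d] += delta
                c2 = Conformation(
                    bead_coords=bc, binder_coords=bn,
                    binder_labels=conf.binder_labels, box_edge=params.box_edge,
                )
                return system_energy(c2, spec, binders, params).total

            fd = -(energy_at(h) - energy_at(-h)) / (2 * h)
            scale = max(abs(forces[p, d]), 1.0)
            assert abs(fd - forces[p, d]) / scale < 1e-4

    def test_neighbour_list_matches_all_pairs(self, tiny_system):
        """Contract: Verlet/cell-list forces equal direct all-pairs evaluation."""
        spec, binders, params, conf = tiny_system
        pos, masks, is_binder, eps = _system_arrays(conf, spec, binders)
        L = params.box_edge
        wpos = pos % L
        fa, *_ , st = _kernels.energy_forces_allpairs(
            pos, L, spec.n_beads, masks, is_binder, eps,
            params.fene_k, params.fene_r0, params.r_rep, params.r_att,
        )
        fl, st2 = _kernels.list_forces(
            pos, wpos, L, spec.n_beads, masks, is_binder, eps,
            params.fene_k, params.fene_r0, params.r_rep, params.r_att, 0.3,
        )
        assert st == st2 == _kernels.OK
        assert np.abs(fa - fl).max() < 1e-10 * max(np.abs(fa).max(), 1.0)

    def test_kernel_matches_reference_route(self, tiny_system):
        spec, binders, params, conf = tiny_system
        pos, masks, is_binder, eps = _system_arrays(conf, spec, binders)
        fa, *_ , st = _kernels.energy_forces_allpairs(
            pos, params.box_edge, spec.n_beads, masks, is_binder, eps,
            params.fene_k, params.fene_r0, params.r_rep, params.r_att,
        )
        fr = system_forces(conf, spec, binders, params)
        assert st == _kernels.OK
        assert np.abs(fa - fr).max() < 1e-9 * max(np.abs(fr).max(), 1.0)


class TestDynamics:
    def test_nve_energy_conservation(self, homopolymer_small):
        """With zero friction the velocity-Verlet integrator conserves energy."""
        spec, params = homopolymer_small
        ens = BinderEnsemble.uniform(["A"], 0.02, 2.0)
        conf = place_binders(init_saw(spec, params, 0), ens, spec, params, 1)
        pos, masks, is_binder, eps = _system_arrays(conf, spec, ens)
        n = pos.shape[0]
        L = params.box_edge
        wpos = pos % L
        rng = np.random.default_rng(3)
        vel = rng.normal(scale=0.5, size=(n, 3))

        def total_energy():
            _, e1, e2, e3, _ = _kernels.energy_forces_allpairs(
                pos, L, spec.n_beads, masks, is_binder, eps,
                params.fene_k, params.fene_r0, params.r_rep, params.r_att,
            )
            return e1 + e2 + e3 + 0.5 * np.sum(vel**2)

        e_start = total_energy()
        st = _kernels.run_chunk(
            pos, wpos, vel, 2000, L, 0.006, 0.0, 1.0, 1.0, spec.n_beads,
            masks, is_binder, eps, params.fene_k, params.fene_r0,
            params.r_rep, params.r_att, 0.3, 1, 200 * n, 200 * n,
        )
        assert st == _kernels.OK
        assert abs(total_energy() - e_start) / abs(e_start) < 5e-3

    def test_equipartition_temperature(self, homopolymer_small):
        """Thermostat recovers T = 1 within 3% (mean KE per dof = T/2)."""
        spec, params = homopolymer_small
        ens = BinderEnsemble.uniform(["A"], 0.1, 1.0)
        conf = place_binders(init_saw(spec, params, 0), ens, spec, params, 1)
        pos, masks, is_binder, eps = _system_arrays(conf, spec, ens)
        n = pos.shape[0]
        wpos = pos % params.box_edge
        vel = np.random.default_rng(3).normal(size=(n, 3))
        temps = []
        for k in range(60):
            st = _kernels.run_chunk(
                pos, wpos, vel, 400, params.box_edge, params.dt, 0.5, 1.0, 1.0,
                spec.n_beads, masks, is_binder, eps, params.fene_k,
                params.fene_r0, params.r_rep, params.r_att, 0.3, 100 + k,
                200 * n, 200 * n,
            )
            assert st == _kernels.OK
            if k >= 10:
                temps.append(np.mean(vel**2))
        assert abs(np.mean(temps) - 1.0) < 0.03

    def test_deterministic_given_seed(self, homopolymer_small):
        spec, params = homopolymer_small
        ens = BinderEnsemble.uniform(["A"], 0.02, 2.0)
        conf = place_binders(init_saw(spec, params, 0), ens, spec, params, 1)
        t1 = run_dynamics(conf, spec, ens, replace(params, seed=5), n_steps=2000)
        t2 = run_dynamics(conf, spec, ens, replace(params, seed=5), n_steps=2000)
        assert np.array_equal(t1.final.bead_coords, t2.final.bead_coords)
        t3 = run_dynamics(conf, spec, ens, replace(params, seed=6), n_steps=2000)
        assert not np.array_equal(t1.final.bead_coords, t3.final.bead_coords)

    def test_fene_bound_every_frame(self, homopolymer_small):
        spec, params = homopolymer_small
        ens = BinderEnsemble.uniform(["A"], 0.05, 5.0)
        conf = place_binders(init_saw(spec, params, 0), ens, spec, params, 1)
        traj = run_dynamics(conf, spec, ens, replace(params, seed=2),
                            n_steps=10_000, sample_every=250)
        for frame in traj.frames:
            bonds = np.linalg.norm(np.diff(frame.bead_coords, axis=0), axis=1)
            assert bonds.max() < params.fene_r0

    def test_no_binders_stays_coil(self):
        """Without binders the chain stays a randomly folded coil: Rg keeps
        fluctuating around the coil mean, with no collapse detected."""
        spec = PolymerSpec.homopolymer(100)
        params = SimulationParams(box_edge=30.0, seed=4)
        conf = init_saw(spec, params, 1)
        conf = place_binders(conf, BinderEnsemble(), spec, params, 2)
        traj = run_dynamics(conf, spec, BinderEnsemble(), params,
                            n_steps=100_000, sample_every=1000)
        cs = detect_collapse(traj.rg_series)
        assert cs.collapse_step is None
        second_half = traj.rg_series[len(traj.rg_series) // 2:]
        sem = second_half.std(ddof=1) / np.sqrt(len(second_half))
        assert abs(traj.rg_series[-1] - second_half.mean()) < 3 * max(sem, 0.5)


class TestRg:
    def test_single_point_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_points_half_distance(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.5)

    def test_uniform_ball(self):
        """Uniform solid sphere of radius R has Rg = sqrt(3/5) R."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(200_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= rng.random(200_000)[:, None] ** (1 / 3) * 2.0
        assert radius_of_gyration(pts) == pytest.approx(np.sqrt(3 / 5) * 2.0, rel=0.01)


class TestDetectCollapse:
    def test_step_drop(self):
        series = np.concatenate([np.full(50, 10.0), np.full(50, 3.0)])
        cs = detect_collapse(series)
        assert cs.drop_fraction == pytest.approx(0.7)
        assert 48 <= cs.collapse_step <= 52
        assert cs.plateau_mean <= cs.coil_mean

    def test_constant_series_no_collapse(self):
        cs = detect_collapse(np.full(60, 5.0))
        assert cs.collapse_step is None
        assert cs.drop_fraction == pytest.approx(0.0)

    def test_linear_ramp_midpoint(self):
        """Noiseless ramp 10 -> 2: the coil level is the first-5% mean (~9.84),
        the plateau the last-25% mean (~2.96); their midpoint is crossed near
        sample 45 under the implemented rule."""
        series = np.linspace(10.0, 2.0, 101)
        cs = detect_collapse(series)
        assert 43 <= cs.collapse_step <= 48

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            detect_collapse(np.ones(10))
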