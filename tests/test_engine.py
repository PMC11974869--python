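"""Spatial SSA engine: exactness oracles, conservation, diffusion and
ensemble-level behavior."""

import numpy as np
import pytest

from nkrsim.config import make_config
from nkrsim.engine import SimulationError, run_ensemble, simulate
from nkrsim.geometry import GeometryParams
from nkrsim.network import (CellCounts, ReactionDef, SpeciesDef,
                            build_network, make_custom_network)
from nkrsim.ode import solve_activating_ode
from tests.conftest import HEADLINE_DOSES


def homogeneous_config(net, geom, placements):
    """Minimal InitialConfig for a custom network: molecules placed in
    explicit chambers; no cluster masks."""
    from nkrsim.config import InitialConfig
    from nkrsim.maps import BinaryMap
    n = geom.n_side
    counts = np.zeros((geom.n_chambers, net.n_species), dtype=np.int32)
    for name, chamber, k in placements:
        counts[chamber, net.species_index(name)] += k
    empty = BinaryMap(grid=np.zeros((n, n), dtype=np.uint8))
    cc = CellCounts(nkg2d=0, kir2dl1=0, nkg2dl=0, hlac=0,
                    sfk=0, vav1=0, shp1=0)
    return InitialConfig(mode="homogeneous", geom=geom, nkg2d_map=empty,
                         kir_map=BinaryMap(grid=empty.grid.copy()),
                         chamber_counts=counts, species_names=net.species_names(),
                         moiety_matrix=net.moiety_matrix(), cell_counts=cc)


class TestTrivialDynamics:
    def test_no_ligands_no_signal(self, network):
        cc = CellCounts.from_network(network, nkg2dl=0)
        cc = CellCounts(nkg2d=cc.nkg2d, kir2dl1=cc.kir2dl1, nkg2dl=0,
                        hlac=0, sfk=cc.sfk, vav1=cc.vav1, shp1=cc.shp1)
        cfg = make_config("disjoint", cc, network, rng=0)
        traj = simulate(cfg, network, t_end=5.0, sample_times=[0, 2.5, 5.0],
                        seed=1)
        assert np.all(traj.pvav1_total == 0)

    def test_time_validation(self, network):
        cfg = make_config("homogeneous",
                          CellCounts.from_network(network, nkg2dl=20),
                          network, rng=1)
        with pytest.raises(ValueError):
            simulate(cfg, network, t_end=-1.0, seed=0)
        with pytest.raises(ValueError):
            simulate(cfg, network, t_end=5.0, sample_times=[0.0, 10.0], seed=0)

    def test_same_seed_reproduces_trajectory(self, network):
        cc = CellCounts.from_network(network, nkg2dl=100)
        cfg = make_config("disjoint", cc, network, rng=5)
        a = simulate(cfg, network, 3.0, [0, 1.5, 3.0], seed=99)
        b = simulate(cfg, network, 3.0, [0, 1.5, 3.0], seed=99)
        assert np.array_equal(a.species_totals, b.species_totals)


class TestTwoStateEquilibrium:
    def test_time_averaged_bound_fraction(self):
        # one receptor + one ligand in a single chamber, binding at
        # k_b and unbinding at k_u: P(bound) = k_b / (k_b + k_u)
        geom = GeometryParams(n_side=1)
        sp = [SpeciesDef("R", "nk-membrane", 0.0, "free", {"NKG2D": 1}),
              SpeciesDef("L", "target-membrane", 0.0, "free", {"NKG2DL": 1}),
              SpeciesDef("C", "complex", 0.0, "free",
                         {"NKG2D": 1, "NKG2DL": 1})]
        kb, ku = 2.0, 3.0
        rx = [ReactionDef(("R", "L"), ("C",), kb, "per_s", None),
              ReactionDef(("C",), ("R", "L"), ku, "per_s", None)]
        # per_s with two reactants: propensity == rate (no volume conv.)
        net = make_custom_network(sp, rx, geom)
        cfg = homogeneous_config(net, geom, [("R", 0, 1), ("L", 0, 1)])
        times = np.arange(0.0, 4000.0, 1.0)
        traj = simulate(cfg, net, times[-1], times, seed=12345)
        bound = traj.total("C")[200:].mean()   # discard transient
        expected = kb / (kb + ku)
        assert bound == pytest.approx(expected, abs=0.03)


class TestDiffusion:
    def test_msd_matches_4dt(self):
        # a lone free molecule: ensemble MSD ~ 4 D t on the lattice
        geom = GeometryParams(n_side=91)
        D = 0.01
        sp = [SpeciesDef("X", "cytosol", D, "free", {"SFK": 1})]
        net = make_custom_network(sp, [], geom)
        center = (45, 45)
        c0 = center[0] * 91 + center[1]
        t_obs = 4.0
        disp2 = []
        for rep in range(400):
            cfg = homogeneous_config(net, geom, [("X", c0, 1)])
            traj = simulate(cfg, net, t_obs, [0.0, t_obs], seed=5000 + rep,
                            record_grid=True)
            pos = np.argwhere(traj.grids[-1][:, 0] > 0)[0][0]
            dx = (pos // 91 - center[0] + 45) % 91 - 45   # minimal image
            dy = (pos % 91 - center[1] + 45) % 91 - 45
            disp2.append(dx * dx + dy * dy)
        msd_um2 = np.mean(disp2) * geom.chamber_area_um2
        assert msd_um2 == pytest.approx(4 * D * t_obs, rel=0.15)


class TestConservation:
    def test_moieties_constant_along_trajectory(self, network):
        cc = CellCounts.from_network(network, nkg2dl=100, hlac=4213)
        cfg = make_config("overlapping", cc, network, rng=3)
        traj = simulate(cfg, network, 5.0, np.arange(0.0, 5.5, 0.5), seed=17)
        m = traj.moiety_totals(network)
        assert np.array_equal(m, np.tile(m[0], (len(m), 1)))
        assert np.all(traj.species_totals >= 0)

    def test_moieties_constant_without_proofreading(self):
        net = build_network(False, False)
        cc = CellCounts.from_network(net, nkg2dl=100, hlac=4213)
        cfg = make_config("homogeneous", cc, net, rng=4)
        traj = simulate(cfg, net, 5.0, [0.0, 2.5, 5.0], seed=18)
        m = traj.moiety_totals(net)
        assert np.array_equal(m, np.tile(m[0], (len(m), 1)))

    def test_pvav1_bounded_by_vav1_pool(self, network):
        cc = CellCounts.from_network(network, nkg2dl=400)
        cfg = make_config("disjoint", cc, network, rng=5)
        traj = simulate(cfg, network, 10.0, [0.0, 5.0, 10.0], seed=19)
        assert np.all(traj.pvav1_total <= cc.vav1)


class TestWellMixedLimit:
    def test_ssa_mean_converges_to_ode(self):
        # activating module in one well-mixed chamber at moderately
        # large copy numbers: the SSA ensemble mean tracks the ODE
        geom = GeometryParams(n_side=1)
        net = build_network(geom=geom)
        n_complex, n_sfk, n_vav = 40, 120, 120
        t_end = 5.0
        means = np.zeros(2)
        n_reps = 24
        for rep in range(n_reps):
            cfg = homogeneous_config(
                net, geom, [("A0", 0, n_complex), ("SFK", 0, n_sfk),
                            ("Vav1", 0, n_vav)])
            traj = simulate(cfg, net, t_end, [2.5, t_end], seed=7000 + rep)
            means += traj.pvav1_total / n_reps
        ode = solve_activating_ode(
            net, initial_complexes=n_complex, t_end=t_end, n_chambers=1,
            counts={"SFK": n_sfk, "Vav1": n_vav})
        expected = np.interp([2.5, t_end], ode.times, ode.pvav1_total)
        assert np.allclose(means, expected, rtol=0.12)


class TestEnsembles:
    def test_replicate_validation(self, network):
        with pytest.raises(ValueError):
            run_ensemble(network, "disjoint", doses=[20], n_reps=1, t_end=1.0)
        with pytest.raises(ValueError):
            run_ensemble(network, "disjoint", doses=[], n_reps=3, t_end=1.0)

    def test_dose_monotonicity_within_error(self, headline_ensembles):
        # mean pVav1 non-decreasing in ligand dose (up to sampling noise)
        for (mode, hlac), ens in headline_ensembles.items():
            resp = ens.responses_at(20.0)
            means = np.array([resp[d].mean() for d in HEADLINE_DOSES])
            ses = np.array([resp[d].std(ddof=1) / np.sqrt(len(resp[d]))
                            for d in HEADLINE_DOSES])
            slack = 2 * np.sqrt(ses[1:] ** 2 + ses[:-1] ** 2)
            assert np.all(np.diff(means) >= -slack), (mode, hlac, means)

    def test_geometry_ordering_of_mean_response(self, headline_responses):
        # at t=20 s, dose 400, low HLA-C: disjoint > homogeneous >
        # overlapping ensemble means
        d = headline_responses[("disjoint", 4213)][400].mean()
        h = headline_responses[("homogeneous", 4213)][400].mean()
        o = headline_responses[("overlapping", 4213)][400].mean()
        assert d > h > o

    def test_saturation_bounded_by_ode_plateau(self, headline_responses,
                                               network):
        # high-dose response plateaus near (receptor count) x
        # (per-complex deterministic steady state)
        ss = solve_activating_ode(network).steady_state_pvav1
        top = headline_responses[("disjoint", 4213)][400].mean()
        assert top <= 1.25 * 53 * ss
        assert top >= 0.5 * 53 * ss
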