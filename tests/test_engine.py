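"""Tau-leap engine: propensity/diffusion-rate primitives, conservation,
analytic decay, equilibrium, injection statistics, determinism."""

import numpy as np
import pytest

from spinerd.engine import (
    EngineConfig,
    InjectionEvent,
    diffusion_rate,
    reaction_propensity,
    run,
)
from spinerd.mesh import Coupling
from spinerd.model import NAV, ReactionSpec


def rx(name, reactants, products, k):
    return ReactionSpec(name=name, reactants=tuple(reactants),
                        products=tuple(products), rate_constant=k)


class TestPropensity:
    def test_first_order(self):
        # G-alpha GTP hydrolysis at 10/s with 5 molecules
        r = rx("hydrolysis", [("GaGTP", 1)], [("GaGDP", 1)], 10.0)
        assert reaction_propensity(r, {"GaGTP": 5}, 0.006) == 50.0

    def test_second_order_unit_conversion(self):
        # kf = 0.1 /nM/s in a 0.006 um^3 voxel: k_conv = 0.1/(NAV*0.006)
        r = rx("bind", [("PDE1", 1), ("CaMCa4", 1)], [("PDE1CaMCa4", 1)], 0.1)
        a = reaction_propensity(r, {"PDE1": 10, "CaMCa4": 20}, 0.006)
        kconv = 0.1 / (6.02214076e23 * 0.006e-15 * 1e-9)
        assert kconv == pytest.approx(27.68, rel=1e-3)
        assert a == pytest.approx(kconv * 200, rel=1e-12)

    def test_zero_count_gives_zero(self):
        r = rx("bind", [("A", 1), ("B", 1)], [("AB", 1)], 1.0)
        assert reaction_propensity(r, {"A": 0, "B": 100}, 0.01) == 0.0

    def test_homodimer_n_n_minus_one(self):
        r = rx("dimer", [("A", 2)], [("AA", 1)], 1.0)
        a1 = reaction_propensity(r, {"A": 1}, 0.01)
        a5 = reaction_propensity(r, {"A": 5}, 0.01)
        assert a1 == 0.0
        assert a5 == pytest.approx(1.0 / (NAV * 0.01) * 20)


class TestDiffusionRate:
    def test_printed_camp_example(self):
        c = Coupling(0, 1, face_area=0.12 * 0.4, center_distance=0.125)
        assert diffusion_rate(86.4, c, 0.006) == pytest.approx(5529.6)

    def test_anchored_species_never_jump(self):
        c = Coupling(0, 1, face_area=1.0, center_distance=0.1)
        assert diffusion_rate(0.0, c, 0.01) == 0.0

    def test_equal_cubes_symmetric(self):
        h = 0.1
        c = Coupling(0, 1, face_area=h * h, center_distance=h)
        assert diffusion_rate(5.0, c, h**3) == pytest.approx(5.0 / h**2)


class TestTauLeap:
    def test_diffusion_only_conserves_molecules(self, toy_factory):
        m, mesh = toy_factory(
            reactions=[], species=[("A", 50.0)],
            initial_counts_v0={"A": 500}, initial_counts_v1={"A": 0},
        )
        traj = run(m, mesh, [], EngineConfig(dt=1e-4, t_end=0.5, rng_seed=5,
                                             sample_interval=0.01))
        totals = traj.count_series("A")
        assert (totals == 500).all()

    def test_diffusion_relaxes_to_volume_proportional(self, toy_factory):
        m, mesh = toy_factory(
            reactions=[], species=[("A", 50.0)],
            initial_counts_v0={"A": 3000}, initial_counts_v1={"A": 0},
            volumes=(0.01, 0.02),
        )
        traj = run(m, mesh, [], EngineConfig(dt=1e-4, t_end=2.0, rng_seed=5,
                                             sample_interval=0.05),
                   groups={"v0": [0], "v1": [1]})
        # occupancy of v1 should settle near 2/3 (volume share)
        late = traj.counts[-10:, :, traj.species_names.index("A")]
        frac = late[:, traj.group_names.index("v1")].mean() / 3000
        assert frac == pytest.approx(2 / 3, abs=0.05)

    def test_exponential_decay_mean(self, toy_factory):
        means = []
        for seed in range(40):
            m, mesh = toy_factory(
                reactions=[rx("decay", [("A", 1)], [("B", 1)], 1.0)],
                species=[("A", 0.0), ("B", 0.0)],
                initial_counts_v0={"A": 1000}, initial_counts_v1={},
            )
            traj = run(m, mesh, [], EngineConfig(dt=1e-4, t_end=1.0,
                                                 rng_seed=100 + seed,
                                                 sample_interval=0.5))
            means.append(traj.count_series("A")[-1])
        expected = 1000 * np.exp(-1)
        se = np.sqrt(1000 * np.exp(-1) * (1 - np.exp(-1)) / len(means))
        assert abs(np.mean(means) - expected) < 3 * se

    def test_reversible_pair_equilibrium(self, toy_factory):
        # Da+R <-> DaR with the printed rates; Keq = kb/kf = 9000 nM
        V = 0.05
        reactions = [
            rx("f", [("Da", 1), ("R", 1)], [("DaR", 1)], 0.0011111),
            rx("b", [("DaR", 1)], [("Da", 1), ("R", 1)], 10.0),
        ]
        n0 = int(round(20000 * NAV * V))  # 20 uM of each
        m, mesh = toy_factory(
            reactions=reactions, species=[("Da", 0.0), ("R", 0.0), ("DaR", 0.0)],
            initial_counts_v0={"Da": n0, "R": n0}, initial_counts_v1={},
            volumes=(V, 0.01),
        )
        traj = run(m, mesh, [], EngineConfig(dt=2e-5, t_end=4.0, rng_seed=7,
                                             sample_interval=0.02))
        conv = 1.0 / (NAV * V)
        late = slice(100, None)
        da = traj.count_series("Da")[late].mean() * conv
        r_ = traj.count_series("R")[late].mean() * conv
        dar = traj.count_series("DaR")[late].mean() * conv
        assert da * r_ / dar == pytest.approx(9000, rel=0.10)

    def test_injection_expected_molecules(self, toy_factory):
        # 62.5 molecules/ms for 0.7 ms -> 43.75 expected per pulse
        m, mesh = toy_factory(reactions=[], species=[("Ca", 0.0)],
                              initial_counts_v0={}, initial_counts_v1={})
        n_pulses = 400
        events = [
            InjectionEvent("Ca", "v0", 62.5, onset=0.002 * k, duration=0.7e-3)
            for k in range(n_pulses)
        ]
        traj = run(m, mesh, events, EngineConfig(dt=5e-5, t_end=0.002 * n_pulses,
                                                 rng_seed=3, sample_interval=0.1))
        total = traj.count_series("Ca")[-1]
        expected = 43.75 * n_pulses
        se = np.sqrt(n_pulses * 0.25 * 12)  # loose bound on rounding variance
        assert abs(total - expected) < max(3 * se, 0.01 * expected)

    def test_same_seed_reproduces_trajectory(self, anchored_model, coarse_mesh):
        cfg = EngineConfig(dt=1e-4, t_end=0.05, rng_seed=42, sample_interval=0.01)
        a = run(anchored_model, coarse_mesh, [], cfg)
        b = run(anchored_model, coarse_mesh, [], cfg)
        assert np.array_equal(a.counts, b.counts)

    def test_empty_schedule_zero_rates_constant(self, toy_factory):
        m, mesh = toy_factory(
            reactions=[rx("null", [("A", 1)], [("B", 1)], 0.0)],
            species=[("A", 0.0), ("B", 0.0)],
            initial_counts_v0={"A": 77}, initial_counts_v1={"A": 11},
        )
        traj = run(m, mesh, [], EngineConfig(dt=1e-4, t_end=0.2, rng_seed=1,
                                             sample_interval=0.05))
        assert (traj.count_series("A") == 88).all()
        assert (traj.count_series("B") == 0).all()

    def test_counts_never_negative(self, anchored_model, coarse_mesh):
        from spinerd.protocols import build_four_train_ltp

        sched = build_four_train_ltp(coarse_mesh, n_trains=1, first_onset=0.01)
        traj = run(anchored_model, coarse_mesh, sched.events,
                   EngineConfig(dt=1e-4, t_end=0.2, rng_seed=9,
                                sample_interval=0.05))
        assert traj.counts.min() >= 0

    def test_schedule_unknown_set_rejected(self, toy_factory):
        m, mesh = toy_factory(reactions=[], species=[("A", 1.0)],
                              initial_counts_v0={"A": 5}, initial_counts_v1={})
        with pytest.raises(ValueError, match="voxel set"):
            run(m, mesh, [InjectionEvent("A", "nowhere", 1.0, 0.0, 0.1)],
                EngineConfig(dt=1e-4, t_end=0.01, rng_seed=1, sample_interval=0.01))


class TestConservation:
    def test_moiety_totals_constant_without_injection(self, anchored_model,
                                                      coarse_mesh, model):
        traj = run(anchored_model, coarse_mesh, [],
                   EngineConfig(dt=5e-5, t_end=0.5, rng_seed=13,
                                sample_interval=0.1))
        for moiety in ("CaM", "PKAreg", "PKAcat", "GluR1", "PP1", "PP2B",
                       "PDE4B", "PDE4D", "I1", "Calbindin"):
            weights = model.moiety_species(moiety)
            series = traj.count_series(list(weights), weights=weights)
            assert (series == series[0]).all(), moiety
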