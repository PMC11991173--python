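import hashlib

import numpy as np
import pytest

from polycma.cma import (
    CmaSampler,
    SimulationParams,
    apply_loop,
    build_loop,
    metropolis_accept,
    replicate_seed,
    revert_loop,
    run_simulation,
    seed_state,
)
from polycma.energetics import InteractionSet, total_energy
from polycma.enumeration import enumerate_conformations, exact_averages, shape_class
from polycma.lattice import (
    Configuration,
    LatticeSpec,
    init_chain,
    validate_configuration,
)
from polycma.observables import heat_capacity

from .conftest import chain_from_uv


def config_hash(config):
    h = hashlib.sha256()
    h.update(config.occ.tobytes())
    h.update(config.chain_sites.tobytes())
    return h.hexdigest()


class TestLoopMoves:
    def test_pure_solvent_loops_close_and_leave_box_unchanged(self):
        # a 2-bead chain far away; loops in the solvent bulk are identity
        # rearrangements of identical particles
        cfg = chain_from_uv(16, [(0, 0), (1, 0)])
        rs = seed_state(11)
        before = cfg.occ.copy()
        closed = 0
        for _ in range(100):
            move = build_loop(cfg, rs)
            if move.closed:
                closed += 1
                assert move.loop_length >= 2
        assert closed > 50
        assert np.array_equal(cfg.occ, before)  # build_loop never mutates

    def test_every_closed_loop_has_zero_net_displacement(self, relaxed_chain):
        rs = seed_state(23)
        seen = 0
        while seen < 200:
            move = build_loop(relaxed_chain, rs)
            if move.closed:
                assert move.displacement_sum(relaxed_chain.L) == (0, 0)
                apply_loop(relaxed_chain, move)
                seen += 1

    def test_apply_then_revert_restores_configuration_exactly(self, relaxed_chain):
        rs = seed_state(31)
        h0 = config_hash(relaxed_chain)
        for _ in range(100):
            move = build_loop(relaxed_chain, rs)
            if move.closed:
                apply_loop(relaxed_chain, move)
                revert_loop(relaxed_chain, move)
                assert config_hash(relaxed_chain) == h0

    def test_configuration_stays_valid_over_many_applied_loops(self, relaxed_chain):
        rs = seed_state(47)
        applied = 0
        attempts = 0
        while applied < 2000 and attempts < 50000:
            attempts += 1
            move = build_loop(relaxed_chain, rs)
            if move.closed:
                apply_loop(relaxed_chain, move)
                applied += 1
                if applied % 250 == 0:
                    ok, msg = validate_configuration(relaxed_chain)
                    assert ok, msg
        ok, msg = validate_configuration(relaxed_chain)
        assert ok, msg


class TestMetropolis:
    def test_nonpositive_dE_always_accepted(self, rng):
        assert all(metropolis_accept(d, 1.0, rng) for d in (0.0, -0.5, -100.0))

    def test_acceptance_frequency_matches_closed_form(self, rng):
        # dE = kT ln 2 accepts with probability 1/2
        n = 100_000
        acc = sum(metropolis_accept(np.log(2.0), 1.0, rng) for _ in range(n))
        sigma = np.sqrt(n * 0.25)
        assert abs(acc - n / 2) < 3 * sigma

    def test_infinite_temperature_always_accepts(self, rng):
        assert all(
            metropolis_accept(50.0, np.inf, rng) for _ in range(100)
        )


class TestSampler:
    def test_mcs_counter_advances_by_one_per_run_mcs(self, relaxed_chain):
        s = CmaSampler(relaxed_chain, InteractionSet.athermal(), seed=3)
        before = s.counter.mcs
        for _ in range(20):
            s.run_mcs()
        after = s.counter.mcs
        # loop overshoot is carried across calls, so 20 calls advance the
        # clock by 20 MCS up to the final loop's overshoot
        assert after - before >= 20
        assert after - before <= 20 + s.max_hops / s.n_sites
        assert s.counter.mcs == after  # nondecreasing, consistent property

    def test_athermal_energy_stays_zero(self, relaxed_chain):
        s = CmaSampler(relaxed_chain, InteractionSet.athermal(), seed=5)
        e, _, _ = s.run(200, sample_interval_mcs=10)
        assert np.all(e == 0.0)

    def test_incremental_energy_matches_recompute(self, relaxed_chain):
        inter = InteractionSet.poor(1.0)
        s = CmaSampler(relaxed_chain, inter, seed=9)
        s.run(300)
        assert s.energy == pytest.approx(
            total_energy(relaxed_chain, inter), abs=1e-9
        )

    def test_deep_quench_acceptance_below_athermal(self, rng):
        """Cooling a compact poor-solvent system must reject some loops."""
        cfg = init_chain(16, LatticeSpec(24), rng)
        cold = CmaSampler(cfg.copy(), InteractionSet.poor(0.2), seed=1)
        cold.run(500)
        hot = CmaSampler(cfg.copy(), InteractionSet.athermal(), seed=1)
        hot.run(500)
        assert cold.counter.acceptance_rate < hot.counter.acceptance_rate

    def test_same_seed_gives_bit_identical_records(self):
        params = dict(
            n_beads=8,
            box=16,
            interactions=InteractionSet.good(1.0),
            n_equil_mcs=200,
            n_prod_mcs=1000,
            sample_interval_mcs=10,
            seed=77,
        )
        a = run_simulation(SimulationParams(**params))
        b = run_simulation(SimulationParams(**params))
        assert a.records.equals(b.records)
        assert np.array_equal(a.final_config.occ, b.final_config.occ)

    def test_different_replicate_seeds_differ(self):
        assert replicate_seed(3, 0) != replicate_seed(3, 1)
        assert 0 <= replicate_seed(3, 5) < 2**31

    def test_athermal_production_record_count_contract(self):
        params = SimulationParams(
            n_beads=8,
            box=16,
            interactions=InteractionSet.athermal(),
            n_equil_mcs=100,
            n_prod_mcs=1000,
            sample_interval_mcs=10,
            seed=5,
        )
        out = run_simulation(params)
        assert len(out.records) == 100
        assert (out.records.E == 0).all()
        ok, msg = validate_configuration(out.final_config)
        assert ok, msg

    def test_invalid_params_rejected_before_compute(self):
        with pytest.raises(ValueError):
            SimulationParams(
                n_beads=1,
                box=16,
                interactions=InteractionSet.athermal(),
                n_equil_mcs=10,
                n_prod_mcs=10,
                sample_interval_mcs=1,
            )
        with pytest.raises(ValueError):
            SimulationParams(
                n_beads=300,
                box=16,
                interactions=InteractionSet.athermal(),
                n_equil_mcs=10,
                n_prod_mcs=10,
                sample_interval_mcs=1,
            )
        with pytest.raises(ValueError):
            SimulationParams(
                n_beads=8,
                box=16,
                interactions=InteractionSet.athermal(),
                n_equil_mcs=10,
                n_prod_mcs=10,
                sample_interval_mcs=0,
            )


class TestEquilibriumCorrectness:
    """The sampler must reproduce exact enumeration on tiny systems."""

    @pytest.mark.parametrize("preset,kT", [("poor", 1.0), ("good", 1.0)])
    def test_tiny_system_matches_enumeration(self, preset, kT):
        inter = InteractionSet.from_preset(preset, kT)
        exact = exact_averages(4, 6, inter)
        reps = []
        for r in range(6):
            params = SimulationParams(
                n_beads=4,
                box=6,
                interactions=inter,
                n_equil_mcs=3000,
                n_prod_mcs=60_000,
                sample_interval_mcs=20,
                seed=replicate_seed(101, r),
            )
            df = run_simulation(params).records
            reps.append(
                (df.E.mean(), heat_capacity(df.E, kT, 4)[0], df.Rg2.mean())
            )
        a = np.array(reps)
        mean = a.mean(axis=0)
        se = a.std(axis=0, ddof=1) / np.sqrt(len(reps))
        ref = np.array([exact.E_mean, exact.Cv_per_k, exact.Rg2_mean])
        z = (mean - ref) / se
        assert np.all(np.abs(z) < 4.0), f"z-scores {z} vs exact {ref}"

    def test_ergodicity_every_shape_class_visited(self):
        """At infinite temperature every N=4 conformation class must appear."""
        all_classes = {
            shape_class(ch, 5) for ch in enumerate_conformations(4, 5)
        }
        cfg = init_chain(4, LatticeSpec(5), np.random.default_rng(2))
        s = CmaSampler(cfg, InteractionSet.athermal(), seed=12)
        seen = set()
        for _ in range(6000):
            s.run(2)
            seen.add(shape_class(cfg.chain_sites, 5))
            if seen == all_classes:
                break
        assert seen == all_classes
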