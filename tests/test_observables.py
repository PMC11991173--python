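import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polycma.lattice import init_chain, LatticeSpec, unwrap_chain
from polycma.observables import (
    asphericity,
    asphericity_ensemble,
    bridge_count,
    chain_observables,
    correlation_function,
    default_q_grid,
    end_to_end_sq,
    gyration_tensor,
    heat_capacity,
    radius_of_gyration_sq,
    structure_factor,
)

from .conftest import chain_from_uv, straight_rod


class TestSize:
    def test_rod_end_to_end(self):
        assert end_to_end_sq(straight_rod(32, 7)) == pytest.approx(36.0)

    def test_dimer(self):
        cfg = chain_from_uv(16, [(0, 0), (0, 1)])
        assert end_to_end_sq(cfg) == pytest.approx(1.0)
        assert radius_of_gyration_sq(cfg) == pytest.approx(0.25)

    def test_bent_trimer_at_120_degrees(self):
        cfg = chain_from_uv(16, [(0, 0), (1, 0), (1, 1)])
        assert end_to_end_sq(cfg) == pytest.approx(3.0)

    def test_rod_rg2(self):
        # points 0, 1, 2 on a line: variance = 2/3
        assert radius_of_gyration_sq(straight_rod(16, 3)) == pytest.approx(2.0 / 3.0)

    def test_translation_invariance(self):
        a = chain_from_uv(32, [(3, 4), (4, 4), (4, 5), (3, 6)])
        b = chain_from_uv(32, [(10, 20), (11, 20), (11, 21), (10, 22)])
        assert radius_of_gyration_sq(a) == pytest.approx(radius_of_gyration_sq(b))


class TestShape:
    def test_trace_identity_on_random_chains(self, rng):
        for seed in range(5):
            cfg = init_chain(12, LatticeSpec(32), np.random.default_rng(seed))
            l1, l2 = gyration_tensor(cfg)
            assert l1 + l2 == pytest.approx(radius_of_gyration_sq(cfg), rel=1e-9)
            assert l1 >= l2 >= 0

    def test_rod_is_fully_aspherical(self):
        l1, l2 = gyration_tensor(straight_rod(32, 9))
        assert l2 == pytest.approx(0.0, abs=1e-12)
        assert asphericity(l1, l2) == pytest.approx(1.0)

    def test_equilateral_triangle_is_disk_like(self):
        cfg = chain_from_uv(16, [(0, 0), (1, 0), (0, 1)])
        l1, l2 = gyration_tensor(cfg)
        assert l1 == pytest.approx(l2)
        assert asphericity(l1, l2) == pytest.approx(0.0, abs=1e-12)

    def test_asphericity_single_sample_form(self):
        assert asphericity(3.0, 1.0) == pytest.approx(0.25)

    def test_degenerate_point_chain_rejected(self):
        with pytest.raises(ValueError):
            asphericity(0.0, 0.0)

    @given(st.lists(st.tuples(st.floats(0.01, 50), st.floats(0, 50)), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ensemble_asphericity_in_unit_interval(self, pairs):
        l1 = np.array([max(a, b) for a, b in pairs])
        l2 = np.array([min(a, b) for a, b in pairs])
        a2 = asphericity_ensemble(l1, l2)
        assert 0.0 <= a2 <= 1.0

    def test_ensemble_a2_is_one_iff_l2_zero(self):
        l1 = np.array([1.0, 2.0, 5.0])
        assert asphericity_ensemble(l1, np.zeros(3)) == pytest.approx(1.0)

    def test_batched_observables_match_per_config(self, relaxed_chain):
        df = chain_observables(relaxed_chain.L, relaxed_chain.chain_sites[None, :])
        assert df.Ree2[0] == pytest.approx(end_to_end_sq(relaxed_chain))
        l1, l2 = gyration_tensor(relaxed_chain)
        assert df.lambda1[0] == pytest.approx(l1)
        assert df.lambda2[0] == pytest.approx(l2)


class TestHeatCapacity:
    def test_constant_energy_gives_zero(self):
        assert heat_capacity([5.0] * 10, 1.0, 4) == (0.0, 0.0)

    def test_two_level_trace(self):
        # equal occupation of 0 and -1 at kT=1: Var = 1/4
        cv, cv_n = heat_capacity([0.0, -1.0] * 50, 1.0, 4)
        assert cv == pytest.approx(0.25)
        assert cv_n == pytest.approx(0.25 / 4)

    def test_matches_two_pass_variance(self, rng):
        e = rng.integers(-500, 0, size=1000).astype(float)
        cv, _ = heat_capacity(e, 2.0, 16)
        mean = e.mean()
        two_pass = ((e - mean) ** 2).mean()
        assert cv == pytest.approx(0.25 * two_pass, rel=1e-12)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            heat_capacity([1.0], 1.0, 4)


class TestScattering:
    def test_gamma_normalisation_and_self_term(self, relaxed_chain):
        table = correlation_function([relaxed_chain])
        assert table.gamma[table.r2 == 0][0] == pytest.approx(1.0)
        assert table.gamma.sum() == pytest.approx(relaxed_chain.n_beads)

    def test_static_dimer_gamma(self):
        cfg = chain_from_uv(16, [(0, 0), (1, 0)])
        table = correlation_function([cfg])
        assert dict(zip(table.r2.tolist(), table.gamma.tolist())) == {0: 1.0, 1: 1.0}

    def test_dimer_structure_factor_closed_form(self):
        cfg = chain_from_uv(16, [(0, 0), (1, 0)])
        table = correlation_function([cfg])
        q = np.array([0.5, 1.0, np.pi])
        s = structure_factor(table, q)
        assert s.S == pytest.approx(1.0 + np.sin(q) / q)
        assert s.S[-1] == pytest.approx(1.0)  # sin(pi)/pi = 0
        assert s.q2S == pytest.approx(q * q * s.S)

    def test_low_q_limit_approaches_N(self, relaxed_chain):
        table = correlation_function([relaxed_chain])
        s = structure_factor(table, np.array([1e-6]))
        assert s.S[0] == pytest.approx(relaxed_chain.n_beads, rel=1e-6)

    def test_gamma_equivalence_with_direct_double_sum(self, rng):
        """S(q) from distance classes equals the direct pair double sum."""
        for seed in range(5):
            cfg = init_chain(8, LatticeSpec(24), np.random.default_rng(seed + 3))
            q = default_q_grid(24, 15)
            s = structure_factor(correlation_function([cfg]), q).S
            xy = cfg.unwrapped_cartesian()
            d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
            qr = q[:, None] * d.ravel()[None, :]
            kern = np.where(qr > 0, np.sin(np.where(qr > 0, qr, 1.0)) / np.where(qr > 0, qr, 1.0), 1.0)
            direct = kern.sum(axis=1) / cfg.n_beads
            assert s == pytest.approx(direct, rel=1e-10)

    def test_bad_q_grids_rejected(self, relaxed_chain):
        table = correlation_function([relaxed_chain])
        with pytest.raises(ValueError):
            structure_factor(table, np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            structure_factor(table, np.array([2.0, 1.0]))

    def test_mixed_chain_lengths_rejected(self):
        a = chain_from_uv(16, [(0, 0), (1, 0)])
        b = chain_from_uv(16, [(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError):
            correlation_function([a, b])

    def test_bessel_kernel_option(self):
        from scipy.special import j0

        cfg = chain_from_uv(16, [(0, 0), (1, 0)])
        table = correlation_function([cfg])
        q = np.array([0.7, 2.1])
        s = structure_factor(table, q, kernel="bessel")
        assert s.S == pytest.approx(1.0 + j0(q))


class TestBridges:
    def test_straight_rod_has_no_bridges(self):
        assert bridge_count(straight_rod(32, 10)) == 0

    def test_hairpin_solvent_site_bridges_two_strands(self):
        # two antiparallel strands with one solvent row between them:
        # u-strand at v=0 (beads 0..5), turn, back at v=2 (beads 8..13)
        uv = (
            [(k, 0) for k in range(6)]
            + [(6, 0), (6, 1)]
            + [(5 - k, 2) for k in range(6)]
        )
        cfg = chain_from_uv(32, uv)
        n = bridge_count(cfg, min_contour_gap=3)
        assert n >= 1
        # every bridge solvent site must sit between the strands at v=1
        assert bridge_count(cfg, min_contour_gap=100) == 0

    def test_gap_larger_than_chain_gives_zero(self, relaxed_chain):
        assert bridge_count(relaxed_chain, min_contour_gap=relaxed_chain.n_beads) == 0
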