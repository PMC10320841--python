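"""Core equilibrium solver: quadratic root, species state, total<->free maps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ternaq import (
    TernarySystem,
    ValidationError,
    clt_given_free_ligand,
    free_ligand_at_max_clt,
    free_ligand_of_total,
    ltot_at_max_clt,
    state_from_free_ligand,
    state_from_total_ligand,
    total_ligand_of_free,
    validate_system,
)

from .conftest import clt_oracle, random_systems

log_conc = st.floats(min_value=-3, max_value=7)
log_kd = st.floats(min_value=0, max_value=6)
log_alpha = st.floats(min_value=-2, max_value=4)
log_tot = st.floats(min_value=-1, max_value=5)


def system_from_logs(lkc, lkt, la, lc, lt) -> TernarySystem:
    return TernarySystem(10**lkc, 10**lkt, 10**la, 10**lc, 10**lt)


class TestValidateSystem:
    def test_derived_constants(self):
        s = validate_system(k_c1=100, k_t1=1e5, alpha=100, c_tot=1000, t_tot=5)
        assert s.k_c2 == pytest.approx(1.0)
        assert s.k_t2 == pytest.approx(1e3)
        assert s.k_clt == pytest.approx(1e5)

    def test_weak_binder_shifted_kd(self):
        # pre-binding to the counter protein tightens the weak arm alpha-fold
        s = validate_system(k_c1=100, k_t1=100_000, alpha=200, c_tot=5, t_tot=1000)
        assert s.k_t2 == pytest.approx(100_000 / 200)  # = 500 nM

    @pytest.mark.parametrize(
        "bad",
        [
            dict(k_c1=0), dict(k_c1=-5), dict(k_t1=0), dict(alpha=0),
            dict(alpha=-1), dict(c_tot=-1), dict(t_tot=-0.5), dict(k_c1=float("nan")),
        ],
    )
    def test_invalid_parameters_name_the_field(self, bad):
        params = dict(k_c1=100, k_t1=1e5, alpha=100, c_tot=1000, t_tot=5)
        params.update(bad)
        with pytest.raises(ValidationError, match=next(iter(bad))):
            validate_system(**params)

    def test_negative_cooperativity_is_allowed(self):
        assert validate_system(100, 100, 0.01, 10, 10).alpha == 0.01

    def test_path_independence(self):
        s = validate_system(73.0, 4100.0, 37.5, 10, 10)
        assert s.k_c1 / s.k_c2 == pytest.approx(s.alpha, rel=1e-12)
        assert s.k_t1 / s.k_t2 == pytest.approx(s.alpha, rel=1e-12)


class TestCltGivenFreeLigand:
    def test_matches_printed_occupancy(self, biochemical_system):
        clt = clt_given_free_ligand(biochemical_system, 9.8)
        assert clt / biochemical_system.t_tot * 100 == pytest.approx(8.2, abs=0.05)

    def test_degenerate_inputs_give_exact_zero(self, biochemical_system):
        assert clt_given_free_ligand(biochemical_system, 0.0) == 0.0
        no_target = biochemical_system.replace(t_tot=0.0)
        assert clt_given_free_ligand(no_target, 50.0) == 0.0

    def test_symmetric_system_matches_oracle(self):
        s = TernarySystem(k_c1=100, k_t1=100, alpha=1, c_tot=100, t_tot=100)
        assert clt_given_free_ligand(s, 100.0) == pytest.approx(
            clt_oracle(s, 100.0), rel=1e-10
        )

    def test_oracle_equivalence_200_random_systems(self):
        """The quadratic root must coincide with an independent joint solve of
        the coupled mass-action/conservation equations across the whole
        parameter domain (stiff high-alpha and depleted regimes included)."""
        for system, l_free in random_systems(200, seed=20260925):
            ours = clt_given_free_ligand(system, l_free)
            ref = clt_oracle(system, l_free)
            assert ours == pytest.approx(ref, rel=1e-8, abs=1e-300), (system, l_free)

    @given(log_kd, log_kd, log_alpha, log_tot, log_tot, log_conc)
    def test_bounded_by_limiting_protein(self, lkc, lkt, la, lc, lt, ll):
        s = system_from_logs(lkc, lkt, la, lc, lt)
        clt = clt_given_free_ligand(s, 10**ll)
        assert 0.0 <= clt <= min(s.c_tot, s.t_tot) * (1 + 1e-12)

    @given(log_kd, log_kd, log_tot, log_tot, log_conc)
    def test_nondecreasing_in_alpha(self, lkc, lkt, lc, lt, ll):
        alphas = [0.1, 1.0, 10.0, 100.0]
        values = [
            clt_given_free_ligand(system_from_logs(lkc, lkt, math.log10(a), lc, lt), 10**ll)
            for a in alphas
        ]
        for lo, hi in zip(values, values[1:]):
            assert hi >= lo * (1 - 1e-12)

    @given(log_kd, log_kd, log_alpha, log_tot, log_tot, log_conc)
    def test_hook_symmetry(self, lkc, lkt, la, lc, lt, ll):
        """CLT(l) equals CLT(K_C1*K_T1/l): the free-ligand hook is geometrically
        symmetric about sqrt(K_C1*K_T1)."""
        s = system_from_logs(lkc, lkt, la, lc, lt)
        l = 10**ll
        mirrored = s.k_c1 * s.k_t1 / l
        assert clt_given_free_ligand(s, l) == pytest.approx(
            clt_given_free_ligand(s, mirrored), rel=1e-9, abs=1e-300
        )


class TestStateFromFreeLigand:
    def test_zero_ligand_zero_complexes(self, biochemical_system):
        s = state_from_free_ligand(biochemical_system, 0.0)
        assert (s.cl, s.tl, s.clt) == (0.0, 0.0, 0.0)
        assert s.c_free == biochemical_system.c_tot
        assert s.t_free == biochemical_system.t_tot
        assert s.l_tot_implied == 0.0

    def test_implied_total_at_known_free(self, biochemical_system):
        # 1000 nM dosed total corresponds to 269 nM free in this system
        s = state_from_free_ligand(biochemical_system, 269.0)
        assert s.l_tot_implied == pytest.approx(1000, rel=0.01)

    def test_state_matches_oracle(self, chaperone_monitored_system):
        sys_ = chaperone_monitored_system
        s = state_from_free_ligand(sys_, 5000.0)
        ref_clt = clt_oracle(sys_, 5000.0)
        assert s.clt == pytest.approx(ref_clt, rel=1e-10)
        ref_cf = (sys_.c_tot - ref_clt) / (1 + 5000.0 / sys_.k_c1)
        assert s.c_free == pytest.approx(ref_cf, rel=1e-10)
        assert (s.cl + s.clt) / sys_.c_tot == pytest.approx(
            (ref_cf * 5000.0 / sys_.k_c1 + ref_clt) / sys_.c_tot, rel=1e-10
        )

    @given(log_kd, log_kd, log_alpha, log_tot, log_tot, log_conc)
    def test_mass_and_pathway_conservation(self, lkc, lkt, la, lc, lt, ll):
        """Protein mass balances close and the single mass-action condition
        clt*K_C1*K_T1 = alpha*c*t*l holds at every returned state."""
        s = system_from_logs(lkc, lkt, la, lc, lt)
        st_ = state_from_free_ligand(s, 10**ll)
        assert st_.c_free + st_.cl + st_.clt == pytest.approx(s.c_tot, rel=1e-9)
        assert st_.t_free + st_.tl + st_.clt == pytest.approx(s.t_tot, rel=1e-9)
        assert st_.clt * s.k_c1 * s.k_t1 == pytest.approx(
            s.alpha * st_.c_free * st_.t_free * st_.l_free, rel=1e-9, abs=1e-280
        )
        assert min(st_.c_free, st_.t_free, st_.cl, st_.tl, st_.clt) >= 0.0


class TestTotalFreeMaps:
    def test_identity_without_proteins(self):
        s = TernarySystem(100, 100, 1, 0.0, 0.0)
        assert total_ligand_of_free(s, 42.0) == 42.0
        assert free_ligand_of_total(s, 42.0) == 42.0

    def test_printed_inversions(self, biochemical_system):
        assert free_ligand_of_total(biochemical_system, 1000.0) == pytest.approx(269, rel=0.01)
        assert free_ligand_of_total(biochemical_system, 100.0) == pytest.approx(9.8, rel=0.02)

    def test_forward_map_at_printed_free_values(self, biochemical_system):
        assert total_ligand_of_free(biochemical_system, 9.8) == pytest.approx(100, rel=0.01)
        # the dose needed for 100 nM free ligand in this closed system
        assert total_ligand_of_free(biochemical_system, 100.0) == pytest.approx(
            600.8, rel=1e-3
        )

    def test_zero_maps_to_zero(self, biochemical_system):
        assert free_ligand_of_total(biochemical_system, 0.0) == 0.0

    @given(log_kd, log_kd, log_alpha, log_tot, log_tot, log_conc)
    def test_round_trip_and_bounds(self, lkc, lkt, la, lc, lt, ll):
        s = system_from_logs(lkc, lkt, la, lc, lt)
        l = 10**ll
        l_tot = total_ligand_of_free(s, l)
        assert l_tot >= l
        assert free_ligand_of_total(s, l_tot) == pytest.approx(l, rel=1e-9)

    @given(log_kd, log_kd, log_alpha, log_tot, log_tot)
    def test_strictly_increasing(self, lkc, lkt, la, lc, lt):
        s = system_from_logs(lkc, lkt, la, lc, lt)
        grid = np.geomspace(1e-3, 1e7, 25)
        totals = [total_ligand_of_free(s, l) for l in grid]
        assert all(b > a for a, b in zip(totals, totals[1:]))

    def test_state_from_total_consistency(self, hook_demo_system):
        for l_tot in np.geomspace(1.0, 1e6, 13):
            st_ = state_from_total_ligand(hook_demo_system, l_tot)
            assert st_.l_tot_implied == pytest.approx(l_tot, rel=1e-9)
            assert st_.clt == pytest.approx(clt_oracle(hook_demo_system, st_.l_free), rel=1e-9)

    def test_langmuir_limit_without_target(self):
        """With no target the chaperone arm must reduce exactly to the binary
        Langmuir isotherm cl = c_tot*l/(k_c1 + l)."""
        s = TernarySystem(k_c1=100, k_t1=1e5, alpha=200, c_tot=5, t_tot=0)
        for l in np.geomspace(1e-2, 1e6, 17):
            st_ = state_from_free_ligand(s, l)
            assert st_.cl == pytest.approx(s.c_tot * l / (s.k_c1 + l), rel=1e-12)
            assert st_.clt == 0.0


class TestHookMaximum:
    def test_argmax_is_geometric_mean_of_kds(self):
        s = TernarySystem(k_c1=100, k_t1=1e5, alpha=100, c_tot=1000, t_tot=5)
        assert free_ligand_at_max_clt(s) == pytest.approx(3162.28, rel=1e-4)
        # independent of alpha and totals
        s2 = s.replace(alpha=7.0, c_tot=3.0, t_tot=900.0)
        assert free_ligand_at_max_clt(s2) == pytest.approx(3162.28, rel=1e-4)
        sym = TernarySystem(100, 100, 5, 50, 50)
        assert free_ligand_at_max_clt(sym) == pytest.approx(100.0, rel=1e-6)

    def test_grid_search_confirms_argmax(self, chaperone_monitored_system):
        s = chaperone_monitored_system
        peak = free_ligand_at_max_clt(s)
        grid = np.geomspace(peak / 1e4, peak * 1e4, 4001)
        values = [clt_given_free_ligand(s, l) for l in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(peak, rel=0.01)

    @pytest.mark.parametrize("x", [2.0, 10.0, 100.0])
    def test_clt_symmetric_about_argmax(self, biochemical_system, x):
        peak = free_ligand_at_max_clt(biochemical_system)
        assert clt_given_free_ligand(biochemical_system, peak * x) == pytest.approx(
            clt_given_free_ligand(biochemical_system, peak / x), rel=1e-9
        )

    def test_degenerate_system_rejected(self):
        with pytest.raises(ValidationError):
            free_ligand_at_max_clt(TernarySystem(100, 100, 1, 0.0, 10.0))

    def test_total_ligand_at_peak_exceeds_free_peak(self, hook_demo_system):
        free_peak = free_ligand_at_max_clt(hook_demo_system)
        total_peak = ltot_at_max_clt(hook_demo_system)
        assert total_peak > free_peak
        assert total_peak > 1000.0  # sqrt(100 * 10000) plus bound ligand

    def test_total_peak_matches_grid_search(self, chaperone_monitored_system):
        s = chaperone_monitored_system
        total_peak = ltot_at_max_clt(s)
        grid = np.geomspace(total_peak / 100, total_peak * 100, 2001)
        values = [state_from_total_ligand(s, lt).clt for lt in grid]
        best = max(values)
        at_peak = state_from_total_ligand(s, total_peak).clt
        assert at_peak >= best * (1 - 1e-9)

    def test_total_peak_converges_to_free_peak_without_depletion(self):
        s = TernarySystem(100, 1e4, 16, 1e-6, 1e-6)
        assert ltot_at_max_clt(s) == pytest.approx(free_ligand_at_max_clt(s), rel=1e-6)
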