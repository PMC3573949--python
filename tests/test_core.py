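"""Binding constants, mass action, and the equilibrium solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ermodel.core import (
    BindingConstants,
    SystemTotals,
    bound_hormone_metrics,
    complexes_from_free,
    derive_dependent_constants,
    solve_equilibrium,
    species_distribution_scan,
)
from ermodel.params import PUBLISHED_BINDING, default_binding_constants

from .oracles import oracle_equilibrium, oracle_species

pos = st.floats(min_value=1e-3, max_value=1e3)


class TestDetailedBalance:
    @pytest.mark.parametrize("name,expected", [
        ("K5", 20.0),        # K1*K2/K4 = 25*0.2/0.25
        ("K6", 8.0),         # K1*K2*K3/K4^2
        ("K10", 25 * 10 / 30),
        ("K11", 25 * 10 * 150 / 900),
        ("K12", 25 * 10 * 0.8 / (0.25 * 30)),
        ("K14", 40.0),       # K7*K13/K2
    ])
    def test_published_dependent_constants(self, K, name, expected):
        assert getattr(K, name) == pytest.approx(expected, rel=1e-12)

    def test_identity_case(self):
        K = derive_dependent_constants(**{k: 1.0 for k in PUBLISHED_BINDING})
        for name in ("K5", "K6", "K10", "K11", "K12", "K14"):
            assert getattr(K, name) == 1.0

    @given(vals=st.lists(pos, min_size=14, max_size=14))
    @settings(max_examples=50, deadline=None)
    def test_cycle_identities_hold_for_random_constants(self, vals):
        K = derive_dependent_constants(**dict(zip(PUBLISHED_BINDING, vals)))
        assert max(K.detailed_balance_residuals().values()) < 1e-10

    def test_nonpositive_input_names_offender(self):
        bad = dict(PUBLISHED_BINDING, K9=-1.0)
        with pytest.raises(ValueError, match="K9"):
            derive_dependent_constants(**bad)

    def test_inconsistent_constants_rejected(self, K):
        vals = {f: getattr(K, f) for f in PUBLISHED_BINDING}
        full = {**vals, **{k: getattr(K, k) for k in ("K5", "K6", "K10", "K11", "K12", "K14")}}
        full["K5"] = 21.0
        kk = BindingConstants(**full)
        with pytest.raises(ValueError, match="K5"):
            kk.check_detailed_balance()


class TestComplexesFromFree:
    def test_pure_dimerisation(self, K):
        st_ = complexes_from_free(12.5, 0, 0, 0, K)
        assert st_.ER2 == pytest.approx(12.5**2 / 25, rel=1e-12)
        assert all(getattr(st_, n) == 0 for n in
                   ("ERH", "ER2H", "ER2H2", "ER2I", "ER2D", "ER2HID"))

    def test_zero_receptor_zeroes_everything(self, K):
        st_ = complexes_from_free(0, 5, 5, 5, K)
        assert all(v == 0 for n, v in st_.as_dict().items()
                   if n not in ("H", "I", "D"))

    @given(free=st.lists(st.floats(min_value=0.01, max_value=200),
                         min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_matches_explicit_equations(self, free, K):
        st_ = complexes_from_free(*free, K)
        expect = oracle_species(*free, K)
        for name, v in expect.items():
            assert getattr(st_, name) == pytest.approx(v, rel=1e-10)

    def test_negative_free_rejected(self, K):
        with pytest.raises(ValueError):
            complexes_from_free(-1, 0, 0, 0, K)


class TestSolveEquilibrium:
    def test_all_zero_totals(self, K):
        st_ = solve_equilibrium(K, SystemTotals())
        assert all(v == 0 for v in st_.as_dict().values())

    def test_dimerisation_quadratic(self, K):
        # 2*ER^2/K1 + ER = ER_t with ER_t = K1 = 25 -> ER = 12.5
        st_ = solve_equilibrium(K, SystemTotals(ER_t=25.0))
        assert st_.ER == pytest.approx(12.5, rel=1e-10)
        assert st_.ER2 == pytest.approx(6.25, rel=1e-10)

    def test_monomer_binding_quadratic(self):
        # suppress dimerisation: single-site binding (1-x)^2 = K4*x
        K = default_binding_constants(K1=1e9)
        st_ = solve_equilibrium(K, SystemTotals(ER_t=1.0, H_t=1.0))
        x = np.roots([1, -(2 + 0.25), 1])  # ERH root of (1-c)(1-c)=0.25c
        expected = float(min(x))
        assert st_.ERH == pytest.approx(expected, rel=1e-8)
        assert st_.ERH == pytest.approx(0.6096, abs=2e-4)

    def test_full_system_against_oracle(self, K):
        tot = SystemTotals(ER_t=50, H_t=0.5, I_t=100, D_t=0.3)
        st_ = solve_equilibrium(K, tot)
        expect = oracle_equilibrium(K, 50, 0.5, 100, 0.3)
        for name, v in expect.items():
            assert getattr(st_, name) == pytest.approx(v, rel=1e-6)

    def test_random_instances_match_oracle(self, K, rng):
        for _ in range(25):
            tot = rng.uniform(0.0, 300.0, 4)
            st_ = solve_equilibrium(K, SystemTotals(*tot))
            expect = oracle_equilibrium(K, *tot)
            for name, v in expect.items():
                have = getattr(st_, name)
                assert have == pytest.approx(v, rel=1e-6, abs=1e-12), name

    def test_conservation_and_mass_action_residuals(self, K, rng):
        for _ in range(20):
            tot = SystemTotals(*rng.uniform(0.001, 300.0, 4))
            st_ = solve_equilibrium(K, tot)
            back = st_.totals()
            for nm in ("ER_t", "H_t", "I_t", "D_t"):
                assert getattr(back, nm) == pytest.approx(getattr(tot, nm), rel=1e-8)
            assert max(st_.mass_action_residuals(K).values()) < 1e-8

    def test_inhibitor_free_reduces_to_hormone_only(self, K):
        a = solve_equilibrium(K, SystemTotals(ER_t=10, H_t=2, I_t=0, D_t=0.3))
        b = solve_equilibrium(K, SystemTotals(ER_t=10, H_t=2, D_t=0.3))
        for name, v in a.as_dict().items():
            assert v == pytest.approx(getattr(b, name), rel=1e-10, abs=1e-300)
        assert a.ERI == a.ER2I == a.ER2HID == 0

    @given(factor=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=15, deadline=None)
    def test_dimensional_scaling(self, factor, K):
        """Scaling all totals and all K's by c scales every species by c."""
        scaled_K = derive_dependent_constants(
            **{k: v * factor for k, v in PUBLISHED_BINDING.items()})
        base = solve_equilibrium(K, SystemTotals(20, 1, 50, 0.3))
        scaled = solve_equilibrium(
            scaled_K, SystemTotals(20 * factor, factor, 50 * factor, 0.3 * factor))
        for name, v in base.as_dict().items():
            assert getattr(scaled, name) == pytest.approx(v * factor, rel=1e-7)


class TestBoundHormone:
    def test_no_hormone_no_binding(self, K):
        tot = SystemTotals(ER_t=13.0)
        er_b, h_b = bound_hormone_metrics(solve_equilibrium(K, tot), tot)
        assert er_b == 0 and h_b == 0

    def test_saturation_limit(self, K):
        tot = SystemTotals(ER_t=13.0, H_t=1e6)
        _, h_b = bound_hormone_metrics(solve_equilibrium(K, tot), tot)
        assert h_b == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_total_hormone(self, K):
        grid = np.geomspace(1e-3, 1e3, 40)
        h_bs = []
        for h_t in grid:
            tot = SystemTotals(ER_t=13.0, H_t=h_t)
            h_bs.append(bound_hormone_metrics(solve_equilibrium(K, tot), tot)[1])
        assert np.all(np.diff(h_bs) > 0)

    def test_undefined_fraction_without_receptor(self, K):
        st_ = solve_equilibrium(K, SystemTotals(H_t=1.0))
        with pytest.raises(ValueError):
            bound_hormone_metrics(st_, SystemTotals(H_t=1.0))


class TestSpeciesScan:
    def test_single_point_equals_direct_solve(self, K):
        tot = SystemTotals(H_t=0.5, I_t=100.0)
        tab = species_distribution_scan(K, tot, [30.0])
        st_ = solve_equilibrium(K, SystemTotals(30.0, 0.5, 100.0, 0.0))
        for name, v in st_.as_dict().items():
            assert tab.iloc[0][name] == pytest.approx(v, rel=1e-10, abs=1e-300)

    def test_receptor_conservation_per_row(self, K):
        tot = SystemTotals(H_t=0.5, I_t=100.0, D_t=0.3)
        tab = species_distribution_scan(K, tot, [5.0, 50.0, 200.0])
        dimers = ["ER2", "ER2H", "ER2H2", "ER2I", "ER2I2", "ER2HI",
                  "ER2D", "ER2HD", "ER2H2D", "ER2ID", "ER2I2D", "ER2HID"]
        total = (tab["ER"] + tab["ERH"] + tab["ERI"]
                 + 2 * tab[dimers].sum(axis=1))
        assert np.allclose(total, tab["ER_t"], rtol=1e-8)

    def test_free_dimer_prevails_at_high_receptor(self, K):
        """At high ER with tamoxifen present, unliganded ER2 exceeds every
        hormone-bound dimer species (receptor-excess sequestration)."""
        tot = SystemTotals(H_t=0.5, I_t=100.0)
        tab = species_distribution_scan(K, tot, [200.0, 300.0])
        for _, row in tab.iterrows():
            for nm in ("ER2H", "ER2H2", "ER2HI"):
                assert row["ER2"] > row[nm]

    def test_non_ascending_grid_rejected(self, K):
        with pytest.raises(ValueError):
            species_distribution_scan(K, SystemTotals(), [2.0, 1.0])
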