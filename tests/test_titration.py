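"""Microstate model, exact enumeration, Monte Carlo and Em search."""

import math

import numpy as np
import pytest

from conftest import point_site
from rcem.constants import MV_TO_KCAL, R_GAS, K_COULOMB
from rcem.structure import PhysicalConditions
from rcem.titration import (SiteEnergyTable, curve_midpoint, enumerate_exact,
                            find_em, mc_sample, microstate_energy,
                            titration_curve)
from rcem import synthetic


def single_site_table(kind="acid", pka=7.0, em_ref=-429.0, g=0.0):
    dq = {"acid": -1.0, "base": 1.0, "redox": -1.0}[kind]
    site = point_site(f"{kind}-1", kind, 0, dq,
                      model_pka=None if kind == "redox" else pka,
                      em_ref=em_ref if kind == "redox" else None)
    return SiteEnergyTable(sites=[site], g_intr=np.array([g]),
                           W=np.zeros((1, 1)))


def two_site_table(w=1.0, g=(0.0, 0.0), pkas=(7.0, 7.0)):
    sites = [point_site("acid-1", "acid", 0, -1.0, model_pka=pkas[0]),
             point_site("acid-2", "acid", 1, -1.0, model_pka=pkas[1])]
    return SiteEnergyTable(sites=sites, g_intr=np.array(g),
                           W=np.array([[0.0, w], [w, 0.0]]))


class TestMicrostateEnergy:
    def test_reference_state_is_zero(self, default_conditions):
        table = two_site_table()
        assert microstate_energy([0, 0], table, default_conditions) == 0.0

    def test_acid_at_model_pka_has_equal_state_energies(self):
        table = single_site_table(pka=7.0)
        cond = PhysicalConditions(pH=7.0)
        assert microstate_energy([1], table, cond) == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_term_is_w(self, default_conditions):
        table = two_site_table(w=1.0)
        e = {}
        for x in ((0, 0), (0, 1), (1, 0), (1, 1)):
            e[x] = microstate_energy(x, table, default_conditions)
        assert e[(1, 1)] - e[(1, 0)] - e[(0, 1)] + e[(0, 0)] == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self, default_conditions):
        with pytest.raises(ValueError):
            microstate_energy([0, 1, 0], two_site_table(), default_conditions)


class TestEnumerateExact:
    def test_symmetric_single_acid_is_half(self):
        table = single_site_table(pka=7.0)
        res = enumerate_exact(table, PhysicalConditions(pH=7.0))
        assert res.populations[0] == pytest.approx(0.5, abs=1e-12)

    def test_two_coupled_sites_match_hand_computed_boltzmann(self):
        # independent oracle: explicit 4-term partition function
        cond = PhysicalConditions(pH=7.3)
        w, g, pkas = 0.8, (0.2, -0.4), (6.9, 7.6)
        table = two_site_table(w=w, g=g, pkas=pkas)
        rt = R_GAS * cond.temperature
        h = [g[i] + math.log(10) * rt * (pkas[i] - cond.pH) for i in range(2)]
        states = [(0, 0), (0, 1), (1, 0), (1, 1)]
        weights = [math.exp(-(x1 * h[0] + x2 * h[1] + x1 * x2 * w) / rt)
                   for x1, x2 in states]
        z = sum(weights)
        p1 = sum(wt for (x1, _), wt in zip(states, weights) if x1) / z
        p2 = sum(wt for (_, x2), wt in zip(states, weights) if x2) / z
        res = enumerate_exact(table, cond)
        assert res.populations[0] == pytest.approx(p1, abs=1e-12)
        assert res.populations[1] == pytest.approx(p2, abs=1e-12)

    def test_site_limit_enforced(self, default_conditions):
        spec = synthetic.ToySystemSpec(n_sites=12, seed=1)
        _, table, _ = synthetic.make_toy_titration(spec)
        with pytest.raises(ValueError):
            enumerate_exact(table, default_conditions, max_sites=10)


class TestMcSample:
    def test_same_seed_is_bit_identical(self, default_conditions):
        _, table, _ = synthetic.make_toy_titration(
            synthetic.ToySystemSpec(n_sites=6, seed=4))
        a = mc_sample(table, default_conditions, n_sweeps=2000, seed=9)
        b = mc_sample(table, default_conditions, n_sweeps=2000, seed=9)
        assert np.array_equal(a.populations, b.populations)

    def test_twelve_site_system_matches_enumeration(self, default_conditions):
        _, table, exact = synthetic.make_toy_titration(
            synthetic.ToySystemSpec(n_sites=12, seed=1))
        mc = mc_sample(table, default_conditions, n_sweeps=100_000, seed=1)
        assert np.max(np.abs(mc.populations - exact.populations)) < 0.01

    def test_henderson_hasselbalch_one_unit_above_pka(self):
        table = single_site_table(pka=7.0)
        res = mc_sample(table, PhysicalConditions(pH=8.0), n_sweeps=100_000,
                        seed=2)
        assert res.populations[0] == pytest.approx(10.0 / 11.0, abs=0.01)

    def test_acceptance_rate_reported(self, default_conditions):
        table = single_site_table()
        res = mc_sample(table, default_conditions, n_sweeps=100, seed=0)
        assert 0.0 <= res.acceptance_rate <= 1.0
        assert res.n_sweeps == 100 and res.seed == 0


class TestTableValidation:
    def test_asymmetric_w_rejected(self):
        sites = [point_site("a", "acid", 0, -1.0, model_pka=4.0),
                 point_site("b", "acid", 1, -1.0, model_pka=4.0)]
        w = np.array([[0.0, 1.0], [1.2, 0.0]])
        with pytest.raises(ValueError):
            SiteEnergyTable(sites=sites, g_intr=np.zeros(2), W=w)

    def test_nonzero_diagonal_rejected(self):
        site = point_site("a", "acid", 0, -1.0, model_pka=4.0)
        with pytest.raises(ValueError):
            SiteEnergyTable(sites=[site], g_intr=np.zeros(1),
                            W=np.array([[1.0]]))

    def test_tsv_serialization(self, tmp_path):
        table = two_site_table()
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        text = path.read_text()
        assert "acid-1" in text and "acid-2" in text


class TestFindEm:
    def test_isolated_reference_recovery(self, default_conditions):
        table = single_site_table(kind="redox", em_ref=-429.0)
        res = find_em("redox-1", table, default_conditions, tol_mv=0.5)
        assert res.em["redox-1"] == pytest.approx(-429.0, abs=1.0)

    def test_fixed_charge_shifts_em_by_coulomb_energy(self, default_conditions):
        # +1 e at 5 A from the -1 difference charge, eps 4: the interaction
        # is folded into g_intr; Em must shift by +332.06/(4*5) / 0.023061 mV
        shift_kcal = -K_COULOMB / (4.0 * 5.0)
        table = single_site_table(kind="redox", em_ref=-429.0, g=shift_kcal)
        res = find_em("redox-1", table, default_conditions, tol_mv=0.5)
        expect = -429.0 - shift_kcal / MV_TO_KCAL
        assert res.em["redox-1"] == pytest.approx(expect, abs=2.0)

    def test_midpoint_population_condition_holds(self, default_conditions):
        table = _coupled_table()
        res = find_em("redox-1", table, default_conditions, tol_mv=0.5)
        k = next(i for i, s in enumerate(table.sites)
                 if s.site_id == "redox-1")
        assert abs(res.populations[k] - 0.5) <= 0.01
        assert res.bias_applied["redox-1"] == pytest.approx(
            res.em["redox-1"] - (-429.0), abs=1e-9)

    def test_bias_method_equals_titration_curve_midpoint(self, default_conditions):
        table = _coupled_table()
        res = find_em("redox-1", table, default_conditions, tol_mv=0.5)
        grid = np.linspace(res.bias_applied["redox-1"] - 30,
                           res.bias_applied["redox-1"] + 30, 25)
        curve = titration_curve(table, default_conditions, "redox-1", grid)
        midpoint = -429.0 + curve_midpoint(grid, curve)
        assert res.em["redox-1"] == pytest.approx(midpoint, abs=2.0)

    @pytest.mark.parametrize("q", [0.0, 0.25, 0.5, 1.0])
    def test_positive_nearby_charge_never_decreases_em(self, q,
                                                       default_conditions):
        base = single_site_table(kind="redox", em_ref=-429.0, g=0.0)
        em0 = find_em("redox-1", base, default_conditions,
                      tol_mv=0.5).em["redox-1"]
        g = -K_COULOMB * q / (4.0 * 6.0)  # +q at 6 A stabilizes reduction
        table = single_site_table(kind="redox", em_ref=-429.0, g=g)
        em_q = find_em("redox-1", table, default_conditions,
                       tol_mv=0.5).em["redox-1"]
        assert em_q >= em0 - 1.0

    def test_non_redox_site_rejected(self, default_conditions):
        table = single_site_table(kind="acid")
        with pytest.raises(ValueError):
            find_em("acid-1", table, default_conditions)

    def test_bracket_failure_reports_range(self, default_conditions):
        table = single_site_table(kind="redox", em_ref=-429.0, g=-100.0)
        with pytest.raises(RuntimeError, match="bracket"):
            find_em("redox-1", table, default_conditions,
                    bias_range=(-50.0, 50.0))


def _coupled_table():
    spec = synthetic.ToySystemSpec(
        n_sites=4, geometry="shell", seed=3,
        kinds=["redox", "acid", "base", "acid"],
        model_pkas=[0.0, 6.5, 7.5, 7.0], em_refs=[-429.0] * 4)
    _, table, _ = synthetic.make_toy_titration(spec)
    return table
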