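"""Finite-difference LPB solver: oracles, invariants, focusing."""

import math

import numpy as np
import pytest

from conftest import point_site, toy_atom
from rcem import checks, pb, synthetic
from rcem.constants import K_COULOMB, debye_kappa2, debye_length
from rcem.structure import PhysicalConditions, Structure


class TestGridAndModel:
    def test_grid_spec_validation(self):
        with pytest.raises(ValueError):
            pb.GridSpec((0, 0, 0), 32, 1.0)  # even
        with pytest.raises(ValueError):
            pb.GridSpec((0, 0, 0), 31, 1.0)  # too small
        with pytest.raises(ValueError):
            pb.GridSpec((0, 0, 0), 33, -1.0)

    def test_dielectric_geometry_single_atom(self, default_conditions):
        st, _ = synthetic.make_born_system(2.0, 1.0)
        grid = pb.GridSpec((0.0, 0.0, 0.0), 33, 1.0)
        model = pb.build_dielectric_model(st, grid, default_conditions)
        eps_x = model.eps_edges[0]
        c = 16  # center node index
        assert eps_x[c, c, c] == pytest.approx(4.0)  # edge from center: inside
        assert eps_x[0, 0, 0] == pytest.approx(80.0)  # corner edge: solvent

    def test_zero_ionic_strength_gives_zero_screening(self):
        cond = PhysicalConditions(ionic_strength=0.0)
        st, _ = synthetic.make_born_system(2.0, 1.0)
        grid = pb.GridSpec((0.0, 0.0, 0.0), 33, 1.0)
        model = pb.build_dielectric_model(st, grid, cond)
        assert np.all(model.kappa2eps == 0.0)

    def test_debye_length_at_100mM(self):
        # kappa^2 = 8 pi k_e c / (eps k_B T): ~9.7 A at 100 mM, eps 80, 300 K
        assert debye_length(0.1, 80.0, 300.0) == pytest.approx(9.74, abs=0.05)
        assert debye_length(0.0) == math.inf

    def test_grid_must_enclose_charges(self, default_conditions):
        st, _ = synthetic.make_born_system(2.0, 1.0)
        grid = pb.GridSpec((100.0, 0.0, 0.0), 33, 1.0)
        with pytest.raises(pb.SolverError):
            pb.build_dielectric_model(st, grid, default_conditions)


class TestSolveLpb:
    def test_point_charge_uniform_dielectric_matches_coulomb(self):
        cond = PhysicalConditions(ionic_strength=0.0, eps_protein=80.0,
                                  eps_solvent=80.0)
        st, _ = synthetic.make_born_system(2.0, 1.0)
        grid = pb.GridSpec((0.0, 0.0, 0.0), 81, 0.5)
        model = pb.build_dielectric_model(st, grid, cond)
        phi = pb.solve_lpb(model, source_coords=st.coords,
                           source_charges=st.charges)
        got = float(phi.sample([[10.0, 0.0, 0.0]])[0])
        expect = K_COULOMB / (80.0 * 10.0)
        assert got == pytest.approx(expect, rel=0.01)

    def test_screened_potential_matches_debye_hueckel(self):
        r = checks.screened_coulomb()
        assert r.value == pytest.approx(r.reference, rel=0.02)

    def test_zero_charges_give_zero_potential(self, default_conditions):
        st, _ = synthetic.make_born_system(2.0, 0.0)
        grid = pb.GridSpec((0.0, 0.0, 0.0), 33, 1.0)
        model = pb.build_dielectric_model(st, grid, default_conditions)
        phi = pb.solve_lpb(model, source_coords=st.coords,
                           source_charges=st.charges)
        assert np.allclose(phi.phi, 0.0, atol=1e-12)

    def test_superposition_of_two_charges(self, uniform4):
        atoms = [toy_atom(1, (-3.0, 0, 0), charge=1.0),
                 toy_atom(2, (3.0, 0, 0), charge=-0.5)]
        st = Structure(atoms, id="sup")
        grid = pb.GridSpec((0.0, 0.0, 0.0), 41, 1.0)

        def solve(charges):
            model = pb.build_dielectric_model(st, grid, uniform4,
                                              charges=np.asarray(charges))
            return pb.solve_lpb(model, source_coords=st.coords,
                                source_charges=np.asarray(charges)).phi

        both = solve([1.0, -0.5])
        first = solve([1.0, 0.0])
        second = solve([0.0, -0.5])
        assert np.max(np.abs(both - first - second)) < 1e-3 * np.max(np.abs(both))

    def test_reciprocity_on_heterogeneous_toy(self, default_conditions):
        # q_i phi_j(r_i) == q_j phi_i(r_j) inside a dielectric cavity
        atoms = [toy_atom(1, (0, 0, 0), radius=6.0),
                 toy_atom(2, (-2.0, 0, 0), charge=1.0, radius=1.5),
                 toy_atom(3, (2.5, 0.5, 0), charge=1.0, radius=1.5)]
        st = Structure(atoms, id="recip")
        grid = pb.GridSpec((0.0, 0.0, 0.0), 65, 0.5)

        def phi_of(charges):
            model = pb.build_dielectric_model(st, grid, default_conditions,
                                              charges=np.asarray(charges))
            return pb.solve_lpb(model, source_coords=st.coords,
                                source_charges=np.asarray(charges))

        phi_a = phi_of([0.0, 1.0, 0.0]).sample([st.atoms[2].coords])[0]
        phi_b = phi_of([0.0, 0.0, 1.0]).sample([st.atoms[1].coords])[0]
        assert phi_a == pytest.approx(phi_b, rel=0.01)


class TestReactionField:
    def test_born_ion_oracle(self):
        r = checks.born_ion(spacings=(1.0, 0.5))
        assert r.value == pytest.approx(r.reference, rel=0.02)

    def test_born_error_decreases_with_finer_focusing(self):
        st, analytic = synthetic.make_born_system(2.0, 1.0)
        cond = PhysicalConditions(ionic_strength=0.0)
        errs = []
        for sched in ([1.0], [1.0, 0.5], [1.0, 0.5, 0.25]):
            e = pb.reaction_field_energy(st, cond, schedule=sched,
                                         npoints_fine=65)
            errs.append(abs(e - analytic) / abs(analytic))
        assert errs[0] > errs[1] > errs[2]

    def test_uniform_dielectric_gives_zero_reaction_field(self, uniform4):
        st, _ = synthetic.make_born_system(2.0, 1.0)
        e = pb.reaction_field_energy(st, uniform4, schedule=[1.0],
                                     npoints_fine=65)
        assert abs(e) < 0.05

    def test_reaction_field_scales_with_charge_squared(self):
        cond = PhysicalConditions(ionic_strength=0.0)
        st1, _ = synthetic.make_born_system(2.0, 1.0)
        st2, _ = synthetic.make_born_system(2.0, 2.0)
        e1 = pb.reaction_field_energy(st1, cond, schedule=[1.0], npoints_fine=65)
        e2 = pb.reaction_field_energy(st2, cond, schedule=[1.0], npoints_fine=65)
        assert e2 / e1 == pytest.approx(4.0, rel=0.01)

    def test_translation_by_half_spacing_changes_born_energy_little(self):
        cond = PhysicalConditions(ionic_strength=0.0)
        st, analytic = synthetic.make_born_system(2.0, 1.0)
        e0 = pb.reaction_field_energy(st, cond, schedule=[1.0, 0.5],
                                      npoints_fine=65)
        for a in st.atoms:
            a.coords = a.coords + np.array([0.25, 0.0, 0.0])
        e1 = pb.reaction_field_energy(st, cond, schedule=[1.0, 0.5],
                                      npoints_fine=65,
                                      focus=np.zeros(3))
        assert abs(e1 - e0) / abs(analytic) < 0.02


class TestFocusingAndInteraction:
    def test_single_level_schedule_equals_direct_solve(self, uniform4):
        st, _ = synthetic.make_born_system(2.0, 1.0)
        phi_f = pb.focusing_solve(st, uniform4, schedule=[1.0], margin=15.0)
        grid = phi_f.grid
        model = pb.build_dielectric_model(st, grid, uniform4)
        phi_d = pb.solve_lpb(model, source_coords=st.coords,
                             source_charges=st.charges)
        assert np.allclose(phi_f.phi, phi_d.phi, atol=1e-9)

    def test_non_decreasing_schedule_rejected(self, uniform4):
        st, _ = synthetic.make_born_system(2.0, 1.0)
        with pytest.raises(ValueError):
            pb.focusing_solve(st, uniform4, schedule=[1.0, 1.0])

    def test_interaction_matches_coulomb_and_is_symmetric(self, uniform4):
        atoms = [toy_atom(1, (0, 0, 0)), toy_atom(2, (10.0, 0, 0))]
        st = Structure(atoms, id="w")
        s1 = point_site("a1", "acid", 0, -1.0, model_pka=4.0)
        s2 = point_site("a2", "acid", 1, -1.0, model_pka=4.0)
        w12 = pb.interaction_energy(s1, s2, st, uniform4, schedule=[1.0, 0.5])
        w21 = pb.interaction_energy(s2, s1, st, uniform4, schedule=[1.0, 0.5])
        expect = K_COULOMB / (4.0 * 10.0)
        assert w12 == pytest.approx(expect, rel=0.02)
        assert abs(w12 - w21) <= 0.05

    def test_distant_screened_sites_decouple(self):
        cond = PhysicalConditions(ionic_strength=0.1, eps_protein=80.0,
                                  eps_solvent=80.0)
        atoms = [toy_atom(1, (0, 0, 0)), toy_atom(2, (50.0, 0, 0))]
        st = Structure(atoms, id="far")
        s1 = point_site("a1", "acid", 0, -1.0, model_pka=4.0)
        s2 = point_site("a2", "acid", 1, -1.0, model_pka=4.0)
        w = pb.interaction_energy(s1, s2, st, cond, schedule=[2.0])
        assert abs(w) < 0.05

    def test_overlapping_sites_rejected(self, uniform4):
        st = Structure([toy_atom(1, (0, 0, 0))], id="o")
        s1 = point_site("a1", "acid", 0, -1.0, model_pka=4.0)
        s2 = point_site("a2", "acid", 0, -1.0, model_pka=4.0)
        with pytest.raises(ValueError):
            pb.interaction_energy(s1, s2, st, uniform4)

    def test_solver_reports_converged_residual(self, uniform4):
        st, _ = synthetic.make_born_system(2.0, 1.0)
        phi = pb.focusing_solve(st, uniform4, schedule=[1.0])
        assert phi.residual <= 1e-6
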