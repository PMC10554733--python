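"""NSD basis properties, superposition and mode projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcem import nsd, synthetic
from rcem.structure import StructureError


@pytest.fixture(scope="module")
def basis():
    return nsd.default_basis()


class TestBasis:
    def test_modes_orthonormal(self, basis):
        gram = basis.modes @ basis.modes.T
        assert np.allclose(gram, np.eye(6), atol=1e-10)

    def test_modes_orthogonal_to_rigid_motions(self, basis):
        ref = basis.ref_coords
        rigid = np.column_stack([np.ones(24), ref[:, 0], ref[:, 1]])
        assert np.max(np.abs(basis.modes @ rigid)) < 1e-10

    def test_mode_shapes_match_symmetry_labels(self, basis):
        meso = [5, 11, 17, 23]
        sad = basis.mode("sad")
        ruf = basis.mode("ruf")
        dom = basis.mode("dom")
        # saddling leaves meso carbons in plane; ruffling is meso-dominated
        assert np.max(np.abs(sad[meso])) < 1e-10
        assert np.sum(ruf[meso] ** 2) > 0.5
        # ruffling meso carbons alternate in sign around the ring
        assert ruf[5] * ruf[11] < 0 and ruf[11] * ruf[17] < 0
        # doming: all four pyrrole nitrogens displace to the same side
        n_idx = [0, 6, 12, 18]
        assert np.all(np.sign(dom[n_idx]) == np.sign(dom[n_idx][0]))

    def test_waving_pair_related_by_quarter_turn(self, basis):
        c4 = nsd._perm_matrix(nsd._c4_permutation())
        assert np.allclose(c4 @ basis.mode("wav_x"), basis.mode("wav_y"),
                           atol=1e-10)

    def test_basis_file_round_trip(self, basis, tmp_path):
        path = tmp_path / "basis.txt"
        nsd.write_basis(basis, path)
        back = nsd.read_basis(path)
        assert np.allclose(back.ref_coords, basis.ref_coords, atol=1e-7)
        assert np.allclose(back.modes, basis.modes, atol=1e-7)


class TestExtraction:
    def test_canonical_order_and_count(self):
        mac, _ = synthetic.make_deformed_macrocycle(np.zeros(6))
        st = synthetic.macrocycle_structure(mac, resname="BPB")
        out = nsd.extract_macrocycle(st, ("L", 1))
        assert out.coords.shape == (24, 3)
        assert np.allclose(out.coords, mac.coords)

    def test_missing_atom_error_names_it(self):
        mac, _ = synthetic.make_deformed_macrocycle(np.zeros(6))
        st = synthetic.macrocycle_structure(mac)
        from rcem.structure import Structure
        st2 = Structure([a for a in st if a.name != "C1A"], id="broken")
        with pytest.raises(StructureError, match="C1A"):
            nsd.extract_macrocycle(st2, ("L", 1))

    def test_same_ordering_for_both_chlorin_types(self):
        mac, _ = synthetic.make_deformed_macrocycle(np.zeros(6))
        a = nsd.extract_macrocycle(
            synthetic.macrocycle_structure(mac, resname="BCB"), ("L", 1))
        b = nsd.extract_macrocycle(
            synthetic.macrocycle_structure(mac, resname="BPB"), ("L", 1))
        assert np.allclose(a.coords, b.coords)


class TestSuperpose:
    def test_reference_gives_zero_rmsd(self, basis):
        mac = nsd.Macrocycle(coords=basis.ref_coords.copy())
        aligned, rmsd = nsd.superpose(mac, basis)
        assert rmsd < 1e-12
        assert np.allclose(aligned, basis.ref_coords, atol=1e-12)

    def test_rigid_motion_recovered_exactly(self, basis):
        mac, _ = synthetic.make_deformed_macrocycle(np.zeros(6),
                                                    rigid_motion_seed=5)
        aligned, rmsd = nsd.superpose(mac, basis)
        assert rmsd < 1e-9

    def test_pure_saddling_keeps_in_plane_coordinates(self, basis):
        amps = np.array([0.3, 0, 0, 0, 0, 0])
        mac, _ = synthetic.make_deformed_macrocycle(amps, rigid_motion_seed=0)
        aligned, _ = nsd.superpose(mac, basis)
        assert np.allclose(aligned[:, :2], basis.ref_coords[:, :2], atol=1e-9)


class TestProjection:
    def test_zero_deformation_gives_zero_amplitudes(self, basis):
        res = nsd.project_modes(basis.ref_coords, basis)
        assert np.allclose(res.as_array(), 0.0, atol=1e-12)
        assert res.residual == 0.0

    def test_single_mode_recovered(self, basis):
        coords = basis.ref_coords.copy()
        coords[:, 2] += 0.30 * basis.mode("sad")
        res = nsd.project_modes(coords, basis)
        expect = np.array([0.30, 0, 0, 0, 0, 0])
        assert np.allclose(res.as_array(), expect, atol=1e-9)

    def test_mixed_deformation_with_rigid_motion(self, basis):
        amps = np.array([0.2, 0.35, -0.1, 0.1, -0.1, 0.13])
        mac, _ = synthetic.make_deformed_macrocycle(amps, rigid_motion_seed=7)
        res = nsd.analyze_macrocycle(mac, basis)
        assert np.allclose(res.as_array(), amps, atol=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_motion_invariance(self, seed):
        basis = nsd.default_basis()
        amps = np.array([0.15, -0.3, 0.05, 0.2, 0.0, -0.1])
        mac, _ = synthetic.make_deformed_macrocycle(amps, rigid_motion_seed=seed)
        res = nsd.analyze_macrocycle(mac, basis)
        assert np.max(np.abs(res.as_array() - amps)) < 1e-6

    def test_parseval_identity_with_off_basis_noise(self, basis):
        rng = np.random.RandomState(3)
        coords = basis.ref_coords.copy()
        coords[:, 2] += 0.2 * basis.mode("ruf") + 0.05 * rng.normal(size=24)
        res = nsd.project_modes(coords, basis)
        dz2 = float(np.sum((coords[:, 2]) ** 2))
        assert np.sum(res.as_array() ** 2) + res.residual ** 2 == pytest.approx(
            dz2, abs=1e-9)
        assert res.residual > 0  # random noise leaves the 6-mode span

    def test_quarter_turn_maps_waving_x_to_waving_y(self, basis):
        perm = nsd._c4_permutation()
        coords = basis.ref_coords.copy()
        coords[:, 2] += 0.25 * basis.mode("wav_x")
        rotated = coords[perm]  # same physical object, ring indices rotated
        # rotate in-plane coordinates back to canonical frame
        res = nsd.analyze_macrocycle(nsd.Macrocycle(coords=rotated), basis)
        d = res.d
        assert abs(abs(d["wav_y"]) - 0.25) < 1e-6
        assert abs(d["wav_x"]) < 1e-6

    @pytest.mark.parametrize("amp", [0.1, 0.3, 0.6])
    def test_recovery_up_to_point_six_angstrom(self, basis, amp):
        amps = np.array([amp, -amp, amp / 2, 0, amp / 3, -amp / 2])
        mac, _ = synthetic.make_deformed_macrocycle(amps, rigid_motion_seed=2)
        res = nsd.analyze_macrocycle(mac, basis)
        assert np.max(np.abs(res.as_array() - amps)) < 1e-6


class TestTimecourse:
    def test_identical_structures_give_constant_rows(self):
        amps = np.array([0.2, -0.1, 0, 0.05, 0, 0])
        mac, _ = synthetic.make_deformed_macrocycle(amps, rigid_motion_seed=1)
        st = synthetic.macrocycle_structure(mac)
        df = nsd.nsd_timecourse([("0ps", st), ("5ps", st)], {"H_L": ("L", 1)})
        assert len(df) == 2
        assert np.allclose(df.iloc[0, 2:8].astype(float),
                           df.iloc[1, 2:8].astype(float))
        assert not df["changed_sad"].any()

    def test_linear_saddling_growth(self):
        structures = []
        for i, a in enumerate([0.0, 0.1, 0.2, 0.3]):
            mac, _ = synthetic.make_deformed_macrocycle(
                np.array([a, 0.25, 0, 0, 0, 0]), rigid_motion_seed=i)
            structures.append((f"t{i}", synthetic.macrocycle_structure(mac)))
        df = nsd.nsd_timecourse(structures, {"H_L": ("L", 1)})
        sad = df["sad"].to_numpy()
        assert np.allclose(np.diff(sad), 0.1, atol=1e-6)
        assert np.allclose(df["ruf"], 0.25, atol=1e-6)
        # |delta| < 0.03 A flagged unchanged, larger changes flagged
        assert not df["changed_ruf"].any()
        assert list(df["changed_sad"]) == [False, True, True, True]

    def test_unknown_cofactor_errors(self):
        mac, _ = synthetic.make_deformed_macrocycle(np.zeros(6))
        st = synthetic.macrocycle_structure(mac)
        with pytest.raises(StructureError):
            nsd.nsd_timecourse([("0ps", st)], {"H_L": ("Z", 9)})
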