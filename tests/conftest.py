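import numpy as np
import pytest

from rcem.structure import Atom, PhysicalConditions, SiteDefinition, Structure


def toy_atom(serial, xyz, name="Q", resname="TOY", chain="X", seq=None,
             charge=0.0, radius=1.5, occupancy=1.0, altloc="", element="C"):
    return Atom(serial, name, altloc, resname, chain,
                seq if seq is not None else serial, np.asarray(xyz, float),
                occupancy, element, charge=charge, radius=radius)


def point_site(site_id, kind, index, dq_sign, model_pka=None, em_ref=None):
    return SiteDefinition(site_id=site_id, kind=kind, atom_indices=[index],
                          charges_state0=np.array([0.0]),
                          charges_state1=np.array([float(dq_sign)]),
                          model_pka=model_pka, em_ref=em_ref)


@pytest.fixture(scope="session")
def uniform4():
    """Uniform eps=4 vacuum-like conditions (no boundary, no screening)."""
    return PhysicalConditions(ionic_strength=0.0, eps_protein=4.0,
                              eps_solvent=4.0)


@pytest.fixture(scope="session")
def default_conditions():
    return PhysicalConditions()


@pytest.fixture(scope="session")
def peptide_pdb(tmp_path_factory):
    """Tiny Gly-Ala-Ser peptide with an altloc'd atom, a water and an
    unknown ligand, written as PDB text."""
    lines = [
        # GLY 1
        "ATOM      1  N   GLY A   1      -1.458   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   GLY A   1       0.767   1.305   0.000  1.00  0.00           C",
        "ATOM      4  O   GLY A   1       0.190   2.390   0.000  1.00  0.00           O",
        # ALA 2, CB with two conformers (0.70 / 0.30)
        "ATOM      5  N   ALA A   2       2.100   1.240   0.000  1.00  0.00           N",
        "ATOM      6  CA  ALA A   2       2.950   2.420   0.030  1.00  0.00           C",
        "ATOM      7  CB AALA A   2       3.850   2.430   1.270  0.70  0.00           C",
        "ATOM      8  CB BALA A   2       3.950   2.300  -1.150  0.30  0.00           C",
        "ATOM      9  C   ALA A   2       3.790   2.520  -1.240  1.00  0.00           C",
        "ATOM     10  O   ALA A   2       4.220   1.500  -1.790  1.00  0.00           O",
        # SER 3
        "ATOM     11  N   SER A   3       4.020   3.720  -1.700  1.00  0.00           N",
        "ATOM     12  CA  SER A   3       4.810   3.940  -2.910  1.00  0.00           C",
        "ATOM     13  CB  SER A   3       4.000   4.700  -3.970  1.00  0.00           C",
        "ATOM     14  OG  SER A   3       4.760   4.860  -5.160  1.00  0.00           O",
        "ATOM     15  C   SER A   3       6.070   4.720  -2.560  1.00  0.00           C",
        "ATOM     16  O   SER A   3       6.250   5.880  -2.950  1.00  0.00           O",
        "ATOM     17  OXT SER A   3       6.940   4.130  -1.870  1.00  0.00           O",
        # water + unknown ligand
        "HETATM   18  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O",
        "HETATM   19  C1  LIG A 201      12.000  12.000  12.000  1.00  0.00           C",
        "HETATM   20  H1  LIG A 201      12.000  13.100  12.000  1.00  0.00           H",
        "END",
    ]
    path = tmp_path_factory.mktemp("pdb") / "peptide.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
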