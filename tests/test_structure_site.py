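"""Geometry kernels: PDB parsing, distances, contacts, Kabsch, SASA.

Oracles: a quaternion-grid brute-force superposition for Kabsch, analytic
sphere areas for SASA, and tiny hand-built PDB fixtures for parsing.
"""

import numpy as np
import pytest

from thiolprobe.structure_site import (
    AtomRecord,
    DEFAULT_RADII,
    MissingRadiusError,
    StructureModel,
    atom_distance,
    buried_area,
    chain_asa,
    find_contacts,
    interface_area,
    kabsch_superpose,
    read_pdb,
    sasa,
)


def atom(chain, resnum, name, element, x, y, z, **kw):
    return AtomRecord(chain, resnum, "UNK", name, element, x, y, z, **kw)


MINI_PDB = """\
ATOM      1  N   CYS A  36      10.000   0.000   0.000  1.00 10.00           N
ATOM      2  SG ACYS A  36       0.000   0.000   0.000  0.60 10.00           S
ATOM      3  SG BCYS A  36       1.000   0.000   0.000  0.40 10.00           S
ATOM      4  SG  CYS A  39       3.600   0.000   0.000  1.00 10.00           S
ATOM      5  O   MET A  79       0.000   3.500   0.000  1.00 10.00           O
ATOM      6  CA  GLY B   1      50.000  50.000  50.000  1.00 10.00           C
HETATM    7  O   HOH A 101       0.000   0.000   3.000  1.00 10.00           O
END
"""


@pytest.fixture
def mini_model(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return read_pdb(path)


class TestReadPdb:
    def test_altloc_keeps_highest_occupancy(self, mini_model):
        sg = mini_model.atom("A", 36, "SG")
        assert sg.altloc == "A" and sg.occupancy == pytest.approx(0.6)

    def test_waters_flagged_and_excludable(self, mini_model):
        waters = [a for a in mini_model if a.is_water]
        assert len(waters) == 1
        assert len(mini_model.select(chain="A")) < len(
            mini_model.select(chain="A", include_waters=True))

    def test_single_atom_file(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text("ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
                     "  1.00  0.00           C\nEND\n")
        assert len(read_pdb(p)) == 1

    def test_malformed_file_rejected(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM  not a valid record at all\n")
        with pytest.raises(ValueError):
            read_pdb(p)

    def test_missing_atom_lookup(self, mini_model):
        with pytest.raises(KeyError):
            mini_model.atom("A", 99, "SG")


class TestDistanceAndContacts:
    def test_pythagorean_distance(self):
        a = atom("A", 1, "X", "C", 0, 0, 0)
        b = atom("A", 2, "X", "C", 3, 4, 0)
        assert atom_distance(a, b) == 5.0
        assert atom_distance(a, a) == 0.0

    def test_active_site_contact_inventory(self, mini_model):
        # the attacking cysteine's SG sees the resolving SG (3.6 A) and a
        # backbone carbonyl O (3.5 A) within the 4.0 A h-bond cutoff
        sg = mini_model.atom("A", 36, "SG")
        contacts = find_contacts(sg, mini_model.select(chain="A"), cutoff=4.0)
        got = {(c.resnum, c.atom_name): round(d, 1) for _, c, d in contacts}
        assert got[(79, "O")] == 3.5
        assert got[(39, "SG")] == 3.6
        assert (36, "N") not in got  # same residue excluded

    def test_distances_sorted_and_cutoff_respected(self, mini_model):
        sg = mini_model.atom("A", 36, "SG")
        contacts = find_contacts(sg, mini_model, cutoff=3.55,
                                 exclude_same_residue=True)
        dists = [d for _, _, d in contacts]
        assert dists == sorted(dists) and all(d <= 3.55 for d in dists)

    def test_empty_neighbourhood(self, mini_model):
        lone = mini_model.atom("B", 1, "CA")
        assert find_contacts(lone, mini_model, cutoff=4.0) == []

    def test_query_atom_must_be_in_model(self, mini_model):
        stray = atom("Z", 1, "X", "S", 0, 0, 0)
        with pytest.raises(KeyError):
            find_contacts(stray, mini_model)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quaternion_grid_rmsd(P, Q, seed=0):
    """Brute-force minimum RMSD over sampled rotations with local refinement.

    Global random quaternion sampling followed by shrinking Gaussian
    perturbations around the incumbent; no SVD anywhere.
    """
    rng = np.random.default_rng(seed)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def quat_to_R(q):
        w, x, y, z = q / np.linalg.norm(q)
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def cost(q):
        return np.sqrt(((Qc @ quat_to_R(q).T - Pc) ** 2).sum() / len(P))

    best_q, best = None, np.inf
    for _ in range(4000):
        q = rng.normal(size=4)
        c = cost(q)
        if c < best:
            best, best_q = c, q / np.linalg.norm(q)
    scale = 0.3
    for _ in range(12):
        for _ in range(400):
            q = best_q + rng.normal(size=4) * scale
            c = cost(q)
            if c < best:
                best, best_q = c, q / np.linalg.norm(q)
        scale *= 0.5
    return best


class TestKabsch:
    def test_self_superposition_zero(self, rng):
        P = rng.normal(size=(8, 3))
        assert kabsch_superpose(P, P)[2] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self, rng):
        P = rng.normal(size=(15, 3))
        R0 = random_rotation(rng)
        Q = P @ R0.T + np.array([3.0, -2.0, 7.0])
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(Q @ R.T + t, P, atol=1e-9)

    def test_symmetry(self, rng):
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        assert kabsch_superpose(P, Q)[2] == pytest.approx(
            kabsch_superpose(Q, P)[2], abs=1e-9)

    def test_agrees_with_quaternion_grid_oracle(self, rng):
        P = rng.normal(size=(10, 3))
        Q = P @ random_rotation(rng).T + rng.normal(size=(10, 3)) * 0.2
        ours = kabsch_superpose(P, Q)[2]
        oracle = quaternion_grid_rmsd(P, Q)
        assert ours <= oracle + 1e-9  # Kabsch is the exact minimum
        assert oracle == pytest.approx(ours, abs=1e-3)

    def test_proper_rotation_enforced(self, rng):
        P = rng.normal(size=(6, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored cloud: best proper rotation cannot be perfect
        R, _, rmsd = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.01

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestSasa:
    def test_isolated_atom_is_a_full_sphere(self):
        m = StructureModel([atom("A", 1, "C", "C", 0, 0, 0)])
        exact = 4 * np.pi * (DEFAULT_RADII["C"] + 1.4) ** 2
        assert sasa(m)[0] == pytest.approx(exact, rel=0.005)

    def test_distant_atoms_additive(self):
        m = StructureModel([atom("A", 1, "S", "S", 0, 0, 0),
                            atom("A", 2, "S", "S", 100, 0, 0)])
        exact = 4 * np.pi * (DEFAULT_RADII["S"] + 1.4) ** 2
        assert sasa(m).sum() == pytest.approx(2 * exact, rel=0.005)

    def test_caged_atom_has_zero_area(self):
        # surround one atom with a tight shell of 60 atoms at 3 A
        k = np.arange(60) + 0.5
        phi = np.arccos(1 - 2 * k / 60)
        theta = np.pi * (1 + 5 ** 0.5) * k
        shell = 3.0 * np.column_stack([
            np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)])
        atoms = [atom("A", 1, "C", "C", 0, 0, 0)] + [
            atom("A", 2 + i, "C", "C", *p) for i, p in enumerate(shell)]
        assert sasa(StructureModel(atoms))[0] == 0.0

    def test_area_decreases_as_neighbour_approaches(self):
        areas = []
        for d in (8.0, 5.0, 3.5, 2.0, 1.0):
            m = StructureModel([atom("A", 1, "C", "C", 0, 0, 0),
                                atom("A", 2, "C", "C", d, 0, 0)])
            areas.append(sasa(m)[0])
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_missing_radius_is_named_error(self):
        m = StructureModel([atom("A", 1, "FE", "FE", 0, 0, 0)])
        with pytest.raises(MissingRadiusError, match="FE"):
            sasa(m)

    def test_interface_area_zero_when_separated_positive_when_touching(self):
        far = StructureModel([atom("A", 1, "C", "C", 0, 0, 0),
                              atom("B", 1, "C", "C", 50, 0, 0)])
        near = StructureModel([atom("A", 1, "C", "C", 0, 0, 0),
                               atom("B", 1, "C", "C", 4.0, 0, 0)])
        assert interface_area(far, "A", "B") == pytest.approx(0.0, abs=1e-9)
        assert interface_area(near, "A", "B") > 0
        assert buried_area(near, "A", "B") == pytest.approx(
            2 * interface_area(near, "A", "B"))

    def test_chain_asa_selects_chains(self, mini_model):
        a_only = chain_asa(mini_model, ["A"])
        both = chain_asa(mini_model, ["A", "B"])
        assert both > a_only > 0
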