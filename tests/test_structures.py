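"""Structure I/O, coarse-graining, superposition and geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from enmkit.structures import (
    Bead,
    BeadModel,
    ChimeraRecipe,
    ChimeraSegment,
    PDBParseError,
    atomic_mass,
    build_chimera,
    coarse_grain,
    coarse_grain_nucleotide,
    coarse_grain_protein,
    dihedral,
    domain_rotation_angle,
    read_structure,
    rotation_angle,
    superpose,
    virtual_torsion_profile,
    write_bead_pdb,
    write_trajectory_pdb,
)

from conftest import (
    TRIPEPTIDE_PDB,
    bead_model,
    ligand_structure,
    make_structure,
    random_bead_model,
)


class TestReadStructure:
    def test_reads_residues_and_chain(self, tripeptide_path):
        s = read_structure(tripeptide_path)
        assert s.n_atoms == 13  # altloc B of GLY 2 dropped
        assert set(s.chain_id) == {"A"}
        assert [r for _, r in s.residue_keys()] == [1, 2, 3]

    def test_altloc_keeps_highest_occupancy(self, tripeptide_path):
        s = read_structure(tripeptide_path)
        gly_ca = s.coord[(s.res_id == 2) & (s.atom_name == "CA")]
        assert len(gly_ca) == 1
        np.testing.assert_allclose(gly_ca[0], [13.837, 9.084, -5.961],
                                   atol=1e-3)

    def test_truncated_atom_line_names_line_number(self, tmp_path):
        bad = TRIPEPTIDE_PDB.splitlines()
        bad[11] = bad[11][:30]  # truncate SER CA record (line 12)
        p = tmp_path / "bad.pdb"
        p.write_text("\n".join(bad) + "\n")
        with pytest.raises(PDBParseError, match="line 12"):
            read_structure(p)

    def test_missing_file_and_model(self, tripeptide_path, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")
        with pytest.raises(PDBParseError, match="model 3"):
            read_structure(tripeptide_path, model=3)


class TestCoarseGrainProtein:
    def test_beads_at_calpha(self, tripeptide_path):
        s = read_structure(tripeptide_path)
        m = coarse_grain_protein(s)
        assert len(m) == 3
        ca = s.coord[s.atom_name == "CA"]
        np.testing.assert_allclose(m.coords, ca, atol=1e-6)

    def test_residue_mass_is_sum_of_present_atoms(self, tripeptide_path):
        s = read_structure(tripeptide_path)
        m = coarse_grain_protein(s)
        # brute-force oracle: element-mass sum per residue
        for bead in m.beads:
            mask = s.residue_mask(bead.label[0], bead.label[1])
            expected = sum(atomic_mass(e) for e in s.element[mask])
            assert bead.mass == pytest.approx(expected, rel=1e-12)

    def test_total_mass_conserved(self, tripeptide_path):
        s = read_structure(tripeptide_path)
        m = coarse_grain_protein(s)
        total = sum(atomic_mass(e) for e in s.element)
        assert m.masses.sum() == pytest.approx(total, rel=1e-9)

    def test_missing_calpha_strictness(self):
        rows = [("N", "N", "GLY", 1, "A", [0, 0, 0], False),
                ("C", "C", "GLY", 1, "A", [1.5, 0, 0], False),
                ("N", "N", "ALA", 2, "A", [3, 0, 0], False),
                ("CA", "C", "ALA", 2, "A", [4.5, 0, 0], False)]
        s = make_structure(rows)
        with pytest.raises(ValueError, match="no Calpha"):
            coarse_grain_protein(s, strict=True)
        with pytest.warns(UserWarning, match="skipped"):
            m = coarse_grain_protein(s, strict=False)
        assert len(m) == 1


class TestCoarseGrainNucleotide:
    def test_gtp_five_beads_gdp_four(self):
        gtp = coarse_grain_nucleotide(ligand_structure("GTP"), "GTP")
        gdp = coarse_grain_nucleotide(ligand_structure("GDP"), "GDP")
        assert len(gtp) == 5
        assert len(gdp) == 4
        assert not any("gamma" in b.label[2] for b in gdp)

    @pytest.mark.parametrize("kind", ["GTP", "GDP"])
    def test_mass_conserved(self, kind):
        lig = ligand_structure(kind)
        beads = coarse_grain_nucleotide(lig, kind)
        total = sum(atomic_mass(e) for e in lig.element)
        assert sum(b.mass for b in beads) == pytest.approx(total, rel=1e-9)

    def test_gamma_bead_at_mass_weighted_centroid(self):
        lig = ligand_structure("GTP")
        beads = coarse_grain_nucleotide(lig, "GTP")
        gamma = next(b for b in beads if "gamma" in b.label[2])
        names = {"PG", "O1G", "O2G", "O3G", "O3B"}
        idx = [i for i, a in enumerate(lig.atom_name) if str(a) in names]
        w = np.array([atomic_mass(str(lig.element[i])) for i in idx])
        centroid = np.average(lig.coord[idx], axis=0, weights=w)
        np.testing.assert_allclose(gamma.position, centroid, atol=1e-10)

    def test_unknown_atom_rejected(self):
        lig = ligand_structure("GTP")
        bad = lig.select(np.ones(lig.n_atoms, bool))
        bad.atom_name[0] = "XX9"
        with pytest.raises(ValueError, match="XX9"):
            coarse_grain_nucleotide(bad, "GTP")

    def test_coarse_grain_combines_protein_and_ligand(self, tripeptide_path):
        s = read_structure(tripeptide_path)
        lig = ligand_structure("GDP", chain="A", res_id=401)
        combined = make_structure(
            [(str(s.atom_name[i]), str(s.element[i]), str(s.res_name[i]),
              int(s.res_id[i]), "A", s.coord[i], False)
             for i in range(s.n_atoms)]
            + [(str(lig.atom_name[i]), str(lig.element[i]), "GDP", 401, "A",
                lig.coord[i], True) for i in range(lig.n_atoms)]
        )
        model, atom_map = coarse_grain(combined)
        assert len(model) == 3 + 4
        assert sum(len(v) for v in atom_map.values()) == combined.n_atoms


class TestSuperposition:
    def test_self_superposition_is_identity(self):
        m = random_bead_model(8, seed=1)
        sup = superpose(m, m)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("angle", [10.0, 30.0, 120.0])
    def test_recovers_constructed_rotation(self, angle):
        m = random_bead_model(10, seed=2)
        R = Rotation.from_euler("zx", [angle, 7.0], degrees=True)
        moved = m.with_coords(R.apply(m.coords) + [1.0, -2.0, 3.0])
        sup = superpose(m, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        expected = np.degrees(R.magnitude())
        assert rotation_angle(sup.rotation) == pytest.approx(expected,
                                                             abs=1e-6)

    def test_rmsd_symmetric(self):
        a = random_bead_model(12, seed=3)
        b = a.with_coords(a.coords + np.random.default_rng(4).normal(
            0, 0.8, a.coords.shape))
        assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd,
                                                     abs=1e-8)

    def test_rotation_orthonormal(self):
        a = random_bead_model(7, seed=5)
        b = random_bead_model(7, seed=6)
        R = superpose(a, b).rotation
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_or_collinear_pairs(self):
        line = bead_model([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)
        two = bead_model([[0, 0, 0], [1, 1, 1]])
        with pytest.raises(ValueError, match=">=3"):
            superpose(two, two)


class TestVirtualTorsion:
    def test_ideal_helix_profile_constant_and_matches_closed_form(self):
        rise, radius, twist = 1.5, 2.3, np.radians(100.0)
        k = np.arange(12)
        coords = np.column_stack([k * rise, radius * np.cos(twist * k),
                                  radius * np.sin(twist * k)])
        profile = virtual_torsion_profile(bead_model(coords))
        values = np.array([v for _, _, v in profile])
        assert np.ptp(values) < 1e-9
        # independent oracle: reference dihedral implementation
        from Bio.PDB.vectors import Vector, calc_dihedral

        expected = np.degrees(calc_dihedral(*[Vector(*c)
                                              for c in coords[:4]]))
        assert values[0] == pytest.approx(expected, abs=1e-9)
        # a right-handed helix has a positive virtual torsion
        assert values[0] > 0

    def test_planar_zigzag_is_180(self):
        k = np.arange(6)
        zz = np.column_stack([k * 1.5, 0.8 * (-1.0) ** k, np.zeros(6)])
        profile = virtual_torsion_profile(bead_model(zz))
        assert all(abs(v) == pytest.approx(180.0, abs=1e-9)
                   for _, _, v in profile)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match=">=4"):
            virtual_torsion_profile(bead_model([[0, 0, 0], [1, 1, 0],
                                                [2, 0, 0]]))

    def test_angle_range_convention(self):
        # dihedral returns values in (-180, 180]
        assert dihedral(np.array([0, 1, 0.]), np.array([0, 0, 0.]),
                        np.array([1, 0, 0.]), np.array([1, -1, 0.])
                        ) == pytest.approx(180.0)


class TestDomainRotation:
    def test_identical_models_zero_angle(self, hinge):
        closed, _, _ = hinge
        labels_a = [b.label for b in closed.beads if b.label[0] == "A"]
        labels_b = [b.label for b in closed.beads if b.label[0] == "B"]
        assert domain_rotation_angle(closed, closed, labels_a,
                                     labels_b) == pytest.approx(0.0, abs=1e-8)

    def test_recovers_generator_angle(self, hinge):
        closed, open_, truth = hinge
        labels_a = [b.label for b in closed.beads if b.label[0] == "A"]
        labels_b = [b.label for b in closed.beads if b.label[0] == "B"]
        angle = domain_rotation_angle(closed, open_, labels_a, labels_b)
        assert angle == pytest.approx(truth["angle_deg"], abs=0.1)

    @pytest.mark.parametrize("spec_angle", [15.0, 70.0, 130.0])
    def test_recovery_across_angles(self, spec_angle):
        from enmkit.synthetic import HingeSpec, make_hinge_pair

        closed, open_, truth = make_hinge_pair(HingeSpec(angle_deg=spec_angle,
                                                         seed=3))
        labels_a = [b.label for b in closed.beads if b.label[0] == "A"]
        labels_b = [b.label for b in closed.beads if b.label[0] == "B"]
        angle = domain_rotation_angle(closed, open_, labels_a, labels_b)
        assert angle == pytest.approx(spec_angle, abs=0.1)


class TestChimera:
    def test_identity_recipe_reproduces_source(self):
        src = random_bead_model(10, seed=7)
        out = build_chimera(
            ChimeraRecipe([ChimeraSegment("s", "A", 1, 10)], reference="s"),
            {"s": src},
        )
        np.testing.assert_allclose(out.coords, src.coords)
        assert [l[1] for l in out.labels] == [l[1] for l in src.labels]

    def test_graft_carries_displaced_coordinates(self):
        src = random_bead_model(10, seed=8)
        shift = np.array([0.0, 0.0, 7.0])
        displaced = src.with_coords(
            np.vstack([src.coords[:5], src.coords[5:] + shift]))
        anchors = [("A", i, "ALA") for i in (1, 2, 3, 4, 5)]
        out = build_chimera(
            ChimeraRecipe([ChimeraSegment("a", "A", 1, 5),
                           ChimeraSegment("b", "A", 6, 10)],
                          reference="a", anchors=anchors),
            {"a": src, "b": displaced},
        )
        np.testing.assert_allclose(out.coords[5:], src.coords[5:] + shift,
                                   atol=1e-8)

    def test_overlapping_output_ranges_rejected(self):
        src = random_bead_model(10, seed=9)
        recipe = ChimeraRecipe([ChimeraSegment("s", "A", 1, 6),
                                ChimeraSegment("s", "A", 4, 10)],
                               reference="s")
        with pytest.raises(ValueError, match="overlapping"):
            build_chimera(recipe, {"s": src})

    def test_target_renumbering(self):
        src = random_bead_model(6, seed=10)
        out = build_chimera(
            ChimeraRecipe([ChimeraSegment("s", "A", 1, 6, target_start=101)],
                          reference="s"),
            {"s": src},
        )
        assert [l[1] for l in out.labels] == list(range(101, 107))


class TestPDBWriters:
    def test_bead_roundtrip(self, tmp_path):
        m = random_bead_model(9, seed=11)
        path = tmp_path / "beads.pdb"
        write_bead_pdb(m, path)
        back = read_structure(path)
        model, _ = coarse_grain(back)
        np.testing.assert_allclose(model.coords, m.coords, atol=1e-3)

    def test_trajectory_multimodel(self, tmp_path):
        m = random_bead_model(5, seed=12)
        frames = [m, m.with_coords(m.coords + 1.0),
                  m.with_coords(m.coords + 2.0)]
        path = tmp_path / "traj.pdb"
        write_trajectory_pdb(frames, path)
        text = path.read_text()
        assert text.count("MODEL") == 3
        second = read_structure(path, model=2)
        model, _ = coarse_grain(second)
        np.testing.assert_allclose(model.coords, m.coords + 1.0, atol=1e-3)


class TestBeadModelInvariants:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            BeadModel([Bead(0, np.zeros(3), 1.0, "residue", ("A", 1, "ALA")),
                       Bead(1, np.ones(3), 1.0, "residue", ("A", 1, "ALA"))])

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            Bead(0, np.zeros(3), 0.0, "residue", ("A", 1, "ALA"))
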