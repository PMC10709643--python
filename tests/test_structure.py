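"""Hydrogen-bond census, superposition, swap detection, interface reports."""

import numpy as np
import pytest

from conftest import brute_force_rmsd
from tetraswap.structure import (
    AtomRecord,
    Residue,
    StructureModel,
    assembly_free_energy,
    detect_swap,
    find_hbonds,
    framework_rmsd,
    interface_report,
    kabsch_rmsd,
    parse_res_id,
    read_structure,
)


def pdb_line(
    serial, name, res_name, chain, res_seq, x, y, z, element, icode=" ", altloc=" ", occ=1.0
) -> str:
    return (
        f"ATOM  {serial:>5} {name:<4}{altloc}{res_name:<3} {chain}{res_seq:>4}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}"
    )


def atom(chain, seq, name, element, xyz, res_name="GLY", icode=""):
    return AtomRecord(
        chain_id=chain,
        res_name=res_name,
        res_seq=seq,
        icode=icode,
        atom_name=name,
        element=element,
        xyz=tuple(float(v) for v in xyz),
    )


def two_atom_model(distance: float) -> StructureModel:
    ra = Residue("A", "GLY", 1, "", [atom("A", 1, "N", "N", (0, 0, 0))])
    rb = Residue("B", "GLY", 1, "", [atom("B", 1, "O", "O", (0, 0, distance))])
    return StructureModel({"A": [ra], "B": [rb]})


def random_rotation(seed: int) -> np.ndarray:
    q = np.random.default_rng(seed).normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestReadStructure:
    def test_minimal_two_atom_pdb(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(
            pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N")
            + "\n"
            + pdb_line(2, "O", "GLY", "B", 1, 0.0, 0.0, 3.4, "O")
            + "\nEND\n"
        )
        model = read_structure(path)
        atoms = model.select("A") + model.select("B")
        assert len(atoms) == 2
        assert {a.element for a in atoms} == {"N", "O"}

    def test_insertion_code_is_selectable(self, tmp_path):
        path = tmp_path / "icode.pdb"
        lines = [
            pdb_line(1, "CA", "ASP", "A", 27, 0.0, 0.0, 0.0, "C"),
            pdb_line(2, "CA", "ASP", "A", 27, 4.0, 0.0, 0.0, "C", icode="D"),
            pdb_line(3, "CA", "SER", "A", 28, 8.0, 0.0, 0.0, "C"),
        ]
        path.write_text("\n".join(lines) + "\nEND\n")
        model = read_structure(path)
        sel = model.select("A:27d-27d")
        assert len(sel) == 1
        assert sel[0].res_id == "27d"
        # the range 27-27d spans both residues
        assert len(model.select("A:27-27d")) == 2

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        lines = [
            pdb_line(1, "CA", "SER", "A", 1, 0.0, 0.0, 0.0, "C", altloc="A", occ=0.4),
            pdb_line(2, "CA", "SER", "A", 1, 1.0, 0.0, 0.0, "C", altloc="B", occ=0.6),
        ]
        path.write_text("\n".join(lines) + "\nEND\n")
        model = read_structure(path)
        sel = model.select("A")
        assert len(sel) == 1
        assert sel[0].xyz[0] == pytest.approx(1.0)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            read_structure(path)


@pytest.mark.parametrize("token,expected", [("96", (96, "")), ("27d", (27, "D")), ("-1", (-1, ""))])
def test_parse_res_id(token, expected):
    assert parse_res_id(token) == expected


class TestHydrogenBonds:
    def test_pair_inside_cutoff(self):
        bonds = find_hbonds(two_atom_model(3.4), "A", "B")
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(3.4)
        assert bonds[0].scope == "interchain"

    def test_pair_outside_cutoff(self):
        assert find_hbonds(two_atom_model(3.6), "A", "B") == []

    def test_symmetric_in_groups(self, toys):
        ab = find_hbonds(toys.beta_ladder, "A", "B")
        ba = find_hbonds(toys.beta_ladder, "B", "A")
        assert len(ab) == len(ba)
        assert [b.distance for b in ab] == pytest.approx([b.distance for b in ba])

    def test_invariant_under_rigid_motion(self, toys):
        rot = random_rotation(3)
        moved = toys.beta_ladder.transformed(rot, np.array([5.0, -2.0, 11.0]))
        orig = find_hbonds(toys.beta_ladder, "A", "B")
        after = find_hbonds(moved, "A", "B")
        assert [b.distance for b in after] == pytest.approx([b.distance for b in orig])

    def test_declared_ladder_bonds_reproduced_exactly(self, toys):
        bonds = find_hbonds(toys.beta_ladder, "A", "B")
        got = {
            (
                (b.donor_side.chain_id, b.donor_side.res_id, b.donor_side.atom_name),
                (b.acceptor_side.chain_id, b.acceptor_side.res_id, b.acceptor_side.atom_name),
            )
            for b in bonds
        }
        declared = {(a, b) for a, b, _d in toys.declared_bonds}
        assert got == declared
        for b in bonds:
            assert b.distance == pytest.approx(2.9, abs=1e-9)

    def test_overlapping_selections_rejected(self, toys):
        with pytest.raises(ValueError, match="overlap"):
            find_hbonds(toys.beta_ladder, "A", "A:1-3")

    def test_water_water_pairs_never_counted(self):
        wa = Residue("A", "HOH", 100, "", [atom("A", 100, "O", "O", (0, 0, 0), "HOH")])
        wb = Residue("B", "HOH", 101, "", [atom("B", 101, "O", "O", (0, 0, 2.8), "HOH")])
        prot = Residue("B", "SER", 1, "", [atom("B", 1, "OG", "O", (0, 0, -2.9), "SER")])
        model = StructureModel({"A": [wa], "B": [prot, wb]})
        bonds = find_hbonds(model, "A", "B", include_waters=True)
        labels = [b.label() for b in bonds]
        assert len(bonds) == 1 and "Ser" in labels[0]

    def test_carbon_is_not_a_polar_partner(self):
        ra = Residue("A", "ALA", 1, "", [atom("A", 1, "CB", "C", (0, 0, 0), "ALA")])
        rb = Residue("B", "GLY", 1, "", [atom("B", 1, "O", "O", (0, 0, 3.0))])
        model = StructureModel({"A": [ra], "B": [rb]})
        assert find_hbonds(model, "A", "B") == []


class TestKabsch:
    def test_identical_sets_are_zero(self, rng):
        pts = rng.normal(size=(10, 3))
        assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_is_invisible(self, rng):
        pts = rng.normal(size=(12, 3)) * 5.0
        moved = pts @ random_rotation(7).T + np.array([3.0, -1.0, 8.0])
        assert kabsch_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-10)

    def test_symmetry(self, rng):
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.3, size=(8, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), rel=1e-12)

    def test_four_point_toy_matches_brute_force_oracle(self):
        a = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        b = a.copy()
        b[3, 2] += 1.0  # displace one point by 1 A
        assert kabsch_rmsd(a, b) == pytest.approx(brute_force_rmsd(a, b), abs=1e-6)

    def test_reflection_is_not_allowed(self):
        a = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [1, 1, 3]])
        mirrored = a * np.array([1.0, 1.0, -1.0])
        # a proper rotation cannot superpose a chiral set onto its mirror image
        assert kabsch_rmsd(a, mirrored) > 0.1
        assert kabsch_rmsd(a, mirrored) == pytest.approx(
            brute_force_rmsd(a, mirrored), abs=1e-5
        )

    @pytest.mark.parametrize(
        "a,b",
        [
            (np.zeros((2, 3)), np.zeros((2, 3))),  # too few points
            (
                np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),
                np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),
            ),  # collinear
        ],
    )
    def test_degenerate_inputs_rejected(self, a, b):
        with pytest.raises(ValueError):
            kabsch_rmsd(a, b)


class TestDetectSwap:
    def test_swapped_dimer_reports_constructed_block(self, toys):
        report = detect_swap(toys.swapped, ("A", "B"))
        assert report.swapped_segments["A"] == toys.swap_range
        assert report.swapped_segments["B"] == toys.swap_range

    def test_unswapped_dimer_reports_nothing(self, toys):
        report = detect_swap(toys.unswapped, ("A", "B"))
        assert report.swapped_segments == {"A": None, "B": None}

    def test_rotation_invariance(self, toys):
        moved = toys.swapped.transformed(random_rotation(13), np.array([-4.0, 9.0, 2.0]))
        a = detect_swap(toys.swapped, ("A", "B"))
        b = detect_swap(moved, ("A", "B"))
        assert a.swapped_segments == b.swapped_segments
        assert a.hinge_segments == b.hinge_segments
        for chain in ("A", "B"):
            fa = [f for _i, f in a.profiles[chain]]
            fb = [f for _i, f in b.profiles[chain]]
            assert fa == pytest.approx(fb)

    def test_single_chain_rejected(self, toys):
        with pytest.raises(ValueError, match="distinct"):
            detect_swap(toys.swapped, ("A", "A"))


class TestInterfaceReport:
    def _hydrophobic_pair_model(self):
        # TYR on each side of a tight interface, plus a distant polar residue
        a1 = Residue("A", "TYR", 36, "", [atom("A", 36, "CZ", "C", (0, 0, 0), "TYR")])
        a2 = Residue("A", "SER", 10, "", [atom("A", 10, "OG", "O", (30, 0, 0), "SER")])
        b1 = Residue("B", "PHE", 98, "", [atom("B", 98, "CZ", "C", (0, 0, 4.0), "PHE")])
        return StructureModel({"A": [a1, a2], "B": [b1]})

    def test_distant_chains_give_empty_report(self):
        ra = Residue("A", "GLY", 1, "", [atom("A", 1, "N", "N", (0, 0, 0))])
        rb = Residue("B", "GLY", 1, "", [atom("B", 1, "O", "O", (0, 0, 20.0))])
        model = StructureModel({"A": [ra], "B": [rb]})
        rep = interface_report(model, ["A"], ["B"])
        assert rep.contacts == () and rep.n_hbonds == 0 and rep.hydrophobic_cluster == ()

    def test_hydrophobic_cluster_spans_groups(self):
        rep = interface_report(self._hydrophobic_pair_model(), ["A"], ["B"])
        assert "Tyr36_A" in rep.hydrophobic_cluster
        assert "Phe98_B" in rep.hydrophobic_cluster

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            interface_report(self._hydrophobic_pair_model(), [], ["B"])


class TestFrameworkRmsd:
    def _variable_domain(self, seed=0, jitter=0.0):
        gen = np.random.default_rng(seed)
        residues = []
        for seq in list(range(1, 24)) + list(range(35, 50)) + list(range(51, 89)) + list(
            range(98, 108)
        ):
            xyz = gen.normal(scale=8.0, size=3)
            if jitter:
                xyz = xyz + np.random.default_rng(1000 + seq).normal(scale=jitter, size=3)
            residues.append(
                Residue("A", "ALA", seq, "", [atom("A", seq, "CA", "C", xyz, "ALA")])
            )
        return StructureModel({"A": residues})

    def test_self_comparison_is_zero(self):
        model = self._variable_domain()
        out = framework_rmsd(model, "A", model, "A")
        assert out["rmsd"]["FR1+FR2+FR3"] == pytest.approx(0.0, abs=1e-12)
        assert out["rmsd"]["FR4"] == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_moved_copy_is_zero(self):
        model = self._variable_domain()
        moved = model.transformed(random_rotation(5), np.array([1.0, 2.0, 3.0]))
        out = framework_rmsd(moved, "A", model, "A")
        assert out["rmsd"]["FR1+FR2+FR3"] == pytest.approx(0.0, abs=1e-9)

    def test_jittered_copy_matches_oracle_and_expectation(self):
        ref = self._variable_domain(seed=0)
        jit = self._variable_domain(seed=0, jitter=0.5)
        out = framework_rmsd(jit, "A", ref, "A")
        # oracle on the same coordinates
        pre_ref = [
            a.xyz for a in ref.select("A:1-23") + ref.select("A:35-49") + ref.select("A:51-88")
        ]
        pre_jit = [
            a.xyz for a in jit.select("A:1-23") + jit.select("A:35-49") + jit.select("A:51-88")
        ]
        oracle = brute_force_rmsd(pre_jit, pre_ref)
        assert out["rmsd"]["FR1+FR2+FR3"] == pytest.approx(oracle, abs=1e-6)
        # isotropic 0.5 A jitter per coordinate: RMSD near sqrt(3)*0.5
        assert out["rmsd"]["FR1+FR2+FR3"] == pytest.approx(np.sqrt(3.0) * 0.5, rel=0.10)

    def test_missing_residues_are_listed(self):
        ref = self._variable_domain()
        truncated_residues = [r for r in ref.chains["A"] if r.res_seq != 40]
        trunc = StructureModel({"A": truncated_residues})
        out = framework_rmsd(trunc, "A", ref, "A")
        assert "FR2:40" in out["missing"]["FR1+FR2+FR3"]


class TestAssemblyFreeEnergy:
    def test_tetramer_vs_two_dimers_bookkeeping(self):
        assert assembly_free_energy(-4710.89, [-4441.16]) == pytest.approx(-269.73, abs=1e-9)

    def test_self_difference_is_zero(self):
        assert assembly_free_energy(-5.0, [-5.0]) == 0.0

    def test_components_are_additive(self):
        assert assembly_free_energy(-10.0, [-3.0, -4.0]) == assembly_free_energy(-10.0, [-7.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assembly_free_energy(float("nan"), [-1.0])
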