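"""Structure geometry: PDB I/O, secondary-structure assignment, pore
profiles against the closed-form barrel oracle, axial extent, hydrophobic
bands, aromatic girdles, and chain stoichiometry."""

import numpy as np
import pytest

from conftest import rigid_motion
from mlascan.config import GeometryConfig, THREE_TO_ONE
from mlascan.geometry import (
    aromatic_girdles,
    assign_secondary_structure,
    axial_extent,
    chain_stoichiometry,
    count_strand_segments,
    hydrophobic_bands,
    pore_profile,
    read_pdb,
    write_pdb,
)
from mlascan.synthetic_data import (
    build_ca_cylinder,
    build_ca_helix,
    build_ideal_barrel,
    ideal_barrel_radius,
)
from mlascan.types import StructureModel

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def _ca_chain(seq, chain_id, offset):
    """CA-only chain from a one-letter sequence, laid out along x."""
    n = len(seq)
    return StructureModel(
        chain_ids=np.array([chain_id] * n, dtype=object),
        res_ids=np.arange(1, n + 1),
        res_names=np.array([ONE_TO_THREE[c] for c in seq], dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        coords=np.column_stack([
            np.arange(n) * 3.8, np.full(n, offset * 10.0), np.zeros(n)
        ]),
        elements=np.array(["C"] * n, dtype=object),
    )


def _concat(models):
    return StructureModel(
        chain_ids=np.concatenate([m.chain_ids for m in models]),
        res_ids=np.concatenate([m.res_ids for m in models]),
        res_names=np.concatenate([m.res_names for m in models]),
        atom_names=np.concatenate([m.atom_names for m in models]),
        coords=np.vstack([m.coords for m in models]),
        elements=np.concatenate([m.elements for m in models]),
    )


class TestPdbIO:
    def test_barrel_fixture_atom_count(self, tmp_path, barrel10):
        p = tmp_path / "barrel.pdb"
        write_pdb(barrel10, p)
        model = read_pdb(p)
        assert len(model) == 10 * 12  # n_strands x residues_per_strand

    def test_round_trip_coordinates_to_3_decimals(self, tmp_path, barrel10):
        p = tmp_path / "barrel.pdb"
        write_pdb(barrel10, p)
        back = read_pdb(p)
        assert np.allclose(back.coords, barrel10.coords, atol=1e-3)
        assert list(back.res_ids) == list(barrel10.res_ids)

    def test_hetatm_only_file_is_error(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(ValueError, match="no ATOM"):
            read_pdb(p)


class TestSecondaryStructure:
    def test_ideal_helix_is_mostly_H(self, helix20):
        ss = assign_secondary_structure(helix20, "A")
        assert ss.count("H") >= 16
        assert "E" not in ss

    def test_antiparallel_sheet_strands_are_E(self, sheet8):
        ss = assign_secondary_structure(sheet8, "A")
        s1, s2 = ss[:8], ss[8:]
        assert s1.count("E") >= 4 and s2.count("E") >= 4
        assert "H" not in ss

    @pytest.mark.parametrize("n", [8, 10, 12])
    def test_barrel_strand_count_recovered(self, n):
        model = build_ideal_barrel(n, n)
        assert count_strand_segments(model, "A") == n

    @pytest.mark.parametrize("n", [8, 10, 12])
    def test_jittered_barrel_keeps_most_strands(self, n):
        model = build_ideal_barrel(n, n, jitter=0.3, seed=3)
        assert count_strand_segments(model, "A") >= n - 1

    def test_missing_chain_is_error(self, helix20):
        with pytest.raises(KeyError):
            assign_secondary_structure(helix20, "Z")


class TestPoreProfile:
    def test_ca_cylinder_accessible_radius(self):
        model = build_ca_cylinder(radius=10.0, length=30.0, n_per_ring=16, ring_step=1.5)
        prof = pore_profile(model)
        assert prof.min_radius == pytest.approx(10.0 - 1.9, abs=0.1)
        sampled = prof.radii[~np.isnan(prof.radii)]
        assert np.all(np.abs(sampled - 8.1) < 0.2)

    @pytest.mark.parametrize("n,shear", [(8, 8), (8, 10), (10, 10), (10, 12), (12, 12), (12, 14)])
    def test_ideal_barrel_matches_closed_form(self, n, shear):
        model = build_ideal_barrel(n, shear)
        expected = ideal_barrel_radius(n, shear, 3.3, 4.4) - 1.9
        prof = pore_profile(model)
        assert abs(prof.min_radius - expected) < 0.5

    def test_atoms_on_axis_block_the_pore(self):
        cyl = build_ca_cylinder(radius=10.0, length=30.0)
        k = 5
        plug = StructureModel(
            chain_ids=np.array(["B"] * k, dtype=object),
            res_ids=np.arange(1, k + 1),
            res_names=np.array(["GLY"] * k, dtype=object),
            atom_names=np.array(["CA"] * k, dtype=object),
            coords=np.column_stack([np.zeros(k), np.zeros(k), np.linspace(-5, 5, k)]),
            elements=np.array(["C"] * k, dtype=object),
        )
        prof = pore_profile(_concat([cyl, plug]))
        assert prof.min_radius <= 0

    def test_planar_model_is_error(self):
        xx, yy = np.meshgrid(np.arange(5), np.arange(5))
        n = xx.size
        flat = StructureModel(
            chain_ids=np.array(["A"] * n, dtype=object),
            res_ids=np.arange(1, n + 1),
            res_names=np.array(["GLY"] * n, dtype=object),
            atom_names=np.array(["CA"] * n, dtype=object),
            coords=np.column_stack([xx.ravel() * 3.0, yy.ravel() * 3.0, np.zeros(n)]),
            elements=np.array(["C"] * n, dtype=object),
        )
        with pytest.raises(ValueError, match="planar"):
            pore_profile(flat)

    def test_rigid_motion_invariance(self, barrel10):
        prof = pore_profile(barrel10)
        moved = pore_profile(rigid_motion(barrel10, seed=9))
        assert abs(prof.min_radius - moved.min_radius) < 1e-6


class TestAxialExtent:
    def test_two_atoms_100A_apart(self):
        model = StructureModel(
            chain_ids=np.array(["A", "A"], dtype=object),
            res_ids=np.array([1, 2]),
            res_names=np.array(["GLY", "GLY"], dtype=object),
            atom_names=np.array(["CA", "CA"], dtype=object),
            coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 100.0]]),
            elements=np.array(["C", "C"], dtype=object),
        )
        assert axial_extent(model) == pytest.approx(100.0)

    def test_helix_extent_follows_rise_arithmetic(self):
        model = build_ca_helix(100, rise=1.5)
        assert axial_extent(model) == pytest.approx(148.5, abs=3.0)

    def test_rotation_invariance(self, barrel10):
        a = axial_extent(barrel10)
        b = axial_extent(rigid_motion(barrel10, seed=2))
        assert abs(a - b) < 1e-6


class TestHydrophobicBands:
    def test_uniform_polar_model_has_no_bands(self):
        model = build_ca_cylinder(residue_name="SER")
        assert hydrophobic_bands(model) == []

    def test_hydrophobic_caps_give_exactly_two_bands(self):
        model = build_ca_cylinder(
            radius=10, length=40, residue_name="SER", cap_residue="LEU", cap_length=6
        )
        bands = hydrophobic_bands(model)
        assert len(bands) == 2
        (s1, e1), (s2, e2) = sorted(bands)
        assert e1 < 0 < s2  # one band per end

    def test_threshold_above_maximum_gives_empty(self):
        model = build_ca_cylinder(residue_name="LEU")
        assert hydrophobic_bands(model, threshold=10.0) == []


class TestAromaticGirdles:
    def test_rim_planted_aromatics_found_at_both_rims(self):
        model = build_ideal_barrel(10, 10, rim_residue="TRP")
        span = (int(model.res_ids.min()), int(model.res_ids.max()))
        g = aromatic_girdles(model, span)
        rim_z = max(abs(model.coords[:, 2]))
        lo, hi = sorted(g["positions"])
        assert abs(abs(lo) - rim_z) < 2.0 and abs(abs(hi) - rim_z) < 2.0
        assert not g["low_confidence"]

    def test_uniform_aromatics_flagged_low_confidence(self):
        model = build_ca_cylinder(radius=8, length=40, residue_name="TRP")
        g = aromatic_girdles(model, (int(model.res_ids.min()), int(model.res_ids.max())))
        assert g["low_confidence"]

    def test_no_aromatics_gives_empty_result(self, barrel10):
        g = aromatic_girdles(barrel10, (1, int(barrel10.res_ids.max())))
        assert g["positions"] == ()


class TestChainStoichiometry:
    REFS = {
        "MlaE": "MLREWLVALPLAGLGLSLATGNWQVALIAGLGFALASLIFSR" * 2,
        "MlaF": "MNDSKLVRLENVSKRFGDKTVLDGVSLQVNKGEILGLLGPNGAGKS" * 2,
        "MlaD": "MKRNTLEVGVGLFLVLALAVFVFIRLGGGNLFAPEKTYTAYFD" * 2,
    }

    def _complex(self):
        chains = []
        layout = [("MlaE", 2), ("MlaF", 2), ("MlaD", 6)]
        cid = 0
        for comp, count in layout:
            for _ in range(count):
                chains.append(_ca_chain(self.REFS[comp], chr(ord("A") + cid), cid))
                cid += 1
        return _concat(chains)

    def test_2_2_6_stoichiometry_recovered(self):
        counts, unassigned = chain_stoichiometry(self._complex(), self.REFS)
        assert counts == {"MlaE": 2, "MlaF": 2, "MlaD": 6}
        assert unassigned == []

    def test_single_chain_model(self):
        model = _ca_chain(self.REFS["MlaD"], "A", 0)
        counts, _ = chain_stoichiometry(model, self.REFS)
        assert counts == {"MlaE": 0, "MlaF": 0, "MlaD": 1}

    def test_shuffled_chain_order_gives_identical_counts(self):
        model = self._complex()
        order = np.argsort([-ord(c) for c in model.chain_ids], kind="stable")
        shuffled = StructureModel(
            chain_ids=model.chain_ids[order],
            res_ids=model.res_ids[order],
            res_names=model.res_names[order],
            atom_names=model.atom_names[order],
            coords=model.coords[order],
            elements=model.elements[order],
        )
        counts, _ = chain_stoichiometry(shuffled, self.REFS)
        assert counts == {"MlaE": 2, "MlaF": 2, "MlaD": 6}

    def test_unrelated_chain_reported_unassigned(self):
        model = _concat([
            _ca_chain(self.REFS["MlaD"], "A", 0),
            _ca_chain("G" * 80, "B", 1),
        ])
        counts, unassigned = chain_stoichiometry(model, self.REFS)
        assert unassigned == ["B"] and counts["MlaD"] == 1

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            chain_stoichiometry(_ca_chain("ACDE", "A", 0), {})
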