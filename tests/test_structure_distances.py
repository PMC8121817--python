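"""Tetramer loading, residue mapping, Cβ distances, and constraint export."""

import numpy as np
import pytest

from tmfret.structure_distances import (
    ConstraintScheme,
    ConstraintSpec,
    NotATetramerError,
    ResidueSelector,
    StructureQualityError,
    UnmappedPositionError,
    adjacency_dominance_report,
    adjacent_distance,
    build_residue_mapping,
    cbeta_distance_table,
    load_tetramer,
    map_residue,
    write_constraints,
)
from tmfret.synthetic_data import c4_site_positions, simulate_c4_tetramer


class TestLoadTetramer:
    def test_ring_order_matches_construction(self, square_ring_pdb):
        tet = load_tetramer(square_ring_pdb)
        # chains constructed at 0, 90, 180, 270 degrees; angular ordering
        # must visit them as a cyclic rotation of A-B-C-D (possibly reversed)
        ring = tet.ring_order
        assert set(ring) == {"A", "B", "C", "D"}
        idx = {c: i for i, c in enumerate(ring)}
        diffs = {(idx["B"] - idx["A"]) % 4, (idx["C"] - idx["B"]) % 4,
                 (idx["D"] - idx["C"]) % 4}
        assert diffs in ({1}, {3})

    def test_monomer_rejected(self, tmp_path):
        text = simulate_c4_tetramer({6: (10.0, 0.0, 0.0)}, chains="A")
        path = tmp_path / "monomer.pdb"
        path.write_text(text)
        with pytest.raises(NotATetramerError):
            load_tetramer(path)

    def test_missing_file(self):
        with pytest.raises((OSError, RuntimeError, ValueError)):
            load_tetramer("/nonexistent/structure.pdb")


class TestResidueMapping:
    def test_identity_alignment(self):
        mapping = build_residue_mapping("MKTAYIAKQR", "MKTAYIAKQR")
        assert map_residue(5, mapping) == 5

    def test_offset_alignment(self):
        # target has 3 extra leading residues: every position shifts by +3
        mapping = build_residue_mapping("MKTAYIAKQR", "GGSMKTAYIAKQR")
        assert map_residue(1, mapping) == 4
        assert map_residue(7, mapping) == 10

    def test_gap_raises_unmapped(self):
        # target lacks the middle segment of the source
        mapping = build_residue_mapping(
            "MKTAYIAKQRQISFVKSHFSRQLEERLGLIE", "MKTAYIAKQRLGLIE"
        )
        with pytest.raises(UnmappedPositionError):
            # a position inside the deleted segment has no image
            map_residue(18, mapping)
        assert map_residue(2, mapping) == 2


class TestCbetaDistances:
    def test_same_residue_same_chain_is_zero(self, square_ring_pdb):
        tet = load_tetramer(square_ring_pdb)
        table = cbeta_distance_table(tet, 6, 6)
        same = table[table["relation"] == "same"]["distance_A"].iloc[0]
        assert same == pytest.approx(0.0, abs=1e-9)

    def test_square_ring_geometry(self, square_ring_pdb):
        # probe CBs at (±10, ±10, 0): adjacent = 20, diagonal = 20·√2
        tet = load_tetramer(square_ring_pdb)
        table = cbeta_distance_table(tet, 6, 6)
        adj = table[table["relation"].str.startswith("adjacent")]["distance_A"]
        diag = table[table["relation"] == "diagonal"]["distance_A"].iloc[0]
        assert adj.iloc[0] == pytest.approx(20.0, abs=1e-6)
        assert adj.iloc[1] == pytest.approx(20.0, abs=1e-6)
        assert diag == pytest.approx(20.0 * np.sqrt(2.0), abs=1e-6)
        assert adjacent_distance(table) == pytest.approx(20.0, abs=1e-6)

    def test_distance_symmetry(self, standin_structure_pdb):
        tet = load_tetramer(standin_structure_pdb)
        forward = cbeta_distance_table(tet, 10, 20)
        backward = cbeta_distance_table(tet, 20, 10)
        # d(A→B) multiset equals d(B→A) multiset
        assert sorted(forward["distance_A"]) == pytest.approx(
            sorted(backward["distance_A"]), abs=1e-9
        )

    def test_relation_classification_invariant_to_rotation(
        self, square_ring_pdb, tmp_path
    ):
        # rigid-body rotation of the whole structure must not change the
        # per-relation distance multiset
        import gemmi

        st = gemmi.read_structure(str(square_ring_pdb))
        angle = np.deg2rad(37.0)
        # rotation about an arbitrary tilted axis
        rot = gemmi.Mat33(
            [
                [np.cos(angle), -np.sin(angle), 0.0],
                [np.sin(angle), np.cos(angle) * np.cos(0.5), -np.sin(0.5)],
                [0.0, np.sin(0.5), np.cos(0.5) * 1.0],
            ]
        )
        # orthonormalize via QR to get a proper rotation
        q, _ = np.linalg.qr(np.array(rot.tolist()))
        tr = gemmi.Transform()
        tr.mat.fromlist(q.tolist())
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        atom.pos = gemmi.Position(*tr.apply(atom.pos).tolist())
        rotated = tmp_path / "rotated.pdb"
        st.write_pdb(str(rotated))

        t0 = cbeta_distance_table(load_tetramer(square_ring_pdb), 6, 6)
        t1 = cbeta_distance_table(load_tetramer(rotated), 6, 6)
        for rel_class in ("same", "diagonal"):
            a = t0[t0["relation"] == rel_class]["distance_A"].iloc[0]
            b = t1[t1["relation"] == rel_class]["distance_A"].iloc[0]
            assert a == pytest.approx(b, abs=1e-3)
        assert adjacent_distance(t0) == pytest.approx(
            adjacent_distance(t1), abs=1e-3
        )

    def test_missing_residue_is_structure_quality_error(self, square_ring_pdb):
        tet = load_tetramer(square_ring_pdb)
        with pytest.raises(StructureQualityError):
            cbeta_distance_table(tet, 6, 999)


class TestAdjacencyDominance:
    def _table(self, distances):
        import pandas as pd

        return pd.DataFrame(
            {
                "donor_chain": ["A"] * 4,
                "donor_res": [10] * 4,
                "acceptor_chain": list("ABCD"),
                "acceptor_res": [20] * 4,
                "relation": ["same", "adjacent_1", "diagonal", "adjacent_2"],
                "distance_A": distances,
                "provenance": [""] * 4,
            }
        )

    def test_equidistant_acceptors_share_equally(self):
        report = adjacency_dominance_report(self._table([20.0] * 4), 13.0)
        shares = dict(zip(report["relation"], report["rate_share"]))
        assert shares["same"] == pytest.approx(0.25)
        assert shares["adjacent"] == pytest.approx(0.5)  # two chains pooled
        assert shares["diagonal"] == pytest.approx(0.25)

    def test_single_close_acceptor_dominates_completely(self):
        report = adjacency_dominance_report(
            self._table([1e6, 15.0, 1e6, 1e6]), 13.0
        )
        shares = dict(zip(report["relation"], report["rate_share"]))
        assert shares["adjacent"] == pytest.approx(1.0, abs=1e-9)
        dom = report.loc[report["dominant"], "relation"].iloc[0]
        assert dom == "adjacent"

    def test_printed_reference_distances_rate_share(self):
        # per-relation distances of the A'-helix acceptor site, one printed
        # value per relation class (both adjacent chains at the printed
        # adjacent distance): arithmetic on (r0/r)^6 gives 88.4%
        report = adjacency_dominance_report(
            self._table([41.0, 22.1, 28.1, 22.1]), 13.0
        )
        shares = dict(zip(report["relation"], report["rate_share"]))
        assert shares["adjacent"] == pytest.approx(0.8844930122357859, abs=1e-9)
        assert shares["adjacent"] > 0.8

    def test_incomplete_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            adjacency_dominance_report(
                pd.DataFrame({"relation": ["same"], "distance_A": [20.0]}), 13.0
            )


class TestConstraintExport:
    def _spec(self, distance=20.0, sd=1.0):
        return ConstraintSpec(
            donor=ResidueSelector("A", 355),
            acceptor=ResidueSelector("B", 481),
            target_distance=distance,
            sd=sd,
        )

    def test_single_harmonic_line(self, tmp_path):
        path = tmp_path / "one.cst"
        write_constraints([self._spec(20.0, 1.0)], path)
        lines = path.read_text().splitlines()
        records = [l for l in lines if not l.startswith("#")]
        assert records == ["AtomPair CB 355A CB 481B HARMONIC 20.00 1.00"]

    def test_header_records_scheme(self, tmp_path):
        path = tmp_path / "scheme.cst"
        write_constraints([self._spec()], path, ConstraintScheme())
        header = [l for l in path.read_text().splitlines() if l.startswith("#")]
        assert any("atom_pair_cutoff 6 A" in l for l in header)
        assert any("experimental_weight 40" in l for l in header)
        assert any("coordinate_weight 1" in l for l in header)
        assert any("atom_pair_weight 2" in l for l in header)

    def test_byte_stable_output(self, tmp_path):
        p1, p2 = tmp_path / "a.cst", tmp_path / "b.cst"
        write_constraints([self._spec()], p1)
        write_constraints([self._spec()], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_four_state_export(self, tmp_path):
        for state, d in [
            ("resting-cAMP", 24.0),
            ("resting-apo", 20.0),
            ("activated", 21.0),
            ("inactivated", 18.0),
        ]:
            path = tmp_path / f"constraints_{state}.cst"
            write_constraints([self._spec(d, 0.5)], path)
        assert len(list(tmp_path.glob("constraints_*.cst"))) == 4

    def test_invalid_specs_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            ConstraintSpec(
                ResidueSelector("A", 1), ResidueSelector("B", 2),
                target_distance=20.0, sd=0.0,
            )
        with pytest.raises(ValueError):
            write_constraints([], tmp_path / "empty.cst")


def test_c4_site_positions_exact_symmetry():
    # analytic construction: adjacent distances equal, diagonal = adjacent·√2
    pos = c4_site_positions(radius=14.0, z=3.0, phase=0.7)
    d_adj1 = np.linalg.norm(pos[0] - pos[1])
    d_adj2 = np.linalg.norm(pos[0] - pos[3])
    d_diag = np.linalg.norm(pos[0] - pos[2])
    assert d_adj1 == pytest.approx(d_adj2, abs=1e-6)
    assert d_diag == pytest.approx(d_adj1 * np.sqrt(2.0), abs=1e-6)
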