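"""Structure parsing, contact maps, column-residue mapping, coupling
projection and validation statistics."""

import numpy as np
import pytest

from coevoring import (
    Msa,
    contact_map,
    interface_candidates,
    map_columns_to_residues,
    project_couplings,
    read_structure,
    validation_stats,
)
from coevoring.coevolution import Coupling
from coevoring.errors import MappingError, ParameterError, StructureError
from coevoring.structure import StructureModel, write_structure_pdb
from conftest import make_chain


def _coupling(i, j, z=4.0, norm=0.9):
    return Coupling(i=i, j=j, score_raw=1.0, score_apc=1.0, z=z, score_norm=norm)


class TestReadStructure:
    def test_roundtrip_via_pdb_writer(self, two_chain_structure, tmp_path):
        p = tmp_path / "m.pdb"
        write_structure_pdb(two_chain_structure, p)
        back = read_structure(p)
        assert back.chain_ids == ["A", "B"]
        assert np.allclose(back.chain("A").coords(), two_chain_structure.chain("A").coords(), atol=1e-3)
        assert back.chain("A").sequence == "ACDEFG"

    def test_altloc_highest_occupancy(self, altloc_pdb):
        model = read_structure(altloc_pdb)
        res1 = model.chain("A").residues[0]
        assert np.allclose(res1.coord, [11.639, 6.071, -5.147], atol=1e-3)

    def test_altloc_first(self, altloc_pdb):
        model = read_structure(altloc_pdb, altloc_policy="first")
        assert np.allclose(model.chain("A").residues[0].coord, [11.639, 6.071, -5.147], atol=1e-3)

    def test_hetatm_dropped_and_chain_filter(self, altloc_pdb):
        model = read_structure(altloc_pdb)
        assert len(model.chain("A").residues) == 2  # water dropped
        only_a = read_structure(altloc_pdb, chain_filter=["A"])
        assert only_a.chain_ids == ["A"]

    def test_no_ca_errors(self, tmp_path):
        p = tmp_path / "noca.pdb"
        p.write_text("ATOM      1  N   ALA A   1       0.0     0.0     0.0  1.00  0.00           N\nEND\n")
        with pytest.raises(StructureError):
            read_structure(p)


class TestContactMap:
    def test_strict_cutoff_boundary(self):
        a = make_chain("A", [[0.0, 0.0, 0.0]])
        b = make_chain("B", [[10.0, 0.0, 0.0]])
        cm = contact_map(StructureModel(chains=[a, b]), cutoff=10.0)
        assert cm.entries == []  # exactly 10.0 is not a contact

    def test_inter_contact_below_cutoff(self):
        a = make_chain("A", [[0.0, 0.0, 0.0]])
        b = make_chain("B", [[9.9, 0.0, 0.0]])
        cm = contact_map(StructureModel(chains=[a, b]), cutoff=10.0)
        assert len(cm.entries) == 1
        assert cm.entries[0].contact_class == "inter"
        assert cm.entries[0].distance == pytest.approx(9.9)

    def test_intra_separation_filter(self):
        # residues 3 and 6 are 5 A apart but |6-3| < 5 -> excluded
        coords = [[0, 0, 0], [100, 0, 0], [200, 0, 0], [5, 0, 0]]
        chain = make_chain("A", coords, start=3)
        cm = contact_map(StructureModel(chains=[chain]), cutoff=10.0, min_separation=5)
        assert cm.entries == []
        cm2 = contact_map(StructureModel(chains=[chain]), cutoff=10.0, min_separation=3)
        assert len(cm2.entries) == 1

    def test_rigid_motion_invariance(self, two_chain_structure):
        from scipy.spatial.transform import Rotation

        cm = contact_map(two_chain_structure)
        R = Rotation.from_rotvec([0.3, -0.2, 1.1]).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        moved = StructureModel(
            chains=[
                make_chain(c.id, c.coords() @ R.T + shift, seq=c.sequence)
                for c in two_chain_structure.chains
            ]
        )
        cm2 = contact_map(moved)
        assert cm.pairs() == cm2.pairs()
        d1 = sorted(e.distance for e in cm.entries)
        d2 = sorted(e.distance for e in cm2.entries)
        assert np.allclose(d1, d2, atol=1e-9)


class TestColumnResidueMap:
    def _msa(self, ref_row):
        return Msa(ids=["ref"], rows=[ref_row], reference_id="ref")

    def test_identical_sequences_identity_map(self, two_chain_structure):
        m = self._msa("ACDEFG")
        cmap = map_columns_to_residues(m, two_chain_structure, "A")
        assert cmap.coverage == pytest.approx(1.0)
        assert cmap.ref_to_resnum() == {k: k for k in range(1, 7)}

    def test_truncated_structure_offsets_map(self):
        # structure misses the 2 N-terminal residues of the reference
        chain = make_chain("A", np.arange(12).reshape(4, 3), start=1, seq="DEFG")
        m = self._msa("ACDEFG")
        cmap = map_columns_to_residues(m, StructureModel(chains=[chain]), "A")
        assert cmap.coverage == pytest.approx(4 / 6)
        assert cmap.ref_to_resnum() == {3: 1, 4: 2, 5: 3, 6: 4}

    def test_unrelated_sequence_errors(self, two_chain_structure):
        m = self._msa("WWWWWW")
        with pytest.raises(MappingError):
            map_columns_to_residues(m, two_chain_structure, "A")


class TestProjection:
    def _setup(self):
        # chain A: residues 1-4 along x at 20 A spacing, residue 4 bent close
        a = make_chain("A", [[0, 0, 0], [20, 0, 0], [40, 0, 0], [4, 0, 0]], seq="ACDE")
        b = make_chain("B", [[0, 8, 0], [20, 8, 0], [40, 8, 0], [4, 8, 0]], seq="ACDE")
        s = StructureModel(chains=[a, b])
        m = Msa(ids=["ref"], rows=["ACDE"], reference_id="ref")
        cmap = map_columns_to_residues(m, s, "A")
        return s, cmap

    def test_fold_contact(self):
        s, cmap = self._setup()
        out = project_couplings([_coupling(1, 4)], cmap, s, ["B"])
        assert out[0].contact_class == "fold"
        assert out[0].d_intra == pytest.approx(4.0)

    def test_interface_contact(self):
        s, cmap = self._setup()
        out = project_couplings([_coupling(1, 2)], cmap, s, ["B"])
        assert out[0].d_intra == pytest.approx(20.0)
        assert out[0].d_inter_min == pytest.approx(np.sqrt(20**2 + 64))
        # shift the whole B copy so A1 approaches B2 across the interface
        a = s.chains[0]
        b2 = make_chain("B", a.coords() + np.array([-20.0, 8.0, 0.0]), seq="ACDE")
        s2 = StructureModel(chains=[a, b2])
        out2 = project_couplings([_coupling(1, 2)], cmap, s2, ["B"])
        assert out2[0].contact_class == "interface"
        assert out2[0].d_inter_min == pytest.approx(8.0)

    def test_no_contact(self):
        s, cmap = self._setup()
        out = project_couplings([_coupling(1, 3)], cmap, s, ["B"])
        assert out[0].contact_class == "none"

    def test_unmapped_flagged(self):
        s, cmap = self._setup()
        out = project_couplings([_coupling(1, 9)], cmap, s, ["B"])
        assert out[0].contact_class == "unmapped"
        assert not out[0].mapped

    def test_empty_partner_list_rejected(self):
        s, cmap = self._setup()
        with pytest.raises(ParameterError):
            project_couplings([_coupling(1, 2)], cmap, s, [])


class TestValidationStats:
    def _mapped(self, dists_classes):
        from coevoring.structure import MappedCoupling

        out = []
        for k, (d, klass) in enumerate(dists_classes):
            out.append(
                MappedCoupling(
                    coupling=_coupling(k + 1, k + 10),
                    res_i=k + 1,
                    res_j=k + 10,
                    d_intra=d,
                    d_inter_min=None,
                    contact_class=klass,
                )
            )
        return out

    def test_hand_sem(self):
        rep = validation_stats(self._mapped([(4.0, "fold"), (6.0, "fold")]), "intra")
        assert rep.mean_d == pytest.approx(5.0)
        assert rep.sem_d == pytest.approx(1.0)

    def test_all_contacts_full_precision(self):
        rep = validation_stats(self._mapped([(4.0, "fold"), (6.0, "interface")]), "intra")
        assert rep.precision == pytest.approx(1.0)
        assert rep.n_fold + rep.n_interface + rep.n_none == rep.n_couplings

    def test_single_coupling_sem_zero(self):
        rep = validation_stats(self._mapped([(4.0, "fold")]), "intra")
        assert rep.sem_d == 0.0
        assert rep.n_distances == 1

    def test_empty_errors(self):
        with pytest.raises(ParameterError):
            validation_stats([], "intra")


class TestInterfaceCandidates:
    def _mapped_on(self, s, i, j, d_intra, norm=0.25):
        from coevoring.structure import MappedCoupling

        return MappedCoupling(
            coupling=_coupling(i, j, norm=norm),
            res_i=i,
            res_j=j,
            d_intra=d_intra,
            d_inter_min=None,
            contact_class="none" if (d_intra or 99) >= 10 else "fold",
        )

    def test_exposed_high_score_kept(self):
        chain = make_chain("A", [[0, 0, 0], [20, 0, 0], [40, 0, 0]])
        s = StructureModel(chains=[chain])
        cands = interface_candidates([self._mapped_on(s, 1, 3, 20.0)], s, "A")
        assert len(cands) == 1

    def test_fold_contact_rejected(self):
        chain = make_chain("A", [[0, 0, 0], [20, 0, 0], [40, 0, 0]])
        s = StructureModel(chains=[chain])
        assert interface_candidates([self._mapped_on(s, 1, 3, 6.0)], s, "A") == []

    def test_low_score_rejected(self):
        chain = make_chain("A", [[0, 0, 0], [20, 0, 0], [40, 0, 0]])
        s = StructureModel(chains=[chain])
        assert interface_candidates([self._mapped_on(s, 1, 3, 20.0, norm=0.1)], s, "A") == []

    def test_buried_residue_rejected(self):
        # residue 1 sits inside a dense cluster -> high coordination number
        cluster = np.concatenate([np.zeros((1, 3)), np.random.default_rng(0).normal(scale=2, size=(6, 3))])
        far = np.array([[50.0, 0, 0]])
        chain = make_chain("A", np.vstack([cluster, far]))
        s = StructureModel(chains=[chain])
        cands = interface_candidates(
            [self._mapped_on(s, 1, 8, 50.0)], s, "A", exposure_max_neighbors=2
        )
        assert cands == []
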