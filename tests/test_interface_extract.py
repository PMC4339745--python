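import numpy as np
import pytest

import pcalign as pc
from pcalign.errors import LookupTableError, NoInterfaceError
from pcalign.interface_extract import CutoffTable
from pcalign.structure_io import Atom, Residue, Structure


def residue(chain, seq, aa, atom_coords, names=None):
    names = names or [f"C{i}" for i in range(len(atom_coords))]
    return Residue(chain, seq, "", aa,
                   [Atom(n, "C", np.asarray(c, float)) for n, c in zip(names, atom_coords)])


class TestHeavyAtomContact:
    @pytest.mark.parametrize("dist,expected", [(4.4, True), (4.5, True), (4.6, False)])
    def test_boundary_inclusive(self, dist, expected):
        r1 = residue("A", 1, "A", [[0, 0, 0], [10, 0, 0]])
        r2 = residue("B", 1, "A", [[dist, 0, 0], [20, 0, 0]])
        assert pc.heavy_atom_contact(r1, r2) is expected

    def test_minimum_over_all_atom_pairs(self):
        # only the closest pair matters
        r1 = residue("A", 1, "A", [[0, 0, 0], [0, 0, 9]])
        r2 = residue("B", 1, "A", [[0, 0, 12], [0, 0, 13]])
        assert pc.heavy_atom_contact(r1, r2)  # 9 -> 12 is 3 A


class TestCaCutoff:
    def test_linear_formula(self):
        t = CutoffTable(np.full((20, 20), 6.2), np.full((20, 20), 0.8), xi=0.5)
        assert pc.ca_cutoff("S", "K", t) == pytest.approx(6.6)

    def test_zero_xi_gives_mean(self):
        t = CutoffTable(np.full((20, 20), 6.2), np.full((20, 20), 0.8), xi=0.0)
        assert pc.ca_cutoff("S", "K", t) == pytest.approx(6.2)

    def test_symmetry_and_unknown_code(self):
        t = CutoffTable.uniform()
        assert pc.ca_cutoff("S", "K", t) == pc.ca_cutoff("K", "S", t)
        with pytest.raises(LookupTableError):
            pc.ca_cutoff("X", "K", t)

    def test_text_round_trip(self, tmp_path):
        t = CutoffTable(np.full((20, 20), 7.3), np.full((20, 20), 1.1), xi=0.25)
        path = tmp_path / "cutoffs.txt"
        t.to_text(path)
        t2 = CutoffTable.from_text(path)
        np.testing.assert_allclose(t2.mean, t.mean)
        np.testing.assert_allclose(t2.sd, t.sd)
        assert t2.xi == 0.25


class TestComputeCutoffTable:
    def _structure_with_sk_contacts(self, distances):
        """One chain-A Ser against chain-B Lys residues at given Cα distances."""
        chains = {"A": [], "B": []}
        for k, d in enumerate(distances):
            y = 100.0 * k  # separate the pairs so only intended contacts form
            chains["A"].append(residue("A", k + 1, "S", [[0, y, 0], [0, y, 1.0]],
                                       names=["CA", "OG"]))
            chains["B"].append(residue("B", k + 1, "K", [[d, y, 0], [2.0, y, 1.0]],
                                       names=["CA", "NZ"]))
        return Structure("synthetic", chains, mode="atomic")

    def test_hand_computed_statistics(self):
        s = self._structure_with_sk_contacts([6.0, 7.0, 8.0])
        table = pc.compute_cutoff_table([s], xi=0.5)
        i, j = "ACDEFGHIKLMNPQRSTVWY".index("S"), "ACDEFGHIKLMNPQRSTVWY".index("K")
        assert table.mean[i, j] == pytest.approx(7.0)
        assert table.sd[i, j] == pytest.approx(1.0)  # sample sd, ddof=1
        assert pc.ca_cutoff("S", "K", table) == pytest.approx(7.5)

    def test_unobserved_pairs_take_global_fill(self):
        s = self._structure_with_sk_contacts([6.0, 7.0, 8.0])
        table = pc.compute_cutoff_table([s])
        i, j = "ACDEFGHIKLMNPQRSTVWY".index("F"), "ACDEFGHIKLMNPQRSTVWY".index("W")
        assert table.mean[i, j] == pytest.approx(7.0)  # global mean of all obs
        assert table.sd[i, j] == pytest.approx(1.0)

    def test_symmetric_for_all_pairs(self):
        s = self._structure_with_sk_contacts([6.0, 7.0, 8.0])
        table = pc.compute_cutoff_table([s])
        np.testing.assert_array_equal(table.mean, table.mean.T)
        np.testing.assert_array_equal(table.sd, table.sd.T)


class TestExtractInterface:
    def _two_chain_structure(self, sep):
        """Two 3-residue chains; only the middle residues can touch (distance sep)."""
        chains = {"A": [], "B": []}
        for k in range(3):
            x = 20.0 * k
            chains["A"].append(residue("A", k + 1, "A", [[x, 0, 0], [x, 0, 1.0]],
                                       names=["CA", "CB"]))
            z = sep + 1.0 if k == 1 else 50.0
            chains["B"].append(residue("B", k + 1, "G", [[x, 0, z]], names=["CA"]))
        return Structure("two", chains, mode="atomic")

    def test_single_contact_pair(self):
        s = self._two_chain_structure(4.0)  # CB at z=1 vs CA at z=5 -> 4.0 A
        iface = pc.extract_interface(s, {"A"}, {"B"}, mode="atomic")
        assert iface.n_a == 1 and iface.n_b == 1
        assert iface.contacts.sum() == 2  # one symmetric contact
        assert iface.residues[0].source[:2] == ("A", 2)

    def test_no_contacts_raises(self):
        s = self._two_chain_structure(10.0)
        with pytest.raises(NoInterfaceError):
            pc.extract_interface(s, {"A"}, {"B"}, mode="atomic")

    def test_ca_only_mode_uses_table_cutoff(self):
        s = self._two_chain_structure(4.0)
        # CA-CA distance of middle pair is 5.0; uniform cutoff 8.0 accepts it
        iface = pc.extract_interface(s, {"A"}, {"B"}, mode="ca_only",
                                     table=CutoffTable.uniform(8.0))
        assert (iface.n_a, iface.n_b) == (1, 1)
        with pytest.raises(NoInterfaceError):
            pc.extract_interface(s, {"A"}, {"B"}, mode="ca_only",
                                 table=CutoffTable.uniform(4.0))

    def test_rigid_invariance_of_extraction(self):
        s = pc.make_synthetic_complex(8, seed=5)
        iface = pc.extract_interface(s, {"A"}, {"B"})
        t = pc.RigidTransform(
            np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float), np.array([3.0, -2.0, 7.0]))
        moved = Structure("moved", {
            cid: [Residue(r.chain_id, r.seq_id, r.icode, r.aa,
                          [Atom(a.name, a.element, t.apply(a.coord)) for a in r.atoms])
                  for r in res] for cid, res in s.chains.items()}, mode=s.mode)
        iface2 = pc.extract_interface(moved, {"A"}, {"B"})
        assert [r.source for r in iface.residues] == [r.source for r in iface2.residues]
        np.testing.assert_array_equal(iface.contacts, iface2.contacts)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_all_pairs(self, seed):
        """Atomic extraction equals a brute-force double loop over heavy atoms."""
        s = pc.make_synthetic_complex(10, seed=seed)
        iface = pc.extract_interface(s, {"A"}, {"B"}, mode="atomic")
        got = {(r1.source[1], r2.source[1])
               for r1 in iface.residues if r1.fragment == "A"
               for r2 in iface.residues if r2.fragment == "B"
               if iface.contacts[iface.residues.index(r1), iface.residues.index(r2)]}
        expected = set()
        for r1 in s.chains["A"]:
            for r2 in s.chains["B"]:
                dmin = min(np.linalg.norm(a1.coord - a2.coord)
                           for a1 in r1.atoms for a2 in r2.atoms)
                if dmin <= 4.5:
                    expected.add((r1.seq_id, r2.seq_id))
        assert got == expected

    def test_no_orphan_interfacial_residues(self, medium_interface):
        assert medium_interface.contacts.any(axis=1).all()


class TestContactMapFor:
    def test_identity_restriction(self, small_interface):
        sub = list(range(len(small_interface)))
        np.testing.assert_array_equal(
            pc.contact_map_for(small_interface, sub), small_interface.contacts)

    def test_two_residue_contacting_subset(self, small_interface):
        i, j = np.argwhere(small_interface.contacts)[0]
        m = pc.contact_map_for(small_interface, [int(i), int(j)])
        np.testing.assert_array_equal(m, [[False, True], [True, False]])

    def test_empty_subset_and_bad_index(self, small_interface):
        assert pc.contact_map_for(small_interface, []).shape == (0, 0)
        with pytest.raises(IndexError):
            pc.contact_map_for(small_interface, [0, len(small_interface)])
        with pytest.raises(IndexError):
            pc.contact_map_for(small_interface, [0, 0])
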