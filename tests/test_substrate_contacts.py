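import numpy as np
import pytest

from kinactive.motif_map import KinaseMotifMap, actloop_index
from kinactive.structure_model import Atom, Residue, StructureModel
from kinactive.substrate_contacts import (
    LOOP_LABELS,
    SUBSTRATE_POSITIONS,
    ContactMap,
    average_contacts,
    contact_map,
    find_phosphoacceptors,
    flag_domain_swap,
)
from kinactive.fixtures import make_crystal_model


def kinase_map(chain_id="A"):
    return KinaseMotifMap(
        kinase_id="CAMK_TOY1",
        chain_id=chain_id,
        res_saltbridge_lys=30,
        res_saltbridge_glu=50,
        res_glu4=54,
        res_hrd_his=96,
        res_hrd_arg=97,
        res_hrd_asp=98,
        res_dfg_asp=120,
        res_ape_glu=140,
    )


def residue(chain, seq, name, atoms):
    return Residue(chain, seq, "", name, [Atom(n, n[0], np.array(p, float)) for n, p in atoms])


def kinase_chain(chain_id="A"):
    """Minimal enzyme chain: an HRD-Asp with carboxylate oxygens at the origin."""
    return [
        residue(chain_id, 98, "ASP",
                [("CA", (3, 0, 0)), ("CB", (2, 0.5, 0)), ("CG", (1, 0, 0)),
                 ("OD1", (0, 0, 0)), ("OD2", (-0.5, -1.2, 0))]),
    ]


def substrate_chain(chain_id="B", og_pos=(3.0, 0, 0)):
    return [
        residue(chain_id, 10, "SER",
                [("N", (5, 2, 0)), ("CA", (4.5, 1, 0)), ("C", (5.5, 0, 0)),
                 ("O", (6.5, 0.4, 0)), ("CB", (4, 0.5, 1)), ("OG", og_pos)]),
    ]


class TestFindPhosphoacceptors:
    def test_hydroxyl_within_cutoff_is_a_hit(self):
        model = StructureModel("t", {"A": kinase_chain(), "B": substrate_chain()})
        hits = find_phosphoacceptors(model, kinase_map(), use_symmetry=False)
        assert len(hits) == 1
        h = hits[0]
        assert (h.substrate_chain, h.substrate_type) == ("B", "SER")
        assert h.d_oh_asp == pytest.approx(3.0)
        assert not h.is_symmetry_mate

    def test_beyond_cutoff_no_hit(self):
        model = StructureModel(
            "t", {"A": kinase_chain(), "B": substrate_chain(og_pos=(5.0, 0, 0))}
        )
        assert find_phosphoacceptors(model, kinase_map(), use_symmetry=False) == []

    def test_same_chain_hydroxyls_excluded(self):
        chain = kinase_chain() + substrate_chain(chain_id="A")
        model = StructureModel("t", {"A": chain})
        assert find_phosphoacceptors(model, kinase_map(), use_symmetry=False) == []

    def test_phospho_residue_treated_as_parent(self):
        sub = [residue("B", 10, "TPO", [("OG1", (3.2, 0, 0)), ("P", (4.5, 1, 1))])]
        model = StructureModel("t", {"A": kinase_chain(), "B": sub})
        hits = find_phosphoacceptors(model, kinase_map(), use_symmetry=False)
        assert len(hits) == 1 and hits[0].substrate_type == "THR"

    def test_symmetry_translate_produces_mate_hit(self):
        """A lattice translation of the same chain lands a Tyr hydroxyl in range."""
        a = 20.0
        chain = kinase_chain() + [
            residue("A", 150, "TYR", [("OH", (3.2 - a, 0.0, 0.0)), ("CZ", (4.5 - a, 1, 0))])
        ]
        model = make_crystal_model(
            StructureModel("t", {"A": chain}), cell=(a, a, a, 90, 90, 90), spacegroup="P 1"
        )
        hits = find_phosphoacceptors(model, kinase_map(), use_symmetry=True)
        mates = [h for h in hits if h.is_symmetry_mate]
        assert len(mates) == 1
        assert mates[0].d_oh_asp == pytest.approx(3.2, abs=1e-6)
        assert mates[0].lattice_offset == (1, 0, 0)

    def test_asymmetric_unit_hits_are_subset_of_symmetry_hits(self):
        model = make_crystal_model(
            StructureModel("t", {"A": kinase_chain(), "B": substrate_chain()}),
            cell=(50, 50, 50, 90, 90, 90),
        )
        no_sym = find_phosphoacceptors(model, kinase_map(), use_symmetry=False)
        with_sym = find_phosphoacceptors(model, kinase_map(), use_symmetry=True)
        keys = lambda hits: {
            (h.substrate_chain, h.substrate_seqnum, h.is_symmetry_mate) for h in hits
        }
        assert keys(no_sym) <= keys(with_sym)

    def test_no_mapped_asp_is_an_input_error(self):
        model = StructureModel("t", {"B": substrate_chain()})
        with pytest.raises(ValueError):
            find_phosphoacceptors(model, kinase_map(), use_symmetry=False)


class TestDomainSwap:
    def _model_with_ape8(self, og=(0.5, 0, 0)):
        m = kinase_map()
        ape8_seq = actloop_index(m, "APE8")
        chain = kinase_chain() + [
            residue("A", ape8_seq, "THR",
                    [("N", (9, 1, 0)), ("CA", (10, 0, 0)), ("C", (11, 1, 0)),
                     ("CB", (10.2, -1.3, 0.6)), ("OG1", og)])
        ]
        return StructureModel("t", {"A": chain}), m

    def test_hydroxyl_on_ape8_site_is_swap(self):
        model, m = self._model_with_ape8(og=(0.5, 0, 0))
        hit_pos = np.array([1.0, 0, 0])  # 0.5 A from the APE8 gamma oxygen
        hit = _dummy_hit()
        assert flag_domain_swap(hit, model, m, hit_pos) is True
        assert hit.swap_flag is True

    def test_hydroxyl_above_asp_plane_is_not_swap(self):
        model, m = self._model_with_ape8(og=(0.5, 0, 0))
        assert flag_domain_swap(_dummy_hit(), model, m, np.array([0.5, 6.0, 0])) is False

    def test_exactly_on_cutoff_is_not_swap(self):
        model, m = self._model_with_ape8(og=(0.0, 0, 0))
        assert flag_domain_swap(_dummy_hit(), model, m, np.array([1.5, 0, 0])) is False

    def test_unmeasurable_site_is_indeterminate(self):
        model = StructureModel("t", {"A": kinase_chain()})
        assert flag_domain_swap(_dummy_hit(), model, kinase_map(), np.zeros(3)) is None


def _dummy_hit():
    from kinactive.substrate_contacts import PhosphoacceptorHit

    return PhosphoacceptorHit("A", "B", 10, "SER", 3.0)


class TestContactMap:
    def _enzyme_with_loop(self):
        m = kinase_map()
        chain = kinase_chain()
        for label, x in (("DFG4", 0.0), ("DFG5", 40.0)):
            seq = actloop_index(m, label)
            chain.append(residue("A", seq, "GLY", [("CA", (x, 20, 0))]))
        return StructureModel("t", {"A": chain}), m

    def test_single_cell_nonzero(self):
        model, m = self._enzyme_with_loop()
        model.chains["B"] = [residue("B", 10, "ALA", [("CA", (0, 23, 0))])]
        cm = contact_map(model, m, "B", p0=10)
        si = SUBSTRATE_POSITIONS.index(0)
        li = LOOP_LABELS.index("DFG4")
        assert cm.counts[si, li] == 1
        assert cm.counts.sum() == 1

    def test_distant_substrate_gives_zero_map(self):
        model, m = self._enzyme_with_loop()
        model.chains["B"] = [residue("B", 10, "ALA", [("CA", (0, 230, 0))])]
        assert contact_map(model, m, "B", p0=10).counts.sum() == 0

    def test_counts_match_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        m = kinase_map()
        chain = kinase_chain()
        loop_atoms = {}
        for label in ("DFG1", "DFG2", "DFG3", "APE1", "APE2"):
            seq = actloop_index(m, label)
            pts = rng.uniform(0, 12, size=(4, 3))
            chain.append(residue("A", seq, "GLY", [(f"X{i}", p) for i, p in enumerate(pts)]))
            loop_atoms[label] = pts
        sub_atoms = {}
        sub_chain = []
        for k in range(8, 13):
            pts = rng.uniform(0, 12, size=(3, 3))
            sub_chain.append(residue("B", k, "ALA", [(f"Y{i}", p) for i, p in enumerate(pts)]))
            sub_atoms[k - 10] = pts
        model = StructureModel("t", {"A": chain, "B": sub_chain})
        cm = contact_map(model, m, "B", p0=10)
        for offset, spts in sub_atoms.items():
            for label, lpts in loop_atoms.items():
                expected = sum(
                    1
                    for s in spts
                    for l in lpts
                    if np.linalg.norm(np.asarray(s) - np.asarray(l)) < 5.0
                )
                si = SUBSTRATE_POSITIONS.index(offset)
                li = LOOP_LABELS.index(label)
                assert cm.counts[si, li] == expected


class TestAverageContacts:
    def _random_map(self, seed):
        rng = np.random.default_rng(seed)
        return ContactMap(
            counts=rng.integers(0, 5, size=(len(SUBSTRATE_POSITIONS), len(LOOP_LABELS)))
        )

    def test_identical_maps_average_to_themselves(self):
        cm = self._random_map(1)
        cells, per_residue = average_contacts([cm, cm])
        assert np.allclose(cells, cm.counts)

    def test_zero_map_halves_values(self):
        cm = self._random_map(2)
        zero = ContactMap(counts=np.zeros_like(cm.counts))
        cells, _ = average_contacts([cm, zero])
        assert np.allclose(cells, cm.counts / 2.0)

    def test_three_maps_match_hand_aggregation(self):
        maps = [self._random_map(s) for s in (3, 4, 5)]
        cells, per_residue = average_contacts(maps)
        stacked = np.stack([m.counts for m in maps])
        assert np.allclose(cells, stacked.mean(axis=0))
        assert np.allclose(per_residue, stacked.sum(axis=1).mean(axis=0))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_contacts([])
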