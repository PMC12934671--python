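import copy

import numpy as np
import pytest

from kinactive.conformational_labels import (
    Thresholds,
    actloopCT_state,
    actloopNT_state,
    compute_features,
    dihedral_xdf_label,
    evaluate_criteria,
    hrd_state,
    saltbridge_state,
    spatial_dfg_label,
    spine_distances,
)
from kinactive.fixtures import all_pass_spec, build_toy_kinase
from kinactive.geometry import min_pair_distance
from kinactive.structure_model import Atom, Residue, StructureModel


class TestSpatialLabel:
    def test_all_pass_fixture_is_dfgin(self, toy_active):
        model, m, _ = toy_active
        fv = compute_features(model, m)
        assert fv.d_phe_glu4 == pytest.approx(8.0, abs=0.01)
        assert fv.d_phe_lys == pytest.approx(14.0, abs=0.01)
        assert spatial_dfg_label(model, m) == "DFGin"

    def test_swapped_distances_are_dfgout(self, toy_violations):
        model, m, _ = toy_violations["spatial"]
        assert spatial_dfg_label(model, m) == "DFGout"

    def test_intermediate_distances_are_dfginter(self):
        spec = all_pass_spec(distances={"phe_glu4": 12.0, "phe_lys": 16.0})
        model, m, _ = build_toy_kinase(spec)
        assert spatial_dfg_label(model, m) == "DFGinter"

    def test_missing_anchor_gives_none(self, toy_active):
        model, m, _ = toy_active
        model = copy.deepcopy(model)
        phe = model.residue("A", m.res_dfg_asp + 1)
        phe.atoms = [a for a in phe.atoms if a.name in {"N", "CA", "C", "O"}]
        assert spatial_dfg_label(model, m) is None


class TestDihedralLabel:
    def test_all_pass_is_blaminus(self, toy_active):
        model, m, _ = toy_active
        assert dihedral_xdf_label(model, m) == "BLAminus"

    def test_chi1_plus_gives_blaplus(self, toy_violations):
        model, m, _ = toy_violations["dihedral"]
        assert dihedral_xdf_label(model, m) == "BLAplus"

    def test_abaminus_from_peptide_flip_dihedrals(self):
        spec = all_pass_spec(
            dihedrals={"XDFG": (-90.0, -20.0), "DFG1": (-120.0, 130.0)}
        )
        model, m, _ = build_toy_kinase(spec)
        assert dihedral_xdf_label(model, m) == "ABAminus"

    def test_label_matches_stored_regions_and_rotamer(self, toy_active):
        """Cross-check the composed label against the geometry-module outputs."""
        from kinactive.geometry import chi1_minus

        model, m, _ = toy_active
        fv = compute_features(model, m)
        label = dihedral_xdf_label(model, m, features=fv)
        assert (label == "BLAminus") == (
            fv.xdf_regions == ("B", "L", "A") and chi1_minus(fv.phe_chi1) is True
        )

    def test_missing_chi1_gives_none(self, toy_active):
        model, m, _ = toy_active
        model = copy.deepcopy(model)
        phe = model.residue("A", m.res_dfg_asp + 1)
        phe.atoms = [a for a in phe.atoms if a.name != "CG"]
        assert dihedral_xdf_label(model, m) is None


class TestSaltBridge:
    def test_in_and_out(self, toy_active, toy_violations):
        model, m, _ = toy_active
        state = saltbridge_state(model, m)
        assert state.state == "in" and state.value == pytest.approx(3.0, abs=0.01)
        model_out, m_out, _ = toy_violations["saltbr"]
        out = saltbridge_state(model_out, m_out)
        assert out.state == "out" and out.value == pytest.approx(4.5, abs=0.01)

    def test_skip_flag_honored(self, toy_active):
        model, m, _ = toy_active
        m2 = copy.deepcopy(m)
        m2.skip_saltbridge = True
        assert saltbridge_state(model, m2).state == "skipped"

    def test_missing_atoms_give_none(self, toy_active):
        model, m, _ = toy_active
        model = copy.deepcopy(model)
        lys = model.residue("A", m.res_saltbridge_lys)
        lys.atoms = [a for a in lys.atoms if a.name == "CA"]
        assert saltbridge_state(model, m).state == "none"


class TestActLoopNT:
    def test_hydrogen_bond_in(self, toy_active):
        state = actloopNT_state(*toy_active[:2])
        assert state.state == "in" and state.value == pytest.approx(2.9, abs=0.01)

    def test_broken_bond_out(self, toy_violations):
        model, m, _ = toy_violations["actloopNT"]
        state = actloopNT_state(model, m)
        assert state.state == "out" and state.value == pytest.approx(5.0, abs=0.01)


class TestHRD:
    def test_a_l_regions_in(self, toy_active):
        state = hrd_state(*toy_active[:2])
        assert state.state == "in"
        assert state.detail == {"his": "A", "arg": "L"}

    def test_flipped_arg_out(self, toy_violations):
        model, m, _ = toy_violations["hrd"]
        state = hrd_state(model, m)
        assert state.state == "out" and state.detail["arg"] == "B"

    def test_skipped_without_af_asp(self, toy_active):
        model, m, _ = toy_active
        m2 = copy.deepcopy(m)
        m2.has_aF_asp = False
        m2.skip_hrd = True
        assert hrd_state(model, m2).state == "skipped"


class TestActLoopCT:
    def test_nontyr_all_bounds_satisfied(self, toy_active):
        state = actloopCT_state(*toy_active[:2])
        assert state.state == "in"
        assert all(v == "pass" for v in state.detail.values())

    def test_expanded_ape10_distance_fails_named_subfeature(self, toy_violations):
        model, m, _ = toy_violations["actloopCT"]
        state = actloopCT_state(model, m)
        assert state.state == "out"
        assert state.detail["APE10"] == "fail"
        others = {k: v for k, v in state.detail.items() if k != "APE10"}
        assert all(v == "pass" for v in others.values())

    def test_peptide_flip_b_l_accepted(self):
        spec = all_pass_spec(
            dihedrals={"APE7": (-120.0, 130.0), "APE6": (60.0, 40.0)}
        )
        model, m, _ = build_toy_kinase(spec)
        state = actloopCT_state(model, m)
        assert state.detail["APE7/6"] == "pass" and state.state == "in"

    def test_tyr_criteria(self, toy_active_tyr):
        model, m, _ = toy_active_tyr
        state = actloopCT_state(model, m)
        assert state.state == "in"
        # TYR kinases get dihedral bounds on APE9/10 but no Cb distance bounds
        assert "APE9-dihe" in state.detail and "APE11" not in state.detail

    def test_noape_skipped(self, toy_active_noape):
        model, m, _ = toy_active_noape
        assert actloopCT_state(model, m).state == "skipped"

    def test_ape8_ser_thr_requires_gminus(self):
        spec = all_pass_spec(dihedrals={"APE8": (-120.0, 130.0, 60.0)})
        model, m, _ = build_toy_kinase(spec)
        state = actloopCT_state(model, m)
        assert state.state == "out" and state.detail["APE8-chi1"] == "fail"


class TestSpine:
    def test_requested_spine_distances_realized(self):
        spec = all_pass_spec(distances={"spine2": 4.0, "spine3": 4.0})
        model, m, _ = build_toy_kinase(spec)
        s1, s2, s3, intact = spine_distances(model, m)
        assert s2 == pytest.approx(4.0, abs=0.05)
        assert s3 == pytest.approx(4.0, abs=0.05)

    def test_broken_spine3(self):
        spec = all_pass_spec(distances={"spine2": 4.0, "spine3": 6.5})
        model, m, _ = build_toy_kinase(spec)
        *_, s3, intact = spine_distances(model, m)
        assert s3 == pytest.approx(6.5, abs=0.05)
        assert intact is False

    def test_minimum_side_chain_distance_matches_brute_force(self):
        rng = np.random.default_rng(3)
        atoms_a = [Atom(f"C{i}", "C", rng.uniform(-8, 8, 3)) for i in range(20)]
        atoms_b = [Atom(f"N{i}", "N", rng.uniform(-8, 8, 3)) for i in range(20)]
        expected = min(
            np.linalg.norm(x.position - y.position) for x in atoms_a for y in atoms_b
        )
        got = min_pair_distance(
            [a.position for a in atoms_a], [b.position for b in atoms_b]
        )
        assert got == pytest.approx(expected, abs=1e-12)


class TestRobustnessMargin:
    def test_small_coordinate_noise_never_flips_any_criterion(self, toy_active):
        """Criteria sit away from their cutoffs; 0.05 A noise must not flip them."""
        model, m, _ = toy_active
        base_states = {c.name: c.state for c in evaluate_criteria(model, m)[0]}
        rng = np.random.default_rng(11)
        for _ in range(5):
            noisy = copy.deepcopy(model)
            for res in noisy.chains["A"]:
                for atom in res.atoms:
                    atom.position = atom.position + rng.uniform(-0.05, 0.05, 3)
            states = {c.name: c.state for c in evaluate_criteria(noisy, m)[0]}
            assert states == base_states

    def test_recomputation_is_identical(self, toy_active):
        model, m, _ = toy_active
        fv1 = compute_features(model, m)
        fv2 = compute_features(model, m)
        assert fv1 == fv2
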