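"""Residue classification, transition-pattern derivation, rendering, stacking."""

import numpy as np
import pytest

import mol_layers as ml
from mol_layers.rtp import RESIDUE_CLASSES, RTP, RTPRecord
from mol_layers.structure_io import AtomRecord, Structure


def _structure(residue_atoms):
    """Build a structure from [(res_name, n_atoms), ...] with dummy coords."""
    atoms = []
    i = 0
    for res_seq, (res_name, n) in enumerate(residue_atoms, start=1):
        for j in range(n):
            atoms.append(AtomRecord(
                serial=i + 1, atom_name=["N", "CA", "C", "O", "CB"][j % 5],
                element="C", res_name=res_name, chain_id="A", res_seq=res_seq,
                insertion_code="", altloc="", occupancy=1.0,
                coords=(float(i), 0.0, 0.0),
            ))
            i += 1
    return Structure(atoms=atoms, source_id="toy")


def _assignment(layer_list, n_layers):
    return ml.LayerAssignment(layer_of=np.array(layer_list, dtype=np.intp),
                              n_layers=n_layers)


def _rtp(labels_layers, n_layers):
    recs = [
        RTPRecord(i + 1, "A", i + 1, "", name, ml.classify_residue(name), lay,
                  "SURFACE" if lay == 1 else ("IM" if lay == n_layers else f"SANDWICH_{lay}"))
        for i, (name, lay) in enumerate(labels_layers)
    ]
    return RTP(records=recs, n_layers=n_layers)


class TestClassification:
    def test_four_classes_partition_the_twenty_residues(self):
        sizes = {c: len(m) for c, m in RESIDUE_CLASSES.items()}
        assert sizes == {"HPL": 9, "HPB": 7, "POS": 2, "NEG": 2}
        all_members = set().union(*RESIDUE_CLASSES.values())
        assert len(all_members) == 20

    @pytest.mark.parametrize("code,expected", [
        ("GLY", "HPL"), ("THR", "HPL"), ("SER", "HPL"),
        ("ILE", "HPB"), ("ALA", "HPB"),
        ("LYS", "POS"), ("ARG", "POS"),
        ("GLU", "NEG"), ("ASP", "NEG"),
        ("gly", "HPL"),  # case-insensitive
    ])
    def test_known_classifications(self, code, expected):
        assert ml.classify_residue(code) == expected

    def test_nonstandard_residue_gets_explicit_marker(self):
        assert ml.classify_residue("MSE") == "X"
        assert ml.classify_residue("MSE", map_nonstandard=True) == "HPB"  # -> MET


class TestResidueLayers:
    def test_all_surface_residue_labeled_surface(self):
        s = _structure([("ALA", 3)])
        rtp = ml.residue_layers(s, _assignment([1, 1, 1], 1), merge_single_im=False)
        assert rtp.labels == ["SURFACE"]

    def test_deepest_occurrence_wins(self):
        # one residue straddling layers 1 and 3 of a 3-layer peel -> IM,
        # a second residue entirely in layer 1 -> SURFACE
        s = _structure([("ALA", 2), ("GLY", 2)])
        rtp = ml.residue_layers(s, _assignment([1, 3, 1, 2], 3), merge_single_im=False)
        assert rtp.labels == ["IM", "SANDWICH_2"]

    def test_deepest_rule_matches_max_over_atoms(self, globule300):
        layers = ml.peel(globule300)
        rtp = ml.residue_layers(globule300, layers, merge_single_im=False)
        by_res = {}
        for i, atom in enumerate(globule300.atoms):
            key = atom.residue_key
            by_res[key] = max(by_res.get(key, 0), int(layers.layer_of[i]))
        for rec in rtp.records:
            assert rec.layer == by_res[(rec.chain_id, rec.res_seq, rec.insertion_code)]

    def test_single_residue_im_layer_is_merged(self):
        # layer 3 consists of atoms of one residue only -> merged into layer 2
        s = _structure([("ALA", 2), ("GLY", 2), ("LEU", 2)])
        a = _assignment([1, 1, 2, 2, 3, 3], 3)
        merged = ml.merge_single_residue_im(s, a)
        assert merged.n_layers == 2
        assert list(merged.layer_of) == [1, 1, 2, 2, 2, 2]
        rtp = ml.residue_layers(s, a, merge_single_im=True)
        assert rtp.labels == ["SURFACE", "IM", "IM"]

    def test_multi_residue_im_layer_is_not_merged(self):
        s = _structure([("ALA", 2), ("GLY", 1), ("LEU", 1)])
        a = _assignment([1, 1, 2, 2], 2)
        assert ml.merge_single_residue_im(s, a) is a

    def test_merge_never_increases_layer_count(self, globule_ensemble):
        for s in globule_ensemble:
            a = ml.peel(s)
            merged = ml.merge_single_residue_im(s, a)
            assert merged.n_layers <= a.n_layers
            changed = merged.layer_of != a.layer_of
            # only atoms previously in the IM layer can change
            assert set(a.layer_of[changed]).issubset({a.n_layers})

    def test_mismatched_assignment_rejected(self):
        s = _structure([("ALA", 2)])
        with pytest.raises(ValueError, match="covers"):
            ml.residue_layers(s, _assignment([1], 1))


class TestComposition:
    def test_one_residue_per_class_gives_even_quarters(self):
        rtp = _rtp([("GLY", 1), ("ALA", 1), ("LYS", 1), ("GLU", 1)], 1)
        comp = ml.class_composition(rtp)
        assert comp["percent"] == {"HPL": 25, "HPB": 25, "POS": 25, "NEG": 25}
        assert sum(comp["fractions"].values()) == pytest.approx(1.0)

    def test_all_glycine_is_fully_hydrophilic(self):
        rtp = _rtp([("GLY", 1)] * 6, 1)
        comp = ml.class_composition(rtp)
        assert comp["percent"] == {"HPL": 100, "HPB": 0, "POS": 0, "NEG": 0}

    def test_unclassified_residues_counted_but_excluded_from_fractions(self):
        rtp = _rtp([("GLY", 1), ("MSE", 1)], 1)
        comp = ml.class_composition(rtp)
        assert comp["counts"]["X"] == 1
        assert comp["fractions"]["HPL"] == pytest.approx(1.0)


class TestRendering:
    def test_one_d_plain_alphabet(self):
        rtp = _rtp([("ALA", 1), ("GLY", 2), ("LEU", 3)], 3)
        assert ml.render_rtp(rtp, "oneD") == "S2I"

    def test_one_d_length_equals_residue_count(self, globule300):
        rtp = ml.residue_layers(globule300, ml.peel(globule300))
        assert len(ml.render_rtp(rtp, "oneD")) == len(rtp)

    def test_rendering_emits_only_labels_present_in_assignment(self, globule300):
        rtp = ml.residue_layers(globule300, ml.peel(globule300))
        symbols = set(ml.render_rtp(rtp, "oneD"))
        allowed = {"S", "I"} | {str(k) for k in range(2, rtp.n_layers)}
        assert symbols <= allowed

    def test_two_d_block_pairs_sequence_class_and_layer_rows(self):
        rtp = _rtp([("ALA", 1), ("GLY", 2), ("LYS", 3)], 3)
        lines = ml.render_rtp(rtp, "twoD").splitlines()
        assert lines[0] == "seq   AGK"
        assert lines[1] == "class BL+"
        assert lines[2] == "layer S2I"

    def test_colored_one_d_contains_plain_symbols(self):
        rtp = _rtp([("ALA", 1), ("GLY", 2)], 2)
        colored = ml.render_rtp(rtp, "oneD", color=True)
        assert "S" in colored and "I" in colored and "\x1b[" in colored


class TestStacking:
    def test_identity_resampling_returns_the_rtp_itself(self):
        rtp = _rtp([("ALA", 1), ("GLY", 2), ("LEU", 3), ("SER", 1)], 3)
        matrix, _ = ml.stack_rtp([rtp], n_bins=len(rtp))
        assert list(matrix[0]) == rtp.labels

    def test_two_identical_rtps_give_identical_rows(self):
        rtp = _rtp([("ALA", 1), ("GLY", 2), ("LEU", 3)], 3)
        matrix, freq = ml.stack_rtp([rtp, rtp], n_bins=3)
        assert list(matrix[0]) == list(matrix[1])
        assert (freq["count"] == 2).all()

    def test_half_binning_majority(self):
        rtp = _rtp([("ALA", 1), ("GLY", 1), ("LEU", 2), ("SER", 2)], 2)
        matrix, _ = ml.stack_rtp([rtp], n_bins=2)
        assert list(matrix[0]) == ["SURFACE", "IM"]

    def test_ties_resolve_to_the_deeper_layer(self):
        rtp = _rtp([("ALA", 1), ("GLY", 2)], 2)
        matrix, _ = ml.stack_rtp([rtp], n_bins=1)
        assert matrix[0, 0] == "IM"

    def test_more_bins_than_residues_forward_fills(self):
        rtp = _rtp([("ALA", 1), ("GLY", 2)], 2)
        matrix, _ = ml.stack_rtp([rtp], n_bins=4)
        assert list(matrix[0]) == ["SURFACE", "SURFACE", "IM", "IM"]

    def test_invalid_bins_rejected(self):
        rtp = _rtp([("ALA", 1)], 1)
        with pytest.raises(ValueError):
            ml.stack_rtp([rtp], n_bins=0)


def test_rtp_invariant_under_translation_and_axis_permutation(globule300):
    base = ml.residue_layers(globule300, ml.peel(globule300))
    shifted = globule300.translated([5.0, -3.0, 11.0])
    assert ml.residue_layers(shifted, ml.peel(shifted)).labels == base.labels
    perm = globule300.with_coords(globule300.coords[:, [2, 0, 1]] * np.array([-1.0, 1.0, -1.0]))
    assert ml.residue_layers(perm, ml.peel(perm)).labels == base.labels
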