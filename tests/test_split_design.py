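import numpy as np
import pytest

from cnascreen import (
    KNOWN_TRIADS,
    TABLE_SPLITS,
    VariantSpec,
    apply_variant,
    assemble_fusion,
    cap_termini,
    detect_isopeptide,
    emit_md_recipe,
    make_parent_domain,
    make_point_mutant,
    make_split,
    read_md_recipe,
    residue_sequence,
    select_residues,
)
from cnascreen.split_design import FusionPartLibrary, SplitSpec, SplitValidationError

EXPECTED_DELETED = {
    "3phs": [246, 247],
    "4oq1": [241, 242, 243, 244, 245],
    "3kptN": [256, 257],
    "3kptC": [501, 502, 503, 504],
}


def _split_system(label):
    spec = TABLE_SPLITS[label]
    parent = make_parent_domain(spec, *KNOWN_TRIADS.get(label, (None, None, None)),
                                header_id=f"synthetic-{label}")
    triad = detect_isopeptide(parent)[0].triad
    return parent, spec, make_split(parent, spec, triad)


class TestMakeSplit:
    @pytest.mark.parametrize("label", list(TABLE_SPLITS))
    def test_deleted_region_derived_from_spec(self, label):
        _, _, cset = _split_system(label)
        assert cset.deleted_numbers == EXPECTED_DELETED[label]

    @pytest.mark.parametrize("label", list(TABLE_SPLITS))
    def test_residue_conservation(self, label):
        parent, spec, cset = _split_system(label)
        parent_range = select_residues(parent, spec.chain, *spec.domain_range)
        n_parent = len(parent_range.residues())
        assert len(cset.catcher.residues()) + len(cset.deleted) + len(cset.tag.residues()) \
            == n_parent

    @pytest.mark.parametrize("label", list(TABLE_SPLITS))
    def test_sequence_concatenation_reproduces_parent_range(self, label):
        parent, spec, cset = _split_system(label)
        deleted_seq = "".join(
            residue_sequence(parent, spec.chain, n, n) for n in cset.deleted_numbers)
        full = residue_sequence(parent, spec.chain, *spec.domain_range)
        assert cset.catcher_seq + deleted_seq + cset.tag_seq == full

    def test_chains_are_separate_and_disjoint(self):
        _, _, cset = _split_system("4oq1")
        combined = cset.combined()
        assert set(combined.chains) == {"C", "T"}
        catcher_keys = {r.key for r in cset.catcher.residues()}
        tag_keys = {r.key for r in cset.tag.residues()}
        assert not catcher_keys & tag_keys

    def test_acceptor_in_deleted_range_rejected(self, parent_4oq1):
        triad = detect_isopeptide(parent_4oq1)[0].triad
        bad = SplitSpec("A", 146, 240, 253, 259)  # Asn252 falls in the gap
        with pytest.raises(SplitValidationError, match="deleted"):
            make_split(parent_4oq1, bad, triad)

    def test_snoop_like_topology_rejected_with_message(self, parent_4oq1):
        from cnascreen.isopeptide_detect import ActiveSiteTriad
        from cnascreen.structure_io import ResidueRecord

        inverted = ActiveSiteTriad(lys=ResidueRecord("A", 250, "LYS"),
                                   acceptor=ResidueRecord("A", 155, "ASN"))
        with pytest.raises(SplitValidationError, match="Snoop-like"):
            make_split(parent_4oq1, TABLE_SPLITS["4oq1"], inverted)


class TestCapTermini:
    def test_acetyl_and_nmethyl_add_one_residue_each(self, parent_4oq1):
        capped = cap_termini(parent_4oq1, n_term="acetyl", c_term="n_methyl")
        names = [r.res_name for r in capped.residues()]
        assert names.count("ACE") == 1 and names.count("NME") == 1
        assert capped.residues()[0].res_name == "ACE"
        assert capped.residues()[-1].res_name == "NME"

    def test_cap_bond_lengths_ideal(self, parent_4oq1):
        capped = cap_termini(parent_4oq1, n_term="acetyl", c_term="n_methyl")
        res = capped.residues()
        ace, first = res[0], res[1]
        last, nme = res[-2], res[-1]
        assert np.linalg.norm(ace.atom("C").coords - first.atom("N").coords) \
            == pytest.approx(1.33, abs=0.01)
        assert np.linalg.norm(last.atom("C").coords - nme.atom("N").coords) \
            == pytest.approx(1.33, abs=0.01)

    def test_all_ionic_is_identity(self, parent_4oq1):
        capped = cap_termini(parent_4oq1)
        assert capped.n_atoms == parent_4oq1.n_atoms

    def test_missing_backbone_rejected(self, parent_4oq1):
        broken = parent_4oq1.copy()
        first = broken.residues()[0]
        first.atoms = [a for a in first.atoms if a.name != "CA"]
        with pytest.raises(ValueError, match="missing"):
            cap_termini(broken, n_term="acetyl")


class TestVariants:
    def test_n_terminal_single_residue_extension(self, parent_4oq1):
        tag = residue_sequence(parent_4oq1, "A", 246, 259)
        ext = apply_variant(tag, parent_4oq1, VariantSpec(n_extension=(245, 245)), "A")
        assert len(ext) == len(tag) + 1
        assert ext[1:] == tag

    def test_c_terminal_truncation_by_three(self, parent_4oq1):
        tag = residue_sequence(parent_4oq1, "A", 246, 259)
        cut = apply_variant(tag, None, VariantSpec(c_truncation=3))
        assert len(cut) == 11
        assert cut == tag[:-3]

    def test_c_terminal_replacement_same_length(self):
        seq = "TNVSVPTK"
        out = apply_variant(seq, None, VariantSpec(c_replacement="GWI"))
        assert len(out) == len(seq) and out.endswith("GWI")

    def test_catcher_extension_by_numbered_range(self, parent_4oq1):
        catcher = residue_sequence(parent_4oq1, "A", 146, 240)
        # C-terminal extensions are modelled by extending the selection
        extended = residue_sequence(parent_4oq1, "A", 146, 244)
        assert len(extended) == len(catcher) + 4

    def test_n_extension_and_c_edit_commute(self):
        seq = "AHIVMVDAYK"
        v_both = VariantSpec(n_extension="GL", c_truncation=2)
        via_both = apply_variant(seq, None, v_both)
        via_steps = apply_variant(
            apply_variant(seq, None, VariantSpec(c_truncation=2)), None,
            VariantSpec(n_extension="GL"))
        assert via_both == via_steps

    def test_truncation_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            apply_variant("GAK", None, VariantSpec(c_truncation=5))

    def test_two_c_edits_rejected(self):
        with pytest.raises(ValueError):
            VariantSpec(c_truncation=1, c_replacement="W")


class TestPointMutants:
    def test_known_active_site_mutation(self, parent_4oq1):
        catcher = residue_sequence(parent_4oq1, "A", 146, 240)
        mutated = make_point_mutant(catcher, "K155A", numbering_offset=146)
        assert mutated[155 - 146] == "A"
        assert sum(a != b for a, b in zip(catcher, mutated)) == 1

    def test_wild_type_mismatch_rejected(self, parent_4oq1):
        catcher = residue_sequence(parent_4oq1, "A", 146, 240)
        with pytest.raises(ValueError, match="expected W"):
            make_point_mutant(catcher, "W155A", numbering_offset=146)

    def test_apply_then_revert_is_identity(self, parent_4oq1):
        catcher = residue_sequence(parent_4oq1, "A", 146, 240)
        there = make_point_mutant(catcher, "K155A", 146)
        back = make_point_mutant(there, "A155K", 146)
        assert back == catcher


class TestFusionAssembly:
    def test_default_library_parts(self):
        lib = FusionPartLibrary.default()
        assert lib["gs_linker"] == "GSGSGSG"
        assert lib["gse_linker"] == "GSGESG"
        assert lib["ha"] == "YPYDVPDYA"
        assert len(lib["mbp"]) == 370 and len(lib["mcherry"]) == 236

    def test_spans_and_concatenation(self):
        lib = FusionPartLibrary.default()
        lib.add("tag", "AHIVMVDAYKPTK")
        rep = assemble_fusion(["his6", "mbp", "gs_linker", "tag"], lib)
        assert rep.sequence == lib["his6"] + lib["mbp"] + lib["gs_linker"] + "AHIVMVDAYKPTK"
        (n0, s0, e0), *_, (n3, s3, e3) = rep.spans
        assert (n0, s0) == ("his6", 0) and n3 == "tag" and e3 == len(rep.sequence)
        assert set(rep.checksums) == {"his6", "mbp", "gs_linker", "tag"}

    def test_unknown_part_rejected(self):
        with pytest.raises(KeyError, match="unknown fusion part"):
            assemble_fusion(["his6", "nosuch"], FusionPartLibrary.default())


class TestMdRecipe:
    def test_split_recipe_round_trips(self):
        _, _, cset = _split_system("3kptC")
        doc = read_md_recipe(emit_md_recipe(cset))
        assert doc["kind"] == "tag_catcher"
        assert doc["isopeptide_bond_present"] is False
        assert [s["duration_ns"] for s in doc["heating"]["stages"]] == [0.1, 0.4, 0.5]
        assert doc["heating"]["stages"][0]["restraint_kcal_mol_A2"] == 5.0
        assert doc["heating"]["target_temperature_K"] == 310.0
        assert doc["production"] == {"ensemble": "NPT", "length_ns": 200.0,
                                     "timestep_fs": 2.0,
                                     "constraints": "SHAKE (bonds involving hydrogen)"}
        assert doc["solvation"]["margin_angstrom"] == 10.0
        assert doc["solvation"]["water_model"] == "TIP3P"

    def test_intact_domain_keeps_the_bond(self, parent_4oq1):
        doc = read_md_recipe(emit_md_recipe(parent_4oq1))
        assert doc["kind"] == "intact_domain"
        assert doc["isopeptide_bond_present"] is True
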