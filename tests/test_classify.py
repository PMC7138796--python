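"""Stwintron taxonomy: nesting geometry to class labels."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stwintron import (
    DisruptedElement,
    NestingRelation,
    Sensu,
    build_cis,
    classify_nesting,
    derive_relation,
    realize_template,
    resolve_splicing,
)
from stwintron.synth import CisTemplate, Lit, Spacer

# a canonical 46-nt external intron: donor at 0-6, branch at 29-35, acceptor at 43-46
_EXTERNAL = CisTemplate("ext46", (Lit("GUAAGU"), Spacer(23), Lit("ACUAAC"), Spacer(8), Lit("UAG")))
_INTERNAL = CisTemplate("int43", (Lit("GUAAGU"), Spacer(20), Lit("ACUAAC"), Spacer(8), Lit("UAG")))


@pytest.fixture(scope="module")
def external_seq():
    return realize_template(_EXTERNAL, seed=11)[0].residues


@pytest.fixture(scope="module")
def internal_seq():
    return realize_template(_INTERNAL, seed=12)[0].residues


class TestClassifyNesting:
    @pytest.mark.parametrize(
        "k, label, sensu",
        [
            (4, "[D4,5]", Sensu.stricto),
            (6, "[D6,7]", Sensu.lato),
            (7, "[D7,8]", Sensu.lato),
            (1, "[D1,2]", Sensu.stricto),
            (5, "[D5,6]", Sensu.stricto),
        ],
    )
    def test_donor_region_classes(self, external_seq, internal_seq, k, label, sensu):
        _, relation = build_cis(external_seq, internal_seq, k)
        cls = classify_nesting(relation)
        assert cls.label == label and cls.sensu is sensu

    def test_branch_element_disruption(self, external_seq, internal_seq):
        # external branch hexamer starts at offset 29; insertion after its 3rd nt
        _, relation = build_cis(external_seq, internal_seq, 32)
        cls = classify_nesting(relation)
        assert cls.label == "[L3,4]"
        assert cls.sensu is Sensu.stricto
        assert cls.disrupted_element is DisruptedElement.branch

    def test_acceptor_disruption(self, external_seq, internal_seq):
        # acceptor trimer starts at offset 43; insertion between its 2nd and 3rd nt
        _, relation = build_cis(external_seq, internal_seq, 45)
        cls = classify_nesting(relation)
        assert cls.label == "[A2,3]"
        assert cls.disrupted_element is DisruptedElement.acceptor

    def test_inter_element_insertion_is_lato_and_flagged(self, external_seq, internal_seq):
        _, relation = build_cis(external_seq, internal_seq, 15)
        cls = classify_nesting(relation)
        assert cls.sensu is Sensu.lato
        assert cls.disrupted_element is DisruptedElement.inter_element
        assert cls.unattested

    def test_label_names_two_consecutive_integers(self, external_seq, internal_seq):
        for k in range(1, len(external_seq) + 1):
            _, relation = build_cis(external_seq, internal_seq, k)
            m = re.fullmatch(r"\[[DLA](\d+),(\d+)\]", classify_nesting(relation).label)
            assert m and int(m.group(2)) == int(m.group(1)) + 1

    def test_k_zero_rejected(self, external_seq, internal_seq):
        with pytest.raises(ValueError):
            NestingRelation(0, external_seq, internal_seq)


class TestBuildCis:
    def test_roundtrip_k_1_to_7(self, external_seq, internal_seq):
        for k in range(1, 8):
            cis, relation = build_cis(external_seq, internal_seq, k)
            assert relation.insertion_offset_k == k
            assert len(cis) == len(external_seq) + len(internal_seq)
            assert cis.residues[k : k + len(internal_seq)] == internal_seq

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(k=st.integers(min_value=1, max_value=46))
    def test_roundtrip_any_k(self, external_seq, internal_seq, k):
        _, relation = build_cis(external_seq, internal_seq, k)
        assert relation.insertion_offset_k == k

    def test_empty_internal_rejected(self, external_seq):
        with pytest.raises(ValueError):
            build_cis(external_seq, "", 3)

    def test_k_out_of_range_rejected(self, external_seq, internal_seq):
        with pytest.raises(ValueError):
            build_cis(external_seq, internal_seq, len(external_seq) + 1)

    def test_lipofer_geometry_gives_320nt_cis(self, realized):
        seq, truth = realized["lipofer_D45"]
        outcome = resolve_splicing(seq, (0, len(seq)))
        relation = derive_relation(outcome)
        cis, rebuilt = build_cis(relation.external_seq, relation.internal_seq, 4)
        assert len(cis) == 320
        assert cis.residues == seq.residues


class TestDeriveRelation:
    @pytest.mark.parametrize(
        "name, k",
        [("suomiensis_D78", 7), ("starkeyi_D67", 6), ("lipofer_D45", 4), ("japonicus_D78", 7)],
    )
    def test_k_from_two_step_paths(self, realized, name, k):
        seq, _ = realized[name]
        relation = derive_relation(resolve_splicing(seq, (0, len(seq))))
        assert relation.insertion_offset_k == k

    def test_single_intron_outcome_gives_none(self):
        t = CisTemplate("canon", (Lit("GUAAGU"), Spacer(40), Lit("ACUAAC"), Spacer(8), Lit("UAG")))
        seq, _ = realize_template(t, seed=3)
        assert derive_relation(resolve_splicing(seq, (0, len(seq)))) is None

    def test_partition_of_cis(self, realized):
        seq, truth = realized["japonicus_D78"]
        relation = derive_relation(resolve_splicing(seq, (0, len(seq))))
        assert len(relation.internal_seq) == truth.internal_length
        assert len(relation.external_seq) == truth.external_length
        assert relation.cis_length == len(seq)
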