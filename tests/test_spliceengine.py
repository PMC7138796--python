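"""Ordered excision by intron definition, and alternative-path enumeration."""

import pytest

from stwintron import (
    NucleotideSequence,
    excise,
    realize_template,
    resolve_splicing,
    score_donor,
    splicing_report,
)
from stwintron.synth import CisTemplate, Lit, Spacer

EXPECTED_SIGNATURES = {
    "lipofer_D45": {(158, 162)},
    "suomiensis_D78": {(61, 79)},
    "japonicus_D78": {(162, 124)},
    "starkeyi_D67": {(120, 132), (246,)},
}


class TestExcise:
    def test_removes_interval_and_ligates(self):
        seq = NucleotideSequence("GUGAGUAAGUCCC")
        out = excise(seq, (4, 10))
        assert out.residues == "GUGACCC"

    def test_whole_sequence_gives_empty(self):
        seq = NucleotideSequence("GUAAGUUAG")
        assert excise(seq, (0, 9)).residues == ""

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            excise(NucleotideSequence("GUAAGU"), (3, 3))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            excise(NucleotideSequence("GUAAGU"), (2, 9))

    def test_internal_excision_reconstitutes_external_donor(self, realized):
        seq, truth = realized["lipofer_D45"]
        inter = excise(seq, (truth.internal_start, truth.internal_start + truth.internal_length))
        assert inter.residues[:6] == "GUGAGU"
        assert score_donor(inter.residues[:6]) is not None


class TestResolve:
    @pytest.mark.parametrize("name", sorted(EXPECTED_SIGNATURES))
    def test_printed_architectures(self, realized, name):
        seq, _ = realized[name]
        outcome = resolve_splicing(seq, (0, len(seq)))
        assert {p.signature for p in outcome.paths} == EXPECTED_SIGNATURES[name]

    def test_suomiensis_uses_three_prime_donor(self, realized):
        seq, _ = realized["suomiensis_D78"]
        outcome = resolve_splicing(seq, (0, len(seq)))
        (path,) = outcome.paths
        first = path.events[0]
        assert first.intron.donor.sequence == "GUAGGU"
        assert first.primary_start == 7  # the 3'-most of two donors one nt apart

    def test_starkeyi_mature_products_differ_by_six_nt(self, realized):
        seq, _ = realized["starkeyi_D67"]
        outcome = resolve_splicing(seq, (0, len(seq)))
        products = sorted(outcome.mature_products, key=len)
        assert len(products) == 2
        assert len(products[1]) - len(products[0]) == 6
        assert products[1] == "GUACGU"  # the 5' donor copy becomes exonic

    def test_single_canonical_intron_single_path(self):
        t = CisTemplate("canon", (Lit("GUAAGU"), Spacer(40), Lit("ACUAAC"), Spacer(8), Lit("UAG")))
        seq, _ = realize_template(t, seed=2)
        outcome = resolve_splicing(seq, (0, len(seq)))
        assert len(outcome.paths) == 1
        assert outcome.paths[0].signature == (len(seq),)

    def test_nonfunctional_region_gives_empty_outcome(self):
        seq = NucleotideSequence("ACA" * 30)
        outcome = resolve_splicing(seq, (0, len(seq)))
        assert outcome.paths == ()

    def test_length_conservation_on_every_path(self, realized):
        for seq, _ in realized.values():
            outcome = resolve_splicing(seq, (0, len(seq)))
            for path in outcome.paths:
                assert len(outcome.precursor) == len(path.mature) + sum(path.signature)

    def test_intermediate_chain_single_excisions(self, realized):
        for seq, _ in realized.values():
            outcome = resolve_splicing(seq, (0, len(seq)))
            for path in outcome.paths:
                prev = outcome.precursor
                for ev, inter in zip(path.events, path.intermediates):
                    assert inter.residues == excise(prev, ev.intron).residues
                    prev = inter

    def test_two_step_paths_reconstitute_external_donor(self, realized):
        for seq, _ in realized.values():
            outcome = resolve_splicing(seq, (0, len(seq)))
            for path in outcome.paths:
                if len(path.events) != 2:
                    continue
                after_first = path.intermediates[0]
                ext_start = path.events[1].intron.start
                donor = after_first.residues[ext_start : ext_start + 6]
                assert score_donor(donor) is not None

    def test_determinism(self, realized):
        seq, _ = realized["starkeyi_D67"]
        a = resolve_splicing(seq, (0, len(seq)))
        b = resolve_splicing(seq, (0, len(seq)))
        assert [p.signature for p in a.paths] == [p.signature for p in b.paths]
        assert a.mature_products == b.mature_products

    def test_region_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            resolve_splicing(NucleotideSequence("GUAAGU"), (0, 10))


class TestReport:
    def test_starkeyi_report_lists_two_products(self, realized):
        seq, _ = realized["starkeyi_D67"]
        rep = splicing_report(resolve_splicing(seq, (0, len(seq))))
        assert len(rep["mature_products"]) == 2
        assert rep["n_paths"] == 2

    def test_empty_outcome_reports_zero_paths(self):
        rep = splicing_report(resolve_splicing(NucleotideSequence("ACA" * 30), (0, 90)))
        assert rep["n_paths"] == 0 and rep["paths"] == []

    def test_lipofer_intermediate_is_precursor_minus_internal(self, realized):
        seq, _ = realized["lipofer_D45"]
        rep = splicing_report(resolve_splicing(seq, (0, len(seq))))
        (path,) = rep["paths"]
        assert len(path["intermediates"][0]) == len(seq) - 158
        # event coordinates are reported in both conventions
        ev = path["events"][0]
        assert ev["primary_start_1based"] == ev["primary_start_0based"] + 1
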