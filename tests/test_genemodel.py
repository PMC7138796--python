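"""Gene-model arithmetic: phases, mature mRNA, positional conservation."""

import pytest

from stwintron import (
    GeneModel,
    NucleotideSequence,
    conserved_position_matrix,
    introns_of,
    mature_mrna,
    resolve_splicing,
)
from stwintron.synth import builtin_templates, make_gene_fixture, make_orthologue_set

FIG3_OCCUPANCY = {
    "starkeyi": {1, 2, 3, 4, 5},
    "mesembrius": {1, 2, 3, 4, 5},
    "arxii": {1, 2, 3, 4, 5},
    "kononenkoae": {1, 2, 3, 4, 5},
    "lipofer": {1, 2, 3, 4, 5},
    "japonicus": {1, 2, 3, 4},
    "suomiensis": {1, 2, 5},
    "doorenjongii": {1, 2},
    "oligophaga": {1},
}


def _toy_model(exon_lens, intron_lens, coding_start=0, strand="+", genome=None):
    exons, pos = [], 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    total_exonic = sum(exon_lens)
    return GeneModel(
        gene_id="toy",
        exons=tuple(exons),
        coding_start=coding_start,
        coding_end=pos,  # through the last exon end
        strand=strand,
        genome=genome,
    )


class TestIntronPhases:
    def test_seven_coding_nt_upstream_gives_phase_one(self):
        # exon1 contributes 7 coding nt, CDS total 7+8=15 nt
        m = _toy_model([7, 8], [50])
        anns = introns_of(m)
        assert len(anns) == 1 and anns[0].phase == 1

    def test_single_exon_no_introns(self):
        m = _toy_model([9], [])
        assert introns_of(m) == []

    def test_phases_cycle_with_exon_lengths(self):
        m = _toy_model([7, 8, 6, 9], [10, 10, 10])
        anns = introns_of(m)
        assert [a.phase for a in anns] == [7 % 3, (7 + 8) % 3, (7 + 8 + 6) % 3]

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            _toy_model([7, 9], [50])


class TestMatureMrna:
    def test_exon_length_additivity(self):
        genome = NucleotideSequence("GCU" * 30)
        m = _toy_model([10, 20], [60], genome=genome)
        assert len(mature_mrna(m, genome)) == 30

    def test_minus_strand_reverse_complement(self):
        genome = NucleotideSequence("GCAUGC")
        m = GeneModel("toy", ((0, 6),), 0, 6, strand="-", genome=genome)
        assert mature_mrna(m, genome).residues == "GCAUGC"[::-1].translate(
            str.maketrans("ACGU", "UGCA")
        )

    def test_out_of_bounds_exon_rejected(self):
        genome = NucleotideSequence("GCU")
        m = _toy_model([10, 20], [60])
        with pytest.raises(ValueError):
            mature_mrna(m, genome)


class TestGeneFixture:
    def test_lipofer_fixture_second_exon_165nt(self):
        fx = make_gene_fixture(builtin_templates()["lipofer_D45"], 100, 165, seed=5)
        assert len(fx.genome) == 100 + 320 + 165
        mature = mature_mrna(fx.model, fx.genome)
        e2 = fx.model.exons[1]
        assert e2[1] - e2[0] == 165
        assert len(mature) == 100 + 165

    def test_fixture_first_intron_phase_one(self):
        # the attested external-intron phase at the studied position
        fx = make_gene_fixture(builtin_templates()["lipofer_D45"], 100, 165, seed=5)
        assert introns_of(fx.model)[0].phase == 1

    def test_fixture_resolves_to_truth_signature(self):
        fx = make_gene_fixture(builtin_templates()["suomiensis_D78"], 60, 162, seed=8)
        outcome = resolve_splicing(fx.genome, fx.cis_region)
        assert {p.signature for p in outcome.paths} == set(fx.truth.path_signatures)

    def test_too_short_exons_rejected(self):
        with pytest.raises(ValueError):
            make_gene_fixture(builtin_templates()["lipofer_D45"], 2, 165, seed=5)


@pytest.fixture(scope="module")
def fig3():
    models, aln = make_orthologue_set(FIG3_OCCUPANCY, seed=7)
    return models, aln, conserved_position_matrix(models, aln)


class TestConservationMatrix:
    def test_oligophaga_has_one_lone_intron(self, fig3):
        _, _, mat = fig3
        assert mat.loc["oligophaga"].sum() == 1

    def test_suomiensis_lacks_positions_3_and_4(self, fig3):
        _, _, mat = fig3
        row = mat.loc["suomiensis"]
        assert not row["pos3"] and not row["pos4"]
        assert row["pos1"] and row["pos2"] and row["pos5"]

    def test_doorenjongii_only_first_two_positions(self, fig3):
        _, _, mat = fig3
        assert list(mat.loc["doorenjongii"]) == [True, True, False, False, False]

    def test_identical_models_single_green_column_set(self):
        spec = {f"sp{i}": {1, 2, 3} for i in range(4)}
        models, aln = make_orthologue_set(spec, seed=1)
        mat = conserved_position_matrix(models, aln)
        assert mat.shape == (4, 3) and mat.values.all()

    def test_permutation_invariance(self, fig3):
        models, aln, mat = fig3
        mat2 = conserved_position_matrix(list(reversed(models)), aln)
        assert mat.sort_index().equals(mat2.sort_index())

    def test_cds_alignment_mismatch_names_species(self, fig3):
        models, aln, _ = fig3
        bad = aln[:, :-1]  # truncate every row by one residue
        with pytest.raises(ValueError, match="starkeyi"):
            conserved_position_matrix(models[:1], bad)
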