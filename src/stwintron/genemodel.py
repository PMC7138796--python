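"""Exon/intron gene-model arithmetic.

Intron phase is the number of coding nucleotides by which an intron is
displaced into a codon (0, 1 or 2), computed from the cumulative coding
length upstream of the intron in transcription order.  Intron positional
homology across orthologues is established through a protein alignment:
an intron is mapped to the alignment column of the codon containing its
insertion point, and two introns occupy "the same position" iff they
share both that column and the phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .motifs import NucleotideSequence

__all__ = ["GeneModel", "IntronAnnotation", "introns_of", "mature_mrna", "conserved_position_matrix"]


@dataclass(frozen=True)
class GeneModel:
    """Exon coordinates (0-based half-open, genomic) plus the coding span.

    ``coding_start``/``coding_end`` are genomic offsets delimiting the
    ORF within the exon chain.  ``genome`` optionally carries the
    underlying genomic sequence so the CDS can be extracted and
    translated.
    """

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    coding_start: int
    coding_end: int
    strand: str = "+"
    species: str = ""
    genome: NucleotideSequence | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty or inverted exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if not self.coding_start < self.coding_end:
            raise ValueError("coding interval is empty or inverted")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.gene_id} not divisible by 3"
            )

    def _coding_overlap(self, s: int, e: int) -> int:
        return max(0, min(e, self.coding_end) - max(s, self.coding_start))

    @property
    def cds_length(self) -> int:
        return sum(self._coding_overlap(s, e) for s, e in self.exons)

    def cds_residues(self) -> str:
        """The spliced coding sequence in transcription order."""
        if self.genome is None:
            raise ValueError(f"gene model {self.gene_id} carries no genome sequence")
        parts = [
            self.genome.residues[max(s, self.coding_start) : min(e, self.coding_end)]
            for s, e in self.exons
            if self._coding_overlap(s, e)
        ]
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement_rna())
        return cds


@dataclass(frozen=True)
class IntronAnnotation:
    index: int  # 1-based, transcription order
    interval: tuple[int, int]  # genomic, 0-based half-open
    phase: int
    conserved_position: str | None = None


def introns_of(model: GeneModel) -> list[IntronAnnotation]:
    """One annotation per inter-exon gap, phase from upstream coding length."""
    gaps = [
        (model.exons[i][1], model.exons[i + 1][0])
        for i in range(len(model.exons) - 1)
    ]
    out = []
    if model.strand == "+":
        ordered = gaps
    else:
        ordered = list(reversed(gaps))
    for idx, (gs, ge) in enumerate(ordered, start=1):
        if model.strand == "+":
            upstream = sum(
                model._coding_overlap(s, min(e, gs)) for s, e in model.exons if s < gs
            )
        else:
            upstream = sum(
                model._coding_overlap(max(s, ge), e) for s, e in model.exons if e > ge
            )
        out.append(IntronAnnotation(idx, (gs, ge), upstream % 3))
    return out


def mature_mrna(model: GeneModel, genome: NucleotideSequence) -> NucleotideSequence:
    """Concatenated exon residues (reverse-complemented for minus strand)."""
    for s, e in model.exons:
        if not 0 <= s < e <= len(genome):
            raise ValueError(f"exon ({s}, {e}) outside genome of length {len(genome)}")
    joined = "".join(genome.residues[s:e] for s, e in model.exons)
    if model.strand == "-":
        joined = str(Seq(joined).reverse_complement_rna())
    return NucleotideSequence(joined, f"{model.gene_id}|mature")


def _coding_offset_of_gap(model: GeneModel, gap: tuple[int, int]) -> int:
    gs, ge = gap
    if model.strand == "+":
        return sum(model._coding_overlap(s, min(e, gs)) for s, e in model.exons if s < gs)
    return sum(model._coding_overlap(max(s, ge), e) for s, e in model.exons if e > ge)


def conserved_position_matrix(models: list[GeneModel], protein_alignment) -> pd.DataFrame:
    """Species x conserved-position intron occupancy matrix.

    Every intron of every model is mapped to the alignment column of the
    codon containing its (phase-adjusted) insertion point; introns that
    share (column, phase) across species collapse to one conserved
    position.  Rows follow the input model order; columns are sorted by
    alignment column and labelled ``pos1``, ``pos2``, ...
    """
    rows = {rec.id: str(rec.seq) for rec in protein_alignment}
    occupancy: dict[str, set[tuple[int, int]]] = {}
    for model in models:
        name = model.species or model.gene_id
        row = rows.get(name) or rows.get(model.gene_id)
        if row is None:
            raise ValueError(f"no alignment row for species {name!r}")
        translated = str(Seq(model.cds_residues()).translate()).rstrip("*")
        ungapped = row.replace("-", "")
        if translated != ungapped:
            raise ValueError(
                f"translated CDS of species {name!r} does not match its alignment row"
            )
        non_gap_cols = [i for i, c in enumerate(row) if c != "-"]
        keys = set()
        for ann in introns_of(model):
            c = _coding_offset_of_gap(model, ann.interval)
            aa = c // 3
            if not 0 <= aa < len(non_gap_cols):
                continue  # intron outside the aligned protein (UTR etc.)
            keys.add((non_gap_cols[aa], ann.phase))
        occupancy[name] = keys
    all_keys = sorted(set().union(*occupancy.values()) if occupancy else set())
    labels = [f"pos{i + 1}" for i in range(len(all_keys))]
    data = {
        name: [key in keys for key in all_keys] for name, keys in occupancy.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=labels)
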