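"""FASTA and GFF3 input/output.

Sequences are RNA internally and written back to disk in the DNA
alphabet; coordinates are 0-based half-open internally and converted to
GFF3's 1-based inclusive convention only at the file boundary.
"""

from __future__ import annotations

import urllib.parse
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .motifs import NucleotideSequence, normalize

__all__ = ["Feature", "read_fasta", "write_fasta", "read_gff3", "write_gff3"]


@dataclass(frozen=True)
class Feature:
    """One GFF3 feature with internal (0-based half-open) coordinates."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str = "+"
    score: float | None = None
    phase: int | None = None
    source: str = "stwintron"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"inverted or empty feature coordinates [{self.start}, {self.end})"
            )


def read_fasta(path) -> list[NucleotideSequence]:
    """Read FASTA records, normalizing DNA or RNA to the RNA alphabet."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(normalize(str(rec.seq), rec.id))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(seqs: list[NucleotideSequence], path, width: int = 60) -> None:
    """Write sequences in the DNA alphabet (U -> T)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            dna = s.as_dna()
            for i in range(0, len(dna), width):
                fh.write(dna[i : i + width] + "\n")


_ESCAPE = ";=%&,\t\n"


def _enc(value: str) -> str:
    return urllib.parse.quote(value, safe="".join(c for c in map(chr, range(33, 127)) if c not in _ESCAPE))


def _fmt_attrs(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={_enc(str(v))}" for k, v in attrs.items())


def write_gff3(features: list[Feature], path) -> None:
    """Write features as GFF3 (1-based inclusive on disk).

    A nested (internal) intron feature without a Parent link draws a
    validation warning: nesting is expressed through Parent.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if f.type == "intron" and f.attributes.get("nesting") == "internal" and "Parent" not in f.attributes:
                warnings.warn(
                    f"nested intron feature {f.attributes.get('ID', '?')} has no Parent link",
                    stacklevel=2,
                )
            cols = [
                f.seqid,
                f.source,
                f.type,
                str(f.start + 1),
                str(f.end),
                "." if f.score is None else f"{f.score:g}",
                f.strand,
                "." if f.phase is None else str(f.phase),
                _fmt_attrs(f.attributes),
            ]
            fh.write("\t".join(cols) + "\n")


def read_gff3(path) -> list[Feature]:
    """Read a GFF3 file back into internal-coordinate features."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    out = []
    for f in db.all_features(order_by=None):
        if f.end < f.start:
            raise ValueError(f"inverted coordinates on feature {f.id}")
        attrs = {k: ",".join(v) for k, v in f.attributes.items()}
        out.append(
            Feature(
                seqid=f.seqid,
                type=f.featuretype,
                start=f.start - 1,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                score=None if f.score in (".", "", None) else float(f.score),
                phase=None if f.frame in (".", "", None) else int(f.frame),
                source=f.source,
                attributes=attrs,
            )
        )
    return out
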