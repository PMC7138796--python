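"""Splice-element motif models for U2-type introns.

U2 introns carry three conserved elements: a 5' donor (fungal consensus
GURWGY, with an invariant GU dinucleotide at its start), a lariat branch
point element (DYURAY, branch adenosine at position 5) and a 3' acceptor
(HAG).  Real introns deviate from the consensus, and whether a deviant
element is still "good enough" matters: a weak element can be skipped by
the spliceosome, which is what enables alternative excision of complex
intervening sequences.

This module scores individual element windows against the consensus and
assigns each a canonicality tier:

* donor   — must begin with the literal ``GU``; up to one mismatch is
  tolerated over consensus positions 3-6.  Zero mismatches = strong.
* branch  — scored against the primary consensus DYURAY (at most one
  mismatch for validity) and additionally against a strict secondary
  reference HCURAC.  The combined mismatch count is the element's
  *strength*; strength <= 1 is strong.  This two-tier rule captures the
  observation that branch elements such as UUUAAU match DYURAY perfectly
  yet behave as functionally weak, while ACUAAC/ACUGAC/UCUAAC/GCUGAC
  behave as fully canonical.
* acceptor — binary: matches HAG or not.  Acceptors are never graded.

All scoring is context-free and deterministic; sequence position is
attached by the scanning layer (:mod:`stwintron.introncall`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "IUPAC_RNA",
    "NucleotideSequence",
    "SpliceMotifModel",
    "ElementKind",
    "Tier",
    "ElementMatch",
    "normalize",
    "match_iupac",
    "score_donor",
    "score_branch",
    "score_acceptor",
]

#: IUPAC nucleotide codes over the RNA alphabet.
IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "W": frozenset("AU"),
    "S": frozenset("CG"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

_CONCRETE = frozenset("ACGU")


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA sequence with an identifier.

    The internal canonical alphabet is RNA ({A,C,G,U}); DNA input is
    transcribed on ingest by :func:`normalize`.  An empty sequence is
    permitted (it arises as a ligation by-product when an intron spans a
    whole molecule).
    """

    residues: str
    id: str = ""

    def __post_init__(self) -> None:
        bad = next((i for i, c in enumerate(self.residues) if c not in _CONCRETE), None)
        if bad is not None:
            raise ValueError(
                f"non-RNA residue {self.residues[bad]!r} at position {bad} "
                f"in sequence {self.id!r}; use normalize() on raw input"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key) -> str:
        return self.residues[key]

    def with_residues(self, residues: str) -> "NucleotideSequence":
        return NucleotideSequence(residues, self.id)

    def as_dna(self) -> str:
        """Residues written back in the DNA alphabet (U -> T)."""
        return self.residues.replace("U", "T")


def normalize(seq: str, id: str = "") -> NucleotideSequence:
    """Normalize raw nucleotide text to the canonical RNA alphabet.

    Case-insensitive; T is transcribed to U.  Ambiguity codes are not
    accepted in concrete sequences.  Idempotent.
    """
    up = seq.upper().replace("T", "U")
    for i, c in enumerate(up):
        if c not in _CONCRETE:
            raise ValueError(f"non-nucleotide character {seq[i]!r} at position {i}")
    return NucleotideSequence(up, id)


def match_iupac(pattern: str, window: str) -> bool:
    """True iff every residue of *window* is in the corresponding IUPAC class."""
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    try:
        return all(w in IUPAC_RNA[p] for p, w in zip(pattern, window))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in pattern") from exc


def _mismatches(pattern: str, window: str) -> int:
    return sum(w not in IUPAC_RNA[p] for p, w in zip(pattern, window))


@dataclass(frozen=True)
class SpliceMotifModel:
    """Consensus patterns and cutoffs for the three U2 splice elements."""

    donor_pattern: str = "GURWGY"
    branch_pattern: str = "DYURAY"
    branch_strict_pattern: str = "HCURAC"
    acceptor_pattern: str = "HAG"
    donor_mandatory_prefix: str = "GU"
    donor_max_mismatch: int = 1
    branch_max_primary_mismatch: int = 1
    branch_strong_cutoff: int = 1
    branch_invalid_cutoff: int = 5

    def __post_init__(self) -> None:
        for pat, n in [
            (self.donor_pattern, 6),
            (self.branch_pattern, 6),
            (self.branch_strict_pattern, 6),
            (self.acceptor_pattern, 3),
        ]:
            if len(pat) != n or any(c not in IUPAC_RNA for c in pat):
                raise ValueError(f"invalid IUPAC pattern {pat!r} (expected length {n})")
        if not 0 <= self.branch_strong_cutoff < self.branch_invalid_cutoff:
            raise ValueError("require 0 <= branch_strong_cutoff < branch_invalid_cutoff")


class ElementKind(str, enum.Enum):
    donor = "donor"
    branch = "branch"
    acceptor = "acceptor"


class Tier(str, enum.Enum):
    strong = "strong"
    weak = "weak"


@dataclass(frozen=True)
class ElementMatch:
    """One scored splice-element occurrence.

    ``start`` is a 0-based offset into the scanned sequence (-1 for
    context-free scores before placement).  ``strength`` is the combined
    mismatch count for branch elements and equals ``primary_mismatches``
    for donors and acceptors.
    """

    kind: ElementKind
    sequence: str
    primary_mismatches: int
    strength: int
    tier: Tier
    start: int = -1

    def at(self, start: int) -> "ElementMatch":
        return replace(self, start=start)

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


def score_donor(hexamer: str, model: SpliceMotifModel | None = None) -> ElementMatch | None:
    """Score a 6-nt window as a 5' donor; ``None`` if invalid.

    Validity requires the literal GU prefix plus at most
    ``donor_max_mismatch`` mismatches over consensus positions 3-6.
    """
    model = model or SpliceMotifModel()
    if len(hexamer) != 6:
        raise ValueError(f"donor window must be 6 nt, got {len(hexamer)}")
    if not hexamer.startswith(model.donor_mandatory_prefix):
        return None
    mm = _mismatches(model.donor_pattern[2:], hexamer[2:])
    if mm > model.donor_max_mismatch:
        return None
    tier = Tier.strong if mm == 0 else Tier.weak
    return ElementMatch(ElementKind.donor, hexamer, mm, mm, tier)


def score_branch(hexamer: str, model: SpliceMotifModel | None = None) -> ElementMatch | None:
    """Score a 6-nt window as a lariat branch point element; ``None`` if invalid."""
    model = model or SpliceMotifModel()
    if len(hexamer) != 6:
        raise ValueError(f"branch window must be 6 nt, got {len(hexamer)}")
    primary = _mismatches(model.branch_pattern, hexamer)
    if primary > model.branch_max_primary_mismatch:
        return None
    strength = primary + _mismatches(model.branch_strict_pattern, hexamer)
    if strength >= model.branch_invalid_cutoff:
        return None
    tier = Tier.strong if strength <= model.branch_strong_cutoff else Tier.weak
    return ElementMatch(ElementKind.branch, hexamer, primary, strength, tier)


def score_acceptor(trimer: str, model: SpliceMotifModel | None = None) -> ElementMatch | None:
    """Score a 3-nt window as a 3' acceptor; binary, always strong when valid."""
    model = model or SpliceMotifModel()
    if len(trimer) != 3:
        raise ValueError(f"acceptor window must be 3 nt, got {len(trimer)}")
    if not match_iupac(model.acceptor_pattern, trimer):
        return None
    return ElementMatch(ElementKind.acceptor, trimer, 0, 0, Tier.strong)
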