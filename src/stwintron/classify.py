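"""Stwintron taxonomy for nested intron pairs.

A complex intervening sequence (CIS) of two nested U2 introns is named
for the external-intron element the internal intron lands in and the two
consecutive nucleotide positions it separates: ``[Dk,k+1]`` for the 5'
donor, ``[Lm,m+1]`` for the lariat branch point element, ``[Am,m+1]``
for the 3' acceptor.  When the internal intron interrupts one of the
three conserved elements the nesting is a stwintron *sensu stricto*
(internal excision is mechanistically indispensable).  When the two
donors merely abut (k = 6) or sit one nucleotide apart (k = 7), the
introns are still excised inside-out by consecutive reactions — a
stwintron *sensu lato*.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .introncall import CandidateIntron, SplicingParams, find_candidate_introns
from .motifs import NucleotideSequence, SpliceMotifModel, normalize
from .spliceengine import SplicingOutcome

__all__ = [
    "Sensu",
    "DisruptedElement",
    "NestingRelation",
    "StwintronClass",
    "classify_nesting",
    "build_cis",
    "derive_relation",
]


class Sensu(str, enum.Enum):
    stricto = "stricto"
    lato = "lato"
    none = "none"


class DisruptedElement(str, enum.Enum):
    donor = "donor"
    branch = "branch"
    acceptor = "acceptor"
    inter_element = "inter_element"


@dataclass(frozen=True)
class NestingRelation:
    """Geometry of one internal intron nested in one external intron.

    ``insertion_offset_k`` counts the external-intron nucleotides 5' of
    the internal intron's start, i.e. the internal intron sits between
    external positions k and k+1 (1-based).  ``external``/``internal``
    carry element matches with coordinates relative to the respective
    intron's own residues (start 0); they may be ``None`` when the
    constituent sequence is not itself a scorable candidate.
    """

    insertion_offset_k: int
    external_seq: str
    internal_seq: str
    external: CandidateIntron | None = None
    internal: CandidateIntron | None = None

    def __post_init__(self) -> None:
        if self.insertion_offset_k < 1:
            raise ValueError(
                "internal intron precedes the external donor (k = 0): not a nesting"
            )
        if self.insertion_offset_k > len(self.external_seq):
            raise ValueError("insertion offset beyond the external intron")
        if not self.internal_seq:
            raise ValueError("internal intron must be non-empty")

    @property
    def cis_length(self) -> int:
        return len(self.external_seq) + len(self.internal_seq)


@dataclass(frozen=True)
class StwintronClass:
    label: str
    sensu: Sensu
    disrupted_element: DisruptedElement
    unattested: bool = False  # geometry beyond the described k <= 7 range


def classify_nesting(
    relation: NestingRelation, model: SpliceMotifModel | None = None
) -> StwintronClass:
    """Assign the stwintron class of a nesting relation.

    k in 1..5 interrupts the donor hexamer (sensu stricto); k = 6 means
    abutting donors and k = 7 donors one nt apart (both sensu lato).
    For larger k the insertion point is tested against the external
    branch and acceptor elements ([L]/[A], sensu stricto); anything else
    is sensu lato between elements, flagged as unattested geometry.
    """
    k = relation.insertion_offset_k
    if 1 <= k <= 5:
        return StwintronClass(f"[D{k},{k + 1}]", Sensu.stricto, DisruptedElement.donor)
    if k in (6, 7):
        return StwintronClass(f"[D{k},{k + 1}]", Sensu.lato, DisruptedElement.inter_element)
    ext = relation.external
    if ext is not None:
        b = ext.branch.start  # 0-based within the external intron
        if b + 1 <= k <= b + 5:
            m = k - b
            return StwintronClass(f"[L{m},{m + 1}]", Sensu.stricto, DisruptedElement.branch)
        a = ext.acceptor.start
        if a + 1 <= k <= a + 2:
            m = k - a
            return StwintronClass(f"[A{m},{m + 1}]", Sensu.stricto, DisruptedElement.acceptor)
    return StwintronClass(
        f"[D{k},{k + 1}]", Sensu.lato, DisruptedElement.inter_element, unattested=True
    )


def _self_candidate(seq: str, params: SplicingParams) -> CandidateIntron | None:
    """The candidate spanning exactly the whole of ``seq``, if any."""
    if len(seq) < 9:
        return None
    relaxed = replace(params, min_intron_len=9, max_intron_len=max(len(seq), 9))
    for c in find_candidate_introns(NucleotideSequence(seq), (0, len(seq)), relaxed):
        if c.start == 0 and c.end == len(seq):
            return c
    return None


def build_cis(
    external_seq: str,
    internal_seq: str,
    k: int,
    params: SplicingParams | None = None,
) -> tuple[NucleotideSequence, NestingRelation]:
    """Insert ``internal_seq`` after the k-th residue of ``external_seq``.

    Inverse of classification: returns the CIS plus the truth relation.
    """
    params = params or SplicingParams()
    ext = normalize(external_seq).residues
    intr = normalize(internal_seq).residues
    if not intr:
        raise ValueError("internal intron must be non-empty")
    if not 1 <= k <= len(ext):
        raise ValueError(f"insertion offset k={k} out of range 1..{len(ext)}")
    cis = NucleotideSequence(ext[:k] + intr + ext[k:])
    relation = NestingRelation(
        insertion_offset_k=k,
        external_seq=ext,
        internal_seq=intr,
        external=_self_candidate(ext, params),
        internal=_self_candidate(intr, params),
    )
    return cis, relation


def derive_relation(
    outcome: SplicingOutcome, params: SplicingParams | None = None
) -> NestingRelation | None:
    """Extract the nesting relation from a two-step splicing path.

    The first event's intron is the internal intron; the second event's
    intron, mapped back to pre-excision coordinates, is the external
    intron.  Returns ``None`` when the outcome has no two-step path.
    """
    params = params or SplicingParams()
    two_step = next((p for p in outcome.paths if len(p.events) == 2), None)
    if two_step is None:
        return None
    first, second = two_step.events
    internal_start = first.primary_start
    external_start = second.primary_start
    k = internal_start - external_start
    if k < 1:
        # the later intron does not wrap around the earlier one: two
        # consecutive same-start excisions are not a nesting
        return None
    res = outcome.precursor.residues
    internal_seq = res[internal_start : internal_start + first.excised_length]
    external_seq = "".join(res[a:b] for a, b in second.primary_segments)
    shift = second.intron.start
    external = CandidateIntron(
        start=0,
        end=second.intron.length,
        donor=second.intron.donor.at(second.intron.donor.start - shift),
        branch=second.intron.branch.at(second.intron.branch.start - shift),
        acceptor=second.intron.acceptor.at(second.intron.acceptor.start - shift),
    )
    ishift = first.intron.start
    internal = CandidateIntron(
        start=0,
        end=first.intron.length,
        donor=first.intron.donor.at(first.intron.donor.start - ishift),
        branch=first.intron.branch.at(first.intron.branch.start - ishift),
        acceptor=first.intron.acceptor.at(first.intron.acceptor.start - ishift),
    )
    return NestingRelation(
        insertion_offset_k=k,
        external_seq=external_seq,
        internal_seq=internal_seq,
        external=external,
        internal=internal,
    )
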