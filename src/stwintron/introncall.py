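"""Candidate U2 intron enumeration.

A candidate intron is a (donor, branch, acceptor) triple satisfying the
tier model of :mod:`stwintron.motifs`, an overall length window, and a
branch-to-acceptor spacing window.  Enumeration is exhaustive within a
designated region; the caller (typically the splicing engine) decides
which candidate is excised.

``brute_force_candidates`` is an intentionally naive cubic enumeration
kept as an independent oracle for the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import (
    ElementMatch,
    NucleotideSequence,
    SpliceMotifModel,
    Tier,
    score_acceptor,
    score_branch,
    score_donor,
)

__all__ = ["SplicingParams", "CandidateIntron", "find_candidate_introns", "brute_force_candidates"]


@dataclass(frozen=True)
class SplicingParams:
    """Length and spacing constraints for candidate introns.

    The branch hexamer must end between ``branch_to_acceptor_min`` and
    ``branch_to_acceptor_max`` nt upstream of the acceptor trimer start.
    Defaults bracket the architectures observed in *Lipomyces* reticulon
    genes (introns 46-320 nt, branch-acceptor spacers 7-17 nt).
    """

    min_intron_len: int = 40
    max_intron_len: int = 400
    branch_to_acceptor_min: int = 5
    branch_to_acceptor_max: int = 25
    motif_model: SpliceMotifModel = field(default_factory=SpliceMotifModel)

    def __post_init__(self) -> None:
        if not 9 <= self.min_intron_len <= self.max_intron_len:
            raise ValueError("require 9 <= min_intron_len <= max_intron_len")
        if not 0 <= self.branch_to_acceptor_min <= self.branch_to_acceptor_max:
            raise ValueError("require 0 <= branch_to_acceptor_min <= branch_to_acceptor_max")


@dataclass(frozen=True)
class CandidateIntron:
    """One putative U2 intron, 0-based half-open on the scanned sequence.

    ``branch`` is the strongest branch hexamer serving the donor/acceptor
    pair (ties broken 3'-most, mimicking proximity to the acceptor);
    weaker alternates are retained in ``alternate_branches``.
    """

    start: int
    end: int
    donor: ElementMatch
    branch: ElementMatch
    acceptor: ElementMatch
    alternate_branches: tuple[ElementMatch, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def weak_dependent(self) -> bool:
        """True iff the donor or branch element is of weak tier."""
        return self.donor.tier is Tier.weak or self.branch.tier is Tier.weak

    @property
    def total_mismatches(self) -> int:
        return self.donor.primary_mismatches + self.branch.strength

    def sort_key(self) -> tuple[int, int, int]:
        return (self.length, self.total_mismatches, self.start)


def _check_region(seq: NucleotideSequence, region: tuple[int, int]) -> tuple[int, int]:
    lo, hi = region
    if not (0 <= lo <= hi <= len(seq)):
        raise ValueError(f"region {region} outside sequence of length {len(seq)}")
    return lo, hi


def _scan_donors(res: str, lo: int, hi: int, model: SpliceMotifModel) -> list[ElementMatch]:
    out = []
    for i in range(lo, hi - 5):
        m = score_donor(res[i : i + 6], model)
        if m is not None:
            out.append(m.at(i))
    return out


def _scan_acceptors(res: str, lo: int, hi: int, model: SpliceMotifModel) -> list[ElementMatch]:
    out = []
    for j in range(lo, hi - 2):
        m = score_acceptor(res[j : j + 3], model)
        if m is not None:
            out.append(m.at(j))
    return out


def _branches_for_acceptor(
    res: str, lo: int, acc_start: int, params: SplicingParams
) -> list[ElementMatch]:
    """Valid branch hexamers ending within the spacer window of one acceptor."""
    model = params.motif_model
    out = []
    for b_end in range(
        acc_start - params.branch_to_acceptor_max, acc_start - params.branch_to_acceptor_min + 1
    ):
        b = b_end - 6
        if b < lo:
            continue
        m = score_branch(res[b:b_end], model)
        if m is not None:
            out.append(m.at(b))
    return out


def _best_branch(branches: list[ElementMatch]) -> tuple[ElementMatch, tuple[ElementMatch, ...]]:
    # strongest wins; ties go to the 3'-most hexamer
    best = min(branches, key=lambda m: (m.strength, -m.start))
    alts = tuple(m for m in branches if m is not best)
    return best, alts


def find_candidate_introns(
    seq: NucleotideSequence, region: tuple[int, int], params: SplicingParams | None = None
) -> list[CandidateIntron]:
    """Enumerate all candidate U2 introns within ``region`` of ``seq``.

    Exhaustive over (donor, branch, acceptor) triples subject to the
    validity tiers, the length bounds, and the branch-to-acceptor spacer
    window; sorted by (length, combined mismatches, start).
    """
    params = params or SplicingParams()
    lo, hi = _check_region(seq, region)
    res = seq.residues
    donors = _scan_donors(res, lo, hi, params.motif_model)
    acceptors = _scan_acceptors(res, lo, hi, params.motif_model)
    out: list[CandidateIntron] = []
    for acc in acceptors:
        end = acc.start + 3
        branches = _branches_for_acceptor(res, lo, acc.start, params)
        if not branches:
            continue
        for don in donors:
            length = end - don.start
            if not params.min_intron_len <= length <= params.max_intron_len:
                continue
            usable = [b for b in branches if b.start >= don.start + 6]
            if not usable:
                continue
            best, alts = _best_branch(usable)
            out.append(CandidateIntron(don.start, end, don, best, acc, alts))
    out.sort(key=CandidateIntron.sort_key)
    return out


def brute_force_candidates(
    seq: NucleotideSequence, region: tuple[int, int], params: SplicingParams | None = None
) -> list[CandidateIntron]:
    """Cubic-enumeration oracle equivalent to :func:`find_candidate_introns`.

    Restricted to regions of at most 1000 nt.
    """
    params = params or SplicingParams()
    lo, hi = _check_region(seq, region)
    if hi - lo > 1000:
        raise ValueError("brute_force_candidates is limited to regions <= 1000 nt")
    model = params.motif_model
    res = seq.residues
    by_pair: dict[tuple[int, int], list[ElementMatch]] = {}
    matches: dict[tuple[int, int], tuple[ElementMatch, ElementMatch]] = {}
    for d in range(lo, hi):
        don = score_donor(res[d : d + 6], model) if d + 6 <= hi else None
        if don is None:
            continue
        for a in range(lo, hi):
            if a + 3 > hi:
                continue
            acc = score_acceptor(res[a : a + 3], model)
            if acc is None:
                continue
            length = a + 3 - d
            if not params.min_intron_len <= length <= params.max_intron_len:
                continue
            # triples whose branch violates the spacing window fail the
            # constraint check by construction and are skipped outright
            b_lo = max(lo, d + 6, a - 6 - params.branch_to_acceptor_max)
            b_hi = min(hi - 6, a - 6 - params.branch_to_acceptor_min)
            for b in range(b_lo, b_hi + 1):
                br = score_branch(res[b : b + 6], model)
                if br is None:
                    continue
                by_pair.setdefault((d, a), []).append(br.at(b))
                matches[(d, a)] = (don.at(d), acc.at(a))
    out = []
    for (d, a), branches in by_pair.items():
        don, acc = matches[(d, a)]
        best, alts = _best_branch(branches)
        out.append(CandidateIntron(d, a + 3, don, best, acc, alts))
    out.sort(key=CandidateIntron.sort_key)
    return out
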