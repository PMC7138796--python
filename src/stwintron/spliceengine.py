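"""Ordered intron excision by intron definition.

Intron definition pairs the nearest 5' and 3' splice sites across an
intron, so at each step the spliceosome excises the *smallest* valid
candidate within the residual intervening region.  Excision of a nested
internal intron can reconstitute the donor of an external intron, whose
excision then completes removal of the complex intervening sequence
(CIS) — the two-step splicing characteristic of stwintrons.

Alternative splicing arises when the smallest candidate depends on a
*weak* lariat branch point element: a functionally weak 3' splice-site
group may escape recognition, in which case the next-smallest candidate
(typically one large canonical intron spanning the whole CIS) is used
instead.  The engine therefore bifurcates the resolution exactly when
the smallest candidate's branch tier is weak, suppressing that branch/
acceptor group on the alternative path.  A weak donor alone does not
bifurcate: donor choice is driven by intron definition (smallest first),
not by donor canonicality.

Only paths that remove the intervening region completely are returned;
dead ends (a residual region with no remaining candidate) are dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .introncall import CandidateIntron, SplicingParams, find_candidate_introns
from .motifs import NucleotideSequence, Tier

__all__ = [
    "PathMode",
    "SplicingEvent",
    "SplicingPath",
    "SplicingOutcome",
    "excise",
    "resolve_splicing",
    "splicing_report",
]


class PathMode(str, enum.Enum):
    single_step = "single_step"
    two_step = "two_step"
    multi_step = "multi_step"


@dataclass(frozen=True)
class SplicingEvent:
    """One excision: coordinates in the molecule it acted on, plus the
    primary-transcript positions of the excised residues.

    ``primary_segments`` is a tuple of disjoint half-open intervals on
    the primary transcript; it has one element for an internal intron
    and may have several for an external intron whose residues flank a
    previously excised internal intron.
    """

    step: int
    intron: CandidateIntron
    primary_start: int
    primary_segments: tuple[tuple[int, int], ...]

    @property
    def excised_length(self) -> int:
        return self.intron.length


@dataclass(frozen=True)
class SplicingPath:
    events: tuple[SplicingEvent, ...]
    intermediates: tuple[NucleotideSequence, ...]
    mature: NucleotideSequence

    @property
    def mode(self) -> PathMode:
        n = len(self.events)
        if n == 1:
            return PathMode.single_step
        if n == 2:
            return PathMode.two_step
        return PathMode.multi_step

    @property
    def signature(self) -> tuple[int, ...]:
        """Ordered excised lengths — the path's compact identity."""
        return tuple(ev.excised_length for ev in self.events)


@dataclass(frozen=True)
class SplicingOutcome:
    precursor: NucleotideSequence
    region: tuple[int, int]
    paths: tuple[SplicingPath, ...]

    @property
    def mature_products(self) -> tuple[str, ...]:
        """Deduplicated mature residue strings, in path order."""
        seen: dict[str, None] = {}
        for p in self.paths:
            seen.setdefault(p.mature.residues)
        return tuple(seen)


def excise(seq: NucleotideSequence, intron) -> NucleotideSequence:
    """Remove ``[start, end)`` from ``seq`` and ligate the flanks.

    ``intron`` may be a :class:`CandidateIntron` or any ``(start, end)``
    pair.  Zero-length or out-of-bounds intervals are rejected.
    """
    if hasattr(intron, "start"):
        start, end = intron.start, intron.end
    else:
        start, end = intron
    if not 0 <= start < end <= len(seq):
        raise ValueError(
            f"cannot excise [{start}, {end}) from sequence of length {len(seq)}"
        )
    return seq.with_residues(seq.residues[:start] + seq.residues[end:])


def _cur_to_primary(pos: int, excised: list[tuple[int, int]]) -> int:
    """Map a current-molecule offset to the primary transcript.

    ``excised`` holds the already-removed primary intervals, disjoint and
    sorted by primary start.
    """
    p = pos
    for a, b in excised:
        if a <= p:
            p += b - a
        else:
            break
    return p


def _primary_segments(
    start: int, end: int, excised: list[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    """Primary intervals covered by current-molecule interval [start, end)."""
    segs: list[tuple[int, int]] = []
    p = _cur_to_primary(start, excised)
    remaining = end - start
    gaps = sorted(excised)
    while remaining > 0:
        nxt = next(((a, b) for a, b in gaps if a > p), None)
        if nxt is None:
            segs.append((p, p + remaining))
            break
        a, b = nxt
        take = min(remaining, a - p)
        if take > 0:
            segs.append((p, p + take))
            remaining -= take
        if remaining > 0:
            p = b
        else:
            break
    return tuple(segs)


def resolve_splicing(
    premrna: NucleotideSequence,
    cis_region: tuple[int, int],
    params: SplicingParams | None = None,
    max_paths: int = 16,
) -> SplicingOutcome:
    """Resolve ordered excision of ``cis_region`` by intron definition.

    Returns every complete path; the outcome has empty ``paths`` when
    the region contains no resolvable intron chain.  Raises if the
    number of complete paths exceeds ``max_paths``.
    """
    params = params or SplicingParams()
    lo, hi = cis_region
    if not (0 <= lo <= hi <= len(premrna)):
        raise ValueError(f"cis_region {cis_region} outside sequence of length {len(premrna)}")

    paths: list[SplicingPath] = []
    seen_signatures: set[tuple] = set()

    def recurse(
        molecule: NucleotideSequence,
        region_end: int,
        suppressed: frozenset[int],
        events: tuple[SplicingEvent, ...],
        intermediates: tuple[NucleotideSequence, ...],
        excised: list[tuple[int, int]],
    ) -> None:
        if region_end - lo < params.min_intron_len:
            # residual too short to hold any intron: resolution is complete
            # and any leftover residues (e.g. the 6-nt GUACGU retained by the
            # one-step L. starkeyi option) become exonic
            if not events:
                return
            key = tuple(ev.primary_segments for ev in events)
            if key not in seen_signatures:
                seen_signatures.add(key)
                paths.append(SplicingPath(events, intermediates, molecule))
                if len(paths) > max_paths:
                    raise ValueError(f"more than {max_paths} complete splicing paths")
            return
        candidates = [
            c
            for c in find_candidate_introns(molecule, (lo, region_end), params)
            if _cur_to_primary(c.acceptor.start, excised) not in suppressed
        ]
        if not candidates:
            return  # dead end: residual intronic region, no resolution
        smallest = candidates[0]
        if smallest.branch.tier is Tier.weak:
            # the weak 3' splice-site group may escape recognition:
            # alternative path with this branch/acceptor group suppressed
            recurse(
                molecule,
                region_end,
                suppressed | {_cur_to_primary(smallest.acceptor.start, excised)},
                events,
                intermediates,
                excised,
            )
        seg = _primary_segments(smallest.start, smallest.end, excised)
        nxt = excise(molecule, smallest)
        ev = SplicingEvent(
            step=len(events) + 1,
            intron=smallest,
            primary_start=_cur_to_primary(smallest.start, excised),
            primary_segments=seg,
        )
        recurse(
            nxt,
            region_end - smallest.length,
            suppressed,
            events + (ev,),
            intermediates + (nxt,),
            sorted(excised + list(seg)),
        )

    recurse(premrna, hi, frozenset(), (), (), [])
    paths.sort(key=lambda p: (len(p.events), p.signature))
    return SplicingOutcome(premrna, (lo, hi), tuple(paths))


def splicing_report(outcome: SplicingOutcome) -> dict:
    """Serializable per-path report of a splicing outcome.

    Coordinates are given both 0-based half-open (``*_0based``) and
    1-based inclusive (``*_1based``), on the primary transcript.
    """
    def _event(ev: SplicingEvent) -> dict:
        return {
            "step": ev.step,
            "excised_length": ev.excised_length,
            "primary_start_0based": ev.primary_start,
            "primary_start_1based": ev.primary_start + 1,
            "primary_segments_0based": [list(s) for s in ev.primary_segments],
            "primary_segments_1based": [[a + 1, b] for a, b in ev.primary_segments],
            "donor": ev.intron.donor.sequence,
            "donor_tier": ev.intron.donor.tier.value,
            "branch": ev.intron.branch.sequence,
            "branch_tier": ev.intron.branch.tier.value,
            "acceptor": ev.intron.acceptor.sequence,
        }

    return {
        "precursor_id": outcome.precursor.id,
        "precursor_length": len(outcome.precursor),
        "region_0based": list(outcome.region),
        "region_1based": [outcome.region[0] + 1, outcome.region[1]],
        "n_paths": len(outcome.paths),
        "paths": [
            {
                "mode": p.mode.value,
                "signature": list(p.signature),
                "events": [_event(ev) for ev in p.events],
                "intermediates": [m.residues for m in p.intermediates[:-1]],
                "mature": p.mature.residues,
            }
            for p in outcome.paths
        ],
        "mature_products": list(outcome.mature_products),
    }
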