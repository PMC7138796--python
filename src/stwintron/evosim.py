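"""Monte-Carlo simulation of stwintronisation.

New stwintrons can emerge inside an extant canonical U2 intron through
two kinds of endogenous events: small tandem duplications (4-7 nt,
compatible with repair of asymmetric double-strand breaks) anchored at
the functional donor element, and point substitutions that can mature
precursor sequences in the intron interior into functional internal 3'
splice sites.  The simulator applies both event types per generation to
replicate copies of a canonical intron, re-assesses splice-ability with
the intron-definition engine, and records if and when each replicate
first reaches a nested (stwintron) or alternatively spliced state.

Under the ``reject_lethal`` selection proxy, any generation whose events
leave the intervening sequence unresolvable (no complete splicing path,
hence a broken transcript) is discarded and the prior sequence retained
— a minimal stand-in for purifying selection.  ``neutral`` disables the
rejection for null comparisons.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .classify import StwintronClass, classify_nesting, derive_relation
from .introncall import SplicingParams
from .motifs import NucleotideSequence
from .spliceengine import resolve_splicing

__all__ = [
    "State",
    "EvolutionParams",
    "TrajectoryResult",
    "EmergenceStats",
    "duplicate_donor",
    "assess_state",
    "simulate_trajectories",
]

_BASES = "ACGU"


class State(str, enum.Enum):
    canonical = "canonical"
    stwintron_stricto = "stwintron_stricto"
    stwintron_lato = "stwintron_lato"
    alternative = "alternative"
    nonfunctional = "nonfunctional"


_EMERGED = {State.stwintron_stricto, State.stwintron_lato, State.alternative}


@dataclass(frozen=True)
class EvolutionParams:
    """Per-generation event rates and run geometry.

    ``dup_window`` is the half-open range of offsets eligible as the
    duplication anchor; the default covers the donor hexamer, so every
    duplication copies donor material.  ``dup_len_range`` is inclusive.
    """

    p_dup: float = 0.02
    dup_len_range: tuple[int, int] = (4, 7)
    dup_window: tuple[int, int] = (0, 6)
    mu: float = 0.002
    n_generations: int = 100
    n_reps: int = 50
    seed: int = 0
    selection: str = "reject_lethal"

    def __post_init__(self) -> None:
        if not 0 <= self.p_dup <= 1 or not 0 <= self.mu <= 1:
            raise ValueError("p_dup and mu must be probabilities")
        lo, hi = self.dup_len_range
        if not (1 <= lo <= hi <= 20):
            raise ValueError("dup_len_range must lie within [1, 20]")
        if self.selection not in ("reject_lethal", "neutral"):
            raise ValueError("selection must be 'reject_lethal' or 'neutral'")


def duplicate_donor(
    intron_seq: str | NucleotideSequence,
    anchor: int,
    dup_len: int,
    params: EvolutionParams | None = None,
) -> str | NucleotideSequence:
    """Tandemly duplicate ``dup_len`` residues starting at ``anchor``.

    The copy is inserted immediately after the original segment, so the
    sequence grows by exactly ``dup_len`` and residues outside the
    insertion are untouched.
    """
    params = params or EvolutionParams()
    lo, hi = params.dup_window
    if not lo <= anchor < hi:
        raise ValueError(f"anchor {anchor} outside duplication window [{lo}, {hi})")
    dlo, dhi = params.dup_len_range
    if not dlo <= dup_len <= dhi:
        raise ValueError(f"dup_len {dup_len} outside range [{dlo}, {dhi}]")
    res = intron_seq.residues if isinstance(intron_seq, NucleotideSequence) else intron_seq
    if anchor + dup_len > len(res):
        raise ValueError("duplicated segment extends past the sequence end")
    mutated = res[: anchor + dup_len] + res[anchor:]
    if isinstance(intron_seq, NucleotideSequence):
        return intron_seq.with_residues(mutated)
    return mutated


def assess_state(
    intervening_seq: str | NucleotideSequence,
    flank_context: tuple[str, str] = ("", ""),
    params: SplicingParams | None = None,
) -> tuple[State, StwintronClass | None]:
    """Splice-ability state of an intervening sequence in its context.

    canonical — a unique single-step resolution restores the junction;
    stwintron_stricto / stwintron_lato — the unique resolution is
    multi-step, classified through its nesting relation; alternative —
    at least two distinct mature products; nonfunctional — no complete
    path.
    """
    params = params or SplicingParams()
    res = (
        intervening_seq.residues
        if isinstance(intervening_seq, NucleotideSequence)
        else intervening_seq
    )
    f5, f3 = flank_context
    pre = NucleotideSequence(f5 + res + f3, "assess")
    region = (len(f5), len(f5) + len(res))
    try:
        outcome = resolve_splicing(pre, region, params)
    except ValueError:
        return State.alternative, None  # path explosion: treat as alternative
    if not outcome.paths:
        return State.nonfunctional, None
    if len(outcome.mature_products) >= 2:
        return State.alternative, None
    best = outcome.paths[0]  # fewest events first
    if len(best.events) == 1:
        return State.canonical, None
    relation = derive_relation(outcome, params)
    if relation is None:
        return State.stwintron_lato, None  # >2 consecutive excisions
    cls = classify_nesting(relation, params.motif_model)
    state = State.stwintron_stricto if cls.sensu.value == "stricto" else State.stwintron_lato
    return state, cls


@dataclass(frozen=True)
class TrajectoryResult:
    final_state: State
    emergence_generation: int | None
    class_at_emergence: StwintronClass | None
    event_log: tuple[tuple, ...]
    final_length: int = 0


@dataclass(frozen=True)
class EmergenceStats:
    fraction_by_state: dict[State, float]
    mean_emergence_time: float | None
    class_distribution: Counter

    @classmethod
    def from_trajectories(cls, trajectories: list[TrajectoryResult]) -> "EmergenceStats":
        n = len(trajectories)
        counts = Counter(t.final_state for t in trajectories)
        fractions = {s: counts.get(s, 0) / n for s in State}
        times = [t.emergence_generation for t in trajectories if t.emergence_generation is not None]
        classes = Counter(
            t.class_at_emergence.label for t in trajectories if t.class_at_emergence is not None
        )
        return cls(fractions, float(np.mean(times)) if times else None, classes)


def simulate_trajectories(
    start: str | NucleotideSequence,
    params: EvolutionParams,
    splicing: SplicingParams | None = None,
    flank_context: tuple[str, str] = ("", ""),
) -> tuple[EmergenceStats, list[TrajectoryResult]]:
    """Evolve replicate copies of a canonical intron.

    Per generation and replicate: one tandem duplication with
    probability ``p_dup`` (anchor uniform in the duplication window,
    length uniform in ``dup_len_range``), then independent per-site
    substitutions with probability ``mu`` each to a uniformly chosen
    different base.  The state is re-assessed after every generation
    with events.  Fully seeded and reproducible.
    """
    splicing = splicing or SplicingParams()
    res0 = start.residues if isinstance(start, NucleotideSequence) else start
    state0, _ = assess_state(res0, flank_context, splicing)
    if state0 is not State.canonical:
        raise ValueError(f"start sequence assesses as {state0.value}, not canonical")

    trajectories: list[TrajectoryResult] = []
    children = np.random.SeedSequence(params.seed).spawn(params.n_reps)
    for child in children:
        rng = np.random.default_rng(child)
        seq = res0
        state: State = State.canonical
        cls: StwintronClass | None = None
        emergence: int | None = None
        cls_at_emergence: StwintronClass | None = None
        log: list[tuple] = []
        for gen in range(1, params.n_generations + 1):
            prev_seq, prev_state, prev_cls = seq, state, cls
            changed = False
            if rng.random() < params.p_dup:
                lo, hi = params.dup_window
                anchors = [a for a in range(lo, min(hi, len(seq)))]
                dlo, dhi = params.dup_len_range
                dup_len = int(rng.integers(dlo, dhi + 1))
                anchors = [a for a in anchors if a + dup_len <= len(seq)]
                if anchors:
                    anchor = int(rng.choice(anchors))
                    seq = duplicate_donor(seq, anchor, dup_len, params)
                    log.append((gen, "dup", anchor, dup_len))
                    changed = True
            hits = np.flatnonzero(rng.random(len(seq)) < params.mu)
            if hits.size:
                chars = list(seq)
                for i in hits:
                    alternatives = _BASES.replace(chars[i], "")
                    chars[i] = alternatives[int(rng.integers(0, 3))]
                    log.append((gen, "sub", int(i), chars[i]))
                seq = "".join(chars)
                changed = True
            if not changed:
                continue
            state, cls = assess_state(seq, flank_context, splicing)
            if params.selection == "reject_lethal" and state is State.nonfunctional:
                seq, state, cls = prev_seq, prev_state, prev_cls
                log.append((gen, "rejected",))
                continue
            if emergence is None and state in _EMERGED:
                emergence = gen
                cls_at_emergence = cls
        trajectories.append(
            TrajectoryResult(state, emergence, cls_at_emergence, tuple(log), len(seq))
        )
    return EmergenceStats.from_trajectories(trajectories), trajectories
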