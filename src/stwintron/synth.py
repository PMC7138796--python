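"""Seeded generation of synthetic complex intervening sequences (CIS).

A :class:`CisTemplate` is an ordered list of literal splice-element
motifs and fixed-length spacers, together with a truth annotation (where
the internal intron sits, how long each constituent intron is, the
stwintron class, and the expected excision path signatures).  The four
built-in templates reproduce the printed CIS architectures of the
*Lipomyces* reticulon-like gene: *L. lipofer* [D4,5] (320 nt),
*L. suomiensis* [D7,8] (140 nt), *L. japonicus* [D7,8] (286 nt) and
*L. starkeyi* [D6,7] (252 nt, alternatively spliceable).

Spacer content is sampled under a decoy policy guaranteeing that the
realized sequence has no splice-competent motif outside the literals:
no window overlapping spacer residues may form a valid donor (GU plus
at most one mismatch over GURWGY positions 3-6), a valid branch element
(at most one mismatch vs DYURAY), or an acceptor trimer (HAG).  Literals
are sacrosanct and never repaired.  A final verification pass resolves
the realized CIS and requires the template's truth path signatures;
identical (template, seed, policy) always yields identical residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genemodel import GeneModel
from .io import Feature
from .introncall import SplicingParams
from .motifs import IUPAC_RNA, NucleotideSequence, normalize
from .spliceengine import resolve_splicing

__all__ = [
    "Lit",
    "Spacer",
    "TemplateTruth",
    "CisTemplate",
    "DecoyPolicy",
    "builtin_templates",
    "realize_template",
    "GeneFixture",
    "make_gene_fixture",
    "make_orthologue_set",
]

_BASES = np.array(["A", "C", "G", "U"])
_STOPS = {"UAA", "UAG", "UGA"}


@dataclass(frozen=True)
class Lit:
    """A literal motif token; residues are emitted verbatim."""

    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize(self.seq).residues)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Spacer:
    """A fixed-length run of synthetic (decoy-free) residues."""

    length: int

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("spacer length must be >= 0")

    def __len__(self) -> int:
        return self.length


@dataclass(frozen=True)
class TemplateTruth:
    """Expected nesting geometry and excision behaviour of a template."""

    internal_start: int
    internal_length: int
    external_length: int
    class_label: str
    sensu: str
    path_signatures: tuple[tuple[int, ...], ...]

    @property
    def insertion_offset_k(self) -> int:
        return self.internal_start

    @property
    def cis_length(self) -> int:
        return self.internal_length + self.external_length


@dataclass(frozen=True)
class CisTemplate:
    name: str
    tokens: tuple
    truth: TemplateTruth | None = None

    def __post_init__(self) -> None:
        if self.truth is not None:
            if self.truth.cis_length != self.total_length:
                raise ValueError(
                    f"template {self.name}: truth lengths "
                    f"({self.truth.cis_length}) != token total ({self.total_length})"
                )
            for sig in self.truth.path_signatures:
                # a path may leave a short 5' residue exonic (alternative
                # splice), so signatures sum to at most the CIS length
                if sum(sig) > self.total_length:
                    raise ValueError(
                        f"template {self.name}: path signature {sig} exceeds "
                        f"the CIS length {self.total_length}"
                    )

    @property
    def total_length(self) -> int:
        return sum(len(t) for t in self.tokens)

    def literal_spans(self) -> list[tuple[int, int]]:
        """Half-open intervals occupied by literal tokens."""
        spans, pos = [], 0
        for t in self.tokens:
            if isinstance(t, Lit):
                spans.append((pos, pos + len(t)))
            pos += len(t)
        return spans


@dataclass(frozen=True)
class DecoyPolicy:
    """Constraints on spacer content.

    ``forbid_donor_like``: GU-prefixed hexamers with at most this many
    mismatches over GURWGY positions 3-6 are forbidden in spacers.
    ``forbid_branch_like``: hexamers with at most this many mismatches
    vs DYURAY are forbidden.  ``forbid_spurious_acceptor_context``
    excludes every HAG trimer overlapping a spacer, which a fortiori
    leaves no acceptor within reach of any spurious branch element.
    """

    forbid_donor_like: int = 1
    forbid_branch_like: int = 1
    forbid_spurious_acceptor_context: bool = True
    max_rejection_attempts: int = 10000


def builtin_templates() -> dict[str, CisTemplate]:
    """The four printed *Lipomyces* CIS architectures."""
    t = {}
    t["lipofer_D45"] = CisTemplate(
        "lipofer_D45",
        (
            Lit("GUGA"),
            Lit("GUAAGU"), Spacer(131), Lit("ACUGAC"), Spacer(12), Lit("UAG"),
            Lit("GU"), Spacer(137), Lit("ACUAAC"), Spacer(10), Lit("UAG"),
        ),
        TemplateTruth(4, 158, 162, "[D4,5]", "stricto", ((158, 162),)),
    )
    t["suomiensis_D78"] = CisTemplate(
        "suomiensis_D78",
        (
            Lit("GUGAGUG"),
            Lit("GUAGGU"), Spacer(38), Lit("UCUAAC"), Spacer(8), Lit("UAG"),
            Lit("A"), Spacer(45), Lit("ACUGAC"), Spacer(17), Lit("UAG"),
        ),
        TemplateTruth(7, 61, 79, "[D7,8]", "lato", ((61, 79),)),
    )
    t["japonicus_D78"] = CisTemplate(
        "japonicus_D78",
        (
            Lit("GUAAGUG"),
            Lit("GUAAGU"), Spacer(135), Lit("ACUAAC"), Spacer(12), Lit("UAG"),
            Lit("A"), Spacer(97), Lit("AUUAAU"), Spacer(10), Lit("UAG"),
        ),
        TemplateTruth(7, 162, 124, "[D7,8]", "lato", ((162, 124),)),
    )
    # both printed internal branch candidates (AUUCAU and UUUAAU) are literals,
    # so the weak-branch bifurcation is exercised exactly as attested
    t["starkeyi_D67"] = CisTemplate(
        "starkeyi_D67",
        (
            Lit("GUACGU"),
            Lit("GUAAGU"), Spacer(75), Lit("AUUCAU"), Spacer(14),
            Lit("UUUAAU"), Spacer(10), Lit("CAG"),
            Lit("A"), Spacer(109), Lit("GCUGAC"), Spacer(7), Lit("UAG"),
        ),
        TemplateTruth(6, 120, 132, "[D6,7]", "lato", ((120, 132), (246,))),
    )
    return t


def _mm(pattern: str, window: str) -> int:
    return sum(w not in IUPAC_RNA[p] for p, w in zip(pattern, window))


def _window_forbidden(chars: list[str], mask: list[bool], end: int, policy: DecoyPolicy) -> bool:
    """Check windows ending at index ``end`` (inclusive) for decoy motifs.

    Only windows containing at least one spacer residue (mask False) are
    constrained; fully-literal windows belong to the template.
    """
    if end >= 5:
        hexamer = "".join(chars[end - 5 : end + 1])
        if not all(mask[end - 5 : end + 1]):
            if hexamer.startswith("GU") and _mm("RWGY", hexamer[2:]) <= policy.forbid_donor_like:
                return True
            if _mm("DYURAY", hexamer) <= policy.forbid_branch_like:
                return True
    if policy.forbid_spurious_acceptor_context and end >= 2:
        trimer = "".join(chars[end - 2 : end + 1])
        if not all(mask[end - 2 : end + 1]):
            if trimer[0] in "ACU" and trimer[1] == "A" and trimer[2] == "G":
                return True
    return False


def _violations(chars: list[str], mask: list[bool], policy: DecoyPolicy) -> bool:
    return any(_window_forbidden(chars, mask, i, policy) for i in range(len(chars)))


def realize_template(
    template: CisTemplate,
    seed: int,
    policy: DecoyPolicy | None = None,
    params: SplicingParams | None = None,
) -> tuple[NucleotideSequence, TemplateTruth | None]:
    """Fill a template's spacers with decoy-free pseudo-random residues.

    Deterministic for identical (template, seed, policy).  When the
    template carries a truth annotation, the realized sequence is
    verified to resolve to the truth path signatures; a sequence that
    fails the policy or the verification is resampled.  Raises after
    ``policy.max_rejection_attempts`` naming the offending spacer.
    """
    policy = policy or DecoyPolicy()
    params = params or SplicingParams()
    rng = np.random.default_rng(seed)
    attempts = 0
    while True:
        chars: list[str] = []
        mask: list[bool] = []
        for tok_idx, tok in enumerate(template.tokens):
            if isinstance(tok, Lit):
                chars.extend(tok.seq)
                mask.extend([True] * len(tok))
                continue
            base_len = len(chars)
            while True:  # sample this spacer; restart it on dead ends
                ok = True
                for _ in range(tok.length):
                    order = rng.permutation(4)
                    for bi in order:
                        chars.append(_BASES[bi])
                        mask.append(False)
                        if _window_forbidden(chars, mask, len(chars) - 1, policy):
                            chars.pop()
                            mask.pop()
                        else:
                            break
                    else:
                        ok = False  # no base admissible: dead end
                        break
                if ok:
                    break
                del chars[base_len:]
                del mask[base_len:]
                attempts += 1
                if attempts >= policy.max_rejection_attempts:
                    raise RuntimeError(
                        f"decoy-free sampling exhausted after {attempts} attempts "
                        f"at spacer (token {tok_idx}) of template {template.name}"
                    )
        seq = NucleotideSequence("".join(chars), f"{template.name}|seed={seed}")
        # windows running from a spacer into the following literal are only
        # checkable now; a violation discards the whole realization
        if _violations(chars, mask, policy):
            attempts += 1
        elif template.truth is not None:
            outcome = resolve_splicing(seq, (0, len(seq)), params)
            if set(p.signature for p in outcome.paths) == set(template.truth.path_signatures):
                return seq, template.truth
            attempts += 1
        else:
            return seq, None
        if attempts >= policy.max_rejection_attempts:
            raise RuntimeError(
                f"realization of template {template.name} failed verification "
                f"after {attempts} attempts"
            )


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n stop-free codons."""
    out = []
    while len(out) < n:
        codon = "".join(_BASES[rng.integers(0, 4, 3)])
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


@dataclass(frozen=True)
class GeneFixture:
    genome: NucleotideSequence
    model: GeneModel
    features: tuple[Feature, ...]
    truth: TemplateTruth | None
    cis_region: tuple[int, int]


def make_gene_fixture(
    template: CisTemplate,
    exon5_len: int,
    exon3_len: int,
    seed: int,
    policy: DecoyPolicy | None = None,
    params: SplicingParams | None = None,
) -> GeneFixture:
    """Embed a realized CIS between two exons with an intact reading frame.

    The coding sequence starts at the first exon base and runs across
    the predicted mature junction; residues of the 3' exon beyond the
    last full codon are left untranslated.  The truth GFF3 features
    carry the intron nesting as Parent-linked intron features.
    """
    if exon5_len < 3 or exon3_len < 3:
        raise ValueError("exon lengths must be >= 3 to hold a reading frame")
    ss = np.random.SeedSequence(seed)
    s_cis, s_exon = (int(c.generate_state(1)[0]) & 0x7FFFFFFF for c in ss.spawn(2))
    cis, truth = realize_template(template, s_cis, policy, params)
    rng = np.random.default_rng(s_exon)
    cds_len = exon5_len + exon3_len - (exon5_len + exon3_len) % 3
    coding = _random_codons(rng, cds_len // 3)
    utr = "".join(_BASES[rng.integers(0, 4, exon5_len + exon3_len - cds_len)])
    mature = coding + utr
    exon1, exon2 = mature[:exon5_len], mature[exon5_len:]
    L = len(cis)
    genome = NucleotideSequence(exon1 + cis.residues + exon2, f"{template.name}_gene|seed={seed}")
    model = GeneModel(
        gene_id=f"{template.name}_gene",
        exons=((0, exon5_len), (exon5_len + L, exon5_len + L + exon3_len)),
        coding_start=0,
        coding_end=exon5_len + L + cds_len - exon5_len,
        strand="+",
        species=template.name,
        genome=genome,
    )
    sid = genome.id
    gid = model.gene_id
    feats = [
        Feature(sid, "gene", 0, len(genome), attributes={"ID": gid}),
        Feature(sid, "mRNA", 0, len(genome), attributes={"ID": f"{gid}.t1", "Parent": gid}),
        Feature(sid, "exon", 0, exon5_len, attributes={"ID": f"{gid}.e1", "Parent": f"{gid}.t1"}),
        Feature(
            sid, "exon", exon5_len + L, exon5_len + L + exon3_len,
            attributes={"ID": f"{gid}.e2", "Parent": f"{gid}.t1"},
        ),
    ]
    if truth is not None:
        cis_lo = exon5_len
        feats.append(
            Feature(
                sid, "intron", cis_lo, cis_lo + L,
                attributes={
                    "ID": f"{gid}.cis",
                    "Parent": f"{gid}.t1",
                    "stwintron_class": truth.class_label,
                    "sensu": truth.sensu,
                    "nesting": "external",
                },
            )
        )
        feats.append(
            Feature(
                sid, "intron",
                cis_lo + truth.internal_start,
                cis_lo + truth.internal_start + truth.internal_length,
                attributes={
                    "ID": f"{gid}.internal",
                    "Parent": f"{gid}.cis",
                    "nesting": "internal",
                },
            )
        )
    return GeneFixture(genome, model, tuple(feats), truth, (exon5_len, exon5_len + L))


#: default geometry of the 5-position orthologue emulation: 0-based codon
#: index and intron phase of each conserved position (position 1 is the
#: phase-one site occupied by the CIS-bearing intron).
_ORTHO_POSITIONS: tuple[tuple[int, int], ...] = ((5, 1), (12, 0), (19, 2), (26, 0), (33, 1))
_ORTHO_PROTEIN_LEN = 40

#: a short canonical U2 intron used at every occupied position (46 nt,
#: the size of the smallest attested intron at the CIS position)
_ORTHO_INTRON_TEMPLATE = CisTemplate(
    "ortho_intron",
    (Lit("GUAAGU"), Spacer(23), Lit("ACUAAC"), Spacer(8), Lit("UAG")),
)


def make_orthologue_set(
    spec: dict[str, set[int] | list[int] | tuple[int, ...]],
    seed: int,
):
    """Toy orthologue gene models realizing a given intron occupancy.

    ``spec`` maps at most nine species names to the subset of the five
    conserved positions each occupies.  All species share one coding
    sequence (hence a gap-free protein alignment) and differ only in
    which positions carry an intron.  Returns ``(models, alignment)``
    where ``alignment`` is a :class:`Bio.Align.MultipleSeqAlignment`.
    """
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if len(spec) > 9:
        raise ValueError("at most 9 species supported")
    for sp, positions in spec.items():
        if not set(positions) <= {1, 2, 3, 4, 5}:
            raise ValueError(f"species {sp!r}: positions must be within 1..5")
    ss = np.random.SeedSequence(seed)
    s_cds, s_intron = (int(c.generate_state(1)[0]) & 0x7FFFFFFF for c in ss.spawn(2))
    cds = _random_codons(np.random.default_rng(s_cds), _ORTHO_PROTEIN_LEN)
    intron_seq, _ = realize_template(_ORTHO_INTRON_TEMPLATE, s_intron)
    protein = str(Seq(cds).translate())
    models = []
    for sp, positions in spec.items():
        offsets = sorted(3 * _ORTHO_POSITIONS[p - 1][0] + _ORTHO_POSITIONS[p - 1][1]
                         for p in set(positions))
        pieces, exons, gpos, prev = [], [], 0, 0
        for off in offsets:
            pieces.append(cds[prev:off])
            exons.append((gpos, gpos + (off - prev)))
            gpos += (off - prev)
            pieces.append(intron_seq.residues)
            gpos += len(intron_seq)
            prev = off
        pieces.append(cds[prev:])
        exons.append((gpos, gpos + len(cds) - prev))
        gpos += len(cds) - prev
        genome = NucleotideSequence("".join(pieces), sp)
        models.append(
            GeneModel(
                gene_id=f"{sp}_rtl",
                exons=tuple(exons),
                coding_start=0,
                coding_end=gpos,
                strand="+",
                species=sp,
                genome=genome,
            )
        )
    alignment = MultipleSeqAlignment(
        [SeqRecord(Seq(protein), id=sp, description="") for sp in spec]
    )
    return models, alignment
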