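# Methods

## Scope and model organism

`stwintron` analyses complex intervening sequences (CIS) made of nested
U2-type spliceosomal introns — *stwintrons* (spliceosomal twin introns)
— as found at a conserved position of the gene for a reticulon-like
protein in yeasts of the genus *Lipomyces*. The package covers the full
desk-scale pipeline: splice-element scoring, exhaustive candidate-intron
enumeration, ordered excision by intron definition with alternative-path
enumeration, stwintron classification, gene-model arithmetic and intron
position conservation, seeded synthetic-sequence generation, and a
Monte-Carlo simulator of the stwintronisation mechanism by which such
nested introns can arise inside a pre-existing canonical intron.

## Splice-element model

U2 introns are recognised through three elements: the 5' donor (fungal
consensus `GURWGY`), the lariat branch point element (`DYURAY`, branch
adenosine at position 5) and the 3' acceptor (`HAG`).

* **Donor.** Validity requires the literal `GU` dinucleotide at
  positions 1–2 plus at most one mismatch over consensus positions 3–6
  (default `donor_max_mismatch = 1`). Zero mismatches is *strong*, one
  is *weak*. This keeps attested functional donors such as `GUACGU` and
  `GUAGGU` valid while ranking them below the ideal `GUAAGU`/`GUGAGU`.
* **Branch.** Elements such as `UUUAAU` match `DYURAY` perfectly yet
  behave as functionally weak, while `ACUAAC`, `ACUGAC`, `UCUAAC` and
  `GCUGAC` behave as fully canonical. A single primary consensus cannot
  express that distinction, so the model scores a second, strict
  reference `HCURAC` and defines the element's *strength* as the sum of
  mismatches against both patterns. Validity requires at most one
  primary mismatch and strength below 5; strength ≤ 1 is strong. This
  is the minimal two-tier rule consistent with every strong/weak
  judgement the resolved splicing outcomes require (strengths:
  ACUAAC 0, UCUAAC 0, ACUGAC 0, GCUGAC 1 — strong; UUUAAU 2, AUUAAU 2,
  AUUCAU 4 — weak). It is a formalisation choice, not a trained model.
* **Acceptor.** Binary `HAG`; acceptors are never graded because no
  observed outcome requires it.

The internal alphabet is RNA; DNA input is transcribed on ingest and all
file output is written back as DNA.

## Candidate enumeration

A candidate intron is a (donor, branch, acceptor) triple with the intron
length inside `[min_intron_len, max_intron_len]` (default 40–400 nt,
bracketing the observed 46–320 nt with margin) and the branch hexamer
ending 5–25 nt upstream of the acceptor start (observed spacers are
7–17 nt). Enumeration is exhaustive within a caller-designated region.
When several branch hexamers serve one donor/acceptor pair the candidate
carries the strongest, ties broken 3'-most (proximity to the acceptor);
the others are retained as alternates. A deliberately naive cubic
enumerator (`brute_force_candidates`, regions ≤ 1000 nt) serves as an
independent oracle in the tests.

Note one consequence of the spacing window: in the *L. starkeyi* CIS the
printed internal branch candidate `AUUCAU` sits 30 nt upstream of the
internal `CAG` acceptor, outside the default window, so the equally weak
`UUUAAU` (10 nt spacer) is the scored branch. The resolution outcome is
identical either way since both are weak.

## Ordered excision (intron definition)

The engine operationalises intron definition as *smallest candidate
first*: at each step the shortest valid candidate inside the residual
intervening region is excised; ties break by fewest combined element
mismatches, then 5'-most start. Excising a nested internal intron
re-ligates the flanks and can reconstitute the donor of the external
intron, which the next round then excises — the two-step splicing
characteristic of stwintrons.

**Bifurcation.** Alternative paths arise exactly when the smallest
candidate's *branch* element is weak: a functionally weak 3'
splice-site group may escape spliceosomal recognition, so the engine
also explores the path on which that branch/acceptor group is
suppressed for the remainder of the resolution and the next-smallest
candidate is taken. A weak donor alone never bifurcates — donor choice
falls out of intron definition (the smallest intron wins), and making
weak donors bifurcate would predict a second, unobserved product for
the *L. suomiensis* CIS, whose internal donor `GUAGGU` is weak but whose
internal 3' group is perfect. This single rule reproduces all four
attested outcomes: one path each for the *L. lipofer*, *L. suomiensis*
and *L. japonicus* templates and exactly two for *L. starkeyi*
(two-step 120 + 132 nt, or one 246-nt canonical intron that leaves the
6-nt `GUACGU` donor copy exonic).

**Completion.** A path is complete when the residual region is shorter
than `min_intron_len` — nothing excisable can remain, and any leftover
residues become exonic (that is precisely the 6-nt-longer mRNA of the
*L. starkeyi* one-step option). A residual region that still could hold
an intron but has no remaining candidate is a dead end and the path is
discarded; if no path completes, the region is nonfunctional. Paths are
capped (default 16) to guarantee termination on adversarial input;
exceeding the cap raises.

The engine operates on a designated intervening region, not on whole
unannotated transcripts: exon boundaries are always supplied by the
caller or the truth annotation, mirroring how the junction is known from
orthology in practice.

## Classification

For a nesting with insertion offset k (external nucleotides 5' of the
internal intron), k ∈ 1..5 interrupts the donor hexamer → `[Dk,k+1]`
*sensu stricto*; k = 6 (abutting donors) and k = 7 (donors one nt
apart) → *sensu lato*. Larger k is tested against the external branch
and acceptor elements (`[Lm,m+1]`, `[Am,m+1]`, both stricto, numbering
positions within the element); any other insertion point is labelled
`[Dk,k+1]` *sensu lato* with an `unattested` flag, keeping the
classifier total without inventing biology. Two-step paths whose second
intron does not wrap around the first (k < 1, possible on evolved
sequences) yield no nesting relation at all.

## Synthetic templates and the decoy policy

Templates are token lists of literal motifs and fixed-length spacers;
the four built-ins transcribe the printed CIS architectures
(320/140/286/252 nt). Spacer residues are sampled base-by-base under a
rejection policy: no window containing a spacer residue may form a
valid donor (GU + ≤ 1 mismatch), a valid branch (≤ 1 primary mismatch
vs `DYURAY`), or any `HAG` trimer. Excluding all spurious acceptors is
stricter than strictly necessary (no acceptor near a spurious branch
would suffice) but guarantees that *every* valid candidate in a
realized sequence is built from literal elements, making the template's
truth annotation exhaustive. Literals are never repaired. Dead ends
restart the affected spacer; windows that run from a spacer into the
following literal are checked after assembly; and a final verification
resolves the realized CIS and requires the truth path signatures.
Identical (template, seed, policy) yields identical bytes. The
realization is rejection-sampled, so the *sequence* depends on the
seed but the architecture quantities (lengths, k, class, signatures)
are seed-invariant by construction.

Gene fixtures embed a realized CIS between two exons; exon sizes are
counted the way gene diagrams usually count them (start codon to first
intron, last intron to stop codon), so the CDS is truncated to the
largest multiple of 3 and the remainder is 3' UTR. Coding residues are
stop-free sampled codons. The orthologue generator emulates a
nine-species, five-position occupancy pattern with one shared coding
sequence (hence a gap-free protein alignment) and a 46-nt canonical
intron at each occupied position; position 1 is phase one, as attested
for the CIS-bearing intron.

## Gene-model arithmetic and conservation mapping

Intron phase is the cumulative coding length upstream of the intron
(transcription order) modulo 3. Intron positional identity across
orthologues is the pair (alignment column of the codon containing the
insertion point, phase); two introns are the same position iff both
match. Alignments are consumed as given (aligned FASTA); computing them
is out of scope. The conservation matrix is validated only on synthetic
orthologue fixtures — real-genome intron counts and the phylogeny
itself are not reproducible at desk scale and are excluded.

## Stwintronisation simulator

Each replicate of a canonical intron evolves per generation by (i) one
tandem duplication with probability `p_dup` (length uniform on 4–7 nt,
anchor uniform over offsets 0–5, i.e. the donor hexamer, emulating
repair of an asymmetric double-strand break with a small 3' overhang)
and (ii) independent per-site substitutions with probability `mu` to a
uniformly chosen different base. There are no other indels. After every
generation with events the intervening sequence is re-assessed:
canonical (unique single-step resolution), stwintron stricto/lato
(unique multi-step resolution, classified through its nesting),
alternative (≥ 2 mature products), or nonfunctional (no complete path).
Under the `reject_lethal` selection proxy a generation that leaves the
region unresolvable is discarded and the previous state retained;
`neutral` disables this for null comparisons. Defaults (`p_dup` 0.02,
`mu` 0.002, 100 generations, 50 replicates) are arbitrary but
deliberately event-sparse; the rates are not calibrated to any real
mutational process and the simulator makes no claim about evolutionary
time scales or fixation — it explores which routes *can* produce which
configurations.

One empirical observation from the simulator is worth recording: donor
duplication alone (substitution rate zero) can occasionally assemble a
complete nested configuration, because the donor consensus `GUAAGU`
itself contains an acceptor-like `AAG` and shifted tandem repeats of
donor material can create `UAG` trimers and branch-like hexamers. At a
high duplication rate (`p_dup = 0.5`, 12 generations) a fraction of
order 1% of replicates escapes the canonical state without any point
mutation. The two proposed routes — donor duplication and internal
3'-site maturation by substitution — are therefore not strictly
independent requirements, though the duplication-only route is rare.

## Numerical and engineering choices

* Coordinates are 0-based half-open internally, 1-based inclusive only
  in GFF3 files and user-facing text; JSON reports carry both, labelled.
* All randomness flows through `numpy.random.default_rng`/`SeedSequence`
  with explicit integer seeds; replicate streams are spawned, never
  shared.
* Ties in candidate ordering are broken deterministically (length, then
  combined mismatches, then start); branch attachment ties break
  3'-most.
* Degenerate inputs: empty sequences are legal only as ligation
  products; zero-length excisions, inverted regions, out-of-range
  insertion offsets and non-nucleotide characters are rejected with
  positional error messages.
* Problem sizes: the test suite and the acceptance script work at the
  printed template sizes (140–320 nt), 100 realization seeds per
  template, brute-force oracle comparisons up to 1000 nt, and simulator
  runs of a few hundred replicates over ≤ 15 generations — each check
  completes in seconds on one CPU.

## What passing tests do and do not show

The synthetic generator reproduces the printed element architectures
with decoy-free spacers; real intronic sequence is not decoy-free, and
real spliceosomes weigh context the two-tier model ignores (e.g.
branch-to-donor distance constraints, exonic splicing enhancers,
expression level). Recovering the printed intron sizes and classes from
the templates therefore validates the *logic* of intron-definition
resolution and classification, not a predictive model of splicing in
arbitrary genomic sequence. Likewise the conservation mapping is shown
correct on fixtures with a gap-free alignment; gapped alignments
exercise the same column arithmetic but were not validated against a
curated real data set.

## Known limitations

* No position-weight-matrix or species-specific motif learning; tiers
  are rule-based.
* No quantitative isoform abundances (the observed bias between the two
  *L. starkeyi* products is qualitative only).
* `[L]`/`[A]` classes and insertion points between elements beyond
  k = 7 are handled but unattested in the data the package emulates.
* The simulator has no population genetics: no drift, no fixation, no
  effective population size.
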