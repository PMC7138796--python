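# stwintron

Detection, resolution and simulation of **stwintrons** — spliceosomal
twin introns — in nucleotide sequences.

A stwintron is a complex intervening sequence (CIS) of two nested
U2-type introns in which the internal intron must be excised first:
only then is a functional splice element of the external intron
reconstituted, allowing a second, standard splicing reaction to remove
the rest. In the gene for a reticulon-like protein of *Lipomyces*
yeasts, a single conserved intron position carries three differently
nested CIS — `[D4,5]` (internal intron inside the external donor),
`[D6,7]` (abutting donors) and `[D7,8]` (donors one nucleotide apart) —
and the `[D6,7]` form is alternatively spliceable either as a stwintron
or as one large canonical intron. This package implements the whole
analysis as a reusable toolkit: who it is for is anyone studying nested
or alternatively excised spliceosomal introns in compact fungal
genomes.

## The model

U2 introns are scored through their three conserved elements
(5'-donor `GURWGY`, lariat branch element `DYURAY`, 3'-acceptor `HAG`),
each assigned a *strong*/*weak* canonicality tier; branch elements are
graded against both `DYURAY` and a strict secondary reference `HCURAC`
so that perfectly consensus-matching but functionally weak elements
(e.g. `UUUAAU`) are distinguished from fully canonical ones
(`ACUAAC`). Splicing is resolved by **intron definition**: the nearest
5' and 3' splice sites pair across the intron, operationalised as
excision of the smallest valid candidate first. When the smallest
candidate depends on a weak branch element, the resolution bifurcates —
the weak 3' splice-site group may escape recognition — which is exactly
what produces the two alternative *L. starkeyi* products.

Modules: `motifs` (element scoring), `introncall` (candidate
enumeration + brute-force oracle), `spliceengine` (ordered excision,
path enumeration), `classify` (stwintron taxonomy), `genemodel`
(phases, mature mRNA, intron position conservation), `synth` (seeded
template realization with decoy-free spacers), `evosim`
(stwintronisation Monte-Carlo), `io`/`cli` (FASTA/GFF3 and a
command-line layer). See `docs/methods.md` for the full model
description.

## Worked example

Realize the *L. starkeyi* `[D6,7]` CIS template, resolve its splicing
and classify the nesting:

```python
from stwintron import (builtin_templates, realize_template,
                       resolve_splicing, derive_relation, classify_nesting)

seq, truth = realize_template(builtin_templates()["starkeyi_D67"], seed=1)
out = resolve_splicing(seq, (0, len(seq)))
print(f"CIS length: {len(seq)}")
for p in out.paths:
    print(f"{p.mode.value}: excised {list(p.signature)} nt -> mature {len(p.mature)} nt")
rel = derive_relation(out)
cls = classify_nesting(rel)
print(f"class {cls.label} (sensu {cls.sensu.value}), k = {rel.insertion_offset_k}")
print(f"internal {len(rel.internal_seq)} nt, external {len(rel.external_seq)} nt")
```

prints

```
CIS length: 252
single_step: excised [246] nt -> mature 6 nt
two_step: excised [120, 132] nt -> mature 0 nt
class [D6,7] (sensu lato), k = 6
internal 120 nt, external 132 nt
```

The 252-nt CIS is removable two ways: one 246-nt canonical intron that
leaves the 6-nt 5' donor copy (`GUACGU`) in the mature message, or a
120-nt internal intron followed by the 132-nt external intron that
removes everything — the two mRNA isoforms differ by exactly those
6 nt. The insertion offset k = 6 means the two donor elements abut, so
the nesting is a stwintron *sensu lato* of class `[D6,7]`.

The same pipeline runs from the shell:

```bash
stwintron make-synthetic --template starkeyi_D67 --seed 1 --outdir out/
stwintron splice --fasta out/starkeyi_D67.fasta --out report.json
stwintron classify --fasta out/starkeyi_D67.fasta --out class.json
```

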