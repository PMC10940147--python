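# mitobe

A design and quantification toolkit for **strand-selective mitochondrial
base editors** — the dimeric editors that pair a TALE-fused nickase with a
TALE-fused single-strand deaminase (TadA8e-V106W for A→G, rAPOBEC1 for
C→T) to edit human mtDNA without double-strand breaks.

It is written for people designing such editors or analysing their amplicon
sequencing readouts: given a circular genome and a requested base change it
finds nickase recognition sites, predicts which strand is nicked and which
is edited, enumerates and ranks complete dimeric designs with their editing
windows and bystanders, computes genome-wide designability, classifies
pathogenic point mutations by the chemistry needed to correct them, and
calls edits from treated/control per-position base-count tables.

## The model

A dimeric design places a left TALE arm on the top strand and a right arm
on the bottom strand around a spacer (the **editing window**, 8–24 bp by
default). One arm carries the nickase, the other the deaminase. For the
motif-anchored nickases MutH (5′-↓GATC-3′, palindromic) and MutH*
(relaxed, 5′-GATN-3′ by default) the nicked strand is set by the **gap**
*g* between the nickase arm's binding site and the motif:

```
g ∈ [0, 4]  →  nick the strand opposite the nickase-TALE's recognition strand
g ∈ [5, 9]  →  nick the TALE recognition strand itself
g ≥ 10      →  uncharacterized (rejected)
```

with left arms recognizing the top strand and right arms the bottom.
Deamination happens on the transiently single-stranded region and the
product is retained on the strand **not** nicked, so the edited strand is
always the non-nicked one; for MutH* only the motif-carrying strand can be
cut. Nt.BspD6I(C) needs no motif and nicks its TALE's recognition strand at
any gap. Every substrate base in the window on the edited strand is a
potential **bystander**. A position is **designable** for a nickase when it
lies within ±20 bp of one of its nick positions.

Quantification follows the standard amplicon analysis: per-position
conversion frequency *k*/*n*, a two-sided Fisher exact test against the
matched control (significant at *P* < 0.05), a 0.10 % sequencing-error
noise floor, a SNP flag for variants present in the control, and strand
attribution (for an A→G editor, ref-A conversions are top-strand edits and
ref-T conversions bottom-strand edits).

## Worked example

```python
from mitobe import (DesignParams, EditRequest, MUTH, enumerate_designs,
                    plant_motif, random_circular_genome)

genome = plant_motif(random_circular_genome(400, gc=0.45, seed=23), "GATC", 200)
request = EditRequest(position=203, ref="T", desired="C")
candidates, reasons = enumerate_designs(genome, request, MUTH,
                                        DesignParams(require_preceding_t=False))
best = candidates[0]
print(len(candidates), best.gap, best.nick_strand, best.edited_strand,
      len(best.window), len(best.bystanders))
```

prints `3875 0 top bottom 8 0`: 3875 geometrically legal designs; the
top-ranked one anchors the motif 0 bp from the right (nickase) arm, nicks
the top strand, therefore retains the edit on the bottom strand — exactly
what a T>C request requires, since the actually edited A sits on the
bottom strand — with an 8-bp window containing no bystander adenine.

The `examples/` directory holds one short script per capability (site
scanning, design, designability, mutation classification, quantification);
each prints its numbers with a line on what they mean. The same
functionality is exposed as a thin CLI:

```bash
mitobe scan --genome ref.fa --nickase 'MutH*'
mitobe design --genome ref.fa --position 11778 --ref G --alt A --nickase auto
mitobe designability --genome ref.fa --nickase MutH --nickase 'MutH*' --flank 20
mitobe classify --genome ref.fa --catalog mutations.tsv
mitobe quantify --treated t.tsv --control c.tsv --editor ABE
mitobe simulate genome|counts|catalog ...
```

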