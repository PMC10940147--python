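# Methods

## Scope and model

`mitobe` models the design logic of dimeric, strand-selective mitochondrial
base editors and the statistics of their amplicon readout. The biological
model it encodes:

1. **Geometry.** Two TALE arms flank a spacer (the editing window). Left
   arms recognize the top strand (the strand as written in the FASTA),
   right arms the bottom strand. Arm length defaults to 14–18 recognized
   bases, with the conventional requirement of a T immediately 5′ of the
   binding site on the arm's strand (both configurable; the RVD code is
   fixed at A→NI, C→HD, G→NN, T→NG).
2. **Nick-strand rule.** For the motif-anchored nickases (MutH, 5′-↓GATC-3′;
   MutH*, relaxed) the gap between the nickase arm's window-proximal edge
   and the nearest motif edge decides the cut strand: gaps 0–4 bp cut the
   strand opposite the TALE's recognition strand, 5–9 bp cut the
   recognition strand, and ≥10 bp is treated as uncharacterized and
   rejected rather than guessed. MutH* cuts only the strand that carries
   its motif (the GATC window is the palindromic special case where both
   strands carry it). Nt.BspD6I(C) has no motif and cuts its TALE's
   recognition strand at any gap; having no motif edge, its nick is placed
   at the nickase arm's window-proximal edge.
3. **Edited strand.** Deamination survives on the strand *not* nicked.
   Every window position whose edited-strand base equals the deaminase
   substrate (A for the A→G editor, C for the C→T editor) is editable;
   those other than the target are bystanders, motif-internal bases
   included — nicking exposes the whole spacer.
4. **Designability.** A genome position is designable for a nickase when
   its circular distance to some nick position is ≤ 20 bp (closed window,
   41 positions per isolated site). The nick position, not the motif
   midpoint, anchors the window. Density tracks count recognition sites
   per non-overlapping 40-bp tile by default.

## Coordinates and conventions

Internal coordinates are 0-based half-open on the top strand with modular
(circular) indexing; all user-facing positions are 1-based to match mtDNA
mutation nomenclature (m.11778G>A). Genomes are circular by default; a
linear topology is available for amplicon references and disables
wraparound. BED/bedGraph exports split origin-spanning intervals in two.
An N in the genome matches no motif letter, including pattern N
(conservative site calling). Palindromic duplex windows (a GATC matched on
both strands at the same window) are reported once by default
(`dedup_palindromes=False` reports both); MutH* defaults to the GATN motif,
with GATD available where the strict reading (GATC rejected in vivo) is
wanted.

The nick of MutH/MutH* sits 5′ of the motif's G on the motif-carrying
strand (`nick_offset = 0`): top-strand sites nick at the motif start,
bottom-strand sites at motif start + 3 in top-strand coordinates.

## Design enumeration and scoring

For a requested duplex change (one of A>G, T>C, C>T, G>A — the four
deamination-reachable changes) the enumerator loops over window lengths
(8–24 bp by default, a default taken from the characterized range at a
single locus and therefore configurable), window offsets containing the
target, motif anchors wholly inside the window, the nickase-arm side, and
arm lengths, keeping a candidate only if (i) the gap is in the rule table,
(ii) MutH*'s predicted cut strand equals the motif strand, (iii) the
predicted edited strand carries the substrate required by the request, and
(iv) the arm constraints hold. The score is a transparent heuristic, not an
efficiency model:

    score = −1.0·(bystanders) + 0.5·[gap = 3, MutH/MutH*]
            + 0.25·[nickase ∈ {MutH, MutH*}] + 0.25·(target centrality)

The gap-3 bonus reflects the empirically best-performing spacing; the class
prior encodes the stronger strand preference of MutH/MutH* over
Nt.BspD6I(C). Ties break deterministically by (window length, window
start, nickase side), so output ordering is reproducible. Weights live in
`DesignParams`.

The TALE off-target scan is a plain circular Hamming scan of the arm's
binding sequence over both strands (0–2 mismatches), each hit annotated
with a ±50 bp flank.

## Quantification

Input is a pileup-derived count table (position, ref, nA, nC, nG, nT), not
alignments; producing it from BAMs is standard tooling (`samtools mpileup`)
and out of scope. Per position: conversion frequency = product count /
depth; two-sided Fisher exact test (scipy) of (edited, unedited) treated
vs control; significance requires *P* < α (0.05), treated frequency
strictly above the noise floor (0.001, the 0.10 % deep-sequencing error
level), and no SNP flag (control frequency above the same floor). No
multiple-testing correction by default, matching the raw-threshold
convention; Benjamini–Hochberg is available. Product purity = intended
product / all non-reference reads, undefined (None) with no non-reference
observation. The strand bias index is the top-attributed frequency sum
over the total; 1.0 means pure top-strand editing.

## Synthetic data

The generators emulate the statistical structure the analysis assumes:
i.i.d. bases at a set GC content for genomes; binomial edit counts at
per-position rates (efficiency split across strands by `strand_split`,
across products by `purity`) over a uniform error rate for count tables,
with the control carrying error only. They do not model alignment
artifacts, PCR/UMI duplication, position-dependent error, heteroplasmy
drift, or linked editing along reads — so passing tests demonstrate the
correctness of the logic and statistics under the assumed sampling model,
not robustness to real sequencing pathologies. Defaults mirror the
characterized operating points (depth 10 000, error 5×10⁻⁴, efficiency up
to 0.77, purity 0.95). All generators are deterministic under their seed.

## Verification strategy

Every nontrivial operation is checked against an independent brute-force
oracle: the motif scanner against a naive scan of the doubled sequence and
of the reverse-complemented genome; the design enumerator against an
exhaustive loop re-applying each constraint; the designability mask against
per-position distance checks; the Fisher test against an exact rational
hypergeometric enumeration (agreement to 1e-9; exhaustive for row sums
≤ 12, sampled up to margins of 200 — full exhaustion over all margins ≤ 200
is combinatorially out of reach, and the sampled check covers the same
range). Parameter recovery runs 100 seeded simulations at depth 10 000 and
requires the pooled estimates to sit inside 99 % binomial intervals, with
the small miss rate such coverage implies. Problem sizes (genomes ≤ 2 kb
for oracle equivalence, ≤ 500 bp for enumeration equivalence) were chosen
so the whole battery runs in seconds as a routine check.

## Reference sequence

The human mtDNA reference (rCRS, NC_012920.1, 16 569 bp) is not bundled;
`mitobe.rcrs` fetches it once from NCBI (~17 kb) and caches it, or loads a
user-provided copy from `data/NC_012920.1.fasta`. The reference-dependent
checks (23 GATC duplex sites, 485 GATN duplex sites, ~6 % / ~71 %
designable coverage) run only against the genuine sequence and fail with
guidance when it is absent. All other functionality and tests run on
synthetic genomes.

## Known limitations

- No editing-efficiency prediction: the score ranks geometric desirability,
  not outcome. No thermodynamics, methylation-state or chromatinization
  effects on nicking.
- Monomeric (single-arm) editor windows are not modelled — their geometry
  is not characterized well enough to encode.
- The 8–24 bp window bounds and the gap rule table generalize from limited
  loci; both are configurable rather than asserted as universal.
- The gap-10 case is rejected as uncharacterized rather than interpolated.
- Mutation classification covers point substitutions only (no indels), and
  disease-catalog percentages depend on the catalog supplied by the user;
  none is bundled.
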