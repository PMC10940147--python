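"""Genome-wide designable targeting range.

A position is designable when it lies within 20 bp of a nick position.
On a random genome the relaxed GATN motif is ~30x denser than GATC, so its
coverage is far higher; a sequence-unrestricted nickase covers everything.
With the human mtDNA reference in place (data/NC_012920.1.fasta) the same
call reproduces the reference coverage figures (~6% MutH, ~71% MutH*).
"""

from mitobe import (MUTH, MUTH_STAR, NT_BSPD6I_C, density_track,
                    designable_mask, random_circular_genome, scan_motifs)

genome = random_circular_genome(length=16_000, gc=0.44, seed=3)

for nickase in (MUTH, MUTH_STAR, NT_BSPD6I_C):
    track = designable_mask(genome, nickase, flank=20)
    n_sites = len(scan_motifs(genome, nickase)) if nickase.motif else "any"
    print(f"{nickase.name:12s} sites={n_sites!s:>5} "
          f"coverage={100 * track.coverage_fraction:5.1f}%")

counts = density_track(genome, MUTH_STAR, window=40, step=40)
print(f"GATN sites per 40-bp window: mean {counts.mean():.2f}, max {counts.max()}")

# coverage = fraction of genome positions within +/-20 bp of some nick; the
# density track mirrors the per-40-bp recognition-site frequency readout.
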