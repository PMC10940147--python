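"""Scan a circular genome for nickase recognition sites.

Builds a seeded 2-kb synthetic circular genome, plants one GATC, and scans
it with MutH (strict 5'-GATC-3') and MutH* (relaxed 5'-GATN-3'). Every GATC
duplex window is palindromic, so it is reported once; MutH* finds a
superset of the MutH sites.
"""

from mitobe import MUTH, MUTH_STAR, plant_motif, random_circular_genome, scan_motifs

genome = random_circular_genome(length=2000, gc=0.44, seed=7)
genome = plant_motif(genome, "GATC", position=1000)

for nickase in (MUTH, MUTH_STAR):
    sites = scan_motifs(genome, nickase)
    print(f"{nickase.name:6s} ({nickase.motif}): {len(sites)} duplex sites")
    for s in sites[:5]:
        print(f"   position {s.duplex_start + 1} ({s.strand} strand) "
              f"matched {s.matched_seq}, nick at {s.nick_position + 1}")

# Each line is one recognition site: the 1-based duplex position, the strand
# carrying the motif, and where the nickase cuts that strand.
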