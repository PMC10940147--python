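"""Design dimeric editors for one requested base change.

Requests a T>C change (the start-codon-knockout chemistry: the actually
edited A sits on the noncoding bottom strand) near a planted GATC and
enumerates every legal MutH-anchored design. Candidates are ranked by a
heuristic score: fewer bystanders, the empirically best 3-bp gap, and a
centred target all score higher.
"""

from mitobe import (DesignParams, EditRequest, MUTH, designs_to_table,
                    enumerate_designs, plant_motif, random_circular_genome)

genome = plant_motif(random_circular_genome(400, gc=0.45, seed=23), "GATC", 200)
target = next(p for p in range(196, 212) if genome.sequence[p] == "T") + 1

request = EditRequest(position=target, ref="T", desired="C")
params = DesignParams(require_preceding_t=False)
candidates, reasons = enumerate_designs(genome, request, MUTH, params)

print(f"request: m.{target}T>C -> {request.editor_class}, "
      f"edited strand must be {request.required_edited_strand}")
print(f"{len(candidates)} legal designs (rejections: {reasons})")
best = candidates[0]
print(f"best: nickase on {best.nickase_side} arm, gap {best.gap} bp, "
      f"window {len(best.window)} bp, nick on {best.nick_strand}, "
      f"edits retained on {best.edited_strand}, "
      f"{len(best.bystanders)} bystander(s), score {best.score:.2f}")
print(designs_to_table(candidates).head(3).to_string(index=False))

# The edited strand is always the strand NOT nicked; for a top-strand T the
# editable A is on the bottom strand, so every candidate nicks the top.
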