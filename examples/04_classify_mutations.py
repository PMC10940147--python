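"""Classify pathogenic mtDNA point mutations by corrective chemistry.

Runs the three canonical LHON mutations through the classifier: transitions
with a mutant A or T are corrected by the A-to-G editor (mitoABE), those
with a mutant C or G by the C-to-T editor (mitoCBE); transversions are out
of reach for deaminase chemistry.
"""

from mitobe import MutationRecord, catalog_report, classify_mutation

lhon = [MutationRecord(11778, "G", "A", "MT-ND4 / LHON"),
        MutationRecord(3460, "G", "A", "MT-ND1 / LHON"),
        MutationRecord(14484, "T", "C", "MT-ND6 / LHON")]

for rec in lhon:
    plan = classify_mutation(rec)
    print(f"{rec.name:14s} class {plan.mutation_class:10s} -> "
          f"{plan.corrective_editor} editing the {plan.corrective_edited_strand} strand")

report = catalog_report(lhon)
print(f"correctable by a mitoBE chemistry: {report.attrs['correctable_percent']:.0f}%")
print(f"class mix: {report.attrs['class_percent']}")

# m.11778G>A and m.3460G>A carry a mutant A on the top strand (A-to-G
# correction, mitoABE); m.14484T>C carries a mutant C (C-to-T, mitoCBE).
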