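Drop-in location for the human mtDNA reference sequence.

Place the rCRS FASTA (accession NC_012920.1, 16,569 bp) here as
`NC_012920.1.fasta` — e.g. by running `mitobe fetch-rcrs --out
data/NC_012920.1.fasta` once with network access. The reference-dependent
tests and acceptance quantities activate automatically when the file is
present; everything else runs on synthetic genomes.
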