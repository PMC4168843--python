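# Real-data inputs (not distributed)

The published analyses compare two congeneric coral mitochondrial genomes
and a compiled cytochrome b alignment. Those inputs are external database
records and are not shipped with this package. To run the real-data check
in `tests/test_acceptance.py`, place here:

- `genome_pair_aligned.fasta` — the two mitogenomes (GenBank KM051016 and
  DQ643831), aligned to each other (2 records, equal length, e.g. with
  `mafft`).
- `genome_regions.bed` — coding/ribosomal region annotations on that
  alignment's coordinate system, BED 4+ columns with a 5th category column
  (`coding`/`ribosomal`/`other`); region names must include `CYB` and `COI`.
- optionally `cyb_alignment.nex` — the compiled cytochrome b NEXUS
  alignment of scleractinian corals, for the barcode-gap comparison via
  `mitobarcode barcode`.

Everything else in the test suite runs on synthetic data generated at test
time and needs no downloads.
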