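"""Generate reusable synthetic fixtures for both analyses.

Writes a two-genome alignment with BED annotations and a labeled barcode
alignment with its ground-truth taxonomy to ./fixtures/, the same files
the `mitobarcode simulate` subcommand produces.
"""

from pathlib import Path

from mitobarcode import write_fasta
from mitobarcode.seqio import write_regions_bed, write_tsv
from mitobarcode.synthetic_data import (
    SimulationConfig,
    simulate_barcode_set,
    simulate_genome_pair,
)

out = Path("fixtures")
out.mkdir(exist_ok=True)

config = SimulationConfig(seed=20, taxonomy=(6, 3, 3), qualifier_fraction=0.1)

alignment, regions = simulate_genome_pair(config)
write_fasta(alignment, out / "genome_pair.fasta")
write_regions_bed(regions, out / "regions.bed")
print(f"genome pair: {alignment.length} aligned columns, {len(regions)} regions")

barcode = simulate_barcode_set(config)
write_fasta(barcode.alignment, out / "barcode_set.fasta")
write_tsv(barcode.truth_tsv_rows(), out / "ground_truth.tsv",
          header=("label", "genus", "epithet", "qualifier"))
counts = barcode.category_counts()
print(f"barcode set: {len(barcode.alignment)} sequences, "
      f"ground truth {counts['intraspecific']} intraspecific / "
      f"{counts['intrageneric']} intrageneric / {counts['other']} other pairs")
print(f"files written to {out.resolve()}")
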