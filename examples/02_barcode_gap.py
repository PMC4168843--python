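"""Evaluate a candidate barcode locus by stratifying pairwise distances.

Simulates a labeled barcode-locus alignment whose composition matches the
compiled coral cytochrome b dataset (361 sequences, 203 species, 94
genera), computes all pairwise K2P distances, classifies each pair as
intraspecific / intrageneric / other, and summarizes the three
distributions. A locus is useful for barcoding when the intraspecific
distribution is cleanly separated from the rest (a "barcode gap").
"""

from mitobarcode import contrast_table, pairwise_distance_matrix, summarize_contrasts
from mitobarcode.synthetic_data import file_s1_like_barcode_set

barcode_set = file_s1_like_barcode_set(seed=20)
matrix = pairwise_distance_matrix(barcode_set.alignment)
table = contrast_table(matrix)

counts = table.category_counts()
print(f"{len(barcode_set.alignment)} sequences, {table.total_pairs()} pairwise contrasts:")
for cat in ("intraspecific", "intrageneric", "other"):
    print(f"  {cat:<14} {counts[cat]:>6}")
print(f"  missing {table.missing_pairs}, saturated {table.saturated_pairs}, "
      f"skipped {table.skipped_pairs}")

summary = summarize_contrasts(table.contrasts, truncation=0.05)
for cat in ("intraspecific", "intrageneric", "other"):
    s = summary.stats[cat]
    print(f"{cat:<14} mean K2P {s.mean:.4f}  median {s.median:.4f}  max {s.max:.4f}")

print(
    f"\noverlap fraction: {summary.overlap:.4f} -- the share of non-"
    "intraspecific pairs no more divergent than the most divergent "
    "conspecific pair. Near 0 means a clean barcode gap; on real coral "
    "cytochrome b data the strata overlap substantially."
)
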