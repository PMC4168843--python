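"""Scan a pair of aligned mitochondrial genomes for divergent regions.

Simulates two congeneric mitogenomes (18,667 bp, K2P substitutions, a
cytochrome b region evolving at 1.5x the 0.016 background and a fast
non-coding control region), runs the 500 bp / 25 bp sliding-window K2P
scan, and ranks the annotated coding regions by divergence.
"""

from mitobarcode import rank_regions, region_divergence, sliding_window_divergence
from mitobarcode.synthetic_data import SimulationConfig, simulate_genome_pair

config = SimulationConfig(seed=20)
alignment, regions = simulate_genome_pair(config)
a, b = alignment[0], alignment[1]

track = sliding_window_divergence(a, b, window_size=500, step=25)
peak = track.argmax_window()
print(f"{len(track)} windows; peak divergence {peak.d:.4f} at [{peak.start}, {peak.end})")

ranking = rank_regions(region_divergence(a, b, regions, track=track))
print("\ncoding regions by K2P divergence (substitutions/site):")
for rd in ranking[:5]:
    mean_w = "   --  " if rd.mean_window_d is None else f"{rd.mean_window_d:.4f}"
    print(f"  {rd.region.name:<6} d_region={rd.d_region:.4f}  mean-window={mean_w}  ({rd.n} sites)")

top = ranking[0]
print(
    f"\nThe most divergent coding region is {top.region.name} at "
    f"{top.d_region:.3f} substitutions/site -- the locus a barcoding assay "
    "for this pair of taxa should target first."
)
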