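# Methods

## Distance model

All divergence measures use the Kimura 2-parameter (K2P) model. For a
pair of aligned sequences, sites are compared under **pairwise deletion**:
an alignment column enters the comparison only when both characters are
unambiguous bases (A, C, G, T); gaps, `?`, `N` and all IUPAC ambiguity
codes are excluded for that pair alone. With n comparable sites, P =
transitions/n and Q = transversions/n, the distance in expected
substitutions per site is

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q).

Pairwise deletion (rather than complete deletion) maximizes usable sites
in ragged database-derived alignments and matches the default behavior of
the classic phylogenetics packages this workflow descends from; whether a
given historical run used pairwise or complete deletion is usually
undocumented, so the choice is stated here and fixed.

Two degenerate situations are kept distinct. **Saturation** — an observed
(P, Q) outside the model's domain (1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) — yields
a flagged `+inf` sentinel rather than an exception, so one saturated pair
cannot abort a several-hundred-sequence matrix; saturated pairs are
counted in totals but excluded from order statistics, densities and tree
building. **Undefined** — zero comparable sites — raises an error at the
single-pair level; inside a matrix such pairs are recorded as *missing*
(NaN), as are pairs with fewer comparable sites than the minimum-overlap
threshold (default 100 sites, configurable): partial sequences with tiny
overlaps otherwise produce wild distance estimates. The threshold is
echoed in all outputs.

## Sliding-window scan

Windows are defined on alignment columns — gap columns stay in the
coordinate frame but drop out of the counts — with defaults of 500 bp
width and 25 bp step. Full windows start at 0, step, 2·step, …; when the
full windows do not already reach the end of the alignment, one trailing
partial window is appended and flagged, so the track covers every column.
Circularity of the mitochondrial genome is *not* modeled (no wrap-around
windows); the trailing flagged window is the only concession to the
arbitrary linearization point.

For an annotated region the headline statistic `d_region` is the K2P
distance computed once over exactly the region's columns. A region's
"mean divergence" could equally denote the mean of window values inside
it, so `mean_window_d` (over windows fully contained in the region) is
reported alongside; the two differ noticeably only when divergence varies
within the region or the region barely fits one window. Ranking uses
`d_region`, descending, ties broken by start coordinate, restricted by
default to `coding` regions (conserved regions are where barcode primers
can be designed).

Counts are accumulated by prefix sums over per-column indicators, so a
full 18.7 kb scan costs O(alignment length) regardless of step size.

## Barcode-gap analysis

Taxon names are parsed from sequence labels with underscores and spaces
as separators: the genus is the first alphabetic token, the epithet the
next alphabetic token, and the qualifiers `sp.` (identified to genus
only), `cf.` and `aff.` (uncertain identification) are recognized in
epithet position. `cf.` and `aff.` are treated identically, and a
qualifier-bearing name never forms an intraspecific pair — even against
an identical label — because such specimens are only comparable at genus
level. Matching is case-insensitive; labels are stored verbatim.
Real database labels follow no single schema, so the token rules are a
documented decision of this package, not a property of the data.

Every unordered pair is assigned to exactly one of: the three strata
(intraspecific / intrageneric / other, counted over finite distances),
*missing*, *saturated*, or *skipped* (a pair involving an unparseable
label, which is reported and does not stop the run). The identity

intraspecific + intrageneric + other + missing + saturated + skipped = N(N−1)/2

is asserted on every run.

Densities are Gaussian kernel estimates with Silverman's rule-of-thumb
bandwidth, **reflected at d = 0** so no mass leaks below zero and the
density integrates to 1 on [0, ∞). When a stratum has zero spread (all
conspecific sequences identical, say) Silverman's bandwidth degenerates
to 0; a fixed fallback bandwidth of 1e-4 substitutions/site keeps the
density a finite spike at the boundary. The truncation bound (default
0.05, a display convention) clips only the exported density grid; all
statistics use the full range.

The **overlap fraction** is the proportion of finite non-intraspecific
distances ≤ the largest finite intraspecific distance: 0 for a clean
barcode gap, approaching 1 as the strata become indistinguishable. It is
deliberately a crude, assumption-free statistic; it is sensitive to the
single largest intraspecific value and should be read together with the
density plot.

## Neighbor joining

Standard Saitou–Nei agglomeration: join the active pair minimizing
Q(i,j) = (r−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k), branch lengths from the
two-point formulas, new-node distances by the reduction
d(u,k) = ½(d(i,k) + d(j,k) − d(i,j)); the last three nodes attach to a
trifurcating root (the tree is unrooted). Ties in Q are broken by the
smallest (i, j) pair in the current node order, which makes the output
deterministic. Negative branch-length estimates are by default clamped to
zero with the deficit moved to the sister branch of the same join,
preserving tip-to-tip path lengths (toggleable, since the unclamped
estimates are the textbook ones). On additive matrices the algorithm
recovers the generating tree exactly; this is the correctness oracle used
throughout the tests, since a historical tree built with undocumented
tie-breaking cannot be byte-reproduced.

NJ requires a complete matrix. The default pre-processing policy greedily
drops the sequence with the most missing/saturated pairs until the matrix
is complete, and reports what was dropped.

## Synthetic data generator

Substitutions are applied as independent per-site multinomial draws from
the exact K2P transition-probability matrix at the target branch length
(transition rate α = κβ against two transversion targets at rate β each,
normalized to one expected substitution per unit branch length). Because
the matrix is exact rather than a Poisson-event approximation, the
expected K2P distance between two tips equals the total branch length of
the path connecting them, which makes parameter-recovery tests tight.
Default κ = 2, a generic mitochondrial-DNA-like value (configurable).

**Genome pair.** A uniform-random ancestor of 18,667 bp (the length of
the assembled coral mitogenome this workflow was built around) evolves
into two descendants with per-branch divergence
`base_divergence · relative_rate(region) / 2`. The default region map
lays out a scleractinian-like gene order with a CYB region at rate 1.5×
the 0.016 background (expected pair divergence 0.024 vs 0.016), ribosomal
regions slower, and a fast non-coding control region (5×) — the qualitative
divergence profile reported for congeneric coral mitogenomes. Region
positions are invented; only lengths, categories and rate contrasts
matter to the analyses.

**Barcode set.** Sequences evolve on a two-level star-of-stars taxonomy:
root → genus ancestors at branch (D_between − D_within-genus)/2, genus →
species ancestors at (D_within-genus − D_within-species)/2, species →
tips at D_within-species/2, so each stratum's expected pairwise distance
equals its configured depth exactly. Default depths (0.005, 0.03, 0.10)
substitutions/site and locus length 800 bp give clearly separated strata
— appropriate for testing recovery, bookkeeping and classification.
Labels are `Genus_epithet_ACC######` with deterministic pseudo-Latin
names, and a configurable fraction of species is relabeled with `sp.` or
`cf.` to exercise the qualifier rules.

A frozen preset (`file_s1_like_config`) reproduces the composition of
the compiled coral cytochrome b dataset exactly: 361 sequences in 203
species and 94 genera arranged so that 249 pairs are intraspecific and
2,098 intrageneric (species sizes {12, 3×36, 2×75, 1×91}; genus sizes
{46, 34, 33, 3×66, 2×25}); 64,980 = 361·360/2 pairs in all. Three
singleton species carry qualifiers, which leaves the stratum counts
unchanged.

**What the generator does not emulate.** Real compilations have rate
heterogeneity across lineages and sites, uneven and overlapping stratum
depths, misidentified and chimeric records, and alignment gaps from
partial reads — which is precisely why the real cytochrome b data show a
positive overlap fraction while the clean synthetic defaults show ≈0.
Passing the synthetic-data tests therefore demonstrates that counting,
classification, estimation and tree building are correct, not that any
particular real locus has (or lacks) a barcode gap. Indel evolution is
not simulated; gaps enter fixtures only by explicit masking in tests.

## Problem sizes and tolerances

The test and acceptance workloads use: 100 replicate 18 kb genome pairs
for elevated-region recovery (≥95/100 required, estimate within 2 SE of
its analytic expectation); 30 replicate 72-sequence barcode sets for
depth recovery (each stratum mean within 2 SE of its configured depth,
category counts exactly equal to ground truth); 100 random additive
matrices of 5–12 taxa for NJ (path-distance reproduction to 1e-9,
topology identical); 1,000 random count triples for agreement with the
closed-form K2P oracle (1e-12) and 1,000 for the low-divergence limit
(|K2P − p-distance| ≤ 1e-4 at P+Q ≤ 1e-3). The acceptance script averages
the genome-scan divergences over 200 replicate pairs to suppress
per-region sampling noise (a single 1,140 bp region has a standard error
of ≈0.005 at d = 0.024).
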