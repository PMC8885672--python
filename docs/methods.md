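# Methods

## Data model

A structural variant is an **adjacency**: an unordered pair of **breakends**,
each a 1-based chromosome position plus a *side* saying which flank of the
position is retained in the derived chromosome (`extends_left` /
`extends_right`). VCF 4.x BND records are paired through `MATEID` and their
bracket ALT decoded (sequence-first ALT ⇒ local left flank retained; `[` ⇒
the mate's right flank is joined). BEDPE strands map `+` → `extends_right`,
`−` → `extends_left`, with the usual 0-based→1-based shift on read.
Breakends on contigs outside the declared genome are dropped with a logged
count — the pipeline works on a fixed chromosome model. Copy-number input is
a per-sample table of non-overlapping segments with total copy number.

## Two-step KDE clustering

Breakpoints of one sample on one chromosome are treated as draws from an
unknown density; clusters are the basins of its modes at a **fixed, global
bandwidth**, so the same smoothing scale applies to every sample. Defaults
h₁ = 1000 bp (round 1) and h₂ = 400 bp (round 2) are the values selected by
the intra/inter-cluster distance sweep that `bandwidth_sweep` reproduces:
below ~400 bp the inter-cluster distance collapses, above it intra-cluster
distance grows with little inter gain. Round-1 clusters define "regions";
junctions with both ends in one round-1 cluster are loops over a single
region (chromothripsis-like local shattering) and are removed before round 2
so they cannot masquerade as multi-cluster cycles. Only round-2 clusters
survive.

Numerical choices:

* the density is evaluated on grids of step `0.1·h` over the union of
  windows (data ± 4h), merged when overlapping; beyond 4 bandwidths the
  Gaussian tail changes the density by < 1e-3 relative, and each
  contiguous window is mode-hunted separately so window joins cannot fake
  maxima. The kernel sum is evaluated directly (vectorized, chunked); no
  tree approximation.
* peaks are strict local maxima on the grid; plateaus collapse to their
  leftmost point; no sub-grid refinement (cluster centres feed a graph —
  sub-bp precision is irrelevant).
* each breakpoint goes to the nearest peak; exact ties go to the
  lower-coordinate peak.
* the cluster centre is clamped into the member span: a breakpoint sitting
  on the shoulder of a neighbouring mode may be assigned a peak outside its
  own members' range, and the centre must stay a representative coordinate
  of the cluster (for singletons it is the point itself).
* a single distinct coordinate is a cluster at that coordinate, bypassing
  the KDE.

Diagnostics: intra(C) = max(members) − min(members);
inter(Cₖ, Cₖ₊₁) = min(Cₖ₊₁) − max(Cₖ) for clusters consecutive by peak
position; overlapping spans violate the nearest-mode partition and raise.

## Permutation validation

The null keeps *where* breakpoints fall (SVs recur at the same genomic
places) and randomizes *how they are grouped and paired*: all breakends are
pooled (chromosome + position + side intact), re-dealt to samples
preserving each sample's breakend count, and paired uniformly at random
within each sample. Two statistics compare observed data to 100 simulated
datasets:

* **gap dispersion** — per sample/chromosome with ≥ 3 breakpoints, the
  population SD (divisor n) of successive sorted-position gaps, averaged
  unweighted over those groups;
* **cluster density** — breakends per final cluster after running the same
  two-step clustering on each simulated dataset.

Each is tested with a one-sample Z-test, z = (observed − mean_sim)/SD_sim
with the sample SD (n−1) and normal-approximation p-values (two- and
one-sided reported). This standardized-score form approximates the
permutation p and is calibrated: when the input is itself random pairing,
it rejects at the nominal rate. A zero simulated SD yields a flagged
degenerate result rather than a p-value.

**Power at desk scale.** The dispersion statistic gains power from clusters
holding many breakpoints. Planted cycles contribute only two breakends per
cluster, so with a background-dominated mix (e.g. 20 triangles against 200
uniform junctions over a 250-Mb genome) its shift is ~1.3 ensemble-SDs —
directionally right but not significant; with dense clusters (several
stacked cycles per locus) the same test reaches |z| ≈ 10. The
cluster-density statistic is far more sensitive (z ≈ 50+ in both regimes)
because random re-pairing almost never re-creates co-located pairs inside
one sample. The test suite exercises both regimes; on real cohorts (orders
of magnitude more samples) both statistics are expected to be decisive.

## Rearrangement graphs and cycle mining

Per sample, final clusters are vertices (tagged with chromosome and peak
position) and junctions between two distinct clusters are edges; parallel
junctions collapse to one edge with provenance. Mining enumerates every
simple closed cycle with 3–6 distinct vertices — each participating vertex
of degree exactly 2 — by depth-first path extension from every start
vertex, closing a path whenever its last vertex neighbours its first. The
search makes no uniqueness effort; the reduce step collapses duplicates by
a canonical key (the sorted edge set), which is invariant to rotation and
reflection. Because starts are independent, a per-start partitioned search
merged and deduplicated equals the serial result (the parallelization
contract), and a cycle is identified by its **edge set**: a dense subgraph
on k vertices can contain several distinct Hamiltonian cycles and all are
counted. Cohort statistics per size: *confidence* (samples with ≥ 1
occurrence), *frequency* (total occurrences), *average* =
frequency/confidence, reported truncated at two decimals.

## Edge-switching null and Abundance

The randomization keeps each sample's vertices and edge count and the
pooled degree multiset, destroying only the wiring: repeatedly pick two
random edges A–B and C–D from the pooled, sample-tagged edge list (endpoint
order randomized) and replace them with A–D and C–B. A move creating a
self-loop or duplicating an existing edge within an affected sample is
rejected but still consumes one of the 100 × E attempts (E = total edges);
with that budget the acceptance loss is immaterial. Switching is global
with sample tags — edges stay in their sample, so per-sample counts are
conserved, while vertices are cluster loci reusable across samples. Each of
the N = 100 ensemble datasets is switched independently from the original.

Abundance of a pattern: Δ = (f_input − f̄_random)/(f_input + f̄_random + ε)
with ε = 1 (Laplace pseudo-count; keeps Δ defined and damped at small
frequencies). Δ ∈ [−1, 1]; Δ > 0 means overrepresented. The single-edge
pattern is an exact Δ = 0 control since edge counts are conserved.
Per-cancer-type reports restrict frequencies (both real and ensemble) to
that type's samples; the ensemble itself is the global one.

## Triangle classification

Per size-3 cycle: each junction is *inverted* iff both breakends keep the
same flank (head-to-head / tail-to-tail). Each cluster's CN state compares
the segment containing the peak against the median CN of other segments
overlapping peak ± 1 Mb: gain at ≥ +1 copy, loss at ≤ −1, else neutral; an
uncovered peak is neutral with an `uncovered` flag. The profile
*oscillates* when the three states (clusters ordered by chromosome and
position) take exactly two values and alternate (A-B-A). With I = inverted
junctions, rules evaluate in order:

1. I ≥ 2 and oscillating → **non-canonical chromothripsis**
2. I ≥ 2 and ≥ 1 gain → **templated-insertion cycle**
3. I ≥ 2 and all neutral → **chromotrikona**
4. I ≤ 1 and no gain (loss allowed — balanced chains may lose a little
   DNA) → **chromoplexy**
5. otherwise → unclassified.

Oscillation precedes gain because an alternating gain profile is the
chromothripsis signature; a uniform low-level gain without oscillation is
the templated-insertion signature. The source class descriptions are
qualitative ("frequent inverted rearrangements"); the I ≥ 2 threshold, the
±1-copy steps and the 1-Mb flank window are this package's crisp
codification and are exposed in `ClassifierConfig`. Junction orientation
for a deduplicated edge comes from its first (lowest-id) contributing
adjacency. Without CN data only the orientation rules apply (chromoplexy
for I ≤ 1, chromotrikona for I ≥ 2) and calls carry a `no-CN` flag.

Summaries: a symmetric type×type matrix of shared clusters (clusters
appearing in ≥ 1 triangle of each type), and per cancer type × triangle
type the mean per-sample count over the type's triangle-bearing samples
with a normal 95% CI (mean ± 1.96·SD/√n), excluding cancer types with
fewer than 10 triangle-bearing samples.

## Synthetic data

The generator emulates exactly the features the pipeline exploits:
breakpoints concentrated at planted cluster centres (Gaussian jitter, SD
50 bp — well under h₂ = 400, so planted structure survives both rounds),
per-sample junction sets closing into rings of 3–6 centres, junction
orientation patterns per archetype, and step-wise CN profiles (baseline 2,
±1 steps over ±50-kb windows around centres, inside the 1-Mb flank
window). The default genome is 5 chromosomes of 40–60 Mb; auto-drawn
centres keep ≥ 1 Mb separation so CN windows never collide. Background
junctions pair uniform random breakends with random sides. Everything is
deterministic under the seed, and a manifest records centres, cycle edge
sets and expected triangle labels; `verify_manifest` and
`match_planted_cycles` score recovery independently.

What the generator does **not** emulate: realistic SV size/type spectra,
mutational signatures, recurrent loci shared across samples, subclonal
copy number, or caller noise (missed/false junctions). Passing tests
demonstrate that the algorithms recover the structures they define under
controlled noise — not that any particular biological cohort will show
them.

## Problem sizes and defaults in the test suite

The suite uses desk-scale cohorts chosen as the package's own test
conditions: recovery/significance runs use 30 samples with 20 planted
triangles against 200 background junctions; the calibration study uses
background-only data dense enough (1 chromosome × 1.5 Mb, 6 × 25
junctions) for chance cluster collisions, since a background where every
cluster is a singleton makes the density Z-test degenerate and the
calibration vacuous; switching ensembles use N = 20–50 with the full
100 × E switch budget. Cohort-scale numbers from controlled-access data
are out of scope.

## Known limitations

* Round-1/round-2 bandwidths are global constants; no per-sample or
  data-driven bandwidth selection (deliberate — the sweep diagnostics
  exist to choose them once per cohort).
* The dispersion Z-test is underpowered for sparse two-breakend clusters
  (see above).
* The cycle search is exact but exponential in the size cap; it is meant
  for k ≤ 6 on cluster graphs, not for dense general graphs.
* Triangle classification uses one junction per deduplicated edge and
  integer-step CN calls; allele-specific or fractional CN is not modelled.
* No distributed execution; the per-start-vertex mining contract makes the
  search embarrassingly parallel, but the implementation is single-process.
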