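# Methods

This note records the models, conventions and numerical choices behind
`redsnow`, and what the synthetic validation does and does not show.

## Read processing

Demultiplexing requires an exact match of both indices to a declared
sample (no error correction): index sequencing is short and accurate, and
exact matching avoids cross-talk at the cost of a small yield loss.
Quality truncation cuts a read immediately before its first base with
quality < `qmin` (default 3, configurable); the merger then searches all
ungapped overlaps of at least `min_overlap` (default 16) between the
forward read and the reverse-complemented reverse read, keeps the overlap
maximizing matching positions (ties: longer overlap), and rejects the pair
when the best overlap's mismatch fraction exceeds `max_mismatch_frac`
(default 0.25). At overlap conflicts the higher-quality base wins (tie:
forward) and the consensus quality is the maximum of the two — so a
low-quality miscall sitting in the overlap is usually corrected by its
high-quality mate. Reads with ambiguous bases or fewer than 50 nt are
discarded; an optional contaminant screen discards reads whose local
alignment to any contaminant reference covers ≥ 60 nt at ≥ 90% identity
(a tool-independent replacement for a dedicated spike-in mapper). Primers
are matched IUPAC-aware at the 5' end (and as the reverse complement at
the 3' end of merged reads) allowing up to 4 mismatches. Every stage
writes to a ledger and asserts reads-in = reads-out + discards.

## Alignment conventions

One identity convention is used everywhere: matched columns divided by
alignment columns, terminal-gap columns excluded, internal gap columns
counted as mismatches; coverage of a sequence is the fraction of its
residues inside the non-terminal-gap core. `global_align` is an overlap
(free-end-gap) alignment and `local_align` is Smith–Waterman, both with
affine gaps (match +1, mismatch −2, gap open −10, extend −1; a gap of
length L costs 10 + (L−1)). The engine is Bio.Align.PairwiseAligner; the
statistics are computed by a column scan in this package. Where throughput
matters more than affine optimality — the all-pairs CBC scans inside
species delimitation, and the prefilter below — a unit-cost (edit
distance) alignment via edlib is used instead; for the near-identical
pairs involved the two coincide.

## Clustering

Greedy OTU clustering follows the UCLUST contract: phylotypes are visited
in abundance order (ties lexicographic, fixed by dereplication) and each
joins the **first** centroid, in creation order, with identity > 0.98 and
both coverages > 0.80, else founds a new centroid. This makes results a
deterministic function of the input multiset. A conservative edlib
prefilter skips centroids whose edit-distance identity estimate falls
below threshold − 0.03; any pair that could qualify under the affine
engine passes the prefilter, so the result is unchanged (asserted in
tests). Furthest-neighbour (complete-linkage) clustering at 99% identity
is delegated to scipy's `linkage(method="complete")` with a cut at
distance 1 − 0.99, which guarantees every within-cluster pair meets the
threshold; inputs are label-sorted first so merge order is deterministic.

## Chimera screen

The de novo screen keeps the abundance-skew logic of PCR-chimera
detectors: candidate parents must be at least `min_skew` = 2× more
abundant than the query (chimeras arise late in PCR and are rarer than
their templates), capped at the 30 most abundant candidates. Per-position
match profiles of the query against each candidate (edit-optimal
alignment, projected to query coordinates) are combined over all parent
pairs and crossover columns by prefix sums; the best two-segment model
identity `id_model` is compared with the best single-parent identity.
A query is flagged when `id_model ≥ id_best_single + min_gain` (0.02)
**and** `id_model ≥ min_model` (0.98). The second gate is essential: a
PCR chimera is an exact splice of its parents, so the model must nearly
reconstruct the query; without it, genuine low-abundance phylotypes whose
true relatives fail the skew precondition get "explained" by two unrelated
abundant sequences and are falsely flagged. In the pipeline the screen
runs only on queries with ≥ 2 reads — singletons are removed by the next
stage regardless, so the surviving set is identical and only the ledger's
per-reason split differs.

## ITS2 structure, hallmarks, CBC

Folding is deterministic base-pair maximization (Nussinov) over AU/GC/GU
pairs with a minimum hairpin loop of 3; the traceback pairs position i
with the smallest qualifying partner whenever pairing i is optimal, fixing
a unique structure among the maximizers. This is *not* a thermodynamic
prediction; user-supplied Vienna dot-bracket files override it, which is
the intended mode for real data (numba, if importable, accelerates the DP
fill; a pure-Python fill is the fallback). Helices are the stems branching
off the basal loop — the multibranch loop closed by the outermost stem, or
the open exterior loop — numbered I–IV in 5' order; a stem runs through
bulges and internal loops and ends at its apical (or an internal
multibranch) loop. Hallmarks: exactly four helices; an internal-loop
column of helix II presenting U opposite U (any position within helix II —
the source analyses do not pin it down further); a YGGY match on the 5'
strand of helix III inside the apex window. The apex window is the
5'-strand span of the last 10 helix-III base pairs, extended over any
overlapping YGGY match; the width is configurable because "near the apex"
has no canonical numeric definition. A CBC at an aligned column pair
base-paired in both structures means both nucleotides differ with both
pairings canonical (GU counts as canonical, standard ITS2 practice);
exactly one differing nucleotide is a hemi-CBC. Species delimitation draws
an edge between two OTUs when no CBC falls in either structure's apex
window (the union makes the relation symmetric) and takes connected
components, i.e. the same-species relation is closed transitively. In the
pipeline, delimitation runs within taxonomic groups — between groups the
species question does not arise.

## Taxonomy

E-values use the ungapped Karlin–Altschul form E = K·m·n·e^(−λS) with
λ = 1.28, K = 0.46 (nucleotide +1/−2 constants). Only the decision gates
matter for the analysis — E < 10⁻⁸, identity > 0.90, alignment length
(aligned columns, gaps included) > 200 for ITS2 or > 150 for 18S — so the
constants are declared, not fitted. Ties on score break by lowest E then
lexicographic reference id, making assignment independent of database
order. The pipeline assigns OTU centroids and propagates labels to
members; unassigned OTUs are excluded from downstream biogeography, which
is how non-algal reads leave the analysis.

## Biogeography

Presence of a taxon in a region means its summed count over that region's
samples reaches `min_count` (default 1 — any read confers presence, since
no presence threshold is part of the analysis design; singletons have
already been removed globally). Endemism is evaluated at region level
(four regions), not site level; a site-level scheme can be passed as a
custom `RegionScheme`. The summary reports per region the endemic fraction
of the taxa present and the bipolar (and endemic) read share, and two
aggregates each: the arithmetic mean over regions and the pooled variant
(region-taxon incidences pooled for unique fractions; raw reads pooled for
read shares). Both are reported because a printed "average" is ambiguous
between them, and they genuinely differ.

## Statistics

PERMANOVA is the standard one-way distance-based formulation: total sum of
squares Σd²/N over all pairs, within-group analogues per group, pseudo-F
= (SS_A/(a−1))/(SS_W/(N−a)); p-values permute group labels with the
add-one rule p = (#{F* ≥ F} + 1)/(n_perm + 1) (999 permutations by
default), or enumerate all permutations exhaustively for small N. The
Mantel statistic is the Pearson correlation of the off-diagonal entries
(Spearman behind a flag), permuting rows and columns of the second matrix
simultaneously, one-sided greater. Both engines take an explicit seed and
report it. UPGMA uses scipy average linkage; node height is merge distance
/ 2, so the Newick output is exactly ultrametric. Geographic distance is
the haversine great-circle distance on a 6371-km sphere; region-level
distance, where needed, is the mean over inter-site pairs.

## The simulator

`redsnow.sim` emulates the statistical structure of a two-pole red-snow
survey, not its biology. Templates descend from a fixed ~250-nt
hallmark-valid ITS2 scaffold; mutations preserve the scaffold's secondary
structure (loop positions mutate freely; paired positions mutate as whole
canonical-pair replacements), so every template ships with a valid Vienna
structure. The hierarchy is group ancestors (8% divergence from the
scaffold; these double as the reference database) → OTU ancestors (4%
further; within-group, pairwise > 2% apart) → phylotypes (≤ 0.5% further;
within-OTU pairwise < 2%), which makes 98% clustering well-posed by
construction. Species identities are planted as compensated pair states in
four reserved helix-III apex-window pairs, so delimitation has known
truth.

Default study conditions: 4 regions × 3 samples × 20,000 reads, 0.1%
per-base substitution error, 2% chimera rate (uniform crossover splices of
two region-consistent templates). The default template pool (7,263
phylotypes) preserves the uniques-per-read ratio of a full-scale survey
(~0.03 unique sequences per read); per-region endemic-fraction and
bipolar-read-share targets encode the survey regime (endemic fractions
0.779/0.499/0.217/0.708; bipolar shares 0.123/0.478/0.684/0.272).
Abundances are log-normal (σ = 1.0) within category and region,
renormalized so expected category read shares hit their targets exactly
before sampling; per-sample counts are multinomial. Miscalled bases draw
low quality scores (Q2/Q12/Q25 with probability 0.45/0.35/0.20) against a
Q35 baseline, because real instrument errors concentrate at low quality —
this is what makes quality truncation and overlap consensus meaningful.
The error model is substitution-only by default (an indel-rate flag
exists): exact dereplication is the unit of analysis, and indels would
only move reads between the same spurious-variant pools.

What passing the end-to-end test shows: under these conditions the
pipeline recovers planted per-region endemic unique fractions and bipolar
read shares within 3 percentage points, where truth is computed over
templates with ≥ 2 sampled reads (the analysis defines unique sequences
post-singleton-removal). What it does not show: robustness to real-data
features the generator omits — index hopping, PCR amplification bias,
length variation between taxa, quality-profile drift along the read, or
reference databases with patchy coverage.

## Known limitations

* The built-in folder maximizes pair count, not free energy; hallmark
  validation of *de novo* folds of real sequences will often fail, by
  design — supply curated structures for real analyses.
* The chimera model scores two-segment splices only; multi-crossover
  chimeras are detected only insofar as a two-segment model still beats
  the best single parent.
* PERMANOVA is one-way; pairwise region contrasts run as separate one-way
  tests without multiplicity correction (a Bonferroni flag is available).
* The taxonomy layer models a single labelled reference FASTA, not a
  tiered public-database search.
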