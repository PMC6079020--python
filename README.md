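# redsnow

Biogeography of polar red-snow algae from ITS2 amplicons.

Red-pigmented snow algae bloom on thawing snow in both polar regions. The
nuclear rDNA internal transcribed spacer 2 (ITS2) evolves fast enough to
resolve their fine-scale population structure, so a dual-indexed paired-end
amplicon survey of red-snow sites in Antarctica, Svalbard, Greenland and
Alaska can ask: which algae are endemic to one region, which are spread
across the Arctic, and which are bipolar cosmopolitans? `redsnow`
implements that analysis end to end as a reusable, tested Python library —
from raw FASTQ to phylotypes, OTUs, secondary-structure species
delimitation, endemism accounting and permutation statistics — together
with a ground-truth metacommunity simulator so the whole pipeline can be
validated without any sequencing data.

It is intended for microbial ecologists and bioinformaticians who want
either the complete pipeline or its pieces (a UCLUST-style clusterer, a
CBC detector, a seeded PERMANOVA) as importable, deterministic functions.

## The analysis

* **Phylotypes.** Reads are demultiplexed by *exact* dual-index match,
  3'-truncated at the first base below quality `qmin`, merged over their
  best ungapped overlap (higher-quality base wins at conflicts), filtered
  (no ambiguous bases, ≥ 50 nt, contaminant screen), primer-trimmed
  (IUPAC-aware, ≤ 4 mismatches), and collapsed into abundance-annotated
  unique sequences — phylotypes. De novo chimeras and singletons are
  removed.
* **OTUs.** Greedy centroid clustering assigns each phylotype (in
  abundance order) to the first centroid with identity > 98% and both
  coverages > 80% under an affine-gap overlap alignment.
* **Taxonomy.** Queries are assigned to a labelled reference set when the
  top local alignment has E < 10⁻⁸, identity > 90% and alignment length
  > 200 bp (ITS2) or > 150 bp (18S); E = K·m·n·e^(−λS). An in-house
  reference builder cuts ITS2 out of long 18S–ITS2 Sanger sequences and
  clusters them per sample at 99% identity (furthest neighbour).
* **Species.** ITS2 secondary structures (supplied as Vienna files or
  folded by a deterministic base-pair-maximizing algorithm) are checked
  for the eukaryotic hallmarks — four helices, a U–U mismatch in helix II,
  a YGGY motif on the 5' strand near the helix III apex. Two OTUs belong
  to different species when a compensatory base change (CBC: both bases of
  a pair differ, pairing stays canonical) lies in the helix-III apex
  window; species are connected components of the no-CBC relation.
* **Biogeography.** Each taxon's region-presence set is classified as
  endemic (one region), arctic_shared, entire_arctic, or bipolar (≥ 1
  Arctic region *and* Antarctica). Per region the package reports the
  endemic fraction of unique sequences and the read share of bipolar taxa,
  plus arithmetic-mean and pooled read-weighted aggregates.
* **Statistics.** Shannon–Wiener H = −Σ pᵢ ln pᵢ; Bray–Curtis
  BC = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); UPGMA dendrograms; one-way PERMANOVA (pseudo-F
  on the distance partition of sums of squares) and the Mantel test
  against great-circle distances, both with seeded permutations and
  p = (#{permuted ≥ observed} + 1)/(n_perm + 1); a bipartite sample–taxon
  co-occurrence network exported as GraphML.
* **Simulator.** `redsnow.sim` generates regional phylotype pools with
  configured category composition, log-normal abundances renormalized to
  hit per-region category read-share targets exactly, per-base errors with
  realistic low quality at miscalls, PCR chimeras, primers and dual
  indices — plus a per-read truth table for recovery scoring.

## Worked example

`python examples/simulate_and_run.py` simulates 12 samples across the four
regions (2,000 reads each, 0.1% error, 2% chimeras) and runs the full
pipeline:

```
phylotypes after QC/chimera/singleton removal: 318
OTUs at >98% identity:                         135
species (CBC delimitation within groups):      4
per-region endemic unique fraction / bipolar read share:
  Alaska      endemic 0.662   bipolar 0.270
  Antarctica  endemic 0.731   bipolar 0.118
  Greenland   endemic 0.282   bipolar 0.687
  Svalbard    endemic 0.455   bipolar 0.475
mean endemic unique fraction: 0.533
mean bipolar read share:      0.388
PERMANOVA (region): {"pseudo_F": 124.3564, "p_value": 0.001, "n_permutations": 999, "seed": 7}
Mantel (geography):  {"r": 0.8643, "p_value": 0.001, "n_permutations": 999, "seed": 7}
```

Roughly half of the unique sequences are endemic to a single region while
a handful of bipolar phylotypes carries ~39% of all reads; regional
communities differ significantly (PERMANOVA) and dissimilarity tracks
geographic distance (Mantel). The other examples demonstrate CBC species
delimitation, the statistics layer, and reference-database construction.

A thin CLI wraps the same functions: `redsnow simulate --seed 1 --out sim/`
then `redsnow all --r1 sim/R1.fastq --r2 sim/R2.fastq --metadata
sim/metadata.tsv --structures sim/structures.vienna --seed 1 --out run/`.

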