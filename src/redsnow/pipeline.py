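"""End-to-end orchestration: demultiplex -> truncate/merge -> QC -> primer
trim -> dereplicate -> chimera screen -> singleton removal -> 98% OTU
clustering -> taxonomy filter -> structure/hallmarks/CBC -> biogeography ->
community statistics -> network export.

Each stage writes its artifact into the run directory and appends to the
read ledger; identical config and seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import biogeography as bg
from . import stats as cstats
from .align import edlib_align
from .clustering import cluster_phylotypes_to_otus, remove_chimeras
from .reads import (
    QCLedger, SampleMetadata, demultiplex, dereplicate, merge_pairs_batch,
    quality_filter, read_fastq, read_metadata, remove_singletons,
    trim_primer, truncate_at_low_quality, write_phylotypes,
)
from .structure import (
    ITS2Structure, annotate_helices, delimit_species, fold_dotbracket,
    read_vienna, to_rna, validate_hallmarks,
)
from .taxonomy import ReferenceRecord, assign_taxonomy

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    r1: str | Path
    r2: str | Path
    metadata: str | Path
    outdir: str | Path
    reference_db: Sequence[ReferenceRecord] | None = None
    structures: str | Path | None = None  # Vienna file overriding folding
    marker: str = "ITS2"
    fwd_primer: str = "CCAGCASCYGCGGTAATTCC"
    rev_primer: str = "TCCTCCGCTTATTGATATGC"
    qmin: int = 3
    min_overlap: int = 16
    max_mismatch_frac: float = 0.25
    min_len: int = 50
    primer_max_mismatches: int = 4
    contaminants: Mapping[str, str] | None = None
    otu_identity: float = 0.98
    otu_coverage: float = 0.80
    chimera_min_skew: float = 2.0
    chimera_min_gain: float = 0.02
    chimera_min_model: float = 0.98
    chimera_min_query_count: int = 2
    fold_structures: bool = False  # fold centroids lacking a supplied structure
    region_scheme: bg.RegionScheme = field(default_factory=bg.RegionScheme)
    sample_subset: Sequence[str] | None = None
    n_perm: int = 999
    network_subsample: int = 20000
    seed: int = 0

    def validate(self) -> None:
        for p in (self.r1, self.r2, self.metadata):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class PipelineResult:
    outdir: Path
    ledger: QCLedger
    phylotypes: list
    otus: list
    matrix: bg.CommunityMatrix | None
    otu_matrix: bg.CommunityMatrix | None
    classification: dict
    summary: bg.BiogeoSummary | None
    stats: dict
    species: list[list[str]] | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ledger = QCLedger()

    samples = read_metadata(config.metadata)
    if config.sample_subset is not None:
        samples = [s for s in samples if s.sample_id in set(config.sample_subset)]
    logger.info("demultiplexing %d samples", len(samples))
    pairs = zip(read_fastq(config.r1, "forward"), read_fastq(config.r2, "reverse"))
    demuxed = demultiplex(pairs, samples, ledger)

    per_sample_seqs: dict[str, list[str]] = {}
    for s in samples:
        sid = s.sample_id
        sample_pairs = [
            (truncate_at_low_quality(f, config.qmin),
             truncate_at_low_quality(r, config.qmin))
            for f, r in demuxed[sid]
        ]
        merged = merge_pairs_batch(
            sample_pairs, config.min_overlap, config.max_mismatch_frac, ledger)
        clean: list[str] = []
        for read in merged:
            ledger.add("qc_in")
            keep, reason = quality_filter(
                read, config.min_len, config.contaminants)
            if not keep:
                ledger.add(f"discarded_{reason}")
                continue
            t = trim_primer(read, config.fwd_primer,
                            config.primer_max_mismatches, end="5prime")
            if t is not None:
                t = trim_primer(t, config.rev_primer,
                                config.primer_max_mismatches, end="3prime")
            if t is None or len(t) == 0:
                ledger.add("discarded_primer")
                continue
            ledger.add("qc_kept")
            clean.append(t.bases)
        per_sample_seqs[sid] = clean
    ledger.check_conservation(
        "qc_in",
        ["qc_kept", "discarded_ambiguous", "discarded_short",
         "discarded_contaminant", "discarded_primer"],
    )

    logger.info("dereplicating")
    phylotypes = dereplicate(per_sample_seqs)
    ledger.add("phylotypes_raw", len(phylotypes))
    write_phylotypes(phylotypes, outdir / "phylotypes_raw.fasta",
                     outdir / "phylotypes_raw.tsv")

    logger.info("chimera screen on %d phylotypes", len(phylotypes))
    phylotypes, verdicts = remove_chimeras(
        phylotypes,
        min_skew=config.chimera_min_skew,
        min_gain=config.chimera_min_gain,
        min_model=config.chimera_min_model,
        min_query_count=config.chimera_min_query_count,
    )
    with open(outdir / "chimeras.tsv", "w") as fh:
        fh.write("query\tis_chimera\tparent_a\tparent_b\tcrossover\tid_model\tid_best_single\n")
        for v in verdicts:
            fh.write(f"{v.query}\t{int(v.is_chimera)}\t{v.parent_a or ''}\t"
                     f"{v.parent_b or ''}\t{'' if v.crossover is None else v.crossover}\t"
                     f"{v.id_model:.4f}\t{v.id_best_single:.4f}\n")
    ledger.add("chimeras_removed",
               sum(1 for v in verdicts if v.is_chimera))

    phylotypes = remove_singletons(phylotypes, ledger)
    ledger.add("phylotypes_final", len(phylotypes))
    write_phylotypes(phylotypes, outdir / "phylotypes.fasta",
                     outdir / "phylotypes.tsv")

    logger.info("OTU clustering %d phylotypes", len(phylotypes))
    otus, otu_counts = cluster_phylotypes_to_otus(
        phylotypes, config.otu_identity, config.otu_coverage)
    by_id = {p.phylotype_id: p for p in phylotypes}
    with open(outdir / "otus.tsv", "w") as fh:
        fh.write("phylotype_id\totu_id\n")
        for otu in otus:
            for m in otu.members:
                fh.write(f"{m}\t{otu.otu_id}\n")
    with open(outdir / "otu_centroids.fasta", "w") as fh:
        for otu in otus:
            fh.write(f">{otu.otu_id} {otu.centroid}\n{by_id[otu.centroid].sequence}\n")

    # taxonomy: assign centroids, propagate to members, drop unassigned OTUs
    excluded_taxa: set[str] = set()
    assignments = {}
    if config.reference_db:
        logger.info("taxonomic assignment of %d centroids", len(otus))
        for otu in otus:
            a = assign_taxonomy(
                otu.otu_id, by_id[otu.centroid].sequence,
                config.reference_db, config.marker)
            assignments[otu.otu_id] = a
            if not a.assigned:
                excluded_taxa.update(otu.members)
        with open(outdir / "assignments.tsv", "w") as fh:
            fh.write("otu_id\tbest_ref\tevalue\tidentity\talen\tassigned\tgroup_label\n")
            for oid, a in assignments.items():
                fh.write(f"{oid}\t{a.best_ref}\t{a.evalue:.3g}\t{a.identity:.4f}\t"
                         f"{a.alignment_length}\t{int(a.assigned)}\t{a.group_label}\n")
        ledger.add("phylotypes_nonalgal_excluded", len(excluded_taxa))

    kept_phylotypes = [p for p in phylotypes if p.phylotype_id not in excluded_taxa]
    kept_otus = [o for o in otus if o.centroid not in excluded_taxa]

    # secondary structure of OTU centroids
    species = None
    supplied: dict[str, ITS2Structure] = {}
    if config.structures:
        for s in read_vienna(config.structures):
            supplied[to_rna(s.sequence)] = s
    structures: dict[str, ITS2Structure] = {}
    hallmark_rows = []
    for otu in kept_otus:
        seq = to_rna(by_id[otu.centroid].sequence)
        if seq in supplied:
            st = ITS2Structure(otu.otu_id, seq, supplied[seq].dotbracket)
        elif config.fold_structures:
            st = ITS2Structure(otu.otu_id, seq, fold_dotbracket(seq))
        else:
            continue
        annotate_helices(st)
        rep = validate_hallmarks(st)
        hallmark_rows.append((otu.otu_id, rep))
        if rep.overall:
            structures[otu.otu_id] = st
    if hallmark_rows:
        with open(outdir / "hallmarks.tsv", "w") as fh:
            fh.write("otu_id\tfour_helices\thelixII_UU\tyggy\toverall\n")
            for oid, rep in hallmark_rows:
                fh.write(f"{oid}\t{int(rep.four_helices)}\t{int(rep.helixII_UU)}\t"
                         f"{int(rep.yggy_helixIII_5prime_apex)}\t{int(rep.overall)}\n")
    if structures:
        # species boundaries are drawn within taxonomic groups (between
        # groups the question does not arise); the unit-cost aligner is
        # adequate for the near-identical within-group comparisons
        pools: dict[str, list[str]] = {}
        for oid in sorted(structures):
            label = assignments[oid].group_label if oid in assignments else ""
            pools.setdefault(label, []).append(oid)
        species = []
        for label in sorted(pools):
            species.extend(delimit_species(pools[label], structures, edlib_align))
        with open(outdir / "species.tsv", "w") as fh:
            fh.write("species_id\totu_id\n")
            for k, comp in enumerate(species, 1):
                for oid in comp:
                    fh.write(f"SP{k:03d}\t{oid}\n")

    sample_regions = {s.sample_id: s.region for s in samples}
    result_stats: dict = {}
    matrix = otu_matrix = summary = None
    classification: dict = {}
    if kept_phylotypes:
        matrix = bg.CommunityMatrix.from_phylotypes(kept_phylotypes, sample_regions)
        matrix.to_tsv(outdir / "community_phylotypes.tsv")
        kept_otu_counts = {
            o.otu_id: otu_counts[o.otu_id] for o in kept_otus
        }
        odf = pd.DataFrame(kept_otu_counts).fillna(0).astype(int)
        odf = odf.reindex(matrix.counts.index).fillna(0).astype(int)
        otu_matrix = bg.CommunityMatrix(odf, matrix.regions)
        otu_matrix.to_tsv(outdir / "community_otus.tsv")

        classification = bg.classify_all(matrix, scheme=config.region_scheme)
        with open(outdir / "biogeo.tsv", "w") as fh:
            fh.write("taxon_id\tregions_present\tcategory\n")
            for t in sorted(classification):
                c = classification[t]
                fh.write(f"{t}\t{'+'.join(sorted(c.regions_present))}\t{c.category}\n")
        summary = bg.read_share_summary(matrix, classification, config.region_scheme)
        _write_summary(summary, outdir / "summary.json")

        result_stats = _community_statistics(matrix, samples, config, outdir)
        graph = bg.cooccurrence_network(
            matrix, config.network_subsample, seed=config.seed)
        nx.write_graphml(graph, outdir / "network.graphml")
        with open(outdir / "network_edges.tsv", "w") as fh:
            fh.write("sample_id\ttaxon_id\tweight\n")
            for u, v, w in sorted(graph.edges(data="weight")):
                fh.write(f"{u}\t{v}\t{w}\n")

    ledger.to_tsv(outdir / "ledger.tsv")
    return PipelineResult(
        outdir=outdir, ledger=ledger, phylotypes=kept_phylotypes,
        otus=kept_otus, matrix=matrix, otu_matrix=otu_matrix,
        classification=classification, summary=summary,
        stats=result_stats, species=species,
    )


def _write_summary(summary: bg.BiogeoSummary, path: Path) -> None:
    payload = {
        "endemic_unique_fraction": summary.endemic_unique_fraction,
        "bipolar_read_share": summary.bipolar_read_share,
        "endemic_read_share": summary.endemic_read_share,
        "mean_endemic_unique_fraction": summary.mean_endemic_unique_fraction,
        "mean_bipolar_read_share": summary.mean_bipolar_read_share,
        "mean_endemic_read_share": summary.mean_endemic_read_share,
        "pooled_endemic_unique_fraction": summary.pooled_endemic_unique_fraction,
        "pooled_bipolar_read_share": summary.pooled_bipolar_read_share,
        "pooled_endemic_read_share": summary.pooled_endemic_read_share,
        "category_counts": summary.category_counts,
    }
    path.write_text(json.dumps(payload, indent=2))


def _community_statistics(
    matrix: bg.CommunityMatrix,
    samples: Sequence[SampleMetadata],
    config: PipelineConfig,
    outdir: Path,
) -> dict:
    counts = matrix.counts.to_numpy(dtype=float)
    labels = matrix.samples
    shannon = {s: cstats.shannon(counts[i]) for i, s in enumerate(labels)}
    dm = cstats.bray_curtis_matrix(counts, labels)
    dm.to_tsv(outdir / "bray_curtis.tsv")
    (outdir / "dendrogram.nwk").write_text(cstats.upgma_newick(dm) + "\n")
    groups = [str(matrix.regions[s]) for s in labels]
    out: dict = {"shannon": shannon}
    if len(set(groups)) >= 2:
        pr = cstats.permanova(dm, groups, n_perm=config.n_perm, seed=config.seed)
        out["permanova"] = {
            "pseudo_F": pr.statistic, "p_value": pr.p_value,
            "n_permutations": pr.n_permutations, "seed": pr.seed,
        }
    coords = {s.sample_id: (s.latitude, s.longitude) for s in samples}
    if len(labels) >= 4:
        geo = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                b = labels[j]
                geo[i, j] = geo[j, i] = cstats.haversine_km(*coords[a], *coords[b])
        gm = cstats.DistanceMatrix(labels, geo)
        gm.to_tsv(outdir / "geographic_km.tsv")
        mr = cstats.mantel(dm, gm, n_perm=config.n_perm, seed=config.seed)
        out["mantel"] = {
            "r": mr.statistic, "p_value": mr.p_value,
            "n_permutations": mr.n_permutations, "seed": mr.seed,
        }
    with open(outdir / "stats.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out
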