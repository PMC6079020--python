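"""Biogeographic classification of phylotypes/OTUs and read-share
accounting.

Each taxon's region-presence set places it in one of four mutually
exclusive categories under the two-pole scheme (Arctic regions vs
Antarctica):

* ``endemic`` — detected in exactly one region;
* ``arctic_shared`` — two or more Arctic regions, but not all of them,
  and absent from Antarctica;
* ``entire_arctic`` — all Arctic regions, absent from Antarctica;
* ``bipolar`` — at least one Arctic region and Antarctica (the
  cosmopolitan pattern).

The summary reports, per region, the fraction of taxa present there that
are endemic to it and the fraction of reads belonging to bipolar taxa,
each also aggregated across regions both as an arithmetic mean of the
regional values and as a pooled read/taxon-weighted total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RegionScheme",
    "CommunityMatrix",
    "BiogeoClassification",
    "BiogeoSummary",
    "presence_table",
    "classify_biogeo",
    "classify_all",
    "read_share_summary",
    "cooccurrence_network",
]

CATEGORIES = ("endemic", "arctic_shared", "entire_arctic", "bipolar")


@dataclass(frozen=True)
class RegionScheme:
    arctic: frozenset[str] = frozenset({"Svalbard", "Greenland", "Alaska"})
    antarctic: frozenset[str] = frozenset({"Antarctica"})

    @property
    def regions(self) -> frozenset[str]:
        return self.arctic | self.antarctic


DEFAULT_SCHEME = RegionScheme()


@dataclass
class CommunityMatrix:
    """Samples x taxa count matrix with per-sample region labels."""

    counts: pd.DataFrame  # index: sample_id, columns: taxon_id
    regions: pd.Series    # index: sample_id -> region label

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.regions.index):
            self.regions = self.regions.reindex(self.counts.index)
            if self.regions.isna().any():
                raise ValueError("every sample needs a region label")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        empty = self.counts.columns[(self.counts.sum(axis=0) == 0)]
        if len(empty):
            raise ValueError(f"all-zero taxon columns: {list(empty)[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def region_totals(self) -> pd.DataFrame:
        """Region x taxon summed counts."""
        return self.counts.groupby(self.regions).sum()

    def drop_taxa(self, taxa: Sequence[str]) -> "CommunityMatrix":
        kept = self.counts.drop(columns=list(taxa))
        kept = kept.loc[:, kept.sum(axis=0) > 0]
        return CommunityMatrix(kept, self.regions)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.T.to_csv(path, sep="\t", index_label="taxon_id")

    @staticmethod
    def from_phylotypes(phylotypes, sample_regions: Mapping[str, str]) -> "CommunityMatrix":
        data = {p.phylotype_id: p.per_sample_counts for p in phylotypes}
        df = pd.DataFrame(data).fillna(0).astype(int)
        df = df.reindex(sorted(sample_regions)).fillna(0).astype(int)
        return CommunityMatrix(df, pd.Series(dict(sample_regions)).loc[df.index])


@dataclass
class BiogeoClassification:
    taxon_id: str
    regions_present: frozenset[str]
    category: str


@dataclass
class BiogeoSummary:
    endemic_unique_fraction: dict[str, float]
    bipolar_read_share: dict[str, float]
    endemic_read_share: dict[str, float]
    mean_endemic_unique_fraction: float
    mean_bipolar_read_share: float
    mean_endemic_read_share: float
    pooled_endemic_unique_fraction: float
    pooled_bipolar_read_share: float
    pooled_endemic_read_share: float
    category_counts: dict[str, int] = field(default_factory=dict)


def presence_table(
    matrix: CommunityMatrix,
    min_count: int = 1,
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> dict[str, frozenset[str]]:
    """taxon -> set of regions where its summed count >= min_count."""
    unknown = set(matrix.regions.unique()) - set(scheme.regions)
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    totals = matrix.region_totals()
    out: dict[str, frozenset[str]] = {}
    for taxon in matrix.taxa:
        present = frozenset(totals.index[totals[taxon] >= min_count])
        out[taxon] = present
    return out


def classify_biogeo(
    regions_present: frozenset[str] | set[str],
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> str:
    """Deterministic category from a non-empty region-presence set."""
    present = frozenset(regions_present)
    if not present:
        raise ValueError("empty presence set")
    if not present <= scheme.regions:
        raise ValueError(f"presence set outside declared regions: {present}")
    if len(present) == 1:
        return "endemic"
    if present & scheme.arctic and present & scheme.antarctic:
        return "bipolar"
    if present == scheme.arctic:
        return "entire_arctic"
    return "arctic_shared"


def classify_all(
    matrix: CommunityMatrix,
    min_count: int = 1,
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> dict[str, BiogeoClassification]:
    presence = presence_table(matrix, min_count, scheme)
    return {
        t: BiogeoClassification(t, rp, classify_biogeo(rp, scheme))
        for t, rp in presence.items()
        if rp  # taxa below min_count everywhere are unclassifiable
    }


def read_share_summary(
    matrix: CommunityMatrix,
    classification: Mapping[str, BiogeoClassification],
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> BiogeoSummary:
    """Per-region endemic unique fractions and bipolar/endemic read shares.

    Regions with zero reads are excluded from the means.  Pooled variants
    aggregate region-taxon incidences (for unique fractions) and raw reads
    (for read shares) before dividing.
    """
    missing = set(matrix.taxa) - set(classification)
    if missing:
        raise ValueError(f"classification missing taxa: {sorted(missing)[:5]}")
    totals = matrix.region_totals()
    regions = sorted(totals.index)
    bipolar_taxa = [t for t in matrix.taxa if classification[t].category == "bipolar"]
    endemic_frac: dict[str, float] = {}
    bipolar_share: dict[str, float] = {}
    endemic_share: dict[str, float] = {}
    pooled_present = 0
    pooled_endemic_taxa = 0
    for r in regions:
        row = totals.loc[r]
        region_reads = int(row.sum())
        present = [t for t in matrix.taxa if row[t] > 0]
        endemics = [
            t for t in present
            if classification[t].category == "endemic"
            and classification[t].regions_present == frozenset({r})
        ]
        pooled_present += len(present)
        pooled_endemic_taxa += len(endemics)
        if region_reads == 0 or not present:
            endemic_frac[r] = float("nan")
            bipolar_share[r] = float("nan")
            endemic_share[r] = float("nan")
            continue
        endemic_frac[r] = len(endemics) / len(present)
        bipolar_share[r] = float(row[bipolar_taxa].sum()) / region_reads
        endemic_share[r] = float(row[endemics].sum()) / region_reads
    total_reads = float(totals.to_numpy().sum())
    bip_reads = float(totals[bipolar_taxa].to_numpy().sum()) if bipolar_taxa else 0.0
    all_endemic = [t for t in matrix.taxa if classification[t].category == "endemic"]
    end_reads = float(totals[all_endemic].to_numpy().sum()) if all_endemic else 0.0

    def _mean(d: dict[str, float]) -> float:
        vals = [v for v in d.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    cat_counts = {c: 0 for c in CATEGORIES}
    for t in matrix.taxa:
        cat_counts[classification[t].category] += 1
    return BiogeoSummary(
        endemic_unique_fraction=endemic_frac,
        bipolar_read_share=bipolar_share,
        endemic_read_share=endemic_share,
        mean_endemic_unique_fraction=_mean(endemic_frac),
        mean_bipolar_read_share=_mean(bipolar_share),
        mean_endemic_read_share=_mean(endemic_share),
        pooled_endemic_unique_fraction=(
            pooled_endemic_taxa / pooled_present if pooled_present else float("nan")
        ),
        pooled_bipolar_read_share=bip_reads / total_reads if total_reads else float("nan"),
        pooled_endemic_read_share=end_reads / total_reads if total_reads else float("nan"),
        category_counts=cat_counts,
    )


def cooccurrence_network(
    matrix: CommunityMatrix,
    n_subsample: int = 20000,
    seed: int | None = None,
) -> nx.Graph:
    """Bipartite sample-taxon co-occurrence graph.

    Taxa are subsampled uniformly without replacement (all kept when fewer
    than ``n_subsample``); an edge joins a sample to a taxon it contains,
    weighted by the count.  Sample nodes carry their region label.
    """
    if n_subsample < 1:
        raise ValueError("n_subsample must be >= 1")
    rng = np.random.default_rng(seed)
    taxa = matrix.taxa
    if len(taxa) > n_subsample:
        chosen = sorted(rng.choice(len(taxa), size=n_subsample, replace=False))
        taxa = [taxa[i] for i in chosen]
    g = nx.Graph()
    for s in matrix.samples:
        g.add_node(s, bipartite="sample", region=str(matrix.regions[s]))
    for t in taxa:
        g.add_node(t, bipartite="taxon")
    for t in taxa:
        col = matrix.counts[t]
        for s in matrix.samples:
            c = int(col[s])
            if c > 0:
                g.add_edge(s, t, weight=c)
    return g
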