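"""Ground-truth metacommunity and amplicon read simulator.

The generator emulates the statistical structure of a two-pole red-snow
survey: four regions (three Arctic, one Antarctic) with a few snow-covered
sites each, regional phylotype pools with configurable
endemic / Arctic-shared / entire-Arctic / bipolar composition, heavy-tailed
(log-normal) template abundances renormalized to hit target per-region
category read shares exactly, per-base sequencing error, PCR chimera
formation by template splicing, and primer/index decoration of paired
reads.

Templates descend from a fixed hallmark-valid ITS2 scaffold (four helices,
U-U mismatch in helix II, YGGY near the helix-III apex) whose secondary
structure is preserved under mutation: unpaired loop positions mutate
freely, paired positions mutate as whole canonical-pair replacements, and
species identities are encoded as compensated pair states inside the
helix-III apex window, so structure-based delimitation can be exercised
with known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reads import revcomp
from .structure import ITS2Structure, to_rna

__all__ = [
    "SimConfig",
    "Scaffold",
    "Metacommunity",
    "make_scaffold",
    "build_metacommunity",
    "simulate_reads",
    "evaluate_recovery",
]

ARCTIC = ("Svalbard", "Greenland", "Alaska")
ANTARCTIC = ("Antarctica",)

# representative site coordinates (deg): around Langhovde, Ny-Alesund,
# Qaanaaq and the Alaska Range
REGION_COORDS = {
    "Antarctica": (-69.2, 39.7),
    "Svalbard": (78.9, 11.9),
    "Greenland": (77.5, -69.2),
    "Alaska": (63.1, -150.0),
}

FWD_PRIMER = "CCAGCASCYGCGGTAATTCC"   # TAReuk454FWD1
REV_PRIMER = "TCCTCCGCTTATTGATATGC"   # ITS4

_PAIR_PALETTE = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]
_CANONICAL_CHOICES = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Default category counts and read-share targets mirror the regime of a
    two-pole red-snow survey: roughly half of the phylotypes present in a
    region endemic to it, a small entire-Arctic pool, and a handful of
    bipolar phylotypes that nonetheless dominate the reads.
    """

    sites_per_region: int = 3
    reads_per_sample: int = 20000
    read_length: int = 170
    per_base_error: float = 0.001
    chimera_rate: float = 0.02
    # phylotype pool composition: a desk-scale rendering of a survey with
    # ~0.03 unique sequences per read (tens of thousands of uniques from a
    # few million reads), split ~55% endemic on average, with a small
    # bipolar pool that nonetheless dominates the reads
    endemic_counts: dict[str, int] = field(default_factory=lambda: {
        "Antarctica": 1890, "Svalbard": 1080, "Greenland": 324, "Alaska": 2619,
    })
    arctic_shared_counts: dict[str, int] = field(default_factory=lambda: {
        "Svalbard+Greenland": 270, "Svalbard+Alaska": 162, "Greenland+Alaska": 270,
    })
    entire_arctic_count: int = 108
    bipolar_count: int = 540
    # per-region read-share targets by category (endemic takes the rest)
    bipolar_read_share: dict[str, float] = field(default_factory=lambda: {
        "Antarctica": 0.123, "Svalbard": 0.478, "Greenland": 0.684, "Alaska": 0.272,
    })
    arctic_shared_read_share: float = 0.10
    entire_arctic_read_share: float = 0.05
    # abundance and divergence structure
    lognormal_sigma: float = 1.0
    n_groups: int = 4                 # taxonomic groups (reference-db units)
    group_divergence: float = 0.08    # scaffold -> group ancestor
    otu_divergence: float = 0.04      # group ancestor -> OTU ancestor (>2% pairwise)
    within_otu_divergence: float = 0.005  # OTU ancestor -> phylotype (<2% pairwise)
    phylotypes_per_otu: int = 5
    n_species: int = 2                # CBC-coded species states (<= 4)
    indel_rate: float = 0.0
    fwd_primer: str = FWD_PRIMER
    rev_primer: str = REV_PRIMER
    base_quality: int = 35
    # miscalled bases draw low quality scores, as on a real instrument;
    # quality truncation and overlap consensus then remove many of them
    error_qualities: tuple[int, ...] = (2, 12, 25)
    error_quality_probs: tuple[float, ...] = (0.45, 0.35, 0.20)
    seed: int = 0

    @property
    def regions(self) -> tuple[str, ...]:
        return ANTARCTIC + ARCTIC

    def validate(self) -> None:
        for r in self.regions:
            share = self.bipolar_read_share.get(r, 0.0)
            if r in ARCTIC:
                share += self.arctic_shared_read_share + self.entire_arctic_read_share
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"{r}: category read shares exceed 1")
        for v in (self.per_base_error, self.chimera_rate, self.indel_rate):
            if not 0.0 <= v <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not 1 <= self.n_species <= len(_PAIR_PALETTE):
            raise ValueError("n_species must be in 1..4")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @staticmethod
    def from_mapping(m: Mapping) -> "SimConfig":
        return SimConfig(**dict(m))


@dataclass
class Scaffold:
    """Hallmark-valid ITS2 scaffold with mutation bookkeeping."""

    sequence: str          # RNA
    dotbracket: str
    loop_positions: list[int]       # freely mutable unpaired positions
    mutable_pairs: list[tuple[int, int]]   # pairs replaceable by any canonical pair
    window_pairs: list[tuple[int, int]]    # helix-III apex pairs reserved for CBC states

    def structure(self, name: str, sequence: str | None = None) -> ITS2Structure:
        return ITS2Structure(
            name=name,
            sequence=sequence if sequence is not None else self.sequence,
            dotbracket=self.dotbracket,
        )


def _hairpin(stem5: str, loop: str) -> tuple[str, str]:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    stem3 = "".join(comp[c] for c in reversed(stem5))
    seq = stem5 + loop + stem3
    db = "(" * len(stem5) + "." * len(loop) + ")" * len(stem5)
    return seq, db


def make_scaffold() -> Scaffold:
    """Deterministic canonical scaffold (~250 nt).

    Four helices on a basal loop enclosed by an outer stem; helix II
    carries a 1x1 U-U internal loop; the last four 5'-strand pairs of
    helix III spell UGGU (a YGGY match) right at the apical loop; four
    additional apex pairs just below it are reserved to encode species
    states (planted CBCs).
    """
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}

    def rc(s: str) -> str:
        return "".join(comp[c] for c in reversed(s))

    # helix I: 24-bp stem, 6-nt loop
    h1_seq, h1_db = _hairpin("GCAGGCAUCCGAGGCAGGCAUGCA", "AACAAA")
    # helix II: 10-bp stem, U.U internal loop, 8-bp stem, 6-nt loop
    a5, b5 = "GGCAGGCAGC", "GACCGGAC"
    h2_seq = a5 + "U" + b5 + "AAGAAA" + rc(b5) + "U" + rc(a5)
    h2_db = "(" * 10 + "." + "(" * 8 + "." * 6 + ")" * 8 + "." + ")" * 10
    # helix III: 28-bp stem, 7-nt loop; 5' stem ends ...GCAC|UGGU at the apex
    # (UGGU = YGGY); the 4 pairs of GCAC below it are the species slots
    h3_lower = "GGACGCAGGCAUGCCAGGCAGGACGCAG"    # 28 pairs
    h3_window = "GCAC"                   # 4 reserved species-state pairs
    h3_yggy = "UGGU"                     # 4 pairs, 5' strand = YGGY motif
    h3_5p = h3_lower + h3_window + h3_yggy
    h3_seq, h3_db = _hairpin(h3_5p, "AAACAAA")
    # helix IV: 18-bp stem, 6-nt loop
    h4_seq, h4_db = _hairpin("GGCACGGAUGCCAGGCAU", "AAGCAA")
    # outer stem: 8 bp
    out5 = "GGCAGCAC"
    seq = (
        "AA" + out5
        + "AAA" + h1_seq + "AA" + h2_seq + "AA" + h3_seq + "AA" + h4_seq + "AAA"
        + rc(out5) + "AA"
    )
    db = (
        ".." + "(" * 8
        + "..." + h1_db + ".." + h2_db + ".." + h3_db + ".." + h4_db + "..."
        + ")" * 8 + ".."
    )
    s = ITS2Structure(name="scaffold", sequence=seq, dotbracket=db)
    from .structure import annotate_helices, helix_iii_apex_window
    annotate_helices(s)
    assert len(s.helices) == 4, "scaffold must have four helices"
    win = helix_iii_apex_window(s)
    h3 = s.helices[2]
    window_pairs = [p for p in h3.pairs if win[0] <= p[0] < win[1]]
    yggy_start = seq.find("UGGU", win[0])
    # species slots: window pairs whose 5' base is below the YGGY motif
    species_slots = [p for p in window_pairs if p[0] < yggy_start]
    paired = {i for p in s.pairs for i in p}
    loop_positions = [
        i for i, c in enumerate(seq)
        if i not in paired and seq[i] != "U"  # keep the U.U mismatch intact
    ]
    helix_pairs = set(h3.pairs[-10:])  # apex window pairs are reserved
    mutable_pairs = [p for p in s.pairs if p not in helix_pairs]
    return Scaffold(
        sequence=seq,
        dotbracket=db,
        loop_positions=loop_positions,
        mutable_pairs=mutable_pairs,
        window_pairs=species_slots,
    )


def _mutate(seq: list[str], scaffold: Scaffold, n_sub: int, rng: np.random.Generator) -> None:
    """Apply n_sub substitutions preserving the scaffold structure."""
    bases = "ACGU"
    n_loops = len(scaffold.loop_positions)
    done = 0
    guard = 0
    while done < n_sub and guard < 50 * n_sub + 100:
        guard += 1
        if rng.random() < n_loops / (n_loops + 2 * len(scaffold.mutable_pairs)):
            pos = scaffold.loop_positions[rng.integers(n_loops)]
            new = bases[rng.integers(4)]
            if new != seq[pos]:
                seq[pos] = new
                done += 1
        else:
            i, j = scaffold.mutable_pairs[rng.integers(len(scaffold.mutable_pairs))]
            x, y = _CANONICAL_CHOICES[rng.integers(len(_CANONICAL_CHOICES))]
            changed = (seq[i] != x) + (seq[j] != y)
            if changed:
                seq[i], seq[j] = x, y
                done += changed


@dataclass
class Metacommunity:
    config: SimConfig
    scaffold: Scaffold
    templates: pd.DataFrame
    # columns: template_id, sequence (DNA), category, regions ('+'-joined),
    #          otu_ancestor, group, species, weight
    proportions: pd.DataFrame  # region x template expected read proportions
    group_ancestors: dict[str, str] = field(default_factory=dict)  # label -> DNA

    def reference_records(self):
        """Group ancestors as an in-house reference database."""
        from .taxonomy import ReferenceRecord
        return [
            ReferenceRecord(f"REF_{label.replace(' ', '_')}", seq, "ITS2", label)
            for label, seq in sorted(self.group_ancestors.items())
        ]

    def template_structures(self) -> dict[str, ITS2Structure]:
        return {
            row.template_id: self.scaffold.structure(row.template_id, to_rna(row.sequence))
            for row in self.templates.itertuples()
        }

    def sample_layout(self) -> pd.DataFrame:
        rows = []
        rng = np.random.default_rng(self.config.seed + 7)
        for region in self.config.regions:
            lat0, lon0 = REGION_COORDS[region]
            for s in range(self.config.sites_per_region):
                rows.append({
                    "sample_id": f"{region}_s{s + 1}",
                    "site": f"{region}_site{s + 1}",
                    "region": region,
                    "lat": round(float(np.clip(lat0 + rng.uniform(-1, 1), -90, 90)), 4),
                    "lon": round(float(lon0 + rng.uniform(-1, 1)), 4),
                })
        alphabet = np.array(list("ACGT"))
        for i, row in enumerate(rows):
            idx = rng.integers(0, 4, size=16)
            row["i7"] = "".join(alphabet[idx[:8]])
            row["i5"] = "".join(alphabet[idx[8:]])
        return pd.DataFrame(rows)


def _presence_sets(config: SimConfig) -> list[tuple[str, frozenset[str]]]:
    """(category, regions_present) for every template, in a fixed order."""
    out: list[tuple[str, frozenset[str]]] = []
    for region in config.regions:
        for _ in range(config.endemic_counts.get(region, 0)):
            out.append(("endemic", frozenset({region})))
    for key, n in sorted(config.arctic_shared_counts.items()):
        regions = frozenset(key.split("+"))
        if not regions < set(ARCTIC) or len(regions) < 2:
            raise ValueError(f"bad arctic_shared key {key!r}")
        for _ in range(n):
            out.append(("arctic_shared", regions))
    for _ in range(config.entire_arctic_count):
        out.append(("entire_arctic", frozenset(ARCTIC)))
    for _ in range(config.bipolar_count):
        out.append(("bipolar", frozenset(config.regions)))
    return out


def build_metacommunity(config: SimConfig) -> Metacommunity:
    """Generate templates and exact per-region expected read proportions.

    Per region, the configured category shares are allocated exactly:
    templates of a category present in the region split their category's
    share in proportion to their log-normal weights, and endemic templates
    take the remaining share.  Renormalization is exact before sampling.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scaffold = make_scaffold()
    presence = _presence_sets(config)
    n = len(presence)
    L = len(scaffold.sequence)
    n_otus = max(1, -(-n // config.phylotypes_per_otu))
    # group ancestors (taxonomic groups, the reference-database units)
    group_labels = [f"snow group {chr(65 + g)}" for g in range(config.n_groups)]
    group_seqs: list[list[str]] = []
    for g in range(config.n_groups):
        anc = list(scaffold.sequence)
        _mutate(anc, scaffold, round(config.group_divergence * L), rng)
        group_seqs.append(anc)
    # OTU ancestors, each carrying its species' CBC pair state
    ancestors: list[list[str]] = []
    for k in range(n_otus):
        anc = list(group_seqs[k % config.n_groups])
        # vary species states within each group
        species = (k // config.n_groups) % config.n_species
        x, y = _PAIR_PALETTE[species]
        for i, j in scaffold.window_pairs:
            anc[i], anc[j] = x, y
        _mutate(anc, scaffold, round(config.otu_divergence * L), rng)
        ancestors.append(anc)
    rows = []
    seen: set[str] = set()
    for t, (category, regions) in enumerate(presence):
        otu = t % n_otus
        guard = 0
        while True:
            guard += 1
            seq = list(ancestors[otu])
            _mutate(seq, scaffold,
                    max(1, round(config.within_otu_divergence * L)), rng)
            rna = "".join(seq)
            if rna not in seen or guard > 100:
                break
        seen.add(rna)
        rows.append({
            "template_id": f"T{t + 1:04d}",
            "sequence": rna.replace("U", "T"),
            "category": category,
            "regions": "+".join(sorted(regions)),
            "otu_ancestor": f"A{otu + 1:04d}",
            "group": group_labels[otu % config.n_groups],
            "species": f"S{((otu // config.n_groups) % config.n_species) + 1}",
            "weight": float(rng.lognormal(0.0, config.lognormal_sigma)),
        })
    templates = pd.DataFrame(rows)
    group_ancestors = {
        lab: "".join(seq).replace("U", "T")
        for lab, seq in zip(group_labels, group_seqs)
    }
    # exact per-region proportions
    prop = pd.DataFrame(0.0, index=list(config.regions), columns=templates.template_id)
    for region in config.regions:
        shares = {"bipolar": config.bipolar_read_share.get(region, 0.0)}
        if region in ARCTIC:
            shares["arctic_shared"] = config.arctic_shared_read_share
            shares["entire_arctic"] = config.entire_arctic_read_share
        shares["endemic"] = 1.0 - sum(shares.values())
        for category, share in shares.items():
            mask = templates.category.eq(category) & templates.regions.str.split("+").map(
                lambda rs, region=region: region in rs
            )
            sub = templates[mask]
            if sub.empty:
                continue
            w = sub.weight.to_numpy()
            prop.loc[region, sub.template_id] = share * w / w.sum()
        total = prop.loc[region].sum()
        if total > 0:
            prop.loc[region] /= total  # exact renormalization (guards empty categories)
    return Metacommunity(config, scaffold, templates, prop, group_ancestors)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitutions at the given rate; returns error positions mask."""
    if rate <= 0:
        return np.zeros(mat.shape, dtype=bool)
    mask = rng.random(mat.shape) < rate
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum()))
        idx = np.searchsorted(_BASES, mat[mask])  # bases are sorted ACGT
        mat[mask] = _BASES[(idx + shift) % 4]
    return mask


def simulate_reads(
    meta: Metacommunity,
    outdir: str | Path,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate paired FASTQ for every sample; returns the per-read truth.

    Reads are multinomial draws from the region's template proportions;
    chimeras splice two sampled templates at a uniform crossover; each mate
    receives independent per-base substitution errors; amplicons carry the
    primers, and the dual index is written into the Illumina-style header
    comment.  Output: ``R1.fastq``, ``R2.fastq``, ``metadata.tsv``,
    ``templates.fasta``, ``structures.vienna``, ``truth_templates.tsv``,
    ``truth_expected_counts.tsv``, ``truth_reads.tsv``.
    """
    config = meta.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    layout = meta.sample_layout()
    layout.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    with open(outdir / "templates.fasta", "w") as fh:
        for row in meta.templates.itertuples():
            fh.write(f">{row.template_id} {row.category} {row.regions}\n{row.sequence}\n")
    from .structure import write_vienna
    write_vienna(
        [meta.scaffold.structure(r.template_id, to_rna(r.sequence))
         for r in meta.templates.itertuples()],
        outdir / "structures.vienna",
    )
    meta.templates.to_csv(outdir / "truth_templates.tsv", sep="\t", index=False)

    seqs = {r.template_id: r.sequence for r in meta.templates.itertuples()}
    tids = list(meta.proportions.columns)
    rlen = config.read_length
    truth_rows = []
    expected_rows = []
    r1_chunks: list[str] = []
    r2_chunks: list[str] = []
    qline = chr(config.base_quality + 33) * rlen
    eq = np.array(config.error_qualities, dtype=np.uint8)
    eqp = np.array(config.error_quality_probs, dtype=float)
    eqp = eqp / eqp.sum()

    def _qual_lines(mask: np.ndarray) -> list[str]:
        if not mask.any():
            return [qline] * mask.shape[0]
        Q = np.full(mask.shape, config.base_quality + 33, dtype=np.uint8)
        Q[mask] = eq[rng.choice(len(eq), size=int(mask.sum()), p=eqp)] + 33
        return [row.tobytes().decode() for row in Q]
    for sample in layout.itertuples():
        p = meta.proportions.loc[sample.region].to_numpy()
        counts = rng.multinomial(config.reads_per_sample, p)
        for tid, c in zip(tids, counts):
            if c:
                expected_rows.append({
                    "sample_id": sample.sample_id, "template_id": tid,
                    "expected_count": config.reads_per_sample
                    * meta.proportions.loc[sample.region, tid],
                    "sampled_count": int(c),
                })
        read_no = 0
        for tid, c in zip(tids, counts):
            if c == 0:
                continue
            n_chim = rng.binomial(c, config.chimera_rate)
            amp = config.fwd_primer.replace("S", "C").replace("Y", "C") \
                + seqs[tid] + revcomp(config.rev_primer)
            plain = c - n_chim
            if plain:
                fwd = np.frombuffer(amp[:rlen].encode(), dtype=np.uint8)
                rev = np.frombuffer(revcomp(amp)[:rlen].encode(), dtype=np.uint8)
                F = np.tile(fwd, (plain, 1))
                R = np.tile(rev, (plain, 1))
                e1 = _apply_errors(F, config.per_base_error, rng)
                e2 = _apply_errors(R, config.per_base_error, rng)
                nerr = e1.sum(axis=1) + e2.sum(axis=1)
                q1 = _qual_lines(e1)
                q2 = _qual_lines(e2)
                for k in range(plain):
                    rid = f"sim:{sample.sample_id}:{read_no}"
                    read_no += 1
                    hdr = f"{rid} 1:N:0:{sample.i7}+{sample.i5}"
                    r1_chunks.append(f"@{hdr}\n{F[k].tobytes().decode()}\n+\n{q1[k]}\n")
                    r2_chunks.append(f"@{hdr}\n{R[k].tobytes().decode()}\n+\n{q2[k]}\n")
                    truth_rows.append({
                        "sample_id": sample.sample_id, "read_id": rid,
                        "template_id": tid, "is_chimera": False,
                        "partner": "", "n_errors": int(nerr[k]),
                    })
            for _ in range(n_chim):
                partner = tids[rng.choice(len(tids), p=p)]
                a, b = seqs[tid], seqs[partner]
                x = int(rng.integers(30, min(len(a), len(b)) - 30))
                chim = a[:x] + b[x:]
                amp_c = config.fwd_primer.replace("S", "C").replace("Y", "C") \
                    + chim + revcomp(config.rev_primer)
                f = bytearray(amp_c[:rlen].encode())
                r = bytearray(revcomp(amp_c)[:rlen].encode())
                Fc = np.frombuffer(bytes(f), dtype=np.uint8).copy()[None, :]
                Rc = np.frombuffer(bytes(r), dtype=np.uint8).copy()[None, :]
                e1 = _apply_errors(Fc, config.per_base_error, rng)
                e2 = _apply_errors(Rc, config.per_base_error, rng)
                rid = f"sim:{sample.sample_id}:{read_no}"
                read_no += 1
                hdr = f"{rid} 1:N:0:{sample.i7}+{sample.i5}"
                r1_chunks.append(f"@{hdr}\n{Fc[0].tobytes().decode()}\n+\n{_qual_lines(e1)[0]}\n")
                r2_chunks.append(f"@{hdr}\n{Rc[0].tobytes().decode()}\n+\n{_qual_lines(e2)[0]}\n")
                truth_rows.append({
                    "sample_id": sample.sample_id, "read_id": rid,
                    "template_id": tid, "is_chimera": True,
                    "partner": partner, "n_errors": int(e1.sum() + e2.sum()),
                })
    (outdir / "R1.fastq").write_text("".join(r1_chunks))
    (outdir / "R2.fastq").write_text("".join(r2_chunks))
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    pd.DataFrame(expected_rows).to_csv(
        outdir / "truth_expected_counts.tsv", sep="\t", index=False)
    # region-consistency invariant: no read outside its template's regions
    region_of = dict(zip(layout.sample_id, layout.region))
    tmpl_regions = {
        r.template_id: set(r.regions.split("+")) for r in meta.templates.itertuples()
    }
    for row in truth.itertuples():
        assert region_of[row.sample_id] in tmpl_regions[row.template_id], (
            "simulated read outside its template's region set"
        )
    return truth


def evaluate_recovery(
    estimated_classification: Mapping[str, str],
    estimated_summary,
    truth_templates: pd.DataFrame,
    truth_summary,
    phylotype_sequences: Mapping[str, str] | None = None,
    otu_members: Mapping[str, Sequence[str]] | None = None,
) -> dict:
    """Compare pipeline output against simulation truth.

    ``estimated_classification`` maps recovered taxon ids to categories;
    when ``phylotype_sequences`` is given, recovered taxa are matched to
    templates by exact sequence for the confusion matrix.  OTU purity is
    the fraction of OTUs whose matched members share one template
    ancestor.  Share errors are absolute differences of the per-region
    endemic unique fractions and bipolar read shares.
    """
    report: dict = {}
    truth_cat = dict(zip(truth_templates.sequence, truth_templates.category))
    truth_anc = dict(zip(truth_templates.sequence, truth_templates.otu_ancestor))
    if phylotype_sequences is not None:
        confusion: dict[tuple[str, str], int] = {}
        for taxon, cat in estimated_classification.items():
            seq = phylotype_sequences.get(taxon)
            true = truth_cat.get(seq)
            if true is not None:
                confusion[(true, cat)] = confusion.get((true, cat), 0) + 1
        report["confusion"] = confusion
        report["n_matched"] = sum(confusion.values())
        report["n_correct"] = sum(
            v for (t, e), v in confusion.items() if t == e
        )
    if otu_members is not None and phylotype_sequences is not None:
        pure = 0
        scored = 0
        for members in otu_members.values():
            ancs = {
                truth_anc[phylotype_sequences[m]]
                for m in members
                if phylotype_sequences.get(m) in truth_anc
            }
            if ancs:
                scored += 1
                if len(ancs) == 1:
                    pure += 1
        report["otu_purity"] = pure / scored if scored else float("nan")
        report["n_otus_scored"] = scored
    err_endemic = {}
    err_bipolar = {}
    for r in truth_summary.endemic_unique_fraction:
        err_endemic[r] = abs(
            estimated_summary.endemic_unique_fraction[r]
            - truth_summary.endemic_unique_fraction[r]
        )
        err_bipolar[r] = abs(
            estimated_summary.bipolar_read_share[r]
            - truth_summary.bipolar_read_share[r]
        )
    report["endemic_fraction_abs_error"] = err_endemic
    report["bipolar_share_abs_error"] = err_bipolar
    return report
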