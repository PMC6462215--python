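"""Synthetic ChIP-nexus data with ground truth.

Emulates a dual-receptor (MR/GR) ChIP-nexus experiment on a random genome:
binding sites are planted at non-overlapping positions, a fraction carry the
palindromic GRE consensus at their midpoint, and per-condition occupancy
encodes the affinity asymmetry between the high-affinity MR and the
low-affinity GR across a vehicle / CORT-pulse / washout design.  Reads are
emitted with 5' stops at the lambda-exonuclease borders flanking each
protected region (plus-strand reads at the left border, minus-strand reads
at the right border), carry a random barcode, and a configurable fraction
are PCR re-emissions with identical position, strand and barcode.

Coordinate convention: a planted site occupies ``[plus_border,
minus_border)`` so ``minus_border - plus_border == protected_width``;
minus-strand 5' stops are recorded at the exclusive-end coordinate.

Everything is deterministic given ``SimConfig.seed``; independent random
streams are derived per purpose so, e.g., regenerating reads for one
condition never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import CONDITIONS, FACTORS, ConfigError, SimConfig
from .intervals import GenomicInterval

#: Canonical palindromic glucocorticoid response element; N positions are
#: filled with random bases when planted.
GRE_CONSENSUS = "AGAACANNNTGTTCT"

BASES = np.frombuffer(b"ACGT", dtype="S1")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# stream ids for derived RNGs, so each purpose gets an independent stream
_STREAMS = {"genome": 1, "sites": 2, "reads": 3, "input": 4, "genes": 5}


def _rng(config: SimConfig, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream], *extra])


@dataclass
class ReadRecord:
    """One simulated FASTQ read (barcode + genomic insert)."""
    read_id: str
    sequence: str
    quality: str


@dataclass
class SiteTruth:
    site_id: str
    interval: GenomicInterval
    has_motif: bool
    bound: Dict[str, Dict[str, bool]]   # condition -> factor -> bool
    border_plus: int
    border_minus: int


class TruthTable:
    """Planted-site ground truth: coordinates, motif presence, occupancy."""

    def __init__(self, sites: List[SiteTruth], chrom: str):
        self.sites = sites
        self.chrom = chrom

    def __len__(self) -> int:
        return len(self.sites)

    def bound_sites(self, condition: str, factor: str) -> List[SiteTruth]:
        return [s for s in self.sites if s.bound[condition][factor]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            row = {
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "site_id": s.site_id,
                "has_motif": s.has_motif,
            }
            for fac in FACTORS:
                for cond in CONDITIONS:
                    row[f"bound_{fac}_{cond}"] = s.bound[cond][fac]
            row["border_plus"] = s.border_plus
            row["border_minus"] = s.border_minus
            rows.append(row)
        cols = (["chrom", "start", "end", "site_id", "has_motif"]
                + [f"bound_{f}_{c}" for f in FACTORS for c in CONDITIONS]
                + ["border_plus", "border_minus"])
        return pd.DataFrame(rows, columns=cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_bed(self, path) -> None:
        df = self.to_frame()
        bed = df[["chrom", "start", "end", "site_id"]].copy()
        bed["score"] = 0
        bed["strand"] = "."
        bed.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        sites = []
        for _, row in df.iterrows():
            bound = {c: {f: bool(row[f"bound_{f}_{c}"]) for f in FACTORS}
                     for c in CONDITIONS}
            sites.append(SiteTruth(
                site_id=row["site_id"],
                interval=GenomicInterval(row["chrom"], int(row["start"]),
                                         int(row["end"])),
                has_motif=bool(row["has_motif"]),
                bound=bound,
                border_plus=int(row["border_plus"]),
                border_minus=int(row["border_minus"]),
            ))
        chrom = df["chrom"].iloc[0] if len(df) else "chr1"
        return cls(sites, chrom)


def simulate_genome(config: SimConfig) -> str:
    """Random genome with the configured GC content, deterministic in seed."""
    if config.genome_length < 1000:
        raise ConfigError("genome_length must be >= 1000")
    rng = _rng(config, "genome")
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(BASES, size=config.genome_length, p=p)
    return arr.tobytes().decode("ascii")


# sites are kept at least this far from the genome edges so reads and
# scanning windows never run off the chromosome
_EDGE_MARGIN = 1000
_SLOT = 1000          # one site at most per kilobase slot


def plant_sites(genome: str, config: SimConfig) -> Tuple[str, TruthTable]:
    """Plant non-overlapping binding sites; returns modified genome + truth.

    Site class (co-bound / MR-only / GR-only) is drawn from
    ``co_binding_fraction``; per-condition bound flags are then drawn from
    the occupancy table for the capable factor(s).  ``motif_fraction`` of
    sites get the GRE consensus written at their midpoint.
    """
    L = len(genome)
    n = config.n_sites
    if n == 0:
        return genome, TruthTable([], config.chrom)
    usable = L - 2 * _EDGE_MARGIN
    n_slots = usable // _SLOT
    if n > n_slots:
        raise ConfigError(
            f"cannot place {n} non-overlapping sites in a {L} bp genome "
            f"({n_slots} slots of {_SLOT} bp available)")

    rng = _rng(config, "sites")
    slots = np.sort(rng.choice(n_slots, size=n, replace=False))
    pw = config.protected_width
    half = pw // 2
    jitter_room = len(GRE_CONSENSUS) + pw + 2 * config.border_jitter
    offsets = rng.integers(jitter_room, _SLOT - jitter_room, size=n)
    midpoints = _EDGE_MARGIN + slots * _SLOT + offsets

    motif_flags = rng.random(n) < config.motif_fraction
    class_draw = rng.random(n)
    c = config.co_binding_fraction
    # co-bound with prob c, else split evenly between MR-only and GR-only
    capable_mr = (class_draw < c) | (class_draw >= (1 + c) / 2)
    capable_gr = class_draw < (1 + c) / 2

    seq = list(genome)
    sites: List[SiteTruth] = []
    motif = GRE_CONSENSUS
    mhalf = len(motif) // 2
    for i, mid in enumerate(midpoints):
        start = int(mid) - half
        end = start + pw
        if motif_flags[i]:
            ms = int(mid) - mhalf
            for j, base in enumerate(motif):
                seq[ms + j] = (base if base != "N"
                               else str(BASES[rng.integers(4)], "ascii"))
        bound: Dict[str, Dict[str, bool]] = {}
        for cond in CONDITIONS:
            bound[cond] = {}
            for fac, capable in (("MR", capable_mr[i]), ("GR", capable_gr[i])):
                p = config.occupancy.get(cond, {}).get(fac, 0.0)
                bound[cond][fac] = bool(capable and rng.random() < p)
        sites.append(SiteTruth(
            site_id=f"site{i:04d}",
            interval=GenomicInterval(config.chrom, start, end),
            has_motif=bool(motif_flags[i]),
            bound=bound,
            border_plus=start,
            border_minus=end,
        ))
    return "".join(seq), TruthTable(sites, config.chrom)


def _read_from_position(genome: str, stop5: int, strand: str,
                        insert_length: int) -> str:
    """Genomic insert whose 5' end sits at ``stop5`` on ``strand``."""
    if strand == "+":
        return genome[stop5:stop5 + insert_length]
    return reverse_complement(genome[stop5 - insert_length + 1:stop5 + 1])


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> List[str]:
    arr = rng.choice(BASES, size=(n, length))
    return [row.tobytes().decode("ascii") for row in arr]


def _emit(genome: str, positions, strands, barcodes, origins, config: SimConfig,
          rng: np.random.Generator, tag_prefix: str
          ) -> Tuple[List[ReadRecord], pd.DataFrame]:
    """Assemble reads (with PCR duplicates) from original molecules."""
    m = len(positions)
    records: List[ReadRecord] = []
    rows = []
    qual = chr(config.base_quality + 33) * (config.barcode_length
                                            + config.insert_length)
    d = config.duplication_rate
    n_dup = int(round(d / (1.0 - d) * m)) if d > 0 else 0
    dup_of = rng.integers(0, m, size=n_dup) if m and n_dup else np.array([], int)
    order = rng.permutation(m + len(dup_of)) if m else np.array([], int)
    source = list(range(m)) + list(dup_of)
    for k, idx in enumerate(order):
        i = source[idx]
        stop5, strand, bc = int(positions[i]), strands[i], barcodes[i]
        insert = _read_from_position(genome, stop5, strand, config.insert_length)
        records.append(ReadRecord(f"{tag_prefix}_r{k:06d}", bc + insert, qual))
        rows.append({"chrom": config.chrom, "strand": strand, "stop5": stop5,
                     "barcode": bc, "origin": origins[i],
                     "is_duplicate": idx >= m})
    expected = pd.DataFrame(
        rows, columns=["chrom", "strand", "stop5", "barcode", "origin",
                       "is_duplicate"])
    return records, expected


def _background(genome: str, rate_per_kb: float, config: SimConfig,
                rng: np.random.Generator):
    """Uniformly placed reads with random strand; positions keep the insert
    inside the genome."""
    L = len(genome)
    n = int(rng.poisson(rate_per_kb * L / 1000.0))
    positions, strands = [], []
    ins = config.insert_length
    for _ in range(n):
        if rng.random() < 0.5:
            positions.append(int(rng.integers(0, L - ins + 1)))
            strands.append("+")
        else:
            positions.append(int(rng.integers(ins - 1, L)))
            strands.append("-")
    return positions, strands


def simulate_nexus_reads(genome: str, truth: TruthTable, condition: str,
                         factor: str, config: SimConfig
                         ) -> Tuple[List[ReadRecord], pd.DataFrame]:
    """ChIP-nexus reads for one immunoprecipitated factor in one condition.

    For every site bound by ``factor`` in ``condition``,
    ``reads_per_bound_site`` original molecules are emitted, split between
    strands: plus-strand 5' stops at the left border and minus-strand stops
    at the right border, each jittered uniformly within
    ``+/- border_jitter``.  Background molecules are placed uniformly.  On
    top of the originals, ``duplication_rate`` of the final stream are PCR
    duplicates.  Returns the FASTQ-ready records and the expected-tag table
    (one row per emitted read, duplicates flagged).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {CONDITIONS}")
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    rng = _rng(config, "reads", CONDITIONS.index(condition),
               FACTORS.index(factor))
    positions: List[int] = []
    strands: List[str] = []
    origins: List[str] = []
    r = config.reads_per_bound_site
    n_plus = (r + 1) // 2
    j = config.border_jitter
    for site in truth.bound_sites(condition, factor):
        for k in range(r):
            jit = int(rng.integers(-j, j + 1)) if j > 0 else 0
            if k < n_plus:
                positions.append(site.border_plus + jit)
                strands.append("+")
            else:
                positions.append(site.border_minus + jit)
                strands.append("-")
            origins.append(site.site_id)
    bg_pos, bg_strands = _background(genome, config.background_read_rate,
                                     config, rng)
    positions += bg_pos
    strands += bg_strands
    origins += ["background"] * len(bg_pos)
    barcodes = _random_barcodes(rng, len(positions), config.barcode_length)
    return _emit(genome, positions, strands, barcodes, origins, config, rng,
                 f"{factor}_{condition}")


def simulate_input_reads(genome: str, config: SimConfig,
                         condition: str = "input"
                         ) -> Tuple[List[ReadRecord], pd.DataFrame]:
    """Input (no-IP) control sample: uniform coverage at ``input_read_rate``
    reads/kb, with the same barcode and duplication model as IP samples."""
    rng = _rng(config, "input")
    positions, strands = _background(genome, config.input_read_rate, config, rng)
    origins = ["background"] * len(positions)
    barcodes = _random_barcodes(rng, len(positions), config.barcode_length)
    return _emit(genome, positions, strands, barcodes, origins, config, rng,
                 f"input_{condition}")


def synthetic_gene_models(config: SimConfig, n_genes: Optional[int] = None,
                          min_len: int = 1000, max_len: int = 5000
                          ) -> pd.DataFrame:
    """Random non-overlapping gene models (BED6 frame) for annotation tests.

    Plumbing for the annotation stage of the demo pipeline; genes are placed
    independently of planted sites, sparsely enough (one per ~20 kb by
    default) that peaks fall in all four gene-relative categories.
    """
    rng = _rng(config, "genes")
    L = config.genome_length
    if n_genes is None:
        n_genes = max(1, L // 20_000)
    slot = L // n_genes
    rows = []
    for i in range(n_genes):
        length = int(rng.integers(min_len, min(max_len, slot - 200) + 1))
        start = int(i * slot + rng.integers(0, slot - length))
        rows.append({"chrom": config.chrom, "start": start,
                     "end": start + length, "gene_id": f"gene{i:04d}",
                     "score": 0, "strand": "+" if rng.random() < 0.5 else "-"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- file IO

def write_fasta(genome: str, path, chrom: str = "chr1") -> None:
    SeqIO.write([SeqRecord(Seq(genome), id=chrom, description="")],
                str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(records: List[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
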