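"""Read preprocessing: quality/length filtering, barcode extraction,
alignment ingestion, MAPQ filtering and random-barcode PCR deduplication.

The ChIP-nexus read layout is a random barcode (9 nt by default) followed by
the genomic insert.  Reads are first quality-trimmed on the full sequence
(the printed 59-bp cap includes the barcode), then split into barcode +
insert.  Aligned reads become *tags*: (chrom, strand, 5' stop, barcode,
mapq).  PCR duplicates — tags sharing chromosome, strand, 5' stop position
AND barcode — are collapsed to a single representative (first in input
order), which is the step that distinguishes true re-binding events at the
same coordinate (different barcodes) from amplification copies.

Tags are carried as a pandas DataFrame with columns
``chrom, strand, stop5, barcode, mapq``; :class:`NexusTag` is the
single-record view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .config import PipelineConfig
from .simulate import reverse_complement

TAG_COLUMNS = ["chrom", "strand", "stop5", "barcode", "mapq"]


class MalformedReadError(ValueError):
    pass


@dataclass
class RawRead:
    identifier: str
    sequence: str
    qualities: List[int]        # Phred scores, one per base

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise MalformedReadError(
                f"read {self.identifier}: sequence length "
                f"{len(self.sequence)} != quality length {len(self.qualities)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class NexusTag:
    chrom: str
    strand: str
    stop5: int
    barcode: str
    mapq: int


def quality_trim(read: RawRead, config: PipelineConfig) -> Optional[RawRead]:
    """Sliding-window quality trim, then length filter, then cap at max_len.

    Scans 5'->3' windows of ``qual_window`` bases; the read is truncated at
    the start of the first window whose mean Phred falls below
    ``qual_threshold``.  Reads shorter than ``min_len`` after trimming are
    dropped (None).  Survivors are truncated to ``max_len``.
    """
    q = np.asarray(read.qualities, dtype=float)
    w = config.qual_window
    cut = len(read)
    if len(read) >= w:
        means = np.convolve(q, np.ones(w) / w, mode="valid")
        bad = np.nonzero(means < config.qual_threshold)[0]
        if bad.size:
            cut = int(bad[0])
    if cut < config.min_len:
        return None
    cut = min(cut, config.max_len)
    return RawRead(read.identifier, read.sequence[:cut],
                   list(read.qualities[:cut]))


def extract_barcode(read: RawRead, config: PipelineConfig
                    ) -> Optional[Tuple[str, RawRead]]:
    """Split a trimmed read into (random barcode, genomic insert).

    Returns None when no insert base remains after the barcode.
    """
    bl = config.barcode_length
    if len(read) < bl + 1:
        return None
    barcode = read.sequence[:bl]
    insert = RawRead(read.identifier, read.sequence[bl:],
                     list(read.qualities[bl:]))
    return barcode, insert


class GenomeIndex:
    """Exact-match lookup on both strands of a genome, for the naive aligner
    used on synthetic genomes (a stand-in interface for an external aligner
    on real data, which enters through :func:`read_sam_tags`)."""

    def __init__(self, sequences: Dict[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_genome(cls, genome: str, chrom: str = "chr1") -> "GenomeIndex":
        return cls({chrom: genome})

    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def _occurrences(self, query: str, limit: int = 2
                     ) -> List[Tuple[str, str, int]]:
        """Up to ``limit`` (chrom, strand, match_start) occurrences."""
        hits: List[Tuple[str, str, int]] = []
        rc = reverse_complement(query)
        for chrom, seq in self.sequences.items():
            for strand, pat in (("+", query), ("-", rc)):
                start = seq.find(pat)
                while start != -1 and len(hits) < limit:
                    hits.append((chrom, strand, start))
                    start = seq.find(pat, start + 1)
                if len(hits) >= limit:
                    return hits
        return hits


def naive_align(insert: RawRead, index: GenomeIndex, barcode: str = ""
                ) -> Optional[NexusTag]:
    """Exact-substring alignment reporting the 5'-end coordinate.

    A unique match gets MAPQ 42; multi-mappers get MAPQ 0 (removed by the
    downstream MAPQ filter); no match returns None.  For minus-strand
    matches the read's 5' base is the rightmost matched genomic base, and
    that coordinate is reported.
    """
    if len(insert) == 0:
        raise MalformedReadError("cannot align an empty insert")
    hits = index._occurrences(insert.sequence, limit=2)
    if not hits:
        return None
    chrom, strand, start = hits[0]
    stop5 = start if strand == "+" else start + len(insert) - 1
    mapq = 42 if len(hits) == 1 else 0
    return NexusTag(chrom=chrom, strand=strand, stop5=stop5,
                    barcode=barcode, mapq=mapq)


def tags_to_frame(tags: Iterable[NexusTag]) -> pd.DataFrame:
    rows = [(t.chrom, t.strand, t.stop5, t.barcode, t.mapq) for t in tags]
    return pd.DataFrame(rows, columns=TAG_COLUMNS)


def filter_mapq(tags: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Retain uniquely aligned tags: mapq >= mapq_min (default keeps
    mapq > 20), preserving input order."""
    return tags[tags["mapq"] >= config.mapq_min].reset_index(drop=True)


def deduplicate(tags: pd.DataFrame) -> pd.DataFrame:
    """Remove PCR duplicates: collapse tags sharing
    (chrom, strand, stop5, barcode) to the first-encountered one.

    Idempotent; output is a subset of the input in input order.
    """
    if tags["barcode"].isna().any() or (tags["barcode"] == "").any():
        raise ValueError("deduplication requires a barcode on every tag")
    return tags.drop_duplicates(
        subset=["chrom", "strand", "stop5", "barcode"],
        keep="first").reset_index(drop=True)


# ------------------------------------------------------------------ drivers

def read_fastq(path) -> Iterable[RawRead]:
    """Stream FASTQ (Sanger Phred+33) as RawRead records."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield RawRead(entry.name, entry.sequence,
                          list(entry.get_quality_array()))


def read_sam_tags(path, barcode_delim: str = ":") -> pd.DataFrame:
    """Ingest externally aligned reads from SAM/BAM.

    The random barcode is expected in the read name after the last
    ``barcode_delim``.  The 5' stop is the leftmost reference position for
    plus-strand alignments and the rightmost for minus-strand ones.
    """
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            stop5 = (aln.reference_end - 1) if aln.is_reverse \
                else aln.reference_start
            barcode = aln.query_name.rsplit(barcode_delim, 1)[-1]
            rows.append((aln.reference_name, strand, stop5, barcode,
                         aln.mapping_quality))
    return pd.DataFrame(rows, columns=TAG_COLUMNS)


def process_fastq(fastq_path, index: GenomeIndex, config: PipelineConfig
                  ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Full preprocessing chain on a FASTQ file: trim -> split -> align ->
    MAPQ filter -> deduplicate.  Returns deduplicated tags and a per-stage
    filter log."""
    return process_reads(read_fastq(fastq_path), index, config)


def process_reads(reads: Iterable[RawRead], index: GenomeIndex,
                  config: PipelineConfig
                  ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    log = {"input_reads": 0, "trimmed_dropped": 0, "barcode_dropped": 0,
           "unaligned": 0, "aligned": 0, "mapq_filtered": 0,
           "duplicates_removed": 0, "final_tags": 0}
    tags: List[NexusTag] = []
    for raw in reads:
        log["input_reads"] += 1
        trimmed = quality_trim(raw, config)
        if trimmed is None:
            log["trimmed_dropped"] += 1
            continue
        split = extract_barcode(trimmed, config)
        if split is None:
            log["barcode_dropped"] += 1
            continue
        barcode, insert = split
        tag = naive_align(insert, index, barcode=barcode)
        if tag is None:
            log["unaligned"] += 1
            continue
        tags.append(tag)
    frame = tags_to_frame(tags)
    log["aligned"] = len(frame)
    kept = filter_mapq(frame, config)
    log["mapq_filtered"] = len(frame) - len(kept)
    deduped = deduplicate(kept) if len(kept) else kept
    log["duplicates_removed"] = len(kept) - len(deduped)
    log["final_tags"] = len(deduped)
    return deduped, log


def write_tags_bed(tags: pd.DataFrame, path) -> None:
    """Six-column BED: chrom, stop5, stop5+1, barcode, mapq, strand."""
    out = tags.copy()
    out["start"] = out["stop5"]
    out["end"] = out["stop5"] + 1
    out[["chrom", "start", "end", "barcode", "mapq", "strand"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_tags_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "barcode", "mapq",
                            "strand"],
                     dtype={"chrom": str, "barcode": str})
    df["stop5"] = df["start"]
    return df[TAG_COLUMNS]


def write_filter_log(log: Dict[str, int], path) -> None:
    pd.Series(log, name="count").rename_axis("stage").to_csv(path, sep="\t")
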