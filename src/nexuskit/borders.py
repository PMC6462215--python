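"""Strand-specific lambda-exonuclease border detection and pairing.

The exonuclease digests 5'->3' toward the crosslinked receptor, so read 5'
stops pile up at the protected region's edges: plus-strand stops at the
left border and minus-strand stops at the right border.  Borders are
detected as local maxima of the strand-specific stop profile inside called
peak regions, then paired left-to-right under a width constraint matching
the observed protected-region sizes (10-60 bp typical, up to ~100 bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import GenomicInterval
from .peaks import Peak, StopProfile


@dataclass
class BorderPair:
    """Paired borders flanking an exonuclease-protected binding region."""
    chrom: str
    plus_border: int
    minus_border: int
    support: Tuple[int, int]      # (plus stop count, minus stop count)

    def __post_init__(self) -> None:
        if self.plus_border >= self.minus_border:
            raise ValueError("plus border must lie left of the minus border")

    @property
    def width(self) -> int:
        return self.minus_border - self.plus_border

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.plus_border, self.minus_border)


def detect_borders(profile: StopProfile, strand: str, min_count: int,
                   within: GenomicInterval,
                   neighborhood: int = 3) -> List[int]:
    """Local maxima of one strand's stop counts within an interval.

    A position qualifies when its count is >= ``min_count`` and >= every
    count within ``+/- neighborhood`` bp; of a tied run, only the leftmost
    position is reported.
    """
    if within.chrom != profile.chrom:
        raise ValueError("interval chromosome does not match the profile")
    counts = profile.plus if strand == "+" else profile.minus
    lo = max(0, within.start)
    hi = min(profile.length, within.end)
    if hi <= lo:
        return []
    borders: List[int] = []
    for p in range(lo, hi):
        v = counts[p]
        if v < min_count:
            continue
        wlo = max(0, p - neighborhood)
        whi = min(profile.length, p + neighborhood + 1)
        window = counts[wlo:whi]
        if v < window.max():
            continue
        # leftmost tie-break: skip if an equal value sits earlier in window
        if np.any(counts[wlo:p] == v):
            continue
        borders.append(p)
    return borders


def pair_borders(plus_borders: Sequence[int], minus_borders: Sequence[int],
                 config: PipelineConfig, chrom: str = "chr1",
                 profile: Optional[StopProfile] = None
                 ) -> Tuple[List[BorderPair], List[Tuple[str, int]]]:
    """Greedy left-to-right pairing under the width constraint.

    Each plus border (ascending) is paired with the nearest unused
    downstream minus border whose separation lies in
    ``border_width_range``; each border is used at most once.  Returns the
    pairs and the unpaired borders as (strand, position) records.
    """
    lo, hi = config.border_width_range
    minus_sorted = sorted(minus_borders)
    used = [False] * len(minus_sorted)
    pairs: List[BorderPair] = []
    unpaired: List[Tuple[str, int]] = []
    for pb in sorted(plus_borders):
        match = None
        for j, mb in enumerate(minus_sorted):
            if used[j] or mb <= pb:
                continue
            width = mb - pb
            if width < lo:
                continue
            if width > hi:
                break
            match = j
            break
        if match is None:
            unpaired.append(("+", pb))
            continue
        used[match] = True
        mb = minus_sorted[match]
        support = (0, 0)
        if profile is not None:
            support = (int(profile.plus[pb]), int(profile.minus[mb])
                       if mb < profile.length else 0)
        pairs.append(BorderPair(chrom, pb, mb, support))
    unpaired.extend(("-", mb) for j, mb in enumerate(minus_sorted)
                    if not used[j])
    return pairs, unpaired


def border_min_count(profile: StopProfile, within: GenomicInterval,
                     config: PipelineConfig) -> int:
    """Detection threshold: max(configured floor, 2x the local mean
    per-position stop rate inside the search interval)."""
    lo = max(0, within.start)
    hi = min(profile.length, within.end)
    if hi <= lo:
        return config.border_min_count
    local = (profile.plus[lo:hi].sum() + profile.minus[lo:hi].sum()) / (
        2 * (hi - lo))
    return max(config.border_min_count, int(np.ceil(2 * local)))


def find_border_pairs(profile: StopProfile, peaks: List[Peak],
                      config: PipelineConfig
                      ) -> Tuple[List[BorderPair], List[Tuple[str, int]]]:
    """Detect and pair borders within each called peak +/- a margin."""
    pairs: List[BorderPair] = []
    unpaired: List[Tuple[str, int]] = []
    margin = config.border_margin
    for pk in peaks:
        if pk.chrom != profile.chrom:
            continue
        within = GenomicInterval(pk.chrom, max(0, pk.start - margin),
                                 min(profile.length, pk.end + margin))
        mc = border_min_count(profile, within, config)
        plus = detect_borders(profile, "+", mc, within)
        minus = detect_borders(profile, "-", mc, within)
        got, un = pair_borders(plus, minus, config, chrom=pk.chrom,
                               profile=profile)
        pairs.extend(got)
        unpaired.extend(un)
    return pairs, unpaired


def write_border_pairs(pairs: List[BorderPair], path) -> None:
    with open(path, "w") as fh:
        for i, bp in enumerate(pairs):
            fh.write("\t".join(map(str, [
                bp.chrom, bp.plus_border, bp.minus_border, f"pair_{i + 1}",
                bp.support[0] + bp.support[1], "."])) + "\n")


def read_border_pairs(path) -> List[BorderPair]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "support",
                            "strand"], dtype={"chrom": str})
    return [BorderPair(r["chrom"], int(r["start"]), int(r["end"]),
                       (int(r["support"]), 0)) for _, r in df.iterrows()]
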