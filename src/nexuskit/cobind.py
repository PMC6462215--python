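"""Two-factor co-binding statistics and hormone-condition dynamics.

Three analyses: (i) Venn-style overlap counts between two peak sets under
the >= 1 bp direct-overlap rule; (ii) retention ratios between conditions
(e.g. washout peak count as a percentage of the CORT peak count) reported
at one decimal; (iii) the midpoint-referenced co-positioning comparison —
at every site bound by both factors, positions covered by each factor's
binding regions are tallied relative to the midpoint of the reference
factor's region, giving two coverage distributions whose similarity
(Jensen-Shannon divergence, Pearson correlation) quantifies whether the
two receptors occupy the same DNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr

from .config import PipelineConfig
from .intervals import GenomicInterval
from .peaks import Peak


@dataclass
class OverlapResult:
    n_a_only: int
    n_b_only: int
    n_overlapping_a: int          # peaks in A overlapping >= 1 peak in B
    n_overlapping_b: int
    pairs: List[Tuple[int, int]]  # (index in A, index in B) overlapping pairs


def _tree(peaks: Sequence[Peak]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for i, pk in enumerate(peaks):
        trees.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end, i)
    return trees


def overlap_sets(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
                 ) -> OverlapResult:
    """Direct-overlap (>= 1 bp, half-open) counts from both perspectives."""
    trees_b = _tree(peaks_b)
    pairs: List[Tuple[int, int]] = []
    overlapping_a = set()
    overlapping_b = set()
    for i, pk in enumerate(peaks_a):
        for iv in trees_b.get(pk.chrom, IntervalTree()).overlap(pk.start,
                                                                pk.end):
            pairs.append((i, iv.data))
            overlapping_a.add(i)
            overlapping_b.add(iv.data)
    return OverlapResult(
        n_a_only=len(peaks_a) - len(overlapping_a),
        n_b_only=len(peaks_b) - len(overlapping_b),
        n_overlapping_a=len(overlapping_a),
        n_overlapping_b=len(overlapping_b),
        pairs=sorted(pairs))


def count_ratio(numerator: int, denominator: int) -> float:
    """100 * n / d, rounded half-up to one decimal place."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CoverageDistribution:
    """Covered-position tallies at offsets relative to a reference midpoint."""
    offsets: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        t = self.counts.sum()
        return self.counts / t if t > 0 else self.counts.astype(float)

    def mean_offset(self) -> float:
        if self.total == 0:
            return float("nan")
        return float((self.offsets * self.normalized).sum())


def midpoint_coverage(reference_peaks_a: Sequence[Peak],
                      regions_a: Sequence[GenomicInterval],
                      regions_b: Sequence[GenomicInterval],
                      config: PipelineConfig
                      ) -> Tuple[CoverageDistribution, CoverageDistribution]:
    """Midpoint-referenced coverage of both factors at co-bound sites.

    Reference sites are the peaks of A that overlap at least one region of
    B.  At each site, every genomic position covered by an overlapping
    region of A (resp. B) contributes one count at its offset from the A
    midpoint, clipped to ``+/- cobind_halfwidth``.
    """
    hw = config.cobind_halfwidth
    offsets = np.arange(-hw, hw + 1)
    counts_a = np.zeros(len(offsets), dtype=np.int64)
    counts_b = np.zeros(len(offsets), dtype=np.int64)

    trees_a = _interval_tree(regions_a)
    trees_b = _interval_tree(regions_b)
    for pk in reference_peaks_a:
        tb = trees_b.get(pk.chrom)
        if tb is None:
            continue
        b_hits = tb.overlap(pk.start, pk.end)
        if not b_hits:
            continue
        m = (pk.start + pk.end) // 2
        a_hits = trees_a.get(pk.chrom, IntervalTree()).overlap(pk.start,
                                                               pk.end)
        for target, hits in ((counts_a, a_hits), (counts_b, b_hits)):
            for iv in hits:
                lo = max(iv.begin - m, -hw)
                hi = min(iv.end - m, hw + 1)
                if hi > lo:
                    target[lo + hw:hi + hw] += 1
    return (CoverageDistribution(offsets, counts_a),
            CoverageDistribution(offsets, counts_b))


def _interval_tree(regions: Sequence[GenomicInterval]
                   ) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, None)
    return trees


def distribution_similarity(d1: CoverageDistribution,
                            d2: CoverageDistribution
                            ) -> Tuple[float, float]:
    """(Jensen-Shannon divergence in nats, Pearson correlation per offset).

    JSD lies in [0, ln 2]; it is 0 iff the normalized distributions are
    identical and ln 2 for disjoint supports.
    """
    if d1.total == 0 or d2.total == 0:
        raise ValueError("cannot compare a zero-total coverage distribution")
    if len(d1.offsets) != len(d2.offsets) or np.any(d1.offsets != d2.offsets):
        raise ValueError("distributions must share an offset grid")
    p, q = d1.normalized, d2.normalized
    jsd = float(jensenshannon(p, q, base=np.e) ** 2)
    r = float(pearsonr(p, q)[0]) if (p.std() > 0 and q.std() > 0) else 1.0
    return jsd, r


def coverage_table(d_a: CoverageDistribution, d_b: CoverageDistribution
                   ) -> pd.DataFrame:
    return pd.DataFrame({
        "offset": d_a.offsets, "count_A": d_a.counts, "count_B": d_b.counts,
        "norm_A": d_a.normalized, "norm_B": d_b.normalized})
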