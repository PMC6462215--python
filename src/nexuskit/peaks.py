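"""Enrichment peak calling from deduplicated ChIP-nexus tags.

The caller follows the MACS2 design on 5'-stop count data: a fixed-width
window (100 bp default) slides along each chromosome at a 10 bp step; the
pooled-strand tag count in each window is tested against a Poisson null
whose rate lambda_local is the depth-scaled maximum of the input-control
rate measured genome-wide and in 100 bp / 1 kb / 10 kb windows centred on
the candidate.  Window p-values are converted to q-values by
Benjamini-Hochberg, significant windows are merged, and each merged region
is reported as one fixed-width peak centred on its summit.

The summit is taken from the pileup of reads extended to the insert length
toward their 3' end: plus-strand stops at the left exonuclease border and
minus-strand stops at the right border then overlap across the protected
region, so the maximal-pileup plateau is centred on the binding site; the
summit is the centre of that plateau.  (The raw pooled 5'-stop maximum
would instead sit on a border.)

This is a transparent re-implementation, not a wrapper around the MACS2
binary; exact numerical equality with MACS2 output is not promised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .intervals import GenomicInterval

_MIN_P = 1e-300


@dataclass
class StopProfile:
    """Per-strand 5'-stop counts along one chromosome."""
    chrom: str
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        if len(self.plus) != len(self.minus):
            raise ValueError("plus/minus count arrays must share a length")

    @property
    def length(self) -> int:
        return len(self.plus)

    @property
    def total(self) -> int:
        return int(self.plus.sum() + self.minus.sum())

    def pooled(self) -> np.ndarray:
        return self.plus + self.minus


ProfileSet = Dict[str, StopProfile]


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    pvalue: float
    qvalue: float
    fold_enrichment: float
    name: str = "."

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def width(self) -> int:
        return self.end - self.start


def build_stop_profile(tags: pd.DataFrame, chrom_sizes: Dict[str, int]
                       ) -> ProfileSet:
    """Tally 5'-stop counts per strand and position for every chromosome."""
    profiles: ProfileSet = {}
    for chrom, size in chrom_sizes.items():
        sub = tags[tags["chrom"] == chrom]
        if len(sub) and (sub["stop5"].max() >= size or sub["stop5"].min() < 0):
            raise ValueError(f"tag position outside {chrom} (size {size})")
        plus = np.bincount(
            sub.loc[sub["strand"] == "+", "stop5"].to_numpy(dtype=int),
            minlength=size)[:size]
        minus = np.bincount(
            sub.loc[sub["strand"] == "-", "stop5"].to_numpy(dtype=int),
            minlength=size)[:size]
        profiles[chrom] = StopProfile(chrom, plus.astype(np.int64),
                                      minus.astype(np.int64))
    unknown = set(tags["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"tags on chromosomes without sizes: {sorted(unknown)}")
    return profiles


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, monotone in p, clipped to [0,1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _extended_pileup(profile: StopProfile, ext: int) -> np.ndarray:
    """Coverage from extending each stop ``ext`` bases toward its 3' end."""
    L = profile.length
    delta = np.zeros(L + 1, dtype=np.int64)
    pos = np.arange(L)
    delta[:L] += profile.plus
    np.add.at(delta, np.minimum(pos + ext, L), -profile.plus)
    np.add.at(delta, np.maximum(pos - ext + 1, 0), profile.minus)
    delta[pos + 1] -= profile.minus
    return np.cumsum(delta)[:L]


def _plateau_center(values: np.ndarray) -> int:
    """Centre of the longest maximal run (leftmost run on ties)."""
    mx = values.max()
    at_max = np.flatnonzero(values == mx)
    # split into contiguous runs
    breaks = np.flatnonzero(np.diff(at_max) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(at_max) - 1]])
    lengths = ends - starts
    best = int(np.argmax(lengths))          # leftmost longest run
    lo, hi = at_max[starts[best]], at_max[ends[best]]
    return int((lo + hi) // 2)


def call_peaks(treatment: ProfileSet, control: ProfileSet,
               config: PipelineConfig,
               pseudocount: Optional[float] = None) -> List[Peak]:
    """Poisson local-lambda peak calling with input normalisation.

    Control counts are depth-scaled to the treatment; lambda_local for a
    candidate window is the maximum of the control's genome-wide rate and
    its rate in peak-width / 1 kb / 10 kb windows centred on the candidate
    (all expressed as expected counts per peak-width window), floored at
    ``pseudocount``.  Windows with BH q-value below ``peak_fdr`` are merged
    and reported as fixed-width peaks centred on their pileup summit.
    """
    if set(treatment) != set(control):
        raise ValueError("treatment and control must cover the same chromosomes")
    pc = config.pseudocount if pseudocount is None else pseudocount
    w = config.peak_width
    step = config.peak_step
    t_total = sum(p.total for p in treatment.values())
    c_total = sum(p.total for p in control.values())
    genome_len = sum(p.length for p in treatment.values())
    if c_total == 0 and pc <= 0:
        raise ValueError("control has zero depth; call with a positive "
                         "pseudocount to set a lambda floor")
    scale = (t_total / c_total) if c_total > 0 else 0.0
    lam_bg = t_total * w / genome_len

    rows = []          # (chrom, start, count, lam, p)
    for chrom, tprof in treatment.items():
        cprof = control[chrom]
        if tprof.length != cprof.length:
            raise ValueError(f"length mismatch on {chrom}")
        L = tprof.length
        if L < w:
            continue
        t = tprof.pooled()
        c = cprof.pooled()
        starts = np.arange(0, L - w + 1, step)
        csum_t = np.concatenate([[0], np.cumsum(t)])
        csum_c = np.concatenate([[0], np.cumsum(c)])
        counts = csum_t[starts + w] - csum_t[starts]
        centers = starts + w // 2
        lam = np.full(len(starts), lam_bg)
        for W in (w, *config.lambda_windows):
            lo = np.clip(centers - W // 2, 0, L)
            hi = np.clip(centers + (W - W // 2), 0, L)
            local = (csum_c[hi] - csum_c[lo]) * scale * (w / (hi - lo))
            lam = np.maximum(lam, local)
        lam = np.maximum(lam, pc)
        p = poisson.sf(counts - 1, lam)
        for s, k, l, pv in zip(starts, counts, lam, p):
            rows.append((chrom, int(s), int(k), float(l), float(pv)))

    if not rows:
        return []
    pvals = np.array([r[4] for r in rows])
    qvals = bh_fdr(pvals)

    # merge overlapping significant windows per chromosome
    peaks: List[Peak] = []
    df = pd.DataFrame(rows, columns=["chrom", "start", "count", "lam", "p"])
    df["q"] = qvals
    sig = df[(df["q"] < config.peak_fdr) & (df["count"] > 0)]
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        pileup = _extended_pileup(treatment[chrom], config.pileup_extension)
        L = treatment[chrom].length
        region_rows: List[pd.Series] = []
        region_end = None
        def flush():
            if not region_rows:
                return
            rs = int(region_rows[0]["start"])
            re_ = int(region_rows[-1]["start"]) + w
            summit = rs + _plateau_center(pileup[rs:re_])
            best = min(region_rows, key=lambda r: (r["p"], r["start"]))
            start = summit - w // 2
            start = min(max(start, 0), L - w)
            peaks.append(Peak(
                chrom=chrom, start=start, end=start + w, summit=summit,
                pvalue=max(float(best["p"]), _MIN_P),
                qvalue=max(float(best["q"]), _MIN_P),
                fold_enrichment=(best["count"] + pc) / (best["lam"] + pc)))
        for _, row in grp.iterrows():
            if region_end is not None and row["start"] < region_end:
                region_rows.append(row)
                region_end = max(region_end, row["start"] + w)
            else:
                flush()
                region_rows = [row]
                region_end = row["start"] + w
        flush()
    peaks.sort(key=lambda p: (p.chrom, p.start))
    for i, pk in enumerate(peaks):
        if pk.name == ".":
            pk.name = f"peak_{i + 1}"
    return peaks


def reproducible_peaks(pooled_peaks: List[Peak],
                       replicate_peak_sets: List[List[Peak]],
                       min_support: int = 2) -> List[Peak]:
    """Peaks from the pooled-replicate call supported (>= 1 bp overlap) by
    at least ``min_support`` individual replicates."""
    if min_support > len(replicate_peak_sets):
        raise ValueError("min_support exceeds the number of replicates")
    rep_starts = []
    for reps in replicate_peak_sets:
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for pk in reps:
            by_chrom.setdefault(pk.chrom, []).append((pk.start, pk.end))
        rep_starts.append({c: sorted(v) for c, v in by_chrom.items()})

    def overlaps_any(pk: Peak, ivs: List[Tuple[int, int]]) -> bool:
        return any(s < pk.end and pk.start < e for s, e in ivs)

    kept = []
    for pk in pooled_peaks:
        support = sum(
            1 for rep in rep_starts if overlaps_any(pk, rep.get(pk.chrom, [])))
        if support >= min_support:
            kept.append(pk)
    return kept


# ------------------------------------------------------------------ file IO

def write_narrowpeak(peaks: List[Peak], path) -> None:
    """BED6+4 narrowPeak: signal = fold enrichment, -log10 p/q, summit
    offset from peak start."""
    with open(path, "w") as fh:
        for pk in peaks:
            score = int(min(1000, round(-10 * np.log10(max(pk.qvalue,
                                                           _MIN_P)))))
            fh.write("\t".join(map(str, [
                pk.chrom, pk.start, pk.end, pk.name, score, ".",
                f"{pk.fold_enrichment:.4f}",
                f"{-np.log10(max(pk.pvalue, _MIN_P)):.4f}",
                f"{-np.log10(max(pk.qvalue, _MIN_P)):.4f}",
                pk.summit - pk.start])) + "\n")


def read_narrowpeak(path) -> List[Peak]:
    peaks = []
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score",
                            "strand", "fold", "mlogp", "mlogq", "summit_off"],
                     dtype={"chrom": str})
    for _, r in df.iterrows():
        peaks.append(Peak(
            chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
            summit=int(r["start"]) + int(r["summit_off"]),
            pvalue=10 ** -float(r["mlogp"]), qvalue=10 ** -float(r["mlogq"]),
            fold_enrichment=float(r["fold"]), name=str(r["name"])))
    return peaks
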