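"""Known-motif PWM scanning around peak summits.

Log-odds scanning of probability matrices on both strands, with a hit
threshold expressed as a fraction of the maximal achievable score (0.8 by
default).  Two summary analyses mirror standard known-motif reporting: the
fraction of peaks with a hit within a summit window, and the summit-relative
hit-frequency profile that shows whether a motif is centred under the peaks
(as the GRE is for receptor binding sites) or scattered.

Packaged matrices (``load_pwm``) are synthetic consensus-derived
probability matrices for the GRE (AGAACAnnnTGTTCT), GATA3 (AGATAA) and AP-1
(TGACTCA) consensus sequences — not copies of any curated database matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .peaks import Peak
from .simulate import reverse_complement

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class PWM:
    """Position probability matrix with scanning parameters.

    ``matrix`` is (length x 4) over A,C,G,T; rows sum to 1.  Scores are
    log-odds against ``background``; a window is a hit when its score is at
    least ``min_score_fraction`` of the maximal achievable score (and that
    maximum is positive).
    """
    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    min_score_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be length x 4 (A,C,G,T)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each matrix row must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass
class MotifHit:
    position: int          # forward-strand start of the matched window
    strand: str
    score: float


def hit_center(hit: MotifHit, pwm: PWM) -> int:
    return hit.position + len(pwm) // 2


def _encode(sequence: str, mask_lowercase: bool = False) -> np.ndarray:
    if mask_lowercase:
        seq = "".join(b if b.isupper() else "N" for b in sequence)
    else:
        seq = sequence.upper()
    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _CODE.items():
        codes[np.frombuffer(seq.encode(), dtype="S1") == base.encode()] = code
    return codes


def _scores(codes: np.ndarray, pwm: PWM) -> Tuple[np.ndarray, np.ndarray]:
    """Window scores and validity mask (windows containing N are invalid)."""
    n = len(pwm)
    S = len(codes) - n + 1
    if S <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    lo = pwm.log_odds
    windows = np.lib.stride_tricks.sliding_window_view(codes, n)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = lo[np.arange(n)[None, :], safe].sum(axis=1)
    return scores, valid


def scan_pwm(sequence: str, pwm: PWM,
             min_score_fraction: Optional[float] = None,
             mask_lowercase: bool = False) -> List[MotifHit]:
    """Scan both strands; report windows scoring >= the threshold fraction
    of the maximal achievable log-odds score.

    A matrix whose maximal score is not positive (e.g. equal to background
    everywhere) yields no hits.  Hit positions are forward-strand window
    starts regardless of the matched strand.
    """
    frac = pwm.min_score_fraction if min_score_fraction is None \
        else min_score_fraction
    n = len(pwm)
    if n > len(sequence):
        return []
    mx = pwm.max_score
    if mx <= 0:
        return []
    threshold = frac * mx
    hits: List[MotifHit] = []
    codes_f = _encode(sequence, mask_lowercase)
    scores, valid = _scores(codes_f, pwm)
    for i in np.flatnonzero(valid & (scores >= threshold)):
        hits.append(MotifHit(int(i), "+", float(scores[i])))
    rc = reverse_complement(sequence.upper() if not mask_lowercase
                            else "".join(b if b.isupper() else "N"
                                         for b in sequence))
    scores_r, valid_r = _scores(_encode(rc), pwm)
    S = len(sequence) - n + 1
    for i in np.flatnonzero(valid_r & (scores_r >= threshold)):
        hits.append(MotifHit(S - 1 - int(i), "-", float(scores_r[i])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _summit_window(genome: Dict[str, str], pk: Peak, halfwidth: int
                   ) -> Tuple[str, int]:
    """Sequence around the summit, clipped at chromosome edges; returns the
    window sequence and its genomic start."""
    seq = genome[pk.chrom]
    lo = max(0, pk.summit - halfwidth)
    hi = min(len(seq), pk.summit + halfwidth + 1)
    return seq[lo:hi], lo


def motif_enrichment_fraction(peaks: Sequence[Peak], genome: Dict[str, str],
                              pwm: PWM, window: int,
                              mask_lowercase: bool = False) -> float:
    """Fraction of peaks with >= 1 hit within ``+/- window`` of the summit."""
    if not peaks:
        return 0.0
    n_hit = 0
    for pk in peaks:
        seq, _ = _summit_window(genome, pk, window)
        if scan_pwm(seq, pwm, mask_lowercase=mask_lowercase):
            n_hit += 1
    return n_hit / len(peaks)


def motif_frequency_profile(peaks: Sequence[Peak], genome: Dict[str, str],
                            pwm: PWM, halfwidth: int,
                            mask_lowercase: bool = False) -> pd.DataFrame:
    """Summit-relative hit-frequency histogram.

    Offsets are hit centre minus summit, restricted to
    ``[-halfwidth, +halfwidth]``; frequencies are normalised by the number
    of peaks, so the column sums to total retained hits per peak.
    """
    if halfwidth < len(pwm):
        raise ValueError("halfwidth must be at least the motif length")
    offsets = np.arange(-halfwidth, halfwidth + 1)
    counts = np.zeros(len(offsets), dtype=np.int64)
    for pk in peaks:
        seq, lo = _summit_window(genome, pk, halfwidth + len(pwm))
        for hit in scan_pwm(seq, pwm, mask_lowercase=mask_lowercase):
            off = (lo + hit_center(hit, pwm)) - pk.summit
            if -halfwidth <= off <= halfwidth:
                counts[off + halfwidth] += 1
    freq = counts / len(peaks) if peaks else counts.astype(float)
    return pd.DataFrame({"offset": offsets, "count": counts,
                         "frequency": freq})


# ------------------------------------------------------------------ file IO

def read_jaspar(path_or_handle) -> List[PWM]:
    """Read JASPAR-style plain-text matrices (counts or probabilities)."""
    if hasattr(path_or_handle, "read"):
        parsed = bio_motifs.parse(path_or_handle, "jaspar")
    else:
        with open(path_or_handle) as fh:
            parsed = list(bio_motifs.parse(fh, "jaspar"))
    pwms = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float).T
        probs = counts / counts.sum(axis=1, keepdims=True)
        pwms.append(PWM(name=m.name or m.matrix_id or "motif", matrix=probs))
    return pwms


def load_pwm(name: str) -> PWM:
    """Load one of the packaged synthetic consensus-derived matrices:
    ``GRE``, ``GATA3`` or ``AP1``."""
    fname = f"{name}.synthetic.jaspar"
    ref = resources.files("nexuskit").joinpath("data", fname)
    with ref.open() as fh:
        pwms = read_jaspar(fh)
    if not pwms:
        raise FileNotFoundError(f"no matrix found in packaged {fname}")
    return pwms[0]


def consensus_pwm(name: str, consensus: str, strong: float = 0.91) -> PWM:
    """Probability matrix from a consensus string: the consensus base gets
    ``strong`` probability (rest split evenly); N positions are uniform."""
    rows = []
    weak = (1.0 - strong) / 3
    for base in consensus.upper():
        if base == "N":
            rows.append([0.25] * 4)
        else:
            row = [weak] * 4
            row[_CODE[base]] = strong
            rows.append(row)
    return PWM(name=name, matrix=np.array(rows))


def write_jaspar(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name} {pwm.name}\n")
        for i, base in enumerate(ALPHABET):
            vals = " ".join(f"{v:.4f}" for v in pwm.matrix[:, i])
            fh.write(f"{base} [ {vals} ]\n")
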