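"""Recovery metrics against simulator ground truth.

Used by the verification suite and the reproduction script to score how
well each stage recovers what the simulator planted: peak summits against
planted site midpoints, border pairs against planted borders, and
peak-count retention ratios against the occupancy parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .borders import BorderPair
from .peaks import Peak
from .simulate import TruthTable


@dataclass
class RecoveryResult:
    n_truth: int
    n_called: int
    n_recovered: int         # truth sites with a summit within tolerance
    n_false: int             # called peaks matching no truth site

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")

    @property
    def false_rate(self) -> float:
        return self.n_false / self.n_called if self.n_called else 0.0


def summit_recovery(truth: TruthTable, peaks: Sequence[Peak],
                    condition: str, factor: str,
                    tolerance: int = 50) -> RecoveryResult:
    """Match called summits to planted bound-site midpoints within
    ``tolerance`` bp."""
    bound = truth.bound_sites(condition, factor)
    mids = [s.interval.midpoint for s in bound]
    summits = [p.summit for p in peaks]
    recovered = sum(1 for m in mids
                    if any(abs(sm - m) <= tolerance for sm in summits))
    false = sum(1 for sm in summits
                if not any(abs(sm - m) <= tolerance for m in mids))
    return RecoveryResult(n_truth=len(bound), n_called=len(peaks),
                          n_recovered=recovered, n_false=false)


def border_recovery(truth: TruthTable, pairs: Sequence[BorderPair],
                    condition: str, factor: str,
                    tolerance: int = 0) -> Tuple[int, int, List[int]]:
    """(matched pairs, bound truth sites, per-pair max border error).

    A pair matches a bound site when both its borders lie within
    ``tolerance`` bp of the planted ones.
    """
    bound = truth.bound_sites(condition, factor)
    errors: List[int] = []
    matched = 0
    for bp in pairs:
        best = None
        for s in bound:
            err = max(abs(bp.plus_border - s.border_plus),
                      abs(bp.minus_border - s.border_minus))
            if best is None or err < best:
                best = err
        if best is not None:
            errors.append(best)
            if best <= tolerance:
                matched += 1
    return matched, len(bound), errors
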