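"""Target-decoy FDR formulas used downstream of database search.

Peptide-level FDR for one sample/tier is ``(D + 1) / (T + D)`` over
decoy and target PSM counts; values above 1 (possible when T = 0) are
clipped to 1.

The post hoc cohort-level cutoff first finds, per sample, the target
hit with the highest FDR value strictly under the per-sample threshold
(``FDR_i``), tallies decoy and target+decoy hits with FDR <= FDR_i, and
divides total decoys by total hits across the cohort.  A sample with no
sub-threshold target hit contributes zero counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["SearchHit", "peptide_fdr", "cohort_fdr_cutoff"]


@dataclass(frozen=True)
class SearchHit:
    peptide: str
    is_decoy: bool
    fdr: float
    sample_id: str
    tier_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"FDR value {self.fdr} outside [0, 1]")


def peptide_fdr(t: int, d: int) -> float:
    """(D + 1) / (T + D), clipped to 1."""
    if t < 0 or d < 0:
        raise ValueError("counts must be non-negative")
    if t + d == 0:
        raise ValueError("no PSMs: T + D must be positive")
    return min(1.0, (d + 1) / (t + d))


def cohort_fdr_cutoff(
    hits: Iterable[SearchHit], per_sample_threshold: float = 0.01
) -> float:
    """Equivalent cohort-level FDR threshold across samples."""
    by_sample: dict[str, list[SearchHit]] = {}
    for h in hits:
        by_sample.setdefault(h.sample_id, []).append(h)
    total_decoy = 0
    total_all = 0
    for sample_hits in by_sample.values():
        targets = [
            h.fdr for h in sample_hits
            if not h.is_decoy and h.fdr < per_sample_threshold
        ]
        if not targets:
            continue
        fdr_i = max(targets)
        total_decoy += sum(1 for h in sample_hits if h.is_decoy and h.fdr <= fdr_i)
        total_all += sum(1 for h in sample_hits if h.fdr <= fdr_i)
    if total_all == 0:
        return 0.0
    return total_decoy / total_all
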