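"""Sample-level CNV-metric QC and the dual-caller high-confidence consensus.

Two array-based CNV callers (a PennCNV-style caller "A" reporting a
confidence value, and a QuantiSNP-style caller "B" reporting a log Bayes
factor) each produce interval calls.  A call pair is *high confidence* when
both members have the same state, >= 3 supporting SNPs, a score > 10, and
reciprocal overlap >= 50% each way; the consensus interval takes the
innermost boundaries and is discarded if it touches a centromere/telomere
mask.  All inequality bounds are strict, following the published "<"/">"
thresholds; boundary values fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core_io import GenomicInterval


@dataclass(frozen=True)
class CnvCall:
    interval: GenomicInterval
    state: str  # "del" | "dup"
    score: float
    n_snps: int
    source: str  # caller label, e.g. "A" | "B" | "consensus"

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.state not in ("del", "dup"):
            raise ValueError(f"state must be del|dup, got {self.state!r}")


@dataclass(frozen=True)
class CnvSampleMetrics:
    """Per-sample array QC metrics, one set per caller."""

    lrr_sd_a: float
    baf_drift_a: float
    waviness_a: float
    lrr_sd_b: float
    baf_sd_b: float

    def __post_init__(self) -> None:
        for name in ("lrr_sd_a", "baf_drift_a", "lrr_sd_b", "baf_sd_b"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(f"missing CNV QC metric: {name}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.waviness_a is None or math.isnan(self.waviness_a):
            raise ValueError("missing CNV QC metric: waviness_a")


def cnv_sample_qc(
    m: CnvSampleMetrics,
    lrr_sd_max_a: float = 0.35,
    baf_drift_max_a: float = 0.002,
    waviness_abs_max_a: float = 0.04,
    lrr_sd_max_b: float = 0.3,
    baf_sd_max_b: float = 0.15,
) -> tuple[bool, list[str]]:
    """Pass/fail against the per-caller metric bounds; all bounds strict.

    Returns (passed, reasons) where reasons lists every violated criterion.
    """
    reasons: list[str] = []
    if not m.lrr_sd_a < lrr_sd_max_a:
        reasons.append("lrr_sd_a")
    if not m.baf_drift_a < baf_drift_max_a:
        reasons.append("baf_drift_a")
    if not -waviness_abs_max_a < m.waviness_a < waviness_abs_max_a:
        reasons.append("waviness_a")
    if not m.lrr_sd_b < lrr_sd_max_b:
        reasons.append("lrr_sd_b")
    if not m.baf_sd_b < baf_sd_max_b:
        reasons.append("baf_sd_b")
    return (not reasons, reasons)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap of a and b as a fraction of each interval's own length."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("zero-length interval")
    if a.chrom != b.chrom:
        return (0.0, 0.0)
    inter = a.intersection_length(b)
    return (inter / len(a), inter / len(b))


def consensus_calls(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    mask: Sequence[GenomicInterval] = (),
    min_snps: int = 3,
    min_score: float = 10.0,
    min_ro: float = 0.5,
) -> list[CnvCall]:
    """High-confidence consensus between two callers' call sets.

    Eligible pairs: same chrom and state, each member with ``n_snps >=
    min_snps`` and ``score > min_score`` (strict), reciprocal overlap >=
    min_ro each way.  Pairing is greedy by descending reciprocal-overlap
    product with a leftmost tie-break and each input call used at most once.
    The consensus interval is the innermost boundaries
    ``[max(starts), min(ends))``; any consensus overlapping a mask interval
    is removed.
    """
    candidates: list[tuple[float, int, int, int, int]] = []
    for i, a in enumerate(calls_a):
        if a.n_snps < min_snps or not a.score > min_score:
            continue
        for j, b in enumerate(calls_b):
            if b.n_snps < min_snps or not b.score > min_score:
                continue
            if a.state != b.state or a.interval.chrom != b.interval.chrom:
                continue
            fa, fb = reciprocal_overlap(a.interval, b.interval)
            if fa >= min_ro and fb >= min_ro:
                candidates.append((fa * fb, a.interval.start, b.interval.start, i, j))
    # greedy: best overlap product first, leftmost partners on ties
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3], t[4]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[CnvCall] = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = calls_a[i], calls_b[j]
        iv = GenomicInterval(
            a.interval.chrom,
            max(a.interval.start, b.interval.start),
            min(a.interval.end, b.interval.end),
        )
        if any(iv.overlaps(m) for m in mask):
            continue
        out.append(
            CnvCall(
                interval=iv,
                state=a.state,
                score=min(a.score, b.score),
                n_snps=min(a.n_snps, b.n_snps),
                source="consensus",
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return out


def calls_to_frame(calls: Sequence[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "state": [c.state for c in calls],
            "score": [c.score for c in calls],
            "n_snps": [c.n_snps for c in calls],
            "source": [c.source for c in calls],
        }
    )


def frame_to_calls(df: pd.DataFrame, source: str | None = None) -> list[CnvCall]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CnvCall(
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                state=str(row.state),
                score=float(row.score),
                n_snps=int(row.n_snps),
                source=source if source is not None else str(getattr(row, "source", "?")),
            )
        )
    return out
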