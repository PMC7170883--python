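"""Discovery-family step-wise variant filter cascade with per-stage accounting.

From the variants shared by the two sequenced relatives, the cascade keeps,
in order: (1) variants inside a pedigree sharing region, (2) variants whose
annotated consequence is a coding change, (3) variants absent (or at MAF
exactly 0) from the first frequency database, (4) likewise for the second.
The report records the surviving set and count at every stage; counts are
non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import CODING_CONSEQUENCES, VariantRecord, log_stage
from .pedigree import SharingRegion

STAGES = ("shared_qual", "in_shared_regions", "coding_change", "absent_db1", "absent_db2")


@dataclass
class CascadeReport:
    stage_names: tuple[str, ...]
    stage_counts: list[int]
    survivors: list[VariantRecord]

    def __post_init__(self) -> None:
        if any(b > a for a, b in zip(self.stage_counts, self.stage_counts[1:])):
            raise ValueError("stage counts must be non-increasing")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"stage": list(self.stage_names), "n_surviving": self.stage_counts})


def shared_variants(
    records: list[VariantRecord],
    sample_a: str,
    sample_b: str,
    qual_min: float = 20.0,
) -> list[VariantRecord]:
    """Variants carried (>=1 alt allele) by both samples with QUAL >= 20.

    The quality bound is inclusive: a PHRED score of exactly 20 passes.
    """
    for rec in records[:1]:
        for s in (sample_a, sample_b):
            if s not in rec.genotypes:
                raise ValueError(f"sample {s!r} absent from VCF")
    out = []
    for rec in records:
        ga = rec.genotypes.get(sample_a)
        gb = rec.genotypes.get(sample_b)
        if ga is None or gb is None:
            raise ValueError(f"sample missing at {rec.chrom}:{rec.pos}")
        if ga in (1, 2) and gb in (1, 2) and rec.qual >= qual_min:
            out.append(rec)
    return out


def _in_regions(rec: VariantRecord, regions: list[SharingRegion]) -> bool:
    return any(r.interval.contains_pos(rec.chrom, rec.pos) for r in regions)


def filter_cascade(
    shared: list[VariantRecord],
    regions: list[SharingRegion],
    dbs: tuple[str, str] = ("kg1", "dbsnp"),
    consequence_set: frozenset[str] = CODING_CONSEQUENCES,
) -> CascadeReport:
    """Apply the step-wise filters to the shared-variant set.

    Every record must carry a consequence annotation; an unannotated variant
    is an error (annotation is a precondition, not a default).  Database
    novelty is keyed on (chrom, pos, ref, alt): a variant passes a database
    stage when the database has no entry for its key or records a MAF of
    exactly 0.
    """
    unannotated = [r for r in shared if r.consequence is None]
    if unannotated:
        pos = ", ".join(f"{r.chrom}:{r.pos}" for r in unannotated[:5])
        raise ValueError(f"unannotated variants (first shown): {pos}")

    counts = [len(shared)]
    current = shared

    current = [r for r in current if _in_regions(r, regions)]
    counts.append(len(current))

    current = [r for r in current if r.consequence in consequence_set]
    counts.append(len(current))

    for db in dbs:
        current = [r for r in current if r.db_freq.get(db, 0.0) == 0.0]
        counts.append(len(current))

    for stage, n in zip(STAGES, counts):
        log_stage(f"cascade:{stage}", n)
    return CascadeReport(stage_names=STAGES, stage_counts=counts, survivors=current)
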