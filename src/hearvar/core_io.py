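"""Readers, writers and coordinate conventions for the formats the pipeline touches.

All intervals held in memory are 0-based half-open ``[start, end)``; VCF and
SNP-array positions are 1-based.  The conversion lives in exactly one place
(:func:`vcf_pos_to_interval`) so off-by-one questions have a single audit point.

The VCF dialect is a deliberately minimal v4.2 subset: CHROM, POS, ID, REF,
ALT, QUAL, FILTER, FORMAT/GT.  Multi-allelic records are split into biallelic
records on read; phased separators are treated as unphased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("hearvar")

#: sentinel genotype code for a missing call
MISSING: int = -1

#: variant consequence vocabulary used throughout the cascade
CONSEQUENCES = frozenset(
    {
        "frameshift",
        "missense",
        "canonical_splice",
        "stop_gain",
        "stop_loss",
        "start_gain",
        "start_loss",
        "synonymous",
        "noncoding",
        "other",
    }
)

#: consequence classes counted as a coding change in the prioritization cascade
CODING_CONSEQUENCES = frozenset(
    {
        "frameshift",
        "missense",
        "canonical_splice",
        "stop_gain",
        "stop_loss",
        "start_gain",
        "start_loss",
    }
)


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; the message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_pos(self, chrom: str, pos_1based: int) -> bool:
        """True if a 1-based point position falls inside the interval."""
        return self.chrom == chrom and self.start <= pos_1based - 1 < self.end


def vcf_pos_to_interval(chrom: str, pos_1based: int, ref: str) -> GenomicInterval:
    """Convert a 1-based VCF position and REF allele to interval form.

    A VCF position ``p`` with reference allele of length ``L`` occupies
    ``[p-1, p-1+L)`` in 0-based half-open coordinates.
    """
    return GenomicInterval(chrom, pos_1based - 1, pos_1based - 1 + max(1, len(ref)))


@dataclass
class VariantRecord:
    """One biallelic small-variant call with per-sample genotype codes.

    ``genotypes`` maps sample id to an alternate-allele count in {0, 1, 2}
    or :data:`MISSING`.  ``db_freq`` maps a database label (e.g. ``"kg1"``,
    ``"dbsnp"``) to a minor allele frequency; absence of the key means the
    variant is not described in that database.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    genotypes: dict[str, int] = field(default_factory=dict)
    consequence: str | None = None
    db_freq: dict[str, float] = field(default_factory=dict)
    vid: str = "."

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError(f"qual must be >= 0, got {self.qual}")
        for s, g in self.genotypes.items():
            if g not in (0, 1, 2, MISSING):
                raise ValueError(f"bad genotype code {g} for sample {s}")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for db, f in self.db_freq.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"db_freq[{db}]={f} outside [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for database lookups: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def interval(self) -> GenomicInterval:
        return vcf_pos_to_interval(self.chrom, self.pos, self.ref)


@dataclass
class RunConfig:
    """Structured run configuration: thresholds, seed and paths.

    Threshold defaults reproduce the published analysis; every cut-off is
    overridable from YAML.  A seed is mandatory for any stochastic stage.
    """

    seed: int
    thresholds: dict[str, float] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)

    DEFAULT_THRESHOLDS = {
        "qual_min": 20.0,
        "gentrain_min": 0.5,
        "snp_callrate_min": 0.95,
        "sample_callrate_min": 0.95,
        "min_run": 3,
        "cnv_min_snps": 3,
        "cnv_min_score": 10.0,
        "cnv_min_ro": 0.5,
        "lrr_sd_max_a": 0.35,
        "baf_drift_max_a": 0.002,
        "waviness_abs_max_a": 0.04,
        "lrr_sd_max_b": 0.3,
        "baf_sd_max_b": 0.15,
        "maf_min": 0.05,
        "snp_missing_max": 0.05,
        "hwe_p_min": 5e-7,
        "diff_miss_p_min": 1e-5,
        "het_sd_max": 3.0,
        "tag_r2_max": 0.8,
        "alpha": 0.05,
    }

    def __post_init__(self) -> None:
        merged = dict(self.DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"config {path} must set a seed")
        return cls(
            seed=int(raw["seed"]),
            thresholds=dict(raw.get("thresholds", {})),
            paths=dict(raw.get("paths", {})),
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> Iterator[VariantRecord]:
    """Stream a VCF as biallelic :class:`VariantRecord` objects.

    Multi-allelic records are split, one record per ALT allele, sharing the
    position; a sample's code for ALT allele *k* is its count of allele *k*
    and any missing allele call makes the whole genotype missing.
    Sample order is preserved from the header.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises plain exceptions on bad headers
        raise VcfParseError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vcf.samples)
    for var in vcf:
        gts = var.genotypes  # [[a1, a2, phased], ...]
        qual = float(var.QUAL) if var.QUAL is not None else 0.0
        for k, alt in enumerate(var.ALT, start=1):
            genos: dict[str, int] = {}
            for s, g in zip(samples, gts):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    genos[s] = MISSING
                else:
                    genos[s] = sum(1 for a in alleles if a == k)
            yield VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alt,
                qual=qual,
                genotypes=genos,
                vid=var.ID or ".",
            )
    vcf.close()


def write_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as a minimal VCF v4.2 (CHROM..FILTER + FORMAT/GT).

    Sample columns are the union of sample ids over all records, in first-seen
    order.  Genotype codes map back to unphased GT strings (0/0, 0/1, 1/1, ./.).
    """
    samples: list[str] = []
    for rec in records:
        for s in rec.genotypes:
            if s not in samples:
                samples.append(s)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs: list[str] = []
        for rec in records:
            if rec.chrom not in contigs:
                contigs.append(rec.chrom)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", *samples]
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            qual = f"{rec.qual:g}"
            row = [
                rec.chrom,
                str(rec.pos),
                rec.vid,
                rec.ref,
                rec.alt,
                qual,
                "PASS",
                ".",
                "GT",
                *[gt_str[rec.genotypes.get(s, MISSING)] for s in samples],
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED (3+ columns); 0-based half-open semantics preserved verbatim.

    Records with ``start >= end`` are skipped with a warning rather than
    aborting the run.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                log.warning("%s:%d: skipping interval with start >= end (%s:%d-%d)",
                            path, lineno, chrom, start, end)
                continue
            out.append(GenomicInterval(chrom, start, end))
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Tab-separated table with a header row (UTF-8)."""
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


def log_stage(stage: str, n: int) -> None:
    """Per-stage record-count logging (stderr via the package logger)."""
    log.info("%s: %d records", stage, n)
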