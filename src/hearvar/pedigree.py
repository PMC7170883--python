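"""Pedigree representation and the dominant allele-sharing scan.

The scan replaces multipoint IBD inference with a per-SNP obligate-sharing
test followed by run-length smoothing: a SNP is *compatible* with a single
dominantly inherited haplotype when some allele is carried by every affected,
genotyped member and no genotyped unaffected individual is homozygous for
every allele that could play that role.  Maximal runs of compatible SNPs of
length >= ``min_run`` become candidate sharing regions used downstream as an
inclusion mask for variant prioritization.  Missing genotypes are permissive
(count as compatible) so the causal region cannot be lost to missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import MISSING, GenomicInterval, log_stage


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: str  # "male" | "female" | "unknown"
    affected: str  # "yes" | "no" | "unknown"

    @property
    def founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = {ind.iid for ind in self.individuals}
        if len(ids) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in ids:
                    raise ValueError(f"parent {parent!r} of {ind.iid!r} not in pedigree")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            ind.iid: [p for p in (ind.father, ind.mother) if p is not None]
            for ind in self.individuals
        }
        state: dict[str, int] = {}

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 2:
                return
            if state.get(iid) == 1:
                raise ValueError(f"pedigree cycle involving {iid!r}")
            state[iid] = 1
            stack.append(iid)
            for p in parents[iid]:
                visit(p, stack)
            stack.pop()
            state[iid] = 2

        for iid in parents:
            visit(iid, [])

    def __getitem__(self, iid: str) -> Individual:
        for ind in self.individuals:
            if ind.iid == iid:
                return ind
        raise KeyError(iid)

    @property
    def affected_ids(self) -> list[str]:
        return [i.iid for i in self.individuals if i.affected == "yes"]

    @property
    def unaffected_ids(self) -> list[str]:
        return [i.iid for i in self.individuals if i.affected == "no"]


_SEX = {"1": "male", "2": "female", "0": "unknown"}
_AFF = {"2": "yes", "1": "no", "0": "unknown", "-9": "unknown"}


def read_ped(path) -> Pedigree:
    """Read a 6-column PED/FAM file (fid iid father mother sex affection)."""
    inds: list[Individual] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fid, iid, fa, mo, sex, aff = line.split()[:6]
            inds.append(
                Individual(
                    iid=iid,
                    father=None if fa == "0" else fa,
                    mother=None if mo == "0" else mo,
                    sex=_SEX.get(sex, "unknown"),
                    affected=_AFF.get(aff, "unknown"),
                )
            )
    return Pedigree(inds)


def write_ped(ped: Pedigree, path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    aff_code = {"yes": "2", "no": "1", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(
                "\t".join(
                    [
                        "FAM1",
                        ind.iid,
                        ind.father or "0",
                        ind.mother or "0",
                        sex_code[ind.sex],
                        aff_code[ind.affected],
                    ]
                )
                + "\n"
            )


@dataclass
class ArrayGenotypes:
    """SNP-array dosages for a set of individuals.

    ``codes`` is an (n_individuals, n_snps) int array in {0,1,2,MISSING}.
    ``snps`` carries per-SNP metadata: snp_id, chrom, pos (1-based, strictly
    increasing within chrom), gentrain.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError("codes shape inconsistent with sample/snp counts")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("invalid genotype codes present")
        for _, sub in self.snps.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("pos must be strictly increasing within chrom")

    @property
    def snp_call_rate(self) -> np.ndarray:
        return (self.codes != MISSING).mean(axis=0)

    @property
    def sample_call_rate(self) -> np.ndarray:
        return (self.codes != MISSING).mean(axis=1)


@dataclass(frozen=True)
class SharingRegion:
    interval: GenomicInterval
    n_support_snps: int


def qc_array(
    arr: ArrayGenotypes,
    gentrain_min: float = 0.5,
    snp_callrate_min: float = 0.95,
    sample_callrate_min: float = 0.95,
) -> ArrayGenotypes:
    """Array QC: drop SNPs with gentrain < 0.5 or call rate < 95%, then
    samples with call rate <= 95%.

    Thresholds are strict (a gentrain of exactly 0.5 survives; a sample call
    rate of exactly 0.95 does not, mirroring the "genotype rate > 95%" sample
    criterion).
    """
    keep_snp = (arr.snps["gentrain"].to_numpy() >= gentrain_min) & (
        arr.snp_call_rate >= snp_callrate_min
    )
    n_snp_removed = int((~keep_snp).sum())
    codes = arr.codes[:, keep_snp]
    snps = arr.snps.loc[keep_snp].reset_index(drop=True)
    if snps.empty:
        raise ValueError("no SNPs survive QC")

    sample_cr = (codes != MISSING).mean(axis=1) if codes.size else np.zeros(len(arr.sample_ids))
    keep_sample = sample_cr > sample_callrate_min
    n_sample_removed = int((~keep_sample).sum())
    log_stage("qc_array removed SNPs", n_snp_removed)
    log_stage("qc_array removed samples", n_sample_removed)
    return ArrayGenotypes(
        sample_ids=[s for s, k in zip(arr.sample_ids, keep_sample) if k],
        snps=snps,
        codes=codes[keep_sample],
    )


def snp_sharing_compatible(genotypes: dict[str, int], ped: Pedigree) -> bool:
    """Is a SNP consistent with one dominantly shared allele across affecteds?

    True iff some allele a in {ref, alt} is carried (>=1 copy) by every
    affected individual with a non-missing genotype, and no genotyped
    unaffected individual is homozygous for *every* such candidate allele.
    Missing genotypes are permissive.
    """
    affected = ped.affected_ids
    if not affected:
        raise ValueError("affected set is empty")

    def carries(code: int, allele: str) -> bool:
        return code in (0, 1) if allele == "ref" else code in (1, 2)

    def hom(code: int, allele: str) -> bool:
        return code == 0 if allele == "ref" else code == 2

    candidates = []
    for allele in ("ref", "alt"):
        obs = [genotypes[i] for i in affected if genotypes.get(i, MISSING) != MISSING]
        if all(carries(c, allele) for c in obs):
            candidates.append(allele)
    if not candidates:
        return False
    for u in ped.unaffected_ids:
        code = genotypes.get(u, MISSING)
        if code == MISSING:
            continue
        if all(hom(code, a) for a in candidates):
            return False
    return True


def compatibility_vector(arr: ArrayGenotypes, ped: Pedigree) -> np.ndarray:
    """Boolean per-SNP sharing compatibility, vectorised over the array.

    Same decision rule as :func:`snp_sharing_compatible`; kept equivalent by a
    property test.
    """
    ids = set(arr.sample_ids)
    aff_idx = [arr.sample_ids.index(i) for i in ped.affected_ids if i in ids]
    una_idx = [arr.sample_ids.index(i) for i in ped.unaffected_ids if i in ids]
    codes = arr.codes
    aff = codes[aff_idx] if aff_idx else np.empty((0, codes.shape[1]), dtype=codes.dtype)
    # allele carried or missing, for every affected
    ref_ok = ((aff == 0) | (aff == 1) | (aff == MISSING)).all(axis=0)
    alt_ok = ((aff == 1) | (aff == 2) | (aff == MISSING)).all(axis=0)
    compat = ref_ok | alt_ok
    if una_idx:
        una = codes[una_idx]
        # one candidate allele only: a single unaffected hom for it kills the SNP
        only_ref = ref_ok & ~alt_ok
        only_alt = alt_ok & ~ref_ok
        blocked = (only_ref & (una == 0).any(axis=0)) | (only_alt & (una == 2).any(axis=0))
        compat &= ~blocked
    return compat


def sharing_scan(arr: ArrayGenotypes, ped: Pedigree, min_run: int = 3) -> list[SharingRegion]:
    """Maximal runs of >= min_run consecutive compatible SNPs, per chromosome.

    Each run is reported as the interval spanning its outermost compatible
    SNPs, ``[pos(first)-1, pos(last))`` in 0-based half-open form (the last
    SNP's base is included).
    """
    if len(arr.snps) == 0:
        return []
    compat = compatibility_vector(arr, ped)
    regions: list[SharingRegion] = []
    for chrom, sub in arr.snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        c = compat[idx]
        i = 0
        while i < len(c):
            if not c[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(c) and c[j + 1]:
                j += 1
            run_len = j - i + 1
            if run_len >= min_run:
                regions.append(
                    SharingRegion(
                        interval=GenomicInterval(chrom, int(pos[i]) - 1, int(pos[j])),
                        n_support_snps=run_len,
                    )
                )
            i = j + 1
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions
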