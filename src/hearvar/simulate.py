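"""Seeded generators for every input the pipeline consumes.

The real cohorts behind this analysis are access-controlled, so each stage is
exercised on simulated data carrying the same statistical structure: a
four-generation dominant pedigree with a planted shared haplotype and causal
stop-gain variant, dual-caller CNV call sets with planted consensus pairs and
single-criterion decoys, a population cohort generated under the explicit
genotype x hearing interaction model, and startle/vocalization tables with
genotype-dependent effects.  Every generator is a pure function of its seed
and parameters, and ships a :class:`SimTruth` sufficient to score recovery.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    GenomicInterval,
    VariantRecord,
    write_intervals,
    write_tsv,
    write_vcf,
)
from .pedigree import ArrayGenotypes, Individual, Pedigree, write_ped


@dataclass
class SimTruth:
    """Ground truth serialized alongside every simulated dataset."""

    shared_region: tuple[str, int, int] | None = None
    causal_variant: tuple[str, int, str, str] | None = None
    cnv_consensus: list[tuple[str, int, int, str]] = field(default_factory=list)
    cnv_decoy_reasons: list[str] = field(default_factory=list)
    interaction_b: tuple[float, float, float, float] | None = None
    delta_minlow: float | None = None
    delta_vocab: float | None = None
    ppi_detection: dict[str, dict[str, float]] | None = None
    usv_shifts: dict[str, dict[str, float]] | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Discovery family
# ---------------------------------------------------------------------------

#: pedigree topology: a 12-member, 4-generation family in which every
#: descendant of the affected founder I.1 is affected; married-in individuals
#: are unaffected.  Seven members are genotyped on the array (5 affected + the
#: 2 married-in spouses II.4 and III.4); II.2 and IV.1 are whole-genome
#: sequenced.
FAMILY_MEMBERS = [
    # iid, father, mother, sex, affected
    ("I.1", None, None, "male", "yes"),
    ("I.2", None, None, "female", "no"),
    ("II.1", "I.1", "I.2", "male", "yes"),
    ("II.2", "I.1", "I.2", "female", "yes"),
    ("II.3", "I.1", "I.2", "male", "yes"),
    ("II.4", None, None, "female", "no"),
    ("II.5", None, None, "female", "no"),
    ("III.1", "II.1", "II.5", "male", "yes"),
    ("III.3", "II.3", "II.4", "female", "yes"),
    ("III.4", None, None, "male", "no"),
    ("IV.1", "III.3", "III.4", "female", "yes"),
    ("IV.2", "III.3", "III.4", "female", "yes"),
]
GENOTYPED = ["II.1", "II.2", "III.3", "IV.1", "IV.2", "II.4", "III.4"]
GENOTYPED_AFFECTED = ["II.1", "II.2", "III.3", "IV.1", "IV.2"]
WGS_PAIR = ("II.2", "IV.1")


def family_pedigree() -> Pedigree:
    return Pedigree(
        [Individual(iid, fa, mo, sex, aff) for iid, fa, mo, sex, aff in FAMILY_MEMBERS]
    )


@dataclass
class FamilySim:
    pedigree: Pedigree
    array: ArrayGenotypes
    variants: list[VariantRecord]  # annotated, with db frequencies attached
    annotation: pd.DataFrame  # variant key -> consequence
    freq_tables: dict[str, pd.DataFrame]  # db label -> (key, maf)
    truth: SimTruth


def sim_family(
    seed: int,
    n_snps: int = 2000,
    n_chrom: int = 4,
    region_span: int = 5_000_000,
    snp_spacing: int = 50_000,
) -> FamilySim:
    """Simulate the discovery family: array genotypes with a dominant shared
    haplotype over a planted region, and a small shared-variant set in which
    one planted stop-gain survives the whole filter cascade while decoys die
    at each stage (low QUAL, not shared, out of region, synonymous, known in
    each database).
    """
    rng = np.random.default_rng(seed)
    ped = family_pedigree()

    per_chrom = n_snps // n_chrom
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    snp_rows = []
    for c in chroms:
        for k in range(per_chrom):
            snp_rows.append((f"{c}_snp{k}", c, (k + 1) * snp_spacing))
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    snps["gentrain"] = np.round(rng.uniform(0.6, 0.95, len(snps)), 4)
    m = len(snps)

    # planted shared region: a block of consecutive SNPs on chr1
    n_region = max(3, region_span // snp_spacing)
    start_idx = per_chrom // 3
    region_idx = np.arange(start_idx, min(start_idx + n_region, per_chrom))
    region_pos = snps.loc[region_idx, "pos"].to_numpy()
    region = GenomicInterval("chr1", int(region_pos[0]) - 1, int(region_pos[-1]))

    p_alt = rng.uniform(0.2, 0.8, m)
    codes = np.zeros((len(GENOTYPED), m), dtype=int)
    for i in range(len(GENOTYPED)):
        a1 = rng.random(m) < p_alt
        a2 = rng.random(m) < p_alt
        codes[i] = a1.astype(int) + a2.astype(int)

    # risk haplotype over the region: every genotyped affected carries it;
    # married-ins never homozygous for it (they did not transmit it)
    risk_allele = (rng.random(len(region_idx)) < p_alt[region_idx]).astype(int)  # 0=ref,1=alt
    for i, iid in enumerate(GENOTYPED):
        aff = iid in GENOTYPED_AFFECTED
        for r, j in enumerate(region_idx):
            h = risk_allele[r]
            if aff:
                other = int(rng.random() < p_alt[j])
                codes[i, j] = h + other
            else:
                if (h == 1 and codes[i, j] == 2) or (h == 0 and codes[i, j] == 0):
                    codes[i, j] = 1

    # a deliberately incompatible stretch on chr2 isolates the out-of-region decoy
    incomp_idx = per_chrom + per_chrom // 2 + np.arange(-2, 3)
    for j in incomp_idx:
        codes[GENOTYPED.index("II.1"), j] = 0
        codes[GENOTYPED.index("II.2"), j] = 2

    # sprinkle missingness away from the planted/incompatible anchors
    protected = set(region_idx) | set(incomp_idx)
    miss = rng.random(codes.shape) < 0.01
    for j in protected:
        miss[:, j] = False
    codes[miss] = -1

    arr = ArrayGenotypes(sample_ids=list(GENOTYPED), snps=snps, codes=codes)

    # --- shared-variant set for the WGS pair ------------------------------
    mid = int(region_pos[len(region_pos) // 2])
    out_pos = int(snps.loc[incomp_idx[2], "pos"])  # centre of the incompatible stretch
    a, b = WGS_PAIR

    def var(chrom, pos, ref, alt, qual, ga, gb, consequence, db_freq, vid):
        return VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
            genotypes={a: ga, b: gb}, consequence=consequence,
            db_freq=db_freq, vid=vid,
        )

    causal = var("chr1", mid + 11, "C", "T", 99.0, 1, 1, "stop_gain", {}, "planted_stopgain")
    variants = [
        causal,
        var("chr1", mid + 101, "G", "A", 15.0, 1, 1, "stop_gain", {}, "decoy_lowqual"),
        var("chr1", mid + 201, "T", "C", 55.0, 1, 0, "missense", {}, "decoy_notshared"),
        var("chr2", out_pos + 7, "A", "G", 60.0, 1, 1, "missense", {}, "decoy_outregion"),
        var("chr1", mid + 301, "C", "G", 80.0, 2, 1, "synonymous", {}, "decoy_synonymous"),
        var("chr1", mid + 401, "A", "T", 70.0, 1, 1, "noncoding", {}, "decoy_noncoding"),
        var("chr1", mid + 501, "G", "T", 90.0, 1, 1, "missense", {"kg1": 0.01}, "decoy_in_db1"),
        var("chr1", mid + 601, "T", "A", 85.0, 1, 2, "frameshift",
            {"kg1": 0.0, "dbsnp": 0.005}, "decoy_in_db2"),
    ]
    variants.sort(key=lambda v: (v.chrom, v.pos))

    annotation = pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "consequence": [v.consequence for v in variants],
        }
    )
    freq_tables = {}
    for db in ("kg1", "dbsnp"):
        rows = [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "maf": v.db_freq[db]}
            for v in variants
            if db in v.db_freq
        ]
        freq_tables[db] = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"])

    truth = SimTruth(
        shared_region=(region.chrom, region.start, region.end),
        causal_variant=causal.key,
    )
    return FamilySim(
        pedigree=ped, array=arr, variants=variants,
        annotation=annotation, freq_tables=freq_tables, truth=truth,
    )


def write_family(sim: FamilySim, outdir: str | Path) -> None:
    """Serialize a family simulation as PED + VCF + TSV + JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ped(sim.pedigree, outdir / "family.ped")
    write_vcf(sim.variants, outdir / "family.vcf")
    arr = sim.array
    geno = pd.DataFrame(arr.codes.T, columns=arr.sample_ids)
    write_tsv(pd.concat([arr.snps, geno], axis=1), outdir / "array_genotypes.tsv")
    write_tsv(sim.annotation, outdir / "annotation.tsv")
    for db, tab in sim.freq_tables.items():
        write_tsv(tab, outdir / f"freq_{db}.tsv")
    sim.truth.to_json(outdir / "simtruth.json")


# ---------------------------------------------------------------------------
# CNV call sets
# ---------------------------------------------------------------------------

_DECOY_REASONS = ("low_score", "few_snps", "low_ro", "single_caller", "mask_overlap")


@dataclass
class CnvSim:
    calls_a: pd.DataFrame
    calls_b: pd.DataFrame
    mask: list[GenomicInterval]
    truth: SimTruth


def sim_cnv(seed: int, n_true: int = 5, n_decoy: int = 10) -> CnvSim:
    """Dual-caller CNV call sets: ``n_true`` planted pairs satisfying every
    consensus criterion and ``n_decoy`` pairs violating exactly one each
    (score <= 10, < 3 SNPs, < 50% reciprocal overlap, single caller, or
    overlapping the centromere/telomere mask), placed in disjoint genomic
    slots so pairings are unambiguous.
    """
    rng = np.random.default_rng(seed)
    rows_a, rows_b = [], []
    mask: list[GenomicInterval] = []
    consensus_truth: list[tuple[str, int, int, str]] = []
    reasons: list[str] = []

    slot = 10_000_000  # one call pair per slot; slots never interact
    for k in range(n_true + n_decoy):
        chrom = f"chr{k % 3 + 1}"
        base = (k // 3 + 1) * slot
        length = int(rng.integers(50_000, 300_000))
        shift = int(0.2 * length)
        state = "del" if rng.random() < 0.5 else "dup"
        a = (base, base + length)
        b = (base + shift, base + shift + length)  # RO = 0.8 each way
        score_a = float(np.round(rng.uniform(12, 40), 2))
        score_b = float(np.round(rng.uniform(12, 40), 2))
        nsnp_a = int(rng.integers(5, 30))
        nsnp_b = int(rng.integers(5, 30))
        reason = None
        if k >= n_true:
            reason = _DECOY_REASONS[(k - n_true) % len(_DECOY_REASONS)]
            reasons.append(reason)
            if reason == "low_score":
                score_b = 10.0  # not > 10
            elif reason == "few_snps":
                nsnp_a = 2
            elif reason == "low_ro":
                b = (base + int(0.7 * length), base + int(0.7 * length) + length)
            elif reason == "mask_overlap":
                mask.append(GenomicInterval(chrom, a[0] + length // 2 - 1000,
                                            a[0] + length // 2 + 1000))
        rows_a.append((chrom, a[0], a[1], state, score_a, nsnp_a))
        if reason != "single_caller":
            rows_b.append((chrom, b[0], b[1], state, score_b, nsnp_b))
        if reason is None:
            consensus_truth.append((chrom, max(a[0], b[0]), min(a[1], b[1]), state))

    cols = ["chrom", "start", "end", "state", "score", "n_snps"]
    truth = SimTruth(cnv_consensus=sorted(consensus_truth), cnv_decoy_reasons=reasons)
    return CnvSim(
        calls_a=pd.DataFrame(rows_a, columns=cols),
        calls_b=pd.DataFrame(rows_b, columns=cols),
        mask=mask,
        truth=truth,
    )


def write_cnv(sim: CnvSim, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(sim.calls_a, outdir / "cnv_calls_a.tsv")
    write_tsv(sim.calls_b, outdir / "cnv_calls_b.tsv")
    write_intervals(sim.mask, outdir / "cnv_mask.bed")
    sim.truth.to_json(outdir / "simtruth.json")


# ---------------------------------------------------------------------------
# Population cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    genotypes: pd.DataFrame  # sample x SNP dosage table (snp ids as columns)
    traits: pd.DataFrame
    truth: SimTruth


#: default interaction coefficients (b0, b1, b2, b3) for
#: vocab = b0 + b1*g + b2*MinLow + b3*g*MinLow + e.  The intercept and noise
#: are placed so simulated scores stay within the instrument's 0-246 range
#: (the estimand is the interaction coefficient, not the ceiling artifact).
DEFAULT_B = (210.0, -1.0, -0.8, -0.3)


def sim_cohort(
    seed: int,
    n: int = 2000,
    maf_vector: np.ndarray | None = None,
    b: tuple[float, float, float, float] = DEFAULT_B,
    carrier_freq: float = 0.0085,
    delta_minlow: float = 1.2,
    delta_vocab: float = -17.65,
    noise_sd: float = 18.0,
    minlow_snp_beta: float = 0.5,
) -> CohortSim:
    """Simulate a genotyped cohort under the stated interaction model.

    Genotypes are in Hardy-Weinberg proportions at the given MAFs (first SNP
    is the index SNP).  Per-ear 0.5 kHz thresholds share a per-child base
    level (normal, mean 9.96 dB HL, SD 5.81, the published non-carrier
    moments) shifted by ``delta_minlow`` for pathogenic-variant carriers
    (frequency ``carrier_freq``) and by ``minlow_snp_beta`` per index-SNP
    allele.  Vocabulary follows ``b0 + b1*g + b2*MinLow + b3*g*MinLow + e``
    plus the carrier shift, truncated to [0, 246] (a warning fires if
    truncation exceeds 10%).  The DLD-defining traits (WOLD, CCC subscales)
    are generated with ~0.5 correlation to vocabulary.
    """
    rng = np.random.default_rng(seed)
    if maf_vector is None:
        maf_vector = np.array([0.3, 0.1, 0.15, 0.2, 0.25, 0.35, 0.4, 0.45])
    maf_vector = np.asarray(maf_vector, dtype=float)
    m = len(maf_vector)
    G = rng.binomial(2, maf_vector, size=(n, m)).astype(float)
    g = G[:, 0]

    carrier = rng.random(n) < carrier_freq

    base_low = rng.normal(9.96, 5.81, n) + delta_minlow * carrier + minlow_snp_beta * g
    ac_l_05 = np.round(base_low + rng.normal(0, 1.0, n), 1)
    ac_r_05 = np.round(base_low + rng.normal(0, 1.0, n), 1)
    minlow = np.minimum(ac_l_05, ac_r_05)

    base_mid = rng.normal(8.0, 5.0, n)
    ears_mid = {}
    for ear in ("l", "r"):
        for f in ("1", "2", "4"):
            ears_mid[f"ac_{ear}_{f}"] = np.round(base_mid + rng.normal(0, 1.5, n), 1)

    b0, b1, b2, b3 = b
    vocab_raw = (
        b0 + b1 * g + b2 * minlow + b3 * g * minlow
        + delta_vocab * carrier
        + rng.normal(0, noise_sd, n)
    )
    trunc_frac = np.mean((vocab_raw < 0) | (vocab_raw > 246))
    if trunc_frac > 0.10:
        warnings.warn(
            f"interaction coefficients truncate {trunc_frac:.1%} of vocabulary scores",
            stacklevel=2,
        )
    vocab = np.clip(vocab_raw, 0, 246)

    z_vocab = (vocab - vocab.mean()) / vocab.std()
    rho = 0.5

    def correlated(mean, sd):
        return mean + sd * (rho * z_vocab + np.sqrt(1 - rho**2) * rng.standard_normal(n))

    wold = np.round(correlated(7.76, 1.95), 2)
    ccc_fluency = np.round(correlated(10.0, 3.0), 2)
    ccc_syntax = np.round(correlated(10.0, 3.0), 2)
    nwr = np.clip(np.round(correlated(7.3, 2.5)), 0, 12)

    traits = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "vocab": np.round(vocab, 1),
            "nwr": nwr,
            "wold": wold,
            "ccc_fluency": ccc_fluency,
            "ccc_syntax": ccc_syntax,
            "nviq": np.round(rng.normal(100, 15, n), 0),
            "asd_flag": rng.random(n) < 0.01,
            "sen_flag": rng.random(n) < 0.03,
            "ethnicity": np.where(rng.random(n) < 0.95, "british", "other"),
            "gestation_weeks": np.round(rng.normal(39.5, 2.0, n), 1),
            "birthweight_g": np.round(rng.normal(3400, 500, n), 0),
            "ac_l_05": ac_l_05,
            "ac_r_05": ac_r_05,
            **ears_mid,
            "carrier_flag": carrier,
        }
    )
    geno = pd.DataFrame(G, columns=[f"snp{j}" for j in range(m)])
    geno.insert(0, "id", traits["id"])

    truth = SimTruth(
        interaction_b=tuple(float(x) for x in b),
        delta_minlow=float(delta_minlow),
        delta_vocab=float(delta_vocab),
    )
    return CohortSim(genotypes=geno, traits=traits, truth=truth)


def write_cohort(sim: CohortSim, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(sim.genotypes, outdir / "cohort_genotypes.tsv")
    write_tsv(sim.traits, outdir / "cohort_traits.tsv")
    sim.truth.to_json(outdir / "simtruth.json")


# ---------------------------------------------------------------------------
# Mouse behaviour: PPI trials and USV syllables
# ---------------------------------------------------------------------------

#: cued-startle suppression (fraction of the uncued response removed when the
#: cue is detected) per genotype and task band.  Heterozygotes are impaired on
#: the low-frequency task, knockouts on the high-frequency task.
DEFAULT_PPI_DETECTION = {
    "WT": {"NST_15k": 0.6, "NST_40k": 0.6},
    "HT": {"NST_15k": 0.3, "NST_40k": 0.6},
    "KO": {"NST_15k": 0.6, "NST_40k": 0.3},
}

#: per-genotype shifts on USV syllable properties (heterozygotes call higher,
#: shorter and louder; knockouts call higher)
DEFAULT_USV_SHIFTS = {
    "WT": {"freq_khz": 0.0, "duration_ms": 0.0, "volume_db": 0.0},
    "HT": {"freq_khz": 5.0, "duration_ms": -10.0, "volume_db": 3.0},
    "KO": {"freq_khz": 3.0, "duration_ms": 0.0, "volume_db": 0.0},
}


@dataclass
class PpiUsvSim:
    trials: pd.DataFrame
    syllables: pd.DataFrame
    truth: SimTruth


def sim_ppi_usv(
    seed: int,
    n_per_genotype: int = 12,
    detection: dict[str, dict[str, float]] | None = None,
    usv_shifts: dict[str, dict[str, float]] | None = None,
    n_trials_per_condition: int = 20,
    subject_sd: float = 0.08,
    trial_log_sd: float = 0.3,
) -> PpiUsvSim:
    """Simulate startle trials and USV syllable tables for WT/HT/KO mice.

    Trial amplitudes are log-normal around a per-subject baseline; cued
    trials are suppressed by the genotype x task detection fraction (plus
    per-subject noise), so the expected attenuation score is
    ``100 * (1 - detection)``.  Syllable tables include out-of-band and
    too-close syllables so the inclusion filter has work to do.
    """
    rng = np.random.default_rng(seed)
    detection = DEFAULT_PPI_DETECTION if detection is None else detection
    usv_shifts = DEFAULT_USV_SHIFTS if usv_shifts is None else usv_shifts
    genotypes = list(detection.keys())
    tasks = sorted({t for d in detection.values() for t in d})

    trial_rows = []
    syll_rows = []
    for gt in genotypes:
        for s in range(n_per_genotype):
            subject = f"{gt}_{s:02d}"
            base = rng.normal(np.log(300.0), 0.2)
            for task in tasks:
                d = float(np.clip(detection[gt][task] + rng.normal(0, subject_sd), 0.0, 0.95))
                for day in (1,):
                    for cond, mu in (("uncued", base), ("cued", base + np.log(1 - d))):
                        amps = np.exp(rng.normal(mu, trial_log_sd, n_trials_per_condition))
                        for amp in amps:
                            trial_rows.append(
                                (subject, gt, task, day, 1.0, cond, float(np.round(amp, 3)))
                            )
            # USV syllables for this subject
            n_syll = int(rng.poisson(120))
            dur = np.clip(rng.normal(60, 40, n_syll), 1, 250) + usv_shifts[gt]["duration_ms"]
            dur = np.clip(dur, 1, 250)
            # inter-syllable gaps mostly well clear of the 5 ms rule, with a
            # few planted too-close pairs so the filter has work to do
            gap_s = rng.exponential(0.10, n_syll) + 0.006
            gap_s[rng.random(n_syll) < 0.05] = 0.002
            onsets = np.empty(n_syll)
            t = 0.0
            for k in range(n_syll):
                t += gap_s[k]
                onsets[k] = t
                t += dur[k] / 1000.0
            freq = rng.normal(75, 12, n_syll) + usv_shifts[gt]["freq_khz"]
            vol = rng.normal(60, 5, n_syll) + usv_shifts[gt]["volume_db"]
            cats = rng.choice(
                ["Short", "Down-FM", "Up-FM", "Chevron", "Flat", "1-Freq Step", "Noisy", "Complex"],
                n_syll,
            )
            for k in range(n_syll):
                syll_rows.append(
                    (
                        subject, gt,
                        float(np.round(onsets[k], 4)),
                        float(np.round(dur[k], 2)),
                        float(np.round(freq[k], 2)),
                        float(np.round(vol[k], 2)),
                        cats[k],
                    )
                )

    trials = pd.DataFrame(
        trial_rows,
        columns=["subject", "genotype", "task", "day", "cue_level", "condition", "asr_amplitude"],
    )
    syllables = pd.DataFrame(
        syll_rows,
        columns=["subject", "genotype", "onset_s", "duration_ms", "mean_freq_khz", "volume_db", "category"],
    )
    truth = SimTruth(ppi_detection=detection, usv_shifts=usv_shifts)
    return PpiUsvSim(trials=trials, syllables=syllables, truth=truth)


def write_ppi_usv(sim: PpiUsvSim, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(sim.trials, outdir / "startle_trials.tsv")
    write_tsv(sim.syllables, outdir / "usv_syllables.tsv")
    sim.truth.to_json(outdir / "simtruth.json")
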