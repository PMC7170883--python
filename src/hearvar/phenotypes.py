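"""Cohort phenotype construction: inclusion filters, derived hearing measures,
developmental language disorder (DLD) case/control status and carrier
contrasts.

A trait table is a per-individual pandas DataFrame.  Recognised columns (any
may be missing / NaN):

=================  =========================================================
``vocab``          early vocabulary, summed use+understand score in [0, 246]
``plurals`` ...    further language subscales
``nwr``            nonword repetition, 0-12
``wold``           WOLD comprehension
``ccc_syntax`` / ``ccc_fluency``   CCC subscales
``nviq``           nonverbal IQ
``asd_flag`` / ``sen_flag``        autism / special-educational-needs flags
``ethnicity``      string label; inclusion requires ``"british"``
``gestation_weeks`` / ``birthweight_g``
``ac_{l,r}_{05,1,2,4}``   per-ear air-conduction thresholds (dB HL) at
                          0.5 / 1 / 2 / 4 kHz
``carrier_flag``   carries a pathogenic variant in the candidate gene
=================  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import log_stage

EAR_COLS = {
    "l": {"05": "ac_l_05", "1": "ac_l_1", "2": "ac_l_2", "4": "ac_l_4"},
    "r": {"05": "ac_r_05", "1": "ac_r_1", "2": "ac_r_2", "4": "ac_r_4"},
}
MID_FREQS = ("1", "2", "4")

#: hearing impairment for DLD exclusion: any mid-frequency AC threshold above this
HEARING_IMPAIRED_DB = 20.0


def cohort_filter(traits: pd.DataFrame, mode: str = "base") -> pd.DataFrame:
    """Cohort inclusion filters.

    ``base``: gestation > 32 weeks, birthweight > 1500 g, British ethnicity,
    any phenotype present.  ``common_variant`` additionally excludes
    nonverbal IQ < 65 and any ear/frequency threshold > 40 dB HL.  All bounds
    strict.  Exclusion counts are logged per criterion.
    """
    if mode not in ("base", "common_variant"):
        raise ValueError(f"unknown mode {mode!r}")
    df = traits
    keep = pd.Series(True, index=df.index)

    crit = df["gestation_weeks"] > 32
    log_stage("cohort_filter excluded: gestation", int((keep & ~crit.fillna(False)).sum()))
    keep &= crit.fillna(False)

    crit = df["birthweight_g"] > 1500
    log_stage("cohort_filter excluded: birthweight", int((keep & ~crit.fillna(False)).sum()))
    keep &= crit.fillna(False)

    crit = df["ethnicity"].astype(str).str.lower() == "british"
    log_stage("cohort_filter excluded: ethnicity", int((keep & ~crit).sum()))
    keep &= crit

    pheno_cols = [
        c
        for c in df.columns
        if c
        not in ("id", "ethnicity", "gestation_weeks", "birthweight_g", "carrier_flag")
    ]
    crit = df[pheno_cols].notna().any(axis=1)
    log_stage("cohort_filter excluded: no phenotype", int((keep & ~crit).sum()))
    keep &= crit

    if mode == "common_variant":
        crit = ~(df["nviq"] < 65).fillna(False)
        log_stage("cohort_filter excluded: nviq", int((keep & ~crit).sum()))
        keep &= crit
        thr_cols = [c for ear in EAR_COLS.values() for c in ear.values() if c in df.columns]
        crit = ~(df[thr_cols] > 40).any(axis=1)
        log_stage("cohort_filter excluded: hearing", int((keep & ~crit).sum()))
        keep &= crit

    return df.loc[keep].copy()


def min_low(traits: pd.DataFrame) -> pd.Series:
    """MinLow: minimum over ears of the 0.5 kHz air-conduction threshold.

    Missing when neither ear has a 0.5 kHz measurement.
    """
    return traits[[EAR_COLS["l"]["05"], EAR_COLS["r"]["05"]]].min(axis=1, skipna=True)


def min_mid(traits: pd.DataFrame) -> pd.Series:
    """MinMid: per ear, the mean of the 1/2/4 kHz thresholds; then the
    minimum across ears with a complete triple.  Missing when no ear has all
    three frequencies.
    """
    per_ear = {}
    for ear, cols in EAR_COLS.items():
        sub = traits[[cols[f] for f in MID_FREQS]]
        mean = sub.mean(axis=1)
        mean[sub.isna().any(axis=1)] = np.nan
        per_ear[ear] = mean
    return pd.concat(per_ear, axis=1).min(axis=1, skipna=True)


def _hearing_impaired(traits: pd.DataFrame) -> pd.Series:
    """Any 1/2/4 kHz air-conduction threshold above 20 dB HL (either ear).

    Missing thresholds are treated as unimpaired: the flag only fires on
    observed evidence.
    """
    cols = [EAR_COLS[e][f] for e in EAR_COLS for f in MID_FREQS]
    return (traits[cols] > HEARING_IMPAIRED_DB).any(axis=1)


def classify_dld(traits: pd.DataFrame) -> pd.Series:
    """Per-individual DLD status: ``case`` / ``control`` / ``excluded``.

    Cases perform at least 1 SD below the cohort mean on WOLD comprehension,
    OR more than 1 SD below the mean on both CCC fluency and CCC syntax, with
    no autism flag and no hearing impairment.  Controls score above the
    cohort mean on all three language measures, have nonverbal IQ > 80 and
    carry neither the autism nor the special-needs flag.  "Above expected
    levels" is operationalised as strictly above the cohort mean.  Individuals
    missing any of the three language measures are excluded outright.
    Means/SDs are computed on the table passed in (run after cohort_filter).
    """
    measures = ("wold", "ccc_fluency", "ccc_syntax")
    stats = {m: (traits[m].mean(), traits[m].std(ddof=1)) for m in measures}

    wold_mu, wold_sd = stats["wold"]
    flu_mu, flu_sd = stats["ccc_fluency"]
    syn_mu, syn_sd = stats["ccc_syntax"]

    asd = traits.get("asd_flag", pd.Series(False, index=traits.index)).fillna(False).astype(bool)
    sen = traits.get("sen_flag", pd.Series(False, index=traits.index)).fillna(False).astype(bool)
    impaired = _hearing_impaired(traits)

    complete = traits[list(measures)].notna().all(axis=1)

    low_wold = traits["wold"] <= wold_mu - wold_sd
    low_ccc = (traits["ccc_fluency"] < flu_mu - flu_sd) & (traits["ccc_syntax"] < syn_mu - syn_sd)
    case = complete & (low_wold | low_ccc) & ~asd & ~impaired

    above = (
        (traits["wold"] > wold_mu)
        & (traits["ccc_syntax"] > syn_mu)
        & (traits["ccc_fluency"] > flu_mu)
    )
    nviq_ok = (traits["nviq"] > 80).fillna(False)
    control = complete & above & nviq_ok & ~asd & ~sen & ~case

    status = pd.Series("excluded", index=traits.index, dtype=object)
    status[case] = "case"
    status[control] = "control"
    return status


@dataclass
class ContrastResult:
    """Carrier vs non-carrier contrast on one measure."""

    measure: str
    n_carrier: int
    n_noncarrier: int
    mean_carrier: float
    mean_noncarrier: float
    mean_diff: float
    cohens_d: float
    d_ci: tuple[float, float]
    relative_risk: float | None = None
    rr_ci: tuple[float, float] | None = None


def cohens_d_pooled(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Cohen's d with pooled SD and a normal-approximation 95% CI."""
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    d = (np.mean(x) - np.mean(y)) / np.sqrt(s2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return float(d), (float(d - 1.96 * se), float(d + 1.96 * se))


def relative_risk(a: int, n1: int, b: int, n2: int) -> tuple[float | None, tuple[float, float] | None]:
    """Risk ratio (a/n1)/(b/n2) with a log-scale 95% CI.

    Undefined (None) when the comparison-group risk is zero; the CI is
    undefined whenever any cell needed by the log-variance is zero.
    """
    if n1 == 0 or n2 == 0 or b == 0:
        return None, None
    rr = (a / n1) / (b / n2)
    if a == 0:
        return rr, None
    se = np.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    return float(rr), (float(rr * np.exp(-1.96 * se)), float(rr * np.exp(1.96 * se)))


def carrier_contrast(traits: pd.DataFrame, measure: str, binary: bool = False) -> ContrastResult:
    """Compare carriers and non-carriers on one measure.

    Quantitative measures get the mean difference (carrier minus non-carrier)
    and Cohen's d with pooled SD; binary measures additionally get the
    relative risk.
    """
    flag = traits["carrier_flag"].fillna(False).astype(bool)
    vals = traits[measure]
    x = vals[flag & vals.notna()].to_numpy(dtype=float)
    y = vals[~flag & vals.notna()].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("need >=1 carrier and >=1 non-carrier with data")
    d, d_ci = cohens_d_pooled(x, y)
    res = ContrastResult(
        measure=measure,
        n_carrier=len(x),
        n_noncarrier=len(y),
        mean_carrier=float(np.mean(x)),
        mean_noncarrier=float(np.mean(y)),
        mean_diff=float(np.mean(x) - np.mean(y)),
        cohens_d=d,
        d_ci=d_ci,
    )
    if binary:
        a, b = int(np.sum(x > 0)), int(np.sum(y > 0))
        res.relative_risk, res.rr_ci = relative_risk(a, len(x), b, len(y))
    return res
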