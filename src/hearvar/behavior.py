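"""Prepulse-inhibition attenuation scoring and ultrasonic-vocalization
syllable filtering/summaries.

The attenuation score (ATT) for one (subject, task, day, cue level) cell is

    ATT = 100 * mean(cued ASR amplitude) / mean(uncued ASR amplitude)

so 100 means the startle was unchanged by the cue and lower values mean
better cue detection.  Group comparisons first collapse each subject to one
mean score, then run a one-way ANOVA, optionally adjusting for a covariate
(the frequency-matched simple-tone score) via a linear model with Type-II
sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

TRIAL_COLS = ("subject", "genotype", "task", "day", "cue_level", "condition", "asr_amplitude")
SYLLABLE_COLS = ("onset_s", "duration_ms", "mean_freq_khz", "volume_db", "category")

USV_CATEGORIES = (
    "Short", "Down-FM", "Up-FM", "Chevron", "Flat", "1-Freq Step", "Noisy", "Complex",
)


@dataclass(frozen=True)
class AttenuationScore:
    subject: str
    task: str
    day: int
    cue_level: float
    att: float  # percent; NaN when the uncued mean is zero


def attenuation_scores(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell attenuation scores from a startle-trial table.

    Each (subject, task, day, cue_level) cell needs at least one cued and one
    uncued trial; a cell missing either is an error naming the cell.  A zero
    uncued mean yields NaN with ``undefined=True`` for that cell.
    Returns a DataFrame with the cell keys, genotype and ``att``.
    """
    if (trials["asr_amplitude"] < 0).any():
        raise ValueError("ASR amplitudes must be >= 0")
    bad = set(trials["condition"]) - {"cued", "uncued"}
    if bad:
        raise ValueError(f"unknown trial conditions: {sorted(bad)}")
    rows = []
    for key, cell in trials.groupby(["subject", "task", "day", "cue_level"], sort=True):
        cued = cell.loc[cell["condition"] == "cued", "asr_amplitude"]
        uncued = cell.loc[cell["condition"] == "uncued", "asr_amplitude"]
        if len(cued) == 0 or len(uncued) == 0:
            raise ValueError(f"cell {key} lacks {'cued' if len(cued) == 0 else 'uncued'} trials")
        um = uncued.mean()
        att = float("nan") if um == 0 else 100.0 * cued.mean() / um
        rows.append(
            {
                "subject": key[0],
                "genotype": cell["genotype"].iloc[0],
                "task": key[1],
                "day": key[2],
                "cue_level": key[3],
                "att": att,
                "undefined": um == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupCompareResult:
    f_stat: float
    p: float
    group_means: dict[str, float]  # covariate-adjusted when a covariate is given
    df_between: int
    df_resid: int


def group_compare(
    scores: pd.DataFrame,
    group_col: str = "genotype",
    value_col: str = "att",
    covariate: pd.Series | None = None,
) -> GroupCompareResult:
    """Between-group test on subject-mean scores.

    Subjects are first collapsed to one mean score each.  Without a covariate
    this is a one-way ANOVA; with one, the group F comes from the linear
    model ``score ~ covariate + group`` with Type-II sums of squares, and the
    reported means are adjusted to the covariate's grand mean.  ``covariate``
    is indexed by subject id.
    """
    per_subj = (
        scores.dropna(subset=[value_col])
        .groupby(["subject", group_col], sort=True)[value_col]
        .mean()
        .reset_index()
    )
    groups = per_subj[group_col].unique()
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    sizes = per_subj.groupby(group_col).size()
    if (sizes < 2).any():
        raise ValueError("need >=2 subjects per group")

    if covariate is None:
        arrays = [per_subj.loc[per_subj[group_col] == g, value_col].to_numpy() for g in groups]
        f, p = sps.f_oneway(*arrays)
        if all(np.var(a) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
            f, p = 0.0, 1.0  # identical groups: F defined as 0, no evidence
        means = {str(g): float(a.mean()) for g, a in zip(groups, arrays)}
        return GroupCompareResult(
            f_stat=float(f),
            p=float(p),
            group_means=means,
            df_between=len(groups) - 1,
            df_resid=len(per_subj) - len(groups),
        )

    df = per_subj.copy()
    df["cov"] = df["subject"].map(covariate)
    if df["cov"].isna().any():
        missing = df.loc[df["cov"].isna(), "subject"].tolist()
        raise ValueError(f"covariate missing for subjects: {missing}")
    dummies = pd.get_dummies(df[group_col], drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(df)), df["cov"].to_numpy(), dummies.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: covariate collinear with groups or constant")
    model = smf.ols(f"{value_col} ~ cov + C({group_col})", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    row = anova.loc[f"C({group_col})"]
    grand_cov = df["cov"].mean()
    adj = {}
    for g in groups:
        pred = df[df[group_col] == g].copy()
        pred["cov"] = grand_cov
        adj[str(g)] = float(model.predict(pred).mean())
    return GroupCompareResult(
        f_stat=float(row["F"]),
        p=float(row["PR(>F)"]),
        group_means=adj,
        df_between=int(row["df"]),
        df_resid=int(anova.loc["Residual", "df"]),
    )


def usv_filter(
    syllables: pd.DataFrame,
    fmin_khz: float = 35.0,
    fmax_khz: float = 110.0,
    dmin_ms: float = 8.0,
    dmax_ms: float = 200.0,
    min_gap_ms: float = 5.0,
    drop: str = "pair",
) -> pd.DataFrame:
    """Syllable inclusion filter.

    Keeps syllables with mean frequency in [35, 110] kHz and duration in
    [8, 200] ms (inclusive bounds), then removes syllables closer than 5 ms
    to their neighbour: with ``drop="pair"`` both members of the offending
    pair go, with ``drop="later"`` only the second.  If the table has a
    ``subject`` column the gap rule runs within each subject's recording.
    The output is a subset of the input and the filter is idempotent.
    """
    if drop not in ("pair", "later"):
        raise ValueError(f"unknown drop policy {drop!r}")
    if "subject" in syllables.columns and syllables["subject"].nunique() > 1:
        parts = [
            usv_filter(sub, fmin_khz, fmax_khz, dmin_ms, dmax_ms, min_gap_ms, drop)
            for _, sub in syllables.groupby("subject", sort=True)
        ]
        return pd.concat(parts, ignore_index=True)
    df = syllables.sort_values("onset_s", kind="stable").reset_index(drop=True)
    in_band = df["mean_freq_khz"].between(fmin_khz, fmax_khz) & df["duration_ms"].between(
        dmin_ms, dmax_ms
    )
    df = df.loc[in_band].reset_index(drop=True)
    if len(df) < 2:
        return df
    onset_ms = df["onset_s"].to_numpy() * 1000.0
    end_ms = onset_ms + df["duration_ms"].to_numpy()
    gap = onset_ms[1:] - end_ms[:-1]
    close = gap < min_gap_ms
    remove = np.zeros(len(df), dtype=bool)
    if drop == "pair":
        remove[:-1] |= close
        remove[1:] |= close
    else:
        remove[1:] |= close
    return df.loc[~remove].reset_index(drop=True)


def usv_summaries(syllables: pd.DataFrame, group_col: str = "genotype") -> pd.DataFrame:
    """Per-group mean +/- SEM of frequency, duration and volume, collapsed
    across syllable categories.  SEM is NaN (flagged) for single-syllable
    groups; absent groups simply produce no row.
    """
    if syllables.empty:
        raise ValueError("need >=1 syllable")
    rows = []
    for g, sub in syllables.groupby(group_col, sort=True):
        row = {"group": g, "n_syllables": len(sub)}
        for col, label in (
            ("mean_freq_khz", "freq_khz"),
            ("duration_ms", "duration_ms"),
            ("volume_db", "volume_db"),
        ):
            row[f"mean_{label}"] = float(sub[col].mean())
            row[f"sem_{label}"] = float(sub[col].sem()) if len(sub) > 1 else float("nan")
        row["sem_defined"] = len(sub) > 1
        rows.append(row)
    return pd.DataFrame(rows)
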