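"""Common- and rare-variant association statistics.

Covers the cohort-genetics layer of the pipeline: SNP/sample QC, greedy
LD-based tag selection, additive single-SNP association (linear or logistic),
the explicit SNP x covariate interaction model
``Y = b0 + b1*ADD + b2*COV1 + b3*ADD*COV1 + e``, a variance-component
(SKAT-style) gene-based score test, Bonferroni thresholds, analytic power for
a variant explaining a given trait-variance fraction, and Fisher/FDR gene-set
enrichment.

The SKAT statistic is ``Q = r' G W G' r`` with ``r`` the residuals of the
null model (intercept + covariates) and ``W`` diagonal variant weights
(Beta(1,25) density on MAF by default).  Its null distribution, a weighted
mixture of 1-df chi-squares, is approximated by the Liu et al. moment-matched
noncentral chi-square; a seeded permutation fallback covers small samples or
a failed approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core_io import log_stage


@dataclass
class GenotypeMatrix:
    """Sample x SNP dosages (0/1/2, NaN = missing) with SNP metadata.

    ``snps`` columns: snp_id, chrom, pos (1-based), a1, a2 (optional alleles).
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray  # float array, NaN missing

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError("dosage shape inconsistent with sample/snp counts")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0/1/2 or NaN")

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency recomputed from the codes."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    @property
    def snp_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    @property
    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def subset(self, sample_keep: np.ndarray | None = None, snp_keep: np.ndarray | None = None) -> "GenotypeMatrix":
        d = self.dosages
        sids = self.sample_ids
        snps = self.snps
        if sample_keep is not None:
            d = d[sample_keep]
            sids = [s for s, k in zip(sids, sample_keep) if k]
        if snp_keep is not None:
            d = d[:, snp_keep]
            snps = snps.loc[snp_keep].reset_index(drop=True)
        return GenotypeMatrix(sample_ids=sids, snps=snps, dosages=d)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_chi2_p(dosage_col: np.ndarray) -> float:
    """Hardy-Weinberg 1-df chi-square p for one SNP's dosages."""
    g = dosage_col[~np.isnan(dosage_col)]
    n = len(g)
    if n == 0:
        return 1.0
    n_aa = float(np.sum(g == 0))
    n_ab = float(np.sum(g == 1))
    n_bb = float(np.sum(g == 2))
    p = (2 * n_bb + n_ab) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.array([n_aa, n_ab, n_bb])
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(sps.chi2.sf(chi2, df=1))


def differential_missingness_p(dosage_col: np.ndarray, labels: np.ndarray) -> float:
    """Fisher exact p for missingness differing between cases and controls."""
    miss = np.isnan(dosage_col)
    a = int(np.sum(miss & (labels == 1)))
    b = int(np.sum(~miss & (labels == 1)))
    c = int(np.sum(miss & (labels == 0)))
    d = int(np.sum(~miss & (labels == 0)))
    return float(sps.fisher_exact([[a, b], [c, d]])[1])


def snp_qc(
    gm: GenotypeMatrix,
    case_control: np.ndarray | None = None,
    maf_min: float = 0.05,
    snp_missing_max: float = 0.05,
    hwe_p_min: float = 5e-7,
    diff_miss_p_min: float = 1e-5,
    sample_callrate_min: float = 0.95,
    het_sd_max: float = 3.0,
) -> GenotypeMatrix:
    """Sample filters, then SNP filters, mirroring standard array QC.

    Samples: call rate < 95% or heterozygosity rate beyond mean +/- 3 SD.
    SNPs: MAF < 5%, missingness > 5%, HWE p < 5e-7, or (given labels)
    case/control differential missingness at Fisher p < the configured bound.
    """
    het = np.zeros(len(gm.sample_ids))
    obs = ~np.isnan(gm.dosages)
    with np.errstate(invalid="ignore"):
        het = np.where(
            obs.sum(axis=1) > 0,
            np.nansum(gm.dosages == 1, axis=1) / np.maximum(obs.sum(axis=1), 1),
            np.nan,
        )
    het_mu, het_sd = np.nanmean(het), np.nanstd(het, ddof=1)
    keep_sample = gm.sample_call_rate >= sample_callrate_min
    if het_sd > 0:
        keep_sample &= np.abs(het - het_mu) <= het_sd_max * het_sd
    log_stage("snp_qc removed samples", int((~keep_sample).sum()))
    gm2 = gm.subset(sample_keep=keep_sample)
    labels = case_control[keep_sample] if case_control is not None else None

    keep = (gm2.maf >= maf_min) & (gm2.snp_missingness <= snp_missing_max)
    hwe = np.array([hwe_chi2_p(gm2.dosages[:, j]) for j in range(gm2.dosages.shape[1])])
    keep &= hwe >= hwe_p_min
    if labels is not None:
        dm = np.array(
            [differential_missingness_p(gm2.dosages[:, j], labels) for j in range(gm2.dosages.shape[1])]
        )
        keep &= dm >= diff_miss_p_min
    log_stage("snp_qc removed SNPs", int((~keep).sum()))
    out = gm2.subset(snp_keep=keep)
    if len(out.snps) == 0:
        raise ValueError("no SNPs survive QC")
    return out


# ---------------------------------------------------------------------------
# LD and tagging
# ---------------------------------------------------------------------------

def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Computed on pairwise-complete observations; NaN when fewer than two
    complete pairs remain or either SNP has zero variance.
    """
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.var(xs) == 0 or np.var(ys) == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def greedy_tag(gm: GenotypeMatrix, r2_max: float = 0.8) -> list[int]:
    """Greedy pairwise tag selection: returns column indices of tag SNPs.

    Every non-tag SNP ends with r^2 >= r2_max to at least one tag, no two
    tags reach r2_max with each other.  Greedy by descending count of
    yet-uncovered neighbours, position order breaking ties.
    """
    m = gm.dosages.shape[1]
    r2 = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            v = ld_r2(gm.dosages[:, i], gm.dosages[:, j])
            r2[i, j] = r2[j, i] = 0.0 if np.isnan(v) else v
    order = np.argsort(gm.snps["pos"].to_numpy(), kind="stable")
    uncovered = set(range(m))
    tags: list[int] = []
    while uncovered:
        best, best_count = None, -1
        for idx in order:
            if idx not in uncovered:
                continue
            count = sum(1 for j in uncovered if j == idx or r2[idx, j] >= r2_max)
            if count > best_count:
                best, best_count = int(idx), count
        tags.append(best)
        uncovered -= {best} | {j for j in uncovered if r2[best, j] >= r2_max}
    return sorted(tags)


# ---------------------------------------------------------------------------
# Single-SNP association
# ---------------------------------------------------------------------------

@dataclass
class AssocResult:
    beta: float  # slope on the dosage (log-odds for binary traits)
    se: float
    stat: float
    p: float
    n_used: int
    flagged: str | None = None  # e.g. "perfect_separation"


def assoc_additive(y: np.ndarray, dosage: np.ndarray, trait_kind: str = "quantitative") -> AssocResult:
    """Additive single-SNP test: linear for quantitative, logistic for binary."""
    ok = ~np.isnan(y) & ~np.isnan(dosage)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"need >=10 complete observations, have {n}")
    g = dosage[ok]
    yy = y[ok]
    if np.var(g) == 0:
        raise ValueError("constant dosage")
    X = sm.add_constant(g)
    if trait_kind == "quantitative":
        fit = sm.OLS(yy, X).fit()
    elif trait_kind == "binary":
        try:
            fit = sm.Logit(yy, X).fit(disp=0)
            if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
                return AssocResult(float(fit.params[1]), float("nan"), float("nan"),
                                   float("nan"), n, flagged="perfect_separation")
        except Exception:
            return AssocResult(float("nan"), float("nan"), float("nan"),
                               float("nan"), n, flagged="perfect_separation")
    else:
        raise ValueError(f"unknown trait_kind {trait_kind!r}")
    return AssocResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        stat=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        n_used=n,
    )


@dataclass
class InteractionFit:
    b0: float
    b1: float
    b2: float
    b3: float
    se: tuple[float, float, float, float]
    wald: tuple[float, float, float, float]
    p: tuple[float, float, float, float]
    p_interaction: float
    n_used: int


def fit_interaction(y: np.ndarray, dosage: np.ndarray, cov: np.ndarray) -> InteractionFit:
    """OLS of ``y ~ 1 + g + c + g*c``; the interaction test is the Wald test
    on the product term's coefficient."""
    ok = ~np.isnan(y) & ~np.isnan(dosage) & ~np.isnan(cov)
    n = int(ok.sum())
    if n < 20:
        raise ValueError(f"need >=20 complete observations, have {n}")
    g, c, yy = dosage[ok], cov[ok], y[ok]
    X = np.column_stack([np.ones(n), g, c, g * c])
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        names = ["const", "ADD", "COV1", "ADDxCOV1"]
        # identify a collinear column by testing rank without each
        dropped = [
            names[k]
            for k in range(4)
            if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {dropped}")
    fit = sm.OLS(yy, X).fit()
    return InteractionFit(
        b0=float(fit.params[0]),
        b1=float(fit.params[1]),
        b2=float(fit.params[2]),
        b3=float(fit.params[3]),
        se=tuple(float(s) for s in fit.bse),
        wald=tuple(float(t) for t in fit.tvalues),
        p=tuple(float(p) for p in fit.pvalues),
        p_interaction=float(fit.pvalues[3]),
        n_used=n,
    )


# ---------------------------------------------------------------------------
# SKAT-style gene-based test
# ---------------------------------------------------------------------------

@dataclass
class SkatResult:
    Q: float
    p: float
    n_variants: int
    weights: str
    method: str = "liu"  # "liu" | "permutation"


def _beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    return sps.beta.pdf(np.clip(maf, 1e-8, 1 - 1e-8), a, b)


def _liu_sf(q: float, lambdas: np.ndarray) -> float:
    """Survival function of sum_j lambda_j chi2_1 at q (Liu-Tang-Zhang 2009
    moment-matched noncentral chi-square)."""
    lam = lambdas[lambdas > 1e-12 * max(lambdas.max(), 1.0)]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        ell = a**2 - 2 * delta
    else:
        delta = 0.0
        ell = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    mu_x = ell + delta
    sigma_x = np.sqrt(2 * (ell + 2 * delta))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(sps.ncx2.sf(t, df=ell, nc=delta))


def skat_test(
    y: np.ndarray,
    genotypes: np.ndarray,
    weights: str = "beta",
    covariates: np.ndarray | None = None,
    maf_range: tuple[float, float] | None = None,
    seed: int | None = None,
    n_perm: int = 2000,
) -> SkatResult:
    """Variance-component score test of a variant set against a quantitative
    trait.

    ``genotypes`` is (n_samples, n_variants) dosages; missing dosages are
    mean-imputed per variant.  ``weights`` is ``"beta"`` (Beta(1,25) density
    on MAF, up-weighting rare variants) or ``"flat"``.  ``maf_range``
    restricts the tested variants (e.g. ``(0, 0.01)`` rare-only,
    ``(0.05, 0.5)`` common-only).  The p-value uses the Liu moment-matched
    approximation; with n < 50, or if the approximation degenerates, a
    seeded residual-permutation p is returned instead.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    n = len(y)
    if G.ndim != 2 or G.shape[0] != n:
        raise ValueError("genotype matrix must be (n_samples, n_variants)")
    # mean-impute missing dosages
    col_mean = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    G = np.where(np.isnan(G), col_mean, G)

    with np.errstate(invalid="ignore"):
        maf = np.minimum(G.mean(axis=0) / 2.0, 1 - G.mean(axis=0) / 2.0)
    keep = G.std(axis=0) > 0
    if maf_range is not None:
        lo, hi = maf_range
        keep &= (maf >= lo) & (maf <= hi)
    if not keep.any():
        raise ValueError("zero polymorphic variants in the tested set")
    G = G[:, keep]
    maf = maf[keep]
    m = G.shape[1]

    if weights == "beta":
        w = _beta_maf_weights(maf)
    elif weights == "flat":
        w = np.ones(m)
    else:
        raise ValueError(f"unknown weights {weights!r}")

    X = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    sigma2 = float(resid @ resid) / (n - X.shape[1])

    Gw = G * np.sqrt(w)  # n x m, so G W G' = Gw Gw'
    score = Gw.T @ resid
    Q = float(score @ score) / sigma2

    # eigenvalues of W^1/2 G' (I - H) G W^1/2 give the null mixture weights
    Xq, _ = np.linalg.qr(X)
    Gp = Gw - Xq @ (Xq.T @ Gw)
    K = Gp.T @ Gp
    lambdas = np.linalg.eigvalsh(K)
    lambdas = lambdas[lambdas > 0]

    method = "liu"
    p: float
    try:
        if n < 50 or lambdas.size == 0:
            raise ValueError("permutation fallback")
        p = _liu_sf(Q, lambdas)
        if not np.isfinite(p) or p <= 0:
            raise ValueError("approximation failed")
    except ValueError:
        rng = np.random.default_rng(0 if seed is None else seed)
        count = 0
        for _ in range(n_perm):
            rp = rng.permutation(resid)
            sp_ = Gw.T @ rp
            qp = float(sp_ @ sp_) / sigma2
            if qp >= Q:
                count += 1
        p = (count + 1) / (n_perm + 1)
        method = "permutation"

    return SkatResult(Q=Q, p=min(float(p), 1.0), n_variants=m, weights=weights, method=method)


# ---------------------------------------------------------------------------
# Thresholds, power, enrichment
# ---------------------------------------------------------------------------

def bonferroni(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def power_variance_explained(
    n: int,
    r2: float,
    alpha: float,
    method: str = "ncp_chi2_1df",
    seed: int | None = None,
    n_reps: int = 5000,
) -> float:
    """Power to detect a variant explaining a fraction ``r2`` of trait
    variance at significance level ``alpha`` in a sample of ``n``.

    Analytic: 1-df chi-square with noncentrality ``n * r2 / (1 - r2)``.
    Simulation: seeded Monte-Carlo of the additive linear test at the stated
    n and variance fraction.
    """
    if not 0 <= r2 < 1 or not 0 < alpha <= 1:
        raise ValueError("need 0 <= r2 < 1 and 0 < alpha <= 1")
    if method == "ncp_chi2_1df":
        if r2 == 0:
            return alpha
        ncp = n * r2 / (1 - r2)
        crit = sps.chi2.isf(alpha, df=1)
        return float(sps.ncx2.sf(crit, df=1, nc=ncp))
    if method == "simulation":
        rng = np.random.default_rng(0 if seed is None else seed)
        maf = 0.3
        hits = 0
        for _ in range(n_reps):
            g = rng.binomial(2, maf, size=n).astype(float)
            gv = np.var(g)
            beta = np.sqrt(r2 / ((1 - r2) * gv)) if r2 > 0 else 0.0
            y = beta * g + rng.standard_normal(n)
            # score-form chi-square of the slope test
            r = np.corrcoef(g, y)[0, 1]
            chi2 = n * r * r
            if sps.chi2.sf(chi2, df=1) < alpha:
                hits += 1
        return hits / n_reps
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EnrichmentRow:
    term: str
    n_hits_in_term: int
    n_term: int
    odds_ratio: float
    p: float
    q: float = field(default=float("nan"))


def enrich_fisher_fdr(
    hit_genes: set[str],
    background_genes: set[str],
    term_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation per term, BH-corrected.

    Terms with no overlap with the background are skipped with a warning.
    """
    if not hit_genes <= background_genes:
        raise ValueError("hit genes must be a subset of the background")
    rows: list[EnrichmentRow] = []
    for term, genes in term_sets.items():
        in_bg = genes & background_genes
        if not in_bg:
            log_stage(f"enrichment term skipped (no background overlap): {term}", 0)
            continue
        a = len(hit_genes & in_bg)
        b = len(hit_genes) - a
        c = len(in_bg) - a
        d = len(background_genes) - len(hit_genes) - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(EnrichmentRow(term, a, len(in_bg), float(odds), float(p)))
    if not rows:
        return pd.DataFrame(columns=["term", "n_hits_in_term", "n_term", "odds_ratio", "p", "q"])
    pvals = [r.p for r in rows]
    q = multipletests(pvals, method="fdr_bh")[1]
    for r, qi in zip(rows, q):
        r.q = float(qi)
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("p", kind="stable").reset_index(drop=True)
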