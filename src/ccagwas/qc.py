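"""SNP/sample quality control and phenotype residualization/normalization.

Preprocessing mirrors standard metabolomics-GWAS practice: SNPs are dropped
for high missingness (>5%), low minor allele frequency (<0.01), departure
from Hardy-Weinberg proportions (exact test P < 1e-6) or poor imputation
quality (Rsq < 0.30 when supplied); samples are dropped for exclusion flags
or >5% genotype missingness. Metabolites are residualized on covariates
(sex, age, cohort, genetic PCs) and the residuals mapped to standard-normal
quantiles by a rank-based inverse normal transformation, so every metabolite
enters association testing with mean 0 and SD 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GenotypeMatrix, PhenotypeTable

__all__ = [
    "QcThresholds",
    "hwe_exact_test",
    "snp_qc_filter",
    "sample_filter",
    "residualize",
    "inverse_normal_transform",
    "pool_cohorts",
    "preprocess_phenotypes",
    "genetic_pcs",
    "CovariateResidualizer",
    "InverseNormalTransformer",
]

#: total genotype count below which the HWE test uses exact integer arithmetic
_HWE_EXACT_N = 500


@dataclass(frozen=True)
class QcThresholds:
    max_missingness: float = 0.05
    min_maf: float = 0.01
    min_hwe_p: float = 1.0e-6
    min_rsq: float = 0.30
    max_sample_missingness: float = 0.05


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, the probability of every
    feasible heterozygote count is evaluated and the P value is the sum of
    probabilities no larger than that of the observed configuration. For
    totals up to 500 the enumeration uses exact integer arithmetic; above
    that, log-gamma weights with a 1e-12 relative tie tolerance.
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_hom1, n_het, n_hom2 = counts
    nr = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)  # rare allele count
    if nr == 0:
        return 1.0
    hets = np.arange(nr % 2, min(nr, 2 * n - nr) + 1, 2)

    if n <= _HWE_EXACT_N:
        weights, total = _hwe_weights_exact(n, nr)
        w_obs = weights[(n_het - (nr % 2)) // 2]
        num = sum(w for w in weights if w <= w_obs)
        return num / total  # big-int division: exact, correctly rounded

    rare_hom = (nr - hets) // 2
    common_hom = n - hets - rare_hom
    logw = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
        + hets * math.log(2.0)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[list(hets).index(n_het)]
    p = w[w <= w_obs * (1.0 + 1e-12)].sum() / w.sum()
    return float(min(p, 1.0))


@lru_cache(maxsize=65536)
def _hwe_weights_exact(n: int, nr: int) -> tuple[tuple[int, ...], int]:
    """Unnormalized configuration counts C(n,h) * C(n-h,(nr-h)/2) * 2^h for
    every feasible heterozygote count h, plus their total (exact integers)."""
    weights = tuple(
        math.comb(n, h) * math.comb(n - h, (nr - h) // 2) * (1 << h)
        for h in range(nr % 2, min(nr, 2 * n - nr) + 1, 2)
    )
    return weights, sum(weights)


def _genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """Hard-call counts from (possibly fractional) dosages, ignoring missing."""
    d = dosage[~np.isnan(dosage)]
    g = np.clip(np.rint(d), 0, 2).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def snp_qc_filter(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the SNP-level filters; every criterion is evaluated on the input.

    Returns the filtered matrix plus a per-SNP report (maf, missingness,
    hwe_p, rsq, pass flag, comma-joined failure reasons).
    """
    thr = thresholds or QcThresholds()
    maf = genotypes.maf()
    miss = genotypes.missingness()
    hwe_p = np.empty(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        counts = _genotype_counts(genotypes.dosages[:, j])
        hwe_p[j] = hwe_exact_test(*counts) if sum(counts) else np.nan
    rsq = (
        genotypes.snps["rsq"].to_numpy(dtype=float)
        if "rsq" in genotypes.snps.columns
        else np.full(genotypes.n_snps, np.nan)
    )

    reasons = []
    for j in range(genotypes.n_snps):
        why = []
        if miss[j] > thr.max_missingness:
            why.append("missingness")
        if not (maf[j] >= thr.min_maf):  # NaN maf (all missing) also fails
            why.append("maf")
        if hwe_p[j] < thr.min_hwe_p:
            why.append("hwe")
        if not np.isnan(rsq[j]) and rsq[j] < thr.min_rsq:
            why.append("rsq")
        reasons.append(",".join(why))
    passed = np.array([r == "" for r in reasons])

    report = pd.DataFrame(
        {
            "id": genotypes.snps["id"],
            "maf": maf,
            "missingness": miss,
            "hwe_p": hwe_p,
            "rsq": rsq,
            "pass": passed,
            "reasons": reasons,
        }
    )
    if not passed.any():
        warnings.warn("all SNPs removed by QC filters")
    filtered = genotypes.take_snps(np.flatnonzero(passed))
    return filtered, report


def sample_filter(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    max_missingness: float = 0.05,
) -> tuple[PhenotypeTable, GenotypeMatrix]:
    """Drop flagged samples and samples with high genotype missingness.

    Exclusion-flag columns (e.g. lipid-lowering therapy, pregnancy) are
    boolean columns declared on the phenotype table. Genotype and phenotype
    rows stay aligned.
    """
    if pheno.samples != geno.samples:
        raise ValueError("sample_filter requires pre-aligned tables (see align_samples)")
    flagged = np.zeros(pheno.n_samples, dtype=bool)
    for col in pheno.exclusion_cols:
        flagged |= pheno.data[col].to_numpy(dtype=bool)
    high_miss = geno.missing_mask.mean(axis=1) > max_missingness
    keep = ~(flagged | high_miss)
    if not keep.any():
        raise ValueError("sample filtering removed every sample")
    return pheno.take_samples(keep), geno.take_samples(keep)


def _design_with_intercept(covariates: np.ndarray) -> np.ndarray:
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] == 1 and covariates.shape[1] > 1:
        covariates = covariates.T
    return np.column_stack([np.ones(covariates.shape[0]), covariates])


def _check_full_rank(design: np.ndarray, names: list[str] | None = None) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that add no rank, scanning left to right
        bad = []
        cur = design[:, [0]]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([cur, design[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                label = names[j - 1] if names else f"column {j - 1}"
                bad.append(label)
            else:
                cur = cand
        raise ValueError(f"covariate matrix is rank deficient; offending columns: {bad}")


def residualize(
    values: np.ndarray,
    covariates: np.ndarray,
    names: list[str] | None = None,
) -> np.ndarray:
    """Least-squares residuals of ``values`` on covariates plus an intercept.

    Residuals are orthogonal to every covariate column and to the intercept
    (so they have mean zero). ``values`` may be a vector or a samples x
    traits matrix. Rank-deficient designs are rejected with the offending
    columns named.
    """
    values = np.asarray(values, dtype=float)
    design = _design_with_intercept(covariates)
    if design.shape[0] != values.shape[0]:
        raise ValueError("values and covariates disagree on sample count")
    _check_full_rank(design, names)
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ coef


def inverse_normal_transform(values: np.ndarray, offset: str = "half") -> np.ndarray:
    """Rank-based inverse normal transformation.

    Maps value with (average, ties shared) rank r among n non-missing points
    to ``Phi^{-1}((r - c) / (n + d))``: ``offset='half'`` uses c=0.5, d=0;
    ``offset='blom'`` uses c=3/8, d=1/4. Strictly rank-preserving; missing
    values pass through as NaN.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    x = values[mask]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("constant input cannot be inverse-normal transformed")
    ranks = stats.rankdata(x, method="average")
    n = x.size
    if offset == "half":
        q = (ranks - 0.5) / n
    elif offset == "blom":
        q = (ranks - 3.0 / 8.0) / (n + 0.25)
    else:
        raise ValueError(f"unknown INT offset {offset!r}")
    out[mask] = stats.norm.ppf(q)
    return out


def preprocess_phenotypes(
    pheno: PhenotypeTable, include_cohort: bool | None = None, offset: str = "half"
) -> PhenotypeTable:
    """Residualize every metabolite on the covariates, then inverse-normal
    transform the residuals (residualize -> INT, in that fixed order)."""
    if include_cohort is None:
        include_cohort = pheno.cohort_col is not None and pheno.data[pheno.cohort_col].nunique() > 1
    cov = pheno.covariate_matrix(include_cohort=include_cohort)
    Y = pheno.metabolite_matrix()
    if cov.shape[1]:
        Y = residualize(Y, cov, names=list(pheno.covariates))
    Y = np.column_stack([inverse_normal_transform(Y[:, j], offset=offset) for j in range(Y.shape[1])])
    # exact mean-0 / SD-1 per metabolite (the INT alone leaves SD slightly < 1)
    Y -= np.nanmean(Y, axis=0)
    Y /= np.nanstd(Y, axis=0)
    return pheno.with_metabolite_values(Y)


def pool_cohorts(tables: list[PhenotypeTable], offset: str = "half") -> PhenotypeTable:
    """Stack cohorts, re-residualize with cohort as a covariate, re-apply INT.

    All tables must carry identical metabolite columns; covariates are taken
    as the intersection across cohorts (a covariate absent from one cohort,
    e.g. age in a birth cohort, cannot be adjusted for jointly).
    """
    if not tables:
        raise ValueError("no cohorts supplied")
    met0 = set(tables[0].metabolites)
    for t in tables[1:]:
        if set(t.metabolites) != met0:
            raise ValueError("cohorts carry different metabolite sets")
    metabolites = list(tables[0].metabolites)
    shared_cov = [c for c in tables[0].covariates if all(c in t.covariates for t in tables)]

    frames = []
    labels = []
    for i, t in enumerate(tables):
        cohort = (
            t.data[t.cohort_col].astype(str)
            if t.cohort_col is not None
            else pd.Series(f"cohort{i + 1}", index=t.data.index)
        )
        frames.append(t.data[metabolites + shared_cov])
        labels.append(cohort)
    data = pd.concat(frames, axis=0)
    data["cohort"] = pd.concat(labels, axis=0)
    if data.index.has_duplicates:
        raise ValueError("sample ids collide across cohorts")

    pooled = PhenotypeTable(
        data=data, metabolites=metabolites, covariates=shared_cov, cohort_col="cohort"
    )
    return preprocess_phenotypes(pooled, include_cohort=len(tables) > 1, offset=offset)


def genetic_pcs(genotypes: GenotypeMatrix, n_components: int = 10) -> np.ndarray:
    """Top principal components of the standardized dosage matrix.

    Missing dosages are mean-imputed per SNP for the decomposition only.
    Used when genetic PC covariates are not supplied with the phenotypes.
    """
    X = genotypes.dosages.copy()
    mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mean, idx[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    from sklearn.decomposition import PCA

    n_components = min(n_components, min(X.shape) - 1)
    return PCA(n_components=n_components, svd_solver="auto", random_state=0).fit_transform(X)


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """Transformer returning least-squares residuals on a fixed covariate set.

    Parameters
    ----------
    covariates : array-like, shape (n_samples, n_covariates)
        Design columns (an intercept is always added).
    """

    def __init__(self, covariates=None):
        self.covariates = covariates

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.covariates is None:
            raise ValueError("covariates must be supplied")
        design = _design_with_intercept(np.asarray(self.covariates, dtype=float))
        _check_full_rank(design)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        self.design_ = design
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        coef, *_ = np.linalg.lstsq(self.design_, X, rcond=None)
        return X - self.design_ @ coef


class InverseNormalTransformer(BaseEstimator, TransformerMixin):
    """Column-wise rank-based inverse normal transformation.

    The mapping is rank-based on the data it is applied to (there is no
    out-of-sample quantile function), so ``transform`` re-ranks its input.
    """

    def __init__(self, offset: str = "half"):
        self.offset = offset

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack(
            [inverse_normal_transform(X[:, j], offset=self.offset) for j in range(X.shape[1])]
        )
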