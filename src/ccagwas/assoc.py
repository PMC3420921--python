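"""Single-SNP association statistics.

Univariate: ordinary least squares of one metabolite on minor-allele dosage
(0..2), two-sided t test of the slope.

Multivariate: canonical correlation between one SNP and a network of k
metabolites. With a single exogenous variable only one canonical pair
exists, and the squared canonical correlation rho^2 equals the multiple R^2
from regressing the dosage on the metabolite set. Wilks' lambda is then
lambda = 1 - rho^2, and

    F = ((n - k - 1) / k) * rho^2 / (1 - rho^2),   df = (k, n - k - 1)

is exactly F distributed under the null for this single-pair setting (it is
the overall-regression F test), so no multi-set Rao approximation is needed.
Each test also reports a loading per metabolite: the Pearson correlation
between that metabolite and the metabolite-side canonical variate, oriented
to correlate positively with minor-allele count, quantifying the
metabolite's contribution to the joint signal.

Missing dosages are handled by complete-case analysis per SNP x network by
default; per-SNP mean imputation is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "UnivariateResult",
    "MultivariateResult",
    "univariate_test",
    "canonical_r2",
    "wilks_to_F",
    "canonical_loadings",
    "multivariate_test",
    "conditional_multivariate_test",
    "min_univariate_p",
]

#: rho^2 at or above this is reported as a degenerate (collinear) fit
_DEGENERATE_R2 = 1.0 - 1e-10


@dataclass
class UnivariateResult:
    snp_id: str
    metabolite_id: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    flag: str | None = None


@dataclass
class MultivariateResult:
    snp_id: str
    network_id: int | str
    rho2: float
    wilks_lambda: float
    F: float
    df1: int
    df2: int
    p: float
    loadings: dict[str, float]
    weights: dict[str, float] = field(default_factory=dict)
    n: int = 0
    flag: str | None = None


def _complete_mask(g: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    mask = ~np.isnan(g)
    if Y is not None:
        mask &= ~np.isnan(Y).any(axis=1)
    return mask


def univariate_test(
    genotype: np.ndarray,
    metabolite: np.ndarray,
    snp_id: str = "",
    metabolite_id: str = "",
) -> UnivariateResult:
    """OLS of metabolite on dosage with intercept; two-sided t test of b = 0."""
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(metabolite, dtype=float)
    mask = _complete_mask(g) & ~np.isnan(y)
    g, y = g[mask], y[mask]
    n = g.size
    if n < 3:
        raise ValueError("need at least 3 complete genotype/metabolite pairs")
    if np.ptp(g) == 0:
        return UnivariateResult(snp_id, metabolite_id, np.nan, np.nan, np.nan, np.nan, n, "monomorphic")
    fit = stats.linregress(g, y)
    t = fit.slope / fit.stderr if fit.stderr > 0 else 0.0
    p = float(fit.pvalue) if fit.stderr > 0 else 1.0
    return UnivariateResult(snp_id, metabolite_id, float(fit.slope), float(fit.stderr), float(t), p, n)


def canonical_r2(genotype: np.ndarray, Y: np.ndarray) -> float:
    """Squared canonical correlation between one SNP and a metabolite set.

    Computed as the multiple R^2 of the dosage regressed on the metabolites
    (with intercept), which equals rho^2 when the exogenous set has a single
    member. Rank-deficient metabolite sets and constant genotypes are
    rejected.
    """
    g = np.asarray(genotype, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    mask = _complete_mask(g, Y)
    g, Y = g[mask], Y[mask]
    n, k = Y.shape
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} complete cases, have {n}")
    if np.ptp(g) == 0:
        raise ValueError("constant genotype")
    Yc = Y - Y.mean(axis=0)
    if np.linalg.matrix_rank(Yc, tol=1e-10 * max(n, k)) < k:
        raise ValueError("metabolite set is rank deficient (collinear columns)")
    gc = g - g.mean()
    coef, *_ = np.linalg.lstsq(Yc, gc, rcond=None)
    resid = gc - Yc @ coef
    ss_tot = float(gc @ gc)
    rho2 = 1.0 - float(resid @ resid) / ss_tot
    return float(np.clip(rho2, 0.0, 1.0))


def wilks_to_F(rho2: float, n: int, k: int):
    """Wilks' lambda and its F transform for a single canonical pair.

    Returns ``(lambda, F, df1, df2, p)`` with lambda = 1 - rho^2,
    F = ((n-k-1)/k) * rho^2/(1-rho^2) on (k, n-k-1) df, and p the upper-tail
    F probability.
    """
    if not (0.0 <= rho2 < 1.0):
        raise ValueError(f"rho2 must lie in [0, 1), got {rho2}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    lam = 1.0 - rho2
    df1, df2 = k, n - k - 1
    F = (df2 / df1) * (rho2 / lam)
    p = float(stats.f.sf(F, df1, df2))
    if p == 0.0:  # extreme upper tail underflows; keep p in (0, 1]
        p = 5e-324
    return lam, float(F), df1, df2, p


def canonical_loadings(Y: np.ndarray, genotype: np.ndarray):
    """Structure correlations of each metabolite with the canonical variate.

    The metabolite-side canonical variate is the fitted value of the dosage
    regressed on the metabolite set, oriented to correlate positively with
    minor-allele count. Returns ``(loadings, weights, flag)`` where weights
    are the (orientation-consistent) regression coefficients and ``flag`` is
    ``"degenerate"`` when the variate has zero variance.
    """
    g = np.asarray(genotype, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    mask = _complete_mask(g, Y)
    g, Y = g[mask], Y[mask]
    Yc = Y - Y.mean(axis=0)
    gc = g - g.mean()
    coef, *_ = np.linalg.lstsq(Yc, gc, rcond=None)
    variate = Yc @ coef
    v_sd = variate.std()
    if v_sd == 0:
        return np.full(Y.shape[1], np.nan), coef, "degenerate"
    if np.corrcoef(variate, gc)[0, 1] < 0:  # orientation guard (R^2 >= 0 makes this rare)
        variate, coef = -variate, -coef
    y_sd = Yc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        loadings = (Yc * variate[:, None]).mean(axis=0) / (y_sd * v_sd)
    return np.clip(loadings, -1.0, 1.0), coef, None


def multivariate_test(
    genotype: np.ndarray,
    Y: np.ndarray,
    metabolite_ids: list[str],
    snp_id: str = "",
    network_id: int | str = 0,
    missing: str = "complete",
) -> MultivariateResult:
    """CCA/Wilks' lambda test of one SNP against one metabolite network.

    ``missing='complete'`` drops samples with a missing dosage for this SNP;
    ``missing='mean'`` mean-imputes the dosage first. A degenerate fit
    (rho^2 within 1e-10 of 1) is reported with p = 0 and flagged rather than
    raised, so genome scans never abort mid-run.
    """
    g = np.asarray(genotype, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    if missing == "mean":
        g = np.where(np.isnan(g), np.nanmean(g), g)
    mask = _complete_mask(g, Y)
    gm, Ym = g[mask], Y[mask]
    n, k = Ym.shape
    if len(metabolite_ids) != k:
        raise ValueError("metabolite_ids length must match network width")
    rho2 = canonical_r2(gm, Ym)
    if rho2 >= _DEGENERATE_R2:
        loadings, weights, _ = canonical_loadings(Ym, gm)
        return MultivariateResult(
            snp_id, network_id, rho2, 1.0 - rho2, np.inf, k, n - k - 1, 0.0,
            dict(zip(metabolite_ids, np.asarray(loadings, float))),
            dict(zip(metabolite_ids, np.asarray(weights, float))),
            n, "degenerate",
        )
    lam, F, df1, df2, p = wilks_to_F(rho2, n, k)
    loadings, weights, flag = canonical_loadings(Ym, gm)
    return MultivariateResult(
        snp_id, network_id, rho2, lam, F, df1, df2, p,
        dict(zip(metabolite_ids, np.asarray(loadings, float))),
        dict(zip(metabolite_ids, np.asarray(weights, float))),
        n, flag,
    )


def conditional_multivariate_test(
    genotype: np.ndarray,
    Y: np.ndarray,
    conditioning: np.ndarray,
    metabolite_ids: list[str],
    snp_id: str = "",
    network_id: int | str = 0,
) -> MultivariateResult:
    """Multivariate test after conditioning the network on proximal SNP(s).

    Each network metabolite is regressed (with intercept) onto the
    conditioning dosages and the residuals replace the metabolites; the
    multivariate test then runs unchanged on the target SNP. An attenuated
    signal indicates the target is not independent of the conditioning
    locus. Collinear conditioning columns are reduced with a warning.
    """
    g = np.asarray(genotype, dtype=float)
    C = np.atleast_2d(np.asarray(conditioning, dtype=float))
    if C.shape[0] == 1 and C.shape[1] > 1:
        C = C.T
    if C.size == 0:
        raise ValueError("conditioning set is empty")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    for j in range(C.shape[1]):
        cj = C[:, j]
        both = ~np.isnan(cj) & ~np.isnan(g)
        if both.any() and np.array_equal(cj[both], g[both]):
            warnings.warn("conditioning SNP is identical to the target SNP")

    mask = _complete_mask(g, Y) & ~np.isnan(C).any(axis=1)
    gm, Ym, Cm = g[mask], Y[mask], C[mask]
    Cm = Cm - Cm.mean(axis=0)
    keep = []
    basis = np.empty((Cm.shape[0], 0))
    for j in range(Cm.shape[1]):
        cand = np.column_stack([basis, Cm[:, j]])
        if np.linalg.matrix_rank(cand, tol=1e-10 * Cm.shape[0]) > basis.shape[1]:
            basis = cand
            keep.append(j)
    if len(keep) < Cm.shape[1]:
        warnings.warn(
            f"conditioning set is collinear; using {len(keep)} of {Cm.shape[1]} columns"
        )
    coef, *_ = np.linalg.lstsq(basis, Ym - Ym.mean(axis=0), rcond=None)
    Yres = Ym - Ym.mean(axis=0) - basis @ coef
    return multivariate_test(gm, Yres, metabolite_ids, snp_id, network_id)


def min_univariate_p(results: list[UnivariateResult], network_members: list[str]):
    """Lowest univariate P over a network's members (the comparison rule for
    judging multivariate hits against single-metabolite scans).

    Ties keep the lexicographically first metabolite id. Returns
    ``(p, metabolite_id)``.
    """
    members = set(network_members)
    if not members:
        raise ValueError("empty network")
    hits = [
        r for r in results
        if r.metabolite_id in members and r.flag is None and not np.isnan(r.p)
    ]
    if not hits:
        raise ValueError("no univariate results for the network's members")
    best = min(hits, key=lambda r: (r.p, r.metabolite_id))
    return best.p, best.metabolite_id
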