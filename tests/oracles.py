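"""Independent reference implementations used only for cross-checking.

Each oracle takes a deliberately different computational route from the
package code it validates (exact factorial enumeration, normal equations,
naive quadratic agglomeration, likelihood grid search).
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE P by enumerating every feasible heterozygote count with its
    exact configuration weight n! * 2^h / (n_rr! h! n_cc!) as a big integer."""
    n = n_AA + n_Aa + n_aa
    nr = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if nr == 0:
        return 1.0
    fact = math.factorial
    weights = {}
    for h in range(nr % 2, min(nr, 2 * n - nr) + 1, 2):
        n_rr = (nr - h) // 2
        n_cc = n - h - n_rr
        weights[h] = fact(n) * 2**h // (fact(n_rr) * fact(h) * fact(n_cc))
    w_obs = weights[n_Aa]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, sum(weights.values())))


def hwe_group_table(n: int, nr: int) -> dict[int, float]:
    """P value for every feasible het count at fixed (total, rare-allele count)."""
    fact = math.factorial
    hets = list(range(nr % 2, min(nr, 2 * n - nr) + 1, 2))
    w = {}
    for h in hets:
        n_rr = (nr - h) // 2
        w[h] = fact(n) * 2**h // (fact(n_rr) * fact(h) * fact(n - h - n_rr))
    total = sum(w.values())
    return {h: float(Fraction(sum(v for v in w.values() if v <= w[h]), total)) for h in hets}


def ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Multiple R^2 via the normal equations (X'X) b = X'y with intercept."""
    X1 = np.column_stack([np.ones(len(y)), X])
    b = np.linalg.solve(X1.T @ X1, X1.T @ y)
    resid = y - X1 @ b
    yc = y - y.mean()
    return 1.0 - float(resid @ resid) / float(yc @ yc)


def ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    X1 = np.column_stack([np.ones(len(y)), X])
    b = np.linalg.solve(X1.T @ X1, X1.T @ y)
    return y - X1 @ b


def naive_linkage_heights(D: np.ndarray, method: str = "average") -> list[float]:
    """O(n^3) agglomeration on a plain distance matrix; returns merge heights."""
    clusters = [[i] for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ds = [D[i, j] for i in clusters[a] for j in clusters[b]]
                if method == "average":
                    d = sum(ds) / len(ds)
                elif method == "complete":
                    d = max(ds)
                else:
                    d = min(ds)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def _haplotype_cell_probs(f: np.ndarray) -> np.ndarray:
    """3x3 genotype cell probabilities from haplotype freqs [ab, aB, Ab, AB]."""
    minor_a = np.array([0, 0, 1, 1])
    minor_b = np.array([0, 1, 0, 1])
    P = np.zeros((3, 3))
    for h1 in range(4):
        for h2 in range(4):
            i = minor_a[h1] + minor_a[h2]
            j = minor_b[h1] + minor_b[h2]
            P[i, j] += f[h1] * f[h2]
    return P


def ld_grid_search(counts: np.ndarray, n_grid: int = 2001) -> tuple[float, float]:
    """Maximize the multinomial likelihood over the AB-haplotype frequency
    (allele frequencies fixed at their MLEs), then return (r2, D').

    Two-stage grid: a coarse pass over the feasible interval, then a fine
    pass around the coarse optimum."""
    n = counts.sum()
    gA = counts.sum(axis=1)
    gB = counts.sum(axis=0)
    pA = (gA[1] + 2 * gA[2]) / (2 * n)
    pB = (gB[1] + 2 * gB[2]) / (2 * n)
    lo0 = max(0.0, pA + pB - 1.0)
    hi0 = min(pA, pB)

    def _scan(lo, hi):
        best_ll, best_fab = -np.inf, lo
        for fab in np.linspace(lo, hi, n_grid):
            f = np.array([1 - pA - pB + fab, pB - fab, pA - fab, fab])
            if np.any(f < -1e-12):
                continue
            P = _haplotype_cell_probs(np.clip(f, 0, 1))
            with np.errstate(divide="ignore"):
                ll = float(np.sum(counts * np.log(np.where(P > 0, P, 1e-300))))
            if ll > best_ll:
                best_ll, best_fab = ll, fab
        return best_fab

    fab = _scan(lo0, hi0)
    step = (hi0 - lo0) / (n_grid - 1)
    fab = _scan(max(lo0, fab - 2 * step), min(hi0, fab + 2 * step))
    D = fab - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom == 0 else D * D / denom
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if D >= 0 else min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    return float(min(r2, 1.0)), float(min(dprime, 1.0))
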