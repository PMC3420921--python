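"""Genome-scan orchestration.

Runs the univariate and/or multivariate tests over every SNP, applies the
Bonferroni thresholds (base 5.0e-8 divided by the number of networks for
multivariate tests, by the number of metabolites for univariate tests),
defines 200 kb loci around top SNPs by greedy clumping, estimates genomic
inflation as the slope of observed vs expected -log10(p) quantiles over the
least-significant 90% of tests, compares the two scan modes locus by locus,
and summarises LD between SNP pairs via EM haplotype-frequency estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .assoc import min_univariate_p, multivariate_test
from .containers import GenotypeMatrix, MetaboliteNetwork, PhenotypeTable, align_samples

__all__ = [
    "significance_threshold",
    "round_sig",
    "ScanResult",
    "CanonicalCorrelationScan",
    "run_genome_scan",
    "Locus",
    "define_loci",
    "InflationReport",
    "genomic_inflation",
    "multivariate_vs_univariate_summary",
    "ld_stats",
]

BASE_ALPHA = 5.0e-8  # genome-wide base level (independent common haploblocks)
LOCUS_SPAN = 200_000


def significance_threshold(base: float, n_tests: int) -> float:
    """Bonferroni threshold ``base / n_tests`` (unrounded; round only for display)."""
    if not (0.0 < base < 1.0):
        raise ValueError("base significance level must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return base / n_tests


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures, for reporting thresholds."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


@dataclass
class ScanResult:
    multivariate: pd.DataFrame | None
    univariate: pd.DataFrame | None
    thresholds: dict[str, float]
    networks: list[MetaboliteNetwork] = field(default_factory=list)


class CanonicalCorrelationScan(BaseEstimator):
    """Genome scan estimator: SNP x network CCA tests and/or SNP x metabolite OLS.

    Parameters
    ----------
    networks : list of MetaboliteNetwork
        Metabolite groupings to use as multivariate phenotype sets.
    mode : {"multivariate", "univariate", "both"}
    base_alpha : float
        Genome-wide base significance level, divided by the number of
        networks (multivariate) or metabolites (univariate).
    missing : {"complete", "mean"}
        Per-SNP handling of missing dosages.

    After ``fit(geno, pheno)``: ``multivariate_results_``,
    ``univariate_results_`` (DataFrames, or None for modes not run) and
    ``thresholds_``.
    """

    def __init__(self, networks=None, mode="both", base_alpha=BASE_ALPHA, missing="complete"):
        self.networks = networks
        self.mode = mode
        self.base_alpha = base_alpha
        self.missing = missing

    def fit(self, X: GenotypeMatrix, y: PhenotypeTable = None):
        if y is None:
            raise ValueError("fit requires a PhenotypeTable as y")
        if self.mode not in ("multivariate", "univariate", "both"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        geno, pheno = align_samples(X, y)
        networks = self.networks or []
        if self.mode in ("multivariate", "both") and not networks:
            raise ValueError("multivariate scan needs networks")

        mets = list(pheno.metabolites)
        Y = pheno.metabolite_matrix()
        snps = geno.snps
        order_cols = {"snp": snps["id"], "chrom": snps["chrom"], "pos": snps["pos"]}

        thresholds = {
            "multivariate": significance_threshold(self.base_alpha, max(len(networks), 1)),
            "univariate": significance_threshold(self.base_alpha, max(len(mets), 1)),
        }

        mv_rows = []
        uni_frames = []
        col_of = {m: j for j, m in enumerate(mets)}
        for j in range(geno.n_snps):
            g = geno.dosages[:, j]
            if self.missing == "mean":
                g = np.where(np.isnan(g), np.nanmean(g), g)
            if self.mode in ("univariate", "both"):
                uni_frames.append(self._univariate_one(g, Y, mets, order_cols, j))
            if self.mode in ("multivariate", "both"):
                for net in networks:
                    cols = [col_of[m] for m in net.members]
                    try:
                        res = multivariate_test(
                            g, Y[:, cols], net.members,
                            snp_id=str(snps["id"].iloc[j]), network_id=net.network_id,
                        )
                    except ValueError:
                        continue  # monomorphic / rank-deficient for this SNP
                    mv_rows.append(
                        {
                            "snp": res.snp_id,
                            "chrom": snps["chrom"].iloc[j],
                            "pos": int(snps["pos"].iloc[j]),
                            "network": net.network_id,
                            "n": res.n,
                            "rho2": res.rho2,
                            "wilks_lambda": res.wilks_lambda,
                            "F": res.F,
                            "df1": res.df1,
                            "df2": res.df2,
                            "p": res.p,
                            "loadings": res.loadings,
                            "flag": res.flag,
                        }
                    )

        mv = None
        if self.mode in ("multivariate", "both"):
            mv = pd.DataFrame(mv_rows)
            if len(mv):
                mv["significant"] = mv["p"] < thresholds["multivariate"]
                mv = mv.sort_values(["chrom", "pos", "network"], kind="stable").reset_index(drop=True)
        uni = None
        if self.mode in ("univariate", "both"):
            uni = pd.concat(uni_frames, ignore_index=True) if uni_frames else pd.DataFrame()
            if len(uni):
                uni["significant"] = uni["p"] < thresholds["univariate"]
                uni = uni.sort_values(["chrom", "pos", "metabolite"], kind="stable").reset_index(drop=True)

        self.multivariate_results_ = mv
        self.univariate_results_ = uni
        self.thresholds_ = thresholds
        self.networks_ = list(networks)
        return self

    @staticmethod
    def _univariate_one(g, Y, mets, order_cols, j):
        """Vectorized OLS of every metabolite on one SNP's dosage."""
        mask = ~np.isnan(g)
        gm = g[mask]
        Ym = Y[mask]
        n = gm.size
        sx = gm.std()
        if n < 3 or sx == 0:
            return pd.DataFrame(
                {
                    "snp": order_cols["snp"].iloc[j],
                    "chrom": order_cols["chrom"].iloc[j],
                    "pos": int(order_cols["pos"].iloc[j]),
                    "metabolite": mets,
                    "n": n,
                    "beta": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
                    "flag": "monomorphic",
                }
            )
        gc = gm - gm.mean()
        Yc = Ym - Ym.mean(axis=0)
        sy = Yc.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (gc @ Yc) / (n * sx * sy)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        beta = r * sy / sx
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.where(t != 0, beta / t, (sy / sx) / np.sqrt(n - 2))
        return pd.DataFrame(
            {
                "snp": order_cols["snp"].iloc[j],
                "chrom": order_cols["chrom"].iloc[j],
                "pos": int(order_cols["pos"].iloc[j]),
                "metabolite": mets,
                "n": n,
                "beta": beta, "se": se, "t": t, "p": p,
                "flag": None,
            }
        )

    def result(self) -> ScanResult:
        return ScanResult(
            multivariate=self.multivariate_results_,
            univariate=self.univariate_results_,
            thresholds=self.thresholds_,
            networks=self.networks_,
        )


def run_genome_scan(
    genotypes: GenotypeMatrix,
    pheno: PhenotypeTable,
    networks: list[MetaboliteNetwork],
    mode: str = "both",
    base_alpha: float = BASE_ALPHA,
    missing: str = "complete",
) -> ScanResult:
    """One row per SNP x network (multivariate) and per SNP x metabolite
    (univariate), ordered by chromosome, position, network/metabolite."""
    est = CanonicalCorrelationScan(
        networks=networks, mode=mode, base_alpha=base_alpha, missing=missing
    )
    est.fit(genotypes, pheno)
    return est.result()


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    top_snp: str
    top_p: float
    networks: list = field(default_factory=list)
    snps: list = field(default_factory=list)
    novel: bool | None = None


def define_loci(significant: pd.DataFrame, span: int = LOCUS_SPAN) -> list[Locus]:
    """Greedy clumping of significant SNPs into 200 kb loci.

    Repeatedly takes the most significant remaining SNP (ties broken toward
    the lower chromosome/position), opens a ``span``-wide window centered on
    it (clipped at the chromosome start), absorbs every significant SNP
    inside, and records the union of associated network ids. Loci are
    returned sorted by chromosome then position.
    """
    if significant is None or len(significant) == 0:
        return []
    df = significant.copy()
    half = span // 2
    group_col = "network" if "network" in df.columns else (
        "metabolite" if "metabolite" in df.columns else None
    )
    best = (
        df.sort_values(["p", "chrom", "pos"], kind="stable")
        .groupby("snp", sort=False)
        .first()
        .reset_index()
    )
    best = best.sort_values(["p", "chrom", "pos"], kind="stable").reset_index(drop=True)
    remaining = set(best["snp"])
    loci = []
    for _, row in best.iterrows():
        if row["snp"] not in remaining:
            continue
        start = max(1, int(row["pos"]) - half + 1)
        end = start + span - 1
        inside = best[
            (best["chrom"] == row["chrom"])
            & (best["pos"] >= start)
            & (best["pos"] <= end)
            & best["snp"].isin(remaining)
        ]
        members = list(inside["snp"])
        remaining -= set(members)
        nets = sorted(
            df[df["snp"].isin(members)][group_col].unique().tolist()
        ) if group_col else []
        loci.append(
            Locus(
                chrom=str(row["chrom"]),
                start=start,
                end=end,
                top_snp=str(row["snp"]),
                top_p=float(row["p"]),
                networks=nets,
                snps=members,
            )
        )
    loci.sort(key=lambda L: (L.chrom, L.start))
    return loci


@dataclass
class InflationReport:
    slope: float
    n_tests: int
    fraction_used: float = 0.90

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("inflation slope must be positive")


def genomic_inflation(pvalues: np.ndarray, fraction: float = 0.90) -> InflationReport:
    """Slope of observed vs expected -log10(p) over the least-significant tests.

    Observed order statistics of -log10(p) are regressed through the origin
    on the expected uniform quantiles -log10((i - 0.5)/m); only the
    ``fraction`` of points with smallest expected quantiles (the least
    significant tests) enter the fit, which excludes true-signal tails.
    A slope near 1 indicates calibrated statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    m = p.size
    if m < 100:
        raise ValueError("need at least 100 p-values for inflation estimation")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(-np.log10(p))  # ascending: least significant first
    exp = -np.log10((np.arange(m, 0, -1) - 0.5) / m)  # ascending, matched to obs
    k = int(math.floor(fraction * m))
    x, yv = exp[:k], obs[:k]
    slope = float((x @ yv) / (x @ x))
    return InflationReport(slope=slope, n_tests=m, fraction_used=fraction)


def multivariate_vs_univariate_summary(
    mv: pd.DataFrame,
    uni: pd.DataFrame,
    networks: list[MetaboliteNetwork],
    mv_threshold: float,
    uni_threshold: float,
    span: int = LOCUS_SPAN,
):
    """Locus x network detection comparison between the two scan modes.

    Loci are clumped from the union of SNPs significant in either mode. A
    locus-network pair counts as univariate-detected when any absorbed SNP's
    lowest single-metabolite P over the network's members clears the
    univariate threshold (the min-p rule). Returns ``(table, venn)`` where
    ``venn`` has keys ``both``, ``multivariate_only``, ``univariate_only``.
    """
    member_of = {net.network_id: set(net.members) for net in networks}
    empty = pd.DataFrame(columns=["chrom", "start", "end", "top_snp", "network",
                                  "multivariate", "univariate", "both"])
    mv_sig = mv[mv["p"] < mv_threshold] if mv is not None and len(mv) else None
    uni_sig = uni[uni["p"] < uni_threshold] if uni is not None and len(uni) else None
    frames = [x for x in (mv_sig, uni_sig) if x is not None and len(x)]
    if not frames:
        return empty, {"both": 0, "multivariate_only": 0, "univariate_only": 0}
    pooled = pd.concat(
        [f[["snp", "chrom", "pos", "p"]] for f in frames], ignore_index=True
    )
    loci = define_loci(pooled, span=span)

    rows = []
    for locus in loci:
        snps = set(locus.snps)
        for net in networks:
            mv_hit = bool(
                mv_sig is not None
                and len(mv_sig[(mv_sig["snp"].isin(snps)) & (mv_sig["network"] == net.network_id)])
            )
            uni_hit = False
            if uni_sig is not None:
                sub = uni_sig[
                    uni_sig["snp"].isin(snps) & uni_sig["metabolite"].isin(member_of[net.network_id])
                ]
                uni_hit = len(sub) > 0
            if mv_hit or uni_hit:
                rows.append(
                    {
                        "chrom": locus.chrom,
                        "start": locus.start,
                        "end": locus.end,
                        "top_snp": locus.top_snp,
                        "network": net.network_id,
                        "multivariate": mv_hit,
                        "univariate": uni_hit,
                        "both": mv_hit and uni_hit,
                    }
                )
    table = pd.DataFrame(rows) if rows else empty
    venn = {
        "both": int(table["both"].sum()) if len(table) else 0,
        "multivariate_only": int((table["multivariate"] & ~table["univariate"]).sum()) if len(table) else 0,
        "univariate_only": int((table["univariate"] & ~table["multivariate"]).sum()) if len(table) else 0,
    }
    return table, venn


def _em_haplotype_freqs(counts: np.ndarray, tol: float = 1e-12, max_iter: int = 2000):
    """EM haplotype frequencies from a 3x3 unphased two-locus genotype table."""
    n = counts.sum()
    # allele frequencies
    gA = counts.sum(axis=1)  # genotype counts at locus 1 (0,1,2 minor alleles)
    gB = counts.sum(axis=0)
    pA = (gA[1] + 2 * gA[2]) / (2 * n)
    pB = (gB[1] + 2 * gB[2]) / (2 * n)
    # start from linkage equilibrium
    f = np.array([(1 - pA) * (1 - pB), (1 - pA) * pB, pA * (1 - pB), pA * pB])  # ab,aB,Ab,AB
    n_dh = counts[1, 1]  # double heterozygotes: phase ambiguous
    # haplotype counts from the unambiguous cells; f index = 2*(minor at A) + (minor at B)
    base = np.zeros(4)
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            if i == 1:  # one het locus: (A, j/2) and (a, j/2)
                base[2 + j // 2] += c
                base[0 + j // 2] += c
            elif j == 1:
                base[2 * (i // 2) + 1] += c
                base[2 * (i // 2) + 0] += c
            else:  # both homozygous: two identical haplotypes
                base[2 * (i // 2) + (j // 2)] += 2 * c
    for _ in range(max_iter):
        # split double heterozygotes between (AB,ab) and (Ab,aB)
        num = f[3] * f[0]
        den = num + f[1] * f[2]
        frac = 0.5 if den == 0 else num / den
        hap = base.copy()
        hap[3] += n_dh * frac
        hap[0] += n_dh * frac
        hap[1] += n_dh * (1 - frac)
        hap[2] += n_dh * (1 - frac)
        f_new = hap / (2 * n)
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    return f, pA, pB


def ld_stats(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """r^2 and D' between two SNPs from unphased dosages.

    Dosages are rounded to hard calls, haplotype frequencies estimated by EM
    over the phase-ambiguous double heterozygotes, and r^2 / D' computed from
    the converged frequencies. Symmetric in its arguments.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    mask = ~np.isnan(a) & ~np.isnan(b)
    a = np.clip(np.rint(a[mask]), 0, 2).astype(int)
    b = np.clip(np.rint(b[mask]), 0, 2).astype(int)
    if a.size == 0:
        raise ValueError("no complete genotype pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic input")
    counts = np.zeros((3, 3))
    for i, j in zip(a, b):
        counts[i, j] += 1
    # canonical orientation so that swapping the arguments is a bitwise no-op
    if tuple(counts.T.ravel()) < tuple(counts.ravel()):
        counts = counts.T
    f, pA, pB = _em_haplotype_freqs(counts)
    D = f[3] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom == 0 else D * D / denom
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    return float(np.clip(r2, 0.0, 1.0)), float(np.clip(dprime, 0.0, 1.0))
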