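"""Synthetic two-cohort genotype + metabolite datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: ~130 quantitative metabolite measures organised in correlated blocks
("networks"), genotypes drawn in Hardy-Weinberg proportions at specified minor
allele frequencies with optional haplotype-copying LD, SNPs with pleiotropic
effects spread across a network's members, additive covariate effects (sex,
age, cohort, genetic PCs) and two-cohort structure. Every simulation returns
a :class:`GroundTruth` recording planted memberships, effects and the target
covariance so recovery can be tested.

Metabolite margins are Gaussian: the analysis operates on inverse-normal
transformed residuals, so unit-variance Gaussian phenotypes are the matching
scale for simulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeTable

#: 11 block sizes totalling 130 metabolites, mimicking a serum NMR panel
#: organised into lipoprotein-subclass / lipid / small-molecule groups.
DEFAULT_NETWORK_SIZES = (24, 18, 16, 14, 12, 10, 9, 8, 7, 6, 6)


@dataclass
class Effect:
    """A pleiotropic SNP effect planted on one network.

    ``var_frac`` is the variance fraction the SNP explains in a fully loaded
    member; ``pattern`` scales it per member (entries in [0, 1], default all
    ones). Member ``j`` of the target network receives variance fraction
    ``var_frac * pattern[j]``.
    """

    snp_index: int
    network_index: int
    var_frac: float
    pattern: list[float] | None = None


@dataclass
class SimulationConfig:
    n_samples_per_cohort: tuple[int, ...] = (3300, 3300)
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_spec: list[tuple[int, float]] | None = None
    network_spec: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(s, 0.7, 0.1) for s in DEFAULT_NETWORK_SIZES]
    )
    effect_spec: list[Effect] = field(default_factory=list)
    covariate_spec: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.2, "age": 0.2, "cohort": 0.5}
    )
    missing_rate_genotype: float = 0.01
    dosage_noise: float = 0.0
    snp_spacing: int = 5000
    n_pcs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_samples_per_cohort):
            raise ValueError("sample counts per cohort must be positive")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.missing_rate_genotype < 1.0):
            raise ValueError("missing_rate_genotype must be in [0, 1)")
        for size, rho in self.ld_block_spec or []:
            if size < 1 or not (0.0 <= rho <= 1.0):
                raise ValueError(f"bad LD block spec ({size}, {rho})")
        if not self.network_spec:
            raise ValueError("network_spec must be non-empty")
        for size, within, between in self.network_spec:
            if size < 1:
                raise ValueError("network size must be >= 1")
            if not (-1.0 <= within <= 1.0 and -1.0 <= between <= 1.0):
                raise ValueError("network correlations must lie in [-1, 1]")
        # per-metabolite variance budget: all planted fractions must sum < 1
        sizes = [s for s, _, _ in self.network_spec]
        budget = np.zeros(sum(sizes))
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        for eff in self.effect_spec:
            if not (0.0 <= eff.var_frac < 1.0):
                raise ValueError("variance-explained fraction must be in [0, 1)")
            if not (0 <= eff.network_index < len(sizes)):
                raise ValueError(f"effect targets unknown network {eff.network_index}")
            if not (0 <= eff.snp_index < self.n_snps):
                raise ValueError(f"effect targets unknown SNP index {eff.snp_index}")
            k = sizes[eff.network_index]
            pattern = np.ones(k) if eff.pattern is None else np.asarray(eff.pattern, float)
            if pattern.shape != (k,):
                raise ValueError("loading pattern length must equal network size")
            budget[offsets[eff.network_index] : offsets[eff.network_index] + k] += (
                eff.var_frac * pattern
            )
        if np.any(budget >= 1.0):
            raise ValueError("planted variance fractions sum to >= 1 for some metabolite")

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_samples_per_cohort))

    @property
    def n_metabolites(self) -> int:
        return int(sum(s for s, _, _ in self.network_spec))


@dataclass
class GroundTruth:
    """Planted structure of one simulation, for recovery tests."""

    network_of: dict[str, int]
    causal: list[dict]
    target_cov: np.ndarray
    cohorts: list[str]

    def __post_init__(self) -> None:
        for entry in self.causal:
            if "snp" not in entry or "betas" not in entry:
                raise ValueError("causal entries need 'snp' and 'betas'")

    def network_members(self, idx: int) -> list[str]:
        return [m for m, b in self.network_of.items() if b == idx]

    def to_json(self, path) -> None:
        obj = {
            "network_of": self.network_of,
            "causal": self.causal,
            "target_cov": np.asarray(self.target_cov).tolist(),
            "cohorts": self.cohorts,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            network_of=obj["network_of"],
            causal=obj["causal"],
            target_cov=np.asarray(obj["target_cov"]),
            cohorts=obj["cohorts"],
        )


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw dosages in Hardy-Weinberg proportions, with optional LD blocks.

    Each SNP's MAF is drawn uniformly from ``config.maf_range`` and two
    haplotypes per individual are sampled, so genotype counts follow HWE
    exactly. LD blocks are generated by haplotype copying: within a block all
    sites share the block MAF and each site copies the previous site's allele
    with probability equal to the block's haplotype correlation, otherwise
    redraws it. Correlation therefore decays geometrically with intra-block
    distance; copying probability 1 yields identical columns (r^2 = 1).

    Positions are evenly spaced (``snp_spacing``, default 5 kb) on a single
    synthetic chromosome so 200 kb locus logic is exercised.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_samples, config.n_snps
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)

    haplo = np.empty((2 * n, m), dtype=np.int8)
    blocks = list(config.ld_block_spec or [])
    j = 0
    for size, rho in blocks:
        size = min(size, m - j)
        if size <= 0:
            break
        p = mafs[j]
        mafs[j : j + size] = p
        haplo[:, j] = rng.random(2 * n) < p
        for col in range(j + 1, j + size):
            copy = rng.random(2 * n) < rho
            fresh = rng.random(2 * n) < p
            haplo[:, col] = np.where(copy, haplo[:, col - 1], fresh)
        j += size
    if j < m:
        haplo[:, j:] = rng.random((2 * n, m - j)) < mafs[j:]

    dosages = (haplo[0::2] + haplo[1::2]).astype(float)

    if config.dosage_noise > 0:
        w = config.dosage_noise
        dosages = np.clip(dosages + rng.uniform(-w, w, size=dosages.shape), 0.0, 2.0)
    if config.missing_rate_genotype > 0:
        mask = rng.random(dosages.shape) < config.missing_rate_genotype
        dosages[mask] = np.nan

    snps = pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": (np.arange(m) + 1) * config.snp_spacing,
            "ref": "A",
            "alt": "G",
            "maf_true": mafs,
        }
    )
    samples = [f"S{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, snps=snps, samples=samples)


def build_network_covariance(network_spec) -> np.ndarray:
    """Unit-variance block covariance with stated within/between correlations.

    The cross-block correlation between blocks *i* and *j* is the mean of
    their two ``between`` values. The result is validated positive
    semi-definite and rejected otherwise.
    """
    if not network_spec:
        raise ValueError("network_spec must be non-empty")
    sizes = [int(s) for s, _, _ in network_spec]
    withins = [w for _, w, _ in network_spec]
    betweens = [b for _, _, b in network_spec]
    p = sum(sizes)
    cov = np.zeros((p, p))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for i in range(len(sizes)):
        si = slice(offsets[i], offsets[i + 1])
        cov[si, si] = withins[i]
        for j in range(i + 1, len(sizes)):
            sj = slice(offsets[j], offsets[j + 1])
            cross = 0.5 * (betweens[i] + betweens[j])
            cov[si, sj] = cross
            cov[sj, si] = cross
    np.fill_diagonal(cov, 1.0)
    min_eig = float(np.linalg.eigvalsh(cov).min())
    if min_eig < -1e-8:
        raise ValueError(
            f"requested network covariance is not positive semi-definite "
            f"(smallest eigenvalue {min_eig:.3g}); reduce |between| or |within|"
        )
    return cov


def _metabolite_names(sizes) -> list[str]:
    names = []
    for b, size in enumerate(sizes):
        names.extend(f"met_b{b + 1:02d}_{k + 1:02d}" for k in range(size))
    return names


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, GroundTruth]:
    """Metabolites = genetic effects + covariate effects + correlated noise.

    Each planted effect contributes ``sqrt(f_m / var(g))`` per minor-allele
    count to member *m* (so the SNP explains variance fraction ``f_m`` of that
    metabolite); the Gaussian noise has the target block covariance, scaled so
    every metabolite's genetic-plus-noise variance is 1 before covariate
    effects are added. Covariates (sex, age, cohort, PCs) act additively with
    the effect sizes in ``covariate_spec`` and are nuisance terms the
    preprocessing step is expected to remove.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = genotypes.n_samples
    if n != config.n_samples:
        raise ValueError(
            f"genotype matrix has {n} samples but config specifies {config.n_samples}"
        )
    sizes = [s for s, _, _ in config.network_spec]
    p = sum(sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    names = _metabolite_names(sizes)
    cov = build_network_covariance(config.network_spec)

    # genetic part and per-metabolite variance budget
    genetic = np.zeros((n, p))
    frac = np.zeros(p)
    causal: list[dict] = []
    for eff in config.effect_spec:
        k = sizes[eff.network_index]
        pattern = np.ones(k) if eff.pattern is None else np.asarray(eff.pattern, float)
        g = genotypes.dosages[:, eff.snp_index]
        g = np.where(np.isnan(g), np.nanmean(g), g)
        var_g = g.var()
        if var_g <= 0:
            warnings.warn(f"monomorphic causal SNP index {eff.snp_index}; effect skipped")
            continue
        fm = eff.var_frac * pattern
        betas = np.sqrt(fm / var_g)
        cols = slice(offsets[eff.network_index], offsets[eff.network_index] + k)
        genetic[:, cols] += np.outer(g - g.mean(), betas)
        frac[cols] += fm
        causal.append(
            {
                "snp": str(genotypes.snps["id"].iloc[eff.snp_index]),
                "snp_index": int(eff.snp_index),
                "network_index": int(eff.network_index),
                "metabolites": names[offsets[eff.network_index] : offsets[eff.network_index] + k],
                "betas": betas.tolist(),
                "var_frac": (fm).tolist(),
            }
        )

    # correlated Gaussian noise, scaled to fill the remaining variance
    jitter = 1e-10 * np.eye(p)
    chol = np.linalg.cholesky(cov + jitter)
    noise = rng.standard_normal((n, p)) @ chol.T
    noise *= np.sqrt(np.clip(1.0 - frac, 0.0, None))

    values = genetic + noise

    # covariates
    cohorts = np.concatenate(
        [np.full(nc, f"cohort{i + 1}") for i, nc in enumerate(config.n_samples_per_cohort)]
    )
    covdata: dict[str, np.ndarray] = {}
    covdata["sex"] = rng.integers(0, 2, size=n).astype(float)
    covdata["age"] = rng.standard_normal(n)
    for k in range(config.n_pcs):
        covdata[f"pc{k + 1}"] = rng.standard_normal(n)
    spec = config.covariate_spec or {}
    for name, beta in spec.items():
        if name == "cohort":
            shift = (cohorts != cohorts[0]).astype(float)
            values += beta * shift[:, None]
        elif name in covdata:
            values += beta * covdata[name][:, None]
        elif name.startswith("pc") and name not in covdata:
            raise ValueError(f"covariate_spec names unknown PC column {name!r}")
        else:
            raise ValueError(f"covariate_spec names unknown covariate {name!r}")

    data = pd.DataFrame(values, columns=names, index=pd.Index(genotypes.samples, name="sample_id"))
    for cname, cvals in covdata.items():
        data[cname] = cvals
    data["cohort"] = cohorts
    pheno = PhenotypeTable(
        data=data,
        metabolites=names,
        covariates=list(covdata.keys()),
        cohort_col="cohort",
    )
    truth = GroundTruth(
        network_of={nm: b for b, size in enumerate(sizes) for nm in names[offsets[b] : offsets[b] + size]},
        causal=causal,
        target_cov=cov,
        cohorts=cohorts.tolist(),
    )
    return pheno, truth


def simulate_dataset(config: SimulationConfig):
    """Genotypes + phenotypes + ground truth from one config and seed."""
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config, rng)
    pheno, truth = simulate_phenotypes(geno, config, rng)
    return geno, pheno, truth
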