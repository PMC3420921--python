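"""In-memory containers shared across the pipeline.

Dosages live in a plain ``(n_samples, n_snps)`` float array with ``NaN`` for
missing calls; per-SNP metadata (id, chromosome, 1-based position, optional
imputation Rsq) travels alongside in a DataFrame. Phenotypes are a pandas
DataFrame indexed by sample id, with declared metabolite and covariate column
lists so downstream code never has to guess which columns are measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SNP_META_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    Attributes
    ----------
    dosages : ndarray, shape (n_samples, n_snps)
        Expected minor-allele counts in [0, 2]; ``NaN`` marks missing calls.
    snps : DataFrame
        One row per SNP with at least ``id``, ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``; may carry ``rsq`` (imputation quality).
    samples : list of str
        Sample identifiers, aligned with dosage rows.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNP records for {m} dosage columns")
        missing = [c for c in ("id", "chrom", "pos") if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps table lacks columns: {missing}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP from non-missing dosages, folded to <= 0.5."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missingness(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snps["id"].to_numpy() == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP id not found: {snp_id}")
        return int(hits[0])

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def take_snps(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, indices],
            snps=self.snps.iloc[indices].reset_index(drop=True),
            samples=list(self.samples),
        )

    def take_samples(self, row_mask: np.ndarray) -> "GenotypeMatrix":
        row_mask = np.asarray(row_mask)
        return GenotypeMatrix(
            dosages=self.dosages[row_mask],
            snps=self.snps.copy(),
            samples=[s for s, keep in zip(self.samples, row_mask) if keep],
        )


@dataclass
class PhenotypeTable:
    """Samples x metabolites table plus covariates and cohort labels.

    ``data`` is indexed by sample id and holds metabolite columns, covariate
    columns, an optional cohort column and optional boolean exclusion-flag
    columns (e.g. lipid-lowering therapy, pregnancy).
    """

    data: pd.DataFrame
    metabolites: list[str]
    covariates: list[str] = field(default_factory=list)
    cohort_col: str | None = None
    exclusion_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        declared = list(self.metabolites) + list(self.covariates) + list(self.exclusion_cols)
        if self.cohort_col is not None:
            declared.append(self.cohort_col)
        missing = [c for c in declared if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table lacks declared columns: {missing}")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def metabolite_matrix(self) -> np.ndarray:
        return self.data[self.metabolites].to_numpy(dtype=float)

    def covariate_matrix(self, include_cohort: bool = False) -> np.ndarray:
        """Covariates as a design matrix; cohort expanded to 0/1 indicators."""
        blocks = []
        if self.covariates:
            blocks.append(self.data[self.covariates].to_numpy(dtype=float))
        if include_cohort and self.cohort_col is not None:
            dummies = pd.get_dummies(self.data[self.cohort_col], drop_first=True)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy(dtype=float))
        if not blocks:
            return np.empty((self.n_samples, 0))
        return np.column_stack(blocks)

    def take_samples(self, row_mask: np.ndarray) -> "PhenotypeTable":
        return replace(self, data=self.data.loc[np.asarray(row_mask)])

    def with_metabolite_values(self, values: np.ndarray) -> "PhenotypeTable":
        data = self.data.copy()
        data[self.metabolites] = values
        return replace(self, data=data)


@dataclass
class MetaboliteNetwork:
    """One detected cluster of metabolites, treated as a joint phenotype set."""

    network_id: int
    members: list[str]
    mean_intra_r: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "network": self.network_id,
            "members": list(self.members),
            "mean_intra_r": self.mean_intra_r,
        }


def align_samples(geno: GenotypeMatrix, pheno: PhenotypeTable):
    """Restrict both tables to the shared samples, in the genotype order.

    Raises if the two tables share no samples.
    """
    shared = [s for s in geno.samples if s in set(pheno.samples)]
    if not shared:
        raise ValueError("genotype and phenotype tables share no sample ids")
    gmask = np.array([s in set(shared) for s in geno.samples])
    geno2 = geno.take_samples(gmask)
    pheno2 = replace(pheno, data=pheno.data.loc[shared])
    return geno2, pheno2
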