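"""File formats: VCF / dosage-TSV genotypes, phenotype TSV, result tables.

Coordinates are 1-based inclusive everywhere (VCF convention); the locus BED
export converts to 0-based half-open. Dosage values round-trip bitwise
through the dosage-TSV dialect and GT-coded VCF (integers; 17 significant
digits in text). DS-coded VCF round-trips at float32 precision because
htslib represents FORMAT floats as 32-bit.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MetaboliteNetwork, PhenotypeTable
from .scan import InflationReport, Locus, ScanResult

logger = logging.getLogger("ccagwas")

_VCF_HEADER = """##fileformat=VCFv4.2
##source=ccagwas
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage (expected minor allele count)">
"""


def write_vcf(geno: GenotypeMatrix, path, field: str = "DS") -> None:
    """Minimal biallelic VCF (CHROM, POS, ID, REF=A, ALT=G, GT or DS)."""
    if field not in ("GT", "DS"):
        raise ValueError("field must be GT or DS")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.samples) + "\n")
        for j in range(geno.n_snps):
            row = geno.snps.iloc[j]
            d = geno.dosages[:, j]
            if field == "DS":
                vals = [("." if np.isnan(x) else format(x, ".17g")) for x in d]
            else:
                gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
                vals = [
                    "./." if np.isnan(x) else gt_map[int(np.clip(round(x), 0, 2))]
                    for x in d
                ]
            ref = row.get("ref", "A") or "A"
            alt = row.get("alt", "G") or "G"
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{ref}\t{alt}\t.\tPASS\t.\t{field}\t"
                + "\t".join(vals)
                + "\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_cols, meta, seen = [], [], {}
    n_multiallelic = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multiallelic += 1
            continue
        ds = None
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where(col < -0.5, np.nan, col)  # cyvcf2 missing sentinel
        else:
            gt = variant.gt_types  # 0=hom-ref 1=het 2=unknown 3=hom-alt
            col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if snp_id in seen:
            seen[snp_id] += 1
            new_id = f"{snp_id}.{seen[snp_id]}"
            warnings.warn(f"duplicate SNP id {snp_id} renamed to {new_id}")
            snp_id = new_id
        else:
            seen[snp_id] = 0
        dosage_cols.append(col)
        meta.append(
            {
                "id": snp_id,
                "chrom": str(variant.CHROM),
                "pos": int(variant.POS),
                "ref": variant.REF,
                "alt": variant.ALT[0],
            }
        )
    if n_multiallelic:
        logger.info("skipped %d multiallelic records", n_multiallelic)
    if not meta:
        raise ValueError(f"no biallelic records in {path}")
    dosages = np.column_stack(dosage_cols)
    out = GenotypeMatrix(dosages=dosages, snps=pd.DataFrame(meta), samples=samples)
    out.n_multiallelic_skipped = n_multiallelic
    return out


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    """Dosage-matrix dialect: one row per SNP, metadata then sample columns."""
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    meta = geno.snps.reindex(columns=meta_cols, fill_value=".")
    mat = pd.DataFrame(geno.dosages.T, columns=geno.samples)
    pd.concat([meta.reset_index(drop=True), mat], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.17g"
    )


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA", "."], dtype={"chrom": str},
                     float_precision="round_trip")
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in ("id", "chrom", "pos") if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV lacks columns {missing}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if df["id"].duplicated().any():
        counts: dict[str, int] = {}
        ids = []
        for s in df["id"]:
            if s in counts:
                counts[s] += 1
                warnings.warn(f"duplicate SNP id {s} renamed to {s}.{counts[s]}")
                ids.append(f"{s}.{counts[s]}")
            else:
                counts[s] = 0
                ids.append(s)
        df["id"] = ids
    return GenotypeMatrix(
        dosages=df[sample_cols].to_numpy(dtype=float).T,
        snps=df[[c for c in meta_cols if c in df.columns]].copy(),
        samples=sample_cols,
    )


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the dosage-TSV dialect.

    ``fmt`` is inferred from the extension when omitted. In VCF the DS field
    is preferred when present, otherwise GT is converted to 0/1/2; missing
    entries become NaN; multiallelic records are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "dosage-tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt in ("dosage-tsv", "tsv"):
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA",
                      float_format="%.17g")


def read_phenotypes(
    path,
    covariates: list[str] | None = None,
    cohort_col: str | None = None,
    exclusion_cols: list[str] | None = None,
    na_values=("NA",),
) -> PhenotypeTable:
    """Phenotype TSV with a mandatory ``sample_id`` column.

    Columns not declared as covariates / cohort / exclusion flags are taken
    as metabolites and must be numeric.
    """
    df = pd.read_csv(path, sep="\t", na_values=list(na_values), keep_default_na=False,
                     float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table requires a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    covariates = list(covariates or [])
    exclusion_cols = list(exclusion_cols or [])
    special = set(covariates) | set(exclusion_cols) | ({cohort_col} if cohort_col else set())
    metabolites = [c for c in df.columns if c not in special]
    for c in metabolites:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric values in metabolite column {c!r}") from exc
    return PhenotypeTable(
        data=df,
        metabolites=metabolites,
        covariates=covariates,
        cohort_col=cohort_col,
        exclusion_cols=exclusion_cols,
    )


def write_networks(networks: list[MetaboliteNetwork], path) -> None:
    with open(path, "w") as fh:
        json.dump([net.to_dict() for net in networks], fh, indent=1)


def read_networks(path) -> list[MetaboliteNetwork]:
    with open(path) as fh:
        items = json.load(fh)
    return [
        MetaboliteNetwork(
            network_id=it["network"], members=list(it["members"]),
            mean_intra_r=it.get("mean_intra_r"),
        )
        for it in items
    ]


def _multivariate_frame(mv: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the in-memory multivariate table into stats + long loadings."""
    stats_df = mv.drop(columns=["loadings"], errors="ignore")
    rows = []
    if "loadings" in mv.columns:
        for _, r in mv.iterrows():
            for met, val in (r["loadings"] or {}).items():
                rows.append(
                    {"snp": r["snp"], "network": r["network"], "metabolite": met, "loading": val}
                )
    loadings = pd.DataFrame(rows, columns=["snp", "network", "metabolite", "loading"])
    return stats_df, loadings


def loci_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": L.chrom,
                "start": L.start,
                "end": L.end,
                "top_snp": L.top_snp,
                "top_p": L.top_p,
                "networks": ",".join(str(x) for x in L.networks),
                "n_snps": len(L.snps),
                "novel": L.novel,
            }
            for L in loci
        ],
        columns=["chrom", "start", "end", "top_snp", "top_p", "networks", "n_snps", "novel"],
    )


def write_loci_bed(loci: list[Locus], path) -> None:
    """Locus export as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for L in loci:
            fh.write(f"{L.chrom}\t{L.start - 1}\t{L.end}\t{L.top_snp}\n")


def write_results(
    result: ScanResult,
    outdir,
    loci: list[Locus] | None = None,
    qc_report: pd.DataFrame | None = None,
    inflation: InflationReport | None = None,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write scan outputs as TSV/JSON under ``outdir``; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _tsv(df: pd.DataFrame, name: str):
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, na_rep="NA", float_format="%.17g")
        written[name] = p

    if result.univariate is not None:
        _tsv(result.univariate, "univariate.tsv")
    if result.multivariate is not None:
        stats_df, loadings = _multivariate_frame(result.multivariate)
        _tsv(stats_df, "multivariate.tsv")
        _tsv(loadings, "loadings.tsv")
    if result.networks:
        write_networks(result.networks, outdir / "networks.json")
        written["networks.json"] = outdir / "networks.json"
    if loci is not None:
        _tsv(loci_frame(loci), "loci.tsv")
        write_loci_bed(loci, outdir / "loci.bed")
        written["loci.bed"] = outdir / "loci.bed"
    if qc_report is not None:
        _tsv(qc_report, "qc_report.tsv")
    if inflation is not None:
        pd.DataFrame(
            [{"slope": inflation.slope, "n_tests": inflation.n_tests,
              "fraction_used": inflation.fraction_used}]
        ).to_csv(outdir / "inflation.tsv", sep="\t", index=False)
        written["inflation.tsv"] = outdir / "inflation.tsv"

    import ccagwas

    info = {
        "package": "ccagwas",
        "version": getattr(ccagwas, "__version__", "unknown"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "thresholds": result.thresholds,
    }
    if manifest:
        info.update(manifest)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(info, fh, indent=1, default=str)
    written["manifest.json"] = outdir / "manifest.json"
    return written
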