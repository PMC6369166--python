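"""File input/output: genotypes (VCF, PLINK text, native TSV), phenotypes,
scan results and configuration.

Dosages loaded from VCF or PLINK are recoded to minor-allele counts (the
reference allele is taken to be the major allele at load time); the native
TSV dump stores dosages verbatim and round-trips exactly.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import GenotypeMatrix, PhenotypeTable, ScanConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_results",
    "read_results",
    "read_scan_config",
]

RESULT_COLUMNS = ["snp_id", "chrom", "pos", "test", "F", "df1", "df2", "p", "neg_log10_p"]


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Load a biallelic SNP dosage matrix.

    Parameters
    ----------
    path
        For ``vcf`` and ``native-tsv``, the file itself.  For ``plink``, the
        shared prefix of the ``.ped``/``.map`` pair (a path ending in either
        extension is also accepted).
    format
        One of ``vcf``, ``plink``, ``native-tsv`` or ``auto`` (by extension).
    """
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in (".vcf", ".gz", ".bcf"):
            format = "vcf"
        elif suffix in (".ped", ".map"):
            format = "plink"
        elif suffix in (".tsv", ".txt"):
            format = "native-tsv"
        else:
            raise ValueError(f"cannot infer genotype format from {path.name!r}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink":
        return _read_plink(path)
    if format == "native-tsv":
        return _read_native_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _flip_to_minor(dosages: np.ndarray) -> np.ndarray:
    """Recode columns so the counted allele is the minor one (freq <= 0.5)."""
    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    return dosages


def _impute_column(col: np.ndarray, snp_id: str) -> np.ndarray:
    """Round-to-integer mean imputation of missing calls in one SNP column."""
    miss = np.isnan(col)
    if miss.any():
        if miss.all():
            raise ValueError(f"SNP {snp_id} has no called genotypes")
        fill = float(np.clip(round(col[~miss].mean()), 0, 2))
        logger.warning(
            "SNP %s: imputed %d missing genotypes with rounded mean %g",
            snp_id, int(miss.sum()), fill,
        )
        col[miss] = fill
    return col


def _read_vcf(path: Path):
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise IOError(f"cannot open VCF {path}: {exc}") from exc
    samples = np.asarray(vcf.samples, dtype=object)
    rows, snp_ids, chroms, poss = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(np.float64)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append(_impute_column(dos, snp_id))
        snp_ids.append(snp_id)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"no biallelic sites found in {path}")
    dosages = _flip_to_minor(np.column_stack(rows))
    return GenotypeMatrix(dosages, snp_ids, chroms, poss, samples)


def _read_plink(path: Path):
    if path.suffix in (".ped", ".map"):
        prefix = path.with_suffix("")
    else:
        prefix = path
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    for f in (ped_path, map_path):
        if not f.exists():
            raise IOError(f"PLINK file {f} not found")
    snp_map = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str, "snp_id": str},
    )
    m = len(snp_map)
    sample_ids, allele_rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])
    if not sample_ids:
        raise ValueError(f"{ped_path} contains no samples")
    alleles = np.asarray(allele_rows, dtype=object).reshape(len(sample_ids), m, 2)
    dosages = np.empty((len(sample_ids), m))
    for k in range(m):
        a = alleles[:, k, :]
        called = a[a != "0"]
        uniq = sorted(set(called.tolist()))
        if len(uniq) > 2:
            raise ValueError(f"SNP {snp_map.snp_id[k]} has >2 alleles: {uniq}")
        if len(uniq) == 0:
            raise ValueError(f"SNP {snp_map.snp_id[k]} has no called genotypes")
        counted = uniq[-1]  # recoded to minor allele below; any consistent pick works
        col = (a == counted).sum(axis=1).astype(np.float64)
        col[(a == "0").any(axis=1)] = np.nan
        dosages[:, k] = _impute_column(col, snp_map.snp_id[k])
    dosages = _flip_to_minor(dosages)
    return GenotypeMatrix(dosages, snp_map.snp_id, snp_map.chrom, snp_map.pos, sample_ids)


def _read_native_tsv(path: Path):
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read genotype TSV {path}: {exc}") from exc
    required = ["snp_id", "chrom", "pos"]
    if df.columns[:3].tolist() != required:
        raise ValueError(f"{path} is not a native genotype TSV (expected columns {required})")
    sample_ids = df.columns[3:].tolist()
    if not sample_ids:
        raise ValueError(f"{path} contains no sample columns")
    return GenotypeMatrix(
        dosages=df[sample_ids].to_numpy(dtype=np.float64).T,
        snp_ids=df["snp_id"],
        chrom=df["chrom"],
        pos=df["pos"],
        sample_ids=sample_ids,
    )


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Dump a GenotypeMatrix as the native TSV (SNPs as rows, samples as columns)."""
    df = pd.DataFrame({"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos})
    dos = pd.DataFrame(
        g.dosages.T.astype(np.int64), columns=g.sample_ids.tolist(), index=df.index
    )
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    """Phenotype CSV: first column sample_id, remaining columns variates, NA = missing."""
    try:
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read phenotype CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a sample_id column plus at least one variate")
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return PhenotypeTable(
        values=np.where(np.isnan(values), 0.0, values),
        mask=~np.isnan(values),
        variate_names=df.columns[1:].tolist(),
        sample_ids=df.iloc[:, 0].astype(str).tolist(),
    )


def write_phenotypes(ph: PhenotypeTable, path) -> None:
    values = np.where(ph.mask, ph.values, np.nan)
    df = pd.DataFrame(values, columns=ph.variate_names.tolist())
    df.insert(0, "sample_id", ph.sample_ids)
    df.to_csv(path, index=False, na_rep="NA")


def write_results(results, path) -> None:
    """Write per-SNP test results as a TSV, numbers to 6 significant digits."""
    if not results:
        raise ValueError("no results to write")
    rows = [
        {
            "snp_id": t.snp_id, "chrom": t.chrom, "pos": t.pos, "test": t.test,
            "F": t.F, "df1": t.df1, "df2": t.df2, "p": t.p_value,
            "neg_log10_p": t.neg_log10_p,
        }
        for t in results
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    except OSError as exc:
        raise IOError(f"cannot write results to {path}: {exc}") from exc


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is not a results TSV; missing columns {missing}")
    return df


def read_scan_config(path) -> ScanConfig:
    """Load scan settings from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    reml = raw.pop("reml", {})
    cfg = ScanConfig(
        variates=list(raw.get("variates", [])),
        test=raw.get("test", "both"),
        exact_reml=bool(raw.get("exact_reml", False)),
        reml_tol=float(reml.get("tolerance", 1e-6)),
        reml_max_iter=int(reml.get("max_iter", 5000)),
        seed=raw.get("seed"),
    )
    if cfg.reml_tol <= 0 or not math.isfinite(cfg.reml_tol):
        raise ValueError("REML tolerance must be positive and finite")
    return cfg
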