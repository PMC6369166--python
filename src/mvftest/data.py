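"""Core data containers for genotypes, relationship matrices and phenotypes.

The containers are deliberately thin: plain numpy arrays plus identifier
metadata, validated on construction.  Dosages are minor-allele counts in
{0, 1, 2}; a fully inbred panel only ever carries {0, 2}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "PhenotypeTable",
    "ScanConfig",
    "prune_maf",
    "compute_grm",
]


@dataclass
class GenotypeMatrix:
    """n x M biallelic dosage matrix with per-SNP map metadata.

    Parameters
    ----------
    dosages
        Integer allele counts, shape ``(n, M)``, values in {0, 1, 2}.
    snp_ids, chrom, pos
        Per-SNP identifier, chromosome label and 1-based physical position.
        Positions must be strictly increasing within a chromosome.
    sample_ids
        Length-n sample identifiers.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n, m = self.dosages.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 samples and M >= 1 SNPs, got {n} x {m}")
        for name, arr, expect in (
            ("snp_ids", self.snp_ids, m),
            ("chrom", self.chrom, m),
            ("pos", self.pos, m),
            ("sample_ids", self.sample_ids, n),
        ):
            if arr.shape != (expect,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({expect},)")
        if np.isnan(self.dosages).any():
            raise ValueError("missing dosages are not allowed after load")
        if not np.isin(self.dosages, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be allele counts in {0, 1, 2}")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the SNP columns in ``index`` (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            sample_ids=self.sample_ids[index],
        )


@dataclass
class GRM:
    """Genomic relationship matrix ``A`` with its sample identifiers."""

    A: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = len(self.sample_ids)
        if self.A.shape != (n, n):
            raise ValueError(f"A has shape {self.A.shape}, expected ({n}, {n})")
        if not np.allclose(self.A, self.A.T, atol=1e-8):
            raise ValueError("A is not symmetric")
        if np.trace(self.A) <= 0:
            raise ValueError("A has non-positive trace")

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]

    def subset_samples(self, index: np.ndarray) -> "GRM":
        index = np.asarray(index)
        return GRM(A=self.A[np.ix_(index, index)], sample_ids=self.sample_ids[index])


@dataclass
class PhenotypeTable:
    """n x d phenotype matrix with an explicit observation mask.

    ``values[i, j]`` is meaningful only where ``mask[i, j]`` is True.  Every
    individual must be observed for at least one variate; vectorising the
    observed cells (variate-major) yields the stacked response of the mixed
    model.
    """

    values: np.ndarray
    mask: np.ndarray
    variate_names: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.variate_names = np.asarray(self.variate_names, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n, d = self.values.shape
        if self.mask.shape != (n, d):
            raise ValueError("mask shape does not match values")
        if len(self.variate_names) != d or len(self.sample_ids) != n:
            raise ValueError("metadata lengths inconsistent with values")
        if not self.mask.any(axis=1).all():
            raise ValueError("every individual must be observed for at least one variate")
        if np.isnan(self.values[self.mask]).any():
            raise ValueError("observed cells contain NaN")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variates(self) -> int:
        return self.values.shape[1]

    def select_variates(self, names) -> "PhenotypeTable":
        idx = []
        for name in names:
            where = np.nonzero(self.variate_names == name)[0]
            if len(where) == 0:
                raise KeyError(f"variate {name!r} not in table")
            idx.append(where[0])
        idx = np.asarray(idx)
        sub_mask = self.mask[:, idx]
        keep = sub_mask.any(axis=1)
        return PhenotypeTable(
            values=self.values[np.ix_(keep, idx)],
            mask=sub_mask[keep],
            variate_names=self.variate_names[idx],
            sample_ids=self.sample_ids[keep],
        )

    def subset_samples(self, index: np.ndarray) -> "PhenotypeTable":
        index = np.asarray(index)
        return PhenotypeTable(
            values=self.values[index],
            mask=self.mask[index],
            variate_names=self.variate_names,
            sample_ids=self.sample_ids[index],
        )


@dataclass
class ScanConfig:
    """Settings for a genome-wide scan.

    ``test`` selects which statistics are produced; ``exact_reml`` refits the
    variance components for every SNP instead of reusing the null-model fit
    (the P3D shortcut), which is only sensible for small marker panels.
    """

    variates: list = field(default_factory=list)
    test: str = "both"  # "univariate" | "multivariate" | "both"
    exact_reml: bool = False
    reml_tol: float = 1e-6
    reml_max_iter: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.test not in ("univariate", "multivariate", "both"):
            raise ValueError(f"unknown test type {self.test!r}")

    def validate_against(self, ph: PhenotypeTable) -> None:
        missing = [v for v in self.variates if v not in set(ph.variate_names)]
        if missing:
            raise KeyError(f"variates not in phenotype table: {missing}")


def prune_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop SNPs with minor allele frequency below ``threshold``.

    Retains exactly the SNPs with MAF >= threshold.  Pruning is idempotent.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    keep = np.nonzero(g.maf() >= threshold)[0]
    if len(keep) == 0:
        raise ValueError(f"all SNPs have MAF < {threshold}; nothing left to analyse")
    if len(keep) < g.n_snps:
        logger.info("MAF pruning removed %d of %d SNPs", g.n_snps - len(keep), g.n_snps)
    if len(keep) == g.n_snps:
        return g
    return g.subset_snps(keep)


def compute_grm(g: GenotypeMatrix, psd_tol: float = 1e-8) -> GRM:
    """VanRaden method-1 genomic relationship matrix.

    A = W W' / (2 * sum_k p_k (1 - p_k)) where column k of W is the dosage
    centred by twice the observed allele frequency p_k.  Monomorphic SNPs
    contribute a zero column and are excluded from the denominator.  Negative
    eigenvalues (numerical) are clipped at ``psd_tol`` and A reconstructed.
    """
    p = g.allele_freq()
    poly = (p > 0.0) & (p < 1.0)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs to build a GRM")
    pk = p[poly]
    W = g.dosages[:, poly] - 2.0 * pk
    denom = 2.0 * np.sum(pk * (1.0 - pk))
    A = (W @ W.T) / denom
    A = 0.5 * (A + A.T)
    evals = np.linalg.eigvalsh(A)
    if evals[0] < -psd_tol:
        logger.info(
            "GRM has negative eigenvalues (min %.3e); clipping at %.1e and reconstructing",
            evals[0], psd_tol,
        )
        w, U = np.linalg.eigh(A)
        w = np.clip(w, psd_tol, None)
        A = (U * w) @ U.T
        A = 0.5 * (A + A.T)
    return GRM(A=A, sample_ids=g.sample_ids)
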