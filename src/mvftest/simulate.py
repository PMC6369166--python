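"""Synthetic data engine: inbred genotypes with LD, a 20-QTL architecture on
correlated variates at heritability 0.5, and structured phenotype missingness.

The genotype generator is a self-contained mosaic-haplotype scheme: a small
pool of founder haplotypes related by sequential mutation is built per
chromosome, and each fully inbred (selfed-to-homozygosity) individual is a
recombinant mosaic of founders, so linkage disequilibrium decays with marker
distance within a chromosome and is absent across chromosomes.  It aims at a
realistic LD shape for a small selfing panel, not at matching any particular
coalescent history, so quantities tied to the coalescent site-frequency
spectrum (e.g. the exact number of markers surviving MAF pruning) are not
reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimScenario",
    "QTLArchitecture",
    "SimTruth",
    "simulate_genotypes",
    "sample_qtls",
    "draw_effects",
    "simulate_phenotypes",
    "apply_missingness",
]

# Mosaic generator knobs: founder-pool size, per-site mutation probability of
# the sequential founder chain, and the per-interval founder-switch
# probability of each individual's mosaic (mean segment ~50 SNPs).
_N_FOUNDERS = 24
_MUTATION_P = 0.10
_SWITCH_P = 0.02


@dataclass
class SimScenario:
    """One simulation condition of the power study.

    ``a_d`` is the relative target-QTL effect on the last variate; the
    effects on intermediate variates are evenly spaced between 1 and ``a_d``.
    ``m_prop`` is the fraction of phenotype cells masked, at most (d-1)/d so
    that each individual keeps at least one observed variate.
    """

    d: int = 2
    r: float = 0.0
    a_d: float = 1.0
    m_prop: float = 0.0
    n: int = 200
    n_chr: int = 5
    snps_per_chr: int = 2000
    maf_threshold: float = 0.02
    qtl_per_chr: int = 4
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValueError("|r| must be < 1")
        if not abs(self.a_d) <= 1:
            raise ValueError("|a_d| must be <= 1")
        max_m = (self.d - 1) / self.d
        if not 0 <= self.m_prop <= max_m + 1e-12:
            raise ValueError(
                f"m_prop must lie in [0, (d-1)/d] = [0, {max_m:.4g}] so every individual "
                "keeps at least one observed variate"
            )

    def a_schedule(self) -> np.ndarray:
        """Per-variate relative effects: evenly spaced from 1 down to a_d."""
        return np.linspace(1.0, self.a_d, self.d)


@dataclass
class QTLArchitecture:
    """Sampled QTL positions and (once drawn) their per-variate effects."""

    qtl_indices: np.ndarray            # SNP column indices, all QTLs
    target_index: int                  # one of qtl_indices
    d: int | None = None
    target_effects: np.ndarray | None = None      # length d
    background_effects: np.ndarray | None = None  # (n_qtl - 1) x d
    Sigma: np.ndarray | None = None               # d x d compound symmetry
    S: np.ndarray | None = None                   # d x d diag of realised genetic SDs

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_indices)

    @property
    def background_indices(self) -> np.ndarray:
        return self.qtl_indices[self.qtl_indices != self.target_index]

    def effect_matrix(self) -> np.ndarray:
        """n_qtl x d matrix of effects aligned with ``qtl_indices``."""
        if self.target_effects is None:
            raise ValueError("effects have not been drawn yet")
        out = np.zeros((self.n_qtl, self.d))
        bg = 0
        for row, snp in enumerate(self.qtl_indices):
            if snp == self.target_index:
                out[row] = self.target_effects
            else:
                out[row] = self.background_effects[bg]
                bg += 1
        return out


@dataclass
class SimTruth:
    """Realised genetic values and residuals of one simulated replicate."""

    u: np.ndarray          # n x d total genetic effects
    e: np.ndarray          # n x d residuals
    S: np.ndarray          # d x d diag of genetic SDs used for the residuals
    architecture: QTLArchitecture = field(repr=False, default=None)

    def realized_heritability(self) -> np.ndarray:
        """Per-variate var(u) / var(u + e)."""
        return self.u.var(axis=0, ddof=1) / (self.u + self.e).var(axis=0, ddof=1)


def _compound_symmetry(d: int, r: float) -> np.ndarray:
    return np.full((d, d), r) + (1.0 - r) * np.eye(d)


def simulate_genotypes(
    n: int = 200,
    n_chr: int = 5,
    snps_per_chr: int = 2000,
    seed: int = 0,
) -> GenotypeMatrix:
    """Fully inbred mosaic genotypes: dosages in {0, 2}, LD within chromosomes."""
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    blocks, snp_ids, chroms, poss = [], [], [], []
    for c in range(1, n_chr + 1):
        m = snps_per_chr
        founders = np.empty((_N_FOUNDERS, m), dtype=bool)
        founders[0] = rng.random(m) < 0.5
        for j in range(1, _N_FOUNDERS):
            parent = int(rng.integers(0, j))
            founders[j] = founders[parent] ^ (rng.random(m) < _MUTATION_P)
        # recombinant mosaic: founder choice persists until a switch fires
        choices = rng.integers(0, _N_FOUNDERS, size=(n, m))
        switch = rng.random((n, m)) < _SWITCH_P
        switch[:, 0] = True
        last = np.maximum.accumulate(np.where(switch, np.arange(m), -1), axis=1)
        founder_idx = choices[np.arange(n)[:, None], last]
        hap = founders[founder_idx, np.arange(m)]
        blocks.append(2.0 * hap)
        snp_ids.extend(f"chr{c}_snp{k + 1}" for k in range(m))
        chroms.extend([str(c)] * m)
        poss.extend(((np.arange(m) + 1) * 1000).tolist())
    return GenotypeMatrix(
        dosages=np.concatenate(blocks, axis=1),
        snp_ids=snp_ids, chrom=chroms, pos=poss,
        sample_ids=[f"ind{i + 1}" for i in range(n)],
    )


def sample_qtls(g: GenotypeMatrix, qtl_per_chr: int = 4, seed: int = 0) -> QTLArchitecture:
    """Pick ``qtl_per_chr`` random polymorphic SNPs per chromosome plus a target.

    Returns an architecture skeleton (no effects yet); ``qtl_per_chr = 0``
    gives an empty architecture for null simulations.  The chosen indices are
    recorded so that downstream relationship matrices can exclude them.
    """
    rng = np.random.default_rng(seed)
    if qtl_per_chr == 0:
        return QTLArchitecture(qtl_indices=np.empty(0, dtype=int), target_index=-1)
    maf = g.maf()
    qtls = []
    for c in dict.fromkeys(g.chrom):
        on_chr = np.nonzero((g.chrom == c) & (maf > 0))[0]
        if len(on_chr) < qtl_per_chr:
            raise ValueError(
                f"chromosome {c} has only {len(on_chr)} polymorphic SNPs, "
                f"cannot sample {qtl_per_chr} QTLs"
            )
        qtls.extend(rng.choice(on_chr, size=qtl_per_chr, replace=False).tolist())
    qtls = np.asarray(sorted(qtls))
    target = int(rng.choice(qtls))
    return QTLArchitecture(qtl_indices=qtls, target_index=target)


def draw_effects(
    skeleton: QTLArchitecture,
    d: int,
    r: float,
    a_d: float,
    seed: int = 0,
) -> QTLArchitecture:
    """Draw target and background QTL effects for ``d`` correlated variates.

    The target effect on variate 1 is standard normal and scaled by the
    evenly spaced schedule a_1 = 1 ... a_d on the remaining variates;
    background effects are i.i.d. MVN(0, Sigma) rows, Sigma the
    compound-symmetry correlation matrix with off-diagonal r.
    """
    if not abs(a_d) <= 1:
        raise ValueError("|a_d| must be <= 1")
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    rng = np.random.default_rng(seed)
    Sigma = _compound_symmetry(d, r)
    if skeleton.n_qtl == 0:
        return QTLArchitecture(
            qtl_indices=skeleton.qtl_indices, target_index=skeleton.target_index,
            d=d, target_effects=np.zeros(d), background_effects=np.zeros((0, d)),
            Sigma=Sigma,
        )
    a = np.linspace(1.0, a_d, d)
    b1 = rng.standard_normal()
    L = np.linalg.cholesky(Sigma)
    background = rng.standard_normal((skeleton.n_qtl - 1, d)) @ L.T
    return QTLArchitecture(
        qtl_indices=skeleton.qtl_indices, target_index=skeleton.target_index,
        d=d, target_effects=a * b1, background_effects=background, Sigma=Sigma,
    )


def simulate_phenotypes(
    g: GenotypeMatrix,
    arch: QTLArchitecture,
    seed: int = 0,
) -> tuple[PhenotypeTable, SimTruth]:
    """Phenotypes = genetic values + residuals at heritability 0.5.

    Genetic values sum dosage x effect over all QTLs; residuals are drawn
    MVN(0, S Sigma S) per individual, with S the diagonal of the realised
    genetic standard deviations, so each variate has heritability ~0.5.  With
    no QTLs, S falls back to the identity and phenotypes are pure correlated
    noise.
    """
    if arch.Sigma is None:
        raise ValueError("draw_effects must be called before simulating phenotypes")
    rng = np.random.default_rng(seed)
    n, d = g.n_samples, len(arch.Sigma)
    if arch.n_qtl > 0:
        if (arch.qtl_indices >= g.n_snps).any():
            raise ValueError("QTL indices out of range for this genotype matrix")
        u = g.dosages[:, arch.qtl_indices] @ arch.effect_matrix()
        sd = u.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero genetic variance in a variate; S is undefined")
        S = np.diag(sd)
    else:
        u = np.zeros((n, d))
        S = np.eye(d)
    arch.S = S
    L = S @ np.linalg.cholesky(arch.Sigma)
    e = rng.standard_normal((n, d)) @ L.T
    table = PhenotypeTable(
        values=u + e,
        mask=np.ones((n, d), dtype=bool),
        variate_names=[f"variate{j + 1}" for j in range(d)],
        sample_ids=g.sample_ids,
    )
    return table, SimTruth(u=u, e=e, S=S, architecture=arch)


def apply_missingness(ph: PhenotypeTable, m_prop: float, seed: int = 0) -> PhenotypeTable:
    """Mask exactly round(m_prop * n * d) cells, keeping one observed per row.

    One randomly chosen cell per individual is reserved as always observed,
    and the masked cells are drawn uniformly from the remainder; at the
    maximal proportion (d-1)/d every individual retains exactly its reserved
    variate.
    """
    n, d = ph.values.shape
    max_m = (d - 1) / d
    if not 0 <= m_prop <= max_m + 1e-12:
        raise ValueError(
            f"m_prop must be <= (d-1)/d = {max_m:.4g}: every individual needs at least "
            "one observed variate"
        )
    n_mask = int(round(m_prop * n * d))
    if n_mask == 0:
        return ph
    rng = np.random.default_rng(seed)
    reserved = rng.integers(0, d, size=n)
    candidates = np.array(
        [(i, j) for i in range(n) for j in range(d) if j != reserved[i]]
    )
    pick = rng.choice(len(candidates), size=n_mask, replace=False)
    mask = ph.mask.copy()
    mask[candidates[pick, 0], candidates[pick, 1]] = False
    return PhenotypeTable(
        values=ph.values, mask=mask,
        variate_names=ph.variate_names, sample_ids=ph.sample_ids,
    )
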