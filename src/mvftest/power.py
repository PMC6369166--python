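"""Replicate grids comparing multivariate and univariate F-tests.

For each scenario the pipeline is: simulate genotypes and phenotypes, build
the relationship matrix from the non-QTL SNPs, fit the null variance
components, F-test the target QTL with both tests, and average the
difference of -log10 p (multivariate minus univariate-on-variate-1) over the
replicates whose REML fits converged.  Replicates with a failed fit are
dropped from both sides and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GRM, GenotypeMatrix, PhenotypeTable, ScanConfig, compute_grm, prune_maf
from .ftest import TestResult, gwa_scan
from .simulate import (
    QTLArchitecture,
    SimScenario,
    SimTruth,
    apply_missingness,
    draw_effects,
    sample_qtls,
    simulate_genotypes,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioResult",
    "QQData",
    "derive_seed",
    "simulate_replicate",
    "run_grid",
    "delta_heatmap",
    "negative_snp_qq",
    "qq_slope",
]


@dataclass
class ScenarioResult:
    """Mean target-QTL power gain of one scenario over its replicates."""

    scenario: SimScenario
    mean_delta: float
    n_success: int
    n_fail: int
    deltas: np.ndarray

    def __post_init__(self) -> None:
        if self.n_success + self.n_fail != self.scenario.replicates:
            raise ValueError("success/failure counts do not sum to the replicate count")


@dataclass
class QQData:
    """Sorted observed -log10 p of negative SNPs against uniform quantiles."""

    observed: np.ndarray
    expected: np.ndarray
    r2_threshold: float

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.expected):
            raise ValueError("observed and expected quantiles differ in length")
        if np.any(np.diff(self.observed) < 0):
            raise ValueError("observed quantiles must be sorted ascending")


def derive_seed(master: int, *indices: int) -> int:
    """Deterministic splitmix64-style seed stream, folded below 2**31."""
    z = (int(master) + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    for ix in indices:
        z = (z + (int(ix) + 1) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        z ^= z >> 30
        z = (z * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        z ^= z >> 31
    return int(z % (2**31 - 1))


@dataclass
class SimReplicate:
    """One fully simulated dataset ready for analysis."""

    genotypes: GenotypeMatrix     # post-pruning
    grm: GRM                      # built from non-QTL SNPs
    phenotypes: PhenotypeTable    # missingness applied
    architecture: QTLArchitecture
    truth: SimTruth

    @property
    def target_snp_index(self) -> int:
        return int(self.architecture.target_index)


def simulate_replicate(
    scenario: SimScenario,
    rep: int,
    genotype_cache: dict | None = None,
) -> SimReplicate:
    """Simulate one replicate of a scenario.

    Genotype sets depend only on the replicate index (not on the scenario's
    d, r, a_d or m_prop), so the same marker data underlies every scenario of
    a grid, and ``genotype_cache`` can share them across scenarios.
    """
    geno_key = (scenario.n, scenario.n_chr, scenario.snps_per_chr,
                scenario.maf_threshold, derive_seed(scenario.seed, 0, rep))
    cached = genotype_cache.get(geno_key) if genotype_cache is not None else None
    if cached is None:
        raw = simulate_genotypes(
            n=scenario.n, n_chr=scenario.n_chr, snps_per_chr=scenario.snps_per_chr,
            seed=geno_key[-1],
        )
        cached = prune_maf(raw, scenario.maf_threshold)
        if genotype_cache is not None:
            genotype_cache[geno_key] = cached
    g = cached
    skeleton = sample_qtls(g, scenario.qtl_per_chr, seed=derive_seed(scenario.seed, 1, rep))
    arch = draw_effects(
        skeleton, scenario.d, scenario.r, scenario.a_d,
        seed=derive_seed(scenario.seed, 2, rep, int(1e6 * scenario.r), int(1e6 * scenario.a_d)),
    )
    ph, truth = simulate_phenotypes(
        g, arch, seed=derive_seed(scenario.seed, 3, rep, int(1e6 * scenario.r),
                                  int(1e6 * scenario.a_d)),
    )
    if scenario.m_prop > 0:
        ph = apply_missingness(ph, scenario.m_prop, seed=derive_seed(scenario.seed, 4, rep))
    if arch.n_qtl > 0:
        non_qtl = np.setdiff1d(np.arange(g.n_snps), arch.qtl_indices)
        grm = compute_grm(g.subset_snps(non_qtl))
    else:
        grm = compute_grm(g)
    return SimReplicate(genotypes=g, grm=grm, phenotypes=ph, architecture=arch, truth=truth)


def _target_delta(rep_data: SimReplicate, cfg: ScanConfig) -> float:
    """-log10 p difference (multivariate - univariate on variate 1) at the target QTL."""
    results = gwa_scan(
        rep_data.genotypes, rep_data.phenotypes, rep_data.grm, cfg,
        snp_indices=[rep_data.target_snp_index],
    )
    by_test = {t.test: t for t in results}
    mv = by_test["multivariate"]
    uv = by_test["univariate:variate1"]
    if np.isnan(mv.F) or np.isnan(uv.F):
        raise RuntimeError("target QTL degenerate on analysed samples")
    return mv.neg_log10_p - uv.neg_log10_p


def run_grid(
    grid: list[SimScenario],
    reml_tol: float = 1e-6,
    reml_max_iter: int = 5000,
) -> list[ScenarioResult]:
    """Run every scenario of a grid; deterministic given the scenarios' seeds.

    ``reml_tol``/``reml_max_iter`` are forwarded to the per-replicate null
    REML fits; heavily missing designs converge slowly and may need a cap
    above the default to yield usable success counts.
    """
    if not grid:
        raise ValueError("empty scenario grid")
    cache: dict = {}
    out = []
    for scenario in grid:
        if scenario.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        cfg = ScanConfig(
            variates=["variate1"] if scenario.d == 1 else [], test="both",
            reml_tol=reml_tol, reml_max_iter=reml_max_iter,
        )
        deltas = []
        n_fail = 0
        for rep in range(scenario.replicates):
            rep_data = simulate_replicate(scenario, rep, genotype_cache=cache)
            try:
                deltas.append(_target_delta(rep_data, cfg))
            except RuntimeError as exc:
                n_fail += 1
                logger.warning(
                    "scenario (d=%d, r=%.2f, a_d=%.2f, m=%.3f) replicate %d dropped: %s",
                    scenario.d, scenario.r, scenario.a_d, scenario.m_prop, rep, exc,
                )
        if not deltas:
            logger.warning(
                "scenario (d=%d, r=%.2f, a_d=%.2f, m=%.3f): all %d replicates failed",
                scenario.d, scenario.r, scenario.a_d, scenario.m_prop, scenario.replicates,
            )
        deltas = np.asarray(deltas)
        out.append(ScenarioResult(
            scenario=scenario,
            mean_delta=float(deltas.mean()) if len(deltas) else float("nan"),
            n_success=len(deltas), n_fail=n_fail, deltas=deltas,
        ))
    return out


def delta_heatmap(results: list[ScenarioResult], plot_path=None) -> pd.DataFrame:
    """Long-format (r, a_d) table of mean power gains for one (d, m_prop) grid.

    The scenarios must cover a full rectangular r x a_d grid; untested
    combinations are an error (no interpolation is performed).  When
    ``plot_path`` is given, a heat map is rendered there.
    """
    if not results:
        raise ValueError("no scenario results")
    d_set = {res.scenario.d for res in results}
    m_set = {res.scenario.m_prop for res in results}
    if len(d_set) > 1 or len(m_set) > 1:
        raise ValueError("heat map requires a single (d, m_prop) combination")
    rows = [
        {"r": res.scenario.r, "a_d": res.scenario.a_d,
         "mean_delta": res.mean_delta, "n_success": res.n_success}
        for res in results
    ]
    df = pd.DataFrame(rows)
    r_vals, a_vals = sorted(df.r.unique()), sorted(df.a_d.unique())
    have = set(zip(df.r, df.a_d))
    missing = [(r, a) for r in r_vals for a in a_vals if (r, a) not in have]
    if missing or len(df) != len(r_vals) * len(a_vals):
        raise ValueError(f"non-rectangular grid; missing cells: {missing}")
    if plot_path is not None:
        _render_heatmap(df, plot_path)
    return df


def _render_heatmap(df: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = df.pivot(index="a_d", columns="r", values="mean_delta").sort_index(ascending=False)
    vmax = np.nanmax(np.abs(pivot.to_numpy())) or 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), [f"{v:g}" for v in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{v:g}" for v in pivot.index])
    ax.set_xlabel("phenotypic correlation r")
    ax.set_ylabel("relative effect a_d")
    fig.colorbar(im, ax=ax, label="mean Δ(-log10 p), multivariate - univariate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def negative_snp_qq(
    results: list[TestResult],
    g: GenotypeMatrix,
    arch: QTLArchitecture,
    r2_threshold: float = 0.1,
    test: str = "multivariate",
) -> QQData:
    """QQ data for SNPs on the target chromosome unlinked (r^2 < threshold) to all QTLs.

    Used to verify that the tests do not inflate p-values of null markers.
    """
    if arch.n_qtl == 0:
        raise ValueError("architecture has no QTLs; no target chromosome defined")
    target_chr = g.chrom[arch.target_index]
    qtl_set = set(arch.qtl_indices.tolist())
    on_chr = np.array([
        k for k in np.nonzero(g.chrom == target_chr)[0]
        if k not in qtl_set and g.dosages[:, k].std() > 0
    ])
    # squared Pearson correlation of dosages against every QTL, vectorised
    def standardise(M):
        M = M - M.mean(axis=0)
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        return M / sd

    Xs = standardise(g.dosages[:, on_chr])
    Qs = standardise(g.dosages[:, arch.qtl_indices])
    r2 = (Xs.T @ Qs / g.n_samples) ** 2
    candidate_set = set(g.snp_ids[on_chr[r2.max(axis=1) < r2_threshold]].tolist())
    pvals = np.array([
        t.p_value for t in results
        if t.test == test and t.snp_id in candidate_set and np.isfinite(t.p_value)
    ])
    if len(pvals) == 0:
        raise ValueError(
            f"no negative SNPs at r^2 < {r2_threshold}; consider raising the threshold"
        )
    observed = np.sort(-np.log10(pvals))
    m = len(pvals)
    expected = np.sort(-np.log10((np.arange(1, m + 1) - 0.5) / m))
    return QQData(observed=observed, expected=expected, r2_threshold=r2_threshold)


def qq_slope(qq: QQData) -> float:
    """Least-squares slope of observed on expected -log10 p."""
    return float(np.polyfit(qq.expected, qq.observed, 1)[0])
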