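"""Shared fixtures: small hand-built datasets and one session-scoped
simulated panel reused by the REML / F-test / acceptance suites."""

import numpy as np
import pytest

from mvftest.data import GenotypeMatrix, PhenotypeTable, compute_grm, prune_maf
from mvftest.simulate import simulate_genotypes


def make_genotypes(dosages, chrom=None, pos=None):
    """GenotypeMatrix from a plain (n x M) array with generated metadata."""
    dosages = np.asarray(dosages, dtype=np.float64)
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=[f"snp{k + 1}" for k in range(m)],
        chrom=chrom if chrom is not None else ["1"] * m,
        pos=pos if pos is not None else np.arange(1, m + 1),
        sample_ids=[f"s{i + 1}" for i in range(n)],
    )


def make_phenotypes(values, mask=None, sample_ids=None):
    values = np.asarray(values, dtype=np.float64)
    n, d = values.shape
    return PhenotypeTable(
        values=values,
        mask=np.ones((n, d), dtype=bool) if mask is None else np.asarray(mask, bool),
        variate_names=[f"variate{j + 1}" for j in range(d)],
        sample_ids=sample_ids if sample_ids is not None else [f"s{i + 1}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def sim_panel():
    """One MAF-pruned simulated genotype panel (200 individuals)."""
    return prune_maf(simulate_genotypes(seed=3), 0.02)


@pytest.fixture(scope="session")
def sim_grm(sim_panel):
    return compute_grm(sim_panel)


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated panel for fast mixed-model fits (60 individuals)."""
    return prune_maf(simulate_genotypes(n=60, n_chr=2, snps_per_chr=300, seed=17), 0.02)


@pytest.fixture(scope="session")
def small_grm(small_panel):
    return compute_grm(small_panel)


@pytest.fixture(scope="session")
def criterion_grid():
    """ScenarioResults of the reduced 3 x 3 (r, a_d) sign-pattern grid.

    d = 2, no missingness, n = 200, 20 replicates per cell; shared between
    the acceptance sign-pattern check and the grid-example tests.
    """
    from mvftest.power import run_grid
    from mvftest.simulate import SimScenario

    vals = [-0.8, 0.0, 0.8]
    grid = [
        SimScenario(d=2, r=r, a_d=a, m_prop=0.0, n=200, replicates=20, seed=0)
        for r in vals for a in vals
    ]
    return {(res.scenario.r, res.scenario.a_d): res for res in run_grid(grid)}


@pytest.fixture(scope="session")
def null_panel_scans():
    """Per-replicate p-value arrays from 20 whole-panel scans with no QTLs.

    One shared panel and relationship matrix.  The null has no per-SNP
    fixed effects but a polygenic background at heritability 0.5: per
    replicate, u ~ MVN(0, Su (x) A) and e ~ MVN(0, Se (x) I) with
    Su = Se = the compound-symmetry correlation matrix (r = 0.8), so the
    mixed model is correctly specified and no SNP carries a direct effect.
    A replicate whose null REML fit does not converge aborts its scan and
    is recorded as None (counted as a non-passing replicate by consumers,
    mirroring the harness's drop-and-count handling).
    """
    from mvftest.data import ScanConfig
    from mvftest.ftest import gwa_scan

    g = prune_maf(simulate_genotypes(seed=101), 0.02)
    grm = compute_grm(g)
    n = grm.n_samples
    Sigma = np.array([[1.0, 0.8], [0.8, 1.0]])
    La = np.linalg.cholesky(grm.A + 1e-8 * np.eye(n))
    Ls = np.linalg.cholesky(Sigma)
    rng = np.random.default_rng(202)
    out = []
    for rep in range(20):
        u = La @ rng.standard_normal((n, 2)) @ Ls.T
        e = rng.standard_normal((n, 2)) @ Ls.T
        ph = make_phenotypes(u + e, sample_ids=grm.sample_ids)
        try:
            res = gwa_scan(g, ph, grm, ScanConfig(test="multivariate"))
        except RuntimeError:
            out.append(None)
            continue
        out.append(np.array([t.p_value for t in res if np.isfinite(t.p_value)]))
    return out
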