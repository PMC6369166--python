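"""Univariate and multivariate F-tests for SNP effects in mixed models.

The statistic for a fitted GLS model with marginal covariance V is

    F = (H'b)' [H'(X'V^-1 X)^-1 H]^-1 (H'b) / (f * sigma2)

with b the GLS estimate, H an indicator contrast selecting the f tested
effects, and sigma2 the denominator scale, fixed to 1 when V carries REML
variance-component estimates.  Under the null the statistic is referred to an
F distribution with (f, N - p) degrees of freedom, N being the number of
observed records and p the number of fixed effects; the reduction of the
denominator degrees of freedom due to variance-component estimation is
deliberately ignored (it does not inflate negative-SNP p-values at GWAS
sample sizes, which the test suite checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .data import GRM, GenotypeMatrix, PhenotypeTable, ScanConfig
from .reml import MissingPattern, VarianceComponents, build_Vm, em_reml

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastMatrix",
    "FixedEffectFit",
    "TestResult",
    "build_H",
    "gls_fit",
    "f_statistic",
    "gwa_scan",
]

_P_FLOOR = float(np.finfo(np.float64).tiny)


@dataclass
class ContrastMatrix:
    """Indicator matrix H, one unit column per tested effect."""

    H: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.ndim != 2:
            raise ValueError("H must be 2-dimensional")
        cols = [tuple(c) for c in self.H.T]
        for c in cols:
            if sorted(c) != [0.0] * (len(c) - 1) + [1.0]:
                raise ValueError("columns of H must be unit vectors")
        if len(set(cols)) != len(cols):
            raise ValueError("columns of H must be distinct")

    @property
    def f(self) -> int:
        return self.H.shape[1]


@dataclass
class FixedEffectFit:
    """GLS fixed-effect solution with its estimated covariance."""

    B_hat: np.ndarray
    cov_B: np.ndarray          # (X' V^-1 X)^-1
    quadratic_form: float      # (y - Xb)' V^-1 (y - Xb)
    n_obs: int
    p: int


@dataclass
class TestResult:
    """One SNP x test outcome; F is NaN for degenerate (constant) dosages."""

    snp_id: str | None
    test: str
    F: float
    df1: int
    df2: int
    p_value: float
    neg_log10_p: float
    chrom: str | None = None
    pos: int | None = None


def build_H(p_per_variate: int, d: int, tested_index: int) -> ContrastMatrix:
    """Contrast selecting the ``tested_index``-th (1-based) effect of every variate.

    The stacked fixed effects are ordered variate-major, e.g. for d = 2 with
    an intercept and a SNP per variate: [mu1, B1, mu2, B2].
    """
    if not 1 <= tested_index <= p_per_variate:
        raise ValueError(
            f"tested index {tested_index} out of range for {p_per_variate} effects per variate"
        )
    H = np.zeros((p_per_variate * d, d))
    for j in range(d):
        H[j * p_per_variate + tested_index - 1, j] = 1.0
    return ContrastMatrix(H)


def _name_collinear_columns(X: np.ndarray) -> list[int]:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = diag.max() * max(X.shape) * np.finfo(float).eps
    return sorted(piv[len(diag[diag > thresh]):].tolist())


def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> FixedEffectFit:
    """Generalised least squares via a Cholesky factorisation of V."""
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _name_collinear_columns(X)
        raise np.linalg.LinAlgError(f"design matrix is rank deficient; collinear columns {bad}")
    try:
        cho = cho_factor(np.asarray(V, dtype=np.float64), lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance V is singular or not positive definite") from exc
    return _gls_with_cho(y, X, cho)


def _gls_with_cho(y, X, cho) -> FixedEffectFit:
    VinvX = cho_solve(cho, X)
    XtVX = X.T @ VinvX
    cov_B = np.linalg.inv(XtVX)
    B_hat = cov_B @ (VinvX.T @ y)
    resid = y - X @ B_hat
    qf = float(resid @ cho_solve(cho, resid))
    return FixedEffectFit(
        B_hat=B_hat, cov_B=0.5 * (cov_B + cov_B.T),
        quadratic_form=qf, n_obs=len(y), p=X.shape[1],
    )


def f_statistic(
    fit: FixedEffectFit,
    H: ContrastMatrix,
    sigma2: float = 1.0,
    test: str = "univariate",
    snp_id: str | None = None,
) -> TestResult:
    """F-test of the contrast H'b = 0 on a fitted model."""
    if H.H.shape[0] != len(fit.B_hat):
        raise ValueError("contrast dimension does not match the fitted effects")
    f = H.f
    Hb = H.H.T @ fit.B_hat
    middle = H.H.T @ fit.cov_B @ H.H
    try:
        sol = np.linalg.solve(middle, Hb)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("H'(X'V^-1X)^-1H is singular") from exc
    F = float(Hb @ sol) / (f * sigma2)
    F = max(F, 0.0)
    df2 = fit.n_obs - fit.p
    p = float(stats.f.sf(F, f, df2))
    if p < _P_FLOOR:
        logger.info("p-value underflow for %s; floored at %.3e", snp_id, _P_FLOOR)
        p = _P_FLOOR
    return TestResult(
        snp_id=snp_id, test=test, F=F, df1=f, df2=df2,
        p_value=p, neg_log10_p=-np.log10(p),
    )


def _na_result(snp_id, test, chrom, pos, reason: str) -> TestResult:
    logger.info("SNP %s (%s): no test performed (%s)", snp_id, test, reason)
    return TestResult(
        snp_id=snp_id, test=test, F=np.nan, df1=0, df2=0,
        p_value=np.nan, neg_log10_p=np.nan, chrom=chrom, pos=pos,
    )


def _align_samples(g: GenotypeMatrix, ph: PhenotypeTable, grm: GRM):
    common = [s for s in g.sample_ids if s in set(ph.sample_ids) & set(grm.sample_ids)]
    if len(common) < 2:
        raise ValueError("fewer than 2 samples shared between genotypes, phenotypes and GRM")
    if len(common) < max(g.n_samples, ph.n_samples, grm.n_samples):
        logger.info("sample inner join retains %d individuals", len(common))

    def order(ids):
        lookup = {s: i for i, s in enumerate(ids)}
        return np.array([lookup[s] for s in common])

    return (
        g.subset_samples(order(g.sample_ids)),
        ph.subset_samples(order(ph.sample_ids)),
        grm.subset_samples(order(grm.sample_ids)),
    )


def _scan_one_model(g, values, mask, grm, vc, test_label, snp_index, snp_meta):
    """F-test every requested SNP against one fitted null covariance."""
    pattern = MissingPattern(mask)
    d = pattern.d
    V = build_Vm(vc, grm, pattern)
    cho = cho_factor(V, lower=True)
    y = pattern.stack(values)
    H = build_H(2, d, 2)
    results = []
    ones = np.ones(g.n_samples)
    for k in snp_index:
        snp_id, chrom, pos = snp_meta[k]
        dose = g.dosages[:, k]
        if np.ptp(dose[np.unique(pattern.rec_individual)]) == 0:
            results.append(_na_result(snp_id, test_label, chrom, pos,
                                      "constant dosage on analysed samples"))
            continue
        X = np.column_stack([ones, dose])
        Xobs = pattern.design(X)
        try:
            fit = _gls_with_cho(y, Xobs, cho)
        except np.linalg.LinAlgError:
            results.append(_na_result(snp_id, test_label, chrom, pos, "singular design"))
            continue
        res = f_statistic(fit, H, sigma2=1.0, test=test_label, snp_id=snp_id)
        res.chrom, res.pos = chrom, pos
        logger.debug(
            "%s %s: quadratic-form scale %.4f (fixed at 1 in the denominator)",
            snp_id, test_label, fit.quadratic_form / max(fit.n_obs - fit.p, 1),
        )
        results.append(res)
    return results


def gwa_scan(
    g: GenotypeMatrix,
    ph: PhenotypeTable,
    grm: GRM,
    cfg: ScanConfig | None = None,
    snp_indices=None,
) -> list[TestResult]:
    """Genome-wide (or targeted) scan of per-SNP F-tests.

    Variance components are estimated once under the null model (intercept
    per variate, no SNP) and reused for every SNP test; pass
    ``cfg.exact_reml=True`` to refit them per SNP (small panels only).
    Raises ``RuntimeError`` when the null REML fit does not converge, so that
    callers can drop the affected analysis.
    """
    cfg = cfg or ScanConfig()
    cfg.validate_against(ph)
    g, ph, grm = _align_samples(g, ph, grm)
    variates = list(cfg.variates) if cfg.variates else ph.variate_names.tolist()
    ph_sel = ph.select_variates(variates)
    if snp_indices is None:
        snp_indices = np.arange(g.n_snps)
    snp_meta = {k: (g.snp_ids[k], g.chrom[k], g.pos[k]) for k in np.asarray(snp_indices)}

    def null_fit(table: PhenotypeTable) -> VarianceComponents:
        vc = em_reml(table, grm, tol=cfg.reml_tol, max_iter=cfg.reml_max_iter)
        if not vc.converged:
            raise RuntimeError(
                "null-model EM-REML did not converge; inspect the logs and consider "
                "dropping this analysis"
            )
        return vc

    results: list[TestResult] = []
    if cfg.test in ("multivariate", "both"):
        if cfg.exact_reml:
            results.extend(_scan_exact(g, ph_sel, grm, cfg, "multivariate", snp_indices, snp_meta))
        else:
            vc = null_fit(ph_sel)
            results.extend(_scan_one_model(
                g, ph_sel.values, ph_sel.mask, grm, vc, "multivariate", snp_indices, snp_meta,
            ))
    if cfg.test in ("univariate", "both"):
        for name in ph_sel.variate_names:
            sub = ph_sel.select_variates([name])
            keep = np.array([s in set(sub.sample_ids) for s in g.sample_ids])
            g_sub = g.subset_samples(np.nonzero(keep)[0])
            grm_sub = grm.subset_samples(np.nonzero(keep)[0])
            label = f"univariate:{name}"
            if cfg.exact_reml:
                results.extend(_scan_exact(g_sub, sub, grm_sub, cfg, label, snp_indices, snp_meta))
            else:
                vc = em_reml(sub, grm_sub, tol=cfg.reml_tol, max_iter=cfg.reml_max_iter)
                if not vc.converged:
                    raise RuntimeError(
                        "null-model EM-REML did not converge; inspect the logs and consider "
                        "dropping this analysis"
                    )
                results.extend(_scan_one_model(
                    g_sub, sub.values, sub.mask, grm_sub, vc, label, snp_indices, snp_meta,
                ))
    return results


def _scan_exact(g, ph, grm, cfg, test_label, snp_indices, snp_meta):
    """Per-SNP exact REML mode: refit the variance components for each SNP."""
    results = []
    pattern = MissingPattern(ph.mask)
    d = pattern.d
    y = pattern.stack(ph.values)
    H = build_H(2, d, 2)
    ones = np.ones(g.n_samples)
    for k in np.asarray(snp_indices):
        snp_id, chrom, pos = snp_meta[k]
        dose = g.dosages[:, k]
        if np.ptp(dose) == 0:
            results.append(_na_result(snp_id, test_label, chrom, pos,
                                      "constant dosage on analysed samples"))
            continue
        X = np.column_stack([ones, dose])
        vc = em_reml(ph, grm, covariates=X, tol=cfg.reml_tol, max_iter=cfg.reml_max_iter)
        if not vc.converged:
            results.append(_na_result(snp_id, test_label, chrom, pos, "REML non-convergence"))
            continue
        V = build_Vm(vc, grm, pattern)
        fit = gls_fit(y, pattern.design(X), V)
        res = f_statistic(fit, H, sigma2=1.0, test=test_label, snp_id=snp_id)
        res.chrom, res.pos = chrom, pos
        results.append(res)
    return results
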