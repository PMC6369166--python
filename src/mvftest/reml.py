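"""EM-REML estimation of genetic and residual (co)variance components.

Model (stacked variate-major, d variates, n individuals):

    y = X_m b + u + e,   u ~ N(0, Sigma_u (x) A),   e ~ N(0, Sigma_e (x) I),

with the rows of y, X_m and the covariance restricted to observed phenotype
records.  The EM iteration updates each d x d component from the REML
conditional moments of u and of the (complete-data) residuals; the restricted
log-likelihood is non-decreasing along the recorded path.

Two numerically equivalent evaluation strategies are used:

* complete records: rotate every variate by the eigenvectors of A, after
  which the marginal covariance is block-diagonal with n blocks of size
  d x d (cost O(n d^3) per iteration);
* missing records: work directly on the observed-record covariance matrix
  (cost O(N_obs^3) per iteration), which makes no completeness assumption.

Convergence of plain EM near the optimum is slow (geometric with a rate
close to 1), so the driver wraps the EM map in a SQUAREM-style extrapolation
whose steps are accepted only when the restricted log-likelihood does not
decrease; convergence is still declared from the size of a plain EM update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import GRM, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "MissingPattern",
    "build_Vm",
    "em_reml",
    "restricted_loglik",
]

_PSD_EPS = 1e-8


@dataclass
class VarianceComponents:
    """Estimated genetic (``sigma_u``) and residual (``sigma_e``) covariances.

    Both are d x d symmetric PSD matrices (1 x 1 in the univariate case).
    ``loglik_path`` holds the restricted log-likelihood evaluated at the
    parameters entering each accepted iteration; by the EM property it is
    non-decreasing.
    """

    sigma_u: np.ndarray
    sigma_e: np.ndarray
    converged: bool = True
    n_iter: int = 0
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.sigma_u = np.atleast_2d(np.asarray(self.sigma_u, dtype=np.float64))
        self.sigma_e = np.atleast_2d(np.asarray(self.sigma_e, dtype=np.float64))
        if self.sigma_u.shape != self.sigma_e.shape or self.sigma_u.shape[0] != self.sigma_u.shape[1]:
            raise ValueError("sigma_u and sigma_e must be square with matching shape")
        for name, m in (("sigma_u", self.sigma_u), ("sigma_e", self.sigma_e)):
            if not np.allclose(m, m.T, atol=1e-8):
                raise ValueError(f"{name} is not symmetric")

    @property
    def d(self) -> int:
        return self.sigma_u.shape[0]

    def is_psd(self, tol: float = 1e-6) -> bool:
        return (
            np.linalg.eigvalsh(self.sigma_u)[0] >= -tol
            and np.linalg.eigvalsh(self.sigma_e)[0] >= -tol
        )


class MissingPattern:
    """Observation pattern of an n x d phenotype mask, in stacked order.

    The stacked (variate-major) record ``j * n + i`` corresponds to variate j
    of individual i; observed records are listed in ascending stacked order.
    """

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be n x d")
        if not mask.any(axis=1).all():
            raise ValueError("every individual must be observed for at least one variate")
        self.mask = mask
        self.n, self.d = mask.shape
        self.flat_obs = np.nonzero(mask.T.ravel())[0]
        self.rec_variate = self.flat_obs // self.n
        self.rec_individual = self.flat_obs % self.n
        self.observed_per_variate = [np.nonzero(mask[:, j])[0] for j in range(self.d)]

    @property
    def n_obs(self) -> int:
        return len(self.flat_obs)

    @property
    def complete(self) -> bool:
        return bool(self.mask.all())

    def stack(self, values: np.ndarray) -> np.ndarray:
        """Vectorise an n x d table to the observed stacked response."""
        return values.T.ravel()[self.flat_obs]

    def design(self, X: np.ndarray) -> np.ndarray:
        """Observed rows of the block-diagonal fixed-effect design I_d (x) X."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        p = X.shape[1]
        out = np.zeros((self.n_obs, self.d * p))
        for j in range(self.d):
            rows = self.rec_variate == j
            out[rows, j * p:(j + 1) * p] = X[self.rec_individual[rows]]
        return out


def build_Vm(vc: VarianceComponents, grm: GRM, pattern: MissingPattern) -> np.ndarray:
    """Observed-record phenotypic covariance Sigma_u (x) A + Sigma_e (x) I.

    Rows and columns of unobserved records are deleted from the full
    (n*d) x (n*d) Kronecker-structured matrix.
    """
    if vc.d != pattern.d:
        raise ValueError(f"variance components are {vc.d}-variate, pattern is {pattern.d}-variate")
    if grm.n_samples != pattern.n:
        raise ValueError("GRM size does not match the phenotype pattern")
    if not vc.is_psd():
        raise ValueError("variance components are not positive semidefinite")
    v, i = pattern.rec_variate, pattern.rec_individual
    V = vc.sigma_u[np.ix_(v, v)] * grm.A[np.ix_(i, i)]
    V += vc.sigma_e[np.ix_(v, v)] * (i[:, None] == i[None, :])
    return 0.5 * (V + V.T)


def _project_psd(M: np.ndarray, eps: float = _PSD_EPS):
    """Clip eigenvalues below ``eps`` and reconstruct; report whether clipping fired."""
    M = 0.5 * (M + M.T)
    w, U = np.linalg.eigh(M)
    if w[0] >= eps:
        return M, False
    w = np.clip(w, eps, None)
    R = (U * w) @ U.T
    return 0.5 * (R + R.T), True


def _default_covariates(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if X.shape[0] != n:
        raise ValueError("covariate design has wrong number of rows")
    return X


class _EMSingular(RuntimeError):
    """The covariance implied by a candidate parameter is numerically singular."""


def em_reml(
    ph: PhenotypeTable,
    grm: GRM,
    covariates=None,
    tol: float = 1e-6,
    max_iter: int = 5000,
    method: str = "auto",
    accelerate: bool = True,
) -> VarianceComponents:
    """Estimate Sigma_u, Sigma_e by EM-REML on the observed records.

    Phenotypes are standardised per variate internally (the convergence
    tolerance ``tol`` — maximum absolute change of any component under one
    plain EM update — therefore applies on the standardised scale); estimates
    and the likelihood path are returned on the original scale.
    Initialisation puts half the sample variance of each variate on the
    genetic and half on the residual diagonal.  ``max_iter`` caps the number
    of outer EM iterations (acceleration bookkeeping steps are not charged
    against it).

    ``converged`` is False when the iteration cap is hit, when three
    consecutive EM updates had to be projected back to the PSD cone, or when
    a candidate covariance turned singular; the condition is logged.
    """
    pattern = MissingPattern(ph.mask)
    n, d = pattern.n, pattern.d
    X = _default_covariates(n, covariates)
    p = X.shape[1]
    if pattern.n_obs < d * p + 2:
        raise ValueError(
            f"{pattern.n_obs} observed records cannot identify {d * p} fixed effects "
            "plus two covariance components"
        )
    if method == "auto":
        method = "rotated" if pattern.complete else "direct"
    if method == "rotated" and not pattern.complete:
        raise ValueError("the rotated EM path requires complete records")

    # per-variate standardisation (observed cells only)
    scales = np.array([
        max(float(ph.values[pattern.observed_per_variate[j], j].std(ddof=1)), 1e-30)
        for j in range(d)
    ])
    Y = ph.values / scales

    Su = 0.5 * np.eye(d)
    Se = 0.5 * np.eye(d)

    make = _make_step_rotated if method == "rotated" else _make_step_direct
    step = make(Y, pattern, grm.A, X)
    Su, Se, converged, n_iter, path = _em_drive(
        step, Su, Se, tol=tol, max_iter=max_iter, accelerate=accelerate
    )

    # undo the per-variate standardisation, including its constant shift of
    # the restricted log-likelihood (p fixed effects per variate)
    n_obs_per_variate = ph.mask.sum(axis=0)
    shift = float(np.sum((n_obs_per_variate - p) * np.log(scales)))
    S = np.outer(scales, scales)
    return VarianceComponents(
        sigma_u=Su * S, sigma_e=Se * S,
        converged=converged, n_iter=n_iter,
        loglik_path=np.asarray(path) - shift,
    )


# plain-EM increment below which SQUAREM extrapolation is allowed to engage
_WARM_DELTA = 1e-3


def _em_drive(step, Su, Se, tol, max_iter, accelerate):
    """Run the EM map to convergence, optionally with guarded SQUAREM jumps.

    ``step(Su, Se)`` performs one EM update and returns
    ``(Su_new, Se_new, loglik_at_input, clipped)``.  Monotonicity of the
    recorded path is guaranteed: each extrapolated candidate is first
    stabilised by one EM step, and the stabilised point is only adopted when
    its likelihood does not fall below that of the plain EM iterate; on
    rejection the step length is backtracked towards a plain EM step.
    Extrapolation only starts once the plain EM increment has dropped below
    ``_WARM_DELTA`` — early jumps from a remote start can otherwise settle on
    a different, inferior stationary point of the restricted likelihood.
    """
    path = []
    n_clip = 0

    # The iteration cap counts outer EM iterations (entries of the recorded
    # likelihood path), not the extra EM-map evaluations the acceleration
    # scheme spends on stabilisation and backtracking: an accelerated cycle
    # must never get a smaller effective budget than plain EM.
    try:
        while len(path) < max_iter:
            Su1, Se1, ll0, clip1 = step(Su, Se)
            path.append(ll0)
            n_clip = n_clip + 1 if clip1 else 0
            if n_clip >= 3:
                logger.warning("EM-REML: 3 consecutive PSD projections; declaring non-convergence")
                return Su1, Se1, False, len(path), path
            delta = max(np.abs(Su1 - Su).max(), np.abs(Se1 - Se).max())
            if delta < tol:
                return Su1, Se1, True, len(path), path
            if not accelerate or delta > _WARM_DELTA:
                Su, Se = Su1, Se1
                continue
            Su2, Se2, ll1, clip2 = step(Su1, Se1)
            n_clip = n_clip + 1 if clip2 else 0
            # SQUAREM S3 step length from the two EM increments
            r = np.concatenate([(Su1 - Su).ravel(), (Se1 - Se).ravel()])
            v = np.concatenate([(Su2 - Su1).ravel(), (Se2 - Se1).ravel()]) - r
            vnorm = float(v @ v)
            if vnorm <= 0:
                Su, Se = Su2, Se2
                continue
            alpha = min(-1.0, -float(np.sqrt((r @ r) / vnorm)))
            accepted = False
            for _ in range(6):
                Su_c = Su - 2 * alpha * (Su1 - Su) + alpha**2 * (Su2 - Su1)
                Se_c = Se - 2 * alpha * (Se1 - Se) + alpha**2 * (Se2 - Se1)
                Su_c, cu = _project_psd(Su_c)
                Se_c, ce = _project_psd(Se_c)
                if cu or ce:
                    # a candidate outside the PSD cone would pin later EM
                    # updates to the clipping floor; shorten the jump instead
                    alpha = (alpha - 1.0) / 2.0
                    continue
                try:
                    # stabilise the extrapolated point with one EM step, then
                    # evaluate its likelihood via a second step (whose output
                    # becomes the next iterate when accepted)
                    Su3, Se3, _, _ = step(Su_c, Se_c)
                    Su4, Se4, ll3, _ = step(Su3, Se3)
                except _EMSingular:
                    alpha = (alpha - 1.0) / 2.0
                    continue
                if ll3 >= ll1:
                    Su, Se = Su4, Se4
                    accepted = True
                    break
                alpha = (alpha - 1.0) / 2.0
            if not accepted:
                Su, Se = Su2, Se2
    except _EMSingular as exc:
        logger.warning("EM-REML: %s", exc)
        return Su, Se, False, len(path), path
    logger.warning("EM-REML: no convergence within %d EM iterations", max_iter)
    return Su, Se, False, len(path), path


def _make_step_rotated(Y, pattern, A, X):
    """EM update in the eigenbasis of A; complete records only."""
    n, d = pattern.n, pattern.d
    p = X.shape[1]
    lam, U = np.linalg.eigh(A)
    lam = np.clip(lam, 0.0, None)
    Yt = U.T @ Y                      # n x d
    Xt = U.T @ X                      # n x p
    q = d * p
    const = -0.5 * (n * d - q) * np.log(2.0 * np.pi)

    def step(Su, Se):
        Vi = lam[:, None, None] * Su[None] + Se[None]          # n x d x d
        sign, logdet = np.linalg.slogdet(Vi)
        if (sign <= 0).any():
            raise _EMSingular("singular per-eigenvalue covariance block")
        Vinv = np.linalg.inv(Vi)
        XtVX = np.einsum("ijl,ia,ib->jalb", Vinv, Xt, Xt).reshape(q, q)
        XtVy = np.einsum("ijl,il,ia->ja", Vinv, Yt, Xt).reshape(q)
        W = np.linalg.inv(XtVX)
        beta = W @ XtVy
        Bmat = beta.reshape(d, p).T                            # p x d
        resid = Yt - Xt @ Bmat                                  # n x d
        Py = np.einsum("ijl,il->ij", Vinv, resid)              # n x d
        # diagonal blocks of the REML projection P
        G = np.einsum("ijl,ia->ijla", Vinv, Xt).reshape(n, d, q)
        corr = np.einsum("ikm,mn,iln->ikl", G, W, G)
        Pii = Vinv - corr
        diff = np.einsum("ij,il->ijl", Py, Py) - Pii
        Mu = np.einsum("i,ijl->jl", lam, diff)
        Me = diff.sum(axis=0)
        Su_new, clip_u = _project_psd(Su + Su @ Mu @ Su / n)
        Se_new, clip_e = _project_psd(Se + Se @ Me @ Se / n)
        ll = const - 0.5 * (
            logdet.sum()
            + float(np.linalg.slogdet(XtVX)[1])
            + float(np.einsum("ij,ij->", resid, Py))
        )
        return Su_new, Se_new, ll, (clip_u or clip_e)

    return step


def _make_step_direct(Y, pattern, A, X):
    """EM update on the observed-record covariance; arbitrary missingness."""
    n, d = pattern.n, pattern.d
    v, idx = pattern.rec_variate, pattern.rec_individual
    N = pattern.n_obs
    y = pattern.stack(Y)
    Xobs = pattern.design(X)
    q = Xobs.shape[1]
    same_ind = (idx[:, None] == idx[None, :]).astype(np.float64)
    Aobs = A[np.ix_(idx, idx)]
    D = np.zeros((N, d))
    D[np.arange(N), v] = 1.0
    const = -0.5 * (N - q) * np.log(2.0 * np.pi)

    def step(Su, Se):
        V = Su[np.ix_(v, v)] * Aobs + Se[np.ix_(v, v)] * same_ind
        try:
            cho = cho_factor(0.5 * (V + V.T), lower=True)
        except np.linalg.LinAlgError:
            raise _EMSingular("observed covariance not positive definite") from None
        logdetV = 2.0 * np.log(np.diag(cho[0])).sum()
        VinvX = cho_solve(cho, Xobs)
        XtVX = Xobs.T @ VinvX
        W = np.linalg.inv(XtVX)
        beta = W @ (VinvX.T @ y)
        resid = y - Xobs @ beta
        Py = cho_solve(cho, resid)
        Vinv = cho_solve(cho, np.eye(N))
        P = Vinv - VinvX @ W @ VinvX.T

        Wmat = np.zeros((n, d))                 # scatter T' P y to an n x d table
        np.add.at(Wmat, (idx, v), Py)
        Qu = D.T @ (P * Aobs) @ D
        Qe = D.T @ (P * same_ind) @ D
        Su_new, clip_u = _project_psd(Su + Su @ (Wmat.T @ A @ Wmat - Qu) @ Su / n)
        Se_new, clip_e = _project_psd(Se + Se @ (Wmat.T @ Wmat - Qe) @ Se / n)
        ll = const - 0.5 * (
            logdetV + float(np.linalg.slogdet(XtVX)[1]) + float(resid @ Py)
        )
        return Su_new, Se_new, ll, (clip_u or clip_e)

    return step


def restricted_loglik(
    vc: VarianceComponents,
    ph: PhenotypeTable,
    grm: GRM,
    covariates=None,
) -> float:
    """Restricted log-likelihood of the observed records at fixed components.

    -2 ll = log|V| + log|X' V^-1 X| + (y - Xb)' V^-1 (y - Xb) + (N - q) log 2 pi
    with b the GLS solution and q the number of fixed effects.
    """
    pattern = MissingPattern(ph.mask)
    X = _default_covariates(pattern.n, covariates)
    Xobs = pattern.design(X)
    y = pattern.stack(ph.values)
    V = build_Vm(vc, grm, pattern)
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"observed covariance V_m is singular (condition number {cond:.3e})"
        ) from exc
    logdetV = 2.0 * np.log(np.diag(cho[0])).sum()
    VinvX = cho_solve(cho, Xobs)
    XtVX = Xobs.T @ VinvX
    beta = np.linalg.solve(XtVX, VinvX.T @ y)
    resid = y - Xobs @ beta
    q = Xobs.shape[1]
    ll = -0.5 * (
        logdetV
        + float(np.linalg.slogdet(XtVX)[1])
        + float(resid @ cho_solve(cho, resid))
        + (pattern.n_obs - q) * np.log(2.0 * np.pi)
    )
    if not np.isfinite(ll):
        raise FloatingPointError("restricted log-likelihood is not finite")
    return ll
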