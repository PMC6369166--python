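"""Closed-form power term of the bivariate F-test and the distribution of the
relative effect ratio of correlated effect pairs.

Under the simplifications d = 2, per-record-pair covariance [[1, r], [r, 1]],
identity relationship matrix and a second effect equal to a2 times the first,
the numerator of the multivariate F statistic is b1^2 * (x'x) * f(a2, r) with

    f(a2, r) = (a2^2 - 2 a2 r + 1) / (1 - r^2),

so f > 1 marks the region where the bivariate test gains power over the
univariate one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PowerSurface", "f_a2_r", "power_surface", "ad_fraction", "ad_sign_prob"]


@dataclass
class PowerSurface:
    """f(a2, r) evaluated on a rectangular grid (rows a2, columns r)."""

    a2: np.ndarray
    r: np.ndarray
    f_values: np.ndarray

    def __post_init__(self) -> None:
        if self.f_values.shape != (len(self.a2), len(self.r)):
            raise ValueError("f_values shape does not match the grid")
        if (self.f_values < 0).any():
            raise ValueError("f(a2, r) must be non-negative")


def f_a2_r(a2, r):
    """Bivariate power factor (a2^2 - 2 a2 r + 1) / (1 - r^2); |r| < 1."""
    a2 = np.asarray(a2, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 (division by 1 - r^2)")
    out = (a2**2 - 2.0 * a2 * r + 1.0) / (1.0 - r**2)
    return float(out) if out.ndim == 0 else out


def power_surface(a2_grid, r_grid) -> PowerSurface:
    a2 = np.asarray(a2_grid, dtype=np.float64)
    r = np.asarray(r_grid, dtype=np.float64)
    return PowerSurface(a2=a2, r=r, f_values=f_a2_r(a2[:, None], r[None, :]))


def signed_ratio(pairs: np.ndarray) -> np.ndarray:
    """Relative effect ratio of 2-vectors: smaller magnitude over larger, signed.

    Equal magnitudes give +/-1 according to sign agreement, so the ratio
    always lies in [-1, 1].
    """
    pairs = np.atleast_2d(pairs)
    mags = np.abs(pairs)
    small = mags.min(axis=1)
    big = mags.max(axis=1)
    sign = np.where(pairs[:, 0] * pairs[:, 1] >= 0, 1.0, -1.0)
    with np.errstate(invalid="ignore"):
        ratio = np.where(big > 0, small / big, 1.0)
    return sign * ratio


def ad_fraction(r: float, thresholds, n_draws: int = 1_000_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo fractions of bivariate normal pairs with signed ratio < threshold.

    Draws (B1, B2) ~ MVN(0, [[1, r], [r, 1]]) and evaluates the fraction of
    pairs whose signed relative-effect ratio falls below each threshold.
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n_draws < 10_000:
        raise ValueError("need at least 10,000 draws for a stable estimate")
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=np.float64))
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]))
    pairs = rng.standard_normal((n_draws, 2)) @ L.T
    ad = signed_ratio(pairs)
    return np.array([(ad < t).mean() for t in thresholds])


def ad_sign_prob(r: float) -> float:
    """P(opposite signs) of a standard bivariate normal pair: 1/2 - arcsin(r)/pi."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    return 0.5 - np.arcsin(r) / np.pi
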