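"""Mantel / partial Mantel tests, IBD regressions and AICc model selection.

Isolation by distance is tested by correlating a genetic distance matrix
(linearized F_ST between populations, or â between individuals) with
ln-transformed geographic or least-cost distances.  Significance comes from
jointly permuting rows and columns of one matrix (Mantel), or of the
residuals of the response on the conditioning matrix (Smouse–Long–Sokal
partial Mantel).  Competing single-predictor distance models are compared
by the small-sample Akaike criterion AICc = 2k + n·ln(RSS/n) +
2k(k+1)/(n−k−1), with n the number of populations (not the number of
pairs) as the effective sample size; models within ΔAICc < 2 of the best
are reported as statistically indistinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import SymmetricMatrix

__all__ = [
    "mantel_test",
    "partial_mantel",
    "distance_regression",
    "aicc_model_compare",
    "RegressionModelFit",
]


def _aligned_square(A: SymmetricMatrix, B: SymmetricMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if A.labels != B.labels:
        common = [l for l in A.labels if l in set(B.labels)]
        if len(common) < 4:
            raise ValueError("fewer than 4 shared labels")
        ia = [A.labels.index(l) for l in common]
        ib = [B.labels.index(l) for l in common]
        return A.values[np.ix_(ia, ia)], B.values[np.ix_(ib, ib)], common
    return A.values, B.values, list(A.labels)


def _pair_mask(*mats: np.ndarray) -> np.ndarray:
    """Upper-triangle mask of pairs finite in every matrix (listwise)."""
    k = mats[0].shape[0]
    iu = np.triu_indices(k, 1)
    ok = np.ones(len(iu[0]), dtype=bool)
    for m in mats:
        ok &= np.isfinite(m[iu])
    return ok


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    sx, sy = np.sqrt((x**2).sum()), np.sqrt((y**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in matrix entries")
    return float((x * y).sum() / (sx * sy))


def mantel_test(
    A: SymmetricMatrix,
    B: SymmetricMatrix,
    n_perm: int = 30_000,
    seed: int | None = None,
    tail: str = "greater",
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    r is the Pearson correlation over unordered pairs (missing pairs
    excluded listwise); p permutes rows and columns of A jointly.  The
    default one-tailed (positive) alternative matches the directional IBD
    hypothesis.  Uses the (x+1)/(n+1) p estimator.
    """
    a, b, labels = _aligned_square(A, B)
    k = len(labels)
    if k < 4:
        raise ValueError("need at least 4 labels")
    iu = np.triu_indices(k, 1)
    ok = _pair_mask(a, b)
    r_obs = _pearson(a[iu][ok], b[iu][ok])
    rng = np.random.default_rng(seed)
    hits = 0
    bv = b[iu]
    for _ in range(n_perm):
        perm = rng.permutation(k)
        ap = a[np.ix_(perm, perm)][iu]
        okp = np.isfinite(ap) & np.isfinite(bv)
        r = _pearson(ap[okp], bv[okp])
        if tail == "greater":
            hits += r >= r_obs
        elif tail == "two-sided":
            hits += abs(r) >= abs(r_obs)
        else:
            hits += r <= r_obs
    return r_obs, (hits + 1) / (n_perm + 1)


def _ols_residual_matrix(Y: np.ndarray, X: np.ndarray, mask_iu) -> np.ndarray:
    """Residual matrix of Y on X fitted over upper-triangle pairs."""
    iu, ok = mask_iu
    x, y = X[iu][ok], Y[iu][ok]
    if np.ptp(x) == 0:
        raise ValueError("conditioning matrix has zero variance")
    beta, alpha = np.polyfit(x, y, 1)
    res = Y - (alpha + beta * X)
    np.fill_diagonal(res, 0.0)
    return res


def partial_mantel(
    A: SymmetricMatrix,
    B: SymmetricMatrix,
    C: SymmetricMatrix,
    n_perm: int = 30_000,
    seed: int | None = None,
    tail: str = "greater",
) -> tuple[float, float]:
    """Partial Mantel correlation of A and B controlling for C.

    r_AB·C is derived from the three pairwise Mantel correlations; the
    p-value permutes the residual matrix of A on C against the residuals of
    B on C (Smouse–Long–Sokal).
    """
    a, b, labels = _aligned_square(A, B)
    _, c, labels2 = _aligned_square(A, C)
    if labels != labels2:
        raise ValueError("matrices must share labels")
    k = len(labels)
    iu = np.triu_indices(k, 1)
    ok = _pair_mask(a, b, c)
    av, bv, cv = a[iu][ok], b[iu][ok], c[iu][ok]
    r_ab, r_ac, r_bc = _pearson(av, bv), _pearson(av, cv), _pearson(bv, cv)
    if abs(r_ac) >= 1 - 1e-12 or abs(r_bc) >= 1 - 1e-12:
        raise ValueError("degenerate partial correlation: |r| with C is 1")
    r_part = (r_ab - r_ac * r_bc) / math.sqrt((1 - r_ac**2) * (1 - r_bc**2))

    res_a = _ols_residual_matrix(a, c, (iu, ok))
    res_b = _ols_residual_matrix(b, c, (iu, ok))
    r_obs = _pearson(res_a[iu][ok], res_b[iu][ok])
    rng = np.random.default_rng(seed)
    hits = 0
    rbv = res_b[iu]
    okv = np.zeros(len(iu[0]), dtype=bool)
    okv[:] = _pair_mask(a, b, c)
    for _ in range(n_perm):
        perm = rng.permutation(k)
        rav = res_a[np.ix_(perm, perm)][iu]
        okp = np.isfinite(rav) & okv
        r = _pearson(rav[okp], rbv[okp])
        if tail == "greater":
            hits += r >= r_obs
        elif tail == "two-sided":
            hits += abs(r) >= abs(r_obs)
        else:
            hits += r <= r_obs
    return float(r_part), (hits + 1) / (n_perm + 1)


@dataclass
class RegressionModelFit:
    predictor: str
    slope: float
    intercept: float
    rss: float
    n_pairs: int
    k: int = 1
    mantel_r: float | None = None
    mantel_p: float | None = None
    partial_r: float | None = None
    partial_p: float | None = None
    aicc: float | None = None
    delta_aicc: float | None = None
    verdict: str | None = None


def distance_regression(
    genetic: SymmetricMatrix,
    predictor: SymmetricMatrix,
    log_predictor: bool = False,
    name: str | None = None,
) -> RegressionModelFit:
    """OLS of genetic distance on a predictor distance over unordered pairs."""
    a, b, labels = _aligned_square(genetic, predictor)
    iu = np.triu_indices(len(labels), 1)
    x, y = b[iu], a[iu]
    if log_predictor:
        with np.errstate(divide="ignore"):
            x = np.where(x > 0, np.log(x), np.nan)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(np.sum((y - (intercept + slope * x)) ** 2))
    return RegressionModelFit(
        predictor=name or predictor.units or "predictor",
        slope=float(slope),
        intercept=float(intercept),
        rss=rss,
        n_pairs=int(len(x)),
    )


def aicc(rss: float, n: int, k: int) -> float:
    """AICc = 2k + n·ln(RSS/n) + 2k(k+1)/(n−k−1), n = number of populations."""
    if n <= k + 1:
        raise ValueError("AICc correction undefined for n <= k+1")
    if rss <= 0:
        return -math.inf
    return 2 * k + n * math.log(rss / n) + (2 * k * (k + 1)) / (n - k - 1)


def aicc_model_compare(
    fits: list[RegressionModelFit], n: int
) -> list[RegressionModelFit]:
    """Rank fitted distance models by AICc with the ΔAICc < 2 verdict rule."""
    if not fits:
        raise ValueError("no fits to compare")
    n_pairs = {f.n_pairs for f in fits}
    if len(n_pairs) != 1:
        raise ValueError("fits are not on the same response pairs")
    for f in fits:
        f.aicc = aicc(f.rss, n, f.k)
    best = min(f.aicc for f in fits)
    for f in fits:
        f.delta_aicc = f.aicc - best
        f.verdict = "indistinguishable" if f.delta_aicc < 2 else "worse"
    ranked = sorted(fits, key=lambda f: f.aicc)
    ranked[0].verdict = "best"
    return ranked
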