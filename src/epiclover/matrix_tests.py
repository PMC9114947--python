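"""Isolation-by-distance / isolation-by-habitat matrix association tests.

Differentiation (PhiPT), geographic and habitat-dissimilarity matrices are
compared with

* the simple Mantel test — Pearson correlation of the unfolded upper
  triangles, significance by jointly permuting rows and columns of the
  first matrix, upper-tail by default (positive association);
* the partial Mantel test — first-order partial correlation
  ``r_AB.C = (r_AB - r_AC r_BC) / sqrt((1-r_AC^2)(1-r_BC^2))``, permuting
  the first matrix and recomputing each time;
* multiple matrix regression with randomization (MMRR) — OLS of the
  unfolded response on several unfolded predictors, all vectors centred
  and scaled, with coefficient and F significance from permutations of
  the response matrix.

All permutation p-values use the (b+1)/(m+1) estimator; for small
matrices ``method="exact"`` enumerates every relabelling instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import DistanceMatrix, SiteRecord, ValidationError

__all__ = [
    "geographic_distance_matrix",
    "habitat_dissimilarity_matrix",
    "mantel",
    "partial_mantel",
    "MantelResult",
    "Mmrr",
    "MmrrResults",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def geographic_distance_matrix(sites: Sequence[SiteRecord]) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between site coordinates."""
    lat = np.radians([s.latitude for s in sites])
    lon = np.radians([s.longitude for s in sites])
    dphi = lat[:, None] - lat[None, :]
    dlmb = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlmb / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([s.population_id for s in sites], d, name="geographic_km")


def habitat_dissimilarity_matrix(sites: Sequence[SiteRecord]) -> DistanceMatrix:
    """Binary dissimilarity: 1 for pairs of sites in different habitats,
    0 for pairs sharing a habitat."""
    habs = [s.habitat for s in sites]
    d = np.array([[0.0 if a == b else 1.0 for b in habs] for a in habs])
    return DistanceMatrix([s.population_id for s in sites], d, name="habitat_dissimilarity")


@dataclass(frozen=True)
class MantelResult:
    """Simple or partial Mantel test outcome."""

    r: float
    p: float
    n_perm: int
    tail: str
    conditioned_on: str | None = None
    method: str = "sampled"


def _aligned_condensed(*mats: DistanceMatrix) -> list[np.ndarray]:
    first = mats[0]
    for m in mats[1:]:
        if m.labels != first.labels:
            raise ValidationError(
                f"distance matrices are not aligned: {first.name or 'first'} vs {m.name or 'other'}"
            )
    return [m.condensed() for m in mats]


def _check_nonconstant(vec: np.ndarray, which: str) -> None:
    if np.ptp(vec) == 0.0:
        raise ValidationError(f"matrix {which} is constant; Mantel r undefined")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    return float(x @ y) / denom if denom > 0 else np.nan


def _tail_count(obs: float, perm_vals: np.ndarray, tail: str) -> int:
    if tail == "upper":
        return int((perm_vals >= obs - 1e-12).sum())
    if tail == "two_sided":
        return int((np.abs(perm_vals) >= abs(obs) - 1e-12).sum())
    raise ValidationError(f"unknown tail {tail!r}")


def _permutations(n: int, n_perm: int, method: str, seed) -> tuple[list[np.ndarray], bool]:
    """Permutation orders to evaluate; ``exact`` enumerates all n! orders
    (identity included, so the count base is n!)."""
    if method == "exact":
        if math.factorial(n) > 50000:
            raise ValidationError(f"exact enumeration infeasible for n = {n}")
        return [np.asarray(p) for p in itertools.permutations(range(n))], True
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_perm)], False


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 9999,
    seed=None,
    tail: str = "upper",
    method: str = "sampled",
) -> MantelResult:
    """Simple Mantel test of A against B (A's rows/columns are permuted)."""
    if A.n < 4:
        raise ValidationError("Mantel test needs n >= 4")
    a, b = _aligned_condensed(A, B)
    _check_nonconstant(a, A.name or "A")
    _check_nonconstant(b, B.name or "B")
    r_obs = _pearson(a, b)

    perms, exact = _permutations(A.n, n_perm, method, seed)
    iu = np.triu_indices(A.n, k=1)
    vals = np.empty(len(perms))
    for i, p in enumerate(perms):
        vals[i] = _pearson(A.values[np.ix_(p, p)][iu], b)
    count = _tail_count(r_obs, vals, tail)
    if exact:
        pval = count / len(perms)
    else:
        pval = (count + 1) / (len(perms) + 1)
    return MantelResult(r=r_obs, p=pval, n_perm=len(perms), tail=tail, method=method)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    denom = (1.0 - r_ac**2) * (1.0 - r_bc**2)
    if denom <= 0.0:
        return np.nan
    return (r_ab - r_ac * r_bc) / math.sqrt(denom)


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 9999,
    seed=None,
    tail: str = "upper",
    method: str = "sampled",
) -> MantelResult:
    """Partial Mantel test of A against B conditioned on C.

    A is permuted; ``r_AB`` and ``r_AC`` are recomputed per permutation
    while ``r_BC`` is fixed.
    """
    if A.n < 4:
        raise ValidationError("partial Mantel test needs n >= 4")
    a, b, c = _aligned_condensed(A, B, C)
    for vec, m in ((a, A), (b, B), (c, C)):
        _check_nonconstant(vec, m.name or "input")
    r_ac = _pearson(a, c)
    r_bc = _pearson(b, c)
    if abs(r_ac) >= 1.0 - 1e-12 or abs(r_bc) >= 1.0 - 1e-12:
        raise ValidationError("degenerate conditioning: |r| = 1 with the covariate matrix")
    r_obs = _partial_r(_pearson(a, b), r_ac, r_bc)

    perms, exact = _permutations(A.n, n_perm, method, seed)
    iu = np.triu_indices(A.n, k=1)
    vals = np.empty(len(perms))
    for i, p in enumerate(perms):
        ap = A.values[np.ix_(p, p)][iu]
        vals[i] = _partial_r(_pearson(ap, b), _pearson(ap, c), r_bc)
    vals = vals[~np.isnan(vals)]
    count = _tail_count(r_obs, vals, tail)
    if exact:
        pval = count / len(perms)
    else:
        pval = (count + 1) / (len(vals) + 1)
    return MantelResult(
        r=r_obs, p=pval, n_perm=len(perms), tail=tail,
        conditioned_on=C.name or "C", method=method,
    )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValidationError("constant unfolded matrix; cannot scale")
    return (v - v.mean()) / sd


class Mmrr:
    """Multiple matrix regression with randomization.

    The response and each predictor distance matrix are unfolded to their
    upper-triangle vectors, centred and scaled to unit standard deviation,
    and related by ordinary least squares with intercept.  Significance of
    the standardized coefficients (two-tailed on |t|) and of the overall F
    (upper tail) comes from jointly permuting rows and columns of the
    response matrix.

    Parameters
    ----------
    Y : response DistanceMatrix.
    X : predictor matrices — a sequence, or a mapping name -> matrix.
    """

    def __init__(self, Y: DistanceMatrix, X: Sequence[DistanceMatrix] | Mapping[str, DistanceMatrix]) -> None:
        if isinstance(X, Mapping):
            names = list(X)
            mats = list(X.values())
        else:
            mats = list(X)
            names = [m.name or f"X{i + 1}" for i, m in enumerate(mats)]
        if not mats:
            raise ValidationError("MMRR needs at least one predictor matrix")
        if Y.n < 5:
            raise ValidationError("MMRR needs n >= 5")
        vecs = _aligned_condensed(Y, *mats)
        self.Y = Y
        self.y = _zscore(vecs[0])
        self.Xcols = np.column_stack([_zscore(v) for v in vecs[1:]])
        self.names = names
        self._check_collinearity()

    def _check_collinearity(self, threshold: float = 1e8) -> None:
        if self.Xcols.shape[1] < 2:
            return
        if np.linalg.cond(self.Xcols) > threshold:
            corr = np.corrcoef(self.Xcols, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
            raise ValidationError(
                f"collinear predictors: {self.names[i]!r} and {self.names[j]!r} "
                f"(|r| = {abs(corr[i, j]):.4f})"
            )

    @staticmethod
    def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
        """Coefficients (without intercept), t statistics, R^2, F."""
        n, k = X.shape
        design = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        df_resid = n - k - 1
        sigma2 = rss / df_resid
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        if sigma2 <= 1e-30:  # perfect fit: t and F diverge
            t = np.where(beta[1:] >= 0, np.inf, -np.inf)
            return beta[1:], t, r2, np.inf
        cov = sigma2 * np.linalg.inv(design.T @ design)
        t = beta[1:] / np.sqrt(np.diag(cov)[1:])
        f = (tss - rss) / k / sigma2
        return beta[1:], t, r2, f

    def fit(self, n_permutations: int = 9999, seed=None) -> "MmrrResults":
        beta, t, r2, f = self._ols(self.y, self.Xcols)
        n = self.Y.n
        iu = np.triu_indices(n, k=1)
        if n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        t_count = np.zeros(len(beta), dtype=int)
        f_count = 0
        for _ in range(n_permutations):
            p = rng.permutation(n)
            yp = _zscore(self.Y.values[np.ix_(p, p)][iu])
            _, tp, _, fp = self._ols(yp, self.Xcols)
            t_count += np.abs(tp) >= np.abs(t) - 1e-12
            f_count += fp >= f - 1e-12
        t_p = (t_count + 1) / (n_permutations + 1)
        f_p = (f_count + 1) / (n_permutations + 1)
        return MmrrResults(self.names, beta, t, t_p, r2, f, f_p, n_permutations)


class MmrrResults:
    """Fitted MMRR: standardized coefficients with permutation p-values,
    overall F and R^2."""

    def __init__(self, names, beta, t, t_p, r2, f, f_p, n_permutations) -> None:
        self.coefficients = pd.DataFrame(
            {"coefficient": beta, "t": t, "p": t_p},
            index=pd.Index(names, name="predictor"),
        )
        self.r_squared = float(r2)
        self.f_statistic = float(f)
        self.f_p = float(f_p)
        self.n_permutations = int(n_permutations)

    def summary(self) -> str:
        lines = [
            "MMRR (scaled and centred unfolded distance matrices)",
            self.coefficients.round(4).to_string(),
            f"  R^2 = {self.r_squared:.4f}",
            f"  F = {self.f_statistic:.4f}, p = {self.f_p:.4g} "
            f"({self.n_permutations} permutations)",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<MmrrResults R2={self.r_squared:.4f} F={self.f_statistic:.3f} p={self.f_p:.3g}>"
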