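"""Heritability estimation: father-offspring regression and the REML animal model.

The animal model is the mixed model y = mu + a + e with cov(a) = V_A * A,
cov(e) = V_R * I, where A is the expected additive relationship matrix from
the pedigree.  Narrow-sense heritability is h2 = V_A / (V_A + V_R).  The REML
fit works in the eigenbasis of A: with A = U D U', the rotated model has a
diagonal covariance sigma2 * (h * D + (1 - h) * I), and the restricted
likelihood is profiled down to a one-dimensional search over h in [0, 1),
which is fast, deterministic, and respects the V_A >= 0 boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .genedrop import TraitRealization
from .pedigree import Pedigree, RelationshipMatrix, additive_relationship

__all__ = [
    "HeritabilityEstimate",
    "RelationshipEigen",
    "h2_father_offspring",
    "h2_animal_model_reml",
    "reml_fit",
    "relationship_eigen",
]

_H2_MAX = 1.0 - 1e-6


@dataclass(frozen=True)
class HeritabilityEstimate:
    method: str  # "regression" or "reml"
    h2_hat: float
    va_hat: Optional[float]
    vr_hat: Optional[float]
    se: Optional[float]
    converged: bool
    n: int

    def __post_init__(self):
        if self.method == "reml":
            assert self.va_hat is not None and self.va_hat >= 0
            assert self.vr_hat is not None and self.vr_hat > 0


def _phenotypes(traits: Union[TraitRealization, Mapping[str, float]]
                ) -> dict[str, float]:
    return traits.z_map() if isinstance(traits, TraitRealization) else dict(traits)


def h2_father_offspring(pedigree: Pedigree, mode: str,
                        traits: Union[TraitRealization, Mapping[str, float]],
                        ) -> HeritabilityEstimate:
    """Heritability as twice the father-offspring regression slope.

    One record per father-offspring pair (a father with k phenotyped
    offspring contributes k records); the estimate is 2 * cov(z, o) / var(z)
    with z the fathers' phenotypes over pair records and o the offspring's.
    """
    z = _phenotypes(traits)
    sire = pedigree.sire_idx(mode)
    zf, zo = [], []
    for k, ind in enumerate(pedigree):
        if sire[k] < 0:
            continue
        father = pedigree.ids[sire[k]]
        if ind.id in z and father in z:
            zf.append(z[father])
            zo.append(z[ind.id])
    if len(zf) < 2:
        raise ValueError("need at least two father-offspring pairs")
    x = np.array(zf)
    y = np.array(zo)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("zero phenotypic variance among fathers")
    slope = float(xc @ (y - y.mean())) / sxx
    resid = (y - y.mean()) - slope * xc
    n = len(x)
    se = None
    if n > 2:
        se = 2.0 * float(np.sqrt((resid @ resid) / (n - 2) / sxx))
    return HeritabilityEstimate(method="regression", h2_hat=2.0 * slope,
                                va_hat=None, vr_hat=None, se=se,
                                converged=True, n=n)


@dataclass(frozen=True)
class RelationshipEigen:
    """Cached eigendecomposition of an additive relationship matrix.

    Reusable across REML fits that share a pedigree (e.g. many trait
    replicates on one social pedigree).  Tiny negative eigenvalues from
    finite-precision arithmetic are clamped to zero.
    """

    ids: tuple[str, ...]
    eigvals: np.ndarray
    eigvecs: np.ndarray


def relationship_eigen(rel: RelationshipMatrix,
                       ids: Optional[Sequence[str]] = None) -> RelationshipEigen:
    use = tuple(ids) if ids is not None else rel.ids
    A = rel.loc(use) if ids is not None else rel.matrix
    d, U = eigh(A, driver="evd")
    d = np.clip(d, 0.0, None)
    return RelationshipEigen(ids=use, eigvals=d, eigvecs=U)


def _profile_reml(h: float, d: np.ndarray, ystar: np.ndarray,
                  xstar: np.ndarray) -> tuple[float, float, float]:
    """Profile restricted log-likelihood at heritability ratio ``h``.

    Returns (loglik, sigma2_hat, mu_hat); sigma2 = V_A + V_R is profiled out
    analytically, as is the intercept.
    """
    n = d.size
    v = h * d + (1.0 - h)
    w = 1.0 / v
    xwx = float(w @ xstar ** 2)
    mu = float(w @ (xstar * ystar)) / xwx
    r = ystar - mu * xstar
    rwr = float(w @ r ** 2)
    sigma2 = rwr / (n - 1)
    ll = -0.5 * (float(np.log(v).sum()) + np.log(xwx)
                 + (n - 1) * (1.0 + np.log(2.0 * np.pi * sigma2)))
    return ll, sigma2, mu


def reml_fit(eig: RelationshipEigen, y: np.ndarray,
             xatol: float = 1e-10) -> HeritabilityEstimate:
    """Maximize the profiled restricted likelihood over h2 in [0, 1)."""
    y = np.asarray(y, dtype=float)
    if y.shape != (eig.eigvals.size,):
        raise ValueError("phenotype vector does not match the relationship "
                         "matrix")
    U = eig.eigvecs
    ystar = U.T @ y
    xstar = U.T @ np.ones_like(y)
    d = eig.eigvals

    def neg(h: float) -> float:
        return -_profile_reml(h, d, ystar, xstar)[0]

    res = minimize_scalar(neg, bounds=(0.0, _H2_MAX), method="bounded",
                          options={"xatol": xatol, "maxiter": 500})
    h = float(res.x)
    # the bounded search can stall short of the V_A = 0 boundary
    if neg(0.0) <= res.fun:
        h = 0.0
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        warnings.warn("REML did not converge; returning the best point found")
    ll, sigma2, _ = _profile_reml(h, d, ystar, xstar)
    se = _numeric_se(lambda hh: _profile_reml(hh, d, ystar, xstar)[0], h)
    return HeritabilityEstimate(method="reml", h2_hat=h,
                                va_hat=h * sigma2,
                                vr_hat=(1.0 - h) * sigma2,
                                se=se, converged=converged, n=d.size)


def _numeric_se(ll, h: float, step: float = 1e-4) -> Optional[float]:
    lo, hi = max(0.0, h - step), min(_H2_MAX, h + step)
    if hi - lo < step:  # hard against a boundary; curvature is one-sided
        return None
    mid = 0.5 * (lo + hi)
    d2 = (ll(hi) - 2.0 * ll(mid) + ll(lo)) / ((0.5 * (hi - lo)) ** 2)
    if not np.isfinite(d2) or d2 >= 0:
        return None
    return float(np.sqrt(-1.0 / d2))


def h2_animal_model_reml(pedigree: Pedigree, mode: str,
                         traits: Union[TraitRealization, Mapping[str, float]],
                         eig: Optional[RelationshipEigen] = None,
                         ) -> HeritabilityEstimate:
    """REML animal-model heritability for the phenotyped individuals.

    The relationship matrix is built over the whole pedigree (so ancestors
    shape the expected relationships) and restricted to the phenotyped set.
    Pass a cached ``eig`` (from :func:`relationship_eigen`) to amortize the
    eigendecomposition across trait replicates on the same pedigree.
    """
    z = _phenotypes(traits)
    if eig is None:
        phen = tuple(i for i in pedigree.ids if i in z)
        if not phen:
            raise ValueError("no phenotyped individuals in the pedigree")
        rel = additive_relationship(pedigree, mode)
        eig = relationship_eigen(rel, phen)
    y = np.array([z[i] for i in eig.ids], dtype=float)
    return reml_fit(eig, y)
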