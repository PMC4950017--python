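"""Gene-drop simulation of phenotypes with a stated heritability down a pedigree.

The trait model is the standard additive one: phenotype z = a + eps with
breeding value a and independent environmental deviation eps.  Founders draw
a ~ N(0, h2); a non-founder's breeding value is the mean of its parents' plus
a Mendelian sampling deviation m ~ N(0, h2/2).  An unknown parent's half-share
is replaced by an independent N(0, h2/4) draw (equivalent to dropping from a
phantom unrelated founder), so that var(a) = h2 and var(z) = 1 throughout the
pedigree in the absence of inbreeding.

All per-individual random draws (Mendelian deviations, phantom-parent shares
and environmental deviations) are retained when paternity links are edited, so
that re-deriving breeding values after a paternity reassignment changes only
what flows through the altered links.  That retention is what makes the
social- versus genetic-pedigree comparison a paired one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .pedigree import Pedigree, additive_relationship

__all__ = ["TraitRealization", "simulate_trait", "recompute_after_reassignment"]


@dataclass(frozen=True)
class TraitRealization:
    """Per-individual breeding values, deviations and phenotypes.

    ``m`` holds each individual's own genetic draw: the Mendelian sampling
    deviation, plus the phantom half-share(s) standing in for any unknown
    parent; for founders it is the whole breeding value.  ``a`` and ``z`` are
    therefore reconstructible from ``m``, ``eps`` and the pedigree links.
    """

    h2: float
    ids: tuple[str, ...]
    a: np.ndarray
    m: np.ndarray
    eps: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.z, self.a + self.eps):
            raise ValueError("phenotype must equal breeding value plus "
                             "environmental deviation")

    def z_map(self) -> dict[str, float]:
        return dict(zip(self.ids, self.z.tolist()))

    def z_of(self, ids: Iterable[str]) -> np.ndarray:
        pos = {i: k for k, i in enumerate(self.ids)}
        return self.z[[pos[i] for i in ids]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": list(self.ids), "a": self.a, "m": self.m,
                             "eps": self.eps, "z": self.z})


def _as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trait(pedigree: Pedigree, mode: str = "social", h2: float = 0.5,
                   seed: Union[int, np.random.Generator, None] = None,
                   inbreeding_correction: bool = False) -> TraitRealization:
    """Simulate a unit-variance trait of heritability ``h2`` down the pedigree.

    Parameters
    ----------
    mode : which paternal column ("social" or "genetic") transmission follows.
    inbreeding_correction : scale Mendelian variance by 1 - (F_s + F_d)/2.
        Off by default: the analytical bias model assumes no inbreeding, and
        the permutation pedigrees contain essentially none.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must lie in [0, 1], got {h2}")
    rng = _as_rng(seed)
    n = len(pedigree)
    order = pedigree.topological_order()
    dam = pedigree.dam_idx
    sire = pedigree.sire_idx(mode)
    finb = None
    if inbreeding_correction and h2 > 0:
        A = additive_relationship(pedigree, mode)
        diag = {i: A.value(i, i) for i in A.ids}
        finb = np.array([diag[i] - 1.0 for i in pedigree.ids])

    a = np.empty(n)
    m = np.empty(n)
    for i in order:
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            own_var = h2
            parental = 0.0
        else:
            mend = h2 / 2.0
            if finb is not None:
                fs = finb[s] if s >= 0 else 0.0
                fd = finb[d] if d >= 0 else 0.0
                mend *= max(0.0, 1.0 - (fs + fd) / 2.0)
            own_var = mend
            parental = 0.0
            for p in (s, d):
                if p >= 0:
                    parental += 0.5 * a[p]
                else:
                    own_var += h2 / 4.0  # phantom-founder half-share
        m[i] = rng.normal(0.0, np.sqrt(own_var)) if own_var > 0 else 0.0
        a[i] = parental + m[i]
    eps = rng.normal(0.0, np.sqrt(1.0 - h2), size=n) if h2 < 1 else np.zeros(n)
    return TraitRealization(h2=h2, ids=pedigree.ids, a=a, m=m, eps=eps,
                            z=a + eps)


def recompute_after_reassignment(traits: TraitRealization,
                                 pedigree_new: Pedigree,
                                 changed_offspring: Iterable[str],
                                 mode: str = "genetic") -> TraitRealization:
    """Re-derive breeding values after paternity links were edited.

    Founder draws, Mendelian deviations and environmental deviations are all
    retained; only the changed offspring and (transitively) their descendants
    get new breeding values, computed from the current parents under
    ``mode`` in ``pedigree_new``.  Processing is topological, which makes the
    operation idempotent and order-independent.
    """
    if tuple(pedigree_new.ids) != tuple(traits.ids):
        raise ValueError("pedigree_new must contain exactly the individuals of "
                         "the trait realization, in the same order")
    changed = set(changed_offspring)
    if not changed:
        return traits
    dam = pedigree_new.dam_idx
    sire = pedigree_new.sire_idx(mode)
    for cid in changed:
        if dam[pedigree_new.index_of(cid)] < 0:
            raise ValueError(f"changed offspring '{cid}' has no dam in the "
                             "new pedigree")
    a = traits.a.copy()
    dirty = np.zeros(len(pedigree_new), dtype=bool)
    for cid in changed:
        dirty[pedigree_new.index_of(cid)] = True
    for i in pedigree_new.topological_order():
        s, d = sire[i], dam[i]
        if not dirty[i]:
            if (s >= 0 and dirty[s]) or (d >= 0 and dirty[d]):
                dirty[i] = True
        if dirty[i]:
            parental = (0.5 * a[s] if s >= 0 else 0.0) + \
                       (0.5 * a[d] if d >= 0 else 0.0)
            a[i] = parental + traits.m[i]
    return replace(traits, a=a, z=a + traits.eps)
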