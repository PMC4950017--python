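"""Closed-form bias of father-offspring regression heritability under EPP.

For a trait of true heritability h2, the expected father-offspring regression
estimate computed on the *social* pedigree is

    E[h2_hat] = h2 * [1 + delta_bar * gamma * (beta_e_z - 1)
                        + beta_delta_z * delta_cap]

where, per offspring record, delta_bar is the extra-pair rate (probability an
offspring's genetic sire differs from its social sire), gamma the variance of
social-father phenotype among extra-pair records relative to all records,
beta_e_z the regression of extra-pair-male phenotype on the cuckolded social
father's phenotype, beta_delta_z the regression of the 0/1 cuckoldry
indicator on social-father phenotype, and delta_cap the mean phenotype gap
between extra-pair males and the social fathers they cuckold.

When extra-pair males and cuckolded fathers are phenotype-independent
(gamma = 1, beta_e_z = 0, beta_delta_z = 0) this collapses to the classical
random-misassignment result E[h2_hat] = h2 * (1 - delta_bar).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .genedrop import TraitRealization
from .pedigree import MALE, Pedigree

__all__ = [
    "BiasStatistics",
    "compute_bias_statistics",
    "expected_h2_regression",
    "expected_h2_random",
]


@dataclass(frozen=True)
class BiasStatistics:
    """Realized EPP-bias statistics for one social/genetic pedigree pair.

    ``beta_e_z`` is ``None`` when the social fathers of extra-pair young show
    no phenotypic variance (its contribution to the expected bias vanishes
    with gamma = 0); ``gamma``, ``delta_cap`` and ``sd_diff`` are ``None``
    when there are no extra-pair records at all.
    """

    delta_bar: float
    gamma: Optional[float]
    beta_e_z: Optional[float]
    beta_delta_z: float
    delta_cap: Optional[float]
    sd_diff: Optional[float]
    n_offspring: int
    n_epy: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("delta_bar", "gamma", "beta_e_z", "beta_delta_z",
                 "delta_cap", "sd_diff", "n_offspring", "n_epy")}


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("zero variance in the regressor")
    return float((xc @ (y - y.mean())) / denom)


def compute_bias_statistics(social: Pedigree, genetic: Pedigree,
                            traits: Union[TraitRealization, Mapping[str, float]],
                            event_wise: bool = False) -> BiasStatistics:
    """Measure the bias statistics from a social/genetic pedigree pair.

    The statistical unit for delta_bar, gamma, beta_e_z, beta_delta_z and
    delta_cap is the offspring record (a father with three extra-pair young
    contributes three records); with ``event_wise=True`` the extra-pair
    records are collapsed to distinct (father, brood, EPM) events instead.
    ``sd_diff`` -- the mean phenotype of all extra-pair males minus that of
    all cuckolded males, in units of the SD of the larger group -- always
    uses the male as its unit.
    """
    z = traits.z_map() if isinstance(traits, TraitRealization) else dict(traits)
    recs: list[tuple[str, str, str]] = []  # (offspring, social sire, genetic sire)
    for ind in social:
        gs = genetic[ind.id].genetic_sire_id
        if ind.social_sire_id is None or gs is None:
            continue
        recs.append((ind.id, ind.social_sire_id, gs))
    if not recs:
        raise ValueError("no offspring with both social and genetic sires")
    z_father = np.array([z[s] for _, s, _ in recs])
    delta = np.array([1.0 if s != g else 0.0 for _, s, g in recs])
    if np.var(z_father) == 0.0:
        raise ValueError("zero phenotypic variance among social fathers")

    delta_bar = float(delta.mean())
    beta_delta_z = _slope(z_father, delta)

    ep = [(o, s, g) for (o, s, g), d in zip(recs, delta) if d == 1.0]
    if event_wise:
        seen, dedup = set(), []
        for o, s, g in ep:
            key = (s, social[o].brood_id, g)
            if key not in seen:
                seen.add(key)
                dedup.append((o, s, g))
        ep = dedup

    if not ep:
        gamma = beta_e_z = delta_cap = sd_diff = None
    else:
        z_cuck = np.array([z[s] for _, s, _ in ep])
        z_epm = np.array([z[g] for _, _, g in ep])
        gamma = float(np.var(z_cuck) / np.var(z_father))
        beta_e_z = _slope(z_cuck, z_epm) if gamma > 0.0 else None
        delta_cap = float((z_epm - z_cuck).mean())
        epm_males = sorted({g for _, _, g in ep})
        cuck_males = sorted({s for _, s, _ in ep})
        ze = np.array([z[m] for m in epm_males])
        zc = np.array([z[m] for m in cuck_males])
        larger = ze if len(ze) > len(zc) else zc  # ties: cuckolded group
        if len(larger) < 2 or np.std(larger, ddof=1) == 0.0:
            sd_diff = None
        else:
            sd_diff = float((ze.mean() - zc.mean()) / np.std(larger, ddof=1))

    return BiasStatistics(delta_bar=delta_bar, gamma=gamma, beta_e_z=beta_e_z,
                          beta_delta_z=beta_delta_z, delta_cap=delta_cap,
                          sd_diff=sd_diff, n_offspring=len(recs),
                          n_epy=len(ep))


def expected_h2_regression(h2: float, stats: BiasStatistics) -> float:
    """Expected social-pedigree father-offspring regression estimate.

    Evaluates h2 * [1 + delta_bar*gamma*(beta_e_z - 1) + beta_delta_z*delta_cap].
    A ``None``/zero gamma zeroes the first correction term (the worked case of
    phenotypically identical fathers and extra-pair males), and a ``None``
    delta_cap (no extra-pair records) zeroes the second.
    """
    gamma = stats.gamma or 0.0
    term1 = 0.0
    if gamma > 0.0:
        if stats.beta_e_z is None:
            raise ValueError("beta_e_z is required when gamma > 0")
        term1 = stats.delta_bar * gamma * (stats.beta_e_z - 1.0)
    term2 = 0.0
    if stats.delta_cap is not None:
        term2 = stats.beta_delta_z * stats.delta_cap
    return h2 * (1.0 + term1 + term2)


def expected_h2_random(h2: float, delta_bar: float) -> float:
    """Expected estimate under trait-independent EPP: h2 * (1 - delta_bar)."""
    if not 0.0 <= delta_bar <= 1.0:
        raise ValueError("delta_bar must lie in [0, 1]")
    return h2 * (1.0 - delta_bar)
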