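"""Factorial simulation experiment: heritability bias across EPP scenarios.

One experimental *cell* is a (true heritability, scenario, strength) triple.
Each replicate draws a fresh trait down the social pedigree, permutes
paternity under the scenario, re-derives extra-pair young's traits, and
estimates heritability on both the resulting genetic pedigree (the truth)
and the social pedigree (the observed, partly wrong one).  The cell-level
summaries of the raw and proportional estimate differences reproduce the
qualitative structure of the bias: it grows with heritability, grows with
strength under cuckoldry-linked scenarios, and shrinks when males are
cuckolded by similar males.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genedrop import simulate_trait
from .heritability import (RelationshipEigen, h2_animal_model_reml,
                           h2_father_offspring, relationship_eigen)
from .pedigree import Pedigree, additive_relationship
from .permutation import EppScenario, permute_paternity
from .synthetic import SyntheticPopulation
from .theory import compute_bias_statistics

__all__ = ["run_cell", "run_grid", "summarize"]

log = logging.getLogger(__name__)

_STAT_FIELDS = ("delta_bar", "gamma", "beta_e_z", "beta_delta_z",
                "delta_cap", "sd_diff")


def _replicate_rng(seed: int, cell: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cell, rep)))


def run_cell(social: Pedigree, n_events_per_year: Mapping[int, int],
             p_additional: float, h2: float, scenario: EppScenario,
             n_reps: int, seed: int, estimator: str = "reml",
             social_eig: Optional[RelationshipEigen] = None,
             cell_index: int = 0) -> pd.DataFrame:
    """Simulate one grid cell and return one row per replicate.

    ``estimator`` selects the animal-model REML fit (default) or the cheap
    father-offspring regression ("regression"); the regression columns are
    emitted in both cases.  Pass ``social_eig`` to reuse the social
    pedigree's relationship eigendecomposition across cells.
    """
    if estimator not in ("reml", "regression"):
        raise ValueError("estimator must be 'reml' or 'regression'")
    reml = estimator == "reml"
    if reml and social_eig is None:
        rel = additive_relationship(social, "social")
        social_eig = relationship_eigen(rel, social.ids)
    rows = []
    for rep in range(n_reps):
        rng = _replicate_rng(seed, cell_index, rep)
        try:
            rows.append(_one_replicate(social, n_events_per_year,
                                       p_additional, h2, scenario, rep,
                                       rng, reml, social_eig))
        except Exception:
            log.exception("replicate %d of cell (h2=%s, %s, beta=%s) failed",
                          rep, h2, scenario.scenario_id, scenario.beta)
    if not rows:
        raise RuntimeError("every replicate in the cell failed")
    df = pd.DataFrame(rows)
    df.insert(0, "h2_true", h2)
    df.insert(1, "scenario_id", scenario.scenario_id)
    df.insert(2, "beta", scenario.beta)
    df.insert(3, "lam", scenario.lam)
    return df


def _one_replicate(social, n_events_per_year, p_additional, h2, scenario,
                   rep, rng, reml, social_eig) -> dict:
    traits = simulate_trait(social, "social", h2, rng)
    genetic, traits2, events = permute_paternity(
        social, traits, scenario, n_events_per_year, p_additional, rng)
    stats = compute_bias_statistics(social, genetic, traits2)
    row: dict = {"replicate": rep, "n_events": len(events)}
    row.update({k: stats.as_dict()[k] for k in _STAT_FIELDS})
    reg_g = h2_father_offspring(genetic, "genetic", traits2)
    reg_s = h2_father_offspring(social, "social", traits2)
    row["h2_reg_genetic"] = reg_g.h2_hat
    row["h2_reg_social"] = reg_s.h2_hat
    if reml:
        est_g = h2_animal_model_reml(genetic, "genetic", traits2)
        est_s = h2_animal_model_reml(social, "social", traits2,
                                     eig=social_eig)
        row["h2_hat_genetic"] = est_g.h2_hat
        row["h2_hat_social"] = est_s.h2_hat
    else:
        row["h2_hat_genetic"] = reg_g.h2_hat
        row["h2_hat_social"] = reg_s.h2_hat
    raw = row["h2_hat_genetic"] - row["h2_hat_social"]
    row["raw_diff"] = raw
    row["prop_diff"] = (100.0 * raw / row["h2_hat_genetic"]
                        if row["h2_hat_genetic"] > 0 else np.nan)
    row["prop_diff_true"] = 100.0 * raw / h2 if h2 > 0 else np.nan
    return row


def run_grid(population: SyntheticPopulation,
             h2_values: Sequence[float] = (0.1, 0.3, 0.5, 0.7),
             scenario_ids: Sequence[str] = ("i", "ii", "iii", "iv", "v"),
             betas: Sequence[float] = (0.0, 0.1, 0.2, 0.4, 0.8, 1.6),
             lam: Optional[float] = None,
             n_reps: int = 100, seed: int = 0,
             estimator: str = "reml") -> pd.DataFrame:
    """Run the full factorial experiment on a generated population."""
    if lam is None:
        lam = population.config.lambda_ref
    social = population.social
    social_eig = None
    if estimator == "reml":
        rel = additive_relationship(social, "social")
        social_eig = relationship_eigen(rel, social.ids)
    out = []
    cell = 0
    for h2 in h2_values:
        for sid in scenario_ids:
            for beta in betas:
                scenario = EppScenario(sid, beta=beta, lam=lam)
                out.append(run_cell(social, population.n_events_per_year,
                                    population.p_additional, h2, scenario,
                                    n_reps, seed, estimator, social_eig,
                                    cell_index=cell))
                cell += 1
    return pd.concat(out, ignore_index=True)


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-cell means and standard errors of the bias measures."""
    if rows.empty:
        raise ValueError("no rows to summarize")
    keys = ["h2_true", "scenario_id", "beta"]
    cols = ["raw_diff", "prop_diff", "prop_diff_true",
            "h2_hat_genetic", "h2_hat_social", *_STAT_FIELDS]
    cols = [c for c in cols if c in rows.columns]

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {"n_reps": len(g)}
        for c in cols:
            x = g[c].dropna().to_numpy(dtype=float)
            out[f"{c}_mean"] = x.mean() if x.size else np.nan
            out[f"{c}_se"] = (x.std(ddof=1) / np.sqrt(x.size)
                              if x.size > 1 else np.nan)
        return pd.Series(out)

    res = (rows.groupby(keys, sort=True)[rows.columns]
           .apply(_agg, include_groups=False).reset_index())
    res["n_reps"] = res["n_reps"].astype(int)
    return res
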