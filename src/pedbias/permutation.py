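"""Draw extra-pair paternity events under a logit-linear mating model.

The probability that male *i* sires extra-pair young in the brood of social
father *j* is proportional to

    exp(lambda * d_ij + beta * f(z_i, z_j))

normalized over all ordered pairs of males observed that year (i != j), where
d_ij is the Euclidean nest distance, z a unit-variance phenotype, beta the
strength of the phenotype effect (interpretable as a standardized selection
gradient for the linear scenarios) and lambda the rate of change of extra-pair
success with distance (negative values make distant pairs less likely).

Five scenario score functions f are supported:

    i    z_i            larger males gain extra-pair paternity
    ii   -z_j           larger males suffer less cuckoldry
    iii  z_i - z_j      both effects combined
    iv   |z_i - z_j|    males cuckold the most dissimilar males
    v    -|z_i - z_j|   males cuckold the most similar males

Events are drawn sequentially without replacement on the social-father slot: a
social father can be subject to at most one extra-pair event per run, while
the same male may gain paternity in any number of events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genedrop import TraitRealization, _as_rng
from .pedigree import MALE, Pedigree

__all__ = [
    "EppScenario",
    "EpEvent",
    "pair_weights",
    "draw_ep_events",
    "assign_epy",
    "permute_paternity",
    "ep_selection_gradient",
]

_SCORES: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "i": lambda zi, zj: zi + 0.0 * zj,
    "ii": lambda zi, zj: -zj + 0.0 * zi,
    "iii": lambda zi, zj: zi - zj,
    "iv": lambda zi, zj: np.abs(zi - zj),
    "v": lambda zi, zj: -np.abs(zi - zj),
}


@dataclass(frozen=True)
class EppScenario:
    """A mode of trait-dependent extra-pair paternity.

    ``scenario_id`` selects the score function f(z_i, z_j) (see module
    docstring), ``beta`` its strength, and ``lam`` the distance coefficient.
    """

    scenario_id: str
    beta: float = 0.0
    lam: float = 0.0

    def __post_init__(self):
        if self.scenario_id not in _SCORES:
            raise ValueError(f"unknown scenario {self.scenario_id!r}; "
                             f"expected one of {sorted(_SCORES)}")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def score(self, z_epm: np.ndarray, z_father: np.ndarray) -> np.ndarray:
        """f evaluated on the outer grid of EPM x social-father phenotypes."""
        zi = np.asarray(z_epm, dtype=float)[:, None]
        zj = np.asarray(z_father, dtype=float)[None, :]
        return _SCORES[self.scenario_id](zi, zj)


@dataclass(frozen=True)
class EpEvent:
    """One realized extra-pair event: an EPM siring young in a rival's brood."""

    year: int
    social_father: str
    extra_pair_male: str
    brood: Optional[str]
    reassigned_offspring: frozenset[str]

    def __post_init__(self):
        if self.extra_pair_male == self.social_father:
            raise ValueError("the extra-pair male cannot be the social father")
        if not self.reassigned_offspring:
            raise ValueError("an extra-pair event must reassign at least one "
                             "offspring")


def _exponent(scenario: EppScenario, z_epm, z_father, dist) -> np.ndarray:
    expo = scenario.beta * scenario.score(z_epm, z_father)
    if scenario.lam != 0.0:
        if dist is None or np.isnan(dist).any():
            raise ValueError("a nonzero distance coefficient requires "
                             "locations for every male")
        expo = expo + scenario.lam * np.asarray(dist, dtype=float)
    if not np.all(np.isfinite(expo)):
        raise ValueError("extra-pair weights are not finite; rescale beta or "
                         "lambda")
    return expo


def _weight_matrix(scenario: EppScenario, z_epm, z_father, dist,
                   self_pair: Optional[np.ndarray]) -> np.ndarray:
    """Unnormalized weights; self pairs (i == j) forced to zero."""
    expo = _exponent(scenario, z_epm, z_father, dist)
    w = np.exp(expo - expo.max())  # shift-invariant after normalization
    if self_pair is not None:
        w = np.where(self_pair, 0.0, w)
    if w.sum() <= 0:
        raise ValueError("all extra-pair weights vanished; rescale beta or "
                         "lambda")
    return w


def pair_weights(males: Sequence[str], phenotypes: Mapping[str, float],
                 scenario: EppScenario,
                 locations: Optional[Mapping[str, tuple[float, float]]] = None,
                 ) -> pd.DataFrame:
    """Normalized probability of every ordered (EPM, social father) pair.

    Rows index the potential extra-pair male i, columns the social father j;
    the diagonal (i == j) is excluded and the remaining entries sum to one.
    """
    ids = list(males)
    if len(ids) < 2:
        raise ValueError("at least two males are required")
    z = np.array([phenotypes[i] for i in ids], dtype=float)
    dist = None
    if scenario.lam != 0.0:
        if locations is None:
            raise ValueError("a nonzero distance coefficient requires "
                             "locations for every male")
        xy = np.array([locations[i] for i in ids], dtype=float)
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
    eye = np.eye(len(ids), dtype=bool)
    w = _weight_matrix(scenario, z, z, dist, eye)
    w = w / w.sum()
    return pd.DataFrame(w, index=ids, columns=ids)


def assign_epy(brood_offspring: Sequence[str], p_additional: float,
               seed: Union[int, np.random.Generator, None] = None,
               max_n: Optional[int] = None) -> frozenset[str]:
    """Choose which brood members become extra-pair young for one event.

    One uniformly chosen offspring is always reassigned; every other brood
    member follows independently with probability ``p_additional``.
    ``max_n`` optionally caps the number reassigned (used when calibrating a
    pedigree to an exact extra-pair young count).
    """
    if not brood_offspring:
        raise ValueError("brood must be non-empty")
    if not 0.0 <= p_additional <= 1.0:
        raise ValueError("p_additional must lie in [0, 1]")
    rng = _as_rng(seed)
    ids = list(brood_offspring)
    first = ids[rng.integers(len(ids))]
    chosen = [first]
    for other in ids:
        if other != first and rng.random() < p_additional:
            chosen.append(other)
    if max_n is not None:
        chosen = chosen[:max(1, max_n)]
    return frozenset(chosen)


def draw_ep_events(weights: pd.DataFrame, n_events: int,
                   brood_map: Mapping[str, tuple[Optional[str], Sequence[str]]],
                   seed: Union[int, np.random.Generator, None] = None,
                   p_additional: float = 0.0,
                   year: int = 0) -> list[EpEvent]:
    """Sequentially draw extra-pair events from a pair-weight table.

    ``weights`` has potential EPMs as rows and social fathers as columns (as
    from :func:`pair_weights`, possibly restricted).  After each draw every
    pair involving the drawn social father is removed and the remainder is
    renormalized, so no social father is hit twice; the same EPM may recur.
    ``brood_map`` gives each father's (brood id, offspring ids).
    """
    rng = _as_rng(seed)
    fathers = [c for c in weights.columns if c in brood_map and
               len(brood_map[c][1]) > 0]
    if n_events > len(fathers):
        raise ValueError(f"cannot draw {n_events} events for "
                         f"{len(fathers)} eligible social fathers")
    w = weights.loc[:, fathers].to_numpy(dtype=float).copy()
    epm_ids = list(weights.index)
    events: list[EpEvent] = []
    active = np.ones(len(fathers), dtype=bool)
    for _ in range(n_events):
        cur = w[:, active]
        total = cur.sum()
        if total <= 0:
            raise ValueError("all remaining extra-pair weights vanished; "
                             "rescale beta or lambda")
        flat = cur.ravel() / total
        pick = rng.choice(flat.size, p=flat)
        r, c_local = divmod(pick, cur.shape[1])
        c = np.nonzero(active)[0][c_local]
        father = fathers[c]
        brood, offspring = brood_map[father]
        chosen = assign_epy(offspring, p_additional, rng)
        events.append(EpEvent(year=year, social_father=father,
                              extra_pair_male=epm_ids[r], brood=brood,
                              reassigned_offspring=chosen))
        active[c] = False
    return events


def _year_context(pedigree: Pedigree, year: int, min_age_gap: int,
                  exclude_fathers: set[str]):
    """Offspring broods and candidate males for one cohort year."""
    offspring = [k for k in range(len(pedigree))
                 if pedigree.cohort[k] == year and
                 pedigree.social_sire_idx[k] >= 0]
    brood_map: dict[str, tuple[Optional[str], list[str]]] = {}
    for k in offspring:
        father = pedigree.ids[pedigree.social_sire_idx[k]]
        if father in exclude_fathers:
            continue
        brood_map.setdefault(father, (pedigree.brood[k], []))[1].append(
            pedigree.ids[k])
    candidates = [pedigree.ids[k] for k in range(len(pedigree))
                  if pedigree.sex[k] == MALE and
                  pedigree.cohort[k] <= year - min_age_gap]
    return brood_map, candidates


def permute_paternity(social: Pedigree, traits: TraitRealization,
                      scenario: EppScenario,
                      n_events_per_year: Mapping[int, int],
                      p_additional: float,
                      seed: Union[int, np.random.Generator, None] = None,
                      min_age_gap: int = 1,
                      ) -> tuple[Pedigree, TraitRealization, list[EpEvent]]:
    """Simulate a genetic pedigree by drawing extra-pair events year by year.

    Cohorts are processed chronologically; the events of year t are drawn
    from the phenotypes current at t, and the reassigned offspring (and their
    descendants) have their trait values re-derived before any later year is
    processed, so that trait-dependent mating in later years sees the updated
    phenotypes.  The returned genetic pedigree equals ``social`` except for
    the extra-pair young's sire links.
    """
    rng = _as_rng(seed)
    mapping: dict[str, Optional[str]] = {
        ind.id: ind.social_sire_id for ind in social}
    used_fathers: set[str] = set()
    events: list[EpEvent] = []
    pos = {i: k for k, i in enumerate(social.ids)}
    # breeding values are maintained on index arrays and the pedigree object
    # is materialized once at the end; the result is identical to applying
    # recompute_after_reassignment after every year (same topological math)
    dam = social.dam_idx
    gsire = social.social_sire_idx.copy()
    order = social.topological_order()
    a = traits.a.copy()
    eps = traits.eps
    m = traits.m
    years = sorted(y for y, n in n_events_per_year.items() if n > 0)
    for year in years:
        n_events = n_events_per_year[year]
        brood_map, candidates = _year_context(social, year, min_age_gap,
                                              used_fathers)
        if n_events > len(brood_map):
            raise ValueError(
                f"year {year}: {n_events} events requested but only "
                f"{len(brood_map)} social fathers are available")
        fathers = sorted(brood_map)
        z = a + eps
        z_epm = np.array([z[pos[i]] for i in candidates])
        z_fa = np.array([z[pos[j]] for j in fathers])
        dist = None
        if scenario.lam != 0.0:
            xy_epm = np.array([social.xy[pos[i]] for i in candidates])
            xy_fa = np.array([social.xy[pos[j]] for j in fathers])
            diff = xy_epm[:, None, :] - xy_fa[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=-1))
        self_pair = (np.asarray(candidates, dtype=object)[:, None]
                     == np.asarray(fathers, dtype=object)[None, :])
        w = _weight_matrix(scenario, z_epm, z_fa, dist, self_pair)
        table = pd.DataFrame(w, index=candidates, columns=fathers)
        year_events = draw_ep_events(table, n_events, brood_map, rng,
                                     p_additional, year)
        dirty = np.zeros(len(social), dtype=bool)
        for ev in year_events:
            used_fathers.add(ev.social_father)
            for off in ev.reassigned_offspring:
                mapping[off] = ev.extra_pair_male
                k = pos[off]
                gsire[k] = pos[ev.extra_pair_male]
                dirty[k] = True
        events.extend(year_events)
        if dirty.any():
            for k in order:
                s, d = gsire[k], dam[k]
                if not dirty[k] and ((s >= 0 and dirty[s]) or
                                     (d >= 0 and dirty[d])):
                    dirty[k] = True
                if dirty[k]:
                    a[k] = ((0.5 * a[s] if s >= 0 else 0.0)
                            + (0.5 * a[d] if d >= 0 else 0.0) + m[k])
    genetic = social.with_genetic_sires(mapping)
    traits_out = replace(traits, a=a, z=a + eps)
    return genetic, traits_out, events


def events_to_frame(events: Iterable[EpEvent]) -> pd.DataFrame:
    rows = [{"year": e.year, "social_father": e.social_father,
             "epm": e.extra_pair_male, "brood": e.brood,
             "n_epy": len(e.reassigned_offspring)} for e in events]
    return pd.DataFrame(rows, columns=["year", "social_father", "epm",
                                       "brood", "n_epy"])


def ep_selection_gradient(events: Iterable[EpEvent],
                          phenotypes: Mapping[str, float],
                          males: Sequence[str]) -> float:
    """Realized selection gradient of net extra-pair success on the trait.

    Per male: (extra-pair events gained) - (events lost as the cuckolded
    father), scaled by the mean event rate per male, regressed on phenotype
    by ordinary least squares.  For the linear scenarios with many males this
    recovers beta (scenario i) and 2*beta (scenario iii).
    """
    events = list(events)
    gain: dict[str, int] = {m: 0 for m in males}
    loss: dict[str, int] = {m: 0 for m in males}
    for e in events:
        if e.extra_pair_male in gain:
            gain[e.extra_pair_male] += 1
        if e.social_father in loss:
            loss[e.social_father] += 1
    rate = len(events) / len(males)
    if rate == 0:
        raise ValueError("no events: the gradient is undefined")
    z = np.array([phenotypes[m] for m in males], dtype=float)
    w = np.array([(gain[m] - loss[m]) / rate for m in males])
    zc = z - z.mean()
    return float((zc @ (w - w.mean())) / (zc @ zc))
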