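"""Synthetic breeding-population generator.

Emulates the shape of a multi-year nest-box study of a socially monogamous
passerine: an adults-only pedigree of founders plus locally recruited
offspring born over several cohorts, spatially clustered nests, and a
reference genetic pedigree created by trait-independent, distance-weighted
extra-pair events at a configured extra-pair-young rate, with extra-pair
young clustered within broods.  The defaults mirror the published structure
of the study population this package models: 960 founders, 593 offspring
over the six 2004-2009 cohorts, and a 12.5% extra-pair-young rate.

The generator returns everything the permutation engine conditions on: the
social pedigree, the reference genetic pedigree, the per-year extra-pair
event counts and the within-event probability that additional brood members
are also extra-pair young.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq

from .genedrop import _as_rng
from .pedigree import FEMALE, MALE, Individual, Pedigree
from .permutation import EppScenario, assign_epy, draw_ep_events, _weight_matrix

import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticPopulation", "generate_pedigree"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study population.

    Counts and the extra-pair rate default to the published structure of the
    modeled population; everything unpublished (brood sizes of recruited
    adults, nest spacing, the within-event probability of additional
    extra-pair young, the reference distance decay) is an explicit knob with
    a documented default.
    """

    n_founders: int = 960
    n_offspring: int = 593
    n_cohorts: int = 6
    first_cohort: int = 2004
    epy_rate: float = 0.125
    p_additional: float = 0.5
    brood_size_mean: float = 1.6     # recruited (adult) young per brood, min 1
    nest_spacing: float = 100.0      # metres between nest-box grid points
    nest_jitter: float = 10.0        # SD of positional jitter, metres
    lambda_ref: float = -0.011       # per-metre distance decay of EP events
    founder_lead_years: int = 3      # founder cohorts start this many years early

    def __post_init__(self):
        if not 0.0 <= self.epy_rate < 1.0:
            raise ValueError("epy_rate must lie in [0, 1)")
        if min(self.n_founders, self.n_offspring, self.n_cohorts) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.p_additional <= 1.0:
            raise ValueError("p_additional must lie in [0, 1]")
        if self.brood_size_mean <= 1.0:
            raise ValueError("brood_size_mean must exceed 1")

    @property
    def cohorts(self) -> range:
        return range(self.first_cohort, self.first_cohort + self.n_cohorts)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class SyntheticPopulation:
    """A generated social/genetic pedigree pair plus permutation inputs."""

    social: Pedigree
    genetic: Pedigree
    n_events_per_year: dict[int, int]
    p_additional: float
    config: SyntheticConfig
    seed: Optional[int]


def _truncated_poisson_mu(target_mean: float) -> float:
    """Rate mu of a zero-truncated Poisson with the requested mean."""
    return brentq(lambda mu: mu / (1.0 - np.exp(-mu)) - target_mean,
                  1e-9, 10.0 * target_mean)


def _split_quota(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` across cells."""
    raw = np.array(weights, dtype=float)
    raw = raw / raw.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base.tolist()


def generate_pedigree(config: SyntheticConfig = SyntheticConfig(),
                      seed: Union[int, np.random.Generator, None] = None,
                      ) -> SyntheticPopulation:
    """Generate a social pedigree and its reference genetic counterpart.

    Founders (half male) enter over ``founder_lead_years`` pre-study cohorts
    and the first ``n_cohorts - 1`` study cohorts, each with a fixed nest-box
    territory on a jittered grid.  Every study cohort forms breeding pairs
    among adults at least one year old (founders and earlier recruits alike,
    so multi-generation links arise), producing broods whose recruited sizes
    follow a zero-truncated Poisson.  The reference genetic pedigree then
    reassigns extra-pair young through phenotype-independent, distance-
    weighted events until each cohort hits its share of the target rate.
    """
    rng = _as_rng(seed)
    cohorts = list(config.cohorts)
    founder_cohorts = list(range(config.first_cohort - config.founder_lead_years,
                                 config.first_cohort + config.n_cohorts - 1))
    n_males = config.n_founders // 2
    n_females = config.n_founders - n_males

    # deterministic round-robin founder cohorts -> feasibility is checkable
    # before any sampling
    quotas = _split_quota(config.n_offspring,
                          [1.0] * config.n_cohorts)
    mu = _truncated_poisson_mu(config.brood_size_mean)
    avail_m = [sum(1 for k in range(n_males)
                   if founder_cohorts[k % len(founder_cohorts)] < t)
               for t in cohorts]
    avail_f = [sum(1 for k in range(n_females)
                   if founder_cohorts[k % len(founder_cohorts)] < t)
               for t in cohorts]
    for q, am, af, t in zip(quotas, avail_m, avail_f, cohorts):
        # every brood needs a distinct pair; +1 male so an EPM candidate exists
        if q > 0 and (am < q + 1 or af < q):
            raise ValueError(
                f"infeasible config: cohort {t} may need up to {q} breeding "
                f"pairs but only {am} founder males / {af} founder females "
                "are old enough")

    # nest-box grid large enough for every individual to own a territory
    total = config.n_founders + config.n_offspring
    g = int(np.ceil(np.sqrt(total)))
    boxes = (np.stack(np.meshgrid(np.arange(g), np.arange(g)), axis=-1)
             .reshape(-1, 2) * config.nest_spacing)
    box_order = rng.permutation(len(boxes))[:total]
    coords = boxes[box_order] + rng.normal(0.0, config.nest_jitter,
                                           size=(total, 2))

    inds: list[Individual] = []
    loc_iter = iter(range(total))
    males: list[str] = []
    females: list[str] = []
    for k in range(config.n_founders):
        sex = MALE if k < n_males else FEMALE
        kk = k if k < n_males else k - n_males
        ident = f"{'M' if sex == MALE else 'F'}{kk + 1:04d}"
        inds.append(Individual(
            id=ident, sex=sex,
            cohort=founder_cohorts[kk % len(founder_cohorts)],
            location=tuple(coords[next(loc_iter)])))
        (males if sex == MALE else females).append(ident)

    by_id = {i.id: i for i in inds}
    offspring_count = 0
    for t, quota in zip(cohorts, quotas):
        if quota == 0:
            continue
        # brood sizes: zero-truncated Poisson, trimmed to hit the quota
        sizes: list[int] = []
        while sum(sizes) < quota:
            s = 0
            while s == 0:
                s = int(rng.poisson(mu))
            sizes.append(min(s, quota - sum(sizes)))
        pool_m = [m for m in males if by_id[m].cohort < t]
        pool_f = [f for f in females if by_id[f].cohort < t]
        if len(pool_m) < len(sizes) + 1 or len(pool_f) < len(sizes):
            raise ValueError(f"infeasible config: cohort {t} needs "
                             f"{len(sizes)} pairs")
        pair_m = rng.choice(pool_m, size=len(sizes), replace=False)
        pair_f = rng.choice(pool_f, size=len(sizes), replace=False)
        for b, (size, dad, mum) in enumerate(zip(sizes, pair_m, pair_f)):
            brood = f"B{t}-{b + 1:03d}"
            for c in range(size):
                offspring_count += 1
                sex = MALE if rng.random() < 0.5 else FEMALE
                ident = f"O{offspring_count:04d}"
                child = Individual(
                    id=ident, sex=sex, cohort=t, dam_id=str(mum),
                    social_sire_id=str(dad), genetic_sire_id=str(dad),
                    brood_id=brood, location=tuple(coords[next(loc_iter)]))
                inds.append(child)
                by_id[ident] = child
                (males if sex == MALE else females).append(ident)
    social = Pedigree(inds)

    genetic, n_events = _reference_epp(social, config, rng)
    return SyntheticPopulation(social=social, genetic=genetic,
                               n_events_per_year=n_events,
                               p_additional=config.p_additional,
                               config=config,
                               seed=seed if isinstance(seed, int) else None)


def _reference_epp(social: Pedigree, config: SyntheticConfig,
                   rng: np.random.Generator) -> tuple[Pedigree, dict[int, int]]:
    """Trait-independent, distance-weighted EP events hitting the target rate."""
    scenario = EppScenario("i", beta=0.0, lam=config.lambda_ref)
    cohorts = list(config.cohorts)
    n_off = [int(np.sum((social.cohort == t) & (social.social_sire_idx >= 0)))
             for t in cohorts]
    target = int(round(config.epy_rate * sum(n_off)))
    epy_quota = _split_quota(target, [max(q, 1e-9) for q in n_off])

    pos = {i: k for k, i in enumerate(social.ids)}
    mapping: dict[str, Optional[str]] = {
        ind.id: ind.social_sire_id for ind in social}
    used_fathers: set[str] = set()
    n_events: dict[int, int] = {}
    for t, need in zip(cohorts, epy_quota):
        n_events[t] = 0
        while need > 0:
            brood_map: dict[str, tuple[Optional[str], list[str]]] = {}
            for k in np.nonzero(social.cohort == t)[0]:
                if social.social_sire_idx[k] < 0:
                    continue
                father = social.ids[social.social_sire_idx[k]]
                if father in used_fathers:
                    continue
                brood_map.setdefault(
                    father, (social.brood[k], []))[1].append(social.ids[k])
            if not brood_map:
                raise ValueError(f"infeasible config: cohort {t} ran out of "
                                 "social fathers before reaching the "
                                 "extra-pair target")
            fathers = sorted(brood_map)
            candidates = [social.ids[k] for k in range(len(social))
                          if social.sex[k] == MALE and social.cohort[k] <= t - 1]
            xy_c = np.array([social.xy[pos[i]] for i in candidates])
            xy_f = np.array([social.xy[pos[j]] for j in fathers])
            diff = xy_c[:, None, :] - xy_f[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=-1))
            self_pair = np.array([[i == j for j in fathers]
                                  for i in candidates])
            w = _weight_matrix(scenario, np.zeros(len(candidates)),
                               np.zeros(len(fathers)), dist, self_pair)
            table = pd.DataFrame(w, index=candidates, columns=fathers)
            ev = draw_ep_events(table, 1, brood_map, rng,
                                config.p_additional, year=t)[0]
            # trim the final event so the realized count matches the target
            chosen = sorted(ev.reassigned_offspring)[:need]
            used_fathers.add(ev.social_father)
            for off in chosen:
                mapping[off] = ev.extra_pair_male
            need -= len(chosen)
            n_events[t] += 1
    return social.with_genetic_sires(mapping), n_events
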