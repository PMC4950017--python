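"""Pedigree data model, I/O, additive relationship matrices and structure summaries.

A :class:`Pedigree` carries, for every individual, a maternal link and *two*
paternal links: the social sire (the male observed attending the brood) and the
genetic sire (the male that actually fathered the offspring).  The ``mode``
argument of most operations selects which paternal column defines the pedigree
("social" or "genetic").  An offspring whose two sires differ is an extra-pair
young (EPY); its genetic sire is the extra-pair male (EPM) and its social sire
is a cuckolded male.
"""

from __future__ import annotations

import io
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "RelationshipMatrix",
    "StructureSummary",
    "read_pedigree",
    "write_pedigree",
    "additive_relationship",
    "structure_summary",
]

MALE = "M"
FEMALE = "F"

_SEX_ALIASES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
}

_MISSING = {"", "NA", "na", "NaN", "nan", None}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts, ...)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``location`` is a planar (x, y) coordinate in metres (the bird's nest /
    territory position) or ``None`` when unknown; distance-dependent extra-pair
    models require it.
    """

    id: str
    sex: str
    cohort: int
    dam_id: Optional[str] = None
    social_sire_id: Optional[str] = None
    genetic_sire_id: Optional[str] = None
    brood_id: Optional[str] = None
    location: Optional[tuple[float, float]] = None


class Pedigree:
    """Validated, immutable collection of :class:`Individual` records.

    Validation enforces: unique ids, parent references resolve, sires are male
    and dams female, parents born strictly before offspring, no ancestral
    cycles under either paternal link mode, and brood members sharing dam and
    social sire.
    """

    def __init__(self, individuals: Iterable[Individual]):
        inds = list(individuals)
        ids = [i.id for i in inds]
        if len(set(ids)) != len(ids):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise PedigreeError(f"duplicate individual id(s): {dup}")
        self._individuals = tuple(inds)
        self._index = {i.id: k for k, i in enumerate(inds)}
        n = len(inds)
        self.ids = tuple(ids)
        self.sex = np.array([i.sex for i in inds])
        self.cohort = np.array([i.cohort for i in inds], dtype=int)
        self.dam_idx = self._link_array([i.dam_id for i in inds], "dam")
        self.social_sire_idx = self._link_array(
            [i.social_sire_id for i in inds], "social sire")
        self.genetic_sire_idx = self._link_array(
            [i.genetic_sire_id for i in inds], "genetic sire")
        self.brood = tuple(i.brood_id for i in inds)
        xy = np.full((n, 2), np.nan)
        for k, i in enumerate(inds):
            if i.location is not None:
                xy[k] = i.location
        self.xy = xy
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _link_array(self, parents: Sequence[Optional[str]], kind: str) -> np.ndarray:
        out = np.full(len(parents), -1, dtype=int)
        for k, p in enumerate(parents):
            if p is None:
                continue
            if p not in self._index:
                raise PedigreeError(
                    f"{kind} '{p}' of '{self.ids[k] if hasattr(self, 'ids') else self._individuals[k].id}'"
                    " is not in the pedigree")
            out[k] = self._index[p]
        return out

    def _validate(self) -> None:
        for kind, idx in (("dam", self.dam_idx),
                          ("social sire", self.social_sire_idx),
                          ("genetic sire", self.genetic_sire_idx)):
            want = FEMALE if kind == "dam" else MALE
            bad = np.nonzero((idx >= 0) & (self.sex[np.clip(idx, 0, None)] != want))[0]
            if bad.size:
                k = bad[0]
                raise PedigreeError(
                    f"{kind} '{self.ids[idx[k]]}' of '{self.ids[k]}' is not "
                    f"{'female' if want == FEMALE else 'male'}")
        for kind, idx in (("dam", self.dam_idx),
                          ("social sire", self.social_sire_idx),
                          ("genetic sire", self.genetic_sire_idx)):
            bad = np.nonzero((idx >= 0) &
                             (self.cohort[np.clip(idx, 0, None)] >= self.cohort))[0]
            if bad.size:
                # a cohort violation is the only way an ancestral cycle can
                # arise, so the (slow) cycle search runs only on this path
                for mode in ("social", "genetic"):
                    self._check_acyclic(mode)
                k = bad[0]
                raise PedigreeError(
                    f"{kind} '{self.ids[idx[k]]}' of '{self.ids[k]}' was not born "
                    "strictly before its offspring")
        groups: dict[str, list[int]] = defaultdict(list)
        for k, b in enumerate(self.brood):
            if b is not None:
                groups[b].append(k)
        for b, members in groups.items():
            dams = {self.dam_idx[k] for k in members}
            sires = {self.social_sire_idx[k] for k in members}
            if len(dams) > 1 or len(sires) > 1:
                raise PedigreeError(
                    f"brood '{b}' members do not share dam and social sire")

    def _check_acyclic(self, mode: str) -> None:
        sire = self.sire_idx(mode)
        n = len(self)
        state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 on stack, 2 done

        def parents(k: int):
            for p in (self.dam_idx[k], sire[k]):
                if p >= 0:
                    yield p

        for start in range(n):
            if state[start]:
                continue
            stack = [(start, parents(start))]
            state[start] = 1
            path = [start]
            while stack:
                k, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    state[k] = 2
                    stack.pop()
                    path.pop()
                    continue
                if state[nxt] == 1:
                    cyc = path[path.index(nxt):] + [nxt]
                    names = " -> ".join(self.ids[i] for i in cyc)
                    raise PedigreeError(
                        f"cyclic ancestry under {mode} links: {names}")
                if state[nxt] == 0:
                    state[nxt] = 1
                    path.append(nxt)
                    stack.append((nxt, parents(nxt)))

    # -- basic protocol -------------------------------------------------------

    def __len__(self) -> int:
        return len(self._individuals)

    def __iter__(self):
        return iter(self._individuals)

    def __getitem__(self, id: str) -> Individual:
        return self._individuals[self._index[id]]

    def index_of(self, id: str) -> int:
        return self._index[id]

    @property
    def individuals(self) -> tuple[Individual, ...]:
        return self._individuals

    def sire_idx(self, mode: str) -> np.ndarray:
        """Paternal link column as positional indices (-1 = unknown)."""
        if mode == "social":
            return self.social_sire_idx
        if mode == "genetic":
            return self.genetic_sire_idx
        raise ValueError(f"mode must be 'social' or 'genetic', got {mode!r}")

    @property
    def has_genetic_sires(self) -> bool:
        return bool(np.any(self.genetic_sire_idx >= 0))

    def topological_order(self) -> np.ndarray:
        """Indices sorted so every parent precedes its offspring.

        The strict parent-before-offspring cohort invariant makes a stable
        cohort sort sufficient.
        """
        return np.argsort(self.cohort, kind="stable")

    def founders(self, mode: str = "social") -> np.ndarray:
        sire = self.sire_idx(mode)
        return np.nonzero((self.dam_idx < 0) & (sire < 0))[0]

    def with_genetic_sires(self, mapping: Mapping[str, Optional[str]]) -> "Pedigree":
        """New pedigree with genetic sire links replaced for the mapped ids."""
        new = []
        for ind in self._individuals:
            if ind.id in mapping:
                new.append(Individual(
                    id=ind.id, sex=ind.sex, cohort=ind.cohort,
                    dam_id=ind.dam_id, social_sire_id=ind.social_sire_id,
                    genetic_sire_id=mapping[ind.id], brood_id=ind.brood_id,
                    location=ind.location))
            else:
                new.append(ind)
        return Pedigree(new)

    # -- I/O ------------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        def name(idx):
            return [self.ids[i] if i >= 0 else None for i in idx]

        return pd.DataFrame({
            "id": list(self.ids),
            "dam": name(self.dam_idx),
            "social_sire": name(self.social_sire_idx),
            "genetic_sire": name(self.genetic_sire_idx),
            "sex": self.sex,
            "cohort": self.cohort,
            "brood": list(self.brood),
            "x": self.xy[:, 0],
            "y": self.xy[:, 1],
        })


def _clean(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in _MISSING else s


def read_pedigree(source) -> Pedigree:
    """Read a pedigree table (CSV or TSV) into a validated :class:`Pedigree`.

    Expected columns: id, dam, social_sire, genetic_sire, sex, cohort, brood,
    x, y (header mandatory; missing values as empty fields or "NA").  Row
    order is irrelevant.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    required = {"id", "dam", "social_sire", "sex", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree table is missing columns: {sorted(missing)}")
    inds = []
    for _, row in df.iterrows():
        sex_raw = _clean(row["sex"])
        if sex_raw is None or sex_raw.lower() not in _SEX_ALIASES:
            raise PedigreeError(f"unrecognized sex {row['sex']!r} for id {row['id']!r}")
        x = _clean(row.get("x"))
        y = _clean(row.get("y"))
        loc = (float(x), float(y)) if x is not None and y is not None else None
        inds.append(Individual(
            id=str(row["id"]).strip(),
            sex=_SEX_ALIASES[sex_raw.lower()],
            cohort=int(row["cohort"]),
            dam_id=_clean(row["dam"]),
            social_sire_id=_clean(row["social_sire"]),
            genetic_sire_id=_clean(row.get("genetic_sire")),
            brood_id=_clean(row.get("brood")),
            location=loc,
        ))
    return Pedigree(inds)


def write_pedigree(pedigree: Pedigree, path) -> None:
    """Write the standard pedigree CSV (missing values as "NA")."""
    df = pedigree.to_frame()
    df.to_csv(path, index=False, na_rep="NA")


# -- additive relationships ---------------------------------------------------


@dataclass(frozen=True)
class RelationshipMatrix:
    """Expected additive relationship matrix A in topological order."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    _pos: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "_pos", {i: k for k, i in enumerate(self.ids)})

    def loc(self, ids: Sequence[str]) -> np.ndarray:
        """Submatrix for ``ids`` in the given order."""
        idx = np.array([self._pos[i] for i in ids])
        return self.matrix[np.ix_(idx, idx)]

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self._pos[a], self._pos[b]])


def additive_relationship(pedigree: Pedigree, mode: str = "social") -> RelationshipMatrix:
    """Expected additive relationship matrix by the recursive tabular method.

    Processing individuals parents-first: A_ii = 1 + A_{s,d}/2 (inbreeding is
    handled exactly) and A_ij = (A_{s,j} + A_{d,j})/2 for j earlier than i,
    with unknown parents contributing zero.
    """
    order = pedigree.topological_order()
    n = len(pedigree)
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    dam = pedigree.dam_idx
    sire = pedigree.sire_idx(mode)
    A = np.zeros((n, n))
    for k, i in enumerate(order):
        s, d = sire[i], dam[i]
        sp = pos[s] if s >= 0 else -1
        dp = pos[d] if d >= 0 else -1
        if sp >= 0 and dp >= 0:
            row = 0.5 * (A[sp, :k] + A[dp, :k])
            diag = 1.0 + 0.5 * A[sp, dp]
        elif sp >= 0:
            row = 0.5 * A[sp, :k]
            diag = 1.0
        elif dp >= 0:
            row = 0.5 * A[dp, :k]
            diag = 1.0
        else:
            row = None
            diag = 1.0
        if row is not None:
            A[k, :k] = row
            A[:k, k] = row
        A[k, k] = diag
    return RelationshipMatrix(tuple(pedigree.ids[i] for i in order), A)


# -- structure summaries ------------------------------------------------------


@dataclass(frozen=True)
class StructureSummary:
    """Paternity-related pedigree structure counts.

    Sib-pair conventions: a full-sib pair shares a known dam and a known sire;
    a maternal (paternal) half-sib pair shares a known dam (sire) without
    being a known full-sib pair.  Cuckoldry counts are ``None`` when the
    genetic sire column is entirely absent.
    """

    n_individuals_with_known_sire: int
    n_sires: int
    n_cuckolded_males: Optional[int]
    n_extra_pair_males: Optional[int]
    n_father_offspring_links: int
    n_full_sib_pairs: int
    n_paternal_half_sib_pairs: int
    n_maternal_half_sib_pairs: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _pairs(counts: Iterable[int]) -> int:
    return sum(c * (c - 1) // 2 for c in counts)


def structure_summary(pedigree: Pedigree, mode: str = "social",
                      reference: Optional[Pedigree] = None) -> StructureSummary:
    """Count the paternity-related links used to check permutation fidelity.

    ``reference`` optionally supplies the social links against which cuckoldry
    is scored (defaults to the pedigree's own social column); genetic links
    always come from ``pedigree``.
    """
    sire = pedigree.sire_idx(mode)
    dam = pedigree.dam_idx
    known = sire >= 0
    n_known = int(known.sum())
    n_sires = len(set(sire[known].tolist()))

    social_src = reference if reference is not None else pedigree
    if pedigree.has_genetic_sires:
        soc = np.array([social_src.social_sire_idx[social_src.index_of(i)]
                        for i in pedigree.ids])
        soc_ids = np.array([social_src.ids[s] if s >= 0 else "" for s in soc])
        gen = pedigree.genetic_sire_idx
        gen_ids = np.array([pedigree.ids[s] if s >= 0 else "" for s in gen])
        both = (soc_ids != "") & (gen_ids != "")
        epy = both & (soc_ids != gen_ids)
        n_cuck = len(set(soc_ids[epy].tolist()))
        n_epm = len(set(gen_ids[epy].tolist()))
    else:
        n_cuck = n_epm = None

    sire_groups: dict[int, int] = defaultdict(int)
    dam_groups: dict[int, int] = defaultdict(int)
    full_groups: dict[tuple[int, int], int] = defaultdict(int)
    for k in range(len(pedigree)):
        if sire[k] >= 0:
            sire_groups[sire[k]] += 1
        if dam[k] >= 0:
            dam_groups[dam[k]] += 1
        if sire[k] >= 0 and dam[k] >= 0:
            full_groups[(sire[k], dam[k])] += 1
    full = _pairs(full_groups.values())
    return StructureSummary(
        n_individuals_with_known_sire=n_known,
        n_sires=n_sires,
        n_cuckolded_males=n_cuck,
        n_extra_pair_males=n_epm,
        n_father_offspring_links=n_known,
        n_full_sib_pairs=full,
        n_paternal_half_sib_pairs=_pairs(sire_groups.values()) - full,
        n_maternal_half_sib_pairs=_pairs(dam_groups.values()) - full,
    )
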