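"""Encounter-history data model, I/O and structural transforms.

Multi-state mark--resight data: each marked individual is scored once per
annual occasion as undetected (0), detected in state 1 (failed or
non-breeder) or detected in state 2 (successful breeder, fledged at least
one nestling).  The module also implements the classic history-splitting
transform used to accommodate trap-dependence (a segment per release, with
an "age" class on recapture distinguishing the first occasion after a
release from later ones) and a minimal MARK-compatible ``.inp`` dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "OccasionSet",
    "EncounterHistory",
    "EncounterHistorySet",
    "HistorySegment",
    "SplitHistorySet",
    "read_encounter_table",
    "pool_identical_histories",
    "split_histories_for_trapdep",
    "write_mark_inp",
    "read_mark_inp",
    "annual_breeding_success",
]

SEXES = ("F", "M")
STATES = (1, 2)

FIRST_AFTER_RELEASE = "first-after-release"
LATER = "later"


@dataclass(frozen=True)
class OccasionSet:
    """Ordered annual sampling occasions.

    ``resighting_active[t]`` is False for occasions with no field effort:
    detection probability is structurally 0 there, but the occasion is kept
    so that one-interval survival indexing is preserved (the two nominal
    intervals around an inactive occasion jointly estimate a compound
    two-year survival).
    """

    years: tuple[int, ...]
    resighting_active: tuple[bool, ...]

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        active = tuple(bool(a) for a in self.resighting_active)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "resighting_active", active)
        if len(years) != len(active):
            raise ValueError("years and resighting_active must have equal length")
        if len(years) < 2:
            raise ValueError("need at least 2 occasions")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        if sum(active) < 2:
            raise ValueError("need at least 2 occasions with resighting active")

    @classmethod
    def from_years(cls, years: Iterable[int],
                   inactive: Iterable[int] = ()) -> "OccasionSet":
        years = tuple(years)
        inactive = set(inactive)
        return cls(years, tuple(y not in inactive for y in years))

    @property
    def n_occasions(self) -> int:
        return len(self.years)

    @property
    def n_intervals(self) -> int:
        return len(self.years) - 1

    def index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise KeyError(f"year {year} is not an occasion") from None

    def active_indices(self) -> list[int]:
        return [t for t, a in enumerate(self.resighting_active) if a]

    def prev_active(self, t: int) -> int | None:
        """Most recent occasion before ``t`` with resighting effort."""
        for u in range(t - 1, -1, -1):
            if self.resighting_active[u]:
                return u
        return None


@dataclass(frozen=True)
class EncounterHistory:
    individual_id: str
    sex: str
    observations: tuple[int, ...]

    def __post_init__(self) -> None:
        obs = tuple(int(o) for o in self.observations)
        object.__setattr__(self, "observations", obs)
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if any(o not in (0, 1, 2) for o in obs):
            raise ValueError("observation codes must be in {0,1,2}")
        if not any(obs):
            raise ValueError("history must contain at least one detection")

    @property
    def first_capture(self) -> int:
        return next(t for t, o in enumerate(self.observations) if o)

    @property
    def detections(self) -> list[int]:
        return [t for t, o in enumerate(self.observations) if o]


@dataclass(frozen=True)
class EncounterHistorySet:
    occasions: OccasionSet
    histories: tuple[EncounterHistory, ...]
    weights: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        hists = tuple(self.histories)
        object.__setattr__(self, "histories", hists)
        w = self.weights or tuple(1 for _ in hists)
        w = tuple(int(x) for x in w)
        object.__setattr__(self, "weights", w)
        if len(w) != len(hists):
            raise ValueError("weights length must match histories")
        if any(x <= 0 for x in w):
            raise ValueError("weights must be positive")
        if sum(w) == 0:
            raise ValueError("total weighted individuals must be > 0")
        T = self.occasions.n_occasions
        for h in hists:
            if len(h.observations) != T:
                raise ValueError(
                    f"history {h.individual_id} has length {len(h.observations)}, "
                    f"expected {T}")
            for t, o in enumerate(h.observations):
                if o and not self.occasions.resighting_active[t]:
                    raise ValueError(
                        f"history {h.individual_id}: detection at inactive "
                        f"occasion {self.occasions.years[t]}")

    @property
    def n_histories(self) -> int:
        return len(self.histories)

    @property
    def total_individuals(self) -> int:
        return sum(self.weights)

    @property
    def total_detections(self) -> int:
        return sum(w * sum(1 for o in h.observations if o)
                   for h, w in zip(self.histories, self.weights))


@dataclass(frozen=True)
class HistorySegment:
    """One release-to-next-detection slice of a parent history.

    ``observations`` covers the full study horizon, zero outside the
    segment.  ``recapture_class[t]`` is ``first-after-release`` exactly at
    the first active occasion after the release, ``later`` at every later
    occasion within the segment, and ``None`` outside it.
    """

    parent_id: str
    sex: str
    release_occasion: int
    observations: tuple[int, ...]
    recapture_class: tuple[str | None, ...]
    weight: int = 1


@dataclass(frozen=True)
class SplitHistorySet:
    occasions: OccasionSet
    segments: tuple[HistorySegment, ...]


# ---------------------------------------------------------------------------
# I/O

def read_encounter_table(path: str | Path,
                         occasions: OccasionSet) -> EncounterHistorySet:
    """Read a headered CSV/TSV of (individual_id, sex, year, state) rows.

    One row per detection; unobserved (individual, year) pairs are coded 0.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"individual_id": str})
    required = {"individual_id", "sex", "year", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"encounter table missing columns: {sorted(missing)}")

    year_to_idx = {y: t for t, y in enumerate(occasions.years)}
    seen: dict[tuple[str, int], int] = {}
    obs: dict[str, list[int]] = {}
    sex_of: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        ind = str(row.individual_id)
        if pd.isna(row.sex) or str(row.sex) not in SEXES:
            raise ValueError(
                f"row {i}: sex missing or invalid for individual {ind!r} "
                "(analyses are sex-structured)")
        sex = str(row.sex)
        year = int(row.year)
        if year not in year_to_idx:
            raise ValueError(f"row {i}: unknown year {year} for {ind!r}")
        state = int(row.state)
        if state not in STATES:
            raise ValueError(f"row {i}: state {state} outside {{1,2}} for {ind!r}")
        if (ind, year) in seen:
            raise ValueError(
                f"row {i}: duplicate encounter for ({ind!r}, {year})")
        seen[(ind, year)] = state
        if ind in sex_of and sex_of[ind] != sex:
            raise ValueError(f"row {i}: inconsistent sex for {ind!r}")
        sex_of[ind] = sex
        obs.setdefault(ind, [0] * occasions.n_occasions)
        obs[ind][year_to_idx[year]] = state

    histories = tuple(
        EncounterHistory(ind, sex_of[ind], tuple(codes))
        for ind, codes in obs.items())
    return EncounterHistorySet(occasions, histories)


def pool_identical_histories(hset: EncounterHistorySet) -> EncounterHistorySet:
    """Merge histories with identical (sex, observations), summing weights.

    Pooling preserves the total weight and, because the likelihood is a
    weighted sum of per-history terms, the weighted log-likelihood.
    """
    pooled: dict[tuple[str, tuple[int, ...]], list] = {}
    for h, w in zip(hset.histories, hset.weights):
        key = (h.sex, h.observations)
        if key in pooled:
            pooled[key][1] += w
        else:
            pooled[key] = [h, w]
    hists, weights = zip(*pooled.values())
    return EncounterHistorySet(hset.occasions, tuple(hists), tuple(weights))


def split_histories_for_trapdep(hset: EncounterHistorySet) -> SplitHistorySet:
    """Cut each history at every detection into release-conditioned segments.

    A segment runs from a detection occasion to the next detection
    (inclusive) or to the study end; the first *active* occasion after the
    release carries recapture class ``first-after-release``, all later
    in-segment occasions ``later``.
    """
    occ = hset.occasions
    T = occ.n_occasions
    segments: list[HistorySegment] = []
    for h, w in zip(hset.histories, hset.weights):
        dets = h.detections
        for k, rel in enumerate(dets):
            end = dets[k + 1] if k + 1 < len(dets) else T - 1
            obs = [0] * T
            cls: list[str | None] = [None] * T
            obs[rel] = h.observations[rel]
            if end > rel:
                obs[end] = h.observations[end]
            first_active = next(
                (t for t in range(rel + 1, T) if occ.resighting_active[t]),
                None)
            for t in range(rel + 1, end + 1):
                cls[t] = (FIRST_AFTER_RELEASE if t == first_active else LATER)
            segments.append(HistorySegment(
                h.individual_id, h.sex, rel, tuple(obs), tuple(cls), w))
    return SplitHistorySet(occ, tuple(segments))


# ---------------------------------------------------------------------------
# MARK .inp dialect: digit history, one frequency column per sex
# (female first, then male), terminated by ";".  "#" starts a comment.

def write_mark_inp(hset: EncounterHistorySet, path: str | Path) -> None:
    path = Path(path)
    pooled = pool_identical_histories(hset)
    lines = ["# encounter histories; columns: history freqF freqM"]
    order = sorted(
        zip(pooled.histories, pooled.weights),
        key=lambda hw: (hw[0].observations, hw[0].sex))
    for h, w in order:
        digits = "".join(str(o) for o in h.observations)
        f = w if h.sex == "F" else 0
        m = w if h.sex == "M" else 0
        lines.append(f"{digits} {f} {m};")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_mark_inp(path: str | Path,
                  occasions: OccasionSet) -> EncounterHistorySet:
    path = Path(path)
    histories: list[EncounterHistory] = []
    weights: list[int] = []
    counter = 0
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not line.endswith(";"):
            raise ValueError(f"malformed .inp line (missing ';'): {raw!r}")
        parts = line[:-1].split()
        if len(parts) != 3:
            raise ValueError(f"malformed .inp line: {raw!r}")
        digits, freq_f, freq_m = parts[0], int(parts[1]), int(parts[2])
        obs = tuple(int(c) for c in digits)
        for sex, freq in (("F", freq_f), ("M", freq_m)):
            if freq > 0:
                counter += 1
                histories.append(EncounterHistory(f"h{counter}", sex, obs))
                weights.append(freq)
    return EncounterHistorySet(occasions, tuple(histories), tuple(weights))


# ---------------------------------------------------------------------------

def annual_breeding_success(nest_records: pd.DataFrame) -> pd.Series:
    """Mean number of fledglings per initiated nest, per year.

    A nest counts only if at least one egg was laid (``initiated``); years
    with no initiated nest are returned as NaN (missing, not zero).
    Expected columns: year, nest_id, n_fledged, initiated.
    """
    df = nest_records
    required = {"year", "nest_id", "n_fledged", "initiated"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"nest table missing columns: {sorted(missing)}")
    if (df["n_fledged"] < 0).any():
        raise ValueError("n_fledged must be >= 0")
    init = df[df["initiated"].astype(bool)]
    means = init.groupby("year")["n_fledged"].mean()
    return means.reindex(sorted(df["year"].unique()))
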