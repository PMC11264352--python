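"""Generators with known truth for every input the pipeline consumes.

Three families: multi-state encounter histories (with trap-happiness, sex
structure and inactive occasions), biologging tracks built from
piecewise-constant activity schedules, and DEE covariate datasets.  Every
generator is driven by a single integer seed and reproduces its output
exactly for the same (truth, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .capture_data import EncounterHistory, EncounterHistorySet, OccasionSet
from .energy_budget import ActivityBudget, TrackRecord, ACTIVITIES
from .multistate_cmr import Params

__all__ = [
    "CmrTruth",
    "simulate_histories",
    "simulate_track",
    "DeeTruth",
    "simulate_dee_dataset",
    "middleton_like_occasions",
    "middleton_like_cmr_truth",
    "middleton_like_dee_truth",
]


# ---------------------------------------------------------------------------
# Encounter histories

@dataclass
class CmrTruth:
    """Generating parameters for encounter-history simulation.

    ``params`` holds the natural-scale arrays (phi[state, interval, sex],
    p[state, occasion, sex, trap_class], psi[from_state, interval, sex]);
    recruitment is uniform over active occasions unless a ramp of
    per-occasion recruitment weights is given.
    """

    params: Params
    seed: int = 0
    initial_state_p2: float = 0.5
    recruit_weights: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps({
            "phi": self.params.phi.tolist(),
            "p": self.params.p.tolist(),
            "psi": self.params.psi.tolist(),
            "seed": self.seed,
            "initial_state_p2": self.initial_state_p2,
            "recruit_weights": (None if self.recruit_weights is None
                                else np.asarray(self.recruit_weights).tolist()),
        })


def simulate_histories(truth: CmrTruth, n_individuals: int,
                       occasions: OccasionSet,
                       seed: int | None = None) -> EncounterHistorySet:
    """Simulate encounter histories under the multi-state model.

    Each individual recruits at a random active occasion in an initial
    state, then per interval survives (phi), transitions (psi) and is
    detected (p, trap-class aware, structurally 0 at inactive occasions).
    Individuals never detected are dropped, mirroring the conditioning of
    real encounter data on first capture.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    T = occasions.n_occasions
    phi, p, psi = truth.params.phi, truth.params.p, truth.params.psi
    if not (p > 0).any():
        raise ValueError("all detection probabilities are zero")
    active = np.array(occasions.resighting_active)
    recruit_pool = [t for t in range(T) if active[t]]
    if truth.recruit_weights is not None:
        wts = np.asarray(truth.recruit_weights, dtype=float)[recruit_pool]
        wts = wts / wts.sum()
    else:
        wts = np.full(len(recruit_pool), 1.0 / len(recruit_pool))

    recruit = rng.choice(recruit_pool, size=n_individuals, p=wts)
    sex = rng.integers(0, 2, size=n_individuals)          # 0=F 1=M
    state = 1 + (rng.random(n_individuals)
                 < truth.initial_state_p2).astype(int)     # 1 or 2
    alive = np.ones(n_individuals, dtype=bool)
    obs = np.zeros((n_individuals, T), dtype=np.int8)
    last_det_active = np.zeros(n_individuals, dtype=bool)

    for t in range(T):
        in_study = (recruit <= t)
        # detection at t
        if active[t]:
            trap_cls = np.where(last_det_active, 0, 1)
            ps = p[state - 1, t, sex, trap_cls]
            det = in_study & alive & (rng.random(n_individuals) < ps)
            # an individual's recruitment occasion is where it first becomes
            # available; detection there is stochastic like anywhere else
            obs[det, t] = state[det]
            last_det_active = det.copy()
        # survival + transition over interval t -> t+1
        if t < T - 1:
            sv = phi[state - 1, t, sex]
            survive = rng.random(n_individuals) < sv
            alive = alive & (~in_study | survive)
            move_p = psi[state - 1, t, sex]
            move = rng.random(n_individuals) < move_p
            flip = in_study & alive & move
            state = np.where(flip, 3 - state, state)

    keep = obs.any(axis=1)
    histories = tuple(
        EncounterHistory(f"sim{i}", "F" if sex[i] == 0 else "M",
                         tuple(int(x) for x in obs[i]))
        for i in np.flatnonzero(keep))
    return EncounterHistorySet(occasions, histories)


# ---------------------------------------------------------------------------
# Logger tracks

EARTH_R = 6_371_000.0

_ACTIVITY_SPEED = {"rest_land": 0.0, "surface_swim": 0.5,
                   "dive": 0.5, "fly": 15.0}
_ACTIVITY_ACC = {"rest_land": 0.02, "surface_swim": 0.15,
                 "dive": 0.35, "fly": 1.0}


@dataclass
class TrackNoise:
    gps_sigma_m: float = 0.0
    drop_rate: float = 0.0
    sampling_s: float = 30.0


def simulate_track(schedule: Sequence[tuple[str, float]],
                   noise: TrackNoise,
                   colony: tuple[float, float] = (-146.3, 59.4),
                   seed: int = 0,
                   depth_channel: bool = True,
                   position_channel: bool = True,
                   acc_channel: bool = False,
                   ) -> tuple[list[TrackRecord], ActivityBudget, list[str]]:
    """Simulate a logger track from an (activity, duration_h) schedule.

    Movement per activity: rest at the colony point; flight at 15 m/s with
    persistent heading; surface swimming at 0.5 m/s random walk; dives as
    2--40 m depth excursions while drifting at swim speed.  Gaussian
    position jitter and random fix dropping emulate GPS error.  Returns the
    samples, the true activity budget (schedule fractions) and the true
    per-sample labels.
    """
    for a, d in schedule:
        if a not in ACTIVITIES:
            raise ValueError(f"unknown activity {a!r}")
        if d <= 0:
            raise ValueError("durations must be > 0")
    total_h = sum(d for _, d in schedule)
    if total_h < 24.0:
        warnings.warn(
            f"schedule covers {total_h:g} h < 24 h; the budget filter "
            "will reject this deployment", stacklevel=2)
    rng = np.random.default_rng(seed)
    dt = noise.sampling_s
    lon0, lat0 = colony
    m_per_deg_lat = np.pi * EARTH_R / 180.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(lat0))

    records: list[TrackRecord] = []
    labels: list[str] = []
    t = 0.0
    x, y = 0.0, 0.0          # metres relative to colony
    heading = rng.uniform(0, 2 * np.pi)
    for activity, dur_h in schedule:
        n_steps = int(round(dur_h * 3600.0 / dt))
        speed = _ACTIVITY_SPEED[activity]
        if activity == "fly":
            heading = rng.uniform(0, 2 * np.pi)
        dive_phase = 0.0
        dive_depth = 0.0
        for _ in range(n_steps):
            if activity == "rest_land":
                x, y = 0.0, 0.0
                depth = 0.0
            else:
                if activity == "surface_swim" or activity == "dive":
                    heading += rng.normal(0, 0.5)
                # leave the colony radius promptly for at-sea activities
                r = np.hypot(x, y)
                if r < 400.0 and activity != "rest_land":
                    out = np.arctan2(y, x) if r > 0 else heading
                    x += max(speed, 1.0) * dt * np.cos(out)
                    y += max(speed, 1.0) * dt * np.sin(out)
                else:
                    x += speed * dt * np.cos(heading)
                    y += speed * dt * np.sin(heading)
                if activity == "dive":
                    if dive_phase <= 0:
                        dive_depth = rng.uniform(2.0, 40.0)
                        dive_phase = rng.uniform(30.0, 120.0)
                    depth = dive_depth
                    dive_phase -= dt
                else:
                    depth = 0.0
            if noise.drop_rate and rng.random() < noise.drop_rate:
                t += dt
                continue
            jx = rng.normal(0, noise.gps_sigma_m) if noise.gps_sigma_m else 0.0
            jy = rng.normal(0, noise.gps_sigma_m) if noise.gps_sigma_m else 0.0
            rec = TrackRecord(
                timestamp=t,
                lon=(lon0 + (x + jx) / m_per_deg_lon
                     if position_channel else None),
                lat=(lat0 + (y + jy) / m_per_deg_lat
                     if position_channel else None),
                depth_m=depth if depth_channel else None,
                dyn_acc=(abs(rng.normal(_ACTIVITY_ACC[activity],
                                        0.2 * _ACTIVITY_ACC[activity]))
                         if acc_channel else None),
            )
            records.append(rec)
            labels.append(activity)
            t += dt

    fractions = {a: 0.0 for a in ACTIVITIES}
    for a, d in schedule:
        fractions[a] += d / total_h
    truth = ActivityBudget(bird_id="truth", duration_h=total_h,
                           fractions=fractions)
    return records, truth, labels


# ---------------------------------------------------------------------------
# DEE covariate datasets

@dataclass
class DeeTruth:
    """Generating coefficients for the DEE covariate layer: per-year mean
    DEE (kJ/day), a linear adult-age slope (kJ/day per year of age) and a
    residual SD."""

    year_means: dict[int, float]
    adult_age_slope: float = 0.0
    brood_size_slope: float = 0.0
    brood_age_slope: float = 0.0
    sd: float = 150.0
    seed: int = 0


def simulate_dee_dataset(truth: DeeTruth,
                         n_per_year: dict[int, int] | int,
                         seed: int | None = None) -> pd.DataFrame:
    """Draw per-bird DEE records with covariates uniform over their
    observed field ranges (brood size 1-5, brood age 7-41 d, adult age
    0-15 y)."""
    if truth.sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    i = 0
    for year, mu in truth.year_means.items():
        n = n_per_year if isinstance(n_per_year, int) else n_per_year[year]
        for _ in range(n):
            brood_size = int(rng.integers(1, 6))
            brood_age = int(rng.integers(7, 42))
            adult_age = int(rng.integers(0, 16))
            dee = (mu + truth.adult_age_slope * adult_age
                   + truth.brood_size_slope * brood_size
                   + truth.brood_age_slope * brood_age
                   + rng.normal(0.0, truth.sd))
            rows.append({"bird_id": f"b{i}", "year": year, "sex": "M",
                         "dee_kj_day": dee, "brood_size": brood_size,
                         "brood_age_d": brood_age, "adult_age_y": adult_age})
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The study-like preset: 17 annual occasions (one with no resighting), two
# states, sex-structured detection with 2x trap-happiness, and the four-year
# DEE scenario.

def middleton_like_occasions() -> OccasionSet:
    return OccasionSet.from_years(range(2004, 2021), inactive=[2014])


def middleton_like_cmr_truth(seed: int = 0) -> CmrTruth:
    occ = middleton_like_occasions()
    T = occ.n_occasions
    rng = np.random.default_rng(12345)      # fixed scenario, not per-run
    phi = np.zeros((2, T - 1, 2))
    phi[0] = 0.80 + 0.08 * np.sin(np.arange(T - 1))[None, :, None][0]
    phi[1] = 0.75 + 0.10 * np.cos(np.arange(T - 1))[None, :, None][0]
    phi = np.clip(phi, 0.55, 0.95)
    psi = np.zeros((2, T - 1, 2))
    psi[0] = 0.35
    psi[1] = 0.20
    p_later = np.array([0.40, 0.45])        # state 1, state 2
    p_first = 2.0 * p_later                 # 2x trap-happiness
    p = np.zeros((2, T, 2, 2))
    for t in range(T):
        if occ.resighting_active[t]:
            for s in (0, 1):
                p[s, t, 0, 0] = p_first[s] * 0.95   # females slightly lower
                p[s, t, 1, 0] = p_first[s]
                p[s, t, 0, 1] = p_later[s] * 0.95
                p[s, t, 1, 1] = p_later[s]
    return CmrTruth(Params(phi=phi, p=p, psi=psi), seed=seed)


def middleton_like_dee_truth(seed: int = 0) -> DeeTruth:
    # four-year scenario with means taken from the study design it emulates
    return DeeTruth(
        year_means={2007: 1376.0, 2008: 1722.0, 2012: 1678.0, 2018: 1301.0},
        adult_age_slope=-15.0, sd=150.0, seed=seed)


MIDDLETON_N_PER_YEAR = {2007: 13, 2008: 13, 2012: 22, 2018: 10}
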