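"""Multi-state mark--resight likelihood, fitting, model selection and GOF.

The model is the standard two-observable-state Arnason--Schwarz model
written as a hidden Markov model over latent states {1, 2, dead},
conditioned on the state at first capture.  Per interval, an individual in
state r survives with probability Phi^r_t and, given survival, moves to the
other state with probability psi^{rs}_t (survive-then-move ordering).  Per
occasion after first capture, a live individual in state s is detected with
probability p^s_t; detection may additionally depend on a trap class
("first-after-release" at the first active occasion after a detection,
"later" otherwise), which corrects for trap-happiness.

Parameters live on the logit scale; effect structures are declarative
(subsets of {State, Time, Sex, TrapClass} with interactions) and translated
into treatment-coded design matrices.  Model selection uses AICc with a
three-stage cascade (p, then psi, then Phi).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .capture_data import (
    FIRST_AFTER_RELEASE,
    LATER,
    EncounterHistory,
    EncounterHistorySet,
    OccasionSet,
    SplitHistorySet,
)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelTable",
    "GofResult",
    "Params",
    "FitOptions",
    "build_design",
    "history_loglik",
    "split_loglik",
    "total_loglik",
    "fit_model",
    "aicc",
    "akaike_weights",
    "rank_models",
    "selection_cascade",
    "flag_confounded",
    "trapdep_test",
]

FACTORS = ("State", "Time", "Sex", "TrapClass")
PARAM_CLASSES = ("phi", "p", "psi")


# ---------------------------------------------------------------------------
# Model specification

def _parse_formula(formula: str) -> list[frozenset[str]]:
    """Parse ``"State*Time+Sex"`` into a sorted list of interaction terms.

    ``A*B`` expands to A, B and A:B (all non-empty subsets); ``"."`` or
    ``"1"`` denotes intercept-only.  Returned terms exclude the intercept.
    """
    formula = formula.strip()
    if formula in (".", "1", ""):
        return []
    terms: set[frozenset[str]] = set()
    for chunk in formula.split("+"):
        factors = [f.strip() for f in re.split(r"[*:]", chunk) if f.strip()]
        for f in factors:
            if f not in FACTORS:
                raise ValueError(f"unknown factor {f!r} in formula {formula!r}")
        if "*" in chunk:
            for r in range(1, len(factors) + 1):
                for sub in itertools.combinations(factors, r):
                    terms.add(frozenset(sub))
        elif ":" in chunk:
            terms.add(frozenset(factors))
        else:
            terms.add(frozenset(factors))
    order = {f: i for i, f in enumerate(FACTORS)}
    return sorted(terms, key=lambda t: (len(t), sorted(order[f] for f in t)))


@dataclass(frozen=True)
class ModelSpec:
    """Effect structure for (Phi, p, psi), e.g. ``Phi(State*Time)``.

    ``fixed`` maps a parameter class to a constant natural-scale value
    (e.g. ``{"p": 1.0}``), removing it from estimation and from K.
    Detection at inactive occasions is always fixed at 0 regardless.
    """

    phi: str = "State*Time"
    p: str = "TrapClass*State*Sex"
    psi: str = "State*Time"
    fixed: tuple[tuple[str, float], ...] = ()

    def formula(self, cls: str) -> str:
        return {"phi": self.phi, "p": self.p, "psi": self.psi}[cls]

    @property
    def fixed_map(self) -> dict[str, float]:
        return dict(self.fixed)

    @property
    def trap_aware(self) -> bool:
        return "TrapClass" in self.p

    @property
    def name(self) -> str:
        return (f"Phi({self.phi}) p({self.p}) Psi({self.psi})")

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        m = re.fullmatch(
            r"\s*Phi\(([^)]*)\)\s*p\(([^)]*)\)\s*Psi\(([^)]*)\)\s*", text)
        if not m:
            raise ValueError(f"cannot parse model spec {text!r}")
        return cls(phi=m.group(1), p=m.group(2), psi=m.group(3))


# ---------------------------------------------------------------------------
# Design: map beta coordinates to natural-scale parameter cells

@dataclass
class ClassDesign:
    cells: pd.DataFrame          # one row per estimable cell
    X: np.ndarray                # (n_cells, k) design matrix
    index: np.ndarray            # lookup array -> cell row (or -1 if fixed)
    fixed_value: float           # natural-scale value for fixed cells
    column_labels: list[str]

    @property
    def k(self) -> int:
        return 0 if self.X.size == 0 else self.X.shape[1]


@dataclass
class Design:
    occasions: OccasionSet
    spec: ModelSpec
    classes: dict[str, ClassDesign]
    slices: dict[str, slice]

    @property
    def k(self) -> int:
        return sum(cd.k for cd in self.classes.values())

    def param_arrays(self, beta: np.ndarray) -> "Params":
        out = {}
        for cls, cd in self.classes.items():
            sl = self.slices[cls]
            flat = np.zeros(cd.index.size)
            idx = cd.index.ravel()
            mask = idx >= 0
            if cd.k:
                cell_vals = expit(cd.X @ beta[sl])
                flat[mask] = cell_vals[idx[mask]]
            else:
                flat[mask] = cd.fixed_value
            # index -1 cells stay 0 (p at inactive occasions / occasion 0)
            out[cls] = flat.reshape(cd.index.shape)
        return Params(phi=out["phi"], p=out["p"], psi=out["psi"])


@dataclass
class Params:
    """Natural-scale parameter arrays.

    phi[state, interval, sex]; p[state, occasion, sex, trap_class];
    psi[from_state, interval, sex] (the single free off-diagonal per row:
    psi[0]=psi12, psi[1]=psi21).  Trap class 0 = first-after-release,
    1 = later.
    """

    phi: np.ndarray
    p: np.ndarray
    psi: np.ndarray

    @classmethod
    def constant(cls, occasions: OccasionSet, phi, p, psi,
                 p_first=None) -> "Params":
        """Build time/sex-constant parameter arrays from scalars or
        per-state pairs; ``p_first`` optionally sets the first-after-release
        detection probability (trap-dependence)."""
        T = occasions.n_occasions
        phi = np.broadcast_to(np.reshape(phi, (-1, 1, 1)), (2, T - 1, 2)).copy()
        psi = np.broadcast_to(np.reshape(psi, (-1, 1, 1)), (2, T - 1, 2)).copy()
        p_arr = np.zeros((2, T, 2, 2))
        p_later = np.broadcast_to(np.reshape(p, (-1, 1)), (2, 2))
        p_fst = p_later if p_first is None else \
            np.broadcast_to(np.reshape(p_first, (-1, 1)), (2, 2))
        for t in range(T):
            if occasions.resighting_active[t]:
                p_arr[:, t, :, 0] = p_fst
                p_arr[:, t, :, 1] = p_later
        return cls(phi=phi, p=p_arr, psi=psi)


_LEVELS = {"State": [1, 2], "Sex": ["F", "M"],
           "TrapClass": [FIRST_AFTER_RELEASE, LATER]}


def _class_design(cls: str, formula: str, occasions: OccasionSet,
                  fixed: dict[str, float]) -> ClassDesign:
    T = occasions.n_occasions
    if cls == "phi":
        time_levels = list(range(T - 1))
        shape = (2, T - 1, 2)
        grid = [(s, t, x) for s in (0, 1) for t in time_levels for x in (0, 1)]
    elif cls == "psi":
        time_levels = list(range(T - 1))
        shape = (2, T - 1, 2)
        grid = [(s, t, x) for s in (0, 1) for t in time_levels for x in (0, 1)]
    else:  # p: occasions 1..T-1, active only; trap classes
        time_levels = [t for t in range(1, T) if occasions.resighting_active[t]]
        shape = (2, T, 2, 2)
        grid = [(s, t, x, c) for s in (0, 1) for t in time_levels
                for x in (0, 1) for c in (0, 1)]

    index = -np.ones(shape, dtype=int)
    if cls in fixed:
        for cell in grid:
            index[cell] = 0  # marks a covered cell; value = fixed_value
        return ClassDesign(pd.DataFrame(), np.zeros((0, 0)), index,
                           float(fixed[cls]), [])

    terms = _parse_formula(formula)
    cells = pd.DataFrame(grid, columns=(
        ["State", "Time", "Sex"] if cls != "p"
        else ["State", "Time", "Sex", "TrapClass"]))
    cells["State"] = cells["State"] + 1
    cells["Sex"] = cells["Sex"].map({0: "F", 1: "M"})
    if cls == "p":
        cells["TrapClass"] = cells["TrapClass"].map(
            {0: FIRST_AFTER_RELEASE, 1: LATER})

    levels = dict(_LEVELS)
    levels["Time"] = time_levels
    for t in terms:
        for f in t:
            if f not in cells.columns:
                raise ValueError(
                    f"factor {f!r} not applicable to parameter class {cls!r}")
            if len(levels[f]) < 2:
                raise ValueError(f"factor {f!r} has a single level")

    cols = [np.ones(len(cells))]
    labels = ["(Intercept)"]
    for term in terms:
        factors = sorted(term, key=FACTORS.index)
        dummy_sets = []
        for f in factors:
            lv = levels[f]
            dummy_sets.append([
                (f"{f}[{v}]", (cells[f] == v).to_numpy(float))
                for v in lv[1:]])
        for combo in itertools.product(*dummy_sets):
            lab = ":".join(c[0] for c in combo)
            col = np.ones(len(cells))
            for _, c in combo:
                col = col * c
            cols.append(col)
            labels.append(lab)
    X = np.column_stack(cols)
    for row, cell in enumerate(grid):
        index[cell] = row
    return ClassDesign(cells, X, index, 0.0, labels)


def build_design(spec: ModelSpec, occasions: OccasionSet) -> Design:
    """Translate a ModelSpec into per-class design matrices and the map
    from (class, state, occasion, sex, trap class) to beta coordinates."""
    fixed = spec.fixed_map
    classes = {cls: _class_design(cls, spec.formula(cls), occasions, fixed)
               for cls in PARAM_CLASSES}
    slices = {}
    start = 0
    for cls in PARAM_CLASSES:
        k = classes[cls].k
        slices[cls] = slice(start, start + k)
        start += k
    return Design(occasions, spec, classes, slices)


# ---------------------------------------------------------------------------
# Likelihood

@dataclass
class PackedData:
    """Arrays extracted from an EncounterHistorySet for vectorised
    evaluation: observations, first captures, sex indices, weights, and the
    data-determined trap class per (history, occasion)."""

    obs: np.ndarray        # (n, T) int
    fc: np.ndarray         # (n,)
    sex: np.ndarray        # (n,) 0=F 1=M
    w: np.ndarray          # (n,)
    trap: np.ndarray       # (n, T) 0=first-after-release, 1=later
    occasions: OccasionSet


def pack_histories(hset: EncounterHistorySet) -> PackedData:
    occ = hset.occasions
    T = occ.n_occasions
    n = hset.n_histories
    obs = np.zeros((n, T), dtype=np.int8)
    sex = np.zeros(n, dtype=np.int8)
    for i, h in enumerate(hset.histories):
        obs[i] = h.observations
        sex[i] = 0 if h.sex == "F" else 1
    fc = np.argmax(obs > 0, axis=1)
    w = np.asarray(hset.weights, dtype=float)
    trap = np.ones((n, T), dtype=np.int8)
    for t in range(1, T):
        pa = occ.prev_active(t)
        if pa is not None:
            # first-after-release iff detected at the most recent active
            # occasion before t, and t is the first active occasion since
            first_since = all(not occ.resighting_active[u]
                              for u in range(pa + 1, t))
            if first_since:
                trap[:, t] = np.where(obs[:, pa] > 0, 0, 1)
    return PackedData(obs, fc, sex, w, trap, occ)


def _forward_loglik(packed: PackedData, params: Params) -> np.ndarray:
    """Log-likelihood per history via the scaled forward recursion over
    latent states {1, 2, dead}, conditioned on the first capture."""
    obs, fc, sex = packed.obs, packed.fc, packed.sex
    n, T = obs.shape
    alpha = np.zeros((n, 3))
    rows = np.arange(n)
    alpha[rows, obs[rows, fc] - 1] = 1.0
    logl = np.zeros(n)
    dead = np.zeros(n, dtype=bool)  # histories that hit probability zero
    phi, p, psi = params.phi, params.p, params.psi
    for t in range(1, T):
        act = fc < t
        if not act.any():
            continue
        it = t - 1
        phi1 = phi[0, it, sex]
        phi2 = phi[1, it, sex]
        ps12 = psi[0, it, sex]
        ps21 = psi[1, it, sex]
        a0, a1, a2 = alpha[:, 0], alpha[:, 1], alpha[:, 2]
        n0 = a0 * phi1 * (1.0 - ps12) + a1 * phi2 * ps21
        n1 = a0 * phi1 * ps12 + a1 * phi2 * (1.0 - ps21)
        n2 = a0 * (1.0 - phi1) + a1 * (1.0 - phi2) + a2
        c = packed.trap[:, t].astype(int)
        p1 = p[0, t, sex, c]
        p2 = p[1, t, sex, c]
        o = obs[:, t]
        det1 = o == 1
        det2 = o == 2
        nod = o == 0
        new0 = np.where(det1, n0 * p1, np.where(nod, n0 * (1.0 - p1), 0.0))
        new1 = np.where(det2, n1 * p2, np.where(nod, n1 * (1.0 - p2), 0.0))
        new2 = np.where(nod, n2, 0.0)
        upd = np.stack([new0, new1, new2], axis=1)
        alpha = np.where(act[:, None], upd, alpha)
        norm = alpha.sum(axis=1)
        bad = act & (norm <= 0.0)
        dead |= bad
        safe = np.where(norm > 0, norm, 1.0)
        scale = np.where(act & (norm > 0), safe, 1.0)
        alpha = alpha / scale[:, None]
        logl += np.where(act & (norm > 0), np.log(scale), 0.0)
    total = alpha.sum(axis=1)
    with np.errstate(divide="ignore"):
        logl += np.where(total > 0, np.log(np.where(total > 0, total, 1.0)),
                         -np.inf)
    logl[dead] = -np.inf
    return logl


def _loglik_and_grad(packed: PackedData, design: Design,
                     beta: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted log-likelihood and its analytic gradient w.r.t. beta.

    Forward--backward smoothing gives dlogL/dM_t(i,j) and dlogL/de_t(j)
    for every per-interval transition matrix entry and per-occasion
    emission entry; the chain rule maps those onto the natural-scale cells
    (phi, p, psi) and through the logit link onto beta.
    """
    params = design.param_arrays(beta)
    obs, fc, sex, w = packed.obs, packed.fc, packed.sex, packed.w
    n, T = obs.shape
    phi, p, psi = params.phi, params.p, params.psi
    rows = np.arange(n)

    # ---- forward pass, storing scaled alphas and scale factors
    alphas = np.zeros((T, n, 3))
    cs = np.ones((T, n))
    alpha = np.zeros((n, 3))
    alpha[rows, obs[rows, fc] - 1] = 1.0
    alphas[0] = alpha
    dead = np.zeros(n, dtype=bool)
    for t in range(1, T):
        act = fc < t
        it = t - 1
        phi1 = phi[0, it, sex]; phi2 = phi[1, it, sex]
        ps12 = psi[0, it, sex]; ps21 = psi[1, it, sex]
        a0, a1, a2 = alpha[:, 0], alpha[:, 1], alpha[:, 2]
        n0 = a0 * phi1 * (1 - ps12) + a1 * phi2 * ps21
        n1 = a0 * phi1 * ps12 + a1 * phi2 * (1 - ps21)
        n2 = a0 * (1 - phi1) + a1 * (1 - phi2) + a2
        c = packed.trap[:, t].astype(int)
        p1 = p[0, t, sex, c]; p2 = p[1, t, sex, c]
        o = obs[:, t]
        det1 = o == 1; det2 = o == 2; nod = o == 0
        e0 = np.where(det1, p1, np.where(nod, 1 - p1, 0.0))
        e1 = np.where(det2, p2, np.where(nod, 1 - p2, 0.0))
        e2 = np.where(nod, 1.0, 0.0)
        upd = np.stack([n0 * e0, n1 * e1, n2 * e2], axis=1)
        norm = upd.sum(axis=1)
        bad = act & (norm <= 0)
        dead |= bad
        safe = np.where(norm > 0, norm, 1.0)
        upd = upd / safe[:, None]
        alpha = np.where(act[:, None], upd, alpha)
        alphas[t] = alpha
        cs[t] = np.where(act & ~bad, safe, 1.0)
    if dead.any():
        return -np.inf, np.zeros(design.k)
    logl = np.log(cs[1:]).sum(axis=0)
    total_ll = float(np.dot(w, logl))

    # ---- backward pass with gradient accumulation into cell arrays
    g_phi = np.zeros_like(phi)
    g_p = np.zeros_like(p)
    g_psi = np.zeros_like(psi)
    b = np.ones((n, 3))
    for t in range(T - 1, 0, -1):
        act = fc < t
        if not act.any():
            continue
        it = t - 1
        phi1 = phi[0, it, sex]; phi2 = phi[1, it, sex]
        ps12 = psi[0, it, sex]; ps21 = psi[1, it, sex]
        c = packed.trap[:, t].astype(int)
        p1 = p[0, t, sex, c]; p2 = p[1, t, sex, c]
        o = obs[:, t]
        det1 = o == 1; det2 = o == 2; nod = o == 0
        e0 = np.where(det1, p1, np.where(nod, 1 - p1, 0.0))
        e1 = np.where(det2, p2, np.where(nod, 1 - p2, 0.0))
        e2 = np.where(nod, 1.0, 0.0)
        aprev = alphas[t - 1]
        ct = cs[t]
        eb0 = e0 * b[:, 0] / ct
        eb1 = e1 * b[:, 1] / ct
        eb2 = e2 * b[:, 2] / ct
        wact = w * act
        # G(i,j) = alpha_{t-1}(i) * e(j) * b(j) / c
        G00 = aprev[:, 0] * eb0; G01 = aprev[:, 0] * eb1
        G02 = aprev[:, 0] * eb2
        G10 = aprev[:, 1] * eb0; G11 = aprev[:, 1] * eb1
        G12 = aprev[:, 1] * eb2
        d_phi1 = (G00 * (1 - ps12) + G01 * ps12 - G02) * wact
        d_phi2 = (G10 * ps21 + G11 * (1 - ps21) - G12) * wact
        d_ps12 = phi1 * (G01 - G00) * wact
        d_ps21 = phi2 * (G10 - G11) * wact
        np.add.at(g_phi, (0, it, sex), d_phi1)
        np.add.at(g_phi, (1, it, sex), d_phi2)
        np.add.at(g_psi, (0, it, sex), d_ps12)
        np.add.at(g_psi, (1, it, sex), d_ps21)
        # E(j) = (alpha_{t-1} @ M)(j) * b(j) / c ; emissions e0,e1 depend on p
        m0 = aprev[:, 0] * phi1 * (1 - ps12) + aprev[:, 1] * phi2 * ps21
        m1 = aprev[:, 0] * phi1 * ps12 + aprev[:, 1] * phi2 * (1 - ps21)
        E0 = m0 * b[:, 0] / ct
        E1 = m1 * b[:, 1] / ct
        d_p1 = np.where(det1, E0, np.where(nod, -E0, 0.0)) * wact
        d_p2 = np.where(det2, E1, np.where(nod, -E1, 0.0)) * wact
        np.add.at(g_p, (0, t, sex, c), d_p1)
        np.add.at(g_p, (1, t, sex, c), d_p2)
        # b_{t-1}(i) = sum_j M(i,j) e(j) b(j) / c
        nb0 = phi1 * (1 - ps12) * eb0 + phi1 * ps12 * eb1 + (1 - phi1) * eb2
        nb1 = phi2 * ps21 * eb0 + phi2 * (1 - ps21) * eb1 + (1 - phi2) * eb2
        nb2 = eb2
        newb = np.stack([nb0, nb1, nb2], axis=1)
        b = np.where(act[:, None], newb, b)

    grad = np.zeros(design.k)
    g_arrays = {"phi": g_phi, "p": g_p, "psi": g_psi}
    for cls, cd in design.classes.items():
        if cd.k == 0:
            continue
        sl = design.slices[cls]
        idx = cd.index.ravel()
        mask = idx >= 0
        g_cells = np.zeros(cd.X.shape[0])
        np.add.at(g_cells, idx[mask], g_arrays[cls].ravel()[mask])
        eta = cd.X @ beta[sl]
        nat = expit(eta)
        grad[sl] = cd.X.T @ (g_cells * nat * (1.0 - nat))
    return total_ll, grad


def history_loglik(history: EncounterHistory, occasions: OccasionSet,
                   params: Params, trap_aware: bool = True) -> float:
    """Log-probability of one encounter history under the HMM.

    With ``trap_aware`` False, detection uses the "later" trap class
    everywhere (no trap-dependence).
    """
    hset = EncounterHistorySet(occasions, (history,))
    packed = pack_histories(hset)
    if not trap_aware:
        packed.trap = np.ones_like(packed.trap)
    val = float(_forward_loglik(packed, params)[0])
    if val == -np.inf:
        # keep a diagnostic trail for structurally impossible observations
        return -np.inf
    return val


def total_loglik(hset: EncounterHistorySet, params: Params,
                 trap_aware: bool = True) -> float:
    """Weighted sum of per-history log-likelihoods (-inf propagates)."""
    packed = pack_histories(hset)
    if not trap_aware:
        packed.trap = np.ones_like(packed.trap)
    ll = _forward_loglik(packed, params)
    if np.isneginf(ll).any():
        return -np.inf
    return float(np.dot(packed.w, ll))


def split_loglik(split: SplitHistorySet, params: Params) -> float:
    """Log-likelihood of split (Pradel-transformed) data: each segment is a
    release-conditioned pseudo-history whose recapture class is read from
    the segment labels rather than from the detection history.

    By the chain rule and the Markov property this equals the
    detection-augmented HMM likelihood of the original histories.
    """
    occ = split.occasions
    T = occ.n_occasions
    n = len(split.segments)
    obs = np.zeros((n, T), dtype=np.int8)
    sex = np.zeros(n, dtype=np.int8)
    w = np.zeros(n)
    trap = np.ones((n, T), dtype=np.int8)
    fc = np.zeros(n, dtype=int)
    for i, seg in enumerate(split.segments):
        obs[i] = seg.observations
        sex[i] = 0 if seg.sex == "F" else 1
        w[i] = seg.weight
        fc[i] = seg.release_occasion
        for t, c in enumerate(seg.recapture_class):
            if c == FIRST_AFTER_RELEASE:
                trap[i, t] = 0
    # Occasions beyond a segment's end (the next detection) belong to the
    # next segment and must not contribute: the segment end is treated as
    # the horizon.  A final segment with no further detection runs to the
    # study end and integrates over survival there.
    total = 0.0
    for i, seg in enumerate(split.segments):
        dets = [t for t in range(T) if seg.observations[t] > 0]
        end = dets[-1] if len(dets) > 1 else T - 1
        packed = PackedData(obs[i: i + 1, : end + 1], fc[i: i + 1],
                            sex[i: i + 1], w[i: i + 1],
                            trap[i: i + 1, : end + 1], occ)
        phi = params.phi[:, : end, :]
        psi = params.psi[:, : end, :]
        p = params.p[:, : end + 1, :, :]
        ll = _forward_loglik(packed, Params(phi, p, psi))[0]
        if ll == -np.inf:
            return -np.inf
        total += w[i] * ll
    return float(total)


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class FitOptions:
    start: np.ndarray | None = None
    multistart_n: int = 5
    tol: float = 1e-8
    seed: int = 0
    compute_se: bool = True
    jitter_sd: float = 0.5


@dataclass
class ModelFit:
    spec: ModelSpec
    design: Design
    beta: np.ndarray
    params: Params
    logL: float
    K: int
    ess: float
    AICc: float
    converged: bool
    grad_norm: float
    cov_beta: np.ndarray | None = None
    confounded: set[str] = field(default_factory=set)
    se_unreliable: bool = False
    n_starts_used: int = 1

    @property
    def deviance(self) -> float:
        return -2.0 * self.logL

    def estimates(self) -> pd.DataFrame:
        """Natural-scale estimates with delta-method SEs, one row per
        estimable parameter cell."""
        rows = []
        for cls in PARAM_CLASSES:
            cd = self.design.classes[cls]
            if cd.k == 0:
                continue
            sl = self.design.slices[cls]
            eta = cd.X @ self.beta[sl]
            est = expit(eta)
            if self.cov_beta is not None:
                cov = self.cov_beta[sl, sl]
                var_eta = np.einsum("ij,jk,ik->i", cd.X, cov, cd.X)
                se = np.sqrt(np.clip(var_eta, 0, None)) * est * (1.0 - est)
            else:
                se = np.full(len(est), np.nan)
            for i, (_, cell) in enumerate(cd.cells.iterrows()):
                row = {"class": cls, "estimate": est[i], "se": se[i]}
                row.update(cell.to_dict())
                rows.append(row)
        df = pd.DataFrame(rows)
        if not df.empty:
            df["label"] = [
                f"{r['class']}[state={r.get('State')},t={r.get('Time')},"
                f"sex={r.get('Sex')}"
                + (f",class={r['TrapClass']}" if "TrapClass" in r and
                   isinstance(r.get("TrapClass"), str) else "") + "]"
                for r in df.to_dict("records")]
            df["confounded"] = df["label"].isin(self.confounded)
        return df


def effective_sample_size(hset: EncounterHistorySet) -> float:
    """Weighted release-intervals: each individual contributes one unit per
    interval from its first capture to the end of the study."""
    T = hset.occasions.n_occasions
    return float(sum(w * (T - 1 - h.first_capture)
                     for h, w in zip(hset.histories, hset.weights)))


def aicc(logL: float, K: int, ess: float) -> float:
    """Small-sample Akaike criterion: -2logL + 2K + 2K(K+1)/(ess-K-1)."""
    if ess <= K + 1:
        raise ValueError(
            f"AICc undefined: effective sample size {ess} <= K+1 = {K + 1}")
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (ess - K - 1)


def fit_model(hset: EncounterHistorySet, spec: ModelSpec,
              options: FitOptions | None = None) -> ModelFit:
    """Maximise the weighted log-likelihood on the logit scale
    (quasi-Newton with multistarts), then attach SEs (inverse observed
    information, delta method), K, ESS and AICc."""
    options = options or FitOptions()
    design = build_design(spec, hset.occasions)
    packed = pack_histories(hset)
    if not spec.trap_aware:
        packed.trap = np.ones_like(packed.trap)
    k = design.k

    def neg_ll(beta: np.ndarray) -> float:
        params = design.param_arrays(beta)
        ll = _forward_loglik(packed, params)
        if np.isneginf(ll).any():
            return 1e12
        return -float(np.dot(packed.w, ll))

    def neg_ll_grad(beta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, grad = _loglik_and_grad(packed, design, beta)
        if not np.isfinite(ll):
            return 1e12, np.zeros(design.k)
        return -ll, -grad

    rng = np.random.default_rng(options.seed)
    starts = []
    if options.start is not None:
        starts.append(np.asarray(options.start, dtype=float))
    starts.append(np.zeros(k))
    while len(starts) < max(1, options.multistart_n):
        starts.append(rng.normal(0.0, options.jitter_sd, size=k))

    best = None
    for x0 in starts:
        if k == 0:
            class _R:  # degenerate: nothing to estimate
                x = np.zeros(0); fun = neg_ll(np.zeros(0))
                success = True; jac = np.zeros(0)
            res = _R()
        else:
            res = optimize.minimize(
                neg_ll_grad, x0, jac=True, method="L-BFGS-B",
                options={"maxiter": 2000, "ftol": 1e-12,
                         "gtol": max(options.tol, 1e-9)})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    assert best is not None
    beta = np.atleast_1d(np.asarray(best.x, dtype=float))
    logL = -float(best.fun)
    grad = np.atleast_1d(np.asarray(getattr(best, "jac", np.zeros(k))))
    converged = bool(getattr(best, "success", True)) and logL > -1e11

    cov = None
    se_unreliable = False
    if options.compute_se and k > 0 and converged:
        # observed information via central differences of the analytic
        # gradient (symmetrised)
        H = np.zeros((k, k))
        hs = 1e-5 * (1.0 + np.abs(beta))
        for i in range(k):
            e = np.zeros(k); e[i] = hs[i]
            gp = neg_ll_grad(beta + e)[1]
            gm = neg_ll_grad(beta - e)[1]
            H[i] = (gp - gm) / (2 * hs[i])
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) < 0):
                se_unreliable = True
                cov = np.abs(cov)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            se_unreliable = True
        # boundary estimates make the observed information unreliable
        nat_all = design.param_arrays(beta)
        for arr in (nat_all.phi, nat_all.psi):
            if np.any((arr > 1 - 1e-6) | (arr < 1e-6)):
                se_unreliable = True

    ess = effective_sample_size(hset)
    fit = ModelFit(spec=spec, design=design, beta=beta,
                   params=design.param_arrays(beta), logL=logL, K=k,
                   ess=ess, AICc=aicc(logL, k, ess), converged=converged,
                   grad_norm=float(np.linalg.norm(grad)), cov_beta=cov,
                   se_unreliable=se_unreliable,
                   n_starts_used=len(starts))
    return flag_confounded(fit)


def flag_confounded(fit: ModelFit) -> ModelFit:
    """Mark structurally confounded terminal parameters.

    In fully time-dependent models the survival over the final interval and
    the detection at the final occasion are identifiable only through their
    product; estimates are retained but labelled.  Intervals straddling an
    inactive occasion are flagged jointly confounded (only their product --
    the compound multi-year survival -- is identifiable).
    """
    occ = fit.design.occasions
    T = occ.n_occasions
    labels: set[str] = set()
    phi_time = "Time" in fit.spec.phi
    p_time = "Time" in fit.spec.p
    if phi_time and p_time:
        for s in (1, 2):
            for x in ("F", "M"):
                labels.add(f"phi[state={s},t={T - 2},sex={x}]")
                labels.add(f"p[state={s},t={T - 1},sex={x}]")
    if phi_time:
        for t in range(T):
            if not occ.resighting_active[t] and 0 < t < T - 1:
                for s in (1, 2):
                    for x in ("F", "M"):
                        labels.add(f"phi[state={s},t={t - 1},sex={x}]")
                        labels.add(f"phi[state={s},t={t},sex={x}]")
    fit.confounded = labels
    return fit


# ---------------------------------------------------------------------------
# Ranking and cascade

def akaike_weights(delta_aicc: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    d = np.asarray(delta_aicc, dtype=float)
    w = np.exp(-d / 2.0)
    return w / w.sum()


@dataclass
class ModelTable:
    fits: list[ModelFit]
    delta: np.ndarray
    weights: np.ndarray

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": [f.spec.name for f in self.fits],
            "AICc": [f.AICc for f in self.fits],
            "dAICc": self.delta,
            "weight": self.weights,
            "Np": [f.K for f in self.fits],
            "Deviance": [f.deviance for f in self.fits],
        })


def rank_models(fits: Iterable[ModelFit]) -> ModelTable:
    """Rank converged fits by AICc (ties by smaller K, then name)."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to rank")
    ok.sort(key=lambda f: (f.AICc, f.K, f.spec.name))
    aic = np.array([f.AICc for f in ok])
    delta = aic - aic[0]
    return ModelTable(ok, delta, akaike_weights(delta))


@dataclass
class CascadeResult:
    chosen_p: str
    chosen_psi: str
    phi_table: ModelTable
    stage_tables: dict[str, ModelTable]


def selection_cascade(hset: EncounterHistorySet,
                      p_candidates: Sequence[str],
                      psi_candidates: Sequence[str],
                      phi_candidates: Sequence[str],
                      full_phi: str = "State*Time",
                      full_psi: str = "State*Time",
                      options: FitOptions | None = None) -> CascadeResult:
    """Three-stage AICc selection: p (under full Phi/psi), then psi (under
    the chosen p and full Phi), then Phi (under the chosen p and psi)."""
    options = options or FitOptions(compute_se=False, multistart_n=1)
    stage_tables: dict[str, ModelTable] = {}

    def run_stage(specs: list[ModelSpec], name: str) -> ModelTable:
        fits = []
        for spec in specs:
            try:
                fits.append(fit_model(hset, spec, options))
            except Exception:
                continue
        converged = [f for f in fits if f.converged]
        if not converged:
            raise RuntimeError(
                f"selection cascade stage {name!r}: zero converged fits "
                f"out of {len(specs)} candidates")
        table = rank_models(converged)
        stage_tables[name] = table
        return table

    t1 = run_stage([ModelSpec(phi=full_phi, p=pc, psi=full_psi)
                    for pc in p_candidates], "p")
    chosen_p = t1.best.spec.p
    t2 = run_stage([ModelSpec(phi=full_phi, p=chosen_p, psi=pc)
                    for pc in psi_candidates], "psi")
    chosen_psi = t2.best.spec.psi
    t3 = run_stage([ModelSpec(phi=pc, p=chosen_p, psi=chosen_psi)
                    for pc in phi_candidates], "phi")
    return CascadeResult(chosen_p, chosen_psi, t3, stage_tables)


# ---------------------------------------------------------------------------
# Trap-dependence goodness of fit

@dataclass
class GofComponent:
    occasion: int
    state: int
    table: np.ndarray      # 2x2: rows detected at prev active occasion y/n,
    chi2: float            # cols detected at t y/n
    df: int
    pooled: bool = False


@dataclass
class GofResult:
    components: list[GofComponent]
    statistic: float
    df: int
    p_value: float
    direction: float       # >0: trap-happiness

    @property
    def reject(self) -> bool:
        return self.p_value < 0.05


def _pearson_chi2(table: np.ndarray) -> tuple[float, np.ndarray]:
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = rowsum * colsum / total
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0,
                           (table - expected) ** 2 / expected, 0.0)
    return float(contrib.sum()), expected


def trapdep_test(hset: EncounterHistorySet, alpha: float = 0.05,
                 min_expected: float = 2.0) -> GofResult:
    """Contingency diagnostic for trap-dependence (trap-happiness).

    For each interior active occasion t and departure state, among
    individuals first captured before t and detected again after t (hence
    known alive at t), cross-classify detection at the previous active
    occasion against detection at t.  Components with any expected cell
    below ``min_expected`` are pooled into a single leftover table
    (Cochran-style).  Positive direction = trap-happiness.
    """
    occ = hset.occasions
    T = occ.n_occasions
    if T < 3:
        raise ValueError("trap-dependence test needs at least 3 occasions")
    packed = pack_histories(hset)
    obs, fc, w = packed.obs, packed.fc, packed.w

    components: list[GofComponent] = []
    pooled_table = np.zeros((2, 2))
    pooled_any = False
    direction = 0.0

    det = obs > 0
    any_after = np.zeros_like(det)
    running = np.zeros(det.shape[0], dtype=bool)
    for t in range(T - 1, -1, -1):
        any_after[:, t] = running
        running = running | det[:, t]

    for t in range(1, T - 1):
        if not occ.resighting_active[t]:
            continue
        t0 = occ.prev_active(t)
        if t0 is None:
            continue
        eligible = (fc < t) & any_after[:, t] & (fc <= t0)
        if not eligible.any():
            continue
        # departure state: state at the most recent detection at or before t0
        last_state = np.zeros(det.shape[0], dtype=int)
        for u in range(t0 + 1):
            seen = obs[:, u] > 0
            last_state[seen] = obs[seen, u]
        for s in (1, 2):
            sel = eligible & (last_state == s)
            if not sel.any():
                continue
            a = det[sel, t0]
            b = det[sel, t]
            ww = w[sel]
            table = np.zeros((2, 2))
            table[0, 0] = ww[a & b].sum()
            table[0, 1] = ww[a & ~b].sum()
            table[1, 0] = ww[~a & b].sum()
            table[1, 1] = ww[~a & ~b].sum()
            if table.sum() == 0 or (table.sum(0) == 0).any() \
                    or (table.sum(1) == 0).any():
                continue
            chi2, expected = _pearson_chi2(table)
            dir_term = table[0, 0] - expected[0, 0]
            if expected.min() < min_expected:
                pooled_table += table
                pooled_any = True
                continue
            direction += dir_term
            components.append(GofComponent(t, s, table, chi2, 1))

    if pooled_any:
        tp = pooled_table
        if tp.sum() > 0 and not (tp.sum(0) == 0).any() \
                and not (tp.sum(1) == 0).any():
            chi2, expected = _pearson_chi2(tp)
            if expected.min() >= min_expected:
                direction += tp[0, 0] - expected[0, 0]
                components.append(GofComponent(-1, 0, tp, chi2, 1, pooled=True))

    if not components:
        raise ValueError("insufficient data: all components pooled away")
    statistic = sum(c.chi2 for c in components)
    df = sum(c.df for c in components)
    p = float(stats.chi2.sf(statistic, df))
    return GofResult(components, float(statistic), df, p, float(direction))
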