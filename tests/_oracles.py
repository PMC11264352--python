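"""Independent brute-force oracles used to validate the fast paths.

The latent-path enumerator below is deliberately written without reference
to the forward recursion: it sums, over every alive-state sequence and
death time, the explicit product of survival, transition and detection
terms.  Only usable for short histories (paths grow as 2^T).
"""

from __future__ import annotations

import itertools

import numpy as np

from repcost.capture_data import OccasionSet


def trap_classes(obs: np.ndarray, occ: OccasionSet) -> np.ndarray:
    """Data-determined recapture class per occasion: 0 (first after a
    release) iff the bird was detected at the most recent active occasion
    before t and no active occasion lies between; else 1."""
    T = len(obs)
    cls = np.ones(T, dtype=int)
    for t in range(1, T):
        prev_active = None
        for u in range(t - 1, -1, -1):
            if occ.resighting_active[u]:
                prev_active = u
                break
        if prev_active is None:
            continue
        gap_has_active = any(occ.resighting_active[u]
                             for u in range(prev_active + 1, t))
        if not gap_has_active and obs[prev_active] > 0:
            cls[t] = 0
    return cls


def enumerate_history_prob(obs, sex: int, occ: OccasionSet, params,
                           trap_aware: bool = True) -> float:
    """P(history | first capture) by explicit enumeration of latent paths.

    A path is (last occasion alive `a_last`, state sequence from first
    capture through a_last).  Death, if any, occurs in the interval
    following a_last.
    """
    obs = np.asarray(obs)
    T = len(obs)
    fc = int(np.flatnonzero(obs > 0)[0])
    s0 = int(obs[fc])
    cls = trap_classes(obs, occ) if trap_aware else np.ones(T, dtype=int)
    total = 0.0
    for a_last in range(fc, T):
        for tail in itertools.product((1, 2), repeat=a_last - fc):
            seq = (s0,) + tail
            pr = 1.0
            # survival + transition along the path
            for k in range(len(seq) - 1):
                t = fc + k
                r, s = seq[k], seq[k + 1]
                phi = params.phi[r - 1, t, sex]
                psi = params.psi[r - 1, t, sex]
                pr *= phi * (psi if s != r else (1.0 - psi))
            if a_last < T - 1:
                r = seq[-1]
                pr *= 1.0 - params.phi[r - 1, a_last, sex]
            # detection terms after first capture
            ok = True
            for t in range(fc + 1, T):
                o = int(obs[t])
                if t <= a_last:
                    st = seq[t - fc]
                    pdet = params.p[st - 1, t, sex, cls[t]]
                    if o == 0:
                        pr *= 1.0 - pdet
                    elif o == st:
                        pr *= pdet
                    else:
                        ok = False
                        break
                elif o != 0:
                    ok = False
                    break
            if ok:
                total += pr
    return total


def count_hierarchical_models(n_mains: int) -> int:
    """Independent count of hierarchical two-way-interaction submodels:
    enumerate every (mains subset, interactions subset of all pairs) and
    keep those where each interaction has both mains present."""
    mains = list(range(n_mains))
    all_pairs = list(itertools.combinations(mains, 2))
    count = 0
    for r in range(n_mains + 1):
        for msub in itertools.combinations(mains, r):
            mset = set(msub)
            for k in range(len(all_pairs) + 1):
                for psub in itertools.combinations(all_pairs, k):
                    if all(a in mset and b in mset for a, b in psub):
                        count += 1
    return count
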