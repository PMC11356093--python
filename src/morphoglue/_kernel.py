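"""Compiled development kernel for population-scale runs.

Implements exactly the stage loop of :mod:`morphoglue.development` (same
mover eligibility, same strongest-signal destination with uniform tie-breaks
on the 1/(1+r) decay, same greedy path, blocking and tunneling rules, same
budget accounting) but without trace recording, so a genetic algorithm can
afford one development per embryo per generation.  The shared-stress overlay
is not materialized here because it never feeds back into movement — it is an
observable, recorded only by the reference engine.

Randomness comes from numba's internal Mersenne Twister seeded per call; the
stream differs from ``numpy.random.Generator``, so kernel and reference
engine agree in distribution and in every invariant, not swap-for-swap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["develop_fast", "MODE_SHARING", "MODE_NO_SHARING"]

MODE_SHARING = 0
MODE_NO_SHARING = 1

# status codes
COMPLETED = 0
BUDGET = 1
QUIESCENT = 2
MAX_STAGES = 3


@njit(cache=True)
def _develop_kernel(embryo, target, mode, cap, seed, max_stages):  # pragma: no cover
    np.random.seed(seed)
    n = embryo.shape[0]
    swaps_total = 0
    distance_total = 0.0
    stages = 0
    status = MAX_STAGES
    sqrt2 = np.sqrt(2.0)

    stressed_r = np.empty(n * n, np.int64)
    stressed_c = np.empty(n * n, np.int64)
    vac_r = np.empty(n * n, np.int64)
    vac_c = np.empty(n * n, np.int64)
    vac_req = np.empty(n * n, np.int64)
    cand_r = np.empty(n * n, np.int64)
    cand_c = np.empty(n * n, np.int64)
    # blocked movers stay stuck until another cell dislodges them
    stuck = np.zeros((n, n), np.uint8)

    while stages < max_stages:
        # --- stress scan -------------------------------------------------
        m = 0
        for r in range(n):
            for c in range(n):
                if embryo[r, c] != target[r, c]:
                    stressed_r[m] = r
                    stressed_c[m] = c
                    m += 1
        if m == 0:
            status = COMPLETED
            break
        if swaps_total >= cap:
            status = BUDGET
            break
        # --- vacancies: stressed cells with >= 1 fixed 8-neighbor --------
        nv = 0
        cnt0 = 0
        cnt1 = 0
        for i in range(m):
            r = stressed_r[i]
            c = stressed_c[i]
            seen_fixed = False
            for dr in range(-1, 2):
                for dc in range(-1, 2):
                    if dr == 0 and dc == 0:
                        continue
                    rr = r + dr
                    cc = c + dc
                    if 0 <= rr < n and 0 <= cc < n and embryo[rr, cc] == target[rr, cc]:
                        seen_fixed = True
            if seen_fixed:
                vac_r[nv] = r
                vac_c[nv] = c
                req = target[r, c]
                vac_req[nv] = req
                if req == 0:
                    cnt0 += 1
                else:
                    cnt1 += 1
                nv += 1
        # --- eligible movers ---------------------------------------------
        ncand = 0
        for i in range(m):
            r = stressed_r[i]
            c = stressed_c[i]
            if stuck[r, c]:
                continue
            v = embryo[r, c]
            if (v == 0 and cnt0 > 0) or (v == 1 and cnt1 > 0):
                cand_r[ncand] = r
                cand_c[ncand] = c
                ncand += 1
        if ncand == 0:
            status = QUIESCENT
            break
        moved = False
        while ncand > 0:
            k = np.random.randint(0, ncand)
            mr = cand_r[k]
            mc = cand_c[k]
            # swap-remove the pick from the candidate pool
            cand_r[k] = cand_r[ncand - 1]
            cand_c[k] = cand_c[ncand - 1]
            ncand -= 1
            mv = embryo[mr, mc]
            # destination: nearest eligible vacancy (argmax of 1/(1+r)),
            # ties uniform
            best_d2 = np.int64(1 << 60)
            nties = 0
            for j in range(nv):
                if vac_req[j] != mv:
                    continue
                d2 = (vac_r[j] - mr) ** 2 + (vac_c[j] - mc) ** 2
                if d2 < best_d2:
                    best_d2 = d2
                    nties = 1
                elif d2 == best_d2:
                    nties += 1
            if nties == 0:
                continue
            pick = np.random.randint(0, nties)
            dr_ = np.int64(-1)
            dc_ = np.int64(-1)
            seen = 0
            for j in range(nv):
                if vac_req[j] != mv:
                    continue
                d2 = (vac_r[j] - mr) ** 2 + (vac_c[j] - mc) ** 2
                if d2 == best_d2:
                    if seen == pick:
                        dr_ = vac_r[j]
                        dc_ = vac_c[j]
                        break
                    seen += 1
            # first-step feasibility for no_sharing movers
            if mode == MODE_NO_SHARING:
                fr, fc = _greedy_step(mr, mc, dr_, dc_, n)
                if embryo[fr, fc] == target[fr, fc]:
                    stuck[mr, mc] = 1  # cannot take even one step
                    continue
            # --- execute the move ----------------------------------------
            cur_r, cur_c = mr, mc
            carr_r, carr_c = mr, mc
            while cur_r != dr_ or cur_c != dc_:
                if swaps_total >= cap:
                    break  # truncated mid-path
                nr, nc = _greedy_step(cur_r, cur_c, dr_, dc_, n)
                if embryo[nr, nc] != target[nr, nc]:
                    tmp = embryo[carr_r, carr_c]
                    embryo[carr_r, carr_c] = embryo[nr, nc]
                    embryo[nr, nc] = tmp
                    # stuck markers travel with the displaced cell
                    stuck[carr_r, carr_c] = stuck[nr, nc]
                    stuck[nr, nc] = 0
                    carr_r, carr_c = nr, nc
                else:
                    if mode == MODE_NO_SHARING:
                        stuck[carr_r, carr_c] = 1  # blocked: stuck until dislodged
                        break
                    # sharing: tunnel through without displacing the occupant
                swaps_total += 1
                if nr != cur_r and nc != cur_c:
                    distance_total += sqrt2
                else:
                    distance_total += 1.0
                cur_r, cur_c = nr, nc
            moved = True
            break
        if not moved:
            status = QUIESCENT
            break
        stages += 1
    return swaps_total, distance_total, stages, status


@njit(cache=True, inline="always")
def _greedy_step(cr, cc, dr, dc, n):  # pragma: no cover
    """8-neighbor minimizing distance to (dr, dc); row before column on ties."""
    best_r = cr
    best_c = cc
    best_d2 = np.int64(1 << 60)
    for k in range(8):
        if k == 0:
            sr, sc = -1, 0
        elif k == 1:
            sr, sc = 1, 0
        elif k == 2:
            sr, sc = 0, -1
        elif k == 3:
            sr, sc = 0, 1
        elif k == 4:
            sr, sc = -1, -1
        elif k == 5:
            sr, sc = -1, 1
        elif k == 6:
            sr, sc = 1, -1
        else:
            sr, sc = 1, 1
        rr = cr + sr
        cc2 = cc + sc
        if rr < 0 or rr >= n or cc2 < 0 or cc2 >= n:
            continue
        d2 = (rr - dr) ** 2 + (cc2 - dc) ** 2
        if d2 < best_d2:
            best_d2 = d2
            best_r = rr
            best_c = cc2
    return best_r, best_c


_STATUS_NAMES = {COMPLETED: "completed", BUDGET: "budget",
                 QUIESCENT: "quiescent", MAX_STAGES: "max_stages"}


def develop_fast(
    genome: np.ndarray,
    target: np.ndarray,
    mode: str,
    cap: int,
    seed: int,
    max_stages: int = 10_000,
) -> tuple[np.ndarray, int, float, int, str]:
    """Develop ``genome`` toward ``target`` with the compiled kernel.

    Returns ``(phenotype, swaps_total, distance_total, stages, status)``.
    Hardwired embryos short-circuit: the phenotype is the genome.
    """
    if mode == "hardwired":
        return genome.copy(), 0, 0.0, 0, "hardwired"
    mode_code = MODE_SHARING if mode == "sharing" else MODE_NO_SHARING
    phenotype = np.ascontiguousarray(genome, dtype=np.uint8).copy()
    swaps, dist, stages, status = _develop_kernel(
        phenotype,
        np.ascontiguousarray(target, dtype=np.uint8),
        mode_code,
        np.int64(cap),
        np.int64(seed),
        np.int64(max_stages),
    )
    return phenotype, int(swaps), float(dist), int(stages), _STATUS_NAMES[int(status)]
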