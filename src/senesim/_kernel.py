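"""Compiled hot path of the lattice Monte Carlo.

The whole generation loop (site sampling, death trials, fecundity-weighted
parent choice, crossover, mutation, diffusion swaps, target flips and the
per-generation lattice summaries) runs inside numba so that desk-scale runs
(10^7-10^8 elementary updates) finish in seconds.  State lives in plain
arrays owned by :class:`senesim.lattice.Lattice`; the wrappers there do the
validation and bookkeeping.

Randomness uses numba's global NumPy-legacy stream, seeded once per run via
:func:`seed_kernel`; sequential kernel calls continue the same stream, which
keeps multi-phase protocols (e.g. invasions) reproducible from one seed.
"""

import numpy as np
from numba import njit

from .params import ALPHA_PER_ALLELE, EVOLVABLE_BASELINE_FLOOR

# metrics column order; kept in sync with observables.METRIC_COLUMNS
N_METRICS = 13
(
    COL_T,
    COL_OCC,
    COL_ALPHA,
    COL_AGE,
    COL_DELTA,
    COL_PHI,
    COL_CORR,
    COL_S,
    COL_TAG,
    COL_DEATHS,
    COL_BIRTHS,
    COL_SWAPS,
    COL_FLIPS,
) = range(N_METRICS)

# the 8 orthogonal/diagonal neighbor offsets used for diffusion swaps
_OFF_X = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_OFF_Y = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def hazard(sum_a, tau, delta0, evolvable_baseline):
    """Per-generation death probability of one individual.

    Normally ``delta0 + alpha * tau`` capped at 1 beyond the maximum
    lifespan ``tau_max = floor((1 - delta0) / alpha)``; with
    ``evolvable_baseline`` the hazard is the age-independent
    ``0.002 + 0.01 * sum_a``.
    """
    if evolvable_baseline:
        return EVOLVABLE_BASELINE_FLOOR + ALPHA_PER_ALLELE * sum_a
    if sum_a == 0:
        return delta0
    alpha = ALPHA_PER_ALLELE * sum_a
    tau_max = int(np.floor((1.0 - delta0) / alpha))
    if tau > tau_max:
        return 1.0
    return delta0 + alpha * tau


@njit(cache=True)
def _weighted_pick(w, m):
    tot = 0.0
    for i in range(m):
        tot += w[i]
    r = np.random.random() * tot
    acc = 0.0
    for i in range(m):
        acc += w[i]
        if r < acc:
            return i
    return m - 1


@njit(cache=True)
def _flip_target(phi, phase, Lf):
    """One directional flip; returns the flipped locus index."""
    want = 0 if phase[0] == 0 else 1
    nc = 0
    for k in range(Lf):
        if phi[k] == want:
            nc += 1
    r = np.random.randint(nc)
    idx = -1
    seen = 0
    for k in range(Lf):
        if phi[k] == want:
            if seen == r:
                idx = k
                break
            seen += 1
    phi[idx] = 1 - phi[idx]
    if nc == 1:  # pattern just saturated: reverse sweep direction
        phase[0] = 1 - phase[0]
    return idx


@njit(cache=True)
def _fill_site(
    x,
    y,
    occ,
    age,
    gen,
    sum_a,
    s,
    tag,
    fec_idx,
    sen_idx,
    phi,
    b_pow,
    nrad,
    prec,
    pf,
    pa,
    sexual,
    config_field,
    cand_x,
    cand_y,
    w,
    drawn_x,
    drawn_y,
    child,
):
    """Try to repopulate the empty site (x, y); returns 1 on a birth.

    Parents come from the n-Moore neighborhood (or 8 distinct lattice-wide
    sites in the configuration-field limit) with probability proportional to
    their raw fecundity ``b ** s``; sexual reproduction draws a second,
    distinct parent without replacement (dioecy).  The offspring is the
    mutated (recombinant) copy at age 0, tagged after the first parent.
    """
    N = occ.shape[0]
    Lf = fec_idx.shape[0]
    La = sen_idx.shape[0]
    L = Lf + La
    m = 0
    if config_field:
        ndrawn = 0
        while ndrawn < 8:
            cx = np.random.randint(N)
            cy = np.random.randint(N)
            if cx == x and cy == y:
                continue
            dup = False
            for j in range(ndrawn):
                if drawn_x[j] == cx and drawn_y[j] == cy:
                    dup = True
                    break
            if dup:
                continue
            drawn_x[ndrawn] = cx
            drawn_y[ndrawn] = cy
            ndrawn += 1
            if occ[cx, cy] == 1:
                cand_x[m] = cx
                cand_y[m] = cy
                w[m] = b_pow[s[cx, cy]]
                m += 1
    else:
        for dx in range(-nrad, nrad + 1):
            for dy in range(-nrad, nrad + 1):
                if dx == 0 and dy == 0:
                    continue
                cx = (x + dx) % N
                cy = (y + dy) % N
                if occ[cx, cy] == 1:
                    cand_x[m] = cx
                    cand_y[m] = cy
                    w[m] = b_pow[s[cx, cy]]
                    m += 1
    if sexual:
        if m < 2:
            return 0
        i1 = _weighted_pick(w, m)
        w1 = w[i1]
        w[i1] = 0.0  # dioecy: second parent without replacement
        i2 = _weighted_pick(w, m)
        w[i1] = w1
        p1x = cand_x[i1]
        p1y = cand_y[i1]
        p2x = cand_x[i2]
        p2y = cand_y[i2]
        if np.random.random() < prec:
            cut = 1 + np.random.randint(L - 1)
            if np.random.random() < 0.5:
                for l in range(L):
                    if l < cut:
                        child[l] = gen[p1x, p1y, l]
                    else:
                        child[l] = gen[p2x, p2y, l]
            else:
                for l in range(L):
                    if l < cut:
                        child[l] = gen[p2x, p2y, l]
                    else:
                        child[l] = gen[p1x, p1y, l]
        else:
            if np.random.random() < 0.5:
                for l in range(L):
                    child[l] = gen[p1x, p1y, l]
            else:
                for l in range(L):
                    child[l] = gen[p2x, p2y, l]
        tag[x, y] = tag[p1x, p1y]
    else:
        if m < 1:
            return 0
        i1 = _weighted_pick(w, m)
        p1x = cand_x[i1]
        p1y = cand_y[i1]
        for l in range(L):
            child[l] = gen[p1x, p1y, l]
        tag[x, y] = tag[p1x, p1y]
    if pf > 0.0:
        for k in range(Lf):
            if np.random.random() < pf:
                p = fec_idx[k]
                child[p] = 1 - child[p]
    if pa > 0.0:
        for j in range(La):
            if np.random.random() < pa:
                p = sen_idx[j]
                child[p] = 1 - child[p]
    sv = 0
    for k in range(Lf):
        if child[fec_idx[k]] == phi[k]:
            sv += 1
    av = 0
    for j in range(La):
        av += child[sen_idx[j]]
    for l in range(L):
        gen[x, y, l] = child[l]
    s[x, y] = sv
    sum_a[x, y] = av
    age[x, y] = 0
    occ[x, y] = 1
    return 1


@njit(cache=True)
def run_generations(
    occ,
    age,
    gen,
    sum_a,
    s,
    tag,
    fec_idx,
    sen_idx,
    phi,
    phase,
    t0,
    n_gens,
    delta0,
    b_pow,
    nrad,
    T,
    prec,
    pf,
    pa,
    D,
    sexual,
    directional,
    config_field,
    evolvable_baseline,
    out,
):
    """Advance the lattice by ``n_gens`` generations, filling ``out``.

    One generation = (target flip if due) + N*N elementary updates at
    i.i.d. uniformly drawn sites + one age increment for every survivor,
    then the per-generation lattice summary.
    """
    N = occ.shape[0]
    Lf = fec_idx.shape[0]
    La = sen_idx.shape[0]
    L = Lf + La
    nn = N * N
    maxc = (2 * nrad + 1) ** 2 - 1
    if maxc < 8:
        maxc = 8
    cand_x = np.empty(maxc, np.int64)
    cand_y = np.empty(maxc, np.int64)
    w = np.empty(maxc, np.float64)
    drawn_x = np.empty(8, np.int64)
    drawn_y = np.empty(8, np.int64)
    child = np.empty(L, np.uint8)
    norm = b_pow[Lf]

    for g in range(n_gens):
        t = t0 + g + 1
        flips = 0
        if directional and t % T == 0:
            kflip = _flip_target(phi, phase, Lf)
            flips = 1
            # the flip toggles the match at one locus for every individual
            pos = fec_idx[kflip]
            v = phi[kflip]
            for x in range(N):
                for y in range(N):
                    if occ[x, y] == 1:
                        if gen[x, y, pos] == v:
                            s[x, y] += 1
                        else:
                            s[x, y] -= 1

        deaths = 0
        births = 0
        swaps = 0
        for _step in range(nn):
            x = np.random.randint(N)
            y = np.random.randint(N)
            if occ[x, y] == 1:
                d = hazard(sum_a[x, y], age[x, y], delta0, evolvable_baseline)
                if np.random.random() < d:
                    occ[x, y] = 0
                    deaths += 1
                    # the freed site is immediately exposed to repopulation;
                    # this keeps the grid saturated (empty fraction < 1e-3)
                    births += _fill_site(
                        x, y, occ, age, gen, sum_a, s, tag, fec_idx, sen_idx,
                        phi, b_pow, nrad, prec, pf, pa, sexual, config_field,
                        cand_x, cand_y, w, drawn_x, drawn_y, child,
                    )
            else:
                births += _fill_site(
                    x, y, occ, age, gen, sum_a, s, tag, fec_idx, sen_idx,
                    phi, b_pow, nrad, prec, pf, pa, sexual, config_field,
                    cand_x, cand_y, w, drawn_x, drawn_y, child,
                )
            # diffusion: D expected random adjacent-pair swaps per update
            if D > 0.0:
                nsw = int(D)
                fr = D - nsw
                if fr > 0.0 and np.random.random() < fr:
                    nsw += 1
                for _sw in range(nsw):
                    sx = np.random.randint(N)
                    sy = np.random.randint(N)
                    o = np.random.randint(8)
                    tx = (sx + _OFF_X[o]) % N
                    ty = (sy + _OFF_Y[o]) % N
                    tmp8 = occ[sx, sy]
                    occ[sx, sy] = occ[tx, ty]
                    occ[tx, ty] = tmp8
                    tmp32 = age[sx, sy]
                    age[sx, sy] = age[tx, ty]
                    age[tx, ty] = tmp32
                    tmp16 = sum_a[sx, sy]
                    sum_a[sx, sy] = sum_a[tx, ty]
                    sum_a[tx, ty] = tmp16
                    tmp16 = s[sx, sy]
                    s[sx, sy] = s[tx, ty]
                    s[tx, ty] = tmp16
                    tmp8 = tag[sx, sy]
                    tag[sx, sy] = tag[tx, ty]
                    tag[tx, ty] = tmp8
                    for l in range(L):
                        tmpg = gen[sx, sy, l]
                        gen[sx, sy, l] = gen[tx, ty, l]
                        gen[tx, ty, l] = tmpg
                    swaps += 1

        # age updating step at the end of the iteration
        for x in range(N):
            for y in range(N):
                if occ[x, y] == 1:
                    age[x, y] += 1

        # lattice summary of the end-of-generation state
        cnt = 0
        sa = 0.0
        st = 0.0
        sd = 0.0
        sp = 0.0
        ss = 0.0
        stg = 0.0
        sxy = 0.0
        sxx = 0.0
        syy = 0.0
        for x in range(N):
            for y in range(N):
                if occ[x, y] == 1:
                    cnt += 1
                    al = ALPHA_PER_ALLELE * sum_a[x, y]
                    sa += al
                    st += age[x, y]
                    sd += hazard(sum_a[x, y], age[x, y], delta0, evolvable_baseline)
                    pn = b_pow[s[x, y]] / norm
                    sp += pn
                    ss += s[x, y]
                    stg += tag[x, y]
                    sxy += pn * al
                    sxx += pn * pn
                    syy += al * al
        row = out[g]
        row[COL_T] = t
        row[COL_DEATHS] = deaths
        row[COL_BIRTHS] = births
        row[COL_SWAPS] = swaps
        row[COL_FLIPS] = flips
        if cnt > 0:
            inv = 1.0 / cnt
            row[COL_OCC] = cnt / nn
            mx = sp * inv
            my = sa * inv
            row[COL_ALPHA] = my
            row[COL_AGE] = st * inv
            row[COL_DELTA] = sd * inv
            row[COL_PHI] = mx
            row[COL_S] = ss * inv
            row[COL_TAG] = stg * inv
            varx = sxx * inv - mx * mx
            vary = syy * inv - my * my
            if varx > 1e-15 and vary > 1e-15:
                row[COL_CORR] = (sxy * inv - mx * my) / np.sqrt(varx * vary)
            else:
                row[COL_CORR] = np.nan
        else:
            row[COL_OCC] = 0.0
            row[COL_ALPHA] = np.nan
            row[COL_AGE] = np.nan
            row[COL_DELTA] = np.nan
            row[COL_PHI] = np.nan
            row[COL_S] = np.nan
            row[COL_TAG] = np.nan
            row[COL_CORR] = np.nan
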