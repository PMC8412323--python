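"""Compiled event-loop kernels for the stochastic simulators.

The direct SSA loop and the hybrid co-simulation window loop live here as
numba-njit functions; everything above this module is plain Python.  Rates
that depend on time (the decaying resistant death law) are treated as
constant between events (quasi-static direct SSA) — inter-event times are
far below the decay timescale at the population sizes simulated.

Status codes returned by the kernels:
    0  horizon reached
    1  total extinction
    2  frozen (total propensity zero with cells remaining); clock jumps
       to the horizon with the state unchanged
    3  max_events exceeded (truncated trajectory)
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_EXTINCT = 1
STATUS_FROZEN = 2
STATUS_TRUNCATED = 3


@njit(cache=True)
def _pick_ladder_level(ladder, i):
    # Sample a switch-ladder level proportional to its occupancy.
    tot = ladder[i, 0] + ladder[i, 1] + ladder[i, 2]
    r = np.random.random() * tot
    if r < ladder[i, 0]:
        return 0
    if r < ladder[i, 0] + ladder[i, 1]:
        return 1
    return 2


@njit(cache=True)
def _remove_from_ladder(ladder, i):
    k = _pick_ladder_level(ladder, i)
    ladder[i, k] -= 1


@njit(cache=True)
def ssa_core(
    n,            # int64[S] current counts, modified in place
    ladder,       # int64[S, 3] switch-ladder occupancies (multi-step)
    t_start,
    cb_pre, cd_pre, ct_pre,      # float64[S] per-cell coefficients
    cb_post, cd_post, ct_post,
    is_res,       # int64[S] 1 for absorbing (resistant / MGMT) states
    lat_dest,     # int64[S, Dmax] lateral destinations
    lat_cnt,      # int64[S]
    res_dest,     # int64[S] absorbing target index or -1
    drug_time, t_end, res_divisor,
    res_decay,    # 1: resistant death = cd_post * n * exp(-(t-drug)/div)
    unstable,     # 1: multiply each state's transition outflow by U(0,1)
    rescue, thresh,
    per_dest,     # 0: split total outflow over destinations; 1: per-dest
    multi_step, p_off,
    ladder_scope,  # 0: one ladder per pathway (ladder[i,0] holds the level);
                   # 1: per-cell ladder (ladder[i,k] = cells at level k)
    report_times,  # float64[T] strictly increasing, <= t_end
    out_counts,    # int64[T, S] counts at report times (last value)
    ev_times, ev_kind, ev_src, ev_dst,   # event log (capacity may be 0)
    ev_pops,       # int64[cap, S] counts after each logged event
    ev_ladder,     # int64[cap, S, 3]
    max_events,
):
    S = n.shape[0]
    t = t_start
    rp = 0
    n_report = report_times.shape[0]
    cap = ev_times.shape[0]
    nrec = 0
    nev = 0
    status = STATUS_OK

    birth_r = np.zeros(S)
    death_r = np.zeros(S)
    lat_r = np.zeros(S)
    res_r = np.zeros(S)

    while True:
        total = 0
        for i in range(S):
            total += n[i]
        if total == 0:
            status = STATUS_EXTINCT
            break

        post = t >= drug_time
        lam = 0.0
        for i in range(S):
            ni = n[i]
            if post:
                cb = cb_post[i]
                cd = cd_post[i]
                ct = ct_post[i]
            else:
                cb = cb_pre[i]
                cd = cd_pre[i]
                ct = ct_pre[i]
            b = cb * ni
            if is_res[i] == 1 and post and res_decay == 1:
                d = cd * ni * np.exp(-(t - drug_time) / res_divisor)
            else:
                d = cd * ni
            if unstable == 1:
                ct = ct * np.random.random()
            outflow = ct * ni
            nl = lat_cnt[i]
            has_res = 1 if (post and res_dest[i] >= 0) else 0
            k = nl + has_res
            share = 0.0
            if k > 0 and outflow > 0.0:
                if per_dest == 1:
                    share = outflow
                else:
                    share = outflow / k
            lr = share * nl
            rr = share * has_res
            if rescue == 1 and is_res[i] == 0 and ni < thresh:
                d = 0.0
                rr = 0.0
            birth_r[i] = b
            death_r[i] = d
            lat_r[i] = lr
            res_r[i] = rr
            lam += b + d + lr + rr

        if lam <= 0.0:
            status = STATUS_FROZEN
            break

        tau = -np.log(np.random.random()) / lam
        tnew = t + tau
        if tnew >= t_end:
            t = t_end
            break

        # flush report times strictly before the next event
        while rp < n_report and report_times[rp] < tnew:
            for i in range(S):
                out_counts[rp, i] = n[i]
            rp += 1

        t = tnew

        # select event channel
        v = np.random.random() * lam
        ev_i = -1
        kind = -1
        dst = -1
        acc = 0.0
        for i in range(S):
            acc += birth_r[i]
            if v < acc:
                ev_i = i
                kind = 0
                break
        if ev_i < 0:
            for i in range(S):
                acc += death_r[i]
                if v < acc:
                    ev_i = i
                    kind = 1
                    break
        if ev_i < 0:
            for i in range(S):
                acc += lat_r[i]
                if v < acc:
                    ev_i = i
                    kind = 2
                    j = int(np.random.random() * lat_cnt[i])
                    dst = lat_dest[i, j]
                    break
        if ev_i < 0:
            for i in range(S):
                acc += res_r[i]
                if v < acc:
                    ev_i = i
                    kind = 3
                    dst = res_dest[i]
                    break
        if ev_i < 0:
            # floating-point fallthrough (v ~ lam); skip this draw
            continue

        i = ev_i
        per_cell = multi_step == 1 and ladder_scope == 1 and res_dest[i] >= 0
        if kind == 0:
            n[i] += 1
            if per_cell:
                ladder[i, 0] += 1
        elif kind == 1:
            if per_cell:
                _remove_from_ladder(ladder, i)
            n[i] -= 1
        elif kind == 2:
            if per_cell:
                _remove_from_ladder(ladder, i)
            n[i] -= 1
            n[dst] += 1
            if multi_step == 1 and ladder_scope == 1 and res_dest[dst] >= 0:
                ladder[dst, 0] += 1
        else:  # kind == 3: resistant channel
            if multi_step == 0:
                n[i] -= 1
                n[dst] += 1
            elif ladder_scope == 0:
                # one switch flip on the pathway's ladder; level 3 converts
                # one cell and resets the pathway
                k = ladder[i, 0]
                r = np.random.random()
                if k >= 1 and r < p_off:
                    ladder[i, 0] = k - 1
                else:
                    if k == 2:
                        n[i] -= 1
                        n[dst] += 1
                        ladder[i, 0] = 0
                    else:
                        ladder[i, 0] = k + 1
            else:
                # one switch-flip attempt on a cell drawn from the ladder
                k = _pick_ladder_level(ladder, i)
                r = np.random.random()
                if k >= 1 and r < p_off:
                    ladder[i, k] -= 1
                    ladder[i, k - 1] += 1
                else:
                    ladder[i, k] -= 1
                    if k == 2:  # third switch turns on: lock-in complete
                        n[i] -= 1
                        n[dst] += 1
                    else:
                        ladder[i, k + 1] += 1

        nev += 1
        if cap > 0 and nrec < cap:
            ev_times[nrec] = t
            ev_kind[nrec] = kind
            ev_src[nrec] = i
            ev_dst[nrec] = dst
            for s in range(S):
                ev_pops[nrec, s] = n[s]
                for l in range(3):
                    ev_ladder[nrec, s, l] = ladder[s, l]
            nrec += 1
        if nev >= max_events:
            status = STATUS_TRUNCATED
            break

    if status == STATUS_FROZEN or status == STATUS_EXTINCT:
        t = t_end
    while rp < n_report:
        for i in range(S):
            out_counts[rp, i] = n[i]
        rp += 1
    return nrec, nev, status, t


@njit(cache=True)
def ssa_run(
    seed, n, ladder, t_start,
    cb_pre, cd_pre, ct_pre, cb_post, cd_post, ct_post,
    is_res, lat_dest, lat_cnt, res_dest,
    drug_time, t_end, res_divisor, res_decay,
    unstable, rescue, thresh, per_dest, multi_step, p_off, ladder_scope,
    report_times, out_counts,
    ev_times, ev_kind, ev_src, ev_dst, ev_pops, ev_ladder,
    max_events,
):
    np.random.seed(seed)
    return ssa_core(
        n, ladder, t_start,
        cb_pre, cd_pre, ct_pre, cb_post, cd_post, ct_post,
        is_res, lat_dest, lat_cnt, res_dest,
        drug_time, t_end, res_divisor, res_decay,
        unstable, rescue, thresh, per_dest, multi_step, p_off, ladder_scope,
        report_times, out_counts,
        ev_times, ev_kind, ev_src, ev_dst, ev_pops, ev_ladder,
        max_events,
    )


@njit(cache=True)
def ensemble_run(
    seeds, n_init,
    cb_pre, cd_pre, ct_pre, cb_post, cd_post, ct_post,
    is_res, lat_dest, lat_cnt, res_dest,
    drug_time, t_end, res_divisor, res_decay,
    unstable, rescue, thresh, per_dest, multi_step, p_off, ladder_scope,
    report_times,
    out_counts,   # int64[R, T, S]
    statuses,     # int64[R]
    event_counts,  # int64[R]
    max_events,
):
    S = n_init.shape[0]
    et = np.empty(0, np.float64)
    ek = np.empty(0, np.int64)
    ep = np.empty((0, S), np.int64)
    el = np.empty((0, S, 3), np.int64)
    for r in range(seeds.shape[0]):
        n = n_init.copy()
        ladder = np.zeros((S, 3), np.int64)
        if ladder_scope == 1:
            for i in range(S):
                if res_dest[i] >= 0:
                    ladder[i, 0] = n[i]
        np.random.seed(seeds[r])
        nrec, nev, status, t = ssa_core(
            n, ladder, 0.0,
            cb_pre, cd_pre, ct_pre, cb_post, cd_post, ct_post,
            is_res, lat_dest, lat_cnt, res_dest,
            drug_time, t_end, res_divisor, res_decay,
            unstable, rescue, thresh, per_dest, multi_step, p_off, ladder_scope,
            report_times, out_counts[r],
            et, ek, ek, ek, ep, el,
            max_events,
        )
        statuses[r] = status
        event_counts[r] = nev


@njit(cache=True)
def total_propensity(
    n, t,
    cb_pre, cd_pre, ct_pre, cb_post, cd_post, ct_post,
    is_res, lat_dest, lat_cnt, res_dest,
    drug_time, res_divisor, res_decay, rescue, thresh, per_dest,
):
    """Sum of all event rates at (n, t); instability mode not supported."""
    S = n.shape[0]
    post = t >= drug_time
    lam = 0.0
    for i in range(S):
        ni = n[i]
        if post:
            cb = cb_post[i]
            cd = cd_post[i]
            ct = ct_post[i]
        else:
            cb = cb_pre[i]
            cd = cd_pre[i]
            ct = ct_pre[i]
        b = cb * ni
        if is_res[i] == 1 and post and res_decay == 1:
            d = cd * ni * np.exp(-(t - drug_time) / res_divisor)
        else:
            d = cd * ni
        outflow = ct * ni
        nl = lat_cnt[i]
        has_res = 1 if (post and res_dest[i] >= 0) else 0
        k = nl + has_res
        share = 0.0
        if k > 0 and outflow > 0.0:
            share = outflow if per_dest == 1 else outflow / k
        lr = share * nl
        rr = share * has_res
        if rescue == 1 and is_res[i] == 0 and ni < thresh:
            d = 0.0
            rr = 0.0
        lam += b + d + lr + rr
    return lam


# ---------------------------------------------------------------------------
# Hybrid co-simulation: multi-step cell-state SSA + TMZ-MGMT ODE (RK4)
# ---------------------------------------------------------------------------
# Species order: blood TMZ, interstitial TMZ, intracellular TMZ, methylating
# cation, O6mG, MGMT mRNA, MGMT protein, MGMT-O6mG complex.
# Parameter vector pk (all h^-1 except f_ad, f_fb dimensionless):
#   0 k_bi, 1 k_eb, 2 k_ic, 3 k_ei, 4 k_act, 5 k_eic, 6 k_conv, 7 f_ad,
#   8 k_rep, 9 k_tx, 10 k_dm, 11 k_tl, 12 k_dp, 13 k_dc, 14 f_fb


@njit(cache=True)
def pkpd_rhs(y, gate, pk, dy):
    dy[0] = -(pk[0] + pk[1]) * y[0]
    dy[1] = pk[0] * y[0] - (pk[2] + pk[3]) * y[1]
    dy[2] = pk[2] * y[1] - (pk[4] + pk[5]) * y[2]
    dy[3] = pk[4] * y[2] - pk[6] * y[3]
    repair = pk[8] * y[6] * y[4]
    dy[4] = pk[7] * pk[6] * y[3] - repair
    dy[5] = pk[9] * gate * (1.0 + pk[14] * y[7]) - pk[10] * y[5]
    dy[6] = pk[11] * y[5] - pk[12] * y[6] - repair
    dy[7] = repair - pk[13] * y[7]


@njit(cache=True)
def _rk4_span(y, t0, t1, dt, gate, pk):
    span = t1 - t0
    if span <= 0.0:
        return
    nsteps = int(np.ceil(span / dt))
    h = span / nsteps
    k1 = np.empty(8)
    k2 = np.empty(8)
    k3 = np.empty(8)
    k4 = np.empty(8)
    ytmp = np.empty(8)
    for _ in range(nsteps):
        pkpd_rhs(y, gate, pk, k1)
        for j in range(8):
            ytmp[j] = y[j] + 0.5 * h * k1[j]
        pkpd_rhs(ytmp, gate, pk, k2)
        for j in range(8):
            ytmp[j] = y[j] + 0.5 * h * k2[j]
        pkpd_rhs(ytmp, gate, pk, k3)
        for j in range(8):
            ytmp[j] = y[j] + h * k3[j]
        pkpd_rhs(ytmp, gate, pk, k4)
        for j in range(8):
            y[j] += h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if y[j] < 0.0:
                y[j] = 0.0


@njit(cache=True)
def hybrid_run(
    seed,
    n_init,            # int64[S] hybrid cell states
    cb_day, cd_base_day, ct_day,  # float64[S] per-day coefficients
    is_mgmt,           # int64[S] 1 for the MGMT-locked states
    lat_dest, lat_cnt, res_dest,
    rescue, thresh, per_dest, p_off, ladder_scope,
    kill_gain_day,     # extra death (day^-1) per unit O6mG
    mgmt_kill_fraction,
    sat_o6mg,          # saturation constant of the kill law; <=0 disables
    gate_mode,         # 0: MGMT fraction; 1: thresholded binary gate
    gate_threshold,
    pk, dose_times, dose_amount,
    dt_window, horizon, ode_dt,
    y0,
    out_cells,         # int64[W+1, S]
    out_species,       # float64[W+1, 8]
    out_gate,          # float64[W+1]
    max_events_per_window,
):
    np.random.seed(seed)
    S = n_init.shape[0]
    n = n_init.copy()
    ladder = np.zeros((S, 3), np.int64)
    if ladder_scope == 1:
        for i in range(S):
            if res_dest[i] >= 0:
                ladder[i, 0] = n[i]
    y = y0.copy()

    n_windows = out_cells.shape[0] - 1
    cb_h = np.empty(S)
    cd_h = np.empty(S)
    ct_h = np.empty(S)
    for i in range(S):
        cb_h[i] = cb_day[i] / 24.0
        ct_h[i] = ct_day[i] / 24.0

    first_dose = dose_times[0] if dose_times.shape[0] > 0 else 1.0e18

    et = np.empty(0, np.float64)
    ek = np.empty(0, np.int64)
    ep = np.empty((0, S), np.int64)
    el = np.empty((0, S, 3), np.int64)
    rt = np.empty(0, np.float64)
    oc = np.empty((0, S), np.int64)

    for i in range(S):
        out_cells[0, i] = n[i]
    for j in range(8):
        out_species[0, j] = y[j]
    gsum = 0
    msum = 0
    for i in range(S):
        if is_mgmt[i] == 1:
            msum += n[i]
        if i != 0:  # all non-quiescent states enter the gate denominator
            gsum += n[i]
    g0 = msum / gsum if gsum > 0 else 0.0
    if gate_mode == 1:
        g0 = 1.0 if g0 >= gate_threshold else 0.0
    out_gate[0] = g0

    dp = 0
    status = STATUS_OK
    for w in range(n_windows):
        t0 = w * dt_window
        t1 = t0 + dt_window

        # death coefficients from the O6mG level frozen at window start
        o6mg = y[4]
        kill = kill_gain_day * o6mg
        if sat_o6mg > 0.0:
            kill = kill_gain_day * o6mg / (1.0 + o6mg / sat_o6mg)
        for i in range(S):
            frac = mgmt_kill_fraction if is_mgmt[i] == 1 else 1.0
            cd_h[i] = (cd_base_day[i] + frac * kill) / 24.0

        # lock-in channel opens with the first drug dose
        dtw = -1.0 if t0 >= first_dose else 1.0e18

        nrec, nev, st, tloc = ssa_core(
            n, ladder, 0.0,
            cb_h, cd_h, ct_h, cb_h, cd_h, ct_h,
            is_mgmt, lat_dest, lat_cnt, res_dest,
            dtw, dt_window, 1.0, 0,
            0, rescue, thresh, per_dest, 1, p_off, ladder_scope,
            rt, oc,
            et, ek, ek, ek, ep, el,
            max_events_per_window,
        )
        if st == STATUS_TRUNCATED:
            status = STATUS_TRUNCATED

        # gate from the current (post-SSA) populations
        gsum = 0
        msum = 0
        for i in range(S):
            if is_mgmt[i] == 1:
                msum += n[i]
            if i != 0:
                gsum += n[i]
        gate = msum / gsum if gsum > 0 else 0.0
        if gate_mode == 1:
            gate = 1.0 if gate >= gate_threshold else 0.0

        # ODE advance with dose impulses inside (t0, t1]
        tcur = t0
        while dp < dose_times.shape[0] and dose_times[dp] <= t1:
            td = dose_times[dp]
            if td > tcur:
                _rk4_span(y, tcur, td, ode_dt, gate, pk)
                tcur = td
            y[0] += dose_amount
            dp += 1
        _rk4_span(y, tcur, t1, ode_dt, gate, pk)

        for i in range(S):
            out_cells[w + 1, i] = n[i]
        for j in range(8):
            out_species[w + 1, j] = y[j]
        out_gate[w + 1] = gate

    return status
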