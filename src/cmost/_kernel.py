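"""Numba kernels for the quarterly life-history simulation.

Randomness is counter-based: every stochastic decision is a pure function of
(individual key, draw id, quarter, slot).  Paired scenario arms run with the
same master seed therefore share natural-history randomness exactly — a
lesion evolves identically in both arms until a screening action removes it.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

MAX_Q = 404          # quarters simulated (age 0..100)
MAXL = 128           # lesion slots per individual

# lesion states
L_EMPTY, L_ADENOMA, L_PRECANCER, L_REMOVED, L_CLINICAL = 0, 1, 2, 3, 4
# cancer origins
O_ADENOMA, O_FAST, O_DIRECT = 0, 1, 2
# screening modes
MODE_NONE, MODE_COLO, MODE_SIG, MODE_FOBT, MODE_PERFECT = 0, 1, 2, 3, 4
# procedure types / contexts
P_COLO, P_SIG, P_FOBT = 0, 1, 2
CTX_SCREEN, CTX_SURV, CTX_DIAG, CTX_FOLLOWUP = 0, 1, 2, 3

# draw ids
D_SEX, D_IMULT, D_NATDEATH, D_ADHERE, D_ENROLL, D_SECOND = 1, 2, 3, 4, 5, 6
D_INIT, D_INIT_SEG, D_MULT_E, D_MULT_A, D_LESEVENT = 10, 11, 12, 13, 14
D_DIRECT, D_DIRECT_SEG, D_SOJ, D_SYMPT, D_CRCHAZ = 15, 16, 17, 18, 19
D_REACH, D_DETECT, D_COMPL, D_COMPL_DEATH, D_FOBT_L, D_FOBT_FP, D_FU = (
    30, 31, 32, 33, 34, 35, 36)
D_SIGREACH = 37

# misc tally indices
M_INITIATED, M_REGRESSED, M_RESECTED, M_TOCANCER, M_REMAIN = 0, 1, 2, 3, 4
M_SYNCH, M_PERSON_DIAG, M_CLIP_WARN, M_OVERFLOW = 5, 6, 7, 8
M_ORIGIN_ADE, M_ORIGIN_FAST, M_ORIGIN_DIRECT, M_YEARS_LOST = 9, 10, 11, 12
M_TOTAL_CANCERS = 13
N_MISC = 16

# window tally indices
W_INC, W_LEFT, W_RIGHT, W_DEATH = 0, 1, 2, 3
N_WINDOW = 6

LEFT_MAX_SEG = 6      # rectum .. splenic flexure
RECTUM_MAX_SEG = 2    # rectum + rectosigmoid

_U1 = uint64(0x9E3779B97F4A7C15)
_U2 = uint64(0xBF58476D1CE4E5B9)
_U3 = uint64(0x94D049BB133111EB)
_KA = uint64(0xA24BAED4963EE407)
_KB = uint64(0x9FB21C651E98DF25)
_KC = uint64(0xD6E8FEB86659FD93)


@njit(inline="always", cache=True)
def _mix(z):
    z = (z ^ (z >> uint64(30))) * _U2
    z = (z ^ (z >> uint64(27))) * _U3
    return z ^ (z >> uint64(31))


@njit(inline="always", cache=True)
def _u01(key, a, b, c):
    z = key + uint64(a) * _KA + uint64(b) * _KB + uint64(c) * _KC
    z = _mix(_mix(z) + _U1)
    return (z >> uint64(11)) * 1.1102230246251565e-16  # 2**-53


@njit(inline="always", cache=True)
def individual_key(seed, idx):
    return _mix(uint64(seed) * _U1 + uint64(idx) * _KC + _U3)


@njit(inline="always", cache=True)
def _interp(qs, vs, u):
    n = qs.shape[0]
    if u <= qs[0]:
        return vs[0]
    for i in range(1, n):
        if u <= qs[i]:
            w = (u - qs[i - 1]) / (qs[i] - qs[i - 1])
            return vs[i - 1] + w * (vs[i] - vs[i - 1])
    return vs[n - 1]


@njit(inline="always", cache=True)
def _pick(cdf, u):
    """Index of first cdf entry >= u (categorical draw)."""
    for i in range(cdf.shape[0]):
        if u <= cdf[i]:
            return i
    return cdf.shape[0] - 1


@njit(cache=True)
def sample_sojourn_q(key, slot, mean_q, sd_q):
    """Truncated-normal sojourn time in quarters (> 0), Box-Muller draws."""
    t = 1.0
    for att in range(32):
        u1 = _u01(key, D_SOJ, slot, 2 * att)
        u2 = _u01(key, D_SOJ, slot, 2 * att + 1)
        if u1 < 1e-300:
            u1 = 1e-300
        z = np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)
        t = mean_q + sd_q * z
        if t >= 0.5:
            break
    tq = int(np.floor(t + 0.5))
    if tq < 1:
        tq = 1
    return tq


@njit(cache=True)
def sample_sojourns(seed, n, mean_q, sd_q):
    """Batch of sojourn draws (quarters), one per individual key."""
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        out[i] = sample_sojourn_q(individual_key(seed, i), 0, mean_q, sd_q)
    return out


@njit(cache=True)
def _start_cancer(slot, q, origin, key, lstate, lstage, lseg, cq, csoj, csympt,
                  cumdw, ladebirth, sojourn_mean_q, sojourn_sd_q, sympt_cdf,
                  dwell_w, misc, dwell_hist):
    """Turn slot into a preclinical cancer; draw sojourn/symptomatic stage."""
    lstate[slot] = L_PRECANCER
    lstage[slot] = 1
    cq[slot] = q
    tq = sample_sojourn_q(key, slot, sojourn_mean_q, sojourn_sd_q)
    csoj[slot] = tq
    sstage = _pick(sympt_cdf, _u01(key, D_SYMPT, slot, 0)) + 1
    csympt[slot] = sstage
    # partition sojourn over preclinical stages 1..sstage
    wsum = 0.0
    for k in range(sstage):
        wsum += dwell_w[k]
    acc = 0
    for k in range(3):
        if k < sstage - 1:
            acc += int(np.floor(tq * dwell_w[k] / wsum))
            cumdw[slot, k] = acc
        else:
            cumdw[slot, k] = tq
    cumdw[slot, 3] = tq
    misc[M_TOCANCER] += 0.0 if origin == O_DIRECT else 1.0
    misc[M_TOTAL_CANCERS] += 1.0
    if origin == O_ADENOMA:
        misc[M_ORIGIN_ADE] += 1.0
    elif origin == O_FAST:
        misc[M_ORIGIN_FAST] += 1.0
    else:
        misc[M_ORIGIN_DIRECT] += 1.0
    if origin != O_DIRECT:
        d = q - ladebirth[slot]
        if d < 0:
            d = 0
        if d >= dwell_hist.shape[0]:
            d = dwell_hist.shape[0] - 1
        dwell_hist[d] += 1.0


@njit(inline="always", cache=True)
def _cancer_stage_at(slot, elapsed, cumdw):
    st = 1
    for k in range(3):
        if elapsed >= cumdw[slot, k]:
            st = k + 2
    return st


@njit(cache=True)
def run_population(n, seed, nh, scr, econ, tal):
    """Simulate ``n`` individuals; accumulate tallies in ``tal`` (mutated)."""
    (init_rate_q, early_rate_q, adv_rate_q, rect_mult_early, rect_mult_adv,
     stage_prog, stage_reg, stage_cancer, direct_total_q, direct_seg_cdf,
     loc_cdf, iq, iv, eq, ev, aq, av, sojourn_mean_q, sojourn_sd_q,
     sympt_cdf, dwell_w, crc_haz_q, natdeath_cdf, male_frac) = nh

    (mode, screen_qs, enroll_flag, enroll_lo_q, enroll_hi_q, window_q,
     adherence, fu_adherence, second_frac, reach_cdf, sig_reach_cdf,
     det_stage, flex_mult, sig_pen, compl_p, compl_polyp_mult, compl_fatal,
     fobt_sens, fobt_spec, surv_int_adv_q, surv_int_small_q, surv_postcrc_q,
     surveillance_on, surv_adherence, surv_stop_q) = scr

    (c_proc, c_compl, t_initial, t_cont_q, t_term) = econ

    (alive_at_age, ge1_early, ge1_adv, ge1_any, ge2, ge3, py, inc, inc_mode,
     inc_stage_sympt, inc_stage_screen, inc_left, inc_right, inc_rectum,
     crc_death, other_death, compl_death, procedures, polypectomies,
     compl_counts, costs_year, misc, dwell_hist, window) = tal

    lstate = np.zeros(MAXL, dtype=np.int64)
    lstage = np.zeros(MAXL, dtype=np.int64)
    lseg = np.zeros(MAXL, dtype=np.int64)
    lbirth = np.zeros(MAXL, dtype=np.int64)
    ladebirth = np.zeros(MAXL, dtype=np.int64)
    lme = np.zeros(MAXL, dtype=np.float64)
    lma = np.zeros(MAXL, dtype=np.float64)
    cq = np.zeros(MAXL, dtype=np.int64)
    csoj = np.zeros(MAXL, dtype=np.int64)
    csympt = np.zeros(MAXL, dtype=np.int64)
    cumdw = np.zeros((MAXL, 4), dtype=np.int64)
    sympt_now = np.zeros(MAXL, dtype=np.int64)

    n_screens = screen_qs.shape[0]

    for idx in range(n):
        key = individual_key(seed, idx)
        sex = 1 if _u01(key, D_SEX, 0, 0) < male_frac else 0
        imult = _interp(iq, iv, _u01(key, D_IMULT, 0, 0))
        und = _u01(key, D_NATDEATH, 0, 0)
        nat_death_q = _pick(natdeath_cdf, und)
        adherent = _u01(key, D_ADHERE, 0, 0) < adherence
        second_ok = _u01(key, D_SECOND, 0, 0) < second_frac

        enroll_q = 0
        if enroll_flag == 1:
            span = (enroll_hi_q - enroll_lo_q) // 4 + 1
            ey = int(_u01(key, D_ENROLL, 0, 0) * span)
            if ey >= span:
                ey = span - 1
            enroll_q = enroll_lo_q + 4 * ey
        win_lo = enroll_q
        win_hi = enroll_q + window_q if window_q > 0 else -1

        nles = 0
        treat = 0
        diag_q = -1000
        diag_stage = 0
        next_surv = -1
        had_crc = 0
        alive = True

        for s in range(MAXL):
            lstate[s] = L_EMPTY

        for q in range(MAX_Q):
            age = q >> 2
            if age > 100:
                break
            # ---- birthday tallies -------------------------------------
            if q & 3 == 0:
                alive_at_age[sex, age] += 1.0
                ne = 0
                na = 0
                for s in range(nles):
                    if lstate[s] == L_ADENOMA:
                        if lstage[s] <= 4:
                            ne += 1
                        else:
                            na += 1
                tot = ne + na
                if ne > 0:
                    ge1_early[sex, age] += 1.0
                if na > 0:
                    ge1_adv[sex, age] += 1.0
                if tot > 0:
                    ge1_any[age] += 1.0
                if tot >= 2:
                    ge2[age] += 1.0
                if tot >= 3:
                    ge3[age] += 1.0
            py[sex, age] += 0.25

            # ---- natural history --------------------------------------
            any_sympt = False
            # new adenoma
            p_new = init_rate_q[sex, q] * imult
            if p_new > 1.0:
                p_new = 1.0
            if _u01(key, D_INIT, q, 0) < p_new:
                if nles < MAXL:
                    s = nles
                    nles += 1
                    lstate[s] = L_ADENOMA
                    lstage[s] = 1
                    lseg[s] = _pick(loc_cdf, _u01(key, D_INIT_SEG, q, 0)) + 1
                    lbirth[s] = q
                    ladebirth[s] = q
                    lme[s] = _interp(eq, ev, _u01(key, D_MULT_E, s, 0))
                    lma[s] = _interp(aq, av, _u01(key, D_MULT_A, s, 0))
                    misc[M_INITIATED] += 1.0
                else:
                    misc[M_OVERFLOW] += 1.0
            # per-lesion events
            for s in range(nles):
                st = lstate[s]
                if st == L_ADENOMA and lbirth[s] < q:
                    stg = lstage[s]
                    seg = lseg[s]
                    if stg <= 4:
                        p_prog = (early_rate_q[sex, q] * lme[s]
                                  * stage_prog[stg - 1] * rect_mult_early[seg - 1])
                    else:
                        p_prog = (adv_rate_q[sex, q] * lma[s]
                                  * stage_prog[stg - 1] * rect_mult_adv[seg - 1])
                    p_fast = 0.0
                    if stg <= 5:
                        p_fast = (adv_rate_q[sex, q] * lma[s]
                                  * stage_cancer[stg - 1] * rect_mult_adv[seg - 1])
                    p_reg = stage_reg[stg - 1]
                    ptot = p_prog + p_fast + p_reg
                    if ptot > 1.0:
                        misc[M_CLIP_WARN] += 1.0
                        scale = 1.0 / ptot
                        p_prog *= scale
                        p_fast *= scale
                        p_reg *= scale
                    u = _u01(key, D_LESEVENT, q, s)
                    if u < p_prog:
                        if stg == 6:
                            _start_cancer(s, q, O_ADENOMA, key, lstate, lstage,
                                          lseg, cq, csoj, csympt, cumdw,
                                          ladebirth, sojourn_mean_q,
                                          sojourn_sd_q, sympt_cdf, dwell_w,
                                          misc, dwell_hist)
                        else:
                            lstage[s] = stg + 1
                    elif u < p_prog + p_fast:
                        _start_cancer(s, q, O_FAST, key, lstate, lstage, lseg,
                                      cq, csoj, csympt, cumdw, ladebirth,
                                      sojourn_mean_q, sojourn_sd_q, sympt_cdf,
                                      dwell_w, misc, dwell_hist)
                    elif u < p_prog + p_fast + p_reg:
                        if stg == 1:
                            lstate[s] = L_REMOVED
                            misc[M_REGRESSED] += 1.0
                        else:
                            lstage[s] = stg - 1
                elif st == L_PRECANCER:
                    elapsed = q - cq[s]
                    lstage[s] = _cancer_stage_at(s, elapsed, cumdw)
                    if elapsed >= csoj[s]:
                        lstage[s] = csympt[s]
                        sympt_now[s] = 1
                        any_sympt = True
            # direct cancer
            if _u01(key, D_DIRECT, q, 0) < direct_total_q[q]:
                if nles < MAXL:
                    s = nles
                    nles += 1
                    lseg[s] = _pick(direct_seg_cdf,
                                    _u01(key, D_DIRECT_SEG, q, 0)) + 1
                    lbirth[s] = q
                    ladebirth[s] = q
                    lme[s] = 1.0
                    lma[s] = 1.0
                    _start_cancer(s, q, O_DIRECT, key, lstate, lstage, lseg,
                                  cq, csoj, csympt, cumdw, ladebirth,
                                  sojourn_mean_q, sojourn_sd_q, sympt_cdf,
                                  dwell_w, misc, dwell_hist)
                else:
                    misc[M_OVERFLOW] += 1.0

            # ---- endoscopy / screening --------------------------------
            do_colo = False
            colo_ctx = CTX_DIAG
            if any_sympt:
                do_colo = True
                colo_ctx = CTX_DIAG
            elif (surveillance_on == 1 and next_surv >= 0 and q == next_surv
                  and _u01(key, D_FU, q, 1) < surv_adherence):
                do_colo = True
                colo_ctx = CTX_SURV
            elif mode != MODE_NONE and adherent and treat == 0 and next_surv < 0:
                due = False
                for i in range(n_screens):
                    sq = screen_qs[i] + (enroll_q if enroll_flag == 1 else 0)
                    if sq == q:
                        if i == 0 or second_frac >= 1.0 or second_ok:
                            due = True
                if due:
                    if mode == MODE_COLO:
                        do_colo = True
                        colo_ctx = CTX_SCREEN
                    elif mode == MODE_PERFECT:
                        for s in range(nles):
                            if lstate[s] == L_ADENOMA:
                                lstate[s] = L_REMOVED
                                misc[M_RESECTED] += 1.0
                            elif lstate[s] == L_PRECANCER:
                                lstate[s] = L_REMOVED
                    elif mode == MODE_SIG:
                        procedures[age, P_SIG, CTX_SCREEN] += 1.0
                        costs_year[age, 0] += c_proc[2]
                        reach = _pick(sig_reach_cdf, _u01(key, D_SIGREACH, q, 0)) + 1
                        referral = False
                        for s in range(nles):
                            st = lstate[s]
                            if (st == L_ADENOMA or st == L_PRECANCER) and lseg[s] <= reach:
                                if st == L_ADENOMA and lstage[s] <= 4:
                                    pen = sig_pen[0]
                                    d = det_stage[lstage[s] - 1]
                                elif st == L_ADENOMA:
                                    pen = sig_pen[1]
                                    d = det_stage[lstage[s] - 1]
                                else:
                                    pen = sig_pen[1]
                                    d = det_stage[6]
                                d = d * pen * flex_mult[lseg[s] - 1]
                                if _u01(key, D_DETECT, q, s) < d:
                                    referral = True
                        # complications at a fraction of colonoscopy rates
                        for t in range(4):
                            if _u01(key, D_COMPL, q, t) < compl_p[t] * 0.1:
                                compl_counts[t] += 1.0
                                costs_year[age, 1] += c_compl[t]
                                if _u01(key, D_COMPL_DEATH, q, t) < compl_fatal[t]:
                                    alive = False
                                    compl_death[age] += 1.0
                        if not alive:
                            break
                        if referral and _u01(key, D_FU, q, 0) < fu_adherence:
                            do_colo = True
                            colo_ctx = CTX_FOLLOWUP
                    elif mode == MODE_FOBT:
                        procedures[age, P_FOBT, CTX_SCREEN] += 1.0
                        costs_year[age, 0] += c_proc[3]
                        pos = False
                        has_lesion = False
                        for s in range(nles):
                            st = lstate[s]
                            if st == L_ADENOMA or st == L_PRECANCER:
                                has_lesion = True
                                if st == L_PRECANCER:
                                    sv = fobt_sens[2]
                                elif lstage[s] >= 5:
                                    sv = fobt_sens[1]
                                else:
                                    sv = fobt_sens[0]
                                if _u01(key, D_FOBT_L, q, s) < sv:
                                    pos = True
                        if not has_lesion:
                            if _u01(key, D_FOBT_FP, q, 0) < 1.0 - fobt_spec:
                                pos = True
                        if pos and _u01(key, D_FU, q, 0) < fu_adherence:
                            do_colo = True
                            colo_ctx = CTX_FOLLOWUP

            if do_colo and alive:
                procedures[age, P_COLO, colo_ctx] += 1.0
                costs_year[age, 0] += c_proc[0]
                reach = _pick(reach_cdf, _u01(key, D_REACH, q, 0)) + 1
                polyp = False
                n_small = 0
                n_adv = 0
                cancers_found = 0
                best_stage = 0
                for s in range(nles):
                    st = lstate[s]
                    if st != L_ADENOMA and st != L_PRECANCER:
                        continue
                    forced = st == L_PRECANCER and sympt_now[s] == 1
                    if lseg[s] > reach and not forced:
                        continue
                    if st == L_PRECANCER:
                        d = det_stage[6]
                    else:
                        d = det_stage[lstage[s] - 1]
                    d *= flex_mult[lseg[s] - 1]
                    if forced:
                        d = 1.0
                    if _u01(key, D_DETECT, q, s) >= d:
                        continue
                    if st == L_ADENOMA:
                        lstate[s] = L_REMOVED
                        misc[M_RESECTED] += 1.0
                        polyp = True
                        if lstage[s] >= 5:
                            n_adv += 1
                        else:
                            n_small += 1
                    else:
                        lstate[s] = L_CLINICAL
                        cancers_found += 1
                        stg = lstage[s]
                        if stg > best_stage:
                            best_stage = stg
                        inc[sex, age] += 1.0
                        # mode columns: 0 symptomatic/diagnostic, 1 screening,
                        # 2 surveillance, 3 follow-up
                        if sympt_now[s] == 1 or colo_ctx == CTX_DIAG:
                            inc_mode[age, 0] += 1.0
                            inc_stage_sympt[stg - 1] += 1.0
                        else:
                            if colo_ctx == CTX_SCREEN:
                                inc_mode[age, 1] += 1.0
                            elif colo_ctx == CTX_SURV:
                                inc_mode[age, 2] += 1.0
                            else:
                                inc_mode[age, 3] += 1.0
                            inc_stage_screen[stg - 1] += 1.0
                        if lseg[s] <= LEFT_MAX_SEG:
                            inc_left[age] += 1.0
                        else:
                            inc_right[age] += 1.0
                        if lseg[s] <= RECTUM_MAX_SEG:
                            inc_rectum[age] += 1.0
                        if win_hi > 0 and win_lo <= q < win_hi:
                            window[W_INC] += 1.0
                            if lseg[s] <= LEFT_MAX_SEG:
                                window[W_LEFT] += 1.0
                            else:
                                window[W_RIGHT] += 1.0
                if polyp:
                    polypectomies[age] += 1.0
                    costs_year[age, 0] += c_proc[1]
                if cancers_found > 0:
                    misc[M_PERSON_DIAG] += 1.0
                    if cancers_found >= 2:
                        misc[M_SYNCH] += 1.0
                    treat = 1
                    had_crc = 1
                    diag_q = q
                    diag_stage = best_stage
                    costs_year[age, 2] += t_initial[best_stage - 1]
                    if surveillance_on == 1:
                        next_surv = q + surv_postcrc_q
                    else:
                        next_surv = -1
                elif polyp:
                    if surveillance_on == 1:
                        if n_adv > 0 or n_adv + n_small >= 3:
                            next_surv = q + surv_int_adv_q
                        else:
                            next_surv = q + surv_int_small_q
                    else:
                        next_surv = -1
                else:
                    # clean exam: stay under surveillance if already in it
                    # (until the surveillance stop age), else routine screening
                    if (colo_ctx == CTX_SURV and surveillance_on == 1
                            and q < surv_stop_q):
                        next_surv = q + surv_int_small_q
                    else:
                        next_surv = -1
                cmult = compl_polyp_mult if polyp else 1.0
                for t in range(4):
                    if _u01(key, D_COMPL, q, t) < compl_p[t] * cmult:
                        compl_counts[t] += 1.0
                        costs_year[age, 1] += c_compl[t]
                        if _u01(key, D_COMPL_DEATH, q, t) < compl_fatal[t]:
                            alive = False
                            compl_death[age] += 1.0
                if not alive:
                    break
            for s in range(nles):
                sympt_now[s] = 0

            # ---- treatment costs and CRC death ------------------------
            if treat == 1:
                tq_el = q - diag_q
                if tq_el > 20:
                    treat = 0
                else:
                    if tq_el > 0:
                        costs_year[age, 2] += t_cont_q[diag_stage - 1]
                    if _u01(key, D_CRCHAZ, q, 0) < crc_haz_q[diag_stage - 1]:
                        # CRC death: terminal-phase costs replace continuing
                        # costs over the up-to-12 preceding months
                        nterm = tq_el + 1
                        if nterm > 4:
                            nterm = 4
                        refund = t_cont_q[diag_stage - 1] * min(nterm, max(tq_el, 0))
                        costs_year[age, 2] += t_term[diag_stage - 1] * (nterm / 4.0) - refund
                        crc_death[sex, age] += 1.0
                        yl = (nat_death_q - q) / 4.0
                        if yl > 0:
                            misc[M_YEARS_LOST] += yl
                        if win_hi > 0 and win_lo <= q < win_hi:
                            window[W_DEATH] += 1.0
                        alive = False
                        break

            # ---- other-cause death ------------------------------------
            if q >= nat_death_q:
                other_death[age] += 1.0
                alive = False
                break

        # end of life bookkeeping
        for s in range(nles):
            if lstate[s] == L_ADENOMA:
                misc[M_REMAIN] += 1.0
    return 0
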