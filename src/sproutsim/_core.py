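"""Numba event-loop core of the next-subvolume simulation engine.

Everything here operates on flat arrays prepared by :mod:`sproutsim.engine`.
Each voxel carries 18 event channels: the 12 elementary signalling
reactions (indices 0-11, matching
:data:`sproutsim.subcellular.STOICHIOMETRY`) and 6 migration directions
(indices 12-17).  Per-voxel total propensities and exponential next-event
times are maintained incrementally; after every event the voxels whose
rates depend on the changed state (the overlap neighbourhood of the
signalling radius, which contains the lattice neighbours) are refreshed
and their clocks redrawn — valid by memorylessness.

Deterministic fields are materialised lazily: each voxel stores the time
its ECM density, BM concentration and orientation landscape were last
advanced, and the exact clamped-linear / exponential update is applied on
read.  Voxels are always materialised *before* any Delta level in their
proteolytic footprint changes, so the piecewise-constant integration is
exact.  Cached von Mises direction masses are recomputed whenever the
owning cell's Delta, BM level or local landscape changes (they lag the
slow continuous BM growth between such refreshes).

All rates are per simulation time unit (500 minutes).
"""

import math

import numpy as np
from numba import njit

# -- parameter vector layouts ------------------------------------------------
# Subcellular row (per lineage variant), rates per simulation unit:
SP_BN, SP_BD, SP_BR2, SP_GAMMA, SP_GAMMAE, SP_KT, SP_KC, SP_KV, SP_ETA, \
    SP_I0, SP_LIN, SP_NN, SP_R2S0, SP_LRD, SP_ND, SP_LIR2, SP_NR2 = range(17)
NSP = 17

# Global vector:
G_DW, G_CMAX, G_EF1, G_EF2, G_SF1, G_SF2, G_PMAX, G_SP, G_DP, G_K, G_KM, \
    G_KD, G_AH, G_NH, G_ETAMAX, G_SC, G_DC, G_GMAX, G_SM, G_DM, G_DL, \
    G_ETAL, G_OMEGA, G_XI, G_FREEZE_MIG, G_FREEZE_FIELDS, G_BD_THRESH, \
    G_WNB = range(28)
NG = 28

N_SUB = 12
N_CH = 18

# Direction geometry (order r, ur, ul, l, dl, dr).
_ANG = np.array([0.0, math.pi / 3, 2 * math.pi / 3, math.pi,
                 -2 * math.pi / 3, -math.pi / 3])
DIR_LO = _ANG - math.pi / 6
DIR_HI = _ANG + math.pi / 6

# Stoichiometry (must match sproutsim.subcellular.STOICHIOMETRY).
STOICH = np.array(
    [[1, 0, 0, 0, 0], [0, 1, 0, 0, 0], [0, 0, 0, 1, 0],
     [-1, 0, 0, 0, 0], [0, -1, 0, 0, 0], [0, 0, 0, -1, 0],
     [0, 0, -1, 0, 0], [0, 0, 0, 0, -1],
     [-1, 0, 1, 0, 0], [0, -1, 0, 0, 0], [-1, -1, 0, 0, 0],
     [0, 0, 0, -1, 1]], dtype=np.int64)

# Gauss-Legendre rule for the von Mises interval masses.
_gl = np.polynomial.legendre.leggauss(24)
GL_X = np.ascontiguousarray(_gl[0])
GL_W = np.ascontiguousarray(_gl[1])


@njit(cache=True, inline="always")
def _hs(X, X0, lam, n):
    r = (X / X0) ** n
    return (1.0 + lam * r) / (1.0 + r)


@njit(cache=True, inline="always")
def _eta_c(Dc, G):
    return G[G_ETAMAX] / (1.0 + math.exp(-G[G_SC] * (Dc - G[G_DC])))


@njit(cache=True, inline="always")
def _gamma_m(Dc, G):
    return G[G_GMAX] / (1.0 + math.exp(-G[G_SM] * (Dc - G[G_DM])))


@njit(cache=True, inline="always")
def _exp_draw():
    return -math.log(1.0 - np.random.random())


@njit(cache=True)
def materialise(v, t, E, X, c, m, l, t_field, nb, G):
    """Advance voxel v's deterministic fields exactly to time t."""
    dt = t - t_field[v]
    if dt <= 0.0:
        return
    omega = G[G_OMEGA]
    if G[G_FREEZE_FIELDS] == 0.0:
        # proteolysis by the resident cell plus, at reduced weight, by
        # cells in adjacent voxels (filopodial reach of matrix proteases)
        rate_c = 0.0
        if E[v] == 1:
            Dc = X[v, 1] / omega
            rate_c += _eta_c(Dc, G)
            if m[v] < 1.0:
                m[v] = min(1.0, m[v] + _gamma_m(Dc, G) * dt)
        if c[v] > 0.0:
            for s in range(6):
                k = nb[v, s]
                if k >= 0 and E[k] == 1:
                    rate_c += G[G_WNB] * _eta_c(X[k, 1] / omega, G)
            if rate_c > 0.0:
                c[v] = max(0.0, c[v] - rate_c * dt)
    decay = math.exp(-G[G_ETAL] * dt)
    for s in range(6):
        l[v, s] *= decay
    t_field[v] = t


@njit(cache=True)
def update_masses(v, masses, X, m, l, G):
    """Recompute the cached von Mises direction masses of voxel v."""
    ah = G[G_AH]
    nh = G[G_NH]
    px = 0.0
    py = 0.0
    for s in range(6):
        x = l[v, s]
        if x > 0.0:
            r = (x / ah) ** nh
            w = r / (1.0 + r)
            px += w * math.cos(_ANG[s])
            py += w * math.sin(_ANG[s])
    norm = math.hypot(px, py)
    if norm < 1e-12:
        for s in range(6):
            masses[v, s] = 1.0 / 6.0
        return
    mu = math.atan2(py, px)
    Dc = X[v, 1] / G[G_OMEGA]
    kappa = G[G_K] * math.exp(G[G_KM] * m[v] - G[G_KD] * Dc)
    tot = 0.0
    for s in range(6):
        mid = 0.5 * (DIR_LO[s] + DIR_HI[s])
        half = 0.5 * (DIR_HI[s] - DIR_LO[s])
        acc = 0.0
        for q in range(GL_X.shape[0]):
            phi = mid + half * GL_X[q]
            acc += GL_W[q] * math.exp(kappa * (math.cos(phi - mu) - 1.0))
        masses[v, s] = half * acc
        tot += half * acc
    for s in range(6):
        masses[v, s] /= tot


@njit(cache=True)
def refresh_voxel(v, t, E, lin, X, c, m, l, t_field, Dbar_num, Nbar_num,
                  EN_num, masses, prop, ptot, nb, a_indptr, a_idx, a_w,
                  a_wsum, p_wsum, SP, Vf, G):
    """Recompute all 18 channel propensities of voxel v at time t."""
    materialise(v, t, E, X, c, m, l, t_field, nb, G)
    for ch in range(N_CH):
        prop[v, ch] = 0.0
    if E[v] == 1:
        sp = SP[lin[v]]
        omega = G[G_OMEGA]
        N = float(X[v, 0])
        D = float(X[v, 1])
        I = float(X[v, 2])
        R2 = float(X[v, 3])
        R2s = float(X[v, 4])
        # neighbourhood averages on the concentration scale
        Dbar = Dbar_num[v] / (a_wsum[v] * omega) if a_wsum[v] > 0.0 else 0.0
        Nbar = Nbar_num[v] / (a_wsum[v] * omega) if a_wsum[v] > 0.0 else 0.0
        prop[v, 0] = omega * sp[SP_BN] * _hs(I / omega, sp[SP_I0], sp[SP_LIN], sp[SP_NN])
        prop[v, 1] = omega * sp[SP_BD] * _hs(R2s / omega, sp[SP_R2S0], sp[SP_LRD], sp[SP_ND])
        prop[v, 2] = omega * sp[SP_BR2] * _hs(I / omega, sp[SP_I0], sp[SP_LIR2], sp[SP_NR2])
        prop[v, 3] = sp[SP_GAMMA] * N
        prop[v, 4] = sp[SP_GAMMA] * D
        prop[v, 5] = sp[SP_GAMMA] * R2
        prop[v, 6] = sp[SP_GAMMAE] * I
        prop[v, 7] = sp[SP_GAMMAE] * R2s
        prop[v, 8] = sp[SP_KT] * Dbar * N
        prop[v, 9] = sp[SP_ETA] * sp[SP_KT] * Nbar * D
        prop[v, 10] = (sp[SP_KC] / omega) * N * D
        prop[v, 11] = sp[SP_KV] * Vf[v] * R2
        if G[G_FREEZE_MIG] == 0.0:
            EN = EN_num[v] / p_wsum[v] if p_wsum[v] > 0.0 else 0.0
            up = 1.0 / (1.0 + math.exp(-G[G_SF1] * (EN - G[G_EF1])))
            dn = 1.0 / (1.0 + math.exp(G[G_SF2] * (EN - G[G_EF2])))
            F = up + dn - 1.0
            if F > 0.0:
                base = G[G_DW] * F
                Dc = D / G[G_OMEGA]
                psw = G[G_PMAX] / (1.0 + math.exp(-G[G_SP] * (Dc - G[G_DP])))
                for s in range(6):
                    j = nb[v, s]
                    if j < 0:
                        continue
                    # motility gated on the ECM density of the voxel entered
                    materialise(j, t, E, X, c, m, l, t_field, nb, G)
                    S = 1.0 - c[j] / G[G_CMAX]
                    if S <= 0.0:
                        continue
                    rho = psw if E[j] == 1 else 1.0
                    prop[v, 12 + s] = base * S * rho * masses[v, s]
    tot = 0.0
    for ch in range(N_CH):
        tot += prop[v, ch]
    ptot[v] = tot


@njit(cache=True)
def _recompute_signal_sums(v, E, X, Dbar_num, Nbar_num, EN_num,
                           a_indptr, a_idx, a_w, p_indptr, p_idx, p_w):
    dn = 0.0
    nn = 0.0
    for p in range(a_indptr[v], a_indptr[v + 1]):
        k = a_idx[p]
        dn += a_w[p] * X[k, 1]
        nn += a_w[p] * X[k, 0]
    Dbar_num[v] = dn
    Nbar_num[v] = nn
    en = 0.0
    for p in range(p_indptr[v], p_indptr[v + 1]):
        en += p_w[p] * E[p_idx[p]]
    EN_num[v] = en


@njit(cache=True)
def full_refresh(t, E, lin, X, c, m, l, t_field, Dbar_num, Nbar_num, EN_num,
                 masses, prop, ptot, tnext, nb, a_indptr, a_idx, a_w, a_wsum,
                 p_indptr, p_idx, p_w, p_wsum, SP, Vf, G):
    """From-scratch recomputation of every cached quantity (and new clocks)."""
    n = E.shape[0]
    for v in range(n):
        materialise(v, t, E, X, c, m, l, t_field, nb, G)
    for v in range(n):
        _recompute_signal_sums(v, E, X, Dbar_num, Nbar_num, EN_num,
                               a_indptr, a_idx, a_w, p_indptr, p_idx, p_w)
        update_masses(v, masses, X, m, l, G)
    for v in range(n):
        refresh_voxel(v, t, E, lin, X, c, m, l, t_field, Dbar_num, Nbar_num,
                      EN_num, masses, prop, ptot, nb, a_indptr, a_idx, a_w,
                      a_wsum, p_wsum, SP, Vf, G)
        tnext[v] = t + _exp_draw() / ptot[v] if ptot[v] > 0.0 else np.inf


@njit(cache=True)
def _spawn(v, t, E, lin, X, spawn_lin, init_mean, G, next_label, label):
    """Introduce a fresh cell at plexus voxel v (constant-supply boundary)."""
    E[v] = 1
    lin[v] = spawn_lin[v]
    label[v] = next_label
    xi = G[G_XI]
    for sp_i in range(5):
        mean = init_mean[spawn_lin[v], sp_i]
        u = 2.0 * np.random.random() - 1.0
        X[v, sp_i] = max(0, int(round(mean * (1.0 + xi * u))))


@njit(cache=True)
def run_core(t_start, t_end, seed, E, lin, label, X, c, m, l, t_field,
             Dbar_num, Nbar_num, EN_num, masses, prop, ptot, tnext,
             nb, a_indptr, a_idx, a_w, a_wsum, p_indptr, p_idx, p_w, p_wsum,
             d_indptr, d_idx, SP, Vf, G, is_plexus, spawn_lin, init_mean,
             sample_dt, samp_t, samp_vox, samp_label, samp_lin, samp_D,
             samp_count, next_label_arr, max_events,
             ev_t, ev_vox, ev_ch, ev_count):
    """Run the next-subvolume loop from t_start until t_end (or max_events).

    Trajectory samples (time, voxel, label, lineage, Delta copy number) are
    recorded on the fixed grid ``t_start + k*sample_dt``; optional per-event
    records go to the ev_* buffers while capacity lasts.  Returns the clock.
    """
    np.random.seed(seed)
    n = E.shape[0]
    full_refresh(t_start, E, lin, X, c, m, l, t_field, Dbar_num, Nbar_num,
                 EN_num, masses, prop, ptot, tnext, nb, a_indptr, a_idx, a_w,
                 a_wsum, p_indptr, p_idx, p_w, p_wsum, SP, Vf, G)
    clock = t_start
    next_sample = t_start
    events = 0
    while True:
        # next event
        i = 0
        tmin = tnext[0]
        for v in range(1, n):
            if tnext[v] < tmin:
                tmin = tnext[v]
                i = v
        # record samples up to min(tmin, t_end)
        horizon = tmin if tmin < t_end else t_end
        while next_sample <= horizon + 1e-12:
            k = samp_count[0]
            for v in range(n):
                if E[v] == 1:
                    if k < samp_t.shape[0]:
                        samp_t[k] = next_sample
                        samp_vox[k] = v
                        samp_label[k] = label[v]
                        samp_lin[k] = lin[v]
                        samp_D[k] = X[v, 1]
                        k += 1
            samp_count[0] = k
            next_sample += sample_dt
        if tmin >= t_end or events >= max_events:
            clock = t_end if tmin >= t_end else clock
            break
        clock = tmin
        # channel selection within voxel i
        u = np.random.random() * ptot[i]
        acc = 0.0
        ch = N_CH - 1
        for cc in range(N_CH):
            acc += prop[i, cc]
            if u < acc:
                ch = cc
                break
        if ev_count[0] < ev_t.shape[0]:
            ev_t[ev_count[0]] = clock
            ev_vox[ev_count[0]] = i
            ev_ch[ev_count[0]] = ch
            ev_count[0] += 1
        events += 1

        if ch < N_SUB:
            dN = STOICH[ch, 0]
            dD = STOICH[ch, 1]
            if dD != 0 or dN != 0:
                # materialise footprint before the Delta/Notch level changes
                if G[G_FREEZE_FIELDS] == 0.0 and dD != 0:
                    for p in range(d_indptr[i], d_indptr[i + 1]):
                        materialise(d_idx[p], clock, E, X, c, m, l, t_field,
                                    nb, G)
                for sp_i in range(5):
                    X[i, sp_i] += STOICH[ch, sp_i]
                for p in range(a_indptr[i], a_indptr[i + 1]):
                    k = a_idx[p]
                    Dbar_num[k] += a_w[p] * dD
                    Nbar_num[k] += a_w[p] * dN
                if dD != 0:
                    update_masses(i, masses, X, m, l, G)
                for p in range(d_indptr[i], d_indptr[i + 1]):
                    v = d_idx[p]
                    refresh_voxel(v, clock, E, lin, X, c, m, l, t_field,
                                  Dbar_num, Nbar_num, EN_num, masses, prop,
                                  ptot, nb, a_indptr, a_idx, a_w, a_wsum,
                                  p_wsum, SP, Vf, G)
                    tnext[v] = clock + _exp_draw() / ptot[v] \
                        if ptot[v] > 0.0 else np.inf
            else:
                for sp_i in range(5):
                    X[i, sp_i] += STOICH[ch, sp_i]
                refresh_voxel(i, clock, E, lin, X, c, m, l, t_field,
                              Dbar_num, Nbar_num, EN_num, masses, prop, ptot,
                              nb, a_indptr, a_idx, a_w, a_wsum, p_wsum,
                              SP, Vf, G)
                tnext[i] = clock + _exp_draw() / ptot[i] \
                    if ptot[i] > 0.0 else np.inf
        else:
            s = ch - N_SUB
            j = nb[i, s]
            # materialise both footprints before occupancy/Delta move
            for p in range(d_indptr[i], d_indptr[i + 1]):
                materialise(d_idx[p], clock, E, X, c, m, l, t_field, nb, G)
            for p in range(d_indptr[j], d_indptr[j + 1]):
                materialise(d_idx[p], clock, E, X, c, m, l, t_field, nb, G)
            # orientation stretching by the mover's Delta
            dl = G[G_DL] * (X[i, 1] / G[G_OMEGA])
            l[i, s] += dl
            l[j, s] += dl
            if E[j] == 1:
                # overtaking: the two cells exchange voxels
                for sp_i in range(5):
                    tmp = X[i, sp_i]
                    X[i, sp_i] = X[j, sp_i]
                    X[j, sp_i] = tmp
                tl = lin[i]
                lin[i] = lin[j]
                lin[j] = tl
                tb = label[i]
                label[i] = label[j]
                label[j] = tb
            else:
                E[j] = 1
                lin[j] = lin[i]
                label[j] = label[i]
                for sp_i in range(5):
                    X[j, sp_i] = X[i, sp_i]
                    X[i, sp_i] = 0
                E[i] = 0
                label[i] = -1
                if is_plexus[i] == 1:
                    _spawn(i, clock, E, lin, X, spawn_lin, init_mean, G,
                           next_label_arr[0], label)
                    next_label_arr[0] += 1
            # rebuild neighbourhood sums and rates around both voxels
            for p in range(d_indptr[i], d_indptr[i + 1]):
                v = d_idx[p]
                _recompute_signal_sums(v, E, X, Dbar_num, Nbar_num, EN_num,
                                       a_indptr, a_idx, a_w,
                                       p_indptr, p_idx, p_w)
            for p in range(d_indptr[j], d_indptr[j + 1]):
                v = d_idx[p]
                _recompute_signal_sums(v, E, X, Dbar_num, Nbar_num, EN_num,
                                       a_indptr, a_idx, a_w,
                                       p_indptr, p_idx, p_w)
            update_masses(i, masses, X, m, l, G)
            update_masses(j, masses, X, m, l, G)
            for p in range(d_indptr[i], d_indptr[i + 1]):
                v = d_idx[p]
                refresh_voxel(v, clock, E, lin, X, c, m, l, t_field,
                              Dbar_num, Nbar_num, EN_num, masses, prop, ptot,
                              nb, a_indptr, a_idx, a_w, a_wsum, p_wsum,
                              SP, Vf, G)
                tnext[v] = clock + _exp_draw() / ptot[v] \
                    if ptot[v] > 0.0 else np.inf
            for p in range(d_indptr[j], d_indptr[j + 1]):
                v = d_idx[p]
                refresh_voxel(v, clock, E, lin, X, c, m, l, t_field,
                              Dbar_num, Nbar_num, EN_num, masses, prop, ptot,
                              nb, a_indptr, a_idx, a_w, a_wsum, p_wsum,
                              SP, Vf, G)
                tnext[v] = clock + _exp_draw() / ptot[v] \
                    if ptot[v] > 0.0 else np.inf
    return clock
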