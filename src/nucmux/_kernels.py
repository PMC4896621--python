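"""Numba kernels for the Metropolis sampler.

The rotation primitives are re-implemented here in nopython mode for speed;
the python-level geometry API in :mod:`nucmux.mechanics` goes through
scipy and serves as the independent reference in the tests.

State layout (all modified in place by ``mc_chunk``):

* ``seq``    -- int8[N] base codes (A=0, C=1, G=2, T=3)
* ``R``      -- float64[N,3,3] base-pair orientations (columns = axes)
* ``o``      -- float64[N,3] base-pair origins [A]
* ``stepq``  -- float64[N-1,6] cached step parameters (A / degrees)
* ``E``      -- float64[N-1] cached step energies [kT]

Rotation components of step parameters are stored in degrees, matching the
parameter table; proposal widths arrive in A and degrees.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEG = np.pi / 180.0


@njit(cache=True, fastmath=False)
def _rotvec_to_mat(v, out):
    x, y, z = v[0], v[1], v[2]
    th2 = x * x + y * y + z * z
    th = np.sqrt(th2)
    if th < 1e-12:
        out[0, 0] = 1.0; out[0, 1] = -z; out[0, 2] = y
        out[1, 0] = z; out[1, 1] = 1.0; out[1, 2] = -x
        out[2, 0] = -y; out[2, 1] = x; out[2, 2] = 1.0
        return
    a = np.sin(th) / th
    b = (1.0 - np.cos(th)) / th2
    out[0, 0] = 1.0 - b * (y * y + z * z)
    out[0, 1] = -a * z + b * x * y
    out[0, 2] = a * y + b * x * z
    out[1, 0] = a * z + b * x * y
    out[1, 1] = 1.0 - b * (x * x + z * z)
    out[1, 2] = -a * x + b * y * z
    out[2, 0] = -a * y + b * x * z
    out[2, 1] = a * x + b * y * z
    out[2, 2] = 1.0 - b * (x * x + y * y)


@njit(cache=True, fastmath=False)
def _mat_to_rotvec(R, out):
    tr = R[0, 0] + R[1, 1] + R[2, 2]
    c = (tr - 1.0) / 2.0
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    th = np.arccos(c)
    wx = R[2, 1] - R[1, 2]
    wy = R[0, 2] - R[2, 0]
    wz = R[1, 0] - R[0, 1]
    if th < 1e-7:
        out[0] = 0.5 * wx
        out[1] = 0.5 * wy
        out[2] = 0.5 * wz
    else:
        f = th / (2.0 * np.sin(th))
        out[0] = f * wx
        out[1] = f * wy
        out[2] = f * wz


@njit(cache=True, fastmath=False)
def _mmT_mul(A, B, out):
    # out = A^T @ B
    for i in range(3):
        for j in range(3):
            out[i, j] = A[0, i] * B[0, j] + A[1, i] * B[1, j] + A[2, i] * B[2, j]


@njit(cache=True, fastmath=False)
def _mm_mul(A, B, out):
    for i in range(3):
        for j in range(3):
            out[i, j] = A[i, 0] * B[0, j] + A[i, 1] * B[1, j] + A[i, 2] * B[2, j]


@njit(cache=True, fastmath=False)
def _frames_to_step_nb(R1, o1, R2, o2, out):
    """Step parameters (shift, slide, rise, tilt, roll, twist) between frames."""
    M = np.empty((3, 3))
    _mmT_mul(R1, R2, M)
    rv = np.empty(3)
    _mat_to_rotvec(M, rv)
    Rh = np.empty((3, 3))
    half = np.empty(3)
    half[0] = rv[0] / 2.0; half[1] = rv[1] / 2.0; half[2] = rv[2] / 2.0
    _rotvec_to_mat(half, Rh)
    Rmid = np.empty((3, 3))
    _mm_mul(R1, Rh, Rmid)
    dx = o2[0] - o1[0]; dy = o2[1] - o1[1]; dz = o2[2] - o1[2]
    for k in range(3):
        out[k] = Rmid[0, k] * dx + Rmid[1, k] * dy + Rmid[2, k] * dz
    out[3] = rv[0] / DEG
    out[4] = rv[1] / DEG
    out[5] = rv[2] / DEG


@njit(cache=True, fastmath=False)
def _step_energy_nb(q, st, q0, Qm):
    e = 0.0
    dq = np.empty(6)
    for i in range(6):
        dq[i] = q[i] - q0[st, i]
    for i in range(6):
        row = 0.0
        for j in range(6):
            row += Qm[st, i, j] * dq[j]
        e += dq[i] * row
    return 0.5 * e


@njit(cache=True, fastmath=False)
def _pair_frames_from_mid(midR, mido, q, Ri, oi, Rj, oj):
    """Base-pair frames flanking a fixed midframe with internal step ``q``."""
    half = np.empty(3)
    half[0] = q[3] * DEG / 2.0
    half[1] = q[4] * DEG / 2.0
    half[2] = q[5] * DEG / 2.0
    Rh = np.empty((3, 3))
    _rotvec_to_mat(half, Rh)
    for a in range(3):
        for b in range(3):
            # Rj = midR @ Rh ; Ri = midR @ Rh^T
            Rj[a, b] = midR[a, 0] * Rh[0, b] + midR[a, 1] * Rh[1, b] + midR[a, 2] * Rh[2, b]
            Ri[a, b] = midR[a, 0] * Rh[b, 0] + midR[a, 1] * Rh[b, 1] + midR[a, 2] * Rh[b, 2]
    for a in range(3):
        tw = midR[a, 0] * q[0] + midR[a, 1] * q[1] + midR[a, 2] * q[2]
        oi[a] = mido[a] - tw / 2.0
        oj[a] = mido[a] + tw / 2.0


@njit(cache=True)
def total_energy(E):
    s = 0.0
    for i in range(E.shape[0]):
        s += E[i]
    return s


@njit(cache=True)
def refresh_energies(seq, stepq, E, q0, Qm):
    for i in range(stepq.shape[0]):
        st = 4 * seq[i] + seq[i + 1]
        E[i] = _step_energy_nb(stepq[i], st, q0, Qm)


@njit(cache=True)
def mc_chunk(seq, R, o, stepq, E,
             q0, Qm,
             cons_id, midR, mido,
             free_bp, cons_steps,
             beta, sig_t, sig_r,
             p_spatial,
             mut_positions,
             syn_mode, codon_starts, syn_n, syn_codons,
             n_moves, record_interval,
             rec_seq, rec_E, rec_lo, rec_hi,
             seed):
    """Run ``n_moves`` Metropolis moves; record every ``record_interval`` moves.

    Returns (n recorded, spatial proposals, spatial accepts, mutation
    proposals, mutation accepts).  ``cons_id[s]`` maps a constrained step to
    its midframe row (or -1); ``rec_E`` receives the energy summed over steps
    ``rec_lo..rec_hi`` inclusive at each snapshot.
    """
    np.random.seed(seed)
    N = seq.shape[0]
    n_free = free_bp.shape[0]
    n_cons = cons_steps.shape[0]
    n_spatial_targets = n_free + n_cons
    n_mut = mut_positions.shape[0]
    n_codons = codon_starts.shape[0]

    qtmp = np.empty((3, 6))
    etmp = np.empty(3)
    Rn = np.empty((3, 3))
    on = np.empty(3)
    Rn2 = np.empty((3, 3))
    on2 = np.empty(3)
    dv = np.empty(3)
    newq = np.empty(6)
    newbases = np.empty(3, dtype=np.int8)
    oldbases = np.empty(3, dtype=np.int8)

    n_rec = 0
    sp_prop = 0; sp_acc = 0
    mu_prop = 0; mu_acc = 0

    for mv in range(n_moves):
        spatial = np.random.random() < p_spatial
        if spatial and n_spatial_targets > 0:
            sp_prop += 1
            t = np.random.randint(n_spatial_targets)
            if t < n_free:
                b = free_bp[t]
                # rigid-body Gaussian perturbation of one unconstrained bp
                for k in range(3):
                    dv[k] = sig_r * DEG * np.random.standard_normal()
                _rotvec_to_mat(dv, Rn2)
                _mm_mul(R[b], Rn2, Rn)
                for k in range(3):
                    dv[k] = sig_t * np.random.standard_normal()
                for a in range(3):
                    on[a] = o[b, a] + R[b, a, 0] * dv[0] + R[b, a, 1] * dv[1] + R[b, a, 2] * dv[2]
                dE = 0.0
                nst = 0
                s0 = b - 1
                if s0 >= 0:
                    _frames_to_step_nb(R[s0], o[s0], Rn, on, qtmp[nst])
                    st = 4 * seq[s0] + seq[b]
                    etmp[nst] = _step_energy_nb(qtmp[nst], st, q0, Qm)
                    dE += etmp[nst] - E[s0]
                    nst += 1
                if b <= N - 2:
                    _frames_to_step_nb(Rn, on, R[b + 1], o[b + 1], qtmp[nst])
                    st = 4 * seq[b] + seq[b + 1]
                    etmp[nst] = _step_energy_nb(qtmp[nst], st, q0, Qm)
                    dE += etmp[nst] - E[b]
                    nst += 1
                if dE <= 0.0 or np.random.random() < np.exp(-beta * dE):
                    sp_acc += 1
                    for a in range(3):
                        o[b, a] = on[a]
                        for c in range(3):
                            R[b, a, c] = Rn[a, c]
                    nst = 0
                    if s0 >= 0:
                        for k in range(6):
                            stepq[s0, k] = qtmp[nst, k]
                        E[s0] = etmp[nst]
                        nst += 1
                    if b <= N - 2:
                        for k in range(6):
                            stepq[b, k] = qtmp[nst, k]
                        E[b] = etmp[nst]
            else:
                # internal move of a constrained pair: midframe stays fixed
                s = cons_steps[t - n_free]
                k_id = cons_id[s]
                for k in range(3):
                    newq[k] = stepq[s, k] + sig_t * np.random.standard_normal()
                    newq[k + 3] = stepq[s, k + 3] + sig_r * np.random.standard_normal()
                _pair_frames_from_mid(midR[k_id], mido[k_id], newq, Rn, on, Rn2, on2)
                dE = 0.0
                st = 4 * seq[s] + seq[s + 1]
                e_mid = _step_energy_nb(newq, st, q0, Qm)
                dE += e_mid - E[s]
                nst = 0
                if s - 1 >= 0:
                    _frames_to_step_nb(R[s - 1], o[s - 1], Rn, on, qtmp[nst])
                    st = 4 * seq[s - 1] + seq[s]
                    etmp[nst] = _step_energy_nb(qtmp[nst], st, q0, Qm)
                    dE += etmp[nst] - E[s - 1]
                    nst += 1
                if s + 2 <= N - 1:
                    _frames_to_step_nb(Rn2, on2, R[s + 2], o[s + 2], qtmp[nst])
                    st = 4 * seq[s + 1] + seq[s + 2]
                    etmp[nst] = _step_energy_nb(qtmp[nst], st, q0, Qm)
                    dE += etmp[nst] - E[s + 1]
                    nst += 1
                if dE <= 0.0 or np.random.random() < np.exp(-beta * dE):
                    sp_acc += 1
                    for a in range(3):
                        o[s, a] = on[a]
                        o[s + 1, a] = on2[a]
                        for c in range(3):
                            R[s, a, c] = Rn[a, c]
                            R[s + 1, a, c] = Rn2[a, c]
                    for k in range(6):
                        stepq[s, k] = newq[k]
                    E[s] = e_mid
                    nst = 0
                    if s - 1 >= 0:
                        for k in range(6):
                            stepq[s - 1, k] = qtmp[nst, k]
                        E[s - 1] = etmp[nst]
                        nst += 1
                    if s + 2 <= N - 1:
                        for k in range(6):
                            stepq[s + 1, k] = qtmp[nst, k]
                        E[s + 1] = etmp[nst]
        elif not spatial:
            mu_prop += 1
            if syn_mode == 0:
                if n_mut == 0:
                    continue
                p = mut_positions[np.random.randint(n_mut)]
                old = seq[p]
                alt = np.random.randint(3)
                new = alt if alt < old else alt + 1  # uniform over the 3 others
                dE = 0.0
                nst = 0
                if p - 1 >= 0:
                    st = 4 * seq[p - 1] + new
                    etmp[nst] = _step_energy_nb(stepq[p - 1], st, q0, Qm)
                    dE += etmp[nst] - E[p - 1]
                    nst += 1
                if p <= N - 2:
                    st = 4 * new + seq[p + 1]
                    etmp[nst] = _step_energy_nb(stepq[p], st, q0, Qm)
                    dE += etmp[nst] - E[p]
                    nst += 1
                if dE <= 0.0 or np.random.random() < np.exp(-beta * dE):
                    mu_acc += 1
                    seq[p] = new
                    nst = 0
                    if p - 1 >= 0:
                        E[p - 1] = etmp[nst]
                        nst += 1
                    if p <= N - 2:
                        E[p] = etmp[nst]
            else:
                if n_codons == 0:
                    continue
                cstart = codon_starts[np.random.randint(n_codons)]
                c = 16 * seq[cstart] + 4 * seq[cstart + 1] + seq[cstart + 2]
                nalt = syn_n[c]
                if nalt == 0:
                    continue  # Met/Trp: no synonymous alternative; counted rejected
                alt = syn_codons[c, np.random.randint(nalt)]
                newbases[0] = alt // 16
                newbases[1] = (alt // 4) % 4
                newbases[2] = alt % 4
                for k in range(3):
                    oldbases[k] = seq[cstart + k]
                    seq[cstart + k] = newbases[k]
                dE = 0.0
                lo = cstart - 1
                if lo < 0:
                    lo = 0
                hi = cstart + 2
                if hi > N - 2:
                    hi = N - 2
                for s in range(lo, hi + 1):
                    st = 4 * seq[s] + seq[s + 1]
                    e_new = _step_energy_nb(stepq[s], st, q0, Qm)
                    dE += e_new - E[s]
                if dE <= 0.0 or np.random.random() < np.exp(-beta * dE):
                    mu_acc += 1
                    for s in range(lo, hi + 1):
                        st = 4 * seq[s] + seq[s + 1]
                        E[s] = _step_energy_nb(stepq[s], st, q0, Qm)
                else:
                    for k in range(3):
                        seq[cstart + k] = oldbases[k]

        if record_interval > 0 and (mv + 1) % record_interval == 0:
            if n_rec < rec_seq.shape[0]:
                for k in range(N):
                    rec_seq[n_rec, k] = seq[k]
                ew = 0.0
                for s in range(rec_lo, rec_hi + 1):
                    ew += E[s]
                rec_E[n_rec] = ew
                n_rec += 1

    return n_rec, sp_prop, sp_acc, mu_prop, mu_acc
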