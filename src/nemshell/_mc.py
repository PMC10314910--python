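"""Numba kernels for Metropolis relaxation of the (q0, qm) texture.

The discretization here mirrors the vectorized energy code exactly
(central differences on interior rows, zero area weight at the poles), so
that energies tracked during a sweep agree with a full recomputation.
Only the texture-dependent densities (condensation, intrinsic, deviatoric)
enter the acceptance rule; the bending energy is unaffected by the texture.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# blend window; keep in sync with energy.LAM_ISO_LO / LAM_ISO_HI
_LO = 0.05
_HI = 0.15


@njit(cache=True, fastmath=False)
def _node_f(q0, qm, i, j, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D, C1, C2,
            alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted):
    if W[i] == 0.0:
        return 0.0
    n_phi = q0.shape[1]
    jm = (j - 1) % n_phi
    jp = (j + 1) % n_phi
    ds_ = 2.0 * inv_2ds  # 1/ds
    dphi_ = 2.0 * inv_2dphi  # 1/dphi
    sf0 = (q0[i + 1, j] - q0[i, j]) * ds_
    sb0 = (q0[i, j] - q0[i - 1, j]) * ds_
    sfm = (qm[i + 1, j] - qm[i, j]) * ds_
    sbm = (qm[i, j] - qm[i - 1, j]) * ds_
    scale = inv_rho[i] * dphi_
    con0 = 2.0 * kg2[i] * qm[i, j]
    conm = 2.0 * kg2[i] * q0[i, j]
    pf0 = scale * (q0[i, jp] - q0[i, j]) - con0
    pb0 = scale * (q0[i, j] - q0[i, jm]) - con0
    pfm = scale * (qm[i, jp] - qm[i, j]) + conm
    pbm = scale * (qm[i, j] - qm[i, jm]) + conm
    fi = ki * 0.5 * (sf0 * sf0 + sb0 * sb0 + sfm * sfm + sbm * sbm
                     + pf0 * pf0 + pb0 * pb0 + pfm * pfm + pbm * pbm)
    q2 = q0[i, j] * q0[i, j] + qm[i, j] * qm[i, j]
    if extrinsic:
        fi += ki * (C1[i] * C1[i] + C2[i] * C2[i]) * q2
    trq2 = 2.0 * q2
    fc = -alpha * trq2 + 0.5 * beta * trq2 * trq2
    favg = 0.5 * ke * ((H[i] - Cp) ** 2 + 0.5 * D[i] * D[i])
    if lam0 > 0.0:
        lam = np.sqrt(q2)
        t = (lam / lam0 - _LO) / (_HI - _LO)
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        if lam > 0.0:
            c = H[i] + D[i] * q0[i, j] / lam - Cp
            fdir = 0.5 * ke * c * c
            if fe_weighted:
                w_ = lam / lam0
                if w_ > 1.0:
                    w_ = 1.0
                fdir *= w_
        else:
            fdir = favg
        fe = t * fdir + (1.0 - t) * favg
    else:
        fe = favg
    return W[i] * (fi + fc + fe)


@njit(cache=True, fastmath=False)
def _local_sum(q0, qm, i, j, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D, C1, C2,
               alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted):
    n_s = q0.shape[0]
    n_phi = q0.shape[1]
    e = 0.0
    if 0 < i < n_s - 1:
        e += _node_f(q0, qm, i, j, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D,
                     C1, C2, alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted)
    if i - 1 > 0:
        e += _node_f(q0, qm, i - 1, j, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D,
                     C1, C2, alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted)
    if i + 1 < n_s - 1:
        e += _node_f(q0, qm, i + 1, j, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D,
                     C1, C2, alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted)
    if 0 < i < n_s - 1:
        jm = (j - 1) % n_phi
        jp = (j + 1) % n_phi
        e += _node_f(q0, qm, i, jm, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D,
                     C1, C2, alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted)
        e += _node_f(q0, qm, i, jp, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D,
                     C1, C2, alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted)
    return e


@njit(cache=True, fastmath=False)
def texture_energy(q0, qm, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D, C1, C2,
                   alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted):
    """Total texture-dependent energy (Fc + Fi + Fe) under the MC stencils."""
    e = 0.0
    for i in range(1, q0.shape[0] - 1):
        for j in range(q0.shape[1]):
            e += _node_f(q0, qm, i, j, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D,
                         C1, C2, alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted)
    return e


@njit(cache=True, fastmath=False)
def probe_scale(q0, qm, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D, C1, C2,
                alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted, step,
                n_probe, seed, angle_only=False):
    """Mean |dE| of random trial moves (nothing accepted); sets T_start.

    With angle_only=True only director rotations are probed, whose energy
    scale (elastic + deviatoric) is far below the condensation scale.
    """
    np.random.seed(seed)
    n_s = q0.shape[0]
    n_phi = q0.shape[1]
    acc = 0.0
    cnt = 0
    for _ in range(n_probe):
        i = 1 + np.random.randint(n_s - 2)
        j = np.random.randint(n_phi)
        old0, oldm = q0[i, j], qm[i, j]
        if angle_only:
            psi = 4.0 * step * np.random.normal()
            c, s_ = np.cos(psi), np.sin(psi)
            new0 = c * old0 - s_ * oldm
            newm = s_ * old0 + c * oldm
        else:
            new0 = old0 + step * np.random.normal()
            newm = oldm + step * np.random.normal()
        if new0 * new0 + newm * newm > 0.25:
            continue
        e0 = _local_sum(q0, qm, i, j, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D,
                        C1, C2, alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted)
        q0[i, j], qm[i, j] = new0, newm
        e1 = _local_sum(q0, qm, i, j, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D,
                        C1, C2, alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted)
        q0[i, j], qm[i, j] = old0, oldm
        acc += abs(e1 - e0)
        cnt += 1
    if cnt == 0:
        return 0.0
    return acc / cnt


@njit(cache=True, fastmath=False)
def mc_run(q0, qm, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D, C1, C2,
           alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted, T_arr,
           angle_frac, step, seed):
    """Metropolis single-site sweeps with Gaussian proposals.

    T_arr holds the temperature for each sweep (0 means greedy) and
    angle_frac the per-sweep probability that a proposal is a pure
    director rotation rather than a step in the (q0, qm) disc.  Updates
    q0, qm in place; returns (energy trace per sweep, acceptance per sweep).
    Moves taking lambda above 1/2 are rejected outright.
    """
    np.random.seed(seed)
    n_s = q0.shape[0]
    n_phi = q0.shape[1]
    n_sweeps = T_arr.shape[0]
    trace = np.empty(n_sweeps)
    acc_rate = np.empty(n_sweeps)
    e_tot = texture_energy(q0, qm, W, inv_2ds, inv_2dphi, inv_rho, kg2, H, D,
                           C1, C2, alpha, beta, ki, ke, Cp, lam0, extrinsic, fe_weighted)
    for sw in range(n_sweeps):
        T = T_arr[sw]
        a_frac = angle_frac[sw]
        n_acc = 0
        n_try = 0
        for i in range(n_s):
            for j in range(n_phi):
                old0, oldm = q0[i, j], qm[i, j]
                n_try += 1
                if np.random.random() < a_frac:
                    # rotate the local director: a move along the soft
                    # direction of the condensation potential
                    psi = 4.0 * step * np.random.normal()
                    c, s_ = np.cos(psi), np.sin(psi)
                    new0 = c * old0 - s_ * oldm
                    newm = s_ * old0 + c * oldm
                else:
                    new0 = old0 + step * np.random.normal()
                    newm = oldm + step * np.random.normal()
                if new0 * new0 + newm * newm > 0.25:
                    continue
                e0 = _local_sum(q0, qm, i, j, W, inv_2ds, inv_2dphi, inv_rho,
                                kg2, H, D, C1, C2, alpha, beta, ki, ke, Cp,
                                lam0, extrinsic, fe_weighted)
                q0[i, j], qm[i, j] = new0, newm
                e1 = _local_sum(q0, qm, i, j, W, inv_2ds, inv_2dphi, inv_rho,
                                kg2, H, D, C1, C2, alpha, beta, ki, ke, Cp,
                                lam0, extrinsic, fe_weighted)
                de = e1 - e0
                accept = False
                if de <= 0.0:
                    accept = True
                elif T > 0.0 and np.random.random() < np.exp(-de / T):
                    accept = True
                if accept:
                    e_tot += de
                    n_acc += 1
                else:
                    q0[i, j], qm[i, j] = old0, oldm
        trace[sw] = e_tot
        acc_rate[sw] = n_acc / n_try
    return trace, acc_rate
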