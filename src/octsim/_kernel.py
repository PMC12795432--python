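"""Compiled photon-transport kernels.

The kernels duplicate, in numba-compiled form, the physics of the readable
reference path in :mod:`octsim.transport` (Gaussian-beam launch along the
rulings of the constant-intensity hyperboloid, exponential free paths,
Henyey-Greenstein scattering, continuous absorption weighting, surface-exit
bookkeeping).  ``run_batch_records`` stores per-photon exit records;
``run_batch_profiles`` streams photons directly into conventional- and
hybrid-model depth-profile accumulators without materialising records, which
is what makes ground-truth-scale runs fit in memory.

Counter layout (int64[5]): launched, recorded, discarded_angle,
terminated_weight, terminated_opl.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

STATUS_EXIT = 0
STATUS_WEIGHT = 1
STATUS_OPL = 2


@njit(cache=True)
def _hg_cos(g, u):
    """Henyey-Greenstein scattering cosine from a uniform draw."""
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _trace_one(w0, zR, zf, mua, mus, g, n_med, weight_cutoff, max_opl):
    """Propagate one photon packet; returns
    (status, weight, x, y, vx, vy, vz, opl, lsx, lsy, lsz, n_scatters)."""
    # --- launch along a ruling of x^2+y^2 = r0^2 (1 + ((z-zf)/zR)^2) ---
    u1 = 1.0 - np.random.random()          # (0, 1]
    r0 = w0 * math.sqrt(-0.5 * math.log(u1))
    phi = 2.0 * math.pi * np.random.random()
    sigma = 1.0 if np.random.random() < 0.5 else -1.0
    cp = math.cos(phi)
    sp = math.sin(phi)
    norm = math.sqrt(r0 * r0 + zR * zR)
    vx = -sigma * r0 * sp / norm
    vy = sigma * r0 * cp / norm
    vz = zR / norm
    x = r0 * cp + sigma * (zf / zR) * r0 * sp
    y = r0 * sp - sigma * (zf / zR) * r0 * cp
    z = 0.0

    w = 1.0
    opl = 0.0
    lsx = 0.0
    lsy = 0.0
    lsz = 0.0
    nsc = 0

    while True:
        if mus > 0.0:
            s = -math.log(1.0 - np.random.random()) / mus
        else:
            s = 1e30
        if vz < 0.0 and z + s * vz <= 0.0:
            s_exit = -z / vz
            w *= math.exp(-mua * s_exit)
            opl += n_med * s_exit
            x += vx * s_exit
            y += vy * s_exit
            return (STATUS_EXIT, w, x, y, vx, vy, vz, opl, lsx, lsy, lsz, nsc)
        x += vx * s
        y += vy * s
        z += vz * s
        w *= math.exp(-mua * s)
        opl += n_med * s
        if w < weight_cutoff:
            return (STATUS_WEIGHT, w, x, y, vx, vy, vz, opl, lsx, lsy, lsz, nsc)
        if opl > max_opl:
            return (STATUS_OPL, w, x, y, vx, vy, vz, opl, lsx, lsy, lsz, nsc)
        # scatter
        ct = _hg_cos(g, np.random.random())
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        psi = 2.0 * math.pi * np.random.random()
        cpsi = math.cos(psi)
        spsi = math.sin(psi)
        if abs(vz) > 0.99999:
            nvx = st * cpsi
            nvy = st * spsi
            nvz = ct if vz > 0.0 else -ct
        else:
            den = math.sqrt(1.0 - vz * vz)
            nvx = st * (vx * vz * cpsi - vy * spsi) / den + vx * ct
            nvy = st * (vy * vz * cpsi + vx * spsi) / den + vy * ct
            nvz = -den * st * cpsi + vz * ct
        rnorm = math.sqrt(nvx * nvx + nvy * nvy + nvz * nvz)
        vx = nvx / rnorm
        vy = nvy / rnorm
        vz = nvz / rnorm
        lsx = x
        lsy = y
        lsz = z
        nsc += 1


@njit(cache=True)
def run_batch_records(n_photons, seed, w0, zR, zf, mua, mus, g, n_med,
                      cos_theta_max, weight_cutoff, max_opl, out, counters):
    """Trace ``n_photons`` packets, storing exit records in ``out`` (n, 12).

    Record columns: weight, exit_x, exit_y, vx, vy, vz, theta_i, opl_total,
    lsx, lsy, lsz, n_scatters.  Returns the number of records written.
    """
    np.random.seed(seed)
    m = 0
    for _ in range(n_photons):
        (status, w, x, y, vx, vy, vz, opl,
         lsx, lsy, lsz, nsc) = _trace_one(
            w0, zR, zf, mua, mus, g, n_med, weight_cutoff, max_opl)
        counters[0] += 1
        if status == STATUS_EXIT:
            cos_ti = -vz
            if nsc >= 1 and cos_ti > cos_theta_max:
                out[m, 0] = w
                out[m, 1] = x
                out[m, 2] = y
                out[m, 3] = vx
                out[m, 4] = vy
                out[m, 5] = vz
                out[m, 6] = math.acos(min(1.0, cos_ti))
                out[m, 7] = opl
                out[m, 8] = lsx
                out[m, 9] = lsy
                out[m, 10] = lsz
                out[m, 11] = nsc
                m += 1
                counters[1] += 1
            else:
                counters[2] += 1
        elif status == STATUS_WEIGHT:
            counters[3] += 1
        else:
            counters[4] += 1
    return m


@njit(cache=True)
def run_batch_profiles(n_photons, seed, w0, zR, zf, mua, mus, g, n_med,
                       cos_theta_max, weight_cutoff, max_opl, lc, n_bins,
                       conv_i, conv_i2, conv_n, hyb_i, hyb_i2, hyb_n,
                       counters):
    """Trace packets and accumulate both detection models' depth profiles.

    ``*_i`` receive the summed detected intensities per one-way OPL bin,
    ``*_i2`` the summed squares (for Monte Carlo error estimates) and
    ``*_n`` the contributing-photon counts.
    """
    np.random.seed(seed)
    theta_div = w0 / zR
    mut = mua + mus
    for _ in range(n_photons):
        (status, w, x, y, vx, vy, vz, opl,
         lsx, lsy, lsz, nsc) = _trace_one(
            w0, zR, zf, mua, mus, g, n_med, weight_cutoff, max_opl)
        counters[0] += 1
        if status == STATUS_EXIT:
            cos_ti = -vz
            if nsc >= 1 and cos_ti > cos_theta_max:
                counters[1] += 1
                # conventional: straight-line extension of the exit ray to
                # the mode-waist plane z = zf, Gaussian position and
                # direction amplitude weights
                t = zf / vz
                xr = x + vx * t
                yr = y + vy * t
                wpos = math.exp(-(xr * xr + yr * yr) / (w0 * w0))
                wdir = math.exp(-(vx * vx + vy * vy) / (theta_div * theta_div))
                val = w * wpos * wdir
                j = int(math.floor(opl / (2.0 * lc) + 0.5))
                if 0 <= j < n_bins:
                    conv_i[j] += val
                    conv_i2[j] += val * val
                    conv_n[j] += 1
                # hybrid: spherical wave from the last scatter position
                zp = lsz - zf
                wz2 = w0 * w0 * (1.0 + (zp / zR) * (zp / zR))
                trans = ((w0 / zR) * (w0 / zR) * (w0 * w0 / wz2)
                         * math.exp(-2.0 * (lsx * lsx + lsy * lsy) / wz2))
                padj = math.exp(mut * lsz * (1.0 / cos_ti - 1.0))
                val = w * cos_ti * trans * padj
                lprime = opl + n_med * lsz * (1.0 - 1.0 / cos_ti)
                j = int(math.floor(lprime / (2.0 * lc) + 0.5))
                if 0 <= j < n_bins:
                    hyb_i[j] += val
                    hyb_i2[j] += val * val
                    hyb_n[j] += 1
            else:
                counters[2] += 1
        elif status == STATUS_WEIGHT:
            counters[3] += 1
        else:
            counters[4] += 1
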