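"""Numba-compiled inner loops.

All heavy time stepping funnels through the functions here.  The update per
step is operator-split in the order release -> uptake -> diffusion; receptor
occupancy, when enabled, is integrated against the post-diffusion field of
the same step.  The 7-point Laplacian uses periodic wrap on all axes for the
tissue lattice and periodic-lateral / reflecting-vertical boundaries for the
varicosity box.

Concentrations are in nM, lengths in µm, time in s.  ``alpha`` is the
dimensionless diffusion number Da*dt/dx**2 (stability requires 6*alpha <= 1),
``vmax_dt`` the saturated uptake decrement per step in nM.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "diffuse_periodic",
    "mm_uptake",
    "mm_uptake_map",
    "occupancy_update",
    "run_lattice_chunk",
    "run_lattice_chunk_occ",
    "run_nano_chunk",
]


@njit(cache=False, fastmath=True)
def diffuse_periodic(C, out, alpha):
    """One explicit-Euler diffusion step with periodic wrap on all axes."""
    nx, ny, nz = C.shape
    for i in range(nx):
        im = nx - 1 if i == 0 else i - 1
        ip = 0 if i == nx - 1 else i + 1
        for j in range(ny):
            jm = ny - 1 if j == 0 else j - 1
            jp = 0 if j == ny - 1 else j + 1
            for k in range(nz):
                kl = nz - 1 if k == 0 else k - 1
                kr = 0 if k == nz - 1 else k + 1
                c = C[i, j, k]
                out[i, j, k] = c + alpha * (
                    C[im, j, k] + C[ip, j, k]
                    + C[i, jm, k] + C[i, jp, k]
                    + C[i, j, kl] + C[i, j, kr]
                    - 6.0 * c
                )


@njit(cache=False, fastmath=True)
def mm_uptake(C, out, vmax_dt, km):
    """Michaelis-Menten decrement, uniform Vmax, floored at zero."""
    n = C.size
    Cf = C.reshape(n)
    of = out.reshape(n)
    for idx in range(n):
        c = Cf[idx]
        if c > 0.0:
            d = vmax_dt * c / (km + c)
            of[idx] = c - d if d < c else 0.0
        else:
            of[idx] = c


@njit(cache=False, fastmath=True)
def mm_uptake_map(C, out, vmax_dt, km):
    """Michaelis-Menten decrement with a per-voxel Vmax map."""
    n = C.size
    Cf = C.reshape(n)
    of = out.reshape(n)
    vf = vmax_dt.reshape(n)
    for idx in range(n):
        c = Cf[idx]
        v = vf[idx]
        if c > 0.0 and v > 0.0:
            d = v * c / (km + c)
            of[idx] = c - d if d < c else 0.0
        else:
            of[idx] = c


@njit(cache=False, fastmath=True)
def occupancy_update(occ, C, kon_dt, koff_dt):
    """In-place Euler step of d(occ)/dt = C*kon*(1-occ) - koff*occ."""
    n = occ.size
    of = occ.reshape(n)
    Cf = C.reshape(n)
    for idx in range(n):
        o = of[idx]
        o = o + kon_dt * Cf[idx] * (1.0 - o) - koff_dt * o
        if o < 0.0:
            o = 0.0
        elif o > 1.0:
            o = 1.0
        of[idx] = o


@njit(cache=False, fastmath=True)
def run_lattice_chunk(C, buf, alpha, vmax_dt, km, q_conc,
                      ev_step, ev_vox, ev_ptr,
                      step0, nsteps, trace_every, probe_vox,
                      out_mean, out_probe_c, rec_idx):
    """Integrate ``nsteps`` of release/uptake/diffusion.

    ``ev_step``/``ev_vox`` is the step-sorted quantal-event list (flat voxel
    indices); ``ev_ptr`` the cursor into it.  Every ``trace_every`` steps the
    spatial mean and probe-voxel concentrations are recorded.  Returns the
    (possibly swapped) field and buffer plus updated cursors.
    """
    nx, ny, nz = C.shape
    n = C.size
    nev = ev_step.shape[0]
    npr = probe_vox.shape[0]
    for s in range(nsteps):
        g = step0 + s
        Cf = C.reshape(n)
        while ev_ptr < nev and ev_step[ev_ptr] == g:
            Cf[ev_vox[ev_ptr]] += q_conc
            ev_ptr += 1
        for idx in range(n):
            c = Cf[idx]
            if c > 0.0:
                d = vmax_dt * c / (km + c)
                Cf[idx] = c - d if d < c else 0.0
        tot = 0.0
        for i in range(nx):
            im = nx - 1 if i == 0 else i - 1
            ip = 0 if i == nx - 1 else i + 1
            for j in range(ny):
                jm = ny - 1 if j == 0 else j - 1
                jp = 0 if j == ny - 1 else j + 1
                for k in range(nz):
                    kl = nz - 1 if k == 0 else k - 1
                    kr = 0 if k == nz - 1 else k + 1
                    c = C[i, j, k]
                    v = c + alpha * (
                        C[im, j, k] + C[ip, j, k]
                        + C[i, jm, k] + C[i, jp, k]
                        + C[i, j, kl] + C[i, j, kr]
                        - 6.0 * c
                    )
                    buf[i, j, k] = v
                    tot += v
        tmp = C
        C = buf
        buf = tmp
        if (g + 1) % trace_every == 0:
            out_mean[rec_idx] = tot / n
            Cf = C.reshape(n)
            for p in range(npr):
                out_probe_c[rec_idx, p] = Cf[probe_vox[p]]
            rec_idx += 1
    return C, buf, ev_ptr, rec_idx


@njit(cache=False, fastmath=True)
def run_lattice_chunk_occ(C, buf, occ1, occ2, alpha, vmax_dt, km, q_conc,
                          a1, b1, a2, b2,
                          ev_step, ev_vox, ev_ptr,
                          step0, nsteps, trace_every, probe_vox,
                          out_mean, out_occ1_mean, out_occ2_mean,
                          out_probe_c, out_probe_o1, out_probe_o2, rec_idx):
    """As :func:`run_lattice_chunk` with fused D1/D2 occupancy integration.

    ``a1``/``b1`` are kon*dt and koff*dt of the first receptor (D1), ``a2``/
    ``b2`` of the second (D2).
    """
    nx, ny, nz = C.shape
    n = C.size
    nev = ev_step.shape[0]
    npr = probe_vox.shape[0]
    for s in range(nsteps):
        g = step0 + s
        Cf = C.reshape(n)
        while ev_ptr < nev and ev_step[ev_ptr] == g:
            Cf[ev_vox[ev_ptr]] += q_conc
            ev_ptr += 1
        for idx in range(n):
            c = Cf[idx]
            if c > 0.0:
                d = vmax_dt * c / (km + c)
                Cf[idx] = c - d if d < c else 0.0
        tot = 0.0
        o1tot = 0.0
        o2tot = 0.0
        for i in range(nx):
            im = nx - 1 if i == 0 else i - 1
            ip = 0 if i == nx - 1 else i + 1
            for j in range(ny):
                jm = ny - 1 if j == 0 else j - 1
                jp = 0 if j == ny - 1 else j + 1
                for k in range(nz):
                    kl = nz - 1 if k == 0 else k - 1
                    kr = 0 if k == nz - 1 else k + 1
                    c = C[i, j, k]
                    v = c + alpha * (
                        C[im, j, k] + C[ip, j, k]
                        + C[i, jm, k] + C[i, jp, k]
                        + C[i, j, kl] + C[i, j, kr]
                        - 6.0 * c
                    )
                    buf[i, j, k] = v
                    tot += v
                    o = occ1[i, j, k]
                    o = o + a1 * v * (1.0 - o) - b1 * o
                    if o < 0.0:
                        o = 0.0
                    elif o > 1.0:
                        o = 1.0
                    occ1[i, j, k] = o
                    o1tot += o
                    o = occ2[i, j, k]
                    o = o + a2 * v * (1.0 - o) - b2 * o
                    if o < 0.0:
                        o = 0.0
                    elif o > 1.0:
                        o = 1.0
                    occ2[i, j, k] = o
                    o2tot += o
        tmp = C
        C = buf
        buf = tmp
        if (g + 1) % trace_every == 0:
            out_mean[rec_idx] = tot / n
            out_occ1_mean[rec_idx] = o1tot / n
            out_occ2_mean[rec_idx] = o2tot / n
            Cf = C.reshape(n)
            o1f = occ1.reshape(n)
            o2f = occ2.reshape(n)
            for p in range(npr):
                out_probe_c[rec_idx, p] = Cf[probe_vox[p]]
                out_probe_o1[rec_idx, p] = o1f[probe_vox[p]]
                out_probe_o2[rec_idx, p] = o2f[probe_vox[p]]
            rec_idx += 1
    return C, buf, ev_ptr, rec_idx


@njit(cache=False, fastmath=True)
def run_nano_chunk(C, buf, vmax_dt, km, drive_dt, alpha,
                   step0, nsteps, record_every, centre_i, centre_j,
                   out_mean, out_centre, rec_idx):
    """Integrate the varicosity box: uniform drive, membrane-layer uptake.

    ``vmax_dt`` is a 2-D saturated-decrement map applied to the z=0 voxel
    layer only.  Lateral boundaries wrap; top and bottom are reflecting.
    Records the volume mean and the concentration of the (centre_i, centre_j)
    membrane voxel every ``record_every`` steps.
    """
    nx, ny, nz = C.shape
    n = C.size
    for s in range(nsteps):
        g = step0 + s
        for i in range(nx):
            for j in range(ny):
                vdt = vmax_dt[i, j]
                c = C[i, j, 0] + drive_dt
                if vdt > 0.0 and c > 0.0:
                    d = vdt * c / (km + c)
                    c = c - d if d < c else 0.0
                C[i, j, 0] = c
                for k in range(1, nz):
                    C[i, j, k] += drive_dt
        tot = 0.0
        for i in range(nx):
            im = nx - 1 if i == 0 else i - 1
            ip = 0 if i == nx - 1 else i + 1
            for j in range(ny):
                jm = ny - 1 if j == 0 else j - 1
                jp = 0 if j == ny - 1 else j + 1
                for k in range(nz):
                    c = C[i, j, k]
                    cl = C[i, j, k - 1] if k > 0 else c
                    cr = C[i, j, k + 1] if k < nz - 1 else c
                    v = c + alpha * (
                        C[im, j, k] + C[ip, j, k]
                        + C[i, jm, k] + C[i, jp, k]
                        + cl + cr - 6.0 * c
                    )
                    buf[i, j, k] = v
                    tot += v
        tmp = C
        C = buf
        buf = tmp
        if (g + 1) % record_every == 0:
            out_mean[rec_idx] = tot / n
            out_centre[rec_idx] = C[centre_i, centre_j, 0]
            rec_idx += 1
    return C, buf, rec_idx
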