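"""Numba kernels for the Monte Carlo sweep and the oxygen relaxation.

These are the two inner loops that dominate run time. Both are written as
plain element loops so numba can compile them to machine code; the public
modules (`cpm_core`, `oxygen_pde`) own all bookkeeping and validation.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def mcs_sweep(
    labels,
    types_by_id,
    volumes_by_id,
    lam_by_type,
    vtarget_by_type,
    contact_j,
    src_flat,
    nbr_dir,
    accept_u,
    hstar,
):
    """Run one batch of copy attempts in place.

    Random choices are supplied as pre-drawn arrays (flat source index,
    von Neumann direction 0..3 in the order up/down/left/right, and the
    acceptance uniform) so that all randomness flows through one seeded
    generator on the Python side.

    Copy attempts whose target falls outside the lattice are rejected but
    still count as attempts; attempts between two sites of the same agent
    are no-ops with dH = 0.
    """
    h, w = labels.shape
    n_attempts = src_flat.shape[0]
    for i in range(n_attempts):
        flat = src_flat[i]
        r = flat // w
        c = flat - r * w
        d = nbr_dir[i]
        if d == 0:
            r2 = r - 1
            c2 = c
        elif d == 1:
            r2 = r + 1
            c2 = c
        elif d == 2:
            r2 = r
            c2 = c - 1
        else:
            r2 = r
            c2 = c + 1
        if r2 < 0 or r2 >= h or c2 < 0 or c2 >= w:
            continue
        sid = labels[r, c]
        tid = labels[r2, c2]
        if sid == tid:
            continue
        ts = types_by_id[sid]
        tt = types_by_id[tid]
        dh = 0.0
        # volume-constraint change: target agent loses a site, source gains one
        if tid != 0 and lam_by_type[tt] > 0.0:
            n = float(volumes_by_id[tid])
            v = vtarget_by_type[tt]
            dh += lam_by_type[tt] * ((n - 1.0 - v) ** 2 - (n - v) ** 2)
        if sid != 0 and lam_by_type[ts] > 0.0:
            n = float(volumes_by_id[sid])
            v = vtarget_by_type[ts]
            dh += lam_by_type[ts] * ((n + 1.0 - v) ** 2 - (n - v) ** 2)
        # contact change over the Moore neighbourhood of the target site;
        # factor 2 keeps the ordered double-sum convention of the total energy
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                r3 = r2 + dr
                c3 = c2 + dc
                if r3 < 0 or r3 >= h or c3 < 0 or c3 >= w:
                    continue
                nid = labels[r3, c3]
                tn = types_by_id[nid]
                e_new = 0.0 if nid == sid else contact_j[ts, tn]
                e_old = 0.0 if nid == tid else contact_j[tt, tn]
                dh += 2.0 * (e_new - e_old)
        if dh <= 0.0 or accept_u[i] < np.exp(-dh / hstar):
            labels[r2, c2] = sid
            volumes_by_id[tid] -= 1
            volumes_by_id[sid] += 1


@njit(cache=True)
def steady_state_sor(conc, cell_mask, source, env, kdiff, omega, tol, max_iter):
    """Projected red-black SOR solve of the steady reaction--diffusion balance.

    Solves kdiff * lap(c) + source = 0 on cell sites with medium sites held
    at `env` and c constrained to [0, env] (constant per-cell uptake would
    otherwise drive c negative deep inside large aggregates). Domain-edge
    neighbours outside the lattice are treated as zero-flux.

    Returns the number of sweeps used, or -1 if `tol` (projected residual
    max-norm, mM/s) was not reached within `max_iter` sweeps.
    """
    h, w = conc.shape
    for r in range(h):
        for c in range(w):
            if not cell_mask[r, c]:
                conc[r, c] = env
    for it in range(max_iter):
        for parity in range(2):
            for r in range(h):
                c0 = (r + parity) & 1
                for c in range(c0, w, 2):
                    if not cell_mask[r, c]:
                        continue
                    cc = conc[r, c]
                    up = conc[r - 1, c] if r > 0 else cc
                    dn = conc[r + 1, c] if r < h - 1 else cc
                    lf = conc[r, c - 1] if c > 0 else cc
                    rt = conc[r, c + 1] if c < w - 1 else cc
                    res = kdiff * (up + dn + lf + rt - 4.0 * cc) + source[r, c]
                    val = cc + omega * res / (4.0 * kdiff)
                    if val < 0.0:
                        val = 0.0
                    elif val > env:
                        val = env
                    conc[r, c] = val
        maxres = 0.0
        for r in range(h):
            for c in range(w):
                if not cell_mask[r, c]:
                    continue
                cc = conc[r, c]
                up = conc[r - 1, c] if r > 0 else cc
                dn = conc[r + 1, c] if r < h - 1 else cc
                lf = conc[r, c - 1] if c > 0 else cc
                rt = conc[r, c + 1] if c < w - 1 else cc
                res = kdiff * (up + dn + lf + rt - 4.0 * cc) + source[r, c]
                if cc <= 0.0:
                    # clamped from below: only an upward push counts as failure
                    if res > maxres:
                        maxres = res
                else:
                    if abs(res) > maxres:
                        maxres = abs(res)
        if maxres < tol:
            return it + 1
    return -1
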