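"""Numba-compiled inner loops of the lattice engine.

All functions operate on the flat per-cell arrays owned by
:class:`cleftsim.core.LatticeState`; nothing here allocates.  The split
between ``_delta_H`` (pure) and ``_apply_copy`` (mutating) lets the Python
API expose the exact energy change the Monte-Carlo loop uses.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# 4-neighbourhood used for copy attempts and the edge-count perimeter.
_DX4 = np.array([1, -1, 0, 0], dtype=np.int64)
_DY4 = np.array([0, 0, 1, -1], dtype=np.int64)

REJECT_ENERGY = 1.0e30  # returned when a move would orphan a linked cell


@njit(cache=True)
def _delta_H(owner, ctype, area, tgt_a, lam_a, perim, tgt_p, lam_p,
             sum_x, sum_y, J, contact_off,
             lptr, lidx, link_a, link_b, link_lam, link_L,
             sx, sy, tx, ty):
    """Energy change if owner[ty, tx] were overwritten by owner[sy, sx].

    Computed locally: contact pairs touching the target site, the two
    cells' area/perimeter deviations, and every link attached to either
    cell (via the centroid shift).  Returns 0 for a same-owner pair and
    REJECT_ENERGY when the move would remove the last site of a cell
    that still carries links.
    """
    so = owner[sy, sx]
    to = owner[ty, tx]
    if so == to:
        return 0.0
    H = owner.shape[0]
    W = owner.shape[1]
    t_s = ctype[so]
    t_t = ctype[to]
    dH = 0.0

    # -- contact term (neighbourhood given by contact_off) ---------------
    for k in range(contact_off.shape[0]):
        nx = tx + contact_off[k, 0]
        ny = ty + contact_off[k, 1]
        if nx < 0 or nx >= W or ny < 0 or ny >= H:
            continue
        no = owner[ny, nx]
        tn = ctype[no]
        if no != to:
            dH -= J[t_t, tn]
        if no != so:
            dH += J[t_s, tn]

    # -- area term --------------------------------------------------------
    a_t = float(area[to])
    a_s = float(area[so])
    if lam_a[to] > 0.0:
        d = a_t - tgt_a[to]
        dH += lam_a[to] * ((d - 1.0) ** 2 - d ** 2)
    if lam_a[so] > 0.0:
        d = a_s - tgt_a[so]
        dH += lam_a[so] * ((d + 1.0) ** 2 - d ** 2)

    # -- perimeter term (unit-edge count, 4-neighbourhood) ---------------
    n_t = 0
    n_s = 0
    for k in range(4):
        nx = tx + _DX4[k]
        ny = ty + _DY4[k]
        if nx < 0 or nx >= W or ny < 0 or ny >= H:
            continue
        no = owner[ny, nx]
        if no == to:
            n_t += 1
        if no == so:
            n_s += 1
    if lam_p[to] > 0.0:
        p_old = float(perim[to])
        p_new = p_old + 2.0 * n_t - 4.0
        d = tgt_p[to]
        dH += lam_p[to] * ((p_new - d) ** 2 - (p_old - d) ** 2)
    if lam_p[so] > 0.0:
        p_old = float(perim[so])
        p_new = p_old + 4.0 - 2.0 * n_s
        d = tgt_p[so]
        dH += lam_p[so] * ((p_new - d) ** 2 - (p_old - d) ** 2)

    # -- focal point plasticity (links move with the two centroids) ------
    has_links_t = lptr[to + 1] > lptr[to]
    has_links_s = lptr[so + 1] > lptr[so]
    if has_links_t and area[to] == 1:
        return REJECT_ENERGY  # would orphan a linked cell
    if has_links_t or has_links_s:
        # new centroid of the losing cell
        na_t = a_t - 1.0
        if na_t > 0.0:
            ncx_t = (sum_x[to] - tx) / na_t
            ncy_t = (sum_y[to] - ty) / na_t
        else:
            ncx_t = 0.0
            ncy_t = 0.0
        na_s = a_s + 1.0
        ncx_s = (sum_x[so] + tx) / na_s
        ncy_s = (sum_y[so] + ty) / na_s
        cx_t = sum_x[to] / a_t
        cy_t = sum_y[to] / a_t
        cx_s = sum_x[so] / a_s
        cy_s = sum_y[so] / a_s
        for li in range(lptr[to], lptr[to + 1]):
            i = lidx[li]
            other = link_b[i] if link_a[i] == to else link_a[i]
            if other == so:
                ox_old, oy_old = cx_s, cy_s
                ox_new, oy_new = ncx_s, ncy_s
            else:
                ox_old = sum_x[other] / area[other]
                oy_old = sum_y[other] / area[other]
                ox_new, oy_new = ox_old, oy_old
            l_old = np.sqrt((cx_t - ox_old) ** 2 + (cy_t - oy_old) ** 2)
            l_new = np.sqrt((ncx_t - ox_new) ** 2 + (ncy_t - oy_new) ** 2)
            L = link_L[i]
            dH += link_lam[i] * ((l_new - L) ** 2 - (l_old - L) ** 2)
        for li in range(lptr[so], lptr[so + 1]):
            i = lidx[li]
            other = link_b[i] if link_a[i] == so else link_a[i]
            if other == to:
                continue  # already counted above
            ox = sum_x[other] / area[other]
            oy = sum_y[other] / area[other]
            l_old = np.sqrt((cx_s - ox) ** 2 + (cy_s - oy) ** 2)
            l_new = np.sqrt((ncx_s - ox) ** 2 + (ncy_s - oy) ** 2)
            L = link_L[i]
            dH += link_lam[i] * ((l_new - L) ** 2 - (l_old - L) ** 2)
    return dH


@njit(cache=True)
def _apply_copy(owner, area, perim, sum_x, sum_y, tx, ty, so):
    """Overwrite the target site with owner ``so`` and update caches."""
    to = owner[ty, tx]
    H = owner.shape[0]
    W = owner.shape[1]
    n_t = 0
    n_s = 0
    for k in range(4):
        nx = tx + _DX4[k]
        ny = ty + _DY4[k]
        if nx < 0 or nx >= W or ny < 0 or ny >= H:
            continue
        no = owner[ny, nx]
        if no == to:
            n_t += 1
        if no == so:
            n_s += 1
    owner[ty, tx] = so
    area[to] -= 1
    area[so] += 1
    sum_x[to] -= tx
    sum_x[so] += tx
    sum_y[to] -= ty
    sum_y[so] += ty
    perim[to] += 2 * n_t - 4
    perim[so] += 4 - 2 * n_s


@njit(cache=True)
def _run_attempts(owner, ctype, area, tgt_a, lam_a, perim, tgt_p, lam_p,
                  sum_x, sum_y, J, contact_off, copy_off,
                  lptr, lidx, link_a, link_b, link_lam, link_L,
                  T, n_attempts, rng):
    """Perform ``n_attempts`` Metropolis copy attempts; return accept count.

    Target sites are drawn uniformly from the interior (the one-site
    frame is frozen and never overwritten); the source is a uniformly
    drawn copy-neighbourhood neighbour.  Same-owner draws consume an
    attempt without changing state.
    """
    H = owner.shape[0]
    W = owner.shape[1]
    n_copy = copy_off.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        tx = 1 + int(rng.random() * (W - 2))
        ty = 1 + int(rng.random() * (H - 2))
        k = int(rng.random() * n_copy)
        sx = tx + copy_off[k, 0]
        sy = ty + copy_off[k, 1]
        so = owner[sy, sx]
        if so == owner[ty, tx]:
            continue
        dH = _delta_H(owner, ctype, area, tgt_a, lam_a, perim, tgt_p, lam_p,
                      sum_x, sum_y, J, contact_off,
                      lptr, lidx, link_a, link_b, link_lam, link_L,
                      sx, sy, tx, ty)
        if dH <= 0.0 or rng.random() < np.exp(-dH / T):
            _apply_copy(owner, area, perim, sum_x, sum_y, tx, ty, so)
            accepted += 1
    return accepted
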