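"""Flat-array Metropolis engine (numba-jitted inner loop).

The public, readable implementations of the energy and the Metropolis rule
live in :mod:`epiextrude.vertex_core` / :mod:`epiextrude.mc_dynamics`; this
module holds the performance path used by ``run_simulation``.  Topology
(T1 rewiring) is handled in Python between jitted chunks; only the hot
vertex-move loop is compiled.

Array layout
------------
pos      (nv, 2)     vertex positions
vnf/vfaces           per-vertex incident-face count / ids   (cap MAXF)
vnn/vnbr             per-vertex neighbour count / ids       (cap MAXN)
vlam/vbnd            per-neighbour edge tension / boundary flag
fcount/fring         per-face ring length / vertex ids      (cap MAXK)
fa0/fgam             per-face resting area / contractility
farea/fperim         cached face area and perimeter (kept exact: rewritten
                     from coordinates on every accepted move)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MAXK = 24  # max vertices per face ring
MAXF = 8  # max faces per vertex
MAXN = 8  # max neighbours per vertex

AREA_MIN = 1e-12


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _elastic(area, a0, a0_min):
    if a0 >= a0_min:
        x = area / a0 - 1.0
    else:
        x = area - a0
    return 0.5 * x * x


@njit(cache=True, inline="always")
def _orient(ax, ay, bx, by, cx, cy):
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


@njit(cache=True)
def _face_metrics(pos, fring, fcount, f):
    """Signed area and perimeter of face f from coordinates."""
    k = fcount[f]
    sa = 0.0
    per = 0.0
    x0 = pos[fring[f, k - 1], 0]
    y0 = pos[fring[f, k - 1], 1]
    for j in range(k):
        x1 = pos[fring[f, j], 0]
        y1 = pos[fring[f, j], 1]
        sa += x0 * y1 - x1 * y0
        per += math.sqrt((x1 - x0) ** 2 + (y1 - y0) ** 2)
        x0 = x1
        y0 = y1
    return 0.5 * sa, per


@njit(cache=True)
def refresh_face_caches(pos, fring, fcount, farea, fperim):
    for f in range(fcount.shape[0]):
        sa, per = _face_metrics(pos, fring, fcount, f)
        farea[f] = abs(sa)
        fperim[f] = per


@njit(cache=True)
def _moved_face_ok_and_metrics(pos, fring, fcount, f, vid, nx, ny):
    """(ok, area, perimeter) of face f with vertex vid at (nx, ny).

    ok is False when the moved ring inverts (signed area <= AREA_MIN) or the
    two edges at the moved vertex cross a non-adjacent edge of the ring.
    """
    k = fcount[f]
    sa = 0.0
    per = 0.0
    t = -1
    for j in range(k):
        if fring[f, j] == vid:
            t = j
            break
    # shoelace + perimeter with substitution
    px = pos[fring[f, k - 1], 0]
    py = pos[fring[f, k - 1], 1]
    if fring[f, k - 1] == vid:
        px = nx
        py = ny
    for j in range(k):
        cx = pos[fring[f, j], 0]
        cy = pos[fring[f, j], 1]
        if j == t:
            cx = nx
            cy = ny
        sa += px * cy - cx * py
        per += math.sqrt((cx - px) ** 2 + (cy - py) ** 2)
        px = cx
        py = cy
    sa *= 0.5
    if sa <= AREA_MIN:
        return False, 0.0, 0.0
    # simplicity: edges (t-1, t) and (t, t+1) vs non-adjacent ring edges
    for e in range(2):
        i0 = (t - 1 + e) % k
        i1 = (i0 + 1) % k
        ax = pos[fring[f, i0], 0] if i0 != t else nx
        ay = pos[fring[f, i0], 1] if i0 != t else ny
        bx = pos[fring[f, i1], 0] if i1 != t else nx
        by = pos[fring[f, i1], 1] if i1 != t else ny
        for j in range(k):
            j1 = (j + 1) % k
            if j == i0 or j1 == i0 or j == i1 or j1 == i1:
                continue
            cx = pos[fring[f, j], 0] if j != t else nx
            cy = pos[fring[f, j], 1] if j != t else ny
            dx = pos[fring[f, j1], 0] if j1 != t else nx
            dy = pos[fring[f, j1], 1] if j1 != t else ny
            d1 = _orient(cx, cy, dx, dy, ax, ay)
            d2 = _orient(cx, cy, dx, dy, bx, by)
            if (d1 > 0) != (d2 > 0):
                d3 = _orient(ax, ay, bx, by, cx, cy)
                d4 = _orient(ax, ay, bx, by, dx, dy)
                if (d3 > 0) != (d4 > 0):
                    return False, 0.0, 0.0
    return True, sa, per


@njit(cache=True)
def run_chunk(
    pos,
    vnf,
    vfaces,
    vnn,
    vnbr,
    vlam,
    fcount,
    fring,
    fa0,
    fgam,
    farea,
    fperim,
    n_iter,
    delta_max,
    p_accept,
    a0_min,
    proposal_literal,
    ramp_on,
    targets,
    gfac,
    afac,
    stats,
):
    """Run n_iter Metropolis vertex-move iterations in place.

    One iteration: optional per-iteration parameter ramp on the target
    faces, then a uniformly random vertex, a bounded random trial
    displacement, the local energy difference, and the accept/reject rule
    (downhill always, uphill with probability p_accept); geometry-violating
    proposals are rejected outright.  stats accumulates
    [accepted, rejected, sum of accepted dE].
    """
    nv = pos.shape[0]
    new_area = np.empty(MAXF)
    new_perim = np.empty(MAXF)
    for _ in range(n_iter):
        if ramp_on:
            for ti in range(targets.shape[0]):
                f = targets[ti]
                fgam[f] *= gfac
                fa0[f] *= afac
        v = np.random.randint(0, nv)
        if proposal_literal:
            d = np.random.random() * delta_max
            dx = d
            dy = d
        else:
            dx = (2.0 * np.random.random() - 1.0) * delta_max
            dy = (2.0 * np.random.random() - 1.0) * delta_max
        ox = pos[v, 0]
        oy = pos[v, 1]
        nx = ox + dx
        ny = oy + dy

        ok = True
        dE = 0.0
        nf = vnf[v]
        for a in range(nf):
            f = vfaces[v, a]
            good, sa, per = _moved_face_ok_and_metrics(pos, fring, fcount, f, v, nx, ny)
            if not good:
                ok = False
                break
            new_area[a] = sa
            new_perim[a] = per
            dE += _elastic(sa, fa0[f], a0_min) - _elastic(farea[f], fa0[f], a0_min)
            dE += 0.5 * fgam[f] * (per * per - fperim[f] * fperim[f])
        if ok:
            for a in range(vnn[v]):
                u = vnbr[v, a]
                l_old = math.sqrt((pos[u, 0] - ox) ** 2 + (pos[u, 1] - oy) ** 2)
                l_new = math.sqrt((pos[u, 0] - nx) ** 2 + (pos[u, 1] - ny) ** 2)
                dE += vlam[v, a] * (l_new - l_old)
            if dE < 0.0 or np.random.random() < p_accept:
                pos[v, 0] = nx
                pos[v, 1] = ny
                for a in range(nf):
                    f = vfaces[v, a]
                    farea[f] = new_area[a]
                    fperim[f] = new_perim[a]
                stats[0] += 1.0
                stats[2] += dE
            else:
                stats[1] += 1.0
        else:
            stats[1] += 1.0


@njit(cache=True)
def short_internal_edges(pos, vnn, vnbr, vbnd, d_min, out_u, out_v):
    """Collect internal edges shorter than d_min; returns their count."""
    n = 0
    d2 = d_min * d_min
    for v in range(vnn.shape[0]):
        for k in range(vnn[v]):
            u = vnbr[v, k]
            if u <= v or vbnd[v, k] != 0:
                continue
            dx = pos[u, 0] - pos[v, 0]
            dy = pos[u, 1] - pos[v, 1]
            if dx * dx + dy * dy < d2:
                if n < out_u.shape[0]:
                    out_u[n] = v
                    out_v[n] = u
                    n += 1
    return n


@njit(cache=True)
def all_edge_lengths(pos, vnn, vnbr, out_u, out_v, out_l):
    """Flatten the (u < v) edge list with current lengths; returns count."""
    n = 0
    for v in range(vnn.shape[0]):
        for k in range(vnn[v]):
            u = vnbr[v, k]
            if u <= v:
                continue
            dx = pos[u, 0] - pos[v, 0]
            dy = pos[u, 1] - pos[v, 1]
            if n < out_u.shape[0]:
                out_u[n] = v
                out_v[n] = u
                out_l[n] = math.sqrt(dx * dx + dy * dy)
                n += 1
    return n
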