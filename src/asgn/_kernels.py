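"""Numba kernels: ray traversal, photon-packet propagation, tallies.

All geometry is 2D, lengths in mm, optical coefficients in 1/mm.  The
kernels operate on flat arrays extracted from :class:`asgn.mesh.Mesh2D`;
no Python objects cross the JIT boundary.

Random numbers come from a counter-based splitmix64 generator with one
independent substream per photon packet, so results are bit-reproducible
for a given (seed, P) and independent of packet execution order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

U64 = np.uint64
_GAMMA = U64(0x9E3779B97F4A7C15)
_STREAM = U64(0xD1B54A32D192ED03)

# geometric tolerances (mm); see Mesh2D docs
_EDGE_TOL = 1e-12
_NUDGE = 1e-9
_MAX_STUCK = 32

STATUS_OK = 0
STATUS_EVENT_CAP = 1

# terminal events of a ray / packet leg
TERM_BOUNDARY = 1
TERM_INTERIOR = 0


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _stream_init(seed, pid):
    return _mix64(seed ^ (U64(pid + 1) * _STREAM))


@njit(cache=True, inline="always")
def _u01(state):
    """Advance the stream; return a uniform in (0, 1] and the new state."""
    state = state + _GAMMA
    x = _mix64(state)
    u = (x >> U64(11)) * 1.1102230246251565e-16  # 2**-53
    if u <= 0.0:
        u = 1.1102230246251565e-16
    return u, state


@njit(cache=True, inline="always")
def _hg_theta(g, u):
    """Inverse-CDF draw of the 2D Henyey-Greenstein deflection angle.

    F(theta) = 1/2 + (1/pi) atan(((1+g)/(1-g)) tan(theta/2)) inverts to
    theta = 2 atan(((1-g)/(1+g)) tan(pi (u - 1/2))).
    """
    if g == 0.0:
        return 2.0 * math.pi * (u - 0.5)
    t = math.tan(math.pi * (u - 0.5))
    return 2.0 * math.atan((1.0 - g) / (1.0 + g) * t)


@njit(cache=True)
def hg_sample_batch(g, seed, n):
    """Draw n HG deflection angles with the kernel RNG (diagnostic entry)."""
    out = np.empty(n)
    for i in range(n):
        state = _stream_init(U64(seed), i)
        u, state = _u01(state)
        out[i] = _hg_theta(g, u)
    return out


@njit(cache=True, inline="always")
def _point_in_tri(px, py, nodes, triangles, e, tol):
    ia, ib, ic = triangles[e, 0], triangles[e, 1], triangles[e, 2]
    ax, ay = nodes[ia, 0], nodes[ia, 1]
    bx, by = nodes[ib, 0], nodes[ib, 1]
    cx, cy = nodes[ic, 0], nodes[ic, 1]
    s0 = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    s1 = (cx - bx) * (py - by) - (cy - by) * (px - bx)
    s2 = (ax - cx) * (py - cy) - (ay - cy) * (px - cx)
    return s0 >= -tol and s1 >= -tol and s2 >= -tol


@njit(cache=True)
def locate_kernel(px, py, nodes, triangles, tol):
    """Lowest-id element whose closed triangle contains (px, py); -1 if none."""
    for e in range(triangles.shape[0]):
        if _point_in_tri(px, py, nodes, triangles, e, tol):
            return e
    return -1


@njit(cache=True, inline="always")
def _next_crossing(px, py, dx, dy, elem, edge_origin, edge_normal):
    """Distance along (dx, dy) from (px, py) to the exit edge of elem.

    Returns (t, local_edge).  local_edge is -1 when no forward-facing edge
    is found (degenerate position; caller must recover by nudging).
    """
    best_t = np.inf
    best_e = -1
    for e in range(3):
        nx = edge_normal[elem, e, 0]
        ny = edge_normal[elem, e, 1]
        denom = dx * nx + dy * ny
        if denom > 1e-14:
            ax = edge_origin[elem, e, 0]
            ay = edge_origin[elem, e, 1]
            t = ((ax - px) * nx + (ay - py) * ny) / denom
            if t > -_EDGE_TOL and t < best_t:
                best_t = t
                best_e = e
    if best_t < 0.0:
        best_t = 0.0
    return best_t, best_e


@njit(cache=True)
def trace_ray_kernel(
    px,
    py,
    dx,
    dy,
    elem,
    max_length,
    nodes,
    triangles,
    neighbors,
    edge_origin,
    edge_normal,
    out_elems,
    out_pts,
    out_lens,
):
    """Trace a straight ray through the mesh.

    Fills out_elems[i], out_lens[i] and out_pts[i] (entry point) /
    out_pts[i+1] (exit point) per segment.  Returns (n_segments, terminal)
    with terminal in {TERM_BOUNDARY, TERM_INTERIOR}.
    """
    remaining = max_length
    nseg = 0
    stuck = 0
    cap = out_elems.shape[0]
    terminal = TERM_INTERIOR
    while remaining > 0.0 and nseg < cap:
        t, e = _next_crossing(px, py, dx, dy, elem, edge_origin, edge_normal)
        if e == -1 or t < _EDGE_TOL:
            stuck += 1
        else:
            stuck = 0
        if e == -1 or stuck > _MAX_STUCK:
            # degenerate crossing (vertex hit): nudge forward and relocate
            qx = px + _NUDGE * dx
            qy = py + _NUDGE * dy
            nelem = locate_kernel(qx, qy, nodes, triangles, 1e-9)
            if nelem == -1:
                terminal = TERM_BOUNDARY
                break
            elem = nelem
            stuck = 0
            continue
        step = t if t < remaining else remaining
        out_elems[nseg] = elem
        out_pts[nseg, 0] = px
        out_pts[nseg, 1] = py
        out_lens[nseg] = step
        px += step * dx
        py += step * dy
        out_pts[nseg + 1, 0] = px
        out_pts[nseg + 1, 1] = py
        nseg += 1
        remaining -= step
        if step < t:
            terminal = TERM_INTERIOR
            break
        nb = neighbors[elem, e]
        if nb < 0:
            terminal = TERM_BOUNDARY
            break
        elem = nb
    return nseg, terminal


@njit(cache=True, inline="always")
def _launch(state, src_cum, src_elem, src_ax, src_ay, src_bx, src_by, src_nx, src_ny):
    """Sample a packet start on an illuminated side.

    Position is uniform over the side's total length (edge chosen with
    probability proportional to its length); the angle to the inward
    normal has density proportional to cos(phi) on (-pi/2, pi/2).
    (ax, ay)-(bx, by) are the edge endpoints, (nx, ny) the inward normal.
    """
    u, state = _u01(state)
    ne = src_cum.shape[0]
    target = u * src_cum[ne - 1]
    k = 0
    while k < ne - 1 and src_cum[k] < target:
        k += 1
    prev = src_cum[k - 1] if k > 0 else 0.0
    frac = (target - prev) / (src_cum[k] - prev)
    px = src_ax[k] + frac * (src_bx[k] - src_ax[k])
    py = src_ay[k] + frac * (src_by[k] - src_ay[k])
    u, state = _u01(state)
    phi = math.asin(2.0 * u - 1.0)
    # inward normal and edge tangent
    nx = src_nx[k]
    ny = src_ny[k]
    tx = -ny
    ty = nx
    dx = math.cos(phi) * nx + math.sin(phi) * tx
    dy = math.cos(phi) * ny + math.sin(phi) * ty
    return state, src_elem[k], px, py, dx, dy


@njit(cache=True)
def simulate_kernel(
    nodes,
    triangles,
    neighbors,
    edge_origin,
    edge_normal,
    areas,
    mu_a,
    mu_s,
    g,
    src_elem,
    src_ax,
    src_ay,
    src_bx,
    src_by,
    src_nx,
    src_ny,
    src_cum,
    P,
    seed,
    w_min_frac,
    max_events,
    with_jacobian,
    H_raw,
    J_raw,
    vpos,
    vids,
    vlens,
):
    """Propagate P photon packets; tally absorbed weight and Jacobian.

    H_raw[j] accumulates absorbed weight in element j (divide by A_j for
    energy density).  When with_jacobian, J_raw[j, k] accumulates the raw
    derivative d(absorbed weight in j)/d(mu_a[k]) via the frozen-path
    closed form: across a segment of length s in element j with entry
    weight w and exit weight w', d(w - w')/d mu_a[k] =
    -L_k (w - w') for k visited before the segment, plus s w' for k = j.

    Returns (absorbed, exited, residual, status).
    """
    w0 = 1.0 / P
    w_min = w_min_frac * w0
    absorbed = 0.0
    exited = 0.0
    residual = 0.0
    status = STATUS_OK
    for pid in range(P):
        state = _stream_init(seed, pid)
        state, elem, px, py, dx, dy = _launch(
            state, src_cum, src_elem, src_ax, src_ay, src_bx, src_by, src_nx, src_ny
        )
        u, state = _u01(state)
        tau = -math.log(u)  # optical depth to next scattering event
        w = w0
        nvis = 0
        events = 0
        stuck = 0
        alive = True
        while alive:
            t_edge, e = _next_crossing(px, py, dx, dy, elem, edge_origin, edge_normal)
            if e == -1 or t_edge < _EDGE_TOL:
                stuck += 1
            else:
                stuck = 0
            if e == -1 or stuck > _MAX_STUCK:
                qx = px + _NUDGE * dx
                qy = py + _NUDGE * dy
                nelem = locate_kernel(qx, qy, nodes, triangles, 1e-9)
                if nelem == -1:
                    exited += w
                    alive = False
                else:
                    elem = nelem
                    stuck = 0
                continue
            mus = mu_s[elem]
            scatter_here = mus > 0.0 and tau < mus * t_edge
            if scatter_here:
                step = tau / mus
            else:
                step = t_edge
                tau -= mus * t_edge
            muaj = mu_a[elem]
            w_out = w * math.exp(-muaj * step)
            dw = w - w_out
            H_raw[elem] += dw
            absorbed += dw
            if with_jacobian:
                for idx in range(nvis):
                    J_raw[elem, vids[idx]] -= dw * vlens[idx]
                J_raw[elem, elem] += step * w_out
                k = vpos[elem]
                if k < 0:
                    vpos[elem] = nvis
                    vids[nvis] = elem
                    vlens[nvis] = step
                    nvis += 1
                else:
                    vlens[k] += step
            px += step * dx
            py += step * dy
            w = w_out
            if w < w_min:
                residual += w
                alive = False
            elif scatter_here:
                events += 1
                if events > max_events:
                    status = STATUS_EVENT_CAP
                    alive = False
                else:
                    u, state = _u01(state)
                    theta = _hg_theta(g, u)
                    c = math.cos(theta)
                    s = math.sin(theta)
                    ndx = c * dx - s * dy
                    ndy = s * dx + c * dy
                    dx = ndx
                    dy = ndy
                    u, state = _u01(state)
                    tau = -math.log(u)
            else:
                nb = neighbors[elem, e]
                if nb < 0:
                    exited += w
                    alive = False
                else:
                    elem = nb
        if with_jacobian:
            for idx in range(nvis):
                vpos[vids[idx]] = -1
        if status != STATUS_OK:
            break
    return absorbed, exited, residual, status
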