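"""Numba kernels for mesh geometry and analytic force evaluation.

All faces are fan-triangulated about their vertex centroid; cell volumes
are signed fan tetrahedra about the cell reference point.  Because the
fan is identical from both sides of a shared (possibly non-planar) face,
adjacent cells tile space exactly and the total volume equals the box
volume.

Periodic handling: each face is reassembled by minimum image relative to
its first vertex; the whole face is then shifted to the image nearest the
owning cell's reference point.  Gradients are unaffected by these locally
constant shifts.
"""

import numba
import numpy as np

F8 = numba.float64
I8 = numba.int64


@numba.njit(cache=True)
def _min_image(d, L):
    out = np.empty(3)
    for ax in range(3):
        out[ax] = d[ax] - L[ax] * np.round(d[ax] / L[ax])
    return out


@numba.njit(cache=True)
def _face_local(X, face_vert, lo, hi, L, Q):
    """Unwrapped face coordinates relative to vertex 0's image. Fills Q[:m]."""
    m = hi - lo
    v0 = face_vert[lo]
    for k in range(m):
        v = face_vert[lo + k]
        for ax in range(3):
            Q[k, ax] = X[v, ax] - X[v0, ax]
        d = _min_image(Q[k], L)
        for ax in range(3):
            Q[k, ax] = d[ax]
    return m


@numba.njit(cache=True)
def face_normals_and_centroids(X, face_vert, face_off, L):
    """Area-weighted fan normals and world centroids of every face."""
    nf = len(face_off) - 1
    normals = np.zeros((nf, 3))
    cents = np.zeros((nf, 3))
    maxm = 0
    for f in range(nf):
        m = face_off[f + 1] - face_off[f]
        if m > maxm:
            maxm = m
    Q = np.empty((maxm, 3))
    for f in range(nf):
        lo, hi = face_off[f], face_off[f + 1]
        m = _face_local(X, face_vert, lo, hi, L, Q)
        c = np.zeros(3)
        for k in range(m):
            for ax in range(3):
                c[ax] += Q[k, ax] / m
        v0 = face_vert[lo]
        for ax in range(3):
            cents[f, ax] = X[v0, ax] + c[ax]
        for k in range(m):
            k2 = (k + 1) % m
            a0 = Q[k, 0] - c[0]
            a1 = Q[k, 1] - c[1]
            a2 = Q[k, 2] - c[2]
            b0 = Q[k2, 0] - c[0]
            b1 = Q[k2, 1] - c[1]
            b2 = Q[k2, 2] - c[2]
            normals[f, 0] += 0.5 * (a1 * b2 - a2 * b1)
            normals[f, 1] += 0.5 * (a2 * b0 - a0 * b2)
            normals[f, 2] += 0.5 * (a0 * b1 - a1 * b0)
    return normals, cents


@numba.njit(cache=True)
def mesh_geometry(X, face_vert, face_off, owners, cell_face, cell_off, cell_sign,
                  cell_ref, L):
    """Face areas, cell volumes/surfaces, and cell centroid offsets.

    Returns (area_f, V_c, S_c, cent_off_c) where cent_off_c is the
    area-weighted mean face-centroid displacement from cell_ref (used to
    let reference points track their cells).
    """
    nf = len(face_off) - 1
    nc = len(cell_off) - 1
    area = np.zeros(nf)
    fcent = np.zeros((nf, 3))  # face centroid relative to face vertex 0 image
    maxm = 0
    for f in range(nf):
        m = face_off[f + 1] - face_off[f]
        if m > maxm:
            maxm = m
    Q = np.empty((maxm, 3))
    for f in range(nf):
        lo, hi = face_off[f], face_off[f + 1]
        m = _face_local(X, face_vert, lo, hi, L, Q)
        c = np.zeros(3)
        for k in range(m):
            for ax in range(3):
                c[ax] += Q[k, ax] / m
        for ax in range(3):
            fcent[f, ax] = c[ax]
        a = 0.0
        for k in range(m):
            k2 = (k + 1) % m
            u0 = Q[k, 0] - c[0]
            u1 = Q[k, 1] - c[1]
            u2 = Q[k, 2] - c[2]
            w0 = Q[k2, 0] - c[0]
            w1 = Q[k2, 1] - c[1]
            w2 = Q[k2, 2] - c[2]
            n0 = u1 * w2 - u2 * w1
            n1 = u2 * w0 - u0 * w2
            n2 = u0 * w1 - u1 * w0
            a += 0.5 * np.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
        area[f] = a

    V = np.zeros(nc)
    S = np.zeros(nc)
    cent = np.zeros((nc, 3))
    wsum = np.zeros(nc)
    for cid in range(nc):
        ref = cell_ref[cid]
        for k in range(cell_off[cid], cell_off[cid + 1]):
            f = cell_face[k]
            sg = cell_sign[k]
            lo, hi = face_off[f], face_off[f + 1]
            m = hi - lo
            v0 = face_vert[lo]
            # face centroid in world coords, shifted near the cell ref
            cw = np.empty(3)
            for ax in range(3):
                cw[ax] = X[v0, ax] + fcent[f, ax] - ref[ax]
            d = _min_image(cw, L)  # centroid relative to ref
            S[cid] += area[f]
            wsum[cid] += area[f]
            for ax in range(3):
                cent[cid, ax] += area[f] * d[ax]
            # fan volume about ref: triangles (d, Pk, Pk+1), P = rel coords
            _face_local(X, face_vert, lo, hi, L, Q)
            vol = 0.0
            for kk in range(m):
                k2 = (kk + 1) % m
                p0 = d[0] + Q[kk, 0] - fcent[f, 0]
                p1 = d[1] + Q[kk, 1] - fcent[f, 1]
                p2 = d[2] + Q[kk, 2] - fcent[f, 2]
                q0 = d[0] + Q[k2, 0] - fcent[f, 0]
                q1 = d[1] + Q[k2, 1] - fcent[f, 1]
                q2 = d[2] + Q[k2, 2] - fcent[f, 2]
                c0 = p1 * q2 - p2 * q1
                c1 = p2 * q0 - p0 * q2
                c2 = p0 * q1 - p1 * q0
                vol += (d[0] * c0 + d[1] * c1 + d[2] * c2) / 6.0
            V[cid] += sg * vol
    for cid in range(nc):
        if wsum[cid] > 0:
            for ax in range(3):
                cent[cid, ax] /= wsum[cid]
    return area, V, S, cent


@numba.njit(cache=True)
def accumulate_forces(X, face_vert, face_off, w_area, cell_face, cell_off,
                      cell_sign, u_vol, cell_ref, L, F):
    """Accumulate -dE/dr for energies of the form

        E = sum_f w_area[f] * A_f  +  sum_(c,f) u_vol-term via V_c

    where w_area[f] already sums the surface-elastic and interfacial
    tension coefficients of both owners (dE/dA_f), and u_vol[c] = dE/dV_c.
    F is modified in place (subtracting the gradient).
    """
    nf = len(face_off) - 1
    maxm = 0
    for f in range(nf):
        m = face_off[f + 1] - face_off[f]
        if m > maxm:
            maxm = m
    Q = np.empty((maxm, 3))
    G = np.empty((maxm, 3))

    # --- area gradients ---
    for f in range(nf):
        wf = w_area[f]
        if wf == 0.0:
            continue
        lo, hi = face_off[f], face_off[f + 1]
        m = _face_local(X, face_vert, lo, hi, L, Q)
        c = np.zeros(3)
        for k in range(m):
            for ax in range(3):
                c[ax] += Q[k, ax] / m
        gd = np.zeros(3)
        for k in range(m):
            for ax in range(3):
                G[k, ax] = 0.0
        for k in range(m):
            k2 = (k + 1) % m
            u = Q[k] - c
            w = Q[k2] - c
            n0 = u[1] * w[2] - u[2] * w[1]
            n1 = u[2] * w[0] - u[0] * w[2]
            n2 = u[0] * w[1] - u[1] * w[0]
            nn = np.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
            if nn < 1e-300:
                continue
            n0 /= nn
            n1 /= nn
            n2 /= nn
            # dA/dP_k = 0.5 * (w x n), dA/dP_k2 = 0.5 * (n x u)
            G[k, 0] += 0.5 * (w[1] * n2 - w[2] * n1)
            G[k, 1] += 0.5 * (w[2] * n0 - w[0] * n2)
            G[k, 2] += 0.5 * (w[0] * n1 - w[1] * n0)
            G[k2, 0] += 0.5 * (n1 * u[2] - n2 * u[1])
            G[k2, 1] += 0.5 * (n2 * u[0] - n0 * u[2])
            G[k2, 2] += 0.5 * (n0 * u[1] - n1 * u[0])
            # centroid term: dA/dc = -(dA/dPk + dA/dPk2)
            gd[0] -= 0.5 * (w[1] * n2 - w[2] * n1) + 0.5 * (n1 * u[2] - n2 * u[1])
            gd[1] -= 0.5 * (w[2] * n0 - w[0] * n2) + 0.5 * (n2 * u[0] - n0 * u[2])
            gd[2] -= 0.5 * (w[0] * n1 - w[1] * n0) + 0.5 * (n0 * u[1] - n1 * u[0])
        for k in range(m):
            v = face_vert[lo + k]
            for ax in range(3):
                F[v, ax] -= wf * (G[k, ax] + gd[ax] / m)

    # --- volume gradients ---
    nc = len(cell_off) - 1
    P = np.empty((maxm, 3))
    for cid in range(nc):
        uv = u_vol[cid]
        if uv == 0.0:
            continue
        ref = cell_ref[cid]
        for k in range(cell_off[cid], cell_off[cid + 1]):
            f = cell_face[k]
            coef = uv * cell_sign[k]
            lo, hi = face_off[f], face_off[f + 1]
            m = _face_local(X, face_vert, lo, hi, L, Q)
            c = np.zeros(3)
            for kk in range(m):
                for ax in range(3):
                    c[ax] += Q[kk, ax] / m
            v0 = face_vert[lo]
            cw = np.empty(3)
            for ax in range(3):
                cw[ax] = X[v0, ax] + c[ax] - ref[ax]
            d = _min_image(cw, L)
            for kk in range(m):
                for ax in range(3):
                    P[kk, ax] = d[ax] + Q[kk, ax] - c[ax]
            # dV/dd = (1/6) sum_k Pk x Pk+1 ; dV/dPj = (1/6)(P_{j+1}-P_{j-1}) x d
            gd = np.zeros(3)
            for kk in range(m):
                k2 = (kk + 1) % m
                gd[0] += (P[kk, 1] * P[k2, 2] - P[kk, 2] * P[k2, 1]) / 6.0
                gd[1] += (P[kk, 2] * P[k2, 0] - P[kk, 0] * P[k2, 2]) / 6.0
                gd[2] += (P[kk, 0] * P[k2, 1] - P[kk, 1] * P[k2, 0]) / 6.0
            for kk in range(m):
                kp = (kk + 1) % m
                km = (kk - 1) % m
                e0 = P[kp, 0] - P[km, 0]
                e1 = P[kp, 1] - P[km, 1]
                e2 = P[kp, 2] - P[km, 2]
                g0 = (e1 * d[2] - e2 * d[1]) / 6.0 + gd[0] / m
                g1 = (e2 * d[0] - e0 * d[2]) / 6.0 + gd[1] / m
                g2 = (e0 * d[1] - e1 * d[0]) / 6.0 + gd[2] / m
                v = face_vert[lo + kk]
                F[v, 0] -= coef * g0
                F[v, 1] -= coef * g1
                F[v, 2] -= coef * g2
    return F
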