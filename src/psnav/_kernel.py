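"""JIT-compiled episode inner loop.

This is a performance fusion of the synchronous step in :mod:`psnav.env`
(percepts -> actions -> motion -> reward -> glow/H updates) plus the
per-step order parameters, compiled with numba.  It consumes randomness
in exactly the same order and with the same generator calls as the
pure-numpy path (per step: neighbor-angle noise, target-angle noise,
one uniform per agent for action sampling), so both paths produce the
same trajectories for the same seed up to floating-point reduction
order.  The numpy implementation remains the readable reference; an
equivalence test keeps the two in lock-step.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ALIGN_HALFWIDTH = np.pi / 6


@njit(cache=True)
def episode_kernel(
    positions,
    headings,
    target,
    target_velocity,
    weights_h,
    h_min,
    eta,
    gamma,
    learn,
    k,
    speed,
    max_steps,
    sigma_rad,
    angles_rad,
    lam_d,
    lam_r,
    w_min,
    stop_radius,
    rng,
):  # pragma: no cover - exercised via run_episode
    n = positions.shape[0]
    m = angles_rad.shape[0]
    n_rec = max_steps + 1

    pol = np.empty(n_rec)
    elo = np.empty(n_rec)
    cen = np.empty((n_rec, 2))
    dirs = np.empty((n_rec, 2))
    dist = np.empty(n_rec)
    glow = np.zeros((n, 9, m))
    total_reward = 0.0

    # centroid-motion direction fallback: normalized mean heading at t=0
    mhx = 0.0
    mhy = 0.0
    for i in range(n):
        mhx += headings[i, 0]
        mhy += headings[i, 1]
    mhx /= n
    mhy /= n
    nrm = math.sqrt(mhx * mhx + mhy * mhy)
    if nrm > 1e-9:
        dx, dy = mhx / nrm, mhy / nrm
    else:
        dx, dy = 1.0, 0.0

    tx = target[0]
    ty = target[1]

    nbr_d = np.empty(k)
    nbr_j = np.empty(k, np.int64)
    theta_n = np.empty(n)
    theta_t = np.empty(n)
    percepts = np.empty(n, np.int64)
    r_tot = np.empty(n)

    for rec in range(n_rec):
        if rec > 0:
            step_reward = 0.0
            # --- percepts from the common time-t snapshot -------------
            for i in range(n):
                count = 0
                for j in range(n):
                    if j == i:
                        continue
                    ddx = positions[j, 0] - positions[i, 0]
                    ddy = positions[j, 1] - positions[i, 1]
                    d2 = ddx * ddx + ddy * ddy
                    if count < k:
                        pos = count
                        while pos > 0 and nbr_d[pos - 1] > d2:
                            nbr_d[pos] = nbr_d[pos - 1]
                            nbr_j[pos] = nbr_j[pos - 1]
                            pos -= 1
                        nbr_d[pos] = d2
                        nbr_j[pos] = j
                        count += 1
                    elif d2 < nbr_d[k - 1]:
                        pos = k - 1
                        while pos > 0 and nbr_d[pos - 1] > d2:
                            nbr_d[pos] = nbr_d[pos - 1]
                            nbr_j[pos] = nbr_j[pos - 1]
                            pos -= 1
                        nbr_d[pos] = d2
                        nbr_j[pos] = j
                ax = 0.0
                ay = 0.0
                for q in range(k):
                    ax += headings[nbr_j[q], 0]
                    ay += headings[nbr_j[q], 1]
                ax /= k
                ay /= k
                hx = headings[i, 0]
                hy = headings[i, 1]
                if math.sqrt(ax * ax + ay * ay) < 1e-9:
                    theta_n[i] = 0.0
                else:
                    ang = math.atan2(hx * ay - hy * ax, hx * ax + hy * ay)
                    theta_n[i] = math.pi if ang == -math.pi else ang
                vx = tx - positions[i, 0]
                vy = ty - positions[i, 1]
                if math.sqrt(vx * vx + vy * vy) < 1e-12:
                    theta_t[i] = 0.0
                else:
                    ang = math.atan2(hx * vy - hy * vx, hx * vx + hy * vy)
                    theta_t[i] = math.pi if ang == -math.pi else ang
            if sigma_rad > 0.0:
                noise_n = rng.normal(0.0, sigma_rad, n)
                noise_t = rng.normal(0.0, sigma_rad, n)
                for i in range(n):
                    w = (theta_n[i] + noise_n[i] + math.pi) % (2 * math.pi) - math.pi
                    theta_n[i] = math.pi if w == -math.pi else w
                    w = (theta_t[i] + noise_t[i] + math.pi) % (2 * math.pi) - math.pi
                    theta_t[i] = math.pi if w == -math.pi else w
            for i in range(n):
                if abs(theta_n[i]) <= ALIGN_HALFWIDTH:
                    s_n = 1
                elif theta_n[i] < -ALIGN_HALFWIDTH:
                    s_n = 0
                else:
                    s_n = 2
                if abs(theta_t[i]) <= ALIGN_HALFWIDTH:
                    s_t = 1
                elif theta_t[i] < -ALIGN_HALFWIDTH:
                    s_t = 0
                else:
                    s_t = 2
                percepts[i] = 3 * s_n + s_t

            # --- sample actions and move (synchronously) --------------
            u = rng.random(n)
            tx += target_velocity[0]
            ty += target_velocity[1]
            for i in range(n):
                s = percepts[i]
                rowsum = 0.0
                for kk in range(m):
                    rowsum += weights_h[s, kk]
                c = 0.0
                a = 0
                for kk in range(m):
                    c += weights_h[s, kk] / rowsum
                    if u[i] > c:
                        a += 1
                if a > m - 1:
                    a = m - 1
                ca = math.cos(angles_rad[a])
                sa = math.sin(angles_rad[a])
                hx = headings[i, 0]
                hy = headings[i, 1]
                nhx = ca * hx - sa * hy
                nhy = sa * hx + ca * hy
                px = positions[i, 0]
                py = positions[i, 1]
                npx = px + speed * nhx
                npy = py + speed * nhy
                d_prev = math.sqrt((tx - px) ** 2 + (ty - py) ** 2)
                d_new = math.sqrt((tx - npx) ** 2 + (ty - npy) ** 2)
                r_dis = d_prev - d_new
                if d_new > 0.0:
                    r_dir = (nhx * (tx - npx) + nhy * (ty - npy)) / d_new
                    if r_dir < 0.0:
                        r_dir = 0.0
                else:
                    r_dir = 0.0
                r_tot[i] = lam_d * r_dis + lam_r * r_dir
                step_reward += r_tot[i]
                headings[i, 0] = nhx
                headings[i, 1] = nhy
                positions[i, 0] = npx
                positions[i, 1] = npy
                if learn:
                    glow_i = glow[i]
                    for ss in range(9):
                        for aa in range(m):
                            glow_i[ss, aa] *= 1.0 - eta
                    glow_i[s, a] += 1.0

            # --- shared-memory update: H += sum_i R_i * G_i -----------
            if learn:
                if gamma > 0.0:
                    for ss in range(9):
                        for aa in range(m):
                            weights_h[ss, aa] -= gamma * (weights_h[ss, aa] - 1.0)
                for i in range(n):
                    r = r_tot[i]
                    glow_i = glow[i]
                    for ss in range(9):
                        for aa in range(m):
                            weights_h[ss, aa] += r * glow_i[ss, aa]
                for ss in range(9):
                    for aa in range(m):
                        if weights_h[ss, aa] < h_min:
                            weights_h[ss, aa] = h_min
            total_reward += step_reward

            # --- centroid-motion direction ----------------------------
            cx = 0.0
            cy = 0.0
            for i in range(n):
                cx += positions[i, 0]
                cy += positions[i, 1]
            cx /= n
            cy /= n
            mdx = cx - cen[rec - 1, 0]
            mdy = cy - cen[rec - 1, 1]
            mnorm = math.sqrt(mdx * mdx + mdy * mdy)
            if mnorm >= 1e-9:
                dx, dy = mdx / mnorm, mdy / mnorm

        # --- record order parameters ---------------------------------
        sx = 0.0
        sy = 0.0
        cx = 0.0
        cy = 0.0
        for i in range(n):
            sx += headings[i, 0]
            sy += headings[i, 1]
            cx += positions[i, 0]
            cy += positions[i, 1]
        sx /= n
        sy /= n
        cx /= n
        cy /= n
        pol[rec] = math.sqrt(sx * sx + sy * sy)
        lon_min = lon_max = positions[0, 0] * dx + positions[0, 1] * dy
        tra_min = tra_max = -positions[0, 0] * dy + positions[0, 1] * dx
        for i in range(1, n):
            lon = positions[i, 0] * dx + positions[i, 1] * dy
            tra = -positions[i, 0] * dy + positions[i, 1] * dx
            if lon < lon_min:
                lon_min = lon
            elif lon > lon_max:
                lon_max = lon
            if tra < tra_min:
                tra_min = tra
            elif tra > tra_max:
                tra_max = tra
        width = tra_max - tra_min
        if width < w_min:
            width = w_min
        elo[rec] = (lon_max - lon_min) / width
        cen[rec, 0] = cx
        cen[rec, 1] = cy
        dirs[rec, 0] = dx
        dirs[rec, 1] = dy
        dist[rec] = math.sqrt((tx - cx) ** 2 + (ty - cy) ** 2)
        if stop_radius > 0.0 and dist[rec] <= stop_radius:
            n_rec = rec + 1
            break

    return (
        pol[:n_rec],
        elo[:n_rec],
        cen[:n_rec],
        dirs[:n_rec],
        dist[:n_rec],
        total_reward,
    )
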