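"""Numba kernels for the z-buffer rasterizer.

Screen coordinates are continuous pixel units with (0, 0) at the top-left
corner; depth is handled as 1/z (camera-forward distance), interpolated
linearly in screen space (perspective correct).  Foreground coverage is
resolved on an ``ss x ss`` subpixel grid per pixel; the background plane
is shaded once per pixel center since it varies smoothly.
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _hash01(ix, iy, seed):
    h = (ix * np.int64(374761393) + iy * np.int64(668265263)
         + seed * np.int64(982451653)) & np.int64(0xFFFFFFFF)
    h = ((h ^ (h >> 13)) * np.int64(1274126177)) & np.int64(0xFFFFFFFF)
    return ((h ^ (h >> 16)) & np.int64(0xFFFF)) / 65535.0


@njit(cache=True, inline="always")
def _value_noise(x, y, freq, seed):
    fx = x * freq
    fy = y * freq
    ix = np.int64(np.floor(fx))
    iy = np.int64(np.floor(fy))
    tx = fx - ix
    ty = fy - iy
    # smoothstep interpolation of lattice hashes
    sx = tx * tx * (3.0 - 2.0 * tx)
    sy = ty * ty * (3.0 - 2.0 * ty)
    v00 = _hash01(ix, iy, seed)
    v10 = _hash01(ix + 1, iy, seed)
    v01 = _hash01(ix, iy + 1, seed)
    v11 = _hash01(ix + 1, iy + 1, seed)
    return (v00 * (1 - sx) * (1 - sy) + v10 * sx * (1 - sy)
            + v01 * (1 - sx) * sy + v11 * sx * sy)


@njit(cache=True, inline="always")
def _mottle(x, y, seed):
    """Three-octave value noise in [0, 1]."""
    n = (0.5 * _value_noise(x, y, 8.0, seed)
         + 0.3 * _value_noise(x, y, 29.0, seed + 7)
         + 0.2 * _value_noise(x, y, 101.0, seed + 13))
    return n


@njit(cache=True)
def rasterize(screen_tris, ss_h, ss_w, tri_id, invz):
    """Z-buffer rasterization of projected triangles.

    screen_tris : (n, 3, 3) float64 — per vertex (x, y, 1/z) in subsample
    units; triangles flagged with NaN x are skipped (behind camera).
    tri_id / invz : (ss_h, ss_w) buffers, pre-filled with -1 / 0.
    """
    n = screen_tris.shape[0]
    for t in range(n):
        x0 = screen_tris[t, 0, 0]
        if np.isnan(x0):
            continue
        y0 = screen_tris[t, 0, 1]
        w0 = screen_tris[t, 0, 2]
        x1 = screen_tris[t, 1, 0]
        y1 = screen_tris[t, 1, 1]
        w1 = screen_tris[t, 1, 2]
        x2 = screen_tris[t, 2, 0]
        y2 = screen_tris[t, 2, 1]
        w2 = screen_tris[t, 2, 2]
        area = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
        if area == 0.0:
            continue
        xmin = max(np.int64(np.floor(min(x0, min(x1, x2)))), 0)
        xmax = min(np.int64(np.ceil(max(x0, max(x1, x2)))), ss_w - 1)
        ymin = max(np.int64(np.floor(min(y0, min(y1, y2)))), 0)
        ymax = min(np.int64(np.ceil(max(y0, max(y1, y2)))), ss_h - 1)
        if xmin > xmax or ymin > ymax:
            continue
        inv_area = 1.0 / area
        for j in range(ymin, ymax + 1):
            py = j + 0.5
            for i in range(xmin, xmax + 1):
                px = i + 0.5
                l0 = ((x1 - px) * (y2 - py) - (y1 - py) * (x2 - px)) * inv_area
                l1 = ((x2 - px) * (y0 - py) - (y2 - py) * (x0 - px)) * inv_area
                l2 = 1.0 - l0 - l1
                if l0 < 0.0 or l1 < 0.0 or l2 < 0.0:
                    continue
                iz = l0 * w0 + l1 * w1 + l2 * w2
                if iz > invz[j, i]:
                    invz[j, i] = iz
                    tri_id[j, i] = t


@njit(cache=True)
def shadow_map(world_tris, s_axis1, s_axis2, sun_dir, org1, org2, scale, res, smap):
    """Orthographic sun-view depth map (max distance toward the sun)."""
    n = world_tris.shape[0]
    for t in range(n):
        u = np.empty(3)
        v = np.empty(3)
        d = np.empty(3)
        for k in range(3):
            px = world_tris[t, k, 0]
            py = world_tris[t, k, 1]
            pz = world_tris[t, k, 2]
            u[k] = (px * s_axis1[0] + py * s_axis1[1] + pz * s_axis1[2] - org1) * scale
            v[k] = (px * s_axis2[0] + py * s_axis2[1] + pz * s_axis2[2] - org2) * scale
            d[k] = px * sun_dir[0] + py * sun_dir[1] + pz * sun_dir[2]
        area = (u[1] - u[0]) * (v[2] - v[0]) - (v[1] - v[0]) * (u[2] - u[0])
        if area == 0.0:
            continue
        xmin = max(np.int64(np.floor(min(u[0], min(u[1], u[2])))), 0)
        xmax = min(np.int64(np.ceil(max(u[0], max(u[1], u[2])))), res - 1)
        ymin = max(np.int64(np.floor(min(v[0], min(v[1], v[2])))), 0)
        ymax = min(np.int64(np.ceil(max(v[0], max(v[1], v[2])))), res - 1)
        inv_area = 1.0 / area
        for j in range(ymin, ymax + 1):
            py = j + 0.5
            for i in range(xmin, xmax + 1):
                px = i + 0.5
                l0 = ((u[1] - px) * (v[2] - py) - (v[1] - py) * (u[2] - px)) * inv_area
                l1 = ((u[2] - px) * (v[0] - py) - (v[2] - py) * (u[0] - px)) * inv_area
                l2 = 1.0 - l0 - l1
                if l0 < 0.0 or l1 < 0.0 or l2 < 0.0:
                    continue
                depth = l0 * d[0] + l1 * d[1] + l2 * d[2]
                if depth > smap[j, i]:
                    smap[j, i] = depth


@njit(cache=True, inline="always")
def _sun_occluded(p, s_axis1, s_axis2, sun_dir, org1, org2, scale, res, smap):
    u = (p[0] * s_axis1[0] + p[1] * s_axis1[1] + p[2] * s_axis1[2] - org1) * scale
    v = (p[0] * s_axis2[0] + p[1] * s_axis2[1] + p[2] * s_axis2[2] - org2) * scale
    iu = np.int64(np.floor(u))
    iv = np.int64(np.floor(v))
    if iu < 0 or iu >= res or iv < 0 or iv >= res:
        return False
    d = p[0] * sun_dir[0] + p[1] * sun_dir[1] + p[2] * sun_dir[2]
    return smap[iv, iu] > d + 5e-3


@njit(cache=True)
def shade(tri_id, invz, ss, res, cam_pos, cam_r, cam_d, cam_f, fx,
          tri_normals, tri_colors, sun_dir, diffuse_frac, use_shadow,
          s_axis1, s_axis2, s_org1, s_org2, s_scale, s_res, smap,
          bg_is_water, bg_albedo, bg_mottle, bg_gray, bg_spec, noise_seed,
          rgb_out, green_count):
    """Fused coverage + shading pass.

    Foreground subsamples are shaded with a double-sided Lambertian term
    (plus hard shadow when enabled); the background plane is shaded once
    per pixel center and blended by residual coverage.
    """
    nss = ss * ss
    cx = res * 0.5
    half = 1.0 / (2.0 * ss)
    p = np.empty(3)
    for j in range(res):
        for i in range(res):
            cov = 0
            r_acc = 0.0
            g_acc = 0.0
            b_acc = 0.0
            for sj in range(ss):
                jj = j * ss + sj
                for si in range(ss):
                    ii = i * ss + si
                    t = tri_id[jj, ii]
                    if t < 0:
                        continue
                    cov += 1
                    # reconstruct the world point from screen coords + depth
                    xn = ((ii + 0.5) / ss - cx) / fx
                    yn = ((jj + 0.5) / ss - cx) / fx
                    z = 1.0 / invz[jj, ii]
                    for k in range(3):
                        p[k] = cam_pos[k] + z * (cam_r[k] * xn + cam_d[k] * yn + cam_f[k])
                    lam = abs(tri_normals[t, 0] * sun_dir[0]
                              + tri_normals[t, 1] * sun_dir[1]
                              + tri_normals[t, 2] * sun_dir[2])
                    lit = 1.0
                    if use_shadow and _sun_occluded(p, s_axis1, s_axis2, sun_dir,
                                                    s_org1, s_org2, s_scale, s_res, smap):
                        lit = 0.0
                    inten = diffuse_frac + (1.0 - diffuse_frac) * lam * lit
                    r_acc += tri_colors[t, 0] * inten
                    g_acc += tri_colors[t, 1] * inten
                    b_acc += tri_colors[t, 2] * inten
            if cov < nss:
                # background through the pixel center
                xn = (i + 0.5 - cx) / fx
                yn = (j + 0.5 - cx) / fx
                dx = cam_r[0] * xn + cam_d[0] * yn + cam_f[0]
                dy = cam_r[1] * xn + cam_d[1] * yn + cam_f[1]
                dz = cam_r[2] * xn + cam_d[2] * yn + cam_f[2]
                br = 0.0
                bg = 0.0
                bb = 0.0
                if dz < -1e-9:
                    tg = -cam_pos[2] / dz
                    p[0] = cam_pos[0] + tg * dx
                    p[1] = cam_pos[1] + tg * dy
                    p[2] = 0.0
                    lit = 1.0
                    if use_shadow and _sun_occluded(p, s_axis1, s_axis2, sun_dir,
                                                    s_org1, s_org2, s_scale, s_res, smap):
                        lit = 0.0
                    if bg_is_water:
                        # flat light-gray surface + sun glint along the mirror direction
                        norm = np.sqrt(dx * dx + dy * dy + dz * dz)
                        vr = -dx / norm
                        vg = -dy / norm
                        vb = -dz / norm
                        # reflection of the sun about the +z water normal
                        dot = (vr * -sun_dir[0] + vg * -sun_dir[1] + vb * sun_dir[2])
                        glint = bg_spec * lit * max(dot, 0.0) ** 60
                        base = bg_gray * (diffuse_frac + (1.0 - diffuse_frac)
                                          * sun_dir[2] * lit)
                        br = base + glint
                        bg = base + glint
                        bb = base * 1.03 + glint
                    else:
                        m = 1.0 + bg_mottle * (2.0 * _mottle(p[0], p[1], noise_seed) - 1.0)
                        inten = diffuse_frac + (1.0 - diffuse_frac) * sun_dir[2] * lit
                        br = bg_albedo[0] * m * inten
                        bg = bg_albedo[1] * m * inten
                        bb = bg_albedo[2] * m * inten
                w = nss - cov
                r_acc += br * w
                g_acc += bg * w
                b_acc += bb * w
            rgb_out[j, i, 0] = r_acc / nss
            rgb_out[j, i, 1] = g_acc / nss
            rgb_out[j, i, 2] = b_acc / nss
            green_count[j, i] = cov
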