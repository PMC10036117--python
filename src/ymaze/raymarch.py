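"""Brute-force ray-marching cross-check for the analytic gaze caster.

This module re-derives gaze-ray surface hits by dense sampling along each
ray instead of analytic intersection: a point leaves the maze air volume
when it drops below the floor plane, exits the sky sphere, or crosses the
corridor footprint boundary below the wall tops (detected as a flip of the
even-odd point-in-polygon state between consecutive samples). It exists to
validate :func:`ymaze.geometry.cast_gaze_rays`; it shares only the maze
description with it, not the intersection algorithm.
"""

from __future__ import annotations

import numpy as np

from .geometry import MazeSpec, points_in_footprint

SURF_WALL, SURF_FLOOR, SURF_SKY = 0, 1, 2
SURF_NAMES = np.array(["wall", "floor", "sky"], dtype=object)


def march_rays(spec: MazeSpec, origins: np.ndarray, directions: np.ndarray,
               step: float = 1e-3, block: int = 256):
    """First surface crossed along each ray, by dense marching.

    Returns ``(surface_code, t_hit)``. Floor and sky crossings are located
    by linear interpolation between the bracketing samples; wall (footprint
    boundary) crossings are reported at the bracket midpoint, so ``t_hit``
    is accurate to ``step / 2`` for walls and much better for the smooth
    surfaces. Directions must be unit vectors.
    """
    fr = spec.frame()
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    n = len(o)
    R2 = fr.sky_radius ** 2
    h = fr.wall_height

    # upper bound: sphere exit distance (every ray ends at or before it)
    b = 2.0 * np.einsum("ij,ij->i", o, d)
    c = np.einsum("ij,ij->i", o, o) - R2
    t_max = (-b + np.sqrt(np.maximum(b * b - 4 * c, 0.0))) / 2.0 + 2 * step

    code = np.full(n, -1, dtype=np.int8)
    t_hit = np.full(n, np.nan)
    active = np.arange(n)
    prev_in = points_in_footprint(spec, o[:, :2])
    prev_t = np.zeros(n)
    k = 0
    while active.size:
        ts = (np.arange(k * block, (k + 1) * block) + 1.0) * step
        k += 1
        oa, da = o[active], d[active]
        pts = oa[:, None, :] + ts[None, :, None] * da[:, None, :]
        z = pts[:, :, 2]
        r2 = np.einsum("ijk,ijk->ij", pts, pts)
        flat = pts[:, :, :2].reshape(-1, 2)
        inpoly = points_in_footprint(spec, flat).reshape(len(active), block)

        floor = z <= 0.0
        sky = r2 >= R2
        prev_cols = np.concatenate(
            [prev_in[active][:, None], inpoly[:, :-1]], axis=1)
        zmid = 0.5 * (np.concatenate(
            [np.full((len(active), 1), np.nan), z[:, :-1]], axis=1) + z)
        zmid[:, 0] = 0.5 * ((o[active][:, 2] + (prev_t[active] *
                                                da[:, 2])) + z[:, 0])
        wall = (inpoly != prev_cols) & (zmid <= h)
        any_evt = floor | sky | wall
        hit_rows = np.nonzero(any_evt.any(axis=1))[0]
        for i in hit_rows:
            j = int(np.argmax(any_evt[i]))
            gi = active[i]
            tj = ts[j]
            t_prev = ts[j - 1] if j > 0 else prev_t[gi]
            if wall[i, j] and not (floor[i, j] or sky[i, j]):
                code[gi] = SURF_WALL
                t_hit[gi] = 0.5 * (t_prev + tj)
            elif floor[i, j]:
                z0 = o[gi, 2] + t_prev * d[gi, 2]
                z1 = z[i, j]
                frac = z0 / (z0 - z1) if z0 != z1 else 0.5
                code[gi] = SURF_FLOOR
                t_hit[gi] = t_prev + frac * (tj - t_prev)
            else:
                p0 = o[gi] + t_prev * d[gi]
                r0 = p0 @ p0
                r1 = r2[i, j]
                frac = (R2 - r0) / (r1 - r0) if r1 != r0 else 0.5
                code[gi] = SURF_SKY
                t_hit[gi] = t_prev + frac * (tj - t_prev)
        prev_in[active] = inpoly[:, -1]
        prev_t[active] = ts[-1]
        done = (code[active] >= 0) | (ts[-1] > t_max[active])
        # rays past t_max without an event exit exactly at the sphere
        strag = active[(code[active] < 0) & (ts[-1] > t_max[active])]
        if strag.size:
            code[strag] = SURF_SKY
            t_hit[strag] = t_max[strag] - 2 * step
        active = active[~done]
    return code, t_hit


def sample_interior_rays(spec: MazeSpec, n: int, rng: np.random.Generator):
    """Random gaze rays: origins uniform in the maze air volume below the
    wall tops, directions uniform on the sphere."""
    fr = spec.frame()
    lo = fr.verts.min(axis=0)
    hi = fr.verts.max(axis=0)
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.uniform(lo, hi, size=(2 * n, 2))
        cand = cand[points_in_footprint(spec, cand)]
        pts = np.vstack([pts, cand])
    pts = pts[:n]
    z = rng.uniform(0.05, fr.wall_height - 0.05, size=n)
    origins = np.column_stack([pts, z])
    v = rng.normal(size=(n, 3))
    directions = v / np.linalg.norm(v, axis=1, keepdims=True)
    return origins, directions


def _segment_distances(p: np.ndarray, d: np.ndarray, t_hi: float,
                       segs: np.ndarray) -> float:
    """Min distance between the ray segment [0, t_hi] and 3D segments."""
    a0 = p
    a1 = p + t_hi * d
    best = np.inf
    for b0, b1 in segs:
        u = a1 - a0
        v = b1 - b0
        w0 = a0 - b0
        aa, bb, cc = u @ u, u @ v, v @ v
        dd, ee = u @ w0, v @ w0
        den = aa * cc - bb * bb
        if den > 1e-12:
            s = np.clip((bb * ee - cc * dd) / den, 0.0, 1.0)
        else:
            s = 0.0
        t = np.clip((aa * ee - bb * dd) / den, 0.0, 1.0) if den > 1e-12 \
            else np.clip(ee / cc if cc > 0 else 0.0, 0.0, 1.0)
        # refine s for clamped t
        s = np.clip((bb * t - dd) / aa if aa > 0 else 0.0, 0.0, 1.0)
        t = np.clip((bb * s + ee) / cc if cc > 0 else 0.0, 0.0, 1.0)
        dist = np.linalg.norm((a0 + s * u) - (b0 + t * v))
        best = min(best, dist)
    return best


def _edge_skeleton(spec: MazeSpec) -> np.ndarray:
    """All wall-panel edges (3D segments) where surface labels can meet."""
    fr = spec.frame()
    segs = []
    for p, q in zip(fr.edges_p, fr.edges_q):
        p0 = np.array([p[0], p[1], 0.0])
        p1 = np.array([p[0], p[1], fr.wall_height])
        q0 = np.array([q[0], q[1], 0.0])
        q1 = np.array([q[0], q[1], fr.wall_height])
        segs += [(p0, p1), (q0, q1), (p1, q1), (p0, q0)]
    return np.array(segs)


def crosscheck_rays(spec: MazeSpec, origins: np.ndarray,
                    directions: np.ndarray, step: float = 1e-3,
                    tol: float = 1e-3) -> dict:
    """Compare the analytic caster against the marching oracle.

    A ray agrees when both report the same surface and hit distances within
    ``max(tol, step)``. Disagreements are re-marched at a 50x finer step;
    rays still in conflict are accepted only if the analytic ray passes
    within ``tol`` of a wall-panel edge, where the two labels genuinely
    meet and either answer is within tolerance. Returns a summary dict.
    """
    from .geometry import cast_gaze_rays

    surf, _, t_impl, _ = cast_gaze_rays(spec, origins, directions)
    code_impl = np.array([{"wall": 0, "floor": 1, "sky": 2}[s] for s in surf],
                         dtype=np.int8)
    code_orc, t_orc = march_rays(spec, origins, directions, step=step)
    dt = np.abs(t_impl - t_orc)
    agree = (code_impl == code_orc) & (dt <= max(tol, step))
    n_resolved = 0
    n_ambiguous = 0
    fails = []
    if not np.all(agree):
        bad = np.nonzero(~agree)[0]
        code2, t2 = march_rays(spec, origins[bad], directions[bad],
                               step=step / 50.0)
        skel = _edge_skeleton(spec)
        for i, gi in enumerate(bad):
            if code2[i] == code_impl[gi] and \
                    abs(t2[i] - t_impl[gi]) <= max(tol, step / 25.0):
                n_resolved += 1
                continue
            t_hi = float(max(t_impl[gi], t2[i])) + tol
            if _segment_distances(origins[gi], directions[gi], t_hi,
                                  skel) <= 1.5 * tol:
                n_ambiguous += 1
                continue
            fails.append(int(gi))
    n = len(t_impl)
    return {
        "n": n,
        "n_agree": int(agree.sum()),
        "n_resolved": n_resolved,
        "n_ambiguous": n_ambiguous,
        "n_fail": len(fails),
        "fail_indices": fails,
        "agreement_rate": (n - len(fails)) / n,
        "max_t_err_agree": float(dt[agree].max()) if agree.any() else 0.0,
    }
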