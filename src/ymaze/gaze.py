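"""Head/eye stream fusion, per-sample gaze labelling and dwell analysis.

The 30 Hz head stream is interpolated to the 120 Hz eye-tracker clock
(positions linearly, yaw by angular interpolation on the unwrapped angle,
which equals spherical interpolation for a yaw-only head orientation). The
cyclopean gaze direction averages the two eyes when both are valid, falls
back to the remaining eye when one is dropped, and is missing when both
are. Each non-missing sample is labelled with the surface its ray hits
(wall, floor or sky, the sky split into landmark-centered sectors) and its
elevation above eye level. Dwell proportions exclude missing samples from
the denominator; binned time courses stretch the orientation period over
15 bins and the navigation period over 35, each bin evaluated over a 1 s
window centered on the bin midpoint and clipped at the period edges.
Fixations and saccades are deliberately not separated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import MazeSpec, cast_gaze_rays, gaze_elevation

REGIONS = ("wall", "floor", "sky")


@dataclass
class FusedGaze:
    t: np.ndarray
    origin: np.ndarray          # (n, 3) world gaze origins at eye height
    left: np.ndarray            # (n, 3) world-frame left-eye directions
    right: np.ndarray
    lvalid: np.ndarray          # bool
    rvalid: np.ndarray


@dataclass
class LabelledGazeStream:
    t: np.ndarray
    origin: np.ndarray
    direction: np.ndarray       # cyclopean, world frame (NaN when missing)
    missing: np.ndarray         # bool
    surface: np.ndarray         # object: 'wall'|'floor'|'sky'|None
    sector: np.ndarray          # object: landmark label or None
    elevation: np.ndarray       # degrees, NaN when missing


@dataclass
class DwellSummary:
    proportions: dict            # region -> fraction of non-missing time
    sector_proportions: dict     # landmark label -> fraction
    missing_fraction: float
    timecourse: pd.DataFrame     # columns: bin, period, region, fraction
    n_samples: int
    valid: bool = True           # False when every sample is missing


def _rot_z(yaw: np.ndarray, v: np.ndarray) -> np.ndarray:
    c, s = np.cos(yaw), np.sin(yaw)
    return np.column_stack([c * v[:, 0] - s * v[:, 1],
                            s * v[:, 0] + c * v[:, 1], v[:, 2]])


def fuse_streams(pose: np.ndarray, gaze: np.ndarray) -> FusedGaze:
    """Synchronize the head stream to the gaze clock and rotate the
    eye-frame directions into the world frame.

    ``pose`` columns are (t, x, y, z, yaw) at the head rate; ``gaze``
    columns (t, left xyz, right xyz, left/right validity) at the eye rate.
    Gaze samples outside the pose time range are dropped.
    """
    if len(pose) == 0 or len(gaze) == 0:
        raise ValueError("empty stream")
    tp = pose[:, 0]
    tg = gaze[:, 0]
    if np.any(np.diff(tp) <= 0) or (len(tg) > 1 and np.any(np.diff(tg) <= 0)):
        raise ValueError("non-monotone timestamps")
    keep = (tg >= tp[0]) & (tg <= tp[-1])
    g = gaze[keep]
    tg = g[:, 0]
    origin = np.column_stack([np.interp(tg, tp, pose[:, i])
                              for i in (1, 2, 3)])
    yaw = np.interp(tg, tp, pose[:, 4])   # unwrapped yaw -> angular slerp
    left = _rot_z(yaw, g[:, 1:4])
    right = _rot_z(yaw, g[:, 4:7])
    return FusedGaze(tg, origin, left, right,
                     g[:, 7] > 0.5, g[:, 8] > 0.5)


def cyclopean(left: np.ndarray, lvalid: np.ndarray, right: np.ndarray,
              rvalid: np.ndarray):
    """Per-sample cyclopean direction: renormalized mean of the valid eyes,
    the single valid eye when one signal is dropped, missing when both are.
    Returns ``(directions, missing)`` with NaN rows where missing."""
    left = np.atleast_2d(left)
    right = np.atleast_2d(right)
    lvalid = np.atleast_1d(lvalid).astype(bool)
    rvalid = np.atleast_1d(rvalid).astype(bool)
    n = len(left)
    out = np.full((n, 3), np.nan)
    both = lvalid & rvalid
    mean = left[both] + right[both]
    out[both] = mean / np.linalg.norm(mean, axis=1, keepdims=True)
    lo = lvalid & ~rvalid
    ro = rvalid & ~lvalid
    out[lo] = left[lo] / np.linalg.norm(left[lo], axis=1, keepdims=True)
    out[ro] = right[ro] / np.linalg.norm(right[ro], axis=1, keepdims=True)
    return out, ~(lvalid | rvalid)


def label_stream(fused: FusedGaze, spec: MazeSpec) -> LabelledGazeStream:
    """Label every non-missing sample with its hit surface and elevation."""
    dirs, missing = cyclopean(fused.left, fused.lvalid,
                              fused.right, fused.rvalid)
    n = len(dirs)
    surface = np.full(n, None, dtype=object)
    sector = np.full(n, None, dtype=object)
    elevation = np.full(n, np.nan)
    ok = ~missing
    if ok.any():
        s, _, _, sec = cast_gaze_rays(spec, fused.origin[ok], dirs[ok])
        surface[ok] = s
        sector[ok] = sec
        elevation[ok] = gaze_elevation(dirs[ok])
    return LabelledGazeStream(fused.t, fused.origin, dirs, missing,
                              surface, sector, elevation)


def label_trial(trial, spec: MazeSpec) -> LabelledGazeStream:
    """Convenience: fuse and label one TrialRecord's streams."""
    return label_stream(fuse_streams(trial.pose, trial.gaze), spec)


def _window_fractions(lab: LabelledGazeStream, lo: float, hi: float) -> dict:
    sel = (lab.t >= lo) & (lab.t < hi) & ~lab.missing
    n = int(sel.sum())
    if n == 0:
        return {r: np.nan for r in REGIONS}
    return {r: float((lab.surface[sel] == r).sum()) / n for r in REGIONS}


def dwell_summary(lab: LabelledGazeStream, orientation, navigation,
                  window: float = 1.0, bins=(15, 35)) -> DwellSummary:
    """Dwell proportions, sector proportions and the binned time course.

    ``orientation`` and ``navigation`` are (start, end) times. Overall
    proportions use all samples of the two periods with missing samples
    excluded from the denominator. The time course maps the orientation
    period onto ``bins[0]`` equal-duration bins and navigation onto
    ``bins[1]``; each bin's value is the dwell fraction over a ``window``
    second window centered on the bin midpoint, clipped to the period.
    """
    t = lab.t
    span = (t >= orientation[0]) & (t < max(navigation[1], orientation[1]))
    n_all = int(span.sum())
    ok = span & ~lab.missing
    n_ok = int(ok.sum())
    missing_fraction = 1.0 - n_ok / n_all if n_all else np.nan
    if n_ok == 0:
        empty = pd.DataFrame(columns=["bin", "period", "region", "fraction"])
        return DwellSummary({r: np.nan for r in REGIONS}, {},
                            missing_fraction, empty, n_all, valid=False)
    surf = lab.surface[ok]
    proportions = {r: float((surf == r).sum()) / n_ok for r in REGIONS}
    sectors = lab.sector[ok]
    labels = sorted({s for s in sectors if s is not None})
    sector_proportions = {l: float((sectors == l).sum()) / n_ok
                          for l in labels}

    rows = []
    b = 0
    for (lo, hi), nb, name in ((orientation, bins[0], "orientation"),
                               (navigation, bins[1], "navigation")):
        edges = np.linspace(lo, hi, nb + 1)
        for i in range(nb):
            mid = 0.5 * (edges[i] + edges[i + 1])
            wlo = max(lo, mid - window / 2)
            whi = min(hi, mid + window / 2)
            fr = _window_fractions(lab, wlo, whi)
            for r in REGIONS:
                rows.append(dict(bin=b, period=name, region=r,
                                 fraction=fr[r]))
            b += 1
    tc = pd.DataFrame(rows)
    return DwellSummary(proportions, sector_proportions, missing_fraction,
                        tc, n_all)


def mean_orientation_altitude(lab: LabelledGazeStream, orientation) -> float:
    """Mean gaze elevation (deg) over non-missing orientation samples."""
    sel = (lab.t >= orientation[0]) & (lab.t < orientation[1]) & ~lab.missing
    if not sel.any():
        raise ValueError("no usable samples in the orientation period")
    return float(np.nanmean(lab.elevation[sel]))


def heatmap(points: np.ndarray, region: str, resolution: float = 2.0,
            floor_bounds: float = 3.0):
    """Max-normalized 2D density of surface hit points.

    Sky points are accumulated on an azimuth x elevation grid with
    ``resolution``-degree cells; floor points on an x-y grid over
    ``[-floor_bounds, floor_bounds]`` with cells of ``resolution / 10``
    metres. Returns ``(grid, x_edges, y_edges)`` with the maximal cell
    equal to 1.
    """
    pts = np.atleast_2d(points)
    if len(pts) == 0:
        raise ValueError("empty point set")
    if region == "sky":
        az = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
        r = np.linalg.norm(pts, axis=1)
        el = np.degrees(np.arcsin(np.clip(pts[:, 2] / r, -1, 1)))
        xe = np.arange(0.0, 360.0 + resolution, resolution)
        ye = np.arange(0.0, 90.0 + resolution, resolution)
        grid, _, _ = np.histogram2d(az, el, bins=(xe, ye))
    elif region == "floor":
        cell = resolution / 10.0
        xe = np.arange(-floor_bounds, floor_bounds + cell, cell)
        ye = xe
        grid, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(xe, ye))
    else:
        raise ValueError("heatmap regions are 'sky' and 'floor'")
    peak = grid.max()
    if peak > 0:
        grid = grid / peak
    return grid, xe, ye


def trial_dwell(trial, spec: MazeSpec, window: float = 1.0,
                bins=(15, 35)) -> DwellSummary:
    """Segment, fuse, label and summarize one trial in a single call."""
    from .metrics import segment_trial
    orientation, navigation = segment_trial(trial, spec)
    lab = label_trial(trial, spec)
    return dwell_summary(lab, orientation, navigation, window=window,
                         bins=bins)


def dwell_table(trials, specs: dict) -> pd.DataFrame:
    """Per-trial dwell proportions for a set of trials with gaze data."""
    rows = []
    for tr in trials:
        if len(tr.gaze) == 0:
            continue
        d = trial_dwell(tr, specs[tr.subject_id])
        row = dict(subject_id=tr.subject_id, age_group=tr.age_group,
                   condition=tr.condition, phase=tr.phase,
                   trial_index=tr.trial_index, start_arm=tr.start_arm,
                   missing_fraction=d.missing_fraction, valid=d.valid)
        row.update({f"p_{r}": d.proportions[r] for r in REGIONS})
        for l, v in d.sector_proportions.items():
            row[f"sector_{l}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def altitude_features(trials, specs: dict) -> pd.DataFrame:
    """Per-subject mean orientation-period gaze altitude on probe trials.

    The feature of the strategy/condition classifier: for each subject the
    gaze elevations of the three B-start probe orientation periods are
    averaged (trials without usable samples are skipped).
    """
    from .metrics import segment_trial
    acc: dict = {}
    meta = {}
    for tr in trials:
        if tr.phase != "test" or tr.start_arm != "B" or len(tr.gaze) == 0:
            continue
        spec = specs[tr.subject_id]
        orientation, _ = segment_trial(tr, spec)
        lab = label_trial(tr, spec)
        try:
            alt = mean_orientation_altitude(lab, orientation)
        except ValueError:
            continue
        acc.setdefault(tr.subject_id, []).append(alt)
        meta[tr.subject_id] = (tr.age_group, tr.condition)
    rows = [dict(subject_id=sid, age_group=meta[sid][0],
                 condition=meta[sid][1],
                 mean_orientation_altitude=float(np.mean(v)))
            for sid, v in acc.items()]
    return pd.DataFrame(rows)
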