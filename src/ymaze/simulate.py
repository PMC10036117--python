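"""Seeded agent-based simulator of Y-maze navigation cohorts.

The simulator emulates the protocol the analysis pipeline expects:
learning trials from arm A to the rewarded arm C until four consecutive
successes, then the six-trial test sequence B, A, A, B, A, B in which the
three B-start probe trials reveal the navigation strategy. Each trial
yields a 30 Hz head-pose stream and a 120 Hz binocular gaze stream with
validity flags, with the statistical structure the analysis assumes:
group-dependent allocentric-choice probabilities, state-dependent gaze
elevation profiles (sky-ward orientation toward the facing landmark in the
landmark condition, floor-ward toward the junction fork in the geometry
condition, wall-level gaze while walking), and independent per-sample gaze
drop-out at the study's 22-27 % rates.

Trajectories are piecewise constant-speed polylines with smoothed Gaussian
lateral jitter and a circular-arc turn through the junction; view-matching
agents insert an extra dwell at the maze center where they re-fixate the
circle landmark. Every random quantity flows from one integer seed through
``numpy`` SeedSequence spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MazeSpec, build_maze, in_central_area

POSE_COLS = ("t", "x", "y", "z", "yaw")
GAZE_COLS = ("t", "lx", "ly", "lz", "rx", "ry", "rz", "lvalid", "rvalid")
AGE_GROUPS = ("children", "young", "older")
STRATEGIES = ("egocentric", "allocentric_map", "allocentric_viewmatch")
TEST_SEQUENCE = ("B", "A", "A", "B", "A", "B")
HEAD_RATE = 30.0
GAZE_RATE = 120.0


@dataclass(frozen=True)
class AgentProfile:
    """Latent parameters of one simulated navigator."""

    age_group: str
    strategy: str
    p_allocentric_choice: float      # per probe trial
    learning_error_rate: float       # P(enter arm B) per learning trial
    walk_speed: tuple                # (mean, sd), m/s
    orientation_pause: tuple         # (mean, sd), s
    center_dwell_extra: float = 0.0  # s, view-matchers only
    gaze_state_elevations: dict = field(default_factory=lambda: dict(
        orient_sky=(25.0, 5.0), orient_floor=(-30.0, 6.0),
        navigate_walls=(-2.0, 4.0)))
    missing_rate: float = 0.25       # P(both eyes invalid) per gaze sample
    missing_mode: str = "iid"        # 'iid' | 'bursty' (blink-like runs)
    burst_mean_samples: float = 12.0  # mean blink-burst length (bursty mode)
    single_eye_drop: float = 0.05    # P(exactly one eye invalid)
    lateral_jitter: float = 0.03     # m, walking position noise (smoothed)

    def __post_init__(self):
        for p in (self.p_allocentric_choice, self.learning_error_rate,
                  self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.walk_speed[0] <= 0 or self.orientation_pause[0] < 0:
            raise ValueError("speeds and pauses must be positive")


@dataclass
class TrialRecord:
    """One trial's synchronized pose and gaze streams plus metadata."""

    subject_id: str
    age_group: str
    condition: str
    phase: str                  # 'learning' | 'test'
    trial_index: int
    start_arm: str
    subject_height: float
    pose: np.ndarray            # (n, 5): t, x, y, z(eye), yaw(rad, unwrapped)
    gaze: np.ndarray            # (m, 9): t, l/r unit dirs (head frame), validity
    end_event: str = "stopped_at_endpoint"

    def pose_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.pose, columns=list(POSE_COLS))

    def gaze_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.gaze, columns=list(GAZE_COLS))


@dataclass(frozen=True)
class SimConfig:
    """Cohort recipe: who is simulated and at what fidelity."""

    group_sizes: dict            # (age_group, condition) -> count
    profiles: dict               # (age_group, condition) -> [(weight, AgentProfile)]
    seed: int = 0
    test_sequence: tuple = TEST_SEQUENCE
    stream_detail: str = "full"  # 'full' | 'sparse'
    phases: tuple = ("learning", "test")
    max_learning_trials: int = 40
    head_rate: float = HEAD_RATE
    gaze_rate: float = GAZE_RATE


@dataclass
class CohortSim:
    trials: list
    ground_truth: pd.DataFrame   # one row per subject, latent labels
    config: SimConfig


# ---------------------------------------------------------------------------
# defaults: the study conditions

_SPEED = {"children": (0.85, 0.12), "young": (1.05, 0.12), "older": (0.75, 0.10)}
_PAUSE = {"children": (2.5, 0.8), "young": (1.5, 0.4), "older": (3.5, 1.0)}
_MISS = {"children": 0.25, "young": 0.22, "older": 0.27}
#: observed majority-allocentric cell proportions used as mixture weights
_ALLO_WEIGHT = {
    ("children", "landmark"): 0.32, ("young", "landmark"): 0.88,
    ("older", "landmark"): 0.31, ("children", "geometry"): 0.82,
    ("young", "geometry"): 0.99, ("older", "geometry"): 0.82}
_LEARN_ERR = {
    ("children", "landmark"): 0.35, ("young", "landmark"): 0.15,
    ("older", "landmark"): 0.40, ("children", "geometry"): 0.08,
    ("young", "geometry"): 0.08, ("older", "geometry"): 0.08}
#: cohort cell sizes of the immersive-VR sample (n = 79)
DEFAULT_GROUP_SIZES = {
    ("children", "landmark"): 15, ("young", "landmark"): 11,
    ("older", "landmark"): 16, ("children", "geometry"): 14,
    ("young", "geometry"): 11, ("older", "geometry"): 12}
_HEIGHT = {"children": (1.40, 0.06), "young": (1.72, 0.08),
           "older": (1.68, 0.08)}


def default_profile(age_group: str, condition: str, strategy: str,
                    **kw) -> AgentProfile:
    base = dict(
        age_group=age_group, strategy=strategy,
        p_allocentric_choice=0.95 if strategy != "egocentric" else 0.05,
        learning_error_rate=_LEARN_ERR[(age_group, condition)],
        walk_speed=_SPEED[age_group], orientation_pause=_PAUSE[age_group],
        center_dwell_extra=6.0 if strategy == "allocentric_viewmatch" else 0.0,
        missing_rate=_MISS[age_group])
    base.update(kw)
    return AgentProfile(**base)


def default_config(seed: int = 0, size_scale: float = 1.0,
                   stream_detail: str = "full") -> SimConfig:
    """Cohort with the study's cell sizes and strategy mixtures."""
    sizes = {k: max(1, round(v * size_scale))
             for k, v in DEFAULT_GROUP_SIZES.items()}
    profiles = {}
    for (age, cond) in sizes:
        w_allo = _ALLO_WEIGHT[(age, cond)]
        # older landmark-condition allocentric navigators split between
        # map-based and view-matching behavior; no circle to match elsewhere
        vm = 0.5 if (age == "older" and cond == "landmark") else 0.0
        mix = [(1.0 - w_allo, default_profile(age, cond, "egocentric")),
               (w_allo * (1 - vm), default_profile(age, cond, "allocentric_map"))]
        if vm > 0:
            mix.append((w_allo * vm,
                        default_profile(age, cond, "allocentric_viewmatch")))
        profiles[(age, cond)] = mix
    return SimConfig(group_sizes=sizes, profiles=profiles, seed=seed,
                     stream_detail=stream_detail)


# ---------------------------------------------------------------------------
# trajectory machinery

def _polyline_resample(way: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Positions at arc lengths s along a waypoint polyline."""
    seg = np.diff(way, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    s = np.clip(s, 0.0, cum[-1])
    x = np.interp(s, cum, way[:, 0])
    y = np.interp(s, cum, way[:, 1])
    return np.column_stack([x, y])


def _arc_waypoints(spec: MazeSpec, a_from: str, a_to: str,
                   r_turn: float = 0.45, n_arc: int = 12) -> np.ndarray:
    """Quadratic-Bezier turn through the junction between two arm axes."""
    fr = spec.frame()
    p0 = r_turn * fr.axes[a_from]
    p2 = r_turn * fr.axes[a_to]
    ts = np.linspace(0.0, 1.0, n_arc)[:, None]
    ctrl = np.zeros(2)
    return (1 - ts) ** 2 * p0 + 2 * ts * (1 - ts) * ctrl + ts ** 2 * p2


def _route(spec: MazeSpec, start: str, dest: str,
           detour: str | None) -> np.ndarray:
    """2D waypoint polyline from start arm end to destination arm end."""
    fr = spec.frame()
    legs = [fr.ends[start][None, :]]
    cur = start
    if detour is not None:
        legs.append(_arc_waypoints(spec, cur, detour))
        legs.append((0.6 * spec.corridor_length * fr.axes[detour])[None, :])
        legs.append((0.45 * fr.axes[detour])[None, :])
        cur = detour
    legs.append(_arc_waypoints(spec, cur, dest))
    legs.append(fr.ends[dest][None, :])
    return np.vstack(legs)


def _smooth_noise(rng, n: int, sd: float, width: int = 7) -> np.ndarray:
    if n == 0 or sd == 0:
        return np.zeros((n, 2))
    raw = rng.normal(0.0, sd, size=(n + width, 2))
    kern = np.hanning(width)
    kern /= kern.sum()
    out = np.column_stack([np.convolve(raw[:, i], kern, mode="same")
                           for i in range(2)])
    return out[:n] * (sd / max(out[:n].std(), 1e-12))


def _bursty_mask(rng, n: int, rate: float, mean_burst: float) -> np.ndarray:
    """Two-state (visible/blink) run-length process with the target
    stationary missing rate; real blink losses are bursty, not i.i.d."""
    if rate <= 0:
        return np.zeros(n, dtype=bool)
    mean_gap = mean_burst * (1 - rate) / rate
    out = np.zeros(n, dtype=bool)
    i = 0
    missing = rng.random() < rate
    while i < n:
        mean_len = mean_burst if missing else mean_gap
        run = int(rng.geometric(1.0 / max(mean_len, 1.0)))
        out[i:i + run] = missing
        i += run
        missing = not missing
    return out


def _az_to_dir(az_deg: np.ndarray, elev_deg: np.ndarray) -> np.ndarray:
    az = np.radians(az_deg)
    el = np.radians(np.clip(elev_deg, -89.9, 89.9))
    return np.column_stack([np.cos(el) * np.cos(az),
                            np.cos(el) * np.sin(az), np.sin(el)])


def simulate_trial(spec: MazeSpec, profile: AgentProfile, start_arm: str,
                   phase: str, rng: np.random.Generator, *,
                   subject_id: str = "s0", trial_index: int = 0,
                   stream_detail: str = "full"):
    """Simulate one trial; returns ``(TrialRecord, ground_truth_dict)``.

    Learning trials run A -> C, with probability ``learning_error_rate`` of
    a detour into arm B (the failure criterion). B-start probe trials go to
    C with probability ``p_allocentric_choice``, else to A (the egocentric
    response). A-start test trials repeat the learned route to C.
    """
    fr = spec.frame()
    goal = spec.goal_arm
    detour = None
    if phase == "learning":
        failed = rng.random() < profile.learning_error_rate
        dest = goal
        if failed:
            detour = "B"
        allocentric = None
    else:
        if start_arm == "B":
            allocentric = rng.random() < profile.p_allocentric_choice
            dest = goal if allocentric else "A"
        else:
            allocentric = None
            dest = goal
        failed = False

    sparse = stream_detail == "sparse"
    dt = (1.0 / HEAD_RATE) if not sparse else 0.1
    pause = max(0.3, rng.normal(*profile.orientation_pause))
    speed = max(0.2, rng.normal(*profile.walk_speed))
    way = _route(spec, start_arm, dest, detour)
    seg = np.diff(way, axis=0)
    total_len = float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    # time -> arc length schedule (piecewise linear breakpoints)
    bp_t = [0.0, pause]
    bp_s = [0.0, 0.0]
    dwell = profile.center_dwell_extra if (
        profile.strategy == "allocentric_viewmatch" and phase == "test"
        and start_arm == "B") else 0.0
    if dwell > 0:
        # hold at the closest approach to the maze center
        dense_s = np.linspace(0, total_len, 400)
        dense_p = _polyline_resample(way, dense_s)
        s_center = float(dense_s[np.argmin(np.hypot(*dense_p.T))])
        t_center = pause + s_center / speed
        bp_t += [t_center, t_center + dwell, t_center + dwell +
                 (total_len - s_center) / speed]
        bp_s += [s_center, s_center, total_len]
    else:
        bp_t.append(pause + total_len / speed)
        bp_s.append(total_len)
    stop = 5.2 if not sparse else 0.2
    bp_t.append(bp_t[-1] + stop)
    bp_s.append(total_len)

    t = np.arange(0.0, bp_t[-1] + dt / 2, dt)
    s = np.interp(t, bp_t, bp_s)
    xy = _polyline_resample(way, s)
    walking = (s > 0) & (s < total_len)
    noise = _smooth_noise(rng, len(t), profile.lateral_jitter)
    still_noise = _smooth_noise(rng, len(t), 5e-4)
    xy = xy + np.where(walking[:, None], noise, still_noise)

    # heading: direction of travel; face the center while paused/stopped
    vel = np.gradient(xy, dt, axis=0)
    yaw = np.arctan2(vel[:, 1], vel[:, 0])
    face_center = np.arctan2(-xy[:, 1], -xy[:, 0])
    spd = np.hypot(vel[:, 0], vel[:, 1])
    yaw = np.where(spd > 0.05, yaw, face_center)
    yaw = np.unwrap(yaw)
    z = np.full(len(t), spec.eye_height)
    pose = np.column_stack([t, xy, z, yaw])

    truth = dict(phase=phase, start_arm=start_arm, dest=dest,
                 failed_learning=bool(failed), allocentric=allocentric,
                 pause=pause, speed=speed, dwell=dwell)
    end_event = "goal_reached" if phase == "learning" else "stopped_at_endpoint"

    if sparse:
        gaze = np.empty((0, len(GAZE_COLS)))
        rec = TrialRecord(subject_id, profile.age_group, spec.condition,
                          phase, trial_index, start_arm, spec.subject_height,
                          pose, gaze, end_event)
        return rec, truth

    # ------------------------------------------------------------------ gaze
    tg = np.arange(0.0, t[-1], 1.0 / GAZE_RATE)
    m = len(tg)
    pos_g = np.column_stack([np.interp(tg, t, xy[:, 0]),
                             np.interp(tg, t, xy[:, 1])])
    yaw_g = np.interp(tg, t, yaw)
    t_exit = pause  # locomotion initiation
    orienting = tg < t_exit
    elevs = profile.gaze_state_elevations

    az_target = np.degrees(np.arctan2(-pos_g[:, 1], -pos_g[:, 0]))  # center
    el_mean = np.full(m, elevs["navigate_walls"][0])
    el_sd = np.full(m, elevs["navigate_walls"][1])

    landmark_cond = spec.condition == "landmark"
    looks_up = landmark_cond and (
        phase == "learning" or start_arm != "B"
        or profile.strategy != "egocentric")
    if np.any(orienting):
        if looks_up:
            facing = next(l for l in spec.landmarks
                          if l.facing_arm == start_arm)
            az_target[orienting] = facing.azimuth_deg
            el_mean[orienting], el_sd[orienting] = elevs["orient_sky"]
        elif not landmark_cond:
            el_mean[orienting], el_sd[orienting] = elevs["orient_floor"]
        # egocentric probe agents keep wall-level gaze toward the center

    if dwell > 0 and landmark_cond:
        central = in_central_area(spec, pos_g)
        refix = central & ~orienting
        circle = next(l for l in spec.landmarks if l.label == "circle")
        az_target[refix] = circle.azimuth_deg
        el_mean[refix], el_sd[refix] = elevs["orient_sky"]

    # while walking, look along the direction of travel
    walking_g = np.interp(tg, t, walking.astype(float)) > 0.5
    heading = np.degrees(yaw_g)
    nav = walking_g & ~orienting
    if dwell > 0 and landmark_cond:
        nav &= ~refix
    az_target[nav] = heading[nav]

    elev = rng.normal(el_mean, el_sd)
    az = az_target + rng.normal(0.0, 3.0, size=m)
    world = _az_to_dir(az, elev)
    # into head frame (yaw-only head orientation)
    cy, sy = np.cos(-yaw_g), np.sin(-yaw_g)
    head = np.column_stack([cy * world[:, 0] - sy * world[:, 1],
                            sy * world[:, 0] + cy * world[:, 1],
                            world[:, 2]])

    def eye(dirs):
        pert = rng.normal(0.0, np.radians(0.3), size=(m, 3))
        d = dirs + pert
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    left, right = eye(head), eye(head)
    u = rng.random(m)
    if profile.missing_mode == "bursty":
        both_out = _bursty_mask(rng, m, profile.missing_rate,
                                profile.burst_mean_samples)
    else:
        both_out = u < profile.missing_rate
    left_only = (~both_out) & (u < profile.missing_rate +
                               profile.single_eye_drop / 2)
    right_only = (~both_out & ~left_only) & (
        u < profile.missing_rate + profile.single_eye_drop)
    lvalid = (~both_out & ~left_only).astype(float)
    rvalid = (~both_out & ~right_only).astype(float)
    gaze = np.column_stack([tg, left, right, lvalid, rvalid])

    rec = TrialRecord(subject_id, profile.age_group, spec.condition, phase,
                      trial_index, start_arm, spec.subject_height, pose,
                      gaze, end_event)
    return rec, truth


# ---------------------------------------------------------------------------
# cohorts

def simulate_subject(subject_id: str, profile: AgentProfile, condition: str,
                     height: float, rng: np.random.Generator,
                     config: SimConfig):
    """All trials of one subject; returns (trials, subject_truth)."""
    spec = build_maze(condition, height)
    trials = []
    truths = []
    idx = 0
    n_learning = 0
    criterion_met = False
    if "learning" in config.phases:
        streak = 0
        while n_learning < config.max_learning_trials:
            rec, tr = simulate_trial(
                spec, profile, "A", "learning", rng, subject_id=subject_id,
                trial_index=idx, stream_detail=config.stream_detail)
            trials.append(rec)
            truths.append(tr)
            idx += 1
            n_learning += 1
            streak = 0 if tr["failed_learning"] else streak + 1
            if streak >= 4:
                criterion_met = True
                break
    probe_choices = []
    if "test" in config.phases:
        for start in config.test_sequence:
            rec, tr = simulate_trial(
                spec, profile, start, "test", rng, subject_id=subject_id,
                trial_index=idx, stream_detail=config.stream_detail)
            trials.append(rec)
            truths.append(tr)
            idx += 1
            if start == "B":
                probe_choices.append(bool(tr["allocentric"]))
    n_allo = sum(probe_choices)
    subject_truth = dict(
        subject_id=subject_id, age_group=profile.age_group,
        condition=condition, strategy=profile.strategy,
        p_allocentric_choice=profile.p_allocentric_choice,
        subject_height=height, n_learning_trials=n_learning,
        criterion_met=criterion_met or "learning" not in config.phases,
        n_probe_allocentric=n_allo,
        majority_allocentric=n_allo >= 2 if probe_choices else None)
    return trials, subject_truth


def simulate_cohort(config: SimConfig) -> CohortSim:
    """Simulate every subject of the configured cohort, deterministically."""
    if not config.group_sizes or all(v == 0 for v in config.group_sizes.values()):
        raise ValueError("empty group sizes")
    cells = sorted(config.group_sizes.items())
    n_subjects = sum(n for _, n in cells)
    seeds = np.random.SeedSequence(config.seed).spawn(n_subjects + 1)
    assign_rng = np.random.default_rng(seeds[0])
    trials = []
    rows = []
    k = 0
    for (age, cond), n in cells:
        mix = config.profiles[(age, cond)]
        weights = np.array([w for w, _ in mix], dtype=float)
        weights = weights / weights.sum()
        for i in range(n):
            rng = np.random.default_rng(seeds[1 + k])
            sid = f"{cond[:4]}_{age[:5]}_{i:03d}"
            j = assign_rng.choice(len(mix), p=weights)
            profile = mix[j][1]
            height = float(np.clip(assign_rng.normal(*_HEIGHT[age]),
                                   1.1, 2.1))
            subj_trials, truth = simulate_subject(
                sid, profile, cond, height, rng, config)
            trials.extend(subj_trials)
            rows.append(truth)
            k += 1
    return CohortSim(trials, pd.DataFrame(rows), config)
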