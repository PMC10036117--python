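"""Trial segmentation, navigation variables, and strategy classification.

Each trial splits into an *orientation* period (stimulus onset until the
subject exits a 0.3 m circle around the departure position) and the
subsequent *navigation* period. Seven variables quantify performance:
trials-to-criterion, traveled distance, escape latency, orientation and
navigation durations, average speed (and its height-normalized form) and
time in the central area (the junction plus the inner third of each arm).
Strategy on a B-start probe trial is read from the first 0.4 m endpoint
disk entered: goal arm C = allocentric, arm A (the learned body turn) =
egocentric, anything else unclassifiable. A subject is allocentric if a
majority of the three probe trials are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ARMS, MazeSpec, in_central_area, in_disk


@dataclass
class TrialMetrics:
    orientation_duration: float
    navigation_duration: float
    escape_latency: float
    traveled_distance: float
    average_speed: float
    normalized_speed: float
    time_in_central_area: float
    first_endpoint: str          # 'A' | 'B' | 'C' | 'none'
    success: bool | None         # learning trials only
    strategy: str | None         # probe trials only
    valid: bool = True           # False when navigation never started


@dataclass(frozen=True)
class SketchScore:
    shape_correct: bool
    landmarks_correct: bool
    order_correct: bool
    placement_correct: bool
    goal_correct: bool


def segment_trial(trial, spec: MazeSpec):
    """(orientation, navigation) time intervals of one trial.

    Orientation runs from stimulus onset to the first pose sample outside
    the 0.3 m departure circle; navigation is the remainder. A subject who
    never leaves the circle has an empty navigation interval.
    """
    pose = trial.pose
    if len(pose) == 0:
        raise ValueError("empty pose stream")
    xy = pose[:, 1:3]
    start = spec.frame().ends[trial.start_arm]
    dist = np.hypot(xy[:, 0] - start[0], xy[:, 1] - start[1])
    if dist[0] > spec.departure_radius:
        raise ValueError("trial does not start inside the departure circle")
    outside = np.nonzero(dist > spec.departure_radius)[0]
    t = pose[:, 0]
    if len(outside) == 0:
        return (t[0], t[-1]), (t[-1], t[-1])
    t_exit = t[outside[0]]
    return (t[0], t_exit), (t_exit, t[-1])


def _disk_entry_index(trial, spec: MazeSpec, arm: str, radius: float,
                      hysteresis: float = 0.1) -> int | None:
    """Pose index of the first entry into an arm-end disk.

    A disk occupied at stimulus onset is re-armed only once the subject is
    ``radius + hysteresis`` away from its center, so head sway at the disk
    boundary cannot register a spurious re-entry.
    """
    xy = trial.pose[:, 1:3]
    c = spec.frame().ends[arm]
    dist = np.hypot(xy[:, 0] - c[0], xy[:, 1] - c[1])
    start = 0
    if dist[0] <= radius:
        armed = np.nonzero(dist > radius + hysteresis)[0]
        if len(armed) == 0:
            return None
        start = int(armed[0])
    idx = np.nonzero(dist[start:] <= radius)[0]
    return int(idx[0]) + start if len(idx) else None


def first_endpoint(trial, spec: MazeSpec) -> str:
    """Label of the first 0.4 m endpoint disk *entered* during the trial.

    The start-arm disk occupied at stimulus onset does not count until it
    is left (with a small hysteresis margin) and re-entered; 'none' if no
    disk is ever entered.
    """
    entries = {}
    for arm in ARMS:
        i = _disk_entry_index(trial, spec, arm, spec.endpoint_radius)
        if i is not None:
            entries[arm] = i
    if not entries:
        return "none"
    return min(entries, key=entries.get)


def _nav_end_index(trial, spec: MazeSpec, i_exit: int) -> int:
    """Pose index ending the navigation period.

    Learning: first sample inside the goal disk after leaving the departure
    circle. Test: first sample inside any endpoint disk entered after the
    start disk is left. Falls back to the last sample.
    """
    xy = trial.pose[:, 1:3]
    n = len(xy)
    if trial.phase == "learning":
        goal_in = in_disk(spec, spec.goal_arm, xy, spec.goal_radius)
        idx = np.nonzero(goal_in[i_exit:])[0]
        return int(idx[0]) + i_exit if len(idx) else n - 1
    cand = [i for i in (_disk_entry_index(trial, spec, arm,
                                          spec.endpoint_radius)
                        for arm in ARMS)
            if i is not None and i >= i_exit]
    return min(cand) if cand else n - 1


def compute_metrics(trial, spec: MazeSpec,
                    subject_height: float | None = None) -> TrialMetrics:
    """The per-trial navigation variables.

    Traveled distance sums successive positional displacements over the
    navigation interval (raw 30 Hz samples, no filtering); average speed is
    the traveled distance divided by the navigation duration; normalized
    speed additionally divides by the subject height. Time in the central
    area accumulates sample durations over the whole trial.
    """
    height = subject_height if subject_height is not None \
        else trial.subject_height
    (t0, t_exit), (_, t_end) = segment_trial(trial, spec)
    t = trial.pose[:, 0]
    xy = trial.pose[:, 1:3]
    i_exit = int(np.searchsorted(t, t_exit))
    orientation = t_exit - t0

    fe = first_endpoint(trial, spec)
    dt = np.diff(t, append=t[-1] + (t[-1] - t[-2] if len(t) > 1 else 0.0))
    central = in_central_area(spec, xy)
    t_central = float(dt[central].sum())

    if t_exit >= t_end:   # never left the departure circle
        return TrialMetrics(orientation, 0.0, orientation, np.nan, np.nan,
                            np.nan, t_central, fe,
                            False if trial.phase == "learning" else None,
                            _strategy_label(trial, fe), valid=False)

    i_end = _nav_end_index(trial, spec, i_exit)
    nav_xy = xy[i_exit:i_end + 1]
    steps = np.diff(nav_xy, axis=0)
    distance = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    nav_dur = float(t[i_end] - t_exit)
    speed = distance / nav_dur if nav_dur > 0 else np.nan
    success = learning_success(trial, spec) if trial.phase == "learning" \
        else None
    return TrialMetrics(
        orientation_duration=float(orientation),
        navigation_duration=nav_dur,
        escape_latency=float(orientation + nav_dur),
        traveled_distance=distance,
        average_speed=speed,
        normalized_speed=speed / height,
        time_in_central_area=t_central,
        first_endpoint=fe,
        success=success,
        strategy=_strategy_label(trial, fe))


def learning_success(trial, spec: MazeSpec) -> bool:
    """A learning trial succeeds iff the goal is reached and the trajectory
    never enters arm B's corridor. Re-entering the subject's own arm A is
    allowed by the stated rule."""
    if trial.phase != "learning":
        raise ValueError("learning_success applies to learning trials")
    xy = trial.pose[:, 1:3]
    reached = bool(in_disk(spec, spec.goal_arm, xy, spec.goal_radius).any())
    from .geometry import in_arm_corridor
    entered_b = bool(in_arm_corridor(spec, "B", xy).any())
    return reached and not entered_b


def trials_to_criterion(success_flags) -> int:
    """1-based index of the trial completing the first run of four
    consecutive successes; raises if the criterion is never met."""
    streak = 0
    for i, s in enumerate(success_flags):
        streak = streak + 1 if s else 0
        if streak >= 4:
            return i + 1
    raise ValueError("criterion of four consecutive successes never met")


def _strategy_label(trial, fe: str) -> str | None:
    if trial.phase != "test" or trial.start_arm != "B":
        return None
    return {"C": "allocentric", "A": "egocentric"}.get(fe, "unclassifiable")


def classify_probe_trial(trial, spec: MazeSpec) -> str:
    """Strategy expressed on one B-start probe trial."""
    if trial.phase != "test" or trial.start_arm != "B":
        raise ValueError("probe classification applies to B-start test trials")
    return _strategy_label(trial, first_endpoint(trial, spec))


def subject_strategy(probe_labels) -> str:
    """Majority strategy over the three B-start probe labels.

    Two or more allocentric trials make the subject allocentric; two or
    more egocentric trials egocentric; otherwise (unclassifiable trials
    blocking a majority either way) unclassifiable.
    """
    labels = list(probe_labels)
    if len(labels) != 3:
        raise ValueError(f"expected 3 probe labels, got {len(labels)}")
    n_allo = labels.count("allocentric")
    n_ego = labels.count("egocentric")
    if n_allo >= 2:
        return "allocentric"
    if n_ego >= 2:
        return "egocentric"
    return "unclassifiable"


# ---------------------------------------------------------------------------
# sketch-map scoring

_TRUE_ORDER = ("star", "square", "circle")   # CCW around the maze


def _cyclic_equal(a, b) -> bool:
    a, b = list(a), list(b)
    if len(a) != len(b):
        return False
    return any(a == b[i:] + b[:i] for i in range(len(b)))


def score_sketch(sketch: dict, spec: MazeSpec) -> SketchScore:
    """Score an encoded top-view sketch of the landmark maze.

    ``sketch`` keys: ``shape`` (chosen maze shape id), ``landmarks`` (set
    of chosen labels), ``order`` (labels CCW as drawn), ``placement``
    (per-landmark slot, 'between_arms' or 'arm_end'), ``goal_arm``.
    Order is correct up to rotation only; a mirrored (reflected) cyclic
    order counts as incorrect.
    """
    required = {"shape", "landmarks", "order", "placement", "goal_arm"}
    missing = required - set(sketch)
    if missing:
        raise ValueError(f"malformed sketch record, missing {sorted(missing)}")
    shape_ok = sketch["shape"] == "y_maze"
    lm_ok = set(sketch["landmarks"]) == set(_TRUE_ORDER)
    order = list(sketch["order"])
    order_ok = (len(order) == 3 and set(order) == set(_TRUE_ORDER)
                and _cyclic_equal(order, _TRUE_ORDER))
    placement = sketch["placement"]
    placement_ok = bool(placement) and all(
        placement.get(l) == "between_arms" for l in _TRUE_ORDER)
    goal_ok = sketch["goal_arm"] == spec.goal_arm
    return SketchScore(shape_ok, lm_ok, order_ok, placement_ok, goal_ok)


# ---------------------------------------------------------------------------
# cohort tables

def metrics_table(trials, specs: dict) -> pd.DataFrame:
    """One row of navigation variables per trial.

    ``specs`` maps subject_id -> MazeSpec (wall height is per subject).
    """
    rows = []
    for tr in trials:
        m = compute_metrics(tr, specs[tr.subject_id])
        rows.append(dict(subject_id=tr.subject_id, age_group=tr.age_group,
                         condition=tr.condition, phase=tr.phase,
                         trial_index=tr.trial_index, start_arm=tr.start_arm,
                         **m.__dict__))
    return pd.DataFrame(rows)


def cohort_table(trials, specs: dict) -> pd.DataFrame:
    """One row per subject: factors, strategy, majority-allocentric outcome.

    Unclassifiable subjects are flagged (``classifiable = False``) and
    pooled with the egocentric group for the binary outcome, mirroring how
    they enter profiling analyses; behavioral/gaze analyses should filter
    on the flag.
    """
    probes: dict = {}
    meta = {}
    learn: dict = {}
    for tr in trials:
        meta[tr.subject_id] = (tr.age_group, tr.condition)
        spec = specs[tr.subject_id]
        if tr.phase == "test" and tr.start_arm == "B":
            probes.setdefault(tr.subject_id, []).append(
                classify_probe_trial(tr, spec))
        elif tr.phase == "learning":
            learn.setdefault(tr.subject_id, []).append(
                (tr.trial_index, learning_success(tr, spec)))
    rows = []
    for sid, (age, cond) in meta.items():
        strat = subject_strategy(probes[sid]) if len(
            probes.get(sid, [])) == 3 else "unclassifiable"
        flags = [s for _, s in sorted(learn.get(sid, []))]
        try:
            ttc = trials_to_criterion(flags) if flags else None
        except ValueError:
            ttc = None
        rows.append(dict(
            subject_id=sid, age_group=age, condition=cond, strategy=strat,
            allocentric_majority=int(strat == "allocentric"),
            classifiable=strat != "unclassifiable",
            trials_to_criterion=ttc))
    return pd.DataFrame(rows)
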