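"""On-disk formats, configuration and the end-to-end pipeline.

Trials travel as a long-format table (CSV by default, parquet optional):
one row per stream sample, with a ``stream`` column distinguishing 30 Hz
pose rows from 120 Hz gaze rows. Timestamps must be strictly increasing
within each (trial, stream); schema violations are reported with row
numbers. Every pipeline run writes a manifest recording the seed, a hash
of the configuration and the library versions, so reruns are auditable
and (for the deterministic stages) bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ARMS, CONDITIONS, build_maze
from .simulate import GAZE_COLS, POSE_COLS, TrialRecord

_META = ("subject_id", "trial_id", "age_group", "condition", "phase",
         "start_arm", "subject_height", "end_event", "stream", "t")
_PAYLOAD = ("x", "y", "z", "yaw", "lx", "ly", "lz", "rx", "ry", "rz",
            "lvalid", "rvalid")
TRIAL_COLUMNS = _META + _PAYLOAD


def trials_to_table(trials) -> pd.DataFrame:
    """Flatten TrialRecords into the long-format trial table."""
    frames = []
    for tr in trials:
        tid = f"{tr.subject_id}:{tr.trial_index:02d}"
        base = dict(subject_id=tr.subject_id, trial_id=tid,
                    age_group=tr.age_group, condition=tr.condition,
                    phase=tr.phase, start_arm=tr.start_arm,
                    subject_height=tr.subject_height,
                    end_event=tr.end_event)
        p = pd.DataFrame(tr.pose, columns=list(POSE_COLS))
        p["stream"] = "pose"
        if len(tr.gaze):
            g = pd.DataFrame(tr.gaze, columns=list(GAZE_COLS))
            g["stream"] = "gaze"
            df = pd.concat([p, g], ignore_index=True)
        else:
            df = p
        for k, v in base.items():
            df[k] = v
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for col in TRIAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out[list(TRIAL_COLUMNS)]


def table_to_trials(df: pd.DataFrame) -> list:
    """Validate a trial table and rebuild TrialRecords.

    Raises ``ValueError`` naming the offending rows for missing columns,
    non-monotone timestamps or unknown enum values.
    """
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad_cond = df[~df.condition.isin(CONDITIONS)]
    if len(bad_cond):
        raise ValueError(
            f"unknown condition at row {int(bad_cond.index[0])}: "
            f"{bad_cond.condition.iloc[0]!r}")
    bad_arm = df[~df.start_arm.isin(ARMS)]
    if len(bad_arm):
        raise ValueError(
            f"unknown start_arm at row {int(bad_arm.index[0])}")
    bad_stream = df[~df.stream.isin(("pose", "gaze"))]
    if len(bad_stream):
        raise ValueError(f"unknown stream at row {int(bad_stream.index[0])}")
    trials = []
    for tid, sub in df.groupby("trial_id", sort=False):
        for stream, ss in sub.groupby("stream", sort=False):
            t = ss.t.to_numpy()
            dec = np.nonzero(np.diff(t) <= 0)[0]
            if len(dec):
                row = int(ss.index[dec[0] + 1])
                raise ValueError(
                    f"non-increasing timestamp in trial {tid!r} stream "
                    f"{stream!r} at row {row}")
        head = sub.iloc[0]
        pose = sub[sub.stream == "pose"][["t", "x", "y", "z", "yaw"]]
        gaze = sub[sub.stream == "gaze"][list(GAZE_COLS)]
        trials.append(TrialRecord(
            subject_id=head.subject_id, age_group=head.age_group,
            condition=head.condition, phase=head.phase,
            trial_index=int(tid.rsplit(":", 1)[1]),
            start_arm=head.start_arm,
            subject_height=float(head.subject_height),
            pose=pose.to_numpy(dtype=float),
            gaze=gaze.to_numpy(dtype=float),
            end_event=head.end_event))
    return trials


def write_trials(trials, path, fmt: str = "csv") -> None:
    df = trials_to_table(trials)
    path = Path(path)
    if fmt == "csv":
        # 17 significant digits round-trips float64 exactly
        df.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))
    elif fmt == "parquet":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_trials(path, fmt: str | None = None) -> list:
    path = Path(path)
    if fmt is None:
        fmt = "parquet" if path.suffix == ".parquet" else "csv"
    if fmt == "csv":
        if path.stat().st_size == 0:
            import warnings
            warnings.warn(f"empty trial file {path}")
            return []
        df = pd.read_csv(path, float_precision="round_trip")
    elif fmt == "parquet":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if len(df) == 0:
        import warnings
        warnings.warn(f"empty trial table in {path}")
        return []
    return table_to_trials(df)


def specs_for(trials) -> dict:
    """Per-subject maze specs rebuilt from condition and height."""
    out = {}
    for tr in trials:
        if tr.subject_id not in out:
            out[tr.subject_id] = build_maze(tr.condition, tr.subject_height)
    return out


# ---------------------------------------------------------------------------
# configuration

_CONFIG_KEYS = {"mode", "seed", "out_dir", "cohort", "stages"}
_COHORT_KEYS = {"preset", "size_scale", "stream_detail", "group_sizes"}


def load_config(path) -> dict:
    """Strictly validated pipeline configuration (YAML)."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cohort = cfg.get("cohort", {}) or {}
    unknown = set(cohort) - _COHORT_KEYS
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    cfg.setdefault("mode", "simulate")
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", ["simulate", "metrics", "gaze", "stats",
                              "predict"])
    cfg["cohort"] = cohort
    return cfg


def _manifest(cfg: dict, out: Path) -> None:
    import ymaze

    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.get("seed"),
        "versions": {
            "ymaze": ymaze.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config, out_dir=None) -> Path:
    """simulate -> metrics -> gaze -> stats -> predict, writing artifacts.

    ``config`` is a path to a YAML file or an already-validated dict.
    Returns the artifact directory.
    """
    from . import gaze as gz
    from . import metrics as mx
    from . import stats as st
    from .simulate import default_config, simulate_cohort

    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir or cfg.get("out_dir", "ymaze_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages")
    cohort_cfg = cfg.get("cohort", {})

    sim_cfg = default_config(
        seed=int(cfg.get("seed", 0)),
        size_scale=float(cohort_cfg.get("size_scale", 1.0)),
        stream_detail=cohort_cfg.get("stream_detail", "full"))
    if cohort_cfg.get("group_sizes"):
        sizes = {(a, c): int(n) for (a, c), n in
                 (((k.split("/")[0], k.split("/")[1]), v)
                  for k, v in cohort_cfg["group_sizes"].items())}
        sim_cfg = dataclasses.replace(sim_cfg, group_sizes=sizes)

    sim = simulate_cohort(sim_cfg)
    trials = sim.trials
    specs = specs_for(trials)
    if "simulate" in stages:
        write_trials(trials, out / "trials.csv")
        sim.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        for cond in CONDITIONS:
            spec = build_maze(cond, 1.70)
            (out / f"maze_{cond}.yaml").write_text(spec.to_yaml())

    results: dict = {}
    if "metrics" in stages:
        mt = mx.metrics_table(trials, specs)
        mt.to_csv(out / "metrics.csv", index=False)
        ct = mx.cohort_table(trials, specs)
        ct.to_csv(out / "cohort.csv", index=False)
    if "gaze" in stages and any(len(tr.gaze) for tr in trials):
        dt = gz.dwell_table(trials, specs)
        dt.to_csv(out / "dwell.csv", index=False)
        feats = gz.altitude_features(trials, specs)
        feats.to_csv(out / "features.csv", index=False)
    if "stats" in stages:
        ct = mx.cohort_table(trials, specs)
        fit = st.fit_strategy_glm(ct)
        deltas = {}
        for pair in (("children", "young"), ("children", "older")):
            est = st.second_difference(fit, pair)
            deltas["_vs_".join(pair)] = dict(delta=est.delta, se=est.se,
                                             p=est.p_value)
        results["cell_probabilities"] = {
            f"{a}/{c}": p for (a, c), p in fit.cell_probabilities.items()}
        results["second_differences"] = deltas
        results["power_n"] = st.chisq_power_n(0.356, 2, 0.05, 0.8)
        (out / "stats.json").write_text(json.dumps(results, indent=2))
    if "predict" in stages and (out / "features.csv").exists():
        feats = pd.read_csv(out / "features.csv")
        ct = mx.cohort_table(trials, specs)
        merged = feats.merge(ct[["subject_id", "strategy", "classifiable"]],
                             on="subject_id")
        pred = {}
        lm = merged[(merged.condition == "landmark") & merged.classifiable]
        if lm.strategy.nunique() == 2 and lm.strategy.value_counts().min() >= 4:
            hv = st.holdout_validate(lm.mean_orientation_altitude,
                                     lm.strategy, seed=int(cfg.get("seed", 0)))
            lv = st.loo_validate(lm.mean_orientation_altitude, lm.strategy)
            pred["strategy"] = dict(
                holdout_correct=hv.overall_correct, holdout_p=hv.p_value,
                per_class=hv.per_class_correct, loo_correct=lv.overall_correct)
        if merged.condition.nunique() == 2:
            hv = st.holdout_validate(merged.mean_orientation_altitude,
                                     merged.condition,
                                     seed=int(cfg.get("seed", 0)))
            lv = st.loo_validate(merged.mean_orientation_altitude,
                                 merged.condition)
            pred["condition"] = dict(
                holdout_correct=hv.overall_correct, holdout_p=hv.p_value,
                per_class=hv.per_class_correct, loo_correct=lv.overall_correct)
        (out / "predict.json").write_text(json.dumps(pred, indent=2))
    _manifest(cfg, out)
    return out
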