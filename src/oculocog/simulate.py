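"""Synthetic 60 Hz gaze recordings and behavioral responses.

Generates labeled cohorts of simulated participants: raw monocular gaze
traces for the four oculomotor paradigms plus trial-level responses for the
Stroop and span tasks, with group-dependent generative parameters
(:mod:`oculocog.profiles`).  Saccades follow a minimum-jerk displacement
profile with a main-sequence duration rule (duration ~ 20 ms + 2 ms/deg of
amplitude); pursuit is the target trajectory delayed and gain-scaled plus
Poisson catch-up saccades that close the instantaneous position error;
blinks appear as invalid gaps.  Every trial retains the injected ground
truth (latencies, gains, catch-up amplitudes) so extractors can be tested
for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import paradigm
from .paradigm import (SAMPLING_RATE, GAZE_TASKS, BEHAVIOR_TASKS, Trial,
                       TaskSchedule, target_position)
from .profiles import (GroupProfile, default_profiles, draw_individual_profile)
from .behavior import run_span_task, SPAN_MAX_LENGTH, span_success_probability

DT = 1.0 / SAMPLING_RATE


@dataclass
class GazeTrial:
    """One simulated (or loaded) trial: the schedule entry plus the trace."""

    trial: Trial
    t: np.ndarray        # s, nominal 1/60 s grid
    x: np.ndarray        # deg
    y: np.ndarray        # deg
    valid: np.ndarray    # False during blinks / dropouts
    truth: dict = field(default_factory=dict)  # injected parameters, if simulated

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("sample arrays must share one length")


@dataclass
class SessionRecording:
    """All gaze and behavioral data of one (synthetic) participant."""

    participant_id: str
    group: str
    gaze: dict[str, list[GazeTrial]]
    behavior: dict[str, object]
    truth: GroupProfile | None = None


def _time_grid(duration: float) -> np.ndarray:
    n = int(np.floor(duration * SAMPLING_RATE)) + 1
    return np.arange(n) * DT


def saccade_duration(amplitude: float) -> float:
    """Main-sequence duration rule, floored at two samples."""
    return max(2 * DT, 0.02 + 0.002 * abs(amplitude))


def _min_jerk(t: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Minimum-jerk position fraction in [0, 1] for each time."""
    tau = np.clip((t - onset) / duration, 0.0, 1.0)
    return tau ** 3 * (10.0 + tau * (-15.0 + 6.0 * tau))


def _add_saccade(x: np.ndarray, y: np.ndarray, t: np.ndarray,
                 onset: float, dx: float, dy: float) -> float:
    """Superimpose a minimum-jerk displacement (dx, dy) starting at onset;
    returns the saccade offset time."""
    amp = float(np.hypot(dx, dy))
    dur = saccade_duration(amp)
    s = _min_jerk(t, onset, dur)
    x += dx * s
    y += dy * s
    return onset + dur


def _insert_blinks(valid: np.ndarray, t: np.ndarray, blink_rate: float,
                   rng: np.random.Generator) -> None:
    if blink_rate <= 0 or len(t) == 0:
        return
    duration = t[-1] - t[0]
    n_blinks = rng.poisson(blink_rate / 60.0 * duration)
    for _ in range(n_blinks):
        start = rng.uniform(t[0], t[-1])
        blen = rng.uniform(0.1, 0.2)
        valid[(t >= start) & (t < start + blen)] = False


def _positive_latency(profile: GroupProfile, rng: np.random.Generator) -> float:
    lat = rng.normal(profile.saccade_latency_mean, profile.saccade_latency_sd)
    return float(np.clip(lat, 2 * DT, 0.9))


def simulate_gaze_trial(trial: Trial, profile: GroupProfile,
                        rng: np.random.Generator) -> GazeTrial:
    """Simulate one 60 Hz gaze trace for a trial of any gaze task."""
    if trial.task not in GAZE_TASKS:
        raise ValueError(f"{trial.task!r} is not a gaze task")
    t = _time_grid(trial.duration)
    x = np.zeros_like(t)
    y = np.zeros_like(t)
    truth: dict = {}

    if trial.task == "prosaccade_antisaccade":
        cue = next(e for e in trial.events if e.kind == "step")
        cond = cue.meta["condition"]
        cue_vec = np.array([cue.position_x, cue.position_y])
        goal_vec = cue_vec if cond == "pro" else -cue_vec
        latency = _positive_latency(profile, rng)
        onset = cue.onset + latency
        gain = max(rng.normal(profile.saccade_gain_mean, profile.saccade_gain_sd), 0.05)
        truth.update(latency=latency, gain=gain, condition=cond, anti_error=False)
        if cond == "anti" and rng.random() < profile.anti_error_rate:
            # erroneous saccade toward the cue, then a correction
            truth["anti_error"] = True
            err_land = cue_vec * gain
            off = _add_saccade(x, y, t, onset, *err_land)
            corr_gain = max(rng.normal(profile.saccade_gain_mean,
                                       profile.saccade_gain_sd), 0.05)
            _add_saccade(x, y, t, off + 0.12,
                         goal_vec[0] * corr_gain - err_land[0],
                         goal_vec[1] * corr_gain - err_land[1])
        else:
            _add_saccade(x, y, t, onset, goal_vec[0] * gain, goal_vec[1] * gain)

    elif trial.task == "pursuit":
        sine = next(e for e in trial.events if e.kind == "sine")
        axis = sine.meta["axis"]
        freq, amp = sine.meta["frequency"], sine.meta["amplitude"]
        u = t - sine.onset - profile.pursuit_delay
        smooth = np.where(u > 0, profile.pursuit_gain * amp
                          * np.sin(2 * np.pi * freq * np.clip(u, 0, None)), 0.0)
        pos = smooth.copy()
        # Poisson catch-up saccades closing the instantaneous position error
        catchups: list[float] = []
        if profile.catchup_rate > 0:
            s_time = sine.onset + 0.5 + rng.exponential(1.0 / profile.catchup_rate)
            offset = 0.0
            while s_time < trial.duration - 0.1:
                tgt = amp * np.sin(2 * np.pi * freq * (s_time - sine.onset))
                i = int(np.searchsorted(t, s_time))
                err = tgt - (smooth[min(i, len(t) - 1)] + offset)
                if abs(err) > 0.3:
                    dur = saccade_duration(err)
                    pos += err * _min_jerk(t, s_time, dur)
                    offset += err
                    catchups.append(float(err))
                    s_time += dur
                s_time += rng.exponential(1.0 / profile.catchup_rate)
        truth.update(delay=profile.pursuit_delay, gain=profile.pursuit_gain,
                     catchup_amplitudes=catchups, axis=axis, frequency=freq)
        if axis == "horizontal":
            x = pos
        else:
            y = pos

    elif trial.task == "memory_guided":
        flash = next(e for e in trial.events if e.kind == "flash")
        cross_off = next(e for e in trial.events if e.kind == "cross_offset")
        responded = rng.random() >= profile.memory_fail_rate
        truth.update(responded=responded, target=flash.position_x)
        if responded:
            latency = _positive_latency(profile, rng)
            gain = max(rng.normal(profile.memory_gain_mean,
                                  profile.memory_gain_sd), 0.05)
            truth.update(latency=latency, gain=gain)
            _add_saccade(x, y, t, cross_off.onset + latency,
                         flash.position_x * gain, flash.position_y * gain)

    elif trial.task == "predictive":
        steps = [e for e in trial.events if e.kind == "step"]
        step_lat, step_amp = [], []
        prev_off = 0.0
        cur = 0.0
        for k, ev in enumerate(steps):
            # the first step cannot be anticipated: its direction is unknown
            if k > 0 and rng.random() < profile.predictive_anticipation:
                latency = -abs(rng.normal(profile.predictive_lead_mean,
                                          profile.predictive_latency_sd))
                latency = float(np.clip(latency, -0.24, -DT))
            else:
                latency = float(np.clip(
                    rng.normal(profile.saccade_latency_mean,
                               profile.predictive_latency_sd), 2 * DT, 0.45))
            onset = max(ev.onset + latency, prev_off + DT)
            gain = max(rng.normal(profile.saccade_gain_mean,
                                  profile.saccade_gain_sd), 0.05)
            land = cur + (ev.position_x - cur) * gain
            prev_off = _add_saccade(x, y, t, onset, land - cur, 0.0)
            step_lat.append(onset - ev.onset)
            step_amp.append(abs(land - cur))
            cur = land
        truth.update(step_latencies=step_lat, step_amplitudes=step_amp)

    if profile.fixation_noise_sd > 0:
        x = x + rng.normal(0.0, profile.fixation_noise_sd, len(t))
        y = y + rng.normal(0.0, profile.fixation_noise_sd, len(t))
    valid = np.ones(len(t), dtype=bool)
    _insert_blinks(valid, t, profile.blink_rate, rng)
    return GazeTrial(trial=trial, t=t, x=x, y=y, valid=valid, truth=truth)


# ---------------------------------------------------------------------------
# behavioral tasks

_SPAN_SCALE = 0.6  # logistic scale linking (ability - length) to P(correct)


def _span_responder(profile: GroupProfile, task: str,
                    rng: np.random.Generator):
    ability = profile.span_ability
    if task in ("span_bwd_vis", "span_bwd_digit"):
        ability -= profile.span_backward_deficit
    if task == "span_bwd_digit":
        ability -= profile.digit_backward_deficit
    def respond(length: int) -> bool:
        p = span_success_probability(ability, length, _SPAN_SCALE)
        return bool(rng.random() < p * (1.0 - profile.span_lapse))
    return respond


def simulate_behavior(profile: GroupProfile, rng: np.random.Generator,
                      stroop_seed: int = 0) -> dict[str, object]:
    """Trial-level responses for the four span tasks and the Stroop task."""
    out: dict[str, object] = {}
    for task in ("span_fwd_vis", "span_bwd_vis", "span_fwd_digit",
                 "span_bwd_digit"):
        max_len = SPAN_MAX_LENGTH[task]
        out[task] = run_span_task(_span_responder(profile, task, rng), max_len)
    schedule = paradigm.build_stroop_schedule(stroop_seed)
    responses = []
    for i, trial in enumerate(schedule.trials):
        incong = trial.condition == "incongruent"
        err = (profile.stroop_error_rate_incongruent if incong
               else profile.stroop_error_rate_congruent)
        rt = (profile.stroop_rt_base
              + (profile.stroop_interference if incong else 0.0)
              + abs(rng.normal(0.0, profile.stroop_rt_sd)))
        responses.append({"trial_index": i, "condition": trial.condition,
                          "correct": bool(rng.random() >= err),
                          "rt": float(rt)})
    out["stroop"] = responses
    return out


# ---------------------------------------------------------------------------
# sessions and cohorts

_SCHEDULE_BUILDERS = {
    "prosaccade_antisaccade": paradigm.build_prosaccade_schedule,
    "pursuit": paradigm.build_pursuit_schedule,
    "memory_guided": paradigm.build_memory_guided_schedule,
    "predictive": paradigm.build_predictive_schedule,
}


def simulate_session(participant_id: str, group: str, profile: GroupProfile,
                     rng: np.random.Generator,
                     schedule_seed: int | None = None) -> SessionRecording:
    """Simulate all four gaze tasks and all behavioral tasks for one person."""
    if schedule_seed is None:
        schedule_seed = int(rng.integers(0, 2**31 - 1))
    gaze: dict[str, list[GazeTrial]] = {}
    for task, builder in _SCHEDULE_BUILDERS.items():
        schedule = builder(schedule_seed)
        gaze[task] = [simulate_gaze_trial(tr, profile, rng)
                      for tr in schedule.trials]
    behavior = simulate_behavior(profile, rng, stroop_seed=schedule_seed)
    return SessionRecording(participant_id=participant_id, group=group,
                            gaze=gaze, behavior=behavior, truth=profile)


def generate_cohort(n_young: int, n_control: int, n_mci: int, seed: int,
                    profiles: dict[str, GroupProfile] | None = None,
                    individual_jitter: bool = True) -> list[SessionRecording]:
    """A labeled cohort of simulated participants, deterministic under seed.

    Default sizes (31, 57, 40) mirror a valid three-group sample of 128.
    """
    if min(n_young, n_control, n_mci) < 0:
        raise ValueError("cohort counts must be >= 0")
    profiles = dict(default_profiles(), **(profiles or {}))
    ss = np.random.SeedSequence(int(seed))
    counts = [("young", "Y", n_young), ("control", "C", n_control),
              ("mci", "M", n_mci)]
    children = ss.spawn(sum(n for _, _, n in counts))
    sessions = []
    k = 0
    for group, prefix, n in counts:
        for j in range(n):
            rng = np.random.default_rng(children[k]); k += 1
            prof = profiles[group]
            if individual_jitter:
                prof = draw_individual_profile(prof, rng)
            sessions.append(simulate_session(f"{prefix}{j + 1:03d}", group,
                                             prof, rng))
    return sessions


# ---------------------------------------------------------------------------
# on-disk gaze-CSV dialect

GAZE_COLUMNS = ["participant_id", "task", "trial_index", "condition", "t",
                "target_x", "target_y", "gaze_x", "gaze_y", "valid"]
BEHAVIOR_COLUMNS = ["participant_id", "task", "trial_index",
                    "condition_or_length", "correct", "rt"]


def gaze_frame(session: SessionRecording) -> pd.DataFrame:
    """All gaze samples of a session as one tidy DataFrame."""
    parts = []
    for task, trials in session.gaze.items():
        for i, gt in enumerate(trials):
            tx, ty = target_position(gt.trial, np.clip(gt.t, 0, gt.trial.duration))
            parts.append(pd.DataFrame({
                "participant_id": session.participant_id, "task": task,
                "trial_index": i, "condition": gt.trial.condition,
                "t": gt.t, "target_x": tx, "target_y": ty,
                "gaze_x": gt.x, "gaze_y": gt.y,
                "valid": gt.valid.astype(int)}))
    return pd.concat(parts, ignore_index=True)[GAZE_COLUMNS]


def behavior_frame(session: SessionRecording) -> pd.DataFrame:
    rows = []
    for task in ("span_fwd_vis", "span_bwd_vis", "span_fwd_digit",
                 "span_bwd_digit"):
        run = session.behavior[task]
        for i, (length, correct) in enumerate(run.trials):
            rows.append((session.participant_id, task, i, length,
                         int(correct), np.nan))
    for resp in session.behavior["stroop"]:
        rows.append((session.participant_id, "stroop", resp["trial_index"],
                     resp["condition"], int(resp["correct"]), resp["rt"]))
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)


def write_cohort(sessions: list[SessionRecording], outdir: str | Path) -> None:
    """One gaze CSV per participant per task, one behavior CSV per
    participant, plus a JSON manifest."""
    outdir = Path(outdir)
    (outdir / "gaze").mkdir(parents=True, exist_ok=True)
    (outdir / "behavior").mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in sessions:
        gf = gaze_frame(s)
        for task, sub in gf.groupby("task", sort=False):
            sub.to_csv(outdir / "gaze" / f"{s.participant_id}_{task}.csv",
                       index=False, float_format="%.5f")
        behavior_frame(s).to_csv(
            outdir / "behavior" / f"{s.participant_id}.csv",
            index=False, float_format="%.5f")
        manifest.append({"participant_id": s.participant_id, "group": s.group})
    (outdir / "manifest.json").write_text(
        json.dumps({"participants": manifest}, indent=1, sort_keys=True))


def _session_from_frames(pid: str, group: str, gaze_df: pd.DataFrame,
                         beh_df: pd.DataFrame) -> SessionRecording:
    from .behavior import SpanRun
    gaze: dict[str, list[GazeTrial]] = {}
    for task, tdf in gaze_df.groupby("task", sort=False):
        trials = []
        for idx, trdf in tdf.groupby("trial_index", sort=True):
            trdf = trdf.sort_values("t")
            # reconstruct a minimal Trial from the stored target trajectory
            trials.append(_reconstruct_gaze_trial(task, trdf))
        gaze[task] = trials
    behavior: dict[str, object] = {}
    for task, tdf in beh_df.groupby("task", sort=False):
        tdf = tdf.sort_values("trial_index")
        if task == "stroop":
            behavior[task] = [
                {"trial_index": int(r.trial_index),
                 "condition": r.condition_or_length,
                 "correct": bool(int(r.correct)), "rt": float(r.rt)}
                for r in tdf.itertuples()]
        else:
            pairs = [(int(r.condition_or_length), bool(int(r.correct)))
                     for r in tdf.itertuples()]
            behavior[task] = SpanRun(task=task, trials=pairs,
                                     terminated_early=_ended_on_errors(pairs))
    return SessionRecording(participant_id=pid, group=group, gaze=gaze,
                            behavior=behavior, truth=None)


def _ended_on_errors(pairs) -> bool:
    return len(pairs) >= 3 and all(not c for _, c in pairs[-3:])


def _reconstruct_gaze_trial(task: str, trdf: pd.DataFrame) -> GazeTrial:
    """Rebuild schedule events from the stored target trajectory so loaded
    recordings flow through the same extractor as simulated ones."""
    t = trdf["t"].to_numpy(float)
    tx = trdf["target_x"].to_numpy(float)
    ty = trdf["target_y"].to_numpy(float)
    cond = str(trdf["condition"].iloc[0])
    duration = float(t[-1])
    events = [paradigm.TargetEvent(0.0, 0.0, 0.0, "fixation")]
    if task == "prosaccade_antisaccade":
        moved = np.flatnonzero((np.abs(tx) > 1e-6) | (np.abs(ty) > 1e-6))
        i = moved[0]
        c = cond.split("_")[0]
        events.append(paradigm.TargetEvent(float(t[i]), float(tx[i]),
                                           float(ty[i]), "step",
                                           meta={"role": "cue", "condition": c}))
        timeout = 1.0
    elif task == "pursuit":
        axis = "horizontal" if cond.startswith("h") else "vertical"
        freq = float(cond.split("_")[1])
        sig = tx if axis == "horizontal" else ty
        moved = np.flatnonzero(np.abs(sig) > 1e-6)
        onset = float(t[max(moved[0] - 1, 0)]) if len(moved) else 0.0
        events.append(paradigm.TargetEvent(
            onset, 0.0, 0.0, "sine", duration=duration - onset,
            meta={"axis": axis, "frequency": freq,
                  "amplitude": paradigm.PURSUIT_AMPLITUDE}))
        timeout = None
    elif task == "memory_guided":
        moved = np.flatnonzero(np.abs(tx) > 1e-6)
        i0, i1 = moved[0], moved[-1]
        events.append(paradigm.TargetEvent(
            float(t[i0]), float(tx[i0]), 0.0, "flash",
            duration=float(t[i1] - t[i0]) + DT,
            meta={"eccentricity": abs(float(tx[i0]))}))
        events.append(paradigm.TargetEvent(duration - 1.0, 0.0, 0.0,
                                           "cross_offset"))
        timeout = 1.0
    elif task == "predictive":
        change = np.flatnonzero(np.abs(np.diff(tx)) > 1e-6) + 1
        for k, i in enumerate(change):
            events.append(paradigm.TargetEvent(float(t[i]), float(tx[i]), 0.0,
                                               "step", meta={"step_index": k}))
        timeout = None
    else:
        raise ValueError(f"unknown gaze task {task!r}")
    trial = paradigm.Trial(task=task, condition=cond, events=tuple(events),
                           timeout=timeout, duration=duration)
    return GazeTrial(trial=trial, t=t,
                     x=trdf["gaze_x"].to_numpy(float),
                     y=trdf["gaze_y"].to_numpy(float),
                     valid=trdf["valid"].to_numpy(int).astype(bool))


def read_cohort(directory: str | Path) -> list[SessionRecording]:
    """Load a cohort written by :func:`write_cohort` (or any recordings in
    the same gaze-CSV dialect)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    sessions = []
    for entry in manifest["participants"]:
        pid, group = entry["participant_id"], entry["group"]
        gaze_parts = [pd.read_csv(p)
                      for p in sorted((directory / "gaze").glob(f"{pid}_*.csv"))]
        gaze_df = pd.concat(gaze_parts, ignore_index=True)
        beh_df = pd.read_csv(directory / "behavior" / f"{pid}.csv")
        sessions.append(_session_from_frames(pid, group, gaze_df, beh_df))
    return sessions
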