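"""Deterministic, seedable schedules for the oculomotor and cognitive paradigms.

Four gaze tasks (pro/anti-saccade, smooth pursuit, memory-guided saccade,
predictive saccade) and the Stroop task are encoded as explicit trial
schedules with exact geometry (degrees of visual angle, screen-centre
origin) and timing (seconds).  The same schedule objects drive both the
synthetic gaze simulator and the feature extractor, so target trajectories
are defined once, in closed form, via :func:`target_position`.

Span-task schedules are adaptive (the next list length depends on the
response) and are therefore built on the fly by :mod:`oculocog.behavior`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

SAMPLING_RATE = 60.0  # Hz, monocular gaze

GAZE_TASKS = ("prosaccade_antisaccade", "pursuit", "memory_guided", "predictive")
BEHAVIOR_TASKS = (
    "span_fwd_vis", "span_bwd_vis", "span_fwd_digit", "span_bwd_digit", "stroop",
)

# geometry (degrees of visual angle)
PROANTI_ECCENTRICITY = 9.7
PROANTI_POSITIONS = (
    (PROANTI_ECCENTRICITY, 0.0), (-PROANTI_ECCENTRICITY, 0.0),
    (0.0, PROANTI_ECCENTRICITY), (0.0, -PROANTI_ECCENTRICITY),
)
PURSUIT_AMPLITUDE = 10.0          # half-amplitude either side of centre
PURSUIT_FREQUENCIES = (0.25, 0.4)  # Hz
PURSUIT_TRIAL_DURATION = 10.0      # s of tracking per trial
MEMORY_ECCENTRICITIES = (5.0, 10.0, 15.0)
PREDICTIVE_AMPLITUDE = 10.0        # target alternates between +/-10 deg
PREDICTIVE_RATES = (0.66, 0.8, 1.0, 1.33, 2.0)      # Hz
PREDICTIVE_ISI = {0.66: 1.5, 0.8: 1.25, 1.0: 1.0, 1.33: 0.75, 2.0: 0.5}
PREDICTIVE_N_STEPS = 12

STROOP_WORDS = ("red", "green", "blue")
STROOP_INKS = ("red", "green", "blue")


@dataclass(frozen=True)
class TargetEvent:
    """One timed target occurrence within a trial."""

    onset: float          # s from trial start
    position_x: float     # deg, right positive
    position_y: float     # deg, up positive
    kind: str             # fixation | step | sine | flash | cross_offset | stroop_stimulus
    duration: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("event onset must be >= 0")


@dataclass(frozen=True)
class Trial:
    """One formal trial: task, condition label and its ordered target events."""

    task: str
    condition: str
    events: tuple[TargetEvent, ...]
    timeout: float | None = None
    block: int = 0
    duration: float = 0.0

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("trial events must be ordered by onset")


@dataclass(frozen=True)
class TaskSchedule:
    task: str
    trials: tuple[Trial, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_json(self) -> str:
        return json.dumps(
            {"task": self.task, "seed": self.seed,
             "trials": [asdict(t) for t in self.trials]},
            sort_keys=True)


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


def build_prosaccade_schedule(seed: int) -> TaskSchedule:
    """64 formal pro/anti trials: 4 positions x {pro, anti} x 8 repetitions.

    Fixation lasts U[1.0, 1.5] s, then one peripheral circle changes colour;
    the response window (timeout) is 1.0 s after target onset.
    """
    rng = _rng(seed, 1)
    cells = [(pos, cond) for cond in ("pro", "anti")
             for pos in PROANTI_POSITIONS for _ in range(8)]
    order = rng.permutation(len(cells))
    trials = []
    for i, idx in enumerate(order):
        (px, py), cond = cells[idx]
        fix_dur = rng.uniform(1.0, 1.5)
        events = (
            TargetEvent(0.0, 0.0, 0.0, "fixation", duration=fix_dur),
            TargetEvent(fix_dur, px, py, "step",
                        meta={"role": "cue", "condition": cond}),
        )
        trials.append(Trial(
            task="prosaccade_antisaccade",
            condition=f"{cond}_{px:+.1f}_{py:+.1f}",
            events=events, timeout=1.0, block=i // 32,
            duration=fix_dur + 1.0))
    return TaskSchedule("prosaccade_antisaccade", tuple(trials), int(seed))


def build_pursuit_schedule(seed: int) -> TaskSchedule:
    """8 pursuit trials: {horizontal, vertical} x {0.25, 0.4} Hz x 2 reps.

    The sinusoid starts at centre with amplitude 10 deg either side (total
    excursion 20 deg); 1.2 s of fixation precedes target motion.
    """
    rng = _rng(seed, 2)
    cells = [(axis, f) for axis in ("horizontal", "vertical")
             for f in PURSUIT_FREQUENCIES for _ in range(2)]
    order = rng.permutation(len(cells))
    trials = []
    fix_dur = 1.2
    for i, idx in enumerate(order):
        axis, freq = cells[idx]
        events = (
            TargetEvent(0.0, 0.0, 0.0, "fixation", duration=fix_dur),
            TargetEvent(fix_dur, 0.0, 0.0, "sine",
                        duration=PURSUIT_TRIAL_DURATION,
                        meta={"axis": axis, "frequency": freq,
                              "amplitude": PURSUIT_AMPLITUDE}),
        )
        trials.append(Trial(
            task="pursuit", condition=f"{axis[0]}_{freq}",
            events=events, timeout=None, block=0,
            duration=fix_dur + PURSUIT_TRIAL_DURATION))
    return TaskSchedule("pursuit", tuple(trials), int(seed))


def build_memory_guided_schedule(seed: int) -> TaskSchedule:
    """60 memory-guided trials: 6 locations (+/-5, +/-10, +/-15 deg) x 10 reps.

    100 ms flash, U[4.5, 5.0] s delay with central cross, then cross offset
    opens a 1.0 s response window on a blank screen.
    """
    rng = _rng(seed, 3)
    locations = [s * e for e in MEMORY_ECCENTRICITIES for s in (1.0, -1.0)]
    cells = [loc for loc in locations for _ in range(10)]
    order = rng.permutation(len(cells))
    trials = []
    for i, idx in enumerate(order):
        loc = cells[idx]
        fix_dur = rng.uniform(1.0, 1.5)
        delay = rng.uniform(4.5, 5.0)
        flash_on = fix_dur
        cross_off = flash_on + 0.1 + delay
        events = (
            TargetEvent(0.0, 0.0, 0.0, "fixation", duration=fix_dur),
            TargetEvent(flash_on, loc, 0.0, "flash", duration=0.1,
                        meta={"eccentricity": abs(loc)}),
            TargetEvent(cross_off, 0.0, 0.0, "cross_offset"),
        )
        trials.append(Trial(
            task="memory_guided", condition=f"{loc:+.0f}",
            events=events, timeout=1.0, block=i // 30,
            duration=cross_off + 1.0))
    return TaskSchedule("memory_guided", tuple(trials), int(seed))


def build_predictive_schedule(seed: int) -> TaskSchedule:
    """25 predictive trials: 5 alternation rates x 5 repetitions, 12 steps each.

    The target steps between +/-10 deg horizontally at a fixed inter-step
    interval (1.5/1.25/1.0/0.75/0.5 s); the first step direction is random.
    """
    rng = _rng(seed, 4)
    cells = [r for r in PREDICTIVE_RATES for _ in range(5)]
    order = rng.permutation(len(cells))
    trials = []
    for i, idx in enumerate(order):
        rate = cells[idx]
        isi = PREDICTIVE_ISI[rate]
        fix_dur = rng.uniform(1.0, 1.5)
        first_sign = 1.0 if rng.random() < 0.5 else -1.0
        events = [TargetEvent(0.0, 0.0, 0.0, "fixation", duration=fix_dur)]
        for k in range(PREDICTIVE_N_STEPS):
            sign = first_sign * (1.0 if k % 2 == 0 else -1.0)
            events.append(TargetEvent(
                fix_dur + k * isi, sign * PREDICTIVE_AMPLITUDE, 0.0, "step",
                meta={"step_index": k}))
        trials.append(Trial(
            task="predictive", condition=f"{rate}Hz",
            events=tuple(events), timeout=None, block=i // 5,
            duration=fix_dur + PREDICTIVE_N_STEPS * isi))
    return TaskSchedule("predictive", tuple(trials), int(seed))


def build_stroop_schedule(seed: int) -> TaskSchedule:
    """90 Stroop trials: 3 words x 3 ink colours, each level 10 times, shuffled."""
    rng = _rng(seed, 5)
    cells = [(w, ink) for w in STROOP_WORDS for ink in STROOP_INKS
             for _ in range(10)]
    order = rng.permutation(len(cells))
    trials = []
    for i, idx in enumerate(order):
        word, ink = cells[idx]
        cong = "congruent" if word == ink else "incongruent"
        events = (
            TargetEvent(0.0, 0.0, 0.0, "fixation", duration=0.5),
            TargetEvent(0.5, 0.0, 0.0, "stroop_stimulus",
                        meta={"word": word, "ink": ink}),
        )
        trials.append(Trial(
            task="stroop", condition=cong, events=events,
            timeout=None, block=0, duration=3.0))
    return TaskSchedule("stroop", tuple(trials), int(seed))


_BUILDERS = {
    "prosaccade_antisaccade": build_prosaccade_schedule,
    "pursuit": build_pursuit_schedule,
    "memory_guided": build_memory_guided_schedule,
    "predictive": build_predictive_schedule,
    "stroop": build_stroop_schedule,
}


def build_schedule(task: str, seed: int) -> TaskSchedule:
    try:
        return _BUILDERS[task](seed)
    except KeyError:
        raise ValueError(f"unknown task {task!r}; known: {sorted(_BUILDERS)}")


def target_position(trial: Trial, t) -> tuple:
    """Closed-form target position (deg) at time ``t`` within the trial.

    Piecewise constant for step tasks (right-continuous at step onsets),
    ``A sin(2 pi f (t - t0))`` along the motion axis for pursuit.  Accepts a
    scalar or an array of times; raises for times outside [0, duration].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > trial.duration + 1e-9):
        raise ValueError("time outside trial duration")
    x = np.zeros_like(t_arr)
    y = np.zeros_like(t_arr)
    for ev in trial.events:
        if ev.kind == "sine":
            on = t_arr >= ev.onset - 1e-12
            tau = np.clip(t_arr - ev.onset, 0.0, ev.duration)
            disp = ev.meta["amplitude"] * np.sin(2 * np.pi * ev.meta["frequency"] * tau)
            if ev.meta["axis"] == "horizontal":
                x = np.where(on, disp, x)
                y = np.where(on, 0.0, y)
            else:
                x = np.where(on, 0.0, x)
                y = np.where(on, disp, y)
        elif ev.kind == "flash":
            on = (t_arr >= ev.onset - 1e-12) & (t_arr < ev.onset + ev.duration)
            x = np.where(on, ev.position_x, x)
            y = np.where(on, ev.position_y, y)
        elif ev.kind in ("step", "fixation", "stroop_stimulus"):
            on = t_arr >= ev.onset - 1e-12
            x = np.where(on, ev.position_x, x)
            y = np.where(on, ev.position_y, y)
        # cross_offset carries no position change (screen goes blank)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(x), float(y)
    return x, y


def trial_cue(trial: Trial) -> TargetEvent:
    """The response-defining event of a step-task trial (cue / flash)."""
    for ev in trial.events:
        if ev.kind in ("step", "flash") and ev.meta.get("role", "cue"):
            return ev
    raise ValueError("trial has no cue event")
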