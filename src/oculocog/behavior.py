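"""Adaptive span-task logic and behavioral feature scoring.

The working-memory span tasks (forward/backward visuospatial and digit
span) start at list length 3; a correct trial increments the length, an
error repeats it, and three consecutive errors terminate the run.  One
point is awarded per correct trial.  The Stroop task is scored per
congruency condition: accuracy over all trials, mean reaction time over
correct trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SPAN_TASKS = ("span_fwd_vis", "span_bwd_vis", "span_fwd_digit",
              "span_bwd_digit")
# conventional ceilings: 8 grid locations for the visuospatial variant,
# 9 digits for the auditory one
SPAN_MAX_LENGTH = {"span_fwd_vis": 8, "span_bwd_vis": 8,
                   "span_fwd_digit": 9, "span_bwd_digit": 9}
SPAN_START_LENGTH = 3

BEHAVIOR_FEATURE_NAMES = [
    "beh_fwd_visuospatial", "beh_bwd_visuospatial",
    "beh_fwd_digit", "beh_bwd_digit",
    "beh_stroop_congruent_acc", "beh_stroop_incongruent_acc",
    "beh_stroop_congruent_rt", "beh_stroop_incongruent_rt",
]

_SPAN_FEATURE_OF_TASK = {
    "span_fwd_vis": "beh_fwd_visuospatial",
    "span_bwd_vis": "beh_bwd_visuospatial",
    "span_fwd_digit": "beh_fwd_digit",
    "span_bwd_digit": "beh_bwd_digit",
}


@dataclass
class SpanRun:
    """The trial record of one adaptive span run."""

    task: str
    trials: list[tuple[int, bool]]   # (list length, correct)
    terminated_early: bool           # stopped on 3 consecutive errors


def span_success_probability(ability: float, length: int,
                             scale: float = 0.6) -> float:
    """Logistic link between span ability and single-trial success."""
    return float(1.0 / (1.0 + np.exp(-(ability - length) / scale)))


def run_span_task(responder, max_length: int,
                  task: str = "span") -> SpanRun:
    """Run the adaptive schedule against a per-trial correctness source.

    ``responder(length) -> bool`` supplies each trial's outcome.  Lengths
    start at 3 and never decrease; an error repeats the current length and
    three consecutive errors end the run; a correct trial at ``max_length``
    also ends it.
    """
    if max_length < SPAN_START_LENGTH:
        raise ValueError("max_length must be >= 3")
    trials: list[tuple[int, bool]] = []
    length = SPAN_START_LENGTH
    consecutive_errors = 0
    terminated_early = False
    while True:
        correct = bool(responder(length))
        trials.append((length, correct))
        if correct:
            consecutive_errors = 0
            if length == max_length:
                break
            length += 1
        else:
            consecutive_errors += 1
            if consecutive_errors == 3:
                terminated_early = True
                break
    return SpanRun(task=task, trials=trials, terminated_early=terminated_early)


def score_span(run: SpanRun) -> int:
    """One point per correct trial."""
    return sum(1 for _, correct in run.trials if correct)


def score_stroop(responses) -> dict[str, float]:
    """Accuracy and correct-trial mean RT per congruency condition."""
    out = {}
    for cond in ("congruent", "incongruent"):
        sub = [r for r in responses if r["condition"] == cond]
        if not sub:
            raise ValueError(f"no {cond} trials in Stroop record")
        correct = [r for r in sub if r["correct"]]
        out[f"{cond}_accuracy"] = len(correct) / len(sub)
        out[f"{cond}_rt"] = (float(np.mean([r["rt"] for r in correct]))
                             if correct else float("nan"))
    return out


def assemble_behavior_features(session) -> dict[str, float]:
    """The 8 behavioral features, canonical order, from one session."""
    missing = [t for t in (*SPAN_TASKS, "stroop") if t not in session.behavior]
    if missing:
        raise ValueError(f"session {session.participant_id} lacks behavioral "
                         f"tasks: {missing}")
    feats: dict[str, float] = {}
    for task in SPAN_TASKS:
        feats[_SPAN_FEATURE_OF_TASK[task]] = float(
            score_span(session.behavior[task]))
    s = score_stroop(session.behavior["stroop"])
    feats["beh_stroop_congruent_acc"] = s["congruent_accuracy"]
    feats["beh_stroop_incongruent_acc"] = s["incongruent_accuracy"]
    feats["beh_stroop_congruent_rt"] = s["congruent_rt"]
    feats["beh_stroop_incongruent_rt"] = s["incongruent_rt"]
    return {name: feats[name] for name in BEHAVIOR_FEATURE_NAMES}
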