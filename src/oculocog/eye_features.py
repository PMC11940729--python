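"""The 31 per-participant eye-movement features.

Ten from the pro/anti-saccade task (accuracy, latency, gain per condition
and their means, plus fixation dispersion), twelve from smooth pursuit
(positional-error variance and gaze-target delay per axis x frequency,
their means, saccade compensation, fixation dispersion), five from the
memory-guided task (gain per eccentricity and mean, dispersion) and four
from the predictive task (latency-variance, mean latency, mean gain,
dispersion).

Definitions used here:

* latency: first response saccade onset minus target onset (negative for
  anticipatory predictive saccades);
* gain: saccade displacement projected on the instructed axis divided by
  the target eccentricity (20 deg full step for the predictive task);
* pursuit delay: lag in [0, 0.5] s maximising the cross-correlation of the
  de-saccaded gaze with the target along the motion axis (1-sample grid);
* pursuit variance: variance (deg^2) of the delay-compensated positional
  error along the motion axis;
* saccade compensation: summed catch-up amplitude along the motion axis
  over the target path length (dimensionless);
* fixation dispersion: RMS distance of fixation samples from their
  centroid (deg).
"""

from __future__ import annotations

import numpy as np

from .paradigm import (SAMPLING_RATE, PROANTI_ECCENTRICITY,
                       PURSUIT_FREQUENCIES)
from . import events as ev
from .events import preprocess, detect_saccades, rms_dispersion

DT = 1.0 / SAMPLING_RATE
PRIMARY_SACCADE_MIN_AMPLITUDE = 2.0   # deg; below this it is fixational noise
PURSUIT_MAX_DELAY = 0.5               # s
PREDICTIVE_WINDOW = (-0.25, 0.5)      # s around each step
PREDICTIVE_STEP_SIZE = 20.0           # deg, full alternation amplitude

EYE_FEATURE_NAMES = [
    # pro/anti (10)
    "pa_fixation_dispersion", "pa_mean_accuracy", "pa_pro_accuracy",
    "pa_anti_accuracy", "pa_mean_latency", "pa_pro_latency",
    "pa_anti_latency", "pa_mean_gain", "pa_pro_gain", "pa_anti_gain",
    # pursuit (12)
    "sp_fixation_dispersion", "sp_saccade_compensation", "sp_mean_variance",
    "sp_variance_v_025", "sp_variance_v_04", "sp_variance_h_025",
    "sp_variance_h_04", "sp_mean_delay", "sp_delay_v_025", "sp_delay_v_04",
    "sp_delay_h_025", "sp_delay_h_04",
    # memory-guided (5)
    "mg_fixation_dispersion", "mg_mean_gain", "mg_gain_5", "mg_gain_10",
    "mg_gain_15",
    # predictive (4)
    "ps_fixation_dispersion", "ps_mean_variance", "ps_mean_latency",
    "ps_mean_gain",
]

TASK_FEATURE_BLOCKS = {
    "prosaccade_antisaccade": EYE_FEATURE_NAMES[0:10],
    "pursuit": EYE_FEATURE_NAMES[10:22],
    "memory_guided": EYE_FEATURE_NAMES[22:27],
    "predictive": EYE_FEATURE_NAMES[27:31],
}


def _prepare(gaze_trials):
    """Preprocess + detect saccades for each trial; None for unusable trials."""
    out = []
    for gt in gaze_trials:
        trace = preprocess(gt)
        if trace.unusable:
            out.append((gt, None, None))
        else:
            out.append((gt, trace, detect_saccades(trace)))
    return out


def _nanmean(values) -> float:
    arr = np.asarray([v for v in values if v is not None], float)
    arr = arr[~np.isnan(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def _fixation_dispersion(trace, saccades, t_lo, t_hi) -> float:
    """Dispersion of non-saccade, non-excluded samples in [t_lo, t_hi)."""
    mask = (trace.t >= t_lo) & (trace.t < t_hi) & ~trace.excluded_mask
    for s in saccades:
        mask[s.onset_index:s.offset_index + 1] = False
    if mask.sum() < 3:
        return float("nan")
    return rms_dispersion(trace.x[mask], trace.y[mask])


# ---------------------------------------------------------------------------
# pro/anti saccades


def prosaccade_antisaccade_features(gaze_trials) -> dict[str, float]:
    per_cond = {"pro": {"n": 0, "correct": 0, "lat": [], "gain": []},
                "anti": {"n": 0, "correct": 0, "lat": [], "gain": []}}
    dispersions = []
    for gt, trace, saccades in _prepare(gaze_trials):
        if trace is None:
            continue
        cue = next(e for e in gt.trial.events if e.kind == "step")
        cond = cue.meta["condition"]
        cue_vec = np.array([cue.position_x, cue.position_y])
        goal = cue_vec if cond == "pro" else -cue_vec
        goal_unit = goal / np.linalg.norm(goal)
        dispersions.append(_fixation_dispersion(trace, saccades, 0.0,
                                                cue.onset))
        bucket = per_cond[cond]
        bucket["n"] += 1
        primary = next(
            (s for s in saccades
             if s.onset > cue.onset
             and s.amplitude >= PRIMARY_SACCADE_MIN_AMPLITUDE), None)
        if primary is None or primary.onset > cue.onset + (gt.trial.timeout or 1.0):
            continue
        disp = np.asarray(primary.displacement)
        if float(disp @ goal_unit) > 0:
            bucket["correct"] += 1
            bucket["lat"].append(primary.onset - cue.onset)
            bucket["gain"].append(abs(float(disp @ goal_unit))
                                  / PROANTI_ECCENTRICITY)
    feats = {"pa_fixation_dispersion": _nanmean(dispersions)}
    for cond in ("pro", "anti"):
        b = per_cond[cond]
        feats[f"pa_{cond}_accuracy"] = (b["correct"] / b["n"] if b["n"]
                                        else float("nan"))
        feats[f"pa_{cond}_latency"] = _nanmean(b["lat"])
        feats[f"pa_{cond}_gain"] = _nanmean(b["gain"])
    for stem in ("accuracy", "latency", "gain"):
        feats[f"pa_mean_{stem}"] = (feats[f"pa_pro_{stem}"]
                                    + feats[f"pa_anti_{stem}"]) / 2.0
    order = TASK_FEATURE_BLOCKS["prosaccade_antisaccade"]
    return {k: feats[k] for k in order}


# ---------------------------------------------------------------------------
# smooth pursuit


def _desaccade(signal: np.ndarray, trace, saccades) -> np.ndarray:
    """Replace saccade intervals (and exclusions) by linear interpolation."""
    out = signal.astype(float).copy()
    bad = trace.excluded_mask.copy()
    for s in saccades:
        bad[max(s.onset_index - 1, 0):s.offset_index + 2] = True
    if bad.all():
        return out
    idx = np.arange(len(out))
    out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def estimate_pursuit_delay(gaze: np.ndarray, target: np.ndarray,
                           max_lag: int) -> int:
    """Lag (samples, >= 0) maximising the centred cross-correlation."""
    best_lag, best_r = 0, -np.inf
    n = len(gaze)
    for lag in range(max_lag + 1):
        g = gaze[lag:]
        tg = target[:n - lag]
        gc = g - g.mean()
        tc = tg - tg.mean()
        denom = np.sqrt((gc ** 2).sum() * (tc ** 2).sum())
        r = (gc @ tc) / denom if denom > 0 else 0.0
        if r > best_r:
            best_r, best_lag = r, lag
    return best_lag


def pursuit_features(gaze_trials) -> dict[str, float]:
    per_cond: dict[str, dict[str, list]] = {}
    compensations, dispersions = [], []
    max_lag = int(round(PURSUIT_MAX_DELAY * SAMPLING_RATE))
    for gt, trace, saccades in _prepare(gaze_trials):
        if trace is None:
            continue
        sine = next(e for e in gt.trial.events if e.kind == "sine")
        axis, freq = sine.meta["axis"], sine.meta["frequency"]
        amp = sine.meta["amplitude"]
        dispersions.append(_fixation_dispersion(trace, saccades, 0.0,
                                                sine.onset))
        sel = trace.t >= sine.onset
        g_raw = (trace.x if axis == "horizontal" else trace.y)
        g = _desaccade(g_raw, trace, saccades)[sel]
        tgt = amp * np.sin(2 * np.pi * freq * (trace.t[sel] - sine.onset))
        lag = estimate_pursuit_delay(g, tgt, max_lag)
        err = g[lag:] - tgt[:len(tgt) - lag if lag else None]
        keep = ~trace.excluded_mask[sel][lag:]
        variance = float(np.var(err[keep])) if keep.sum() > 2 else float("nan")
        # catch-up saccades: detected events during target motion
        catch = [s for s in saccades if s.onset >= sine.onset + 0.2]
        axis_idx = 0 if axis == "horizontal" else 1
        summed = sum(abs(s.amplitude * s.direction[axis_idx]) for s in catch)
        path = float(np.abs(np.diff(tgt)).sum())
        compensations.append(summed / path if path > 0 else float("nan"))
        cond = per_cond.setdefault(
            f"{axis[0]}_{'025' if freq == 0.25 else '04'}",
            {"variance": [], "delay": []})
        cond["variance"].append(variance)
        cond["delay"].append(lag * DT)
    feats: dict[str, float] = {
        "sp_fixation_dispersion": _nanmean(dispersions),
        "sp_saccade_compensation": _nanmean(compensations),
    }
    all_var, all_delay = [], []
    for axis_letter in ("v", "h"):
        for ftag in ("025", "04"):
            c = per_cond.get(f"{axis_letter}_{ftag}", {"variance": [],
                                                       "delay": []})
            feats[f"sp_variance_{axis_letter}_{ftag}"] = _nanmean(c["variance"])
            feats[f"sp_delay_{axis_letter}_{ftag}"] = _nanmean(c["delay"])
            all_var.extend(c["variance"])
            all_delay.extend(c["delay"])
    feats["sp_mean_variance"] = _nanmean(all_var)
    feats["sp_mean_delay"] = _nanmean(all_delay)
    order = TASK_FEATURE_BLOCKS["pursuit"]
    return {k: feats[k] for k in order}


# ---------------------------------------------------------------------------
# memory-guided saccades


def memory_guided_features(gaze_trials) -> dict[str, float]:
    gains = {5.0: [], 10.0: [], 15.0: []}
    dispersions = []
    for gt, trace, saccades in _prepare(gaze_trials):
        if trace is None:
            continue
        flash = next(e for e in gt.trial.events if e.kind == "flash")
        cross_off = next(e for e in gt.trial.events if e.kind == "cross_offset")
        ecc = flash.meta["eccentricity"]
        sign = np.sign(flash.position_x)
        dispersions.append(_fixation_dispersion(
            trace, saccades, flash.onset + (flash.duration or 0.1),
            cross_off.onset))
        window_end = cross_off.onset + (gt.trial.timeout or 1.0)
        response = next(
            (s for s in saccades
             if cross_off.onset < s.onset <= window_end
             and s.amplitude >= PRIMARY_SACCADE_MIN_AMPLITUDE), None)
        if response is None:
            continue
        gains[ecc].append(float(sign * response.displacement[0]) / ecc)
    feats = {"mg_fixation_dispersion": _nanmean(dispersions)}
    for ecc, tag in ((5.0, "5"), (10.0, "10"), (15.0, "15")):
        feats[f"mg_gain_{tag}"] = _nanmean(gains[ecc])
    feats["mg_mean_gain"] = _nanmean(
        [feats["mg_gain_5"], feats["mg_gain_10"], feats["mg_gain_15"]])
    order = TASK_FEATURE_BLOCKS["memory_guided"]
    return {k: feats[k] for k in order}


# ---------------------------------------------------------------------------
# predictive saccades


def predictive_features(gaze_trials) -> dict[str, float]:
    latencies, gains, dispersions = [], [], []
    for gt, trace, saccades in _prepare(gaze_trials):
        if trace is None:
            continue
        steps = [e for e in gt.trial.events if e.kind == "step"]
        dispersions.append(_fixation_dispersion(trace, saccades, 0.0,
                                                steps[0].onset))
        used: set[int] = set()
        prev_x = 0.0
        for k, step in enumerate(steps):
            direction = np.sign(step.position_x - prev_x)
            prev_x = step.position_x
            if k == 0:
                continue  # first step is unpredictable
            lo, hi = (step.onset + PREDICTIVE_WINDOW[0],
                      step.onset + PREDICTIVE_WINDOW[1])
            for si, s in enumerate(saccades):
                if si in used or not (lo <= s.onset <= hi):
                    continue
                if s.amplitude < PRIMARY_SACCADE_MIN_AMPLITUDE:
                    continue
                if np.sign(s.direction[0]) != direction:
                    continue
                used.add(si)
                latencies.append(s.onset - step.onset)
                gains.append(s.amplitude / PREDICTIVE_STEP_SIZE)
                break
    feats = {
        "ps_fixation_dispersion": _nanmean(dispersions),
        "ps_mean_variance": (float(np.var(latencies)) if len(latencies) > 1
                             else float("nan")),
        "ps_mean_latency": _nanmean(latencies),
        "ps_mean_gain": _nanmean(gains),
    }
    order = TASK_FEATURE_BLOCKS["predictive"]
    return {k: feats[k] for k in order}


# ---------------------------------------------------------------------------

_EXTRACTORS = {
    "prosaccade_antisaccade": prosaccade_antisaccade_features,
    "pursuit": pursuit_features,
    "memory_guided": memory_guided_features,
    "predictive": predictive_features,
}


def assemble_eye_features(session) -> dict[str, float]:
    """All 31 eye features of one session, canonical order."""
    missing = [t for t in _EXTRACTORS if t not in session.gaze]
    if missing:
        raise ValueError(f"session {session.participant_id} lacks gaze "
                         f"tasks: {missing}")
    feats: dict[str, float] = {}
    for task, fn in _EXTRACTORS.items():
        feats.update(fn(session.gaze[task]))
    return {name: feats[name] for name in EYE_FEATURE_NAMES}
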