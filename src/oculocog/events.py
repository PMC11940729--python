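"""Gaze trace cleaning and oculomotor event detection.

Preprocessing linearly interpolates short invalid gaps (<= 75 ms), flags
longer gaps as excluded, and applies a short Savitzky-Golay smoother
(window 5 samples, order 2) to the positions used for spatial summaries
(fixation dispersion, pursuit error).  Event *timing* is measured on the
interpolated but unsmoothed positions: at 60 Hz the smoother's side-lobes
spread saccade energy 2-3 samples backwards, which would bias latencies
early, so detection velocity comes from the raw central difference.
Saccades are detected with a velocity threshold (default 30 deg/s, minimum
duration 2 samples); the onset is the first suprathreshold sample and the
offset is refined forward to the local velocity minimum above a secondary
criterion (threshold / 3), with displacement measured across one flanking
sample on each side so the sub-threshold tails are kept; fixation
epochs are the remaining intervals of at least 100 ms, summarised by their
centroid and RMS dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .paradigm import SAMPLING_RATE

DT = 1.0 / SAMPLING_RATE
MAX_INTERP_GAP = 0.075          # s; longer invalid gaps are excluded
MIN_VALID_FRACTION = 0.5        # below this the whole trial is unusable
VELOCITY_THRESHOLD = 30.0       # deg/s
MIN_SACCADE_SAMPLES = 2
MIN_FIXATION_DURATION = 0.1     # s
SMOOTH_WINDOW = 5               # samples
SMOOTH_ORDER = 2


@dataclass
class CleanTrace:
    t: np.ndarray
    x: np.ndarray                   # smoothed, for spatial summaries
    y: np.ndarray
    interpolated_mask: np.ndarray   # short gaps filled linearly
    excluded_mask: np.ndarray       # long gaps; never used for features
    unusable: bool = False          # < 50% valid samples
    x_raw: np.ndarray | None = None  # interpolated but unsmoothed, for timing
    y_raw: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.interpolated_mask)
                == len(self.excluded_mask) == n):
            raise ValueError("trace arrays must share one length")
        if np.any(self.interpolated_mask & self.excluded_mask):
            raise ValueError("interpolated and excluded masks must be disjoint")
        if self.x_raw is None:
            self.x_raw = self.x
        if self.y_raw is None:
            self.y_raw = self.y


@dataclass
class SaccadeEvent:
    onset: float
    offset: float
    amplitude: float
    peak_velocity: float
    direction: tuple[float, float]   # unit vector
    landing: tuple[float, float]
    onset_index: int = 0
    offset_index: int = 0
    displacement: tuple[float, float] = (0.0, 0.0)  # deg, onset -> landing

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("saccade offset must follow onset")


@dataclass
class FixationEpoch:
    start: float
    end: float
    centroid: tuple[float, float]
    dispersion: float   # RMS distance from centroid, deg


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def preprocess(gaze_trial) -> CleanTrace:
    """Clean one raw trial: interpolate short gaps, flag long ones, smooth."""
    t = np.asarray(gaze_trial.t, float)
    if len(t) < 10:
        raise ValueError("trial too short to preprocess (< 10 samples)")
    x = np.asarray(gaze_trial.x, float).copy()
    y = np.asarray(gaze_trial.y, float).copy()
    valid = np.asarray(gaze_trial.valid, bool)
    interpolated = np.zeros(len(t), bool)
    excluded = np.zeros(len(t), bool)
    unusable = valid.mean() < MIN_VALID_FRACTION
    for start, stop in _runs(~valid):
        gap = (stop - start) * DT
        interior = 0 < start and stop < len(t)
        if gap <= MAX_INTERP_GAP + 1e-9 and interior:
            idx = np.arange(start, stop)
            x[idx] = np.interp(t[idx], [t[start - 1], t[stop]],
                               [x[start - 1], x[stop]])
            y[idx] = np.interp(t[idx], [t[start - 1], t[stop]],
                               [y[start - 1], y[stop]])
            interpolated[idx] = True
        else:
            excluded[start:stop] = True
    x_raw, y_raw = x.copy(), y.copy()
    if len(t) >= SMOOTH_WINDOW:
        x = savgol_filter(x, SMOOTH_WINDOW, SMOOTH_ORDER)
        y = savgol_filter(y, SMOOTH_WINDOW, SMOOTH_ORDER)
    return CleanTrace(t=t, x=x, y=y, interpolated_mask=interpolated,
                      excluded_mask=excluded, unusable=unusable,
                      x_raw=x_raw, y_raw=y_raw)


def compute_velocity(trace: CleanTrace) -> np.ndarray:
    """2D speed (deg/s): central differences, one-sided at the ends.

    Computed on the unsmoothed (gap-interpolated) positions so event timing
    carries no filter delay.  Samples inside or adjacent (+/-1 sample) to
    excluded regions are NaN, so blink edges cannot masquerade as saccades.
    """
    vx = np.gradient(trace.x_raw, trace.t)
    vy = np.gradient(trace.y_raw, trace.t)
    speed = np.hypot(vx, vy)
    bad = trace.excluded_mask.copy()
    if bad.any():
        grown = bad | np.roll(bad, 1) | np.roll(bad, -1)
        grown[0] |= bad[0]
        grown[-1] |= bad[-1]
        speed = speed.copy()
        speed[grown] = np.nan
    return speed


def detect_saccades(trace: CleanTrace,
                    threshold: float = VELOCITY_THRESHOLD,
                    min_duration: int = MIN_SACCADE_SAMPLES
                    ) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection with local-minimum refinement."""
    speed = compute_velocity(trace)
    above = np.where(np.isnan(speed), False, speed > threshold)
    floor = threshold / 3.0  # refinement stops once speed is this quiet
    events: list[SaccadeEvent] = []
    last_stop = -1
    for start, stop in _runs(above):
        if stop - start < min_duration:
            continue
        # onset = first suprathreshold sample: at 60 Hz the central
        # difference already reacts one sample ahead of motion, which
        # cancels the half-sample quantisation of the true onset; walking
        # further back on noise biases latencies early
        i = start
        j = stop - 1
        while j + 1 < len(speed) and not np.isnan(speed[j + 1]) \
                and floor < speed[j + 1] < speed[j]:
            j += 1
        if trace.excluded_mask[i:j + 1].any():
            continue
        # displacement measured across one flanking quiescent sample on each
        # side, so the sub-threshold min-jerk tails are not clipped
        ia = max(i - 1, last_stop + 1, 0)
        jb = min(j + 1, len(speed) - 1)
        dx = trace.x_raw[jb] - trace.x_raw[ia]
        dy = trace.y_raw[jb] - trace.y_raw[ia]
        amp = float(np.hypot(dx, dy))
        direction = (dx / amp, dy / amp) if amp > 0 else (0.0, 0.0)
        events.append(SaccadeEvent(
            onset=float(trace.t[i]), offset=float(trace.t[j]),
            amplitude=amp,
            peak_velocity=float(np.nanmax(speed[start:stop])),
            direction=direction,
            landing=(float(trace.x_raw[jb]), float(trace.y_raw[jb])),
            onset_index=i, offset_index=j,
            displacement=(float(dx), float(dy))))
        last_stop = j
    return events


def detect_fixations(trace: CleanTrace,
                     saccades: list[SaccadeEvent]) -> list[FixationEpoch]:
    """Fixation epochs: the >= 100 ms complements of saccades and exclusions."""
    in_event = trace.excluded_mask.copy()
    for ev in saccades:
        in_event[ev.onset_index:ev.offset_index + 1] = True
    epochs = []
    for start, stop in _runs(~in_event):
        if (stop - start) * DT < MIN_FIXATION_DURATION:
            continue
        xs, ys = trace.x[start:stop], trace.y[start:stop]
        cx, cy = float(xs.mean()), float(ys.mean())
        disp = float(np.sqrt(np.mean((xs - cx) ** 2 + (ys - cy) ** 2)))
        epochs.append(FixationEpoch(start=float(trace.t[start]),
                                    end=float(trace.t[stop - 1]),
                                    centroid=(cx, cy), dispersion=disp))
    return epochs


def saccades_frame(records):
    """Detected saccades as a tidy table.

    ``records`` yields (participant_id, task, trial_index, events) tuples;
    returns one row per saccade with onset/offset/amplitude/peak velocity,
    ready for ``DataFrame.to_csv``.
    """
    import pandas as pd
    rows = [
        {"participant_id": pid, "task": task, "trial_index": idx,
         "onset": e.onset, "offset": e.offset, "amplitude": e.amplitude,
         "peak_velocity": e.peak_velocity}
        for pid, task, idx, events in records for e in events]
    return pd.DataFrame(rows, columns=["participant_id", "task",
                                       "trial_index", "onset", "offset",
                                       "amplitude", "peak_velocity"])


def rms_dispersion(x: np.ndarray, y: np.ndarray) -> float:
    """RMS distance of samples from their centroid (deg)."""
    if len(x) == 0:
        return float("nan")
    cx, cy = x.mean(), y.mean()
    return float(np.sqrt(np.mean((x - cx) ** 2 + (y - cy) ** 2)))
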