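"""Group-level generative phenotypes for the synthetic cohort.

A :class:`GroupProfile` collects every oculomotor and cognitive parameter
the simulator needs for one group (young adults, elderly controls, MCI).
The defaults encode the qualitative group structure reported for this kind
of cohort: young adults beat elderly participants by a wide margin (>= 1
within-group SD) on latency-, gain- and variability-type parameters, while
MCI differs from elderly controls only by a small correlated oculomotor
shift (a single latent severity factor, ~0.2 SD per feature) plus a larger
(~0.7 SD) working-memory deficit concentrated on the backward digit span.
None of these numbers are estimates of any real cohort; they are documented,
configurable simulation assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict, fields

import numpy as np
import yaml

GROUPS = ("young", "control", "mci")


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters of one group's oculomotor/cognitive phenotype."""

    group: str
    # pro/anti saccades
    saccade_latency_mean: float   # s
    saccade_latency_sd: float     # s, within-subject trial-to-trial
    anti_error_rate: float        # P(first saccade goes to the cue on anti trials)
    saccade_gain_mean: float      # amplitude / eccentricity
    saccade_gain_sd: float
    # smooth pursuit
    pursuit_gain: float           # in (0, 1.2]
    pursuit_delay: float          # s, gaze lag behind target
    catchup_rate: float           # catch-up saccades / s
    # memory-guided saccades
    memory_gain_mean: float
    memory_gain_sd: float
    memory_fail_rate: float       # P(no response saccade in the window)
    # predictive saccades
    predictive_anticipation: float  # P(step is anticipated, negative latency)
    predictive_lead_mean: float     # s, mean anticipatory lead (latency = -lead)
    predictive_latency_sd: float    # s
    # fixation / recording quality
    fixation_noise_sd: float      # deg
    blink_rate: float             # blinks / minute
    # working-memory span
    span_ability: float           # expected maximum list length
    span_lapse: float             # P(error on an otherwise-passed length)
    span_backward_deficit: float  # ability penalty on backward variants
    digit_backward_deficit: float  # extra penalty, backward digit span only
    # Stroop
    stroop_rt_base: float         # s
    stroop_interference: float    # s added on incongruent trials
    stroop_rt_sd: float           # s
    stroop_error_rate_congruent: float
    stroop_error_rate_incongruent: float

    def __post_init__(self):
        for name in ("anti_error_rate", "memory_fail_rate",
                     "predictive_anticipation", "span_lapse",
                     "stroop_error_rate_congruent",
                     "stroop_error_rate_incongruent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.pursuit_gain <= 1.2:
            raise ValueError("pursuit_gain must lie in (0, 1.2]")
        for name in ("saccade_latency_sd", "saccade_gain_sd", "memory_gain_sd",
                     "predictive_latency_sd", "fixation_noise_sd", "stroop_rt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "GroupProfile":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


_YOUNG = GroupProfile(
    group="young",
    saccade_latency_mean=0.18, saccade_latency_sd=0.03, anti_error_rate=0.08,
    saccade_gain_mean=0.95, saccade_gain_sd=0.05,
    pursuit_gain=0.95, pursuit_delay=0.08, catchup_rate=0.8,
    memory_gain_mean=0.90, memory_gain_sd=0.08, memory_fail_rate=0.02,
    predictive_anticipation=0.60, predictive_lead_mean=0.15,
    predictive_latency_sd=0.10,
    fixation_noise_sd=0.15, blink_rate=10.0,
    span_ability=7.5, span_lapse=0.02,
    span_backward_deficit=0.6, digit_backward_deficit=0.0,
    stroop_rt_base=0.55, stroop_interference=0.08, stroop_rt_sd=0.10,
    stroop_error_rate_congruent=0.02, stroop_error_rate_incongruent=0.05,
)

_CONTROL = GroupProfile(
    group="control",
    saccade_latency_mean=0.24, saccade_latency_sd=0.05, anti_error_rate=0.25,
    saccade_gain_mean=0.90, saccade_gain_sd=0.08,
    pursuit_gain=0.85, pursuit_delay=0.12, catchup_rate=1.5,
    memory_gain_mean=0.85, memory_gain_sd=0.10, memory_fail_rate=0.08,
    predictive_anticipation=0.40, predictive_lead_mean=0.12,
    predictive_latency_sd=0.16,
    fixation_noise_sd=0.25, blink_rate=12.0,
    span_ability=6.0, span_lapse=0.05,
    span_backward_deficit=0.6, digit_backward_deficit=0.0,
    stroop_rt_base=0.75, stroop_interference=0.15, stroop_rt_sd=0.15,
    stroop_error_rate_congruent=0.03, stroop_error_rate_incongruent=0.08,
)

# Per-parameter oculomotor deltas applied to the control profile by one unit
# of the MCI latent severity factor.  Each is ~0.2 of the corresponding
# between-subject SD: small per feature, but correlated across features.
MCI_OCULOMOTOR_DELTA = {
    "saccade_latency_mean": +0.005,
    "anti_error_rate": +0.005,
    "saccade_gain_mean": -0.015,
    "pursuit_gain": -0.015,
    "pursuit_delay": +0.005,
    "catchup_rate": +0.05,
    "memory_gain_mean": -0.012,
    "memory_fail_rate": +0.010,
    "predictive_anticipation": -0.005,
    "predictive_latency_sd": +0.008,
    "fixation_noise_sd": +0.005,
}

_MCI = _CONTROL.replace(
    group="mci",
    # mean oculomotor phenotype = control + 1.0 x severity deltas
    **{k: getattr(_CONTROL, k) + v for k, v in MCI_OCULOMOTOR_DELTA.items()},
    # working memory: ~0.7 between-subject SD deficit, loaded on backward
    # digit span (between-subject span SD is ~0.75, see BETWEEN_SUBJECT_CV)
    span_ability=5.9,
    digit_backward_deficit=0.9,
    span_lapse=0.07,
    stroop_rt_base=0.76, stroop_interference=0.155,
)

# between-subject jitter: coefficient of variation on scale-type parameters
BETWEEN_SUBJECT_CV = 0.10
# parameters jittered additively (probabilities, already-bounded quantities)
_PROB_FIELDS = ("anti_error_rate", "memory_fail_rate", "predictive_anticipation",
                "span_lapse", "stroop_error_rate_congruent",
                "stroop_error_rate_incongruent")
_SCALE_FIELDS = ("saccade_latency_mean", "saccade_gain_mean", "pursuit_gain",
                 "pursuit_delay", "catchup_rate", "memory_gain_mean",
                 "predictive_lead_mean", "fixation_noise_sd", "span_ability",
                 "stroop_rt_base", "stroop_interference")


def default_profiles() -> dict[str, GroupProfile]:
    """The three documented default group phenotypes (young, control, mci)."""
    return {"young": _YOUNG, "control": _CONTROL, "mci": _MCI}


def scaled_mci_profile(severity: float) -> GroupProfile:
    """Control profile shifted by ``severity`` units of the MCI oculomotor
    delta, with the working-memory deficit scaled alike.  ``severity = 1``
    reproduces the default MCI profile."""
    kw = {k: getattr(_CONTROL, k) + severity * v
          for k, v in MCI_OCULOMOTOR_DELTA.items()}
    kw["pursuit_gain"] = float(np.clip(kw["pursuit_gain"], 1e-3, 1.2))
    kw["anti_error_rate"] = float(np.clip(kw["anti_error_rate"], 0.0, 1.0))
    kw["memory_fail_rate"] = float(np.clip(kw["memory_fail_rate"], 0.0, 1.0))
    kw["predictive_anticipation"] = float(
        np.clip(kw["predictive_anticipation"], 0.0, 1.0))
    return _MCI.replace(
        span_ability=_CONTROL.span_ability - severity * 0.1,
        digit_backward_deficit=severity * _MCI.digit_backward_deficit,
        **kw)


def draw_individual_profile(profile: GroupProfile,
                            rng: np.random.Generator,
                            severity_sd: float = 0.35) -> GroupProfile:
    """One participant's parameters: group means plus between-subject jitter.

    Scale-type parameters get multiplicative ~10% CV jitter; probabilities
    get small additive jitter clipped to [0, 1].  MCI participants carry a
    correlated shift: a single lognormal severity factor rescales every
    oculomotor delta relative to the control means, so their deficits move
    together (detectable multivariately even when weak per feature).
    """
    kw: dict[str, float] = {}
    base = profile
    if profile.group == "mci":
        severity = float(np.exp(rng.normal(0.0, severity_sd)))
        for k, delta in MCI_OCULOMOTOR_DELTA.items():
            control_val = getattr(profile, k) - delta  # back out the group mean shift
            kw[k] = control_val + severity * delta
    for name in _SCALE_FIELDS:
        v = kw.get(name, getattr(base, name))
        kw[name] = v * (1.0 + BETWEEN_SUBJECT_CV * rng.standard_normal())
    for name in _PROB_FIELDS:
        v = kw.get(name, getattr(base, name))
        kw[name] = float(np.clip(v + 0.02 * rng.standard_normal(), 0.0, 1.0))
    kw["pursuit_gain"] = float(np.clip(kw["pursuit_gain"], 1e-3, 1.2))
    for name in ("saccade_latency_mean", "pursuit_delay", "catchup_rate",
                 "memory_gain_mean", "saccade_gain_mean", "fixation_noise_sd",
                 "predictive_lead_mean", "stroop_rt_base", "stroop_interference",
                 "span_ability"):
        kw[name] = max(kw[name], 1e-3)
    return base.replace(**kw)


def profiles_to_yaml(profiles: dict[str, GroupProfile]) -> str:
    return yaml.safe_dump({g: p.to_dict() for g, p in profiles.items()},
                          sort_keys=True)


def profiles_from_yaml(text: str) -> dict[str, GroupProfile]:
    raw = yaml.safe_load(text)
    names = {f.name for f in fields(GroupProfile)}
    out = {}
    for g, d in raw.items():
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown profile fields: {sorted(unknown)}")
        out[g] = GroupProfile(**d)
    return out
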