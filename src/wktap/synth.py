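"""Synthetic tapping sessions under the Wing-Kristofferson model with drift.

The generative model is the classical two-process account of repetitive
timed movement: a central timekeeper emits triggers separated by
independent intervals ``C_j`` (mean = target interval + a polynomial drift
in stimulus number), and each response follows its trigger by an
independent motor delay ``D_j``.  The j-th inter-response interval is

    I_j = C_j - D_{j-1} + D_j

so successive intervals share one motor delay, which imposes a negative
lag-1 autocovariance ``G(1) = -sigma_D^2`` while ``G(0) = sigma_C^2 +
2 sigma_D^2`` and all higher lags vanish.  The lag-1 autocorrelation
therefore lies in [-0.5, 0]: 0 when the motor delay is noiseless, -0.5
when the clock is.

Both tasks of the synchronization-continuation paradigm are emulated:

* externally paced -- 50 tones at a fixed 1500 ms interval, one tap per
  tone.  No phase correction toward the metronome is modelled (the
  analysis model contains none); simulated tap times therefore wander
  relative to the tone train like a true continuation process.
* self paced -- 6 pacing tones, then unpaced continuation taps.  Mean-rate
  offsets and drift are applied from the first continuation interval
  onward, emulating participants who settle on a tempo of their own once
  the tones stop.

Recording artifacts (missed taps, accidental double taps) are applied to
the realized tap train, and tap times are rounded to the 0.1 ms
granularity of the tap-log format.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (CONDITIONS, EXTERNALLY_PACED, SELF_PACED, TIME_DECIMALS,
                 TapSession)

__all__ = [
    "SimParams", "ConditionSpec", "GroupSpec", "CohortSpec",
    "generate_stimulus_train", "simulate_wk_series", "theoretical_acf",
    "simulate_cohort", "default_cohort_spec", "cohort_spec_from_dict",
    "cohort_spec_to_dict",
]

#: lead-in silence before the first tone, ms (keeps jittered taps >= 0)
SESSION_START_MS = 1500.0


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one session.

    ``drift_coeffs_ms`` are polynomial coefficients (linear, quadratic,
    cubic) in the stimulus index, added to the mean clock interval;
    ``iri_offset_ms`` shifts the mean clock interval away from the target
    (for the self-paced task it applies from the first continuation
    interval, leaving the synchronization phase on the beat).
    """

    target_interval_ms: float = 1500.0
    n_taps: int = 50
    n_practice: int = 6
    clock_sd_ms: float = 58.0
    motor_sd_ms: float = 62.0
    drift_coeffs_ms: tuple[float, ...] = (0.0, 0.0, 0.0)
    iri_offset_ms: float = 0.0
    p_miss: float = 0.0
    p_double: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clock_sd_ms < 0 or self.motor_sd_ms < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 <= self.p_miss < 1 and 0 <= self.p_double < 1):
            raise ValueError("artifact probabilities must lie in [0, 1)")
        if self.n_taps < 10:
            raise ValueError("n_taps must be >= 10")
        if self.n_practice < 1:
            raise ValueError("n_practice must be >= 1")
        if self.target_interval_ms <= 0:
            raise ValueError("target_interval_ms must be > 0")
        if len(self.drift_coeffs_ms) > 3:
            raise ValueError("drift polynomial is at most cubic")


def _drift(coeffs: tuple[float, ...], j: np.ndarray) -> np.ndarray:
    out = np.zeros_like(j, dtype=float)
    for power, c in enumerate(coeffs, start=1):
        out += c * j.astype(float) ** power
    return out


def generate_stimulus_train(condition: str, params: SimParams,
                            start_ms: float = 0.0) -> np.ndarray:
    """Tone onset times for one session.

    Externally paced: ``n_taps`` tones at exactly the target interval.
    Self paced: ``n_practice`` pacing tones at exactly the target interval.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n = params.n_taps if condition == EXTERNALLY_PACED else params.n_practice
    return start_ms + params.target_interval_ms * np.arange(n, dtype=float)


def theoretical_acf(params: SimParams, lag: int) -> float:
    """Autocovariance (ms^2) of the drift-free generative process.

    ``G(0) = sigma_C^2 + 2 sigma_D^2``, ``G(1) = -sigma_D^2``, zero beyond
    lag 1.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if lag == 0:
        return params.clock_sd_ms ** 2 + 2 * params.motor_sd_ms ** 2
    if lag == 1:
        return -params.motor_sd_ms ** 2
    return 0.0


def _apply_artifacts(taps: np.ndarray, params: SimParams,
                     rng: np.random.Generator) -> np.ndarray:
    n = len(taps)
    if params.p_miss > 0:
        # never drop more than half the taps: resample the mask if needed
        while True:
            keep = rng.random(n) >= params.p_miss
            if keep.sum() >= (n + 1) // 2:
                break
        taps = taps[keep]
    if params.p_double > 0 and len(taps) > 1:
        gaps = np.diff(taps)
        hit = rng.random(len(gaps)) < params.p_double
        pos = taps[:-1] + rng.random(len(gaps)) * gaps
        taps = np.sort(np.concatenate([taps, pos[hit]]))
    return taps


def simulate_wk_series(params: SimParams, condition: str,
                       participant_id: str = "sim", group: str = "sim") -> TapSession:
    """Simulate one session of the two-process model.

    Tap times follow ``t_j = t_{j-1} + C_j - D_{j-1} + D_j`` with the first
    tap anchored to the first tone.  Artifacts are applied last and times
    are rounded to 0.1 ms.  Reproducible for a fixed ``params.seed``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(params.seed)
    onsets = generate_stimulus_train(condition, params, start_ms=SESSION_START_MS)

    if condition == EXTERNALLY_PACED:
        n = params.n_taps
        cont = np.arange(n)             # stimulus index of the interval
        offset_on = np.ones(n, dtype=bool)
    else:
        n = params.n_practice + params.n_taps
        cont = np.clip(np.arange(n) - params.n_practice, 0, None)
        offset_on = np.arange(n) >= params.n_practice

    mean_c = (params.target_interval_ms
              + np.where(offset_on, params.iri_offset_ms, 0.0)
              + np.where(offset_on, _drift(params.drift_coeffs_ms, cont), 0.0))
    C = mean_c + params.clock_sd_ms * rng.standard_normal(n)
    D = params.motor_sd_ms * rng.standard_normal(n)
    triggers = onsets[0] + np.concatenate([[0.0], np.cumsum(C[1:])])
    taps = triggers + D

    taps = _apply_artifacts(taps, params, rng)
    taps = np.unique(np.round(taps, TIME_DECIMALS))
    shift = min(0.0, taps.min(), onsets.min())
    if shift < 0:                       # pathological draws only
        taps = taps - shift
        onsets = onsets - shift
    return TapSession(participant_id=participant_id, group=group,
                      condition=condition, stimulus_onsets_ms=onsets,
                      tap_times_ms=taps,
                      target_interval_ms=params.target_interval_ms)


# ---------------------------------------------------------------------------
# cohort-level generation


@dataclass(frozen=True)
class ConditionSpec:
    """Distribution of per-participant generative parameters for one task.

    ``*_between`` are between-participant SDs; each participant draws their
    own clock SD, motor SD, mean-rate offset and total linear drift (ms
    accumulated across the task, converted internally to a per-stimulus
    slope).
    """

    clock_sd_ms: float = 58.0
    motor_sd_ms: float = 62.0
    clock_sd_between: float = 0.0
    motor_sd_between: float = 0.0
    iri_offset_mean_ms: float = 0.0
    iri_offset_sd_ms: float = 0.0
    drift_mean_ms: float = 0.0
    drift_sd_ms: float = 0.0
    p_miss: float = 0.0
    p_double: float = 0.0


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    conditions: dict = field(default_factory=dict)  # condition -> ConditionSpec
    age_mean: float = 63.0
    age_sd: float = 8.0
    prop_male: float = 0.5
    stroop_mean: float | None = None
    stroop_sd: float = 0.0
    digit_span_mean: float | None = None
    digit_span_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("each group needs at least one participant")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    target_interval_ms: float = 1500.0
    n_taps: int = 50
    n_practice: int = 6
    conditions: tuple[str, ...] = CONDITIONS


def default_cohort_spec() -> CohortSpec:
    """Two-group (control vs bvFTD) cohort with realistic magnitudes.

    Group sizes, ages, gender ratios, variance components, self-paced rate
    offsets, drift distributions and cognitive-score distributions follow
    the published group summaries for healthy controls and behavioural-
    variant frontotemporal dementia in this paradigm; modest artifact
    rates emulate response-pad capture errors.
    """
    control = GroupSpec(
        label="control", n=31, age_mean=62.6, age_sd=7.2, prop_male=14 / 31,
        stroop_mean=54.3, stroop_sd=12.7, digit_span_mean=7.2, digit_span_sd=2.0,
        conditions={
            EXTERNALLY_PACED: ConditionSpec(
                clock_sd_ms=58.0, motor_sd_ms=62.0,
                clock_sd_between=20.0, motor_sd_between=15.0,
                iri_offset_mean_ms=-6.0, iri_offset_sd_ms=9.0,
                drift_mean_ms=19.0, drift_sd_ms=32.0,
                p_miss=0.02, p_double=0.01),
            SELF_PACED: ConditionSpec(
                clock_sd_ms=66.0, motor_sd_ms=10.0,
                clock_sd_between=20.0, motor_sd_between=5.0,
                iri_offset_mean_ms=-132.0, iri_offset_sd_ms=217.0,
                drift_mean_ms=-28.0, drift_sd_ms=203.0,
                p_miss=0.02, p_double=0.01),
        })
    bvftd = GroupSpec(
        label="bvFTD", n=20, age_mean=63.6, age_sd=9.6, prop_male=17 / 20,
        stroop_mean=93.1, stroop_sd=41.0, digit_span_mean=5.7, digit_span_sd=2.3,
        conditions={
            EXTERNALLY_PACED: ConditionSpec(
                clock_sd_ms=128.0, motor_sd_ms=33.0,
                clock_sd_between=50.0, motor_sd_between=15.0,
                iri_offset_mean_ms=-8.0, iri_offset_sd_ms=36.0,
                drift_mean_ms=10.0, drift_sd_ms=98.0,
                p_miss=0.02, p_double=0.01),
            SELF_PACED: ConditionSpec(
                clock_sd_ms=127.0, motor_sd_ms=5.0,
                clock_sd_between=60.0, motor_sd_between=5.0,
                iri_offset_mean_ms=-277.0, iri_offset_sd_ms=307.0,
                drift_mean_ms=-129.0, drift_sd_ms=377.0,
                p_miss=0.02, p_double=0.01),
        })
    return CohortSpec(groups=(control, bvftd))


def simulate_cohort(spec: CohortSpec, seed: int) -> tuple[list[TapSession], pd.DataFrame]:
    """Simulate every participant of a cohort under ``spec``.

    Returns one session per participant per condition plus a consistent
    cohort table.  Identical ``(spec, seed)`` yield identical output.
    """
    root = np.random.SeedSequence(seed)
    sessions: list[TapSession] = []
    rows = []
    group_seqs = root.spawn(len(spec.groups))
    for gspec, gseq in zip(spec.groups, group_seqs):
        part_seqs = gseq.spawn(gspec.n)
        for i, pseq in enumerate(part_seqs):
            rng = np.random.default_rng(pseq)
            pid = f"{gspec.label}-{i + 1:03d}"
            age = float(np.round(max(30.0, gspec.age_mean + gspec.age_sd * rng.standard_normal()), 1))
            gender = "M" if rng.random() < gspec.prop_male else "F"
            row = {"participant_id": pid, "group": gspec.label,
                   "age": age, "gender": gender}
            if gspec.stroop_mean is not None:
                row["stroop_interference_s"] = float(np.round(
                    max(5.0, gspec.stroop_mean + gspec.stroop_sd * rng.standard_normal()), 1))
            if gspec.digit_span_mean is not None:
                row["digit_span_backwards"] = float(np.clip(np.round(
                    gspec.digit_span_mean + gspec.digit_span_sd * rng.standard_normal()), 1, 12))
            rows.append(row)

            for cond in spec.conditions:
                cspec = gspec.conditions.get(cond, ConditionSpec())
                clock_sd = max(0.0, cspec.clock_sd_ms
                               + cspec.clock_sd_between * rng.standard_normal())
                motor_sd = max(0.0, cspec.motor_sd_ms
                               + cspec.motor_sd_between * rng.standard_normal())
                offset = (cspec.iri_offset_mean_ms
                          + cspec.iri_offset_sd_ms * rng.standard_normal())
                total_drift = (cspec.drift_mean_ms
                               + cspec.drift_sd_ms * rng.standard_normal())
                slope = total_drift / max(spec.n_taps - 1, 1)
                params = SimParams(
                    target_interval_ms=spec.target_interval_ms,
                    n_taps=spec.n_taps, n_practice=spec.n_practice,
                    clock_sd_ms=clock_sd, motor_sd_ms=motor_sd,
                    drift_coeffs_ms=(slope,), iri_offset_ms=offset,
                    p_miss=cspec.p_miss, p_double=cspec.p_double,
                    seed=int(rng.integers(2 ** 31)))
                sessions.append(simulate_wk_series(params, cond,
                                                   participant_id=pid,
                                                   group=gspec.label))
    cohort = pd.DataFrame(rows)
    return sessions, cohort


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    """Build a :class:`CohortSpec` from a plain (e.g. YAML-loaded) mapping."""
    groups = []
    for g in d["groups"]:
        g = dict(g)
        conds = {cond: ConditionSpec(**cs)
                 for cond, cs in g.pop("conditions", {}).items()}
        groups.append(GroupSpec(conditions=conds, **g))
    top = {k: v for k, v in d.items() if k != "groups"}
    if "conditions" in top:
        top["conditions"] = tuple(top["conditions"])
    return CohortSpec(groups=tuple(groups), **top)


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    """Inverse of :func:`cohort_spec_from_dict` (for resolved-config output)."""
    out = dataclasses.asdict(spec)
    out["groups"] = [
        {**{k: v for k, v in dataclasses.asdict(g).items() if k != "conditions"},
         "conditions": {c: dataclasses.asdict(cs) for c, cs in g.conditions.items()}}
        for g in spec.groups
    ]
    out["conditions"] = list(spec.conditions)
    return out
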