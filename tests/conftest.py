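import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def make_session():
    """Factory for hand-constructed externally-paced sessions."""
    from wktap import EXTERNALLY_PACED, TapSession

    def _make(taps, n_stimuli=None, condition=EXTERNALLY_PACED,
              target=1500.0, pid="p1", group="control"):
        taps = np.asarray(taps, dtype=float)
        if n_stimuli is None:
            n_stimuli = len(taps)
        onsets = target * np.arange(n_stimuli, dtype=float)
        return TapSession(participant_id=pid, group=group, condition=condition,
                          stimulus_onsets_ms=onsets, tap_times_ms=taps,
                          target_interval_ms=target)

    return _make


@pytest.fixture
def synthetic_metric_table():
    """Per-participant results + cohort tables with a known group shift."""

    def _make(n_ref=30, n_cmp=20, shift=-175.0, sd_ref=100.0, sd_cmp=150.0,
              seed=0, metric="mean_iri", condition="self_paced"):
        rng = np.random.default_rng(seed)
        n = n_ref + n_cmp
        groups = ["control"] * n_ref + ["bvFTD"] * n_cmp
        results = pd.DataFrame({
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "group": groups,
            "condition": condition,
            metric: np.concatenate([
                1500 + sd_ref * rng.standard_normal(n_ref),
                1500 + shift + sd_cmp * rng.standard_normal(n_cmp)]),
            "rho1": rng.uniform(-0.6, 0.3, n),
            "drift_ms": rng.normal(0, 100, n),
            "abs_drift_ms": np.abs(rng.normal(0, 100, n)),
        })
        cohort = pd.DataFrame({
            "participant_id": results["participant_id"],
            "group": groups,
            "age": np.round(rng.normal(64, 8, n), 1),
            "gender": rng.choice(["M", "F"], n),
            "digit_span_backwards": rng.integers(2, 13, n).astype(float),
            "stroop_interference_s": np.round(rng.normal(70, 20, n), 1),
        })
        return results, cohort

    return _make
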