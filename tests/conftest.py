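import numpy as np
import pytest

from sclimagery import (EffectSpec, TrainConfig, build_model_inputs,
                        generate_cohort, noise_free, preprocess_cohort,
                        train_ensemble)

#: planted surface driven by the model-1 traits only, well separated and
#: monotone (no interaction), so recovery checks are unambiguous
RECOVERY_SPEC = EffectSpec(
    coefficients={"general_imagery": 1.5, "neuroticism": 3.0,
                  "somatic_anxiety": 2.0, "worry": 0.0,
                  "concentration_disruption": 0.0},
    interactions={},
)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-noise cohort of 20 participants."""
    return generate_cohort(20, EffectSpec(), seed=42)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort whose planted values are exactly recoverable."""
    return generate_cohort(12, noise_free(), seed=7)


@pytest.fixture(scope="session")
def trained_ensemble():
    """A quick ensemble fit on a planted monotone surface (60 participants).

    Returns (ensemble, rows, predictors, spec); shared across interpretation
    tests to keep the suite fast.
    """
    predictors = ("general_imagery", "neuroticism", "somatic_anxiety")
    profiles, recordings, truth = generate_cohort(60, RECOVERY_SPEC, seed=21)
    _, outcomes = preprocess_cohort(recordings)
    rows = build_model_inputs(profiles, outcomes, 1)
    config = TrainConfig(max_epochs=1500, patience=60, k=5, seed=5)
    ensemble = train_ensemble(rows[list(predictors)].to_numpy(),
                              rows["mscl"].to_numpy(), config)
    return ensemble, rows, predictors, RECOVERY_SPEC


def brute_force_iqr_mask(values, factor=1.5):
    """Independent Tukey-fence oracle with hand-rolled linear-interp quartiles."""
    x = sorted(float(v) for v in values)
    n = len(x)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return x[lo] * (1 - frac) + x[hi] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    lo_f, hi_f = q1 - factor * iqr, q3 + factor * iqr
    return np.array([lo_f <= float(v) <= hi_f for v in values])
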