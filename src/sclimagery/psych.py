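"""Scoring and normalization of the five psychological predictors.

The predictors are the general-imagery subscale of the Imagination in Sport
Questionnaire (six items, 1–5), short Big-Five neuroticism (7-point items)
and the three Sport Anxiety Scale subscales (somatic anxiety, worry,
concentration disruption; 4-point items).  Subscales are scored as the item
mean and mapped affinely onto [−1, 1] using the theoretical instrument range
by default (observed range optionally), since the modelling operates on
normalized predictors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import iqr_clean

#: the five trait columns, in canonical order
TRAITS = (
    "general_imagery",
    "neuroticism",
    "somatic_anxiety",
    "worry",
    "concentration_disruption",
)

#: theoretical response range (min, max) of each subscale score
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "general_imagery": (1.0, 5.0),
    "neuroticism": (1.0, 7.0),
    "somatic_anxiety": (1.0, 4.0),
    "worry": (1.0, 4.0),
    "concentration_disruption": (1.0, 4.0),
}

#: predictor triplets of the three regression models
MODEL_PREDICTORS: dict[int, tuple[str, str, str]] = {
    1: ("general_imagery", "neuroticism", "somatic_anxiety"),
    2: ("general_imagery", "neuroticism", "concentration_disruption"),
    3: ("general_imagery", "neuroticism", "worry"),
}


def scale_score(responses, item_range: tuple[float, float]) -> float:
    """Raw subscale score as the mean of item responses.

    Every item must be present and within the declared item range;
    imputation of missing items is out of scope.
    """
    x = np.asarray(responses, dtype=float)
    if x.size == 0:
        raise ValueError("no item responses given")
    if np.any(np.isnan(x)):
        raise ValueError("missing item response; imputation is not supported")
    lo, hi = item_range
    if np.any((x < lo) | (x > hi)):
        raise ValueError(f"item response outside declared range [{lo}, {hi}]")
    return float(np.mean(x))


def normalize_scores(values, value_range: tuple[float, float]) -> np.ndarray:
    """Affine map of raw scores onto [−1, 1]: x ↦ 2(x − min)/(max − min) − 1."""
    lo, hi = value_range
    if not lo < hi:
        raise ValueError(f"invalid range [{lo}, {hi}]: min must be < max")
    x = np.asarray(values, dtype=float)
    if np.any((x < lo) | (x > hi)):
        raise ValueError(f"value outside declared range [{lo}, {hi}]")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def denormalize_scores(values, value_range: tuple[float, float]) -> np.ndarray:
    """Inverse of :func:`normalize_scores`."""
    lo, hi = value_range
    x = np.asarray(values, dtype=float)
    return lo + (x + 1.0) * (hi - lo) / 2.0


def clean_scores(values, *, factor: float = 1.5, method: str = "linear") -> np.ndarray:
    """1.5·IQR retained mask for questionnaire scores (same rule as SCL data)."""
    return iqr_clean(values, factor=factor, method=method)


def normalize_profiles(profiles: pd.DataFrame, *, use_observed_range: bool = False,
                       ranges: dict[str, tuple[float, float]] | None = None,
                       ) -> pd.DataFrame:
    """Add ``<trait>_norm`` columns in [−1, 1] to a raw trait frame.

    Uses the theoretical instrument range by default; ``use_observed_range``
    switches to each column's observed min/max.
    """
    ranges = dict(ranges or INSTRUMENT_RANGES)
    out = profiles.copy()
    for trait in TRAITS:
        if trait not in out.columns:
            raise KeyError(f"profiles are missing trait column {trait!r}")
        if use_observed_range:
            rng = (float(out[trait].min()), float(out[trait].max()))
        else:
            rng = ranges[trait]
        out[f"{trait}_norm"] = normalize_scores(out[trait].to_numpy(), rng)
    return out


def build_model_inputs(profiles: pd.DataFrame, outcomes: pd.DataFrame,
                       model: int) -> pd.DataFrame:
    """Assemble complete-case rows (three normalized predictors + mSCL).

    ``model`` is 1, 2 or 3, selecting the predictor triplet.
    """
    if model not in MODEL_PREDICTORS:
        raise ValueError(f"model must be one of {sorted(MODEL_PREDICTORS)}, got {model}")
    preds = MODEL_PREDICTORS[model]
    cols = [f"{p}_norm" for p in preds]
    missing = [c for c in cols if c not in profiles.columns]
    if missing:
        raise KeyError(f"profiles lack normalized columns {missing}; "
                       "run normalize_profiles first")
    merged = profiles[["participant_id", *cols]].merge(
        outcomes[["participant_id", "mscl"]], on="participant_id", how="inner")
    merged = merged.dropna()
    merged.columns = ["participant_id", *preds, "mscl"]
    return merged.reset_index(drop=True)
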