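"""Longitudinal clinical outcomes and the covariate design matrices.

Four binary wave-1 -> wave-3 outcomes are derived from the two-wave cohort
table:

* ``tug_decline``  -- Timed Up-and-Go below 12 s at baseline, >= 12 s at
  follow-up (transition into mobility impairment);
* ``ugs_decline``  -- usual gait speed >= 100 cm/s at baseline, < 100 cm/s
  at follow-up;
* ``new_faller``   -- no falls in the year before wave 1, >= 1 fall in the
  year before wave 3;
* ``mmse_decline`` -- drop of at least 2 MMSE points between waves.

Each outcome is regressed on exactly one SART predictor in a nested suite
of logistic models (1, 2, 3, 4, 4a) with incrementally richer covariate
adjustment; this module builds the corresponding design matrices with
dummy coding (education ref = primary/none, smoking ref = never, IPAQ ref
= low, drinking-problem ref = no with a separate don't-know indicator).
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TUG_CUTOFF_S",
    "UGS_CUTOFF_CM_S",
    "MMSE_DECLINE_POINTS",
    "OUTCOMES",
    "PREDICTORS",
    "MODEL_IDS",
    "DegenerateOutcomeError",
    "derive_outcomes",
    "merge_waves",
    "covariate_design",
]

TUG_CUTOFF_S = 12.0
UGS_CUTOFF_CM_S = 100.0
MMSE_DECLINE_POINTS = 2.0

OUTCOMES = ("tug_decline", "ugs_decline", "new_faller", "mmse_decline")
PREDICTORS = ("bad_performances", "total_mistakes", "mistakes_in_good_performances")
MODEL_IDS = ("1", "2", "3", "4", "4a")


class DegenerateOutcomeError(ValueError):
    """Raised when an outcome vector has a single class after filtering."""


def _flag(cond_pos: pd.Series, inputs_ok: pd.Series) -> pd.Series:
    return pd.Series(np.where(inputs_ok, cond_pos.astype(float), np.nan), index=cond_pos.index)


def derive_outcomes(
    cohort: pd.DataFrame | Mapping[str, float],
    tug_cutoff: float = TUG_CUTOFF_S,
    ugs_cutoff: float = UGS_CUTOFF_CM_S,
    mmse_points: float = MMSE_DECLINE_POINTS,
) -> pd.DataFrame:
    """Binary outcome flags (1/0, NaN when a required input is missing).

    A pure, row-wise function: permuting input rows permutes the output
    identically.  Accepts a DataFrame or a single record mapping.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.DataFrame([dict(cohort)])
    tug1, tug3 = cohort["tug_w1"], cohort["tug_w3"]
    ugs1, ugs3 = cohort["ugs_w1"], cohort["ugs_w3"]
    f1, f3 = cohort["falls_w1"], cohort["falls_w3"]
    m1, m3 = cohort["mmse_w1"], cohort["mmse_w3"]
    return pd.DataFrame(
        {
            "tug_decline": _flag((tug1 < tug_cutoff) & (tug3 >= tug_cutoff), tug1.notna() & tug3.notna()),
            "ugs_decline": _flag((ugs1 >= ugs_cutoff) & (ugs3 < ugs_cutoff), ugs1.notna() & ugs3.notna()),
            "new_faller": _flag((f1 == 0) & (f3 > 0), f1.notna() & f3.notna()),
            "mmse_decline": _flag((m1 - m3) >= mmse_points, m1.notna() & m3.notna()),
        },
        index=cohort.index,
    )


_WAVE3_COLUMNS = ("tug_w3", "ugs_w3", "falls_w3", "mmse_w3")


def merge_waves(cohort: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Inner-join SART features onto the cohort table and keep the merged
    longitudinal sample: participants with features and any wave-3 data.

    Appends the four derived outcome flags.  Duplicate participant ids are
    rejected; disjoint id sets yield an empty table with a warning.
    """
    for name, df in (("cohort", cohort), ("features", features)):
        dup = df["participant_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate participant_id in {name} table: "
                f"{sorted(df.loc[dup, 'participant_id'].unique()[:5])}"
            )
    merged = cohort.merge(features, on="participant_id", how="inner")
    if merged.empty:
        warnings.warn("cohort and features tables share no participant ids")
        return merged.assign(**{o: pd.Series(dtype=float) for o in OUTCOMES})
    attended_w3 = merged[list(_WAVE3_COLUMNS)].notna().any(axis=1)
    out = merged[attended_w3].reset_index(drop=True)
    out = pd.concat([out, derive_outcomes(out)], axis=1)
    logger.info(
        "merge_waves: %d cohort rows, %d with SART features, %d in merged two-wave sample",
        len(cohort), len(merged), len(out),
    )
    return out


# covariate blocks added at each model stage
_MODEL_STAGES: dict[str, tuple[str, ...]] = {
    "1": (),
    "2": ("mean_rt_ms", "sd_rt_ms"),
    "3": ("mean_rt_ms", "sd_rt_ms", "age", "female", "edu_secondary", "edu_third_higher"),
    "4": (
        "mean_rt_ms", "sd_rt_ms", "age", "female", "edu_secondary", "edu_third_higher",
        "anxiety", "depression", "antihypertensives", "diabetes",
        "smoking_past", "smoking_current", "drinking_yes", "drinking_dont_know",
        "ipaq_medium", "ipaq_high",
    ),
}
_MODEL_STAGES["4a"] = _MODEL_STAGES["4"] + ("ugs_w1",)

# analysis-population restriction: the outcome is a transition from a
# normal baseline, so baseline-impaired rows are dropped by default
_BASELINE_RESTRICTION = {
    "tug_decline": lambda t: t["tug_w1"] < TUG_CUTOFF_S,
    "ugs_decline": lambda t: t["ugs_w1"] >= UGS_CUTOFF_CM_S,
    "new_faller": lambda t: t["falls_w1"] == 0,
    "mmse_decline": lambda t: pd.Series(True, index=t.index),
}


def _dummy_columns(table: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=table.index)
    out["female"] = (table["sex"] == "female").astype(float)
    out["edu_secondary"] = (table["education"] == "secondary").astype(float)
    out["edu_third_higher"] = (table["education"] == "third/higher").astype(float)
    out["smoking_past"] = (table["smoking"] == "past").astype(float)
    out["smoking_current"] = (table["smoking"] == "current").astype(float)
    out["drinking_yes"] = (table["drinking_problem"] == "yes").astype(float)
    out["drinking_dont_know"] = (table["drinking_problem"] == "dont_know").astype(float)
    out["ipaq_medium"] = (table["ipaq"] == "medium").astype(float)
    out["ipaq_high"] = (table["ipaq"] == "high").astype(float)
    # categorical NaNs propagate as missing
    for src, cols in (
        ("sex", ["female"]),
        ("education", ["edu_secondary", "edu_third_higher"]),
        ("smoking", ["smoking_past", "smoking_current"]),
        ("drinking_problem", ["drinking_yes", "drinking_dont_know"]),
        ("ipaq", ["ipaq_medium", "ipaq_high"]),
    ):
        out.loc[table[src].isna(), cols] = np.nan
    return out


def covariate_design(
    table: pd.DataFrame,
    model_id: str,
    predictor: str,
    outcome: str,
    baseline_impaired: str = "drop",
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (with intercept) and outcome vector for one model.

    Complete-case rows only.  ``baseline_impaired='drop'`` (default)
    restricts the analysis population to participants at risk of the
    transition (e.g. TUG < 12 s at baseline for ``tug_decline``);
    ``'keep'`` retains them coded 0, the alternative reading.
    """
    model_id = str(model_id)
    if model_id not in _MODEL_STAGES:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {sorted(_MODEL_STAGES)}")
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}; expected one of {PREDICTORS}")
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if baseline_impaired not in ("drop", "keep"):
        raise ValueError("baseline_impaired must be 'drop' or 'keep'")

    t = table
    if baseline_impaired == "drop":
        t = t[_BASELINE_RESTRICTION[outcome](t).fillna(False)]

    cols = pd.concat([t, _dummy_columns(t)], axis=1)
    names = (predictor,) + _MODEL_STAGES[model_id]
    X = cols[list(names)].astype(float)
    y = cols[outcome].astype(float)
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X[keep], y[keep]
    if y.nunique() < 2:
        raise DegenerateOutcomeError(
            f"outcome {outcome!r} has a single class in the {len(y)}-row analysis set"
        )
    X.insert(0, "const", 1.0)
    return X, y
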