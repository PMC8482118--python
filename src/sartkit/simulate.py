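"""Synthetic two-wave cohort generator.

Generates raw trial-level SART streams and a paired two-wave clinical
table (TUG, UGS, falls, MMSE, demographics, lifestyle covariates) with the
statistical structure the downstream analysis assumes, so the whole
pipeline is testable without access to a restricted cohort.

Error model
-----------
Each cycle of a participant's administration is in one of three latent
attention states:

* ``focused`` -- independent per-presentation errors at low baseline rates
  (omission on GO, commission on NO-GO);
* ``distracted`` -- a short disengagement producing a burst of a few
  omissions (the spot sits just below the bad-performance threshold);
* ``lapse`` -- a severe whole-cycle breakdown in which every presentation
  errs independently with a high rate (omissions dominate, the NO-GO is
  usually pressed).

State propensities and baseline rates are modulated on the log-odds scale
by age and by a participant-level latent attention deficit, which makes
per-cycle mistake counts heavy-tailed and strongly over-dispersed across
participants -- the feature of real sustained-attention data that the
mean + 2 SD spot-size rule exploits.

Outcome model
-------------
Binary wave-1 -> wave-3 outcomes (TUG decline, UGS decline, new faller,
MMSE decline) are drawn from logistic links whose coefficients are part of
the configuration, so the true odds ratio of the bad-performance count on
each outcome is a known constant available for recovery tests.  The
continuous wave-3 measurements are then constructed to be consistent with
the drawn flags while preserving the configured mean TUG increment per
group (participants with vs without bad performances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import protocol
from .features import SARTStream

__all__ = [
    "GeneratorConfig",
    "ParticipantProfile",
    "ConfigError",
    "default_config",
    "generate_profiles",
    "generate_sart_stream",
    "generate_cohort",
    "write_cohort_csv",
]

REFERENCE_AGE = 60.0  # years; all age effects are centred here

COHORT_COLUMNS = [
    "participant_id",
    "tug_w1",
    "tug_w3",
    "ugs_w1",
    "ugs_w3",
    "falls_w1",
    "falls_w3",
    "mmse_w1",
    "mmse_w3",
    "age",
    "sex",
    "education",
    "anxiety",
    "depression",
    "antihypertensives",
    "diabetes",
    "smoking",
    "drinking_problem",
    "ipaq",
]


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _default_outcome_coefficients() -> dict[str, dict[str, float]]:
    # Log-odds effects; 'age' is per year above REFERENCE_AGE.  The
    # bad-performance effects default to the fully adjusted odds ratios the
    # validation study reports (1.287 TUG decline, 1.114 new faller, ...),
    # so end-to-end runs resemble the published effect magnitudes.
    return {
        "tug_decline": {
            "intercept": -3.35,
            "bad_performances": math.log(1.287),
            "age": 0.050,
            "antihypertensives": 0.41,
            "diabetes": 0.41,
            "smoking_current": 0.34,
            "ipaq_high": -0.36,
        },
        "ugs_decline": {
            "intercept": -2.70,
            "bad_performances": math.log(1.05),
            "age": 0.077,
            "antihypertensives": 0.34,
        },
        "new_faller": {
            "intercept": -1.95,
            "bad_performances": math.log(1.114),
            "age": math.log(1.020),
        },
        "mmse_decline": {
            "intercept": -2.30,
            "bad_performances": math.log(1.067),
            "age": math.log(1.044),
            "smoking_current": math.log(1.523),
        },
    }


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic cohort.

    Rates of the SART error model refer to a median participant (zero
    latent deficit) at the reference age of 60; the latent-deficit spread
    parameters inflate the cohort means above these medians.
    """

    n_participants: int = 5000
    seed: int = 20210905

    # -- demographics -----------------------------------------------------
    age_range: tuple[float, float] = (50.0, 93.0)
    age_band_edges: tuple[float, ...] = (50.0, 65.0, 75.0, 93.0)
    age_band_weights: tuple[float, ...] = (0.75, 0.18, 0.07)
    sex_female_rate: float = 0.546
    education_weights: Mapping[str, float] = field(
        default_factory=lambda: {"primary/none": 0.212, "secondary": 0.419, "third/higher": 0.369}
    )
    smoking_weights: Mapping[str, float] = field(
        default_factory=lambda: {"never": 0.459, "past": 0.393, "current": 0.148}
    )
    drinking_weights: Mapping[str, float] = field(
        default_factory=lambda: {"no": 0.781, "yes": 0.128, "dont_know": 0.091}
    )
    ipaq_weights: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.278, "medium": 0.362, "high": 0.360}
    )
    anxiety_mean: float = 5.4
    anxiety_sd: float = 3.6
    depression_shape: float = 0.66
    depression_scale: float = 8.5
    antihypertensives_rate: float = 0.133
    diabetes_rate: float = 0.062

    # -- SART error model -------------------------------------------------
    baseline_go_error_rate: float = 0.001
    baseline_nogo_error_rate: float = 0.012
    distraction_cycle_rate: float = 0.085
    distraction_omissions: tuple[int, ...] = (3,)
    distraction_omission_weights: tuple[float, ...] = (1.0,)
    lapse_cycle_rate: float = 0.0009
    lapse_error_rate: float = 0.78
    age_error_slope: float = 0.055
    deficit_lapse_sd: float = 2.9
    deficit_distraction_sd: float = 0.8
    deficit_error_sd: float = 0.5

    # -- RT model ---------------------------------------------------------
    rt_log_mean: float = 5.90
    rt_log_sd: float = 0.185
    rt_participant_log_sd: float = 0.23
    rt_sd_log_sd: float = 0.35
    rt_age_slope: float = 2.0
    rt_floor_ms: float = 120.0

    # -- missing-data emulation -------------------------------------------
    missing_stream_rate: float = 0.017
    no_press_fraction: float = 0.24
    attrition_rate: float = 0.20
    w1_missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {"tug_w1": 0.006, "ugs_w1": 0.010, "mmse_w1": 0.004}
    )

    # -- outcome model ----------------------------------------------------
    outcome_threshold: int = 4
    outcome_coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_outcome_coefficients
    )
    wave_interval_effects: tuple[float, float] = (0.871, 1.512)
    tug_change_sd: float = 1.0
    tug_w1_floor: float = 4.2
    tug_w1_log_mean: float = 1.42
    tug_w1_log_sd: float = 0.40
    tug_age_log_slope: float = 0.018
    ugs_w1_mean: float = 138.0
    ugs_w1_sd: float = 19.5
    ugs_age_slope: float = -0.9
    ugs_change_mean: float = 2.0
    ugs_change_bad_extra: float = 2.5
    ugs_change_sd: float = 9.0
    falls_nb_r: float = 0.12
    falls_w1_mean: float = 0.4
    mmse_deficit_shape: float = 0.55
    mmse_deficit_scale: float = 2.2
    mmse_age_slope: float = 0.05

    # ---------------------------------------------------------------------
    def validate(self) -> "GeneratorConfig":
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range low must be < high")
        prob_fields = [
            "sex_female_rate",
            "baseline_go_error_rate",
            "baseline_nogo_error_rate",
            "distraction_cycle_rate",
            "lapse_cycle_rate",
            "lapse_error_rate",
            "missing_stream_rate",
            "no_press_fraction",
            "attrition_rate",
            "antihypertensives_rate",
            "diabetes_rate",
        ]
        for name in prob_fields:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.lapse_error_rate <= max(self.baseline_go_error_rate, self.baseline_nogo_error_rate):
            raise ConfigError("lapse_error_rate must exceed both baseline error rates")
        if len(self.distraction_omissions) != len(self.distraction_omission_weights):
            raise ConfigError("distraction_omissions and distraction_omission_weights differ in length")
        if any(k < 0 or k > protocol.N_GO_PER_CYCLE for k in self.distraction_omissions):
            raise ConfigError("distraction_omissions entries must lie in 0..8")
        if not 1 <= self.outcome_threshold <= protocol.CYCLE_LENGTH + 1:
            raise ConfigError("outcome_threshold must lie in 1..10")
        for w in ("age_band_weights", "distraction_omission_weights"):
            if any(x < 0 for x in getattr(self, w)):
                raise ConfigError(f"{w} must be non-negative")
        return self

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        def _plain(x):
            if isinstance(x, tuple):
                return [_plain(v) for v in x]
            if isinstance(x, Mapping):
                return {k: _plain(v) for k, v in x.items()}
            return x

        Path(path).write_text(yaml.safe_dump({k: _plain(v) for k, v in asdict(self).items()}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
        tuple_fields = {
            "age_range",
            "age_band_edges",
            "age_band_weights",
            "distraction_omissions",
            "distraction_omission_weights",
            "wave_interval_effects",
        }
        for k in tuple_fields & set(raw):
            raw[k] = tuple(raw[k])
        return cls(**raw).validate()


@dataclass(frozen=True)
class ParticipantProfile:
    """Wave-1 person-level attributes driving the SART and outcome models."""

    participant_id: str
    age_w1: float
    sex: str
    education: str
    latent_attention_deficit: float
    anxiety: int
    depression: int
    antihypertensives: bool
    diabetes: bool
    smoking: str
    drinking_problem: str
    ipaq: str


def default_config() -> GeneratorConfig:
    """The calibrated default configuration.

    Defaults are chosen so a large simulated cohort approximately matches
    the validation study's wave-1 descriptive moments (total SART mistakes
    ~11 per participant, mean correct-press RT ~385 ms, TUG ~8.6 s, UGS
    ~136 cm/s, MMSE ~28.7) and so the pooled mean + 2 SD spot-size rule
    implies a threshold of 4 mistakes per cycle.
    """
    return GeneratorConfig().validate()


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _choice(rng: np.random.Generator, weights: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    return rng.choice(np.asarray(keys, dtype=object), size=n, p=p / p.sum())


def generate_profiles(config: GeneratorConfig, rng: np.random.Generator) -> list[ParticipantProfile]:
    """Draw wave-1 participant profiles (demographics, covariates, deficit)."""
    config.validate()
    n = config.n_participants
    edges = np.asarray(config.age_band_edges, dtype=float)
    w = np.asarray(config.age_band_weights, dtype=float)
    band = rng.choice(len(w), size=n, p=w / w.sum())
    age = rng.uniform(edges[band], edges[band + 1])
    age = np.clip(age, config.age_range[0], config.age_range[1])

    sex = np.where(rng.random(n) < config.sex_female_rate, "female", "male")
    education = _choice(rng, config.education_weights, n)
    smoking = _choice(rng, config.smoking_weights, n)
    drinking = _choice(rng, config.drinking_weights, n)
    ipaq = _choice(rng, config.ipaq_weights, n)
    anxiety = np.clip(np.round(rng.normal(config.anxiety_mean, config.anxiety_sd, n)), 0, 21)
    depression = np.clip(
        np.round(rng.gamma(config.depression_shape, config.depression_scale, n)), 0, 60
    )
    antihyp = rng.random(n) < config.antihypertensives_rate
    diabetes = rng.random(n) < config.diabetes_rate
    z = rng.normal(0.0, 1.0, n)

    width = len(str(n))
    return [
        ParticipantProfile(
            participant_id=f"P{i + 1:0{max(width, 4)}d}",
            age_w1=float(age[i]),
            sex=str(sex[i]),
            education=str(education[i]),
            latent_attention_deficit=float(z[i]),
            anxiety=int(anxiety[i]),
            depression=int(depression[i]),
            antihypertensives=bool(antihyp[i]),
            diabetes=bool(diabetes[i]),
            smoking=str(smoking[i]),
            drinking_problem=str(drinking[i]),
            ipaq=str(ipaq[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# SART streams
# ---------------------------------------------------------------------------

def _adjusted_rate(base: float, agec: float, z: float, slope: float, loading: float) -> float:
    """Shift a base probability on the log-odds scale by age and deficit."""
    if base <= 0.0:
        return 0.0
    if base >= 1.0:
        return 1.0
    return float(expit(logit(base) + slope * agec + loading * z))


def generate_sart_stream(
    profile: ParticipantProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> SARTStream:
    """Simulate one 207-presentation administration for one participant.

    Deterministic given (profile, config, rng state): the same profile and
    a generator seeded identically always yield the same stream.
    """
    agec = profile.age_w1 - REFERENCE_AGE
    z = profile.latent_attention_deficit
    s = config.age_error_slope

    p_lapse = _adjusted_rate(config.lapse_cycle_rate, agec, z, s, config.deficit_lapse_sd)
    p_distr = _adjusted_rate(config.distraction_cycle_rate, agec, z, s, config.deficit_distraction_sd)
    p_distr = min(p_distr, 1.0 - p_lapse)
    p_omit = _adjusted_rate(config.baseline_go_error_rate, agec, z, s, config.deficit_error_sd)
    p_commit = _adjusted_rate(config.baseline_nogo_error_rate, agec, z, s, config.deficit_error_sd)

    nc, ng = protocol.N_CYCLES, protocol.N_GO_PER_CYCLE

    # participant-level RT location and variability
    rt_mu = config.rt_log_mean + config.rt_participant_log_sd * rng.normal()
    rt_sigma = config.rt_log_sd * math.exp(config.rt_sd_log_sd * rng.normal())

    u_state = rng.random(nc)
    state = np.where(u_state < p_lapse, 2, np.where(u_state < p_lapse + p_distr, 1, 0))

    u_omit = rng.random((nc, ng))
    omit = np.where(
        (state == 2)[:, None], u_omit < config.lapse_error_rate, u_omit < p_omit
    )
    # distracted cycles: a burst of k omissions at random GO positions
    k_choices = np.asarray(config.distraction_omissions)
    kw = np.asarray(config.distraction_omission_weights, dtype=float)
    k_draw = rng.choice(k_choices, size=nc, p=kw / kw.sum())
    order = np.argsort(rng.random((nc, ng)), axis=1)
    burst = order < k_draw[:, None]
    omit = np.where((state == 1)[:, None], burst, omit)

    u_commit = rng.random(nc)
    commit = np.where(
        state == 2, u_commit < config.lapse_error_rate,
        np.where(state == 1, False, u_commit < p_commit),
    )

    # assemble the 23 x 9 press grid (column 2 is the NO-GO digit 3)
    pressed = np.zeros((nc, protocol.CYCLE_LENGTH), dtype=bool)
    go_cols = [i for i, d in enumerate(protocol.CYCLE_DIGITS) if d != protocol.NOGO_DIGIT]
    nogo_col = protocol.CYCLE_DIGITS.index(protocol.NOGO_DIGIT)
    pressed[:, go_cols] = ~omit
    pressed[:, nogo_col] = commit

    rt = np.exp(rng.normal(rt_mu, rt_sigma, size=(nc, protocol.CYCLE_LENGTH)))
    rt = np.maximum(rt + config.rt_age_slope * agec, config.rt_floor_ms)
    rt[~pressed] = np.nan

    # missing-data emulation: rare streams with unplottable cycles
    if rng.random() < config.missing_stream_rate:
        n_affected = 1 + int(rng.random() < 0.5)
        cycles = rng.choice(nc, size=n_affected, replace=False)
        if rng.random() < config.no_press_fraction:
            pressed[cycles, :] = False  # no press at all in those cycles
            rt[cycles, :] = np.nan
        else:
            for c in cycles:
                go_pressed = [j for j in go_cols if pressed[c, j]]
                if not go_pressed:
                    continue
                n_lost = min(len(go_pressed), 1 + int(rng.integers(0, 3)))
                lost = rng.choice(go_pressed, size=n_lost, replace=False)
                rt[c, lost] = np.nan  # pressed, but the RT was not recorded

    return SARTStream(
        participant_id=profile.participant_id,
        digit=protocol.digit_sequence(),
        pressed=pressed.ravel(),
        rt_ms=rt.ravel(),
    )


def _bad_performance_counts(streams: Sequence[SARTStream], threshold: int) -> np.ndarray:
    """Cycles with >= threshold mistakes, per stream (generator bookkeeping)."""
    go = protocol.go_mask().reshape(protocol.N_CYCLES, protocol.CYCLE_LENGTH)
    counts = np.empty(len(streams), dtype=int)
    for i, s in enumerate(streams):
        pressed = s.pressed.reshape(protocol.N_CYCLES, protocol.CYCLE_LENGTH)
        mistakes = (go & ~pressed).sum(axis=1) + (~go & pressed).sum(axis=1)
        counts[i] = int((mistakes >= threshold).sum())
    return counts


# ---------------------------------------------------------------------------
# outcomes and the cohort table
# ---------------------------------------------------------------------------

def _term_values(
    name: str,
    profiles_df: pd.DataFrame,
    bad_counts: np.ndarray,
    extra: Mapping[str, np.ndarray],
) -> np.ndarray:
    n = len(profiles_df)
    if name == "intercept":
        return np.ones(n)
    if name == "bad_performances":
        return bad_counts.astype(float)
    if name == "age":
        return profiles_df["age_w1"].to_numpy() - REFERENCE_AGE
    if name == "female":
        return (profiles_df["sex"] == "female").to_numpy(float)
    if name in ("antihypertensives", "diabetes"):
        return profiles_df[name].to_numpy(float)
    if name in ("anxiety", "depression"):
        return profiles_df[name].to_numpy(float)
    if name.startswith("smoking_"):
        return (profiles_df["smoking"] == name.split("_", 1)[1]).to_numpy(float)
    if name.startswith("ipaq_"):
        return (profiles_df["ipaq"] == name.split("_", 1)[1]).to_numpy(float)
    if name.startswith("education_"):
        return (profiles_df["education"] == name.split("_", 1)[1]).to_numpy(float)
    if name in extra:
        return extra[name]
    raise ConfigError(f"outcome_coefficients refers to unknown term {name!r}")


def _linear_predictor(
    coeffs: Mapping[str, float],
    profiles_df: pd.DataFrame,
    bad_counts: np.ndarray,
    extra: Mapping[str, np.ndarray],
) -> np.ndarray:
    lp = np.zeros(len(profiles_df))
    for term, beta in coeffs.items():
        lp += float(beta) * _term_values(term, profiles_df, bad_counts, extra)
    return lp


def generate_cohort(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> tuple[list[SARTStream], pd.DataFrame]:
    """Generate a full synthetic cohort: one SART stream and one two-wave
    clinical record per participant.

    A single master seed (``seed`` argument, falling back to
    ``config.seed``) drives everything; per-participant stream substreams
    are spawned deterministically so cohorts are reproducible regardless of
    generation order.
    """
    config = (config or default_config()).validate()
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    ss_profiles, ss_outcomes, ss_streams = master.spawn(3)

    profiles = generate_profiles(config, np.random.default_rng(ss_profiles))
    streams = [
        generate_sart_stream(p, config, np.random.default_rng(child))
        for p, child in zip(profiles, ss_streams.spawn(len(profiles)))
    ]

    rng = np.random.default_rng(ss_outcomes)
    pdf = pd.DataFrame([p.__dict__ for p in profiles])
    n = len(pdf)
    bad = _bad_performance_counts(streams, config.outcome_threshold)
    any_bad = bad > 0
    age = pdf["age_w1"].to_numpy()
    agec = age - REFERENCE_AGE

    # --- TUG ---------------------------------------------------------------
    tug_w1 = config.tug_w1_floor + np.exp(
        rng.normal(config.tug_w1_log_mean + config.tug_age_log_slope * agec, config.tug_w1_log_sd)
    )
    slope = np.where(any_bad, config.wave_interval_effects[1], config.wave_interval_effects[0])
    tug_w3 = tug_w1 + slope + rng.normal(0.0, config.tug_change_sd, n)

    extra = {"ugs_w1": np.zeros(n)}  # placeholder until UGS drawn below

    # --- UGS ---------------------------------------------------------------
    ugs_w1 = np.maximum(
        config.ugs_w1_mean + config.ugs_age_slope * agec + rng.normal(0.0, config.ugs_w1_sd, n),
        30.0,
    )
    extra["ugs_w1"] = ugs_w1 - 136.0  # centred, for optional link terms
    ugs_w3 = np.maximum(
        ugs_w1
        - (
            config.ugs_change_mean
            + config.ugs_change_bad_extra * any_bad
            + rng.normal(0.0, config.ugs_change_sd, n)
        ),
        25.0,
    )

    # --- binary outcome flags from the logistic links ------------------------
    coeffs = config.outcome_coefficients

    p_tug = expit(_linear_predictor(coeffs["tug_decline"], pdf, bad, extra))
    tug_flag = rng.random(n) < p_tug
    elig_tug = tug_w1 < 12.0
    margin = np.abs(rng.normal(0.0, 0.6, n)) + 0.05
    tug_w3 = np.where(elig_tug & tug_flag, np.maximum(tug_w3, 12.0 + margin), tug_w3)
    tug_w3 = np.where(elig_tug & ~tug_flag, np.minimum(tug_w3, 12.0 - margin), tug_w3)
    tug_w3 = np.maximum(tug_w3, config.tug_w1_floor)

    p_ugs = expit(_linear_predictor(coeffs["ugs_decline"], pdf, bad, extra))
    ugs_flag = rng.random(n) < p_ugs
    elig_ugs = ugs_w1 >= 100.0
    umargin = np.abs(rng.normal(0.0, 4.0, n)) + 0.5
    ugs_w3 = np.where(elig_ugs & ugs_flag, np.minimum(ugs_w3, 100.0 - umargin), ugs_w3)
    ugs_w3 = np.where(elig_ugs & ~ugs_flag, np.maximum(ugs_w3, 100.0 + umargin), ugs_w3)

    # --- falls ---------------------------------------------------------------
    r = config.falls_nb_r
    falls_w1 = rng.negative_binomial(r, r / (r + config.falls_w1_mean), n).astype(float)
    p_fall = expit(_linear_predictor(coeffs["new_faller"], pdf, bad, extra))
    fall_flag = rng.random(n) < p_fall
    recurrent = rng.negative_binomial(0.25, 0.25 / (0.25 + 1.0), n).astype(float)
    new_falls = 1.0 + rng.poisson(0.4, n)
    falls_w3 = np.where(falls_w1 > 0, recurrent, np.where(fall_flag, new_falls, 0.0))

    # --- MMSE ----------------------------------------------------------------
    deficit = rng.gamma(config.mmse_deficit_shape, config.mmse_deficit_scale, n)
    deficit = deficit + np.maximum(0.0, config.mmse_age_slope * (age - 65.0))
    mmse_w1 = np.clip(30 - np.round(deficit), 0, 30)
    p_mmse = expit(_linear_predictor(coeffs["mmse_decline"], pdf, bad, extra))
    mmse_flag = (rng.random(n) < p_mmse) & (mmse_w1 >= 2)
    drop = 2 + rng.poisson(0.8, n)
    drift = np.clip(np.round(rng.normal(0.1, 0.8, n)), -1, 2)
    mmse_w3 = np.where(mmse_flag, np.maximum(mmse_w1 - drop, 0), np.clip(mmse_w1 + drift, 0, 30))

    # --- missingness ---------------------------------------------------------
    cohort = pd.DataFrame(
        {
            "participant_id": pdf["participant_id"],
            "tug_w1": tug_w1,
            "tug_w3": tug_w3,
            "ugs_w1": ugs_w1,
            "ugs_w3": ugs_w3,
            "falls_w1": falls_w1,
            "falls_w3": falls_w3,
            "mmse_w1": mmse_w1,
            "mmse_w3": mmse_w3,
            "age": age,
            "sex": pdf["sex"],
            "education": pdf["education"],
            "anxiety": pdf["anxiety"],
            "depression": pdf["depression"],
            "antihypertensives": pdf["antihypertensives"].astype(int),
            "diabetes": pdf["diabetes"].astype(int),
            "smoking": pdf["smoking"],
            "drinking_problem": pdf["drinking_problem"],
            "ipaq": pdf["ipaq"],
        },
        columns=COHORT_COLUMNS,
    )
    lost = rng.random(n) < config.attrition_rate
    cohort.loc[lost, ["tug_w3", "ugs_w3", "falls_w3", "mmse_w3"]] = np.nan
    for col, rate in config.w1_missing_rates.items():
        cohort.loc[rng.random(n) < rate, col] = np.nan

    return streams, cohort


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)
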