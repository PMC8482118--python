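"""The statistical battery around the SART predictors.

Normality screening (Lilliefors-corrected Kolmogorov-Smirnov and
Shapiro-Wilk), nonparametric wave comparisons (Wilcoxon signed-rank,
Mann-Whitney U), binary logistic regression with Wald inference, Spearman
collinearity screening, the five-model suite per (predictor, outcome)
pair, and the three-predictor comparison table.

All confidence intervals are 95% Wald intervals on the log-odds scale,
exponentiated to the odds-ratio scale; p-values are two-sided Wald tests
per term.  Separation and rank deficiency fail loudly rather than being
silently penalised.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from . import outcomes as outc

logger = logging.getLogger(__name__)

__all__ = [
    "ModelResult",
    "SeparationError",
    "RankDeficiencyError",
    "normality_screen",
    "paired_wilcoxon",
    "mannwhitney_u",
    "fit_logistic",
    "collinearity_check",
    "run_model_suite",
    "compare_predictors",
    "group_slopes",
    "results_to_json",
]

ALPHA = 0.05


class SeparationError(RuntimeError):
    """Raised when the logistic likelihood is unbounded (separated data)."""


class RankDeficiencyError(ValueError):
    """Raised when the design matrix does not have full column rank."""


# ---------------------------------------------------------------------------
# distributional screens and nonparametric comparisons
# ---------------------------------------------------------------------------

def normality_screen(values: Sequence[float]) -> tuple[float, float, bool]:
    """(KS p, Shapiro-Wilk p, normal?) for one numeric vector.

    The KS test uses the Lilliefors correction (mean and SD estimated from
    the data).  The vector is declared normal only when both tests fail to
    reject at the 5% level.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError(f"normality screen needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("normality screen is undefined for a constant vector")
    _, ks_p = lilliefors(x, dist="norm")
    _, sw_p = stats.shapiro(x)
    return float(ks_p), float(sw_p), bool(ks_p >= ALPHA and sw_p >= ALPHA)


def paired_wilcoxon(w1: Sequence[float], w3: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon signed-rank test for two related samples (two-sided).

    Pairs with a missing value are dropped; zero differences are discarded
    (Wilcoxon's convention); the exact null distribution is used for up to
    25 nonzero, untied differences, otherwise the normal approximation
    with continuity correction.
    """
    a = np.asarray(w1, dtype=float)
    b = np.asarray(w3, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~np.isnan(a) & ~np.isnan(b)
    d = b[keep] - a[keep]
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"), method=method)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """One fitted logistic model: per-term OR, 95% CI and p-value."""

    model_id: str
    predictor: str
    outcome: str
    n_used: int
    terms: pd.DataFrame  # index: term; columns: estimate, or_, ci_low, ci_high, p
    converged: bool
    llf: float
    max_abs_spearman: float | None = None

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]

    @property
    def predictor_or(self) -> float:
        return float(self.terms.loc[self.predictor, "or_"])

    @property
    def predictor_ci(self) -> tuple[float, float]:
        row = self.terms.loc[self.predictor]
        return float(row["ci_low"]), float(row["ci_high"])

    @property
    def predictor_p(self) -> float:
        return float(self.terms.loc[self.predictor, "p"])


def fit_logistic(
    design: pd.DataFrame,
    outcome: Sequence[float],
    model_id: str = "",
    predictor: str = "",
    outcome_name: str = "",
) -> ModelResult:
    """Maximum-likelihood logistic fit with Wald 95% CIs per term.

    ``design`` must include its intercept column.  Raises
    :class:`RankDeficiencyError` for collinear designs and
    :class:`SeparationError` when a term perfectly predicts the outcome.
    """
    X = design.astype(float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.unique(y).size < 2:
        raise outc.DegenerateOutcomeError("outcome has a single class")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns "
            f"(most collinear pair: {X.columns[i]!r}, {X.columns[j]!r})"
        )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"separation detected in logistic fit: {exc}") from exc
    se = fit.bse
    big = se[se > 50].index.tolist()
    if big:
        raise SeparationError(
            f"quasi-separation suspected: unbounded standard error for column(s) {big}"
        )
    ci = fit.conf_int(alpha=ALPHA)
    terms = pd.DataFrame(
        {
            "estimate": fit.params,
            "or_": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": fit.pvalues,
        }
    )
    return ModelResult(
        model_id=str(model_id),
        predictor=str(predictor),
        outcome=str(outcome_name),
        n_used=int(len(y)),
        terms=terms,
        converged=bool(fit.mle_retvals.get("converged", True)),
        llf=float(fit.llf),
    )


def collinearity_check(design: pd.DataFrame, limit: float = 0.7) -> tuple[pd.DataFrame, bool]:
    """Pairwise Spearman correlations among non-intercept regressors.

    Returns the |rho| matrix and a pass flag: every off-diagonal |rho|
    below ``limit``.  The validation study reported max rho = 0.422; no
    published cut-off exists, so the limit is configurable and always
    reported alongside the flag.
    """
    X = design.drop(columns=[c for c in ("const", "intercept") if c in design.columns])
    if X.shape[1] < 2:
        raise ValueError("collinearity check needs at least 2 non-intercept columns")
    rho, _ = stats.spearmanr(X.to_numpy())
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    mat = pd.DataFrame(np.abs(rho), index=X.columns, columns=X.columns)
    off = mat.to_numpy().copy()
    np.fill_diagonal(off, 0.0)
    return mat, bool(np.nanmax(off) < limit)


# ---------------------------------------------------------------------------
# the model suite and predictor comparison
# ---------------------------------------------------------------------------

def run_model_suite(
    table: pd.DataFrame,
    predictor: str,
    outcome: str,
    models: Sequence[str] = outc.MODEL_IDS,
    baseline_impaired: str = "drop",
    collinearity_limit: float = 0.7,
) -> dict[str, ModelResult]:
    """Fit the nested logistic models for one (predictor, outcome) pair.

    Model 1 is the bare predictor; 2 adds mean/SD RT; 3 adds age, sex and
    education; 4 adds the remaining lifestyle/clinical covariates; 4a adds
    baseline gait speed.  Adjusted models are screened for collinearity.
    """
    results: dict[str, ModelResult] = {}
    for mid in models:
        X, y = outc.covariate_design(
            table, mid, predictor, outcome, baseline_impaired=baseline_impaired
        )
        try:
            res = fit_logistic(X, y, model_id=mid, predictor=predictor, outcome_name=outcome)
        except (SeparationError, RankDeficiencyError) as exc:
            raise type(exc)(f"model {mid} ({predictor} -> {outcome}): {exc}") from exc
        if X.shape[1] > 2:  # const + >=2 regressors
            mat, ok = collinearity_check(X, limit=collinearity_limit)
            off = mat.to_numpy().copy()
            np.fill_diagonal(off, 0.0)
            res.max_abs_spearman = float(np.nanmax(off))
            if not ok:
                logger.warning(
                    "model %s (%s -> %s): max |Spearman rho| = %.3f exceeds limit %.3f",
                    mid, predictor, outcome, res.max_abs_spearman, collinearity_limit,
                )
        logger.info(
            "model %s (%s -> %s): n=%d, OR=%.3f", mid, predictor, outcome,
            res.n_used, res.predictor_or,
        )
        results[mid] = res
    return results


def _ci_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return max(a[0], b[0]) <= min(a[1], b[1])


def compare_predictors(
    suites: Mapping[str, Mapping[str, ModelResult]],
) -> pd.DataFrame:
    """Side-by-side OR/CI/p table for the three candidate predictors.

    One row per model; CI-overlap flags are non-emptiness of the interval
    intersection for each predictor pair, significance flags use the 5%
    level.  ``suites`` maps predictor name -> model_id -> ModelResult.
    """
    predictors = list(suites)
    model_ids = list(next(iter(suites.values())))
    for p in predictors:
        if list(suites[p]) != model_ids:
            raise ValueError(f"predictor {p!r} is missing fits for some models")
    rows = []
    for mid in model_ids:
        row: dict[str, object] = {
            "outcome": suites[predictors[0]][mid].outcome,
            "model_id": mid,
        }
        for p in predictors:
            r = suites[p][mid]
            lo, hi = r.predictor_ci
            row[f"{p}_or"] = r.predictor_or
            row[f"{p}_ci_low"] = lo
            row[f"{p}_ci_high"] = hi
            row[f"{p}_p"] = r.predictor_p
            row[f"{p}_significant"] = r.predictor_p < ALPHA
        for a, b in combinations(predictors, 2):
            row[f"ci_overlap_{a}__{b}"] = _ci_overlap(
                suites[a][mid].predictor_ci, suites[b][mid].predictor_ci
            )
        rows.append(row)
    return pd.DataFrame(rows)


def group_slopes(table: pd.DataFrame, wave_interval: float = 1.0) -> dict[str, float]:
    """Mean TUG increment per wave interval, by bad-performance group.

    With two time points the slope of the between-wave increment equals
    the mean difference divided by the wave interval (one interval by
    default, i.e. slope in seconds per ~4-year wave gap).
    """
    d = (table["tug_w3"] - table["tug_w1"]).to_numpy(dtype=float)
    bad = table["bad_performances"].to_numpy(dtype=float) > 0
    keep = ~np.isnan(d)
    return {
        "good_only": float(np.mean(d[keep & ~bad])) / wave_interval,
        "any_bad": float(np.mean(d[keep & bad])) / wave_interval,
    }


def results_to_json(
    suites: Mapping[str, Mapping[str, ModelResult]],
    path: str | Path,
) -> None:
    """Write one record per (outcome, predictor, model) with OR, CI, p, n."""
    records = []
    for pred, models in suites.items():
        for mid, r in models.items():
            lo, hi = r.predictor_ci
            records.append(
                {
                    "outcome": r.outcome,
                    "predictor": pred,
                    "model_id": mid,
                    "n_used": r.n_used,
                    "or": r.predictor_or,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": r.predictor_p,
                    "converged": r.converged,
                    "max_abs_spearman": r.max_abs_spearman,
                }
            )
    Path(path).write_text(json.dumps(records, indent=2))
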