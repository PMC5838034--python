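"""Paired observed-vs-null contrasts and AICc-ranked abundance models.

The spatial statistics (R, shared-site proportion, MAD u) are compared with
their density-matched CSR null means by an intercept-only linear mixed model
on the per-unit paired differences, with a random intercept for plot and a
variance component for season nested within plot. When the mixed fit is
singular or the design too small, a seeded sign-flip randomization test on
the differences is used instead and flagged.

Seasonal abundance variation is described by five a priori candidate mean
structures — null, season, age-sex group, group + season, and the saturated
group x season model — fitted as Gaussian mixed models with a plot random
intercept by maximum likelihood and ranked by the small-sample Akaike
information criterion AICc with Akaike weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ComparisonResult",
    "ModelRank",
    "CANDIDATE_MODELS",
    "paired_contrast",
    "mc_rank_pvalue",
    "aicc",
    "akaike_weights",
    "rank_abundance_models",
]

logger = logging.getLogger(__name__)

#: The five candidate abundance mean structures.
CANDIDATE_MODELS = {
    "null": "count ~ 1",
    "season": "count ~ C(season)",
    "group": "count ~ C(group)",
    "group+season": "count ~ C(group) + C(season)",
    "group*season": "count ~ C(group) * C(season)",
}


@dataclass(frozen=True)
class ComparisonResult:
    """Paired observed-vs-null contrast for one statistic and class pair."""

    pair: str
    statistic_name: str
    mean_observed: float
    mean_null: float
    estimate: float  # mean paired difference (observed - null)
    p_value: float
    n_units: int
    method: str  # "mixed" or "randomization"


@dataclass(frozen=True)
class ModelRank:
    """One candidate model's AICc ranking entry."""

    model_name: str
    k: int
    aicc: float
    delta_aicc: float
    weight: float


def paired_contrast(
    observed: np.ndarray,
    null_means: np.ndarray,
    unit_keys: pd.DataFrame,
    pair: str = "",
    statistic_name: str = "",
    alternative: str = "two-sided",
    n_randomization: int = 9999,
    seed: int = 0,
) -> ComparisonResult:
    """Test whether observed statistics deviate from their CSR null means.

    Parameters
    ----------
    observed, null_means
        Per-unit observed values and matched mean null values (same order).
    unit_keys
        DataFrame with ``plot_id`` and a grouping column (``season`` or
        ``survey_date``) aligning each value with its sampling unit.
    alternative
        ``"two-sided"`` (default), or ``"greater"``/``"less"`` for one-tailed
        contrasts (the MAD statistic is tested one-tailed for aggregation).

    The intercept of the mixed model on differences estimates the mean
    paired difference; its Wald test against zero gives the p-value. With a
    singular or non-convergent fit, the fallback is a sign-flip
    randomization test on the unit differences.
    """
    observed = np.asarray(observed, dtype=float)
    null_means = np.asarray(null_means, dtype=float)
    if observed.shape != null_means.shape:
        raise ValueError("observed and null_means must align")
    if len(observed) < 2:
        raise ValueError("need >= 2 units for a paired contrast")
    diffs = observed - null_means
    group_col = "season" if "season" in unit_keys.columns else "survey_date"
    df = pd.DataFrame(
        {
            "diff": diffs,
            "plot": unit_keys["plot_id"].to_numpy(),
            "season": unit_keys[group_col].astype(str).to_numpy(),
        }
    )

    est = float(diffs.mean())
    method = "mixed"
    p = np.nan
    if np.allclose(diffs, diffs[0]):
        # degenerate: zero variance, mixed model cannot be fit
        method = "randomization"
    else:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model = smf.mixedlm(
                    "diff ~ 1",
                    df,
                    groups="plot",
                    vc_formula={"season": "0 + C(season)"},
                )
                fit = model.fit(reml=True)
            # a boundary (singular) fit yields an unreliable Wald SE
            singular = any(
                issubclass(w.category, ConvergenceWarning)
                or "singular" in str(w.message).lower()
                for w in caught
            )
            est = float(fit.params["Intercept"])
            p = float(fit.pvalues["Intercept"])
            if singular or not np.isfinite(p):
                method = "randomization"
        except Exception:  # singular fits raise from several layers
            method = "randomization"

    if method == "randomization":
        est = float(diffs.mean())
        p = _sign_flip_pvalue(diffs, n_randomization, seed)
        logger.info("paired_contrast fell back to randomization for %s/%s", pair, statistic_name)

    p = _apply_tail(p, est, alternative)
    return ComparisonResult(
        pair=pair,
        statistic_name=statistic_name,
        mean_observed=float(observed.mean()),
        mean_null=float(null_means.mean()),
        estimate=est,
        p_value=float(np.clip(p, 0.0, 1.0)),
        n_units=len(observed),
        method=method,
    )


def _sign_flip_pvalue(diffs: np.ndarray, n: int, seed: int) -> float:
    """Two-sided sign-flip randomization p-value for mean difference = 0."""
    if np.allclose(diffs, 0.0):
        return 1.0
    rng = np.random.default_rng(seed)
    obs = abs(diffs.mean())
    signs = rng.choice([-1.0, 1.0], size=(n, len(diffs)))
    null = np.abs((signs * diffs).mean(axis=1))
    return (1.0 + np.count_nonzero(null >= obs)) / (n + 1.0)


def _apply_tail(p_two_sided: float, estimate: float, alternative: str) -> float:
    if alternative == "two-sided":
        return p_two_sided
    favored = estimate > 0 if alternative == "greater" else estimate < 0
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    return p_two_sided / 2.0 if favored else 1.0 - p_two_sided / 2.0


def mc_rank_pvalue(observed: float, null_values: np.ndarray) -> float:
    """One-tailed Monte-Carlo rank p-value for a goodness-of-fit statistic.

    ``p = (1 + #{null >= observed}) / (1 + n_null)`` — the standard
    envelope-test rank for a statistic (such as the MAD u) whose large
    values indicate departure from the null. Exact under exchangeability of
    the observed and null replicates.
    """
    null_values = np.asarray(null_values, dtype=float)
    return float((1 + np.count_nonzero(null_values >= observed)) / (1 + null_values.size))


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    ``AICc = -2 log L + 2k + 2k(k+1)/(n - k - 1)``; undefined when
    ``n <= k + 1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    """Normalized relative likelihoods ``exp(-delta/2) / sum``."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    rel = np.exp(-0.5 * delta)
    return rel / rel.sum()


def rank_abundance_models(abundance: pd.DataFrame) -> pd.DataFrame:
    """Fit and AICc-rank the five candidate abundance models.

    ``abundance`` is the per-(plot, season, group) count table. Each mean
    structure is fitted as a Gaussian linear mixed model with a plot random
    intercept, by maximum likelihood so likelihoods are comparable across
    mean structures. k counts fixed effects plus the random-intercept and
    residual variances.
    """
    if abundance["plot_id"].nunique() < 2:
        raise ValueError("need >= 2 plots for the plot random effect")
    n = len(abundance)
    rows = []
    for name, formula in CANDIDATE_MODELS.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, abundance, groups="plot_id")
                fit = model.fit(reml=False)
            if not np.isfinite(fit.llf):
                raise ValueError(f"non-finite likelihood ({fit.llf})")
            k = int(model.k_fe) + 2  # fixed effects + random-intercept var + residual var
            rows.append({"model_name": name, "k": k, "loglik": float(fit.llf)})
        except Exception as exc:
            logger.warning("model %s unestimable, dropped: %s", name, exc)
    ranks = pd.DataFrame(rows)
    ranks["aicc"] = [aicc(r.loglik, r.k, n) for r in ranks.itertuples()]
    ranks["delta_aicc"] = ranks["aicc"] - ranks["aicc"].min()
    ranks["weight"] = akaike_weights(ranks["aicc"].to_numpy())
    return ranks.sort_values("aicc", kind="mergesort").reset_index(drop=True)
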