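"""End-to-end orchestration: captures in, contrast tables and rankings out.

The full analysis chain is: validate captures -> pool into seasons -> apply
the minimum-capture subset -> classify migrant/resident cohorts -> seasonal
centroids -> per-unit spatial statistics (Clark–Evans R and MAD u per
plot-season, shared-site proportion per plot-survey) -> density-matched CSR
null ensembles -> paired mixed-model contrasts -> AICc-ranked abundance
models.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .capture_data import DEFAULT_GEOMETRY, DEFAULT_SEASONS, PlotGeometry, SeasonWindow
from .cohort_builder import (
    abundance_table,
    assign_seasons,
    classify_cohorts,
    seasonal_centroids,
    subset_min_captures,
)
from .inference import paired_contrast, rank_abundance_models
from .null_models import DEFAULT_N_REPLICATES, null_statistics
from .point_pattern import (
    clark_evans_r,
    default_r_grid,
    estimate_g,
    mad_statistic,
)
from .shared_sites import survey_shared_sites

__all__ = [
    "PAPER_PAIRS",
    "COMBINED_PAIR",
    "pair_label",
    "unit_statistics",
    "run_contrasts",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)

#: The six migrant-resident class pairs analysed throughout.
PAPER_PAIRS: list[tuple] = [
    ("J", "RF"),
    ("J", "RM"),
    ("MF", "RF"),
    ("MF", "RM"),
    ("MM", "RF"),
    ("MM", "RM"),
]

#: All migrant classes against all resident classes, pooled.
COMBINED_PAIR: tuple = (("J", "MF", "MM"), ("RF", "RM"))


def pair_label(pair: tuple) -> str:
    def side(s):
        return s if isinstance(s, str) else ",".join(s)

    return f"{side(pair[0])}-{side(pair[1])}"


def _classes(side) -> list[str]:
    return [side] if isinstance(side, str) else list(side)


def unit_statistics(
    centroids: pd.DataFrame,
    pairs: Sequence[tuple],
    geometry: PlotGeometry = DEFAULT_GEOMETRY,
    r_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Observed R and MAD u per (plot, season, pair).

    Units where either class of the pair has no centroid are skipped (the
    statistics are undefined there); a unit needs >= 1 focal and >= 1
    reference individual.
    """
    if r_grid is None:
        r_grid = default_r_grid(geometry)
    rows = []
    for (plot, season), sub in centroids.groupby(["plot_id", "season"], sort=True):
        pts = sub[["x", "y"]].to_numpy()
        coh = sub["cohort"].to_numpy()
        for pair in pairs:
            f = pts[np.isin(coh, _classes(pair[0]))]
            t = pts[np.isin(coh, _classes(pair[1]))]
            if len(f) == 0 or len(t) == 0:
                continue
            rv = clark_evans_r(f, t, geometry, same_pattern=False)
            est = estimate_g(f, t, geometry, r_grid, same_pattern=False)
            mad = mad_statistic(est.g_hat, est.g_theo, est.r_grid)
            rows.append(
                {
                    "plot_id": plot,
                    "season": season,
                    "pair": pair_label(pair),
                    "n_from": rv.n_from,
                    "n_to": rv.n_to,
                    "mean_observed_nnd": rv.mean_observed_nnd,
                    "expected_nnd": rv.expected_nnd,
                    "R": rv.r_value,
                    "MAD_u": mad.u_statistic,
                    "argmax_r": mad.argmax_r,
                    "direction": mad.direction,
                }
            )
    return pd.DataFrame(rows)


def run_contrasts(
    captures: pd.DataFrame,
    seasons: Sequence[SeasonWindow] = DEFAULT_SEASONS,
    pairs: Sequence[tuple] = (COMBINED_PAIR,),
    geometry: PlotGeometry = DEFAULT_GEOMETRY,
    min_captures: int = 3,
    n_null_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    denominator: str = "pair",
    jitter: bool = False,
) -> pd.DataFrame:
    """Observed-vs-null paired contrasts for R, MAD u and shared sites.

    Returns one row per (statistic, pair) with the contrast estimate, its
    p-value (two-sided for R and shared sites, one-tailed for aggregation
    for MAD u), unit count and fit method. ``jitter`` turns on the seeded
    uniform within-cell jitter of capture locations (sensitivity switch for
    the cell-resolution coincidence artifact; off by default).
    """
    captures = assign_seasons(captures, seasons)
    subset, _ = subset_min_captures(captures, min_captures)
    cohorts = classify_cohorts(subset, seasons)
    cents = seasonal_centroids(
        subset, cohorts, seasons, geometry, jitter_seed=seed if jitter else None
    )
    stats = unit_statistics(cents, pairs, geometry)
    r_grid = default_r_grid(geometry)

    results = []
    for pair in pairs:
        label = pair_label(pair)
        sub = stats[stats["pair"] == label]
        for stat, alternative in (("R", "two-sided"), ("MAD_u", "greater")):
            if len(sub) < 2:
                continue
            null_means = []
            for r in sub.itertuples():
                ens = null_statistics(
                    (r.plot_id, r.season, label),
                    stat,
                    n_from=r.n_from,
                    n_to=r.n_to,
                    n_replicates=n_null_replicates,
                    seed=seed,
                    window=geometry,
                    r_grid=r_grid,
                )
                null_means.append(ens.mean)
            res = paired_contrast(
                sub[stat].to_numpy(),
                np.asarray(null_means),
                sub[["plot_id", "season"]],
                pair=label,
                statistic_name=stat,
                alternative=alternative,
                seed=seed,
            )
            results.append(res)

    shared = _shared_site_contrasts(
        subset, cohorts, pairs, geometry, n_null_replicates, seed, denominator
    )
    results.extend(shared)

    return pd.DataFrame(
        {
            "statistic": [r.statistic_name for r in results],
            "pair": [r.pair for r in results],
            "mean_observed": [r.mean_observed for r in results],
            "mean_null": [r.mean_null for r in results],
            "estimate": [r.estimate for r in results],
            "p_value": [r.p_value for r in results],
            "n_units": [r.n_units for r in results],
            "method": [r.method for r in results],
        }
    )


def _shared_site_contrasts(
    subset, cohorts, pairs, geometry, n_null_replicates, seed, denominator
):
    merged = subset.merge(
        cohorts[["individual_id", "plot_id", "season", "cohort"]],
        on=["individual_id", "plot_id", "season"],
        how="inner",
    )
    out = []
    shared = survey_shared_sites(merged, list(pairs), denominator=denominator)
    if shared.empty:
        return out
    season_of = merged.drop_duplicates(["plot_id", "survey_date"])[
        ["plot_id", "survey_date", "season"]
    ]
    shared = shared.merge(season_of, on=["plot_id", "survey_date"], how="left")
    for pair in pairs:
        label = pair_label(pair)
        sub = shared[(shared["pair"] == label) & shared["defined"]]
        a_cls, b_cls = _classes(pair[0]), _classes(pair[1])
        obs, nulls, keys = [], [], []
        for r in sub.itertuples():
            day = merged[
                (merged["plot_id"] == r.plot_id) & (merged["survey_date"] == r.survey_date)
            ].drop_duplicates("individual_id")
            n_a = int(day["cohort"].isin(a_cls).sum())
            n_b = int(day["cohort"].isin(b_cls).sum())
            if n_a < 1 or n_b < 1:
                continue
            ens = null_statistics(
                (r.plot_id, str(r.survey_date), label),
                "shared_proportion",
                n_from=n_a,
                n_to=n_b,
                n_replicates=n_null_replicates,
                seed=seed,
                window=geometry,
            )
            obs.append(r.proportion)
            nulls.append(ens.mean)
            keys.append((r.plot_id, r.season))
        if len(obs) < 2:
            continue
        out.append(
            paired_contrast(
                np.asarray(obs),
                np.asarray(nulls),
                pd.DataFrame(keys, columns=["plot_id", "season"]),
                pair=label,
                statistic_name="shared_proportion",
                alternative="two-sided",
                seed=seed,
            )
        )
    return out


def run_full_pipeline(
    captures: pd.DataFrame,
    seasons: Sequence[SeasonWindow] = DEFAULT_SEASONS,
    pairs: Sequence[tuple] | None = None,
    geometry: PlotGeometry = DEFAULT_GEOMETRY,
    min_captures: int = 3,
    n_null_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    denominator: str = "pair",
    jitter: bool = False,
) -> dict:
    """Run every analysis stage and return a result bundle.

    The bundle maps stage names to tidy DataFrames/dicts: dataset summary,
    cohort assignments, seasonal centroids, per-unit spatial statistics,
    paired contrasts per class pair, and the AICc abundance-model ranking.
    Deterministic given the seed.
    """
    if pairs is None:
        pairs = [*PAPER_PAIRS, COMBINED_PAIR]
    captures = assign_seasons(captures, seasons)
    subset, summary = subset_min_captures(captures, min_captures)
    cohorts = classify_cohorts(subset, seasons)
    cents = seasonal_centroids(
        subset, cohorts, seasons, geometry, jitter_seed=seed if jitter else None
    )
    stats = unit_statistics(cents, pairs, geometry)
    contrasts = run_contrasts(
        captures,
        seasons=seasons,
        pairs=pairs,
        geometry=geometry,
        min_captures=min_captures,
        n_null_replicates=n_null_replicates,
        seed=seed,
        denominator=denominator,
        jitter=jitter,
    )
    abundance = abundance_table(
        cohorts, seasons=[w.label for w in seasons]
    )
    try:
        ranking = rank_abundance_models(abundance)
    except ValueError as exc:
        logger.warning("abundance ranking skipped: %s", exc)
        ranking = pd.DataFrame()
    return {
        "summary": summary,
        "cohorts": cohorts,
        "centroids": cents,
        "unit_statistics": stats,
        "contrasts": contrasts,
        "abundance": abundance,
        "model_ranking": ranking,
        "seed": seed,
    }


def report_text(bundle: dict) -> str:
    """Plain-text run report summarising every contrast and ranking."""
    s = bundle["summary"]
    lines = [
        "markspat run report",
        "===================",
        f"full dataset: {s['n_captures_full']} captures of {s['n_individuals_full']} individuals",
        f"subsetted (>= {s['min_captures']} captures): {s['n_captures_subset']} captures of "
        f"{s['n_individuals_subset']} individuals",
        "",
        "paired observed-vs-null contrasts",
        "---------------------------------",
    ]
    c = bundle["contrasts"]
    if len(c):
        lines.append(c.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    if len(bundle["model_ranking"]):
        lines += [
            "",
            "abundance model ranking (AICc)",
            "------------------------------",
            bundle["model_ranking"].to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
    lines.append("")
    lines.append(f"seed: {bundle['seed']}")
    return "\n".join(lines)
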