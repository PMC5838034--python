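"""Season pooling, migrant/resident cohort classification, and summaries.

Captures are pooled into multi-month seasonal windows. Within each plot and
season every individual receives one cohort label:

* ``J``  - juvenile (every capture that season below the 19 mm SVL maturity
  threshold); all juveniles are treated as migrants, having only recently
  entered the population.
* ``RF`` / ``RM`` - resident adult female/male: observed in the same plot in
  the immediately preceding season (or present in the first season, where
  tenure cannot be assessed and all adults default to resident).
* ``MF`` / ``MM`` - migrant adult female/male: an adult with no capture in
  that plot the season before.

A juvenile that matures stays resident if it remains in the same plot,
because its juvenile captures count as presence the previous season.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .capture_data import (
    DEFAULT_GEOMETRY,
    DEFAULT_SEASONS,
    PlotGeometry,
    SeasonWindow,
    cell_centers,
)

__all__ = [
    "MATURITY_SVL_MM",
    "assign_seasons",
    "maturity_class",
    "classify_cohorts",
    "subset_min_captures",
    "seasonal_centroids",
    "abundance_table",
]

logger = logging.getLogger(__name__)

#: Snout-vent length threshold (mm) separating juveniles from adults.
MATURITY_SVL_MM = 19.0

MIGRANT_COHORTS = ("J", "MF", "MM")
RESIDENT_COHORTS = ("RF", "RM")


def maturity_class(svl_mm: float) -> str:
    """Age class from snout-vent length: ``juvenile`` below 19 mm, else ``adult``."""
    if svl_mm <= 0:
        raise ValueError(f"svl_mm must be > 0, got {svl_mm}")
    return "juvenile" if svl_mm < MATURITY_SVL_MM else "adult"


def assign_seasons(
    captures: pd.DataFrame, windows: Sequence[SeasonWindow] = DEFAULT_SEASONS
) -> pd.DataFrame:
    """Annotate each capture with the label of the season window containing it.

    Every capture date must fall in exactly one window; a date outside all
    windows raises with the offending date named.
    """
    labels = {}
    for w in windows:
        for ym in w.months():
            if ym in labels:
                raise ValueError(f"season windows overlap at {ym[0]}-{ym[1]:02d}")
            labels[ym] = w.label
    dates = pd.to_datetime(captures["survey_date"])
    keys = list(zip(dates.dt.year, dates.dt.month))
    season = [labels.get(k) for k in keys]
    if any(s is None for s in season):
        i = season.index(None)
        raise ValueError(
            f"capture date {captures['survey_date'].iloc[i]} falls outside all season windows"
        )
    out = captures.copy()
    out["season"] = season
    return out


def classify_cohorts(
    captures: pd.DataFrame, windows: Sequence[SeasonWindow] = DEFAULT_SEASONS
) -> pd.DataFrame:
    """One cohort label per (individual, plot, season).

    Parameters
    ----------
    captures
        Capture table; a ``season`` column is added via :func:`assign_seasons`
        if absent.
    windows
        Ordered season windows defining "the previous season".

    Returns
    -------
    DataFrame with columns ``individual_id, plot_id, season, cohort,
    n_captures_in_season``. Adults whose sex marker is unknown cannot be
    assigned to a sex-specific cohort and are excluded (logged).
    """
    if "season" not in captures.columns:
        captures = assign_seasons(captures, windows)
    order = {w.label: i for i, w in enumerate(windows)}
    unknown = []
    rows = []

    grp = captures.groupby(["individual_id", "plot_id", "season"], sort=False)
    summary = grp.agg(
        n=("survey_date", "size"),
        max_svl=("svl_mm", "max"),
        sexes=("sex", lambda s: tuple(s)),
        svls=("svl_mm", lambda s: tuple(s)),
    ).reset_index()
    summary["season_idx"] = summary["season"].map(order)
    summary = summary.sort_values(["individual_id", "plot_id", "season_idx"], kind="mergesort")

    # presence lookup: (individual, plot) -> set of season indices observed
    presence: dict[tuple[str, str], set[int]] = {}
    for (ind, plot), sub in summary.groupby(["individual_id", "plot_id"], sort=False):
        presence[(ind, plot)] = set(sub["season_idx"])

    # first adult-stage sex per (individual, plot): sex recorded at the first
    # capture with SVL >= threshold, scanning in chronological season order
    for _, r in summary.iterrows():
        ind, plot, season = r["individual_id"], r["plot_id"], r["season"]
        if r["max_svl"] < MATURITY_SVL_MM:
            rows.append((ind, plot, season, "J", r["n"]))
            continue
        sex = _adult_sex(summary, ind, plot)
        if sex not in ("M", "F"):
            unknown.append((ind, plot, season))
            continue
        s_idx = r["season_idx"]
        resident = s_idx == 0 or (s_idx - 1) in presence[(ind, plot)]
        tag = ("R" if resident else "M") + sex
        rows.append((ind, plot, season, tag, r["n"]))

    if unknown:
        logger.warning(
            "%d adult plot-season records with unknown sex excluded from cohorts: %s",
            len(unknown),
            unknown[:5],
        )
    return pd.DataFrame(
        rows, columns=["individual_id", "plot_id", "season", "cohort", "n_captures_in_season"]
    )


def _adult_sex(summary: pd.DataFrame, ind: str, plot: str) -> str:
    sub = summary[(summary["individual_id"] == ind) & (summary["plot_id"] == plot)]
    for _, r in sub.iterrows():
        for svl, sex in zip(r["svls"], r["sexes"]):
            if svl >= MATURITY_SVL_MM:
                return sex
    return "U"


def subset_min_captures(captures: pd.DataFrame, k: int = 3):
    """Restrict to individuals captured at least ``k`` times study-wide.

    Removes transient individuals whose tenure was too brief to carry
    spatial information. Returns ``(filtered, summary)`` where summary holds
    the full and filtered dataset sizes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = captures.groupby("individual_id")["survey_date"].transform("size")
    keep = counts >= k
    filtered = captures[keep].reset_index(drop=True)
    summary = {
        "n_individuals_full": int(captures["individual_id"].nunique()),
        "n_captures_full": int(len(captures)),
        "n_individuals_subset": int(filtered["individual_id"].nunique()),
        "n_captures_subset": int(len(filtered)),
        "min_captures": int(k),
    }
    return filtered, summary


def seasonal_centroids(
    captures: pd.DataFrame,
    cohorts: pd.DataFrame | None = None,
    windows: Sequence[SeasonWindow] = DEFAULT_SEASONS,
    geometry: PlotGeometry = DEFAULT_GEOMETRY,
    jitter_seed: int | None = None,
) -> pd.DataFrame:
    """Mean centroid of space use per individual, plot and season.

    The centroid is the arithmetic mean of the centres of the cells in which
    the individual was captured that plot-season — the canonical point
    location at the data's native (cell) resolution. Because locations are
    only known to the cell, distinct individuals can receive identical
    centroids; ``jitter_seed`` enables a seeded uniform within-cell jitter
    of each capture location as a sensitivity switch (off by default).
    """
    if "season" not in captures.columns:
        captures = assign_seasons(captures, windows)
    if cohorts is None:
        cohorts = classify_cohorts(captures, windows)
    xy = cell_centers(captures["cell_row"].to_numpy(), captures["cell_col"].to_numpy(), geometry)
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        xy = xy + rng.uniform(
            -geometry.cell_size / 2, geometry.cell_size / 2, size=xy.shape
        )
    df = captures[["individual_id", "plot_id", "season"]].copy()
    df["x"] = xy[:, 0]
    df["y"] = xy[:, 1]
    cent = (
        df.groupby(["individual_id", "plot_id", "season"], sort=False)[["x", "y"]]
        .mean()
        .reset_index()
    )
    cent = cent.merge(
        cohorts[["individual_id", "plot_id", "season", "cohort"]],
        on=["individual_id", "plot_id", "season"],
        how="inner",
    )
    return cent.sort_values(
        ["plot_id", "season", "individual_id"], kind="mergesort"
    ).reset_index(drop=True)


def abundance_table(
    cohorts: pd.DataFrame,
    plots: Sequence[str] | None = None,
    seasons: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Distinct individuals per (plot, season) in each age-sex group.

    Groups partition the classified individuals: ``juvenile`` = J cohort,
    ``female`` = MF + RF, ``male`` = MM + RM. Plot-seasons with no captures
    get explicit zero counts when ``plots``/``seasons`` enumerate the frame.
    """
    group_of = {"J": "juvenile", "MF": "female", "RF": "female", "MM": "male", "RM": "male"}
    df = cohorts.copy()
    df["group"] = df["cohort"].map(group_of)
    counts = (
        df.groupby(["plot_id", "season", "group"])["individual_id"].nunique().rename("count")
    )
    plots = sorted(df["plot_id"].unique()) if plots is None else list(plots)
    seasons = sorted(df["season"].unique()) if seasons is None else list(seasons)
    idx = pd.MultiIndex.from_product(
        [plots, seasons, ["juvenile", "female", "male"]], names=["plot_id", "season", "group"]
    )
    out = counts.reindex(idx, fill_value=0).reset_index()
    out["count"] = out["count"].astype(int)
    return out
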