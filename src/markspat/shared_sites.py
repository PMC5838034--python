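"""Per-survey grid-cell co-occupancy between migrant and resident classes.

The shared-site proportion for a focal class pair on one survey is the
number of grid cells holding at least one individual of *each* class of the
pair, divided by the number of cells occupied by at least one individual of
*either* class. It is the discrete, survey-scale analogue of home-range
overlap at the grid's native resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capture_data import DEFAULT_GEOMETRY, PlotGeometry

__all__ = [
    "SharedSiteResult",
    "shared_site_proportion",
    "survey_shared_sites",
    "null_shared_expectation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SharedSiteResult:
    """Co-occupancy of one class pair on one (plot, survey)."""

    plot_id: str
    survey_date: object
    pair: tuple[str, str]
    n_shared_cells: int
    n_occupied_cells: int

    @property
    def proportion(self) -> float:
        """Shared / occupied; NaN when no cell is occupied (undefined)."""
        if self.n_occupied_cells == 0:
            return float("nan")
        return self.n_shared_cells / self.n_occupied_cells

    @property
    def defined(self) -> bool:
        return self.n_occupied_cells > 0


def _normalize_classes(cls) -> set[str]:
    return {cls} if isinstance(cls, str) else set(cls)


def shared_site_proportion(
    survey_captures: pd.DataFrame,
    pair: tuple,
    denominator: str = "pair",
) -> SharedSiteResult:
    """Shared-site proportion for one class pair on one (plot, survey).

    Parameters
    ----------
    survey_captures
        Captures of a single plot and survey date, carrying a ``cohort``
        column; an individual captured more than once that survey counts
        once, at its first recorded cell.
    pair
        ``(focal_classes, reference_classes)``; each side may be a single
        cohort label or a set of labels (e.g. ``("J", "RF")`` or
        ``({"J","MF","MM"}, {"RF","RM"})``). Cells holding both sides count
        as shared; same-class co-occupancy does not.
    denominator
        ``"pair"`` (default) counts cells occupied by either class of the
        pair; ``"all"`` counts cells occupied by any classified individual.
    """
    plots = survey_captures["plot_id"].unique()
    dates = survey_captures["survey_date"].unique()
    if len(plots) > 1 or len(dates) > 1:
        raise ValueError("survey_captures must cover exactly one (plot, survey)")
    a_classes, b_classes = (_normalize_classes(c) for c in pair)

    first = survey_captures.drop_duplicates("individual_id", keep="first")
    cells = list(zip(first["cell_row"], first["cell_col"]))
    coh = first["cohort"].to_numpy()
    cells_a = {c for c, k in zip(cells, coh) if k in a_classes}
    cells_b = {c for c, k in zip(cells, coh) if k in b_classes}
    if denominator == "pair":
        occupied = cells_a | cells_b
    elif denominator == "all":
        occupied = set(cells)
    else:
        raise ValueError("denominator must be 'pair' or 'all'")
    shared = cells_a & cells_b
    res = SharedSiteResult(
        plot_id=str(plots[0]) if len(plots) else "",
        survey_date=dates[0] if len(dates) else None,
        pair=(",".join(sorted(a_classes)), ",".join(sorted(b_classes))),
        n_shared_cells=len(shared),
        n_occupied_cells=len(occupied),
    )
    if not res.defined:
        logger.info("no occupied cells for pair %s on %s/%s", pair, res.plot_id, res.survey_date)
    return res


def survey_shared_sites(
    captures_with_cohorts: pd.DataFrame,
    pairs: list[tuple],
    denominator: str = "pair",
) -> pd.DataFrame:
    """Shared-site proportions for every (plot, survey, pair).

    Input is a capture table joined with cohort labels. Surveys where a pair
    occupies no cells are emitted with NaN proportion and flagged undefined
    so averages can exclude them.
    """
    rows = []
    for (plot, date), sub in captures_with_cohorts.groupby(["plot_id", "survey_date"], sort=True):
        for pair in pairs:
            r = shared_site_proportion(sub, pair, denominator=denominator)
            rows.append(
                {
                    "plot_id": plot,
                    "survey_date": date,
                    "pair": f"{r.pair[0]}-{r.pair[1]}",
                    "n_shared_cells": r.n_shared_cells,
                    "n_occupied_cells": r.n_occupied_cells,
                    "proportion": r.proportion,
                    "defined": r.defined,
                }
            )
    return pd.DataFrame(rows)


def null_shared_expectation(
    n_a: int,
    n_b: int,
    n_cells: int = DEFAULT_GEOMETRY.n_cells,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo mean shared-site proportion under random cell assignment.

    Each of the ``n_a + n_b`` individuals independently occupies a uniformly
    random cell (multinomial placement, the discrete analogue of
    density-matched CSR); the proportion is averaged over replicates,
    excluding the undefined zero-occupancy case (impossible unless both
    counts are zero). Returns NaN when either class is absent.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be nonnegative")
    if n_a == 0 or n_b == 0:
        return float("nan")
    rng = np.random.default_rng() if rng is None else rng
    cells_a = rng.integers(0, n_cells, size=(reps, n_a))
    cells_b = rng.integers(0, n_cells, size=(reps, n_b))
    props = np.empty(reps)
    for i in range(reps):
        a, b = set(cells_a[i]), set(cells_b[i])
        props[i] = len(a & b) / len(a | b)
    return float(props.mean())
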