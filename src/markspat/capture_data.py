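"""Domain types and I/O for gridded mark-recapture capture histories.

The sampling frame is a small rectangular plot divided into a regular grid
of square cells; each capture event records who was caught, in which plot
and cell, on which date, and the animal's snout-vent length (SVL) and sex.
Capture tables are plain comma-delimited text with one capture per row,
the lossless, streamable representation of a capture history.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlotGeometry",
    "SeasonWindow",
    "DEFAULT_GEOMETRY",
    "DEFAULT_SEASONS",
    "CAPTURE_COLUMNS",
    "read_captures",
    "write_captures",
    "validate_captures",
    "cell_center",
    "cell_centers",
]

#: Required columns of a capture table, in canonical order.
CAPTURE_COLUMNS = [
    "individual_id",
    "plot_id",
    "survey_date",
    "cell_row",
    "cell_col",
    "svl_mm",
    "mass_g",
    "sex",
]

_VALID_SEX = frozenset({"M", "F", "U"})


@dataclass(frozen=True)
class PlotGeometry:
    """Rectangular survey plot divided into a regular grid of square cells.

    Defaults describe a 12 m x 9 m plot of forty-eight 1.5 m x 1.5 m cells
    (8 columns x 6 rows).
    """

    width: float = 12.0
    height: float = 9.0
    cell_size: float = 1.5

    def __post_init__(self) -> None:
        nc, nr = self.n_cols, self.n_rows
        if not (
            np.isclose(nc * self.cell_size, self.width)
            and np.isclose(nr * self.cell_size, self.height)
        ):
            raise ValueError(
                "cell_size must tile the window exactly: "
                f"{self.width} x {self.height} with cell {self.cell_size}"
            )

    @property
    def n_cols(self) -> int:
        return int(round(self.width / self.cell_size))

    @property
    def n_rows(self) -> int:
        return int(round(self.height / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def area(self) -> float:
        """Window area A in m^2."""
        return self.width * self.height

    @property
    def perimeter(self) -> float:
        """Window perimeter P in m."""
        return 2.0 * (self.width + self.height)


DEFAULT_GEOMETRY = PlotGeometry()


@dataclass(frozen=True)
class SeasonWindow:
    """A contiguous run of calendar months treated as one pooling season."""

    label: str
    start: tuple[int, int]  # (year, month), inclusive
    end: tuple[int, int]  # (year, month), inclusive

    def __post_init__(self) -> None:
        if self._key(self.start) > self._key(self.end):
            raise ValueError(f"season {self.label!r}: start after end")

    @staticmethod
    def _key(ym: tuple[int, int]) -> int:
        y, m = ym
        if not 1 <= m <= 12:
            raise ValueError(f"month out of range: {m}")
        return y * 12 + (m - 1)

    def contains(self, date: _dt.date) -> bool:
        return self._key(self.start) <= self._key((date.year, date.month)) <= self._key(self.end)

    def months(self) -> list[tuple[int, int]]:
        """All (year, month) pairs covered by the window."""
        a, b = self._key(self.start), self._key(self.end)
        return [(k // 12, k % 12 + 1) for k in range(a, b + 1)]


#: Five seasonal pooling windows spanning the Feb 1982 - Aug 1983 study frame:
#: 1982 dry season, first/second halves of the 1982 wet season, 1983 dry
#: season, and the start of the 1983 wet season.
DEFAULT_SEASONS: tuple[SeasonWindow, ...] = (
    SeasonWindow("dry-1982", (1982, 2), (1982, 5)),
    SeasonWindow("wet1-1982", (1982, 6), (1982, 9)),
    SeasonWindow("wet2-1982", (1982, 10), (1983, 1)),
    SeasonWindow("dry-1983", (1983, 2), (1983, 5)),
    SeasonWindow("wet1-1983", (1983, 6), (1983, 8)),
)


def cell_center(
    cell_row: int, cell_col: int, geometry: PlotGeometry = DEFAULT_GEOMETRY
) -> tuple[float, float]:
    """Planar coordinates (x, y) in metres of the centre of a grid cell.

    Cell indices are 0-based; x runs along columns, y along rows, so cell
    (0, 0) of the default geometry is centred at (0.75, 0.75).
    """
    if not (0 <= cell_row < geometry.n_rows):
        raise ValueError(f"cell_row {cell_row} outside [0, {geometry.n_rows})")
    if not (0 <= cell_col < geometry.n_cols):
        raise ValueError(f"cell_col {cell_col} outside [0, {geometry.n_cols})")
    return ((cell_col + 0.5) * geometry.cell_size, (cell_row + 0.5) * geometry.cell_size)


def cell_centers(
    cell_rows: np.ndarray, cell_cols: np.ndarray, geometry: PlotGeometry = DEFAULT_GEOMETRY
) -> np.ndarray:
    """Vectorised :func:`cell_center`; returns an (n, 2) array of (x, y)."""
    rows = np.asarray(cell_rows, dtype=int)
    cols = np.asarray(cell_cols, dtype=int)
    if rows.size and (rows.min() < 0 or rows.max() >= geometry.n_rows):
        raise ValueError(f"cell_row outside [0, {geometry.n_rows})")
    if cols.size and (cols.min() < 0 or cols.max() >= geometry.n_cols):
        raise ValueError(f"cell_col outside [0, {geometry.n_cols})")
    return np.column_stack(
        [(cols + 0.5) * geometry.cell_size, (rows + 0.5) * geometry.cell_size]
    )


class CaptureValidationError(ValueError):
    """A capture row violates the plot geometry or field invariants."""


def validate_captures(df: pd.DataFrame, geometry: PlotGeometry = DEFAULT_GEOMETRY) -> pd.DataFrame:
    """Validate and canonicalise a capture table.

    Checks column presence, date parseability, 0-based cell indices against
    the geometry, positive SVL, and the sex marker domain {M, F, U}; returns
    a copy sorted by (plot, date, individual). Row numbers in error messages
    are 0-based positions in the input frame.
    """
    missing = [c for c in CAPTURE_COLUMNS if c not in df.columns and c != "mass_g"]
    if missing:
        raise CaptureValidationError(f"missing required columns: {missing}")
    out = df.copy()
    if "mass_g" not in out.columns:
        out["mass_g"] = np.nan

    dates = pd.to_datetime(out["survey_date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        i = int(np.flatnonzero(dates.isna())[0])
        raise CaptureValidationError(
            f"row {i}: malformed survey_date {out['survey_date'].iloc[i]!r} (ISO-8601 required)"
        )
    out["survey_date"] = dates.dt.date

    for col, bound in (("cell_row", geometry.n_rows), ("cell_col", geometry.n_cols)):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0) | (vals >= bound)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CaptureValidationError(
                f"row {i}: {col}={out[col].iloc[i]!r} outside [0, {bound})"
            )
        out[col] = vals.astype(int)

    svl = pd.to_numeric(out["svl_mm"], errors="coerce")
    bad = svl.isna() | (svl <= 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise CaptureValidationError(f"row {i}: svl_mm={out['svl_mm'].iloc[i]!r} must be > 0")
    out["svl_mm"] = svl.astype(float)
    out["mass_g"] = pd.to_numeric(out["mass_g"], errors="coerce")

    sex = out["sex"].astype(str).str.upper()
    bad = ~sex.isin(_VALID_SEX)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CaptureValidationError(
            f"row {i}: sex={out['sex'].iloc[i]!r} not in {sorted(_VALID_SEX)}"
        )
    out["sex"] = sex
    out["individual_id"] = out["individual_id"].astype(str)
    out["plot_id"] = out["plot_id"].astype(str)

    out = out[CAPTURE_COLUMNS].sort_values(
        ["plot_id", "survey_date", "individual_id"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def read_captures(path, geometry: PlotGeometry = DEFAULT_GEOMETRY) -> pd.DataFrame:
    """Read and validate a comma-delimited capture table.

    Expected columns: ``individual_id,plot_id,survey_date,cell_row,cell_col,
    svl_mm,mass_g,sex`` with ISO-8601 dates; ``mass_g`` may be empty.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "plot_id": str})
    return validate_captures(df, geometry)


def write_captures(df: pd.DataFrame, path) -> None:
    """Write a capture table in the canonical delimited-text format."""
    out = df[CAPTURE_COLUMNS].copy()
    out["survey_date"] = pd.to_datetime(out["survey_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
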