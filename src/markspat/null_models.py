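"""Density-matched complete-spatial-randomness null ensembles.

For every observed analysis unit — a (plot, season, class-pair) for the
Clark–Evans R and MAD statistics, a (plot, survey, class-pair) for the
shared-site proportion — replicate null statistics are generated under CSR
with the same class counts as observed. Because a single random draw is a
noisy estimate of the true random mean, a small ensemble of replicates
(default N = 10) is averaged per unit.

Replicate streams are reproducible in isolation: each unit draws from a
sub-seed derived deterministically from the master seed and the unit key.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .capture_data import DEFAULT_GEOMETRY, PlotGeometry
from .point_pattern import (
    PointPattern,
    clark_evans_r,
    default_r_grid,
    estimate_g,
    mad_statistic,
)

__all__ = [
    "NullEnsemble",
    "unit_rng",
    "simulate_csr_pattern",
    "null_statistics",
]

DEFAULT_N_REPLICATES = 10


@dataclass(frozen=True)
class NullEnsemble:
    """Replicate null statistic values for one observed unit."""

    unit: tuple
    statistic_name: str
    replicate_values: np.ndarray
    seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_values))


def unit_rng(seed: int, *key_parts) -> np.random.Generator:
    """Deterministic per-unit generator derived from a master seed and key.

    The unit key (plot, season, pair, ...) is hashed with CRC-32 and spawned
    through a SeedSequence so distinct units get statistically independent
    streams while any unit is reproducible alone.
    """
    digest = zlib.crc32("|".join(str(p) for p in key_parts).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def simulate_csr_pattern(
    n_from: int,
    n_to: int,
    window: PlotGeometry = DEFAULT_GEOMETRY,
    rng: np.random.Generator | int | None = None,
) -> PointPattern:
    """Uniform, independent points in the window with matched class counts.

    Labels are ``"from"`` for the focal class and ``"to"`` for the reference
    class; an empty focal set is legal (the downstream statistic is then
    undefined and the unit skipped).
    """
    if n_from < 0 or n_to < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = n_from + n_to
    pts = rng.uniform((0.0, 0.0), (window.width, window.height), size=(n, 2))
    labels = np.array(["from"] * n_from + ["to"] * n_to)
    return PointPattern(points=pts, labels=labels, window=window)


def _replicate_r(rng, n_from, n_to, window) -> float:
    pat = simulate_csr_pattern(n_from, n_to, window, rng)
    return clark_evans_r(pat.subset("from"), pat.subset("to"), window, same_pattern=False).r_value


def _replicate_mad(rng, n_from, n_to, window, r_grid) -> float:
    pat = simulate_csr_pattern(n_from, n_to, window, rng)
    est = estimate_g(pat.subset("from"), pat.subset("to"), window, r_grid, same_pattern=False)
    return mad_statistic(est.g_hat, est.g_theo, est.r_grid).u_statistic


def _replicate_shared(rng, n_from, n_to, n_cells) -> float:
    a = set(rng.integers(0, n_cells, size=n_from))
    b = set(rng.integers(0, n_cells, size=n_to))
    return len(a & b) / len(a | b)


def null_statistics(
    unit: tuple,
    statistic: str,
    n_from: int,
    n_to: int,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    window: PlotGeometry = DEFAULT_GEOMETRY,
    r_grid: np.ndarray | None = None,
) -> NullEnsemble:
    """Replicate null values of one statistic for one observed unit.

    ``statistic`` is ``"R"`` or ``"MAD_u"`` (continuous CSR patterns in the
    window, matching the seasonal centroid analyses) or
    ``"shared_proportion"`` (independent uniform cell assignment, matching
    the per-survey co-occupancy analysis).
    """
    if n_from < 1 or n_to < 1:
        raise ValueError(f"unit {unit}: degenerate counts ({n_from}, {n_to})")
    rng = unit_rng(seed, statistic, *unit)
    if r_grid is None:
        r_grid = default_r_grid(window)
    vals = np.empty(n_replicates)
    for i in range(n_replicates):
        if statistic == "R":
            vals[i] = _replicate_r(rng, n_from, n_to, window)
        elif statistic == "MAD_u":
            vals[i] = _replicate_mad(rng, n_from, n_to, window, r_grid)
        elif statistic == "shared_proportion":
            vals[i] = _replicate_shared(rng, n_from, n_to, window.n_cells)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return NullEnsemble(unit=unit, statistic_name=statistic, replicate_values=vals, seed=seed)
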