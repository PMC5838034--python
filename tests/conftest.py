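import numpy as np
import pandas as pd
import pytest

from markspat.capture_data import DEFAULT_GEOMETRY


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def geometry():
    return DEFAULT_GEOMETRY


def make_captures(rows):
    """Build a capture table from (id, plot, date, row, col, svl, sex) tuples."""
    return pd.DataFrame(
        rows,
        columns=["individual_id", "plot_id", "survey_date", "cell_row", "cell_col", "svl_mm", "sex"],
    ).assign(mass_g=np.nan)


@pytest.fixture
def tiny_captures():
    """Two individuals, two plots, a handful of captures across seasons."""
    return make_captures(
        [
            ("a1", "p1", "1982-03-01", 0, 0, 20.0, "F"),
            ("a1", "p1", "1982-03-10", 0, 1, 20.2, "F"),
            ("a1", "p1", "1982-07-01", 1, 1, 20.5, "F"),
            ("b1", "p2", "1982-03-05", 5, 7, 17.0, "U"),
            ("b1", "p2", "1982-07-07", 5, 7, 19.5, "M"),
        ]
    )
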