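"""Reference worked-example tables from the Bardsey Island survey.

Small fixtures transcribed from the published shore-based study of
harbour porpoises and Risso's dolphins around Bardsey Island (Wales):
the per-site effort/sighting overview, the forward-selection tables for
both species' habitat models, the reported factor coefficients with
their rate ratios, and the core-area percentages. The reporting
operations of this package are checked against this arithmetic
(column totals, consecutive-CVLL differences, exp(coefficient),
area percentages).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_site_summary",
    "load_site_totals",
    "load_selection_table",
    "load_printed_coefficients",
    "load_printed_core_areas",
    "selection_table_consistency",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("shorewatch.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_site_summary() -> pd.DataFrame:
    """Per-site scans and sighting counts (no totals row)."""
    return _read("table1_site_summary.csv")


def load_site_totals() -> pd.Series:
    """The printed column totals of the site overview."""
    df = _read("table1_totals.csv")
    return df.set_index("column")["printed_total"]


def load_selection_table(species: str) -> pd.DataFrame:
    """Forward-selection table (term, CVLL, delta CVLL, retained flag)."""
    if species not in ("porpoise", "rissos"):
        raise ValueError("species must be 'porpoise' or 'rissos'")
    return _read(f"selection_table_{species}.csv")


def load_printed_coefficients() -> pd.DataFrame:
    """Reported factor-level coefficients and their printed rate ratios."""
    return _read("printed_coefficients.csv")


def load_printed_core_areas() -> pd.DataFrame:
    """Reported 50% core areas, survey areas and their percentage share."""
    return _read("printed_core_areas.csv")


def selection_table_consistency(table: pd.DataFrame,
                                retained_only: bool = True) -> float:
    """Largest |printed delta - consecutive CVLL difference| in a table.

    Retained rows are added in order, so each printed delta must equal
    the difference of consecutive CVLL values (up to print rounding).
    Rejected rows were scored against intermediate models and are not
    consecutive differences, hence excluded by default.
    """
    rows = table[table["retained"]] if retained_only else table
    cvll = rows["cvll"].to_numpy(dtype=float)
    delta = rows["delta_cvll"].to_numpy(dtype=float)
    diffs = np.diff(cvll)
    return float(np.max(np.abs(delta[1:] - diffs)))
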