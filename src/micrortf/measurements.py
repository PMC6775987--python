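"""Conversion of raw growth/respiration records into community-function summaries.

Communities are tracked in 96-well MicroResp plates: cell densities come from
FACS event counts normalized to absolute-count bead standards, per-cell protein
from SYPRO-red fluorescence normalized to a fixed standard mixture, and
respiration from the colour change of a CO2 indicator gel read at 572 nm.
This module turns those raw records into the per-sample function summaries
(max cell density, max total protein, max protein per cell, windowed total CO2,
time to peak) that the RTF framework consumes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CALIBRATION_SLOPE",
    "CALIBRATION_X0",
    "CALIBRATION_Y0",
    "DEFAULT_BEAD_CONCENTRATION",
    "DEFAULT_VOLUME_ML",
    "TIME_POINTS_H",
    "AbsorbanceReading",
    "FunctionSummary",
    "DegenerateStandardError",
    "OutOfCalibrationError",
    "cells_per_ml",
    "protein_per_cell",
    "co2_percent_from_absorbance",
    "absorbance_from_co2",
    "series_to_intervals",
    "total_co2",
    "summarize_functions",
    "summarize_all",
    "detect_stationary",
    "ssm_dom_percent",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "write_summary_tsv",
    "read_summary_tsv",
]

#: Hyperbolic CO2-indicator calibration, %CO2 = slope/(d572 - x0) + y0.
CALIBRATION_SLOPE = 0.1648
CALIBRATION_X0 = 0.2457
CALIBRATION_Y0 = -0.2301

#: Absolute-count bead standard concentration (beads/mL).
DEFAULT_BEAD_CONCENTRATION = 990_000.0

#: Culture volume in the respiration wells (580 uL).
DEFAULT_VOLUME_ML = 0.58

#: Sampling schedule (h). A 160 h point exists in the raw protocol but is
#: excluded by default because late cultures change physical properties.
TIME_POINTS_H = (0.0, 16.0, 24.0, 32.0, 40.0, 64.0, 110.0)


class DegenerateStandardError(ValueError):
    """A normalization standard is zero/negative and cannot be used."""


class OutOfCalibrationError(ValueError):
    """An absorbance reading lies outside the calibrated hyperbola branch."""


@dataclasses.dataclass(frozen=True)
class AbsorbanceReading:
    """A per-interval CO2-indicator reading for one sample."""

    sample_id: str
    start_h: float
    end_h: float
    delta572: float

    def __post_init__(self) -> None:
        if not self.end_h > self.start_h:
            raise ValueError("interval must satisfy end_h > start_h")


@dataclasses.dataclass(frozen=True)
class FunctionSummary:
    """Per-sample community functions F_C.

    ``max_protein_per_cell`` is the ratio of maxima (max total protein over max
    cell density), not the max of per-time-point ratios: cells clump at late
    time points, so pointwise ratios are unreliable.
    """

    sample_id: str
    max_cell_density: float
    max_total_protein: float
    max_protein_per_cell: float
    total_co2_110h: float
    total_co2_40h: float
    time_to_peak_h: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def cells_per_ml(
    cell_events: float,
    bead_events: float,
    bead_concentration: float = DEFAULT_BEAD_CONCENTRATION,
) -> float:
    """Convert gated FACS cell events to cells/mL via the bead standard."""
    if bead_events <= 0:
        raise DegenerateStandardError("bead_events must be positive")
    return cell_events / bead_events * bead_concentration


def protein_per_cell(mean_fluorescence: float, standard_mean_fluorescence: float) -> float:
    """Normalize mean SYPRO-red fluorescence to the fixed protein standard."""
    if standard_mean_fluorescence <= 0:
        raise DegenerateStandardError("standard fluorescence must be positive")
    return mean_fluorescence / standard_mean_fluorescence


def co2_percent_from_absorbance(delta572: float) -> float:
    """Invert the indicator calibration to %CO2 (v/v), clamped below at 0.

    Valid only on the branch above the asymptote d572 > 0.2457; smaller values
    raise :class:`OutOfCalibrationError`.
    """
    if delta572 <= CALIBRATION_X0:
        raise OutOfCalibrationError(
            f"delta572={delta572!r} at or below calibration asymptote {CALIBRATION_X0}"
        )
    pct = CALIBRATION_SLOPE / (delta572 - CALIBRATION_X0) + CALIBRATION_Y0
    return max(pct, 0.0)


def absorbance_from_co2(co2_percent: float) -> float:
    """Algebraic inverse of :func:`co2_percent_from_absorbance` (simulator side)."""
    if co2_percent < 0:
        raise ValueError("co2_percent must be non-negative")
    return CALIBRATION_X0 + CALIBRATION_SLOPE / (co2_percent - CALIBRATION_Y0)


def series_to_intervals(series: pd.DataFrame) -> pd.DataFrame:
    """Turn one sample's time series into per-interval %CO2 records.

    ``series`` rows carry ``time_h`` and ``delta572``; the ``delta572`` on the
    row at time t_k is the absorbance change accumulated over (t_{k-1}, t_k].
    The row at the first time point has no interval and is skipped.
    """
    s = series.sort_values("time_h")
    t = s["time_h"].to_numpy(dtype=float)
    d = s["delta572"].to_numpy(dtype=float)
    rows = []
    for k in range(1, len(t)):
        if np.isnan(d[k]):
            continue
        rows.append(
            {
                "start_h": t[k - 1],
                "end_h": t[k],
                "co2_pct": co2_percent_from_absorbance(d[k]),
            }
        )
    return pd.DataFrame(rows, columns=["start_h", "end_h", "co2_pct"])


def total_co2(
    intervals: pd.DataFrame,
    volume_ml: float = DEFAULT_VOLUME_ML,
    window: tuple[float, float] = (0.0, 110.0),
    blank_intervals: pd.DataFrame | None = None,
) -> float:
    """Blank-corrected normalized total CO2 over ``window``.

    Each interval contributes rate x duration x volume, with rate = %CO2 over
    the interval length; an interval counts if its midpoint falls inside the
    window. ``blank_intervals`` holds the mean blank %CO2 on the same interval
    grid (columns start_h, end_h, co2_pct) and is subtracted per interval
    before summation, removing the atmospheric-CO2 signal.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("empty CO2 window")
    if intervals.empty:
        raise ValueError("need at least one CO2 interval")
    start = intervals["start_h"].to_numpy(dtype=float)
    end = intervals["end_h"].to_numpy(dtype=float)
    pct = intervals["co2_pct"].to_numpy(dtype=float).copy()
    if blank_intervals is not None and len(blank_intervals):
        bmap = {
            (s, e): c
            for s, e, c in zip(
                blank_intervals["start_h"], blank_intervals["end_h"], blank_intervals["co2_pct"]
            )
        }
        pct -= np.array([bmap.get((s, e), 0.0) for s, e in zip(start, end)])
    mid = (start + end) / 2.0
    inside = (mid > lo) & (mid < hi)
    duration = end - start
    rate = pct / duration
    return float(np.sum(rate[inside] * duration[inside] * volume_ml))


def summarize_functions(
    series: pd.DataFrame,
    volume_ml: float = DEFAULT_VOLUME_ML,
    blank_intervals: pd.DataFrame | None = None,
    max_time_h: float = 110.0,
) -> FunctionSummary:
    """Reduce one sample's time series to a :class:`FunctionSummary`.

    Maxima are taken over time points <= ``max_time_h``; total protein at each
    point is cells/mL x protein fluorescence per cell; time to peak is the
    earliest time achieving the cell-density maximum.
    """
    s = series.sort_values("time_h")
    s = s[s["time_h"] <= max_time_h]
    if len(s) < 2:
        raise ValueError("need at least two time points within the window")
    sample_id = str(s["sample_id"].iloc[0]) if "sample_id" in s else ""
    cells = s["cells_per_ml"].to_numpy(dtype=float)
    ppc = s["protein_fluor_per_cell"].to_numpy(dtype=float)
    total_protein = cells * ppc
    max_cells = float(cells.max())
    max_protein = float(total_protein.max())
    t = s["time_h"].to_numpy(dtype=float)
    time_to_peak = float(t[int(np.argmax(cells))])
    intervals = series_to_intervals(s)
    if intervals.empty:
        co2_110 = co2_40 = float("nan")
    else:
        co2_110 = total_co2(intervals, volume_ml, (0.0, 110.0), blank_intervals)
        co2_40 = total_co2(intervals, volume_ml, (0.0, 40.0), blank_intervals)
    return FunctionSummary(
        sample_id=sample_id,
        max_cell_density=max_cells,
        max_total_protein=max_protein,
        max_protein_per_cell=max_protein / max_cells if max_cells > 0 else 0.0,
        total_co2_110h=co2_110,
        total_co2_40h=co2_40,
        time_to_peak_h=time_to_peak,
    )


def mean_blank_intervals(series: pd.DataFrame, blank_ids: Iterable[str]) -> pd.DataFrame | None:
    """Average the %CO2 of blank wells on the shared interval grid."""
    blank_ids = set(blank_ids)
    blanks = series[series["sample_id"].isin(blank_ids)]
    if blanks.empty:
        return None
    per_blank = [series_to_intervals(g) for _, g in blanks.groupby("sample_id", sort=True)]
    cat = pd.concat(per_blank, ignore_index=True)
    return (
        cat.groupby(["start_h", "end_h"], as_index=False)["co2_pct"].mean().sort_values("start_h")
    )


def summarize_all(
    series: pd.DataFrame,
    blank_ids: Iterable[str] = (),
    volume_ml: float = DEFAULT_VOLUME_ML,
    max_time_h: float = 110.0,
) -> pd.DataFrame:
    """Summaries for every non-blank sample in a long-format time-series table."""
    blank_ids = set(blank_ids)
    blank = mean_blank_intervals(series, blank_ids)
    rows = []
    for sample_id, g in series.groupby("sample_id", sort=True):
        if sample_id in blank_ids:
            continue
        rows.append(summarize_functions(g, volume_ml, blank, max_time_h).as_dict())
    return pd.DataFrame(rows).set_index("sample_id")


def detect_stationary(
    cell_counts: Sequence[float], growth_threshold: float = 0.20
) -> int | None:
    """Index of the first stationary-phase time point, or None.

    Stationary phase: relative growth between two consecutive points drops
    below ``growth_threshold`` after some earlier consecutive pair exceeded it.
    """
    c = np.asarray(cell_counts, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least three time points")
    if np.any(c <= 0):
        raise ValueError("cell counts must be positive")
    growth = np.diff(c) / c[:-1]
    seen_growth = False
    for k, g in enumerate(growth):
        if seen_growth and g < growth_threshold:
            return k + 1
        if g > growth_threshold:
            seen_growth = True
    return None


def ssm_dom_percent(
    dry_mass_mg: float = 22.0,
    stock_volume_ml: float = 10.0,
    dilution_fold: float = 10.0,
) -> float:
    """Dissolved-organic-matter concentration of the growth medium, % (w/v).

    Lyophilizing 10 mL of the 10x seaweed-extract stock leaves 22 mg of dry
    material; diluting the stock 10-fold gives the working medium, so the
    default arithmetic yields 0.022% (w/v).
    """
    mg_per_ml = dry_mass_mg / stock_volume_ml / dilution_fold
    return mg_per_ml / 10.0  # 1% w/v == 10 mg/mL


# -- TSV dialect -------------------------------------------------------------

_TS_COLUMNS = ["sample_id", "time_h", "cells_per_ml", "protein_fluor_per_cell", "delta572"]


def write_timeseries_tsv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, sep="\t", index=False, columns=_TS_COLUMNS, float_format="%.10g")


def read_timeseries_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_summary_tsv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, sep="\t", float_format="%.10g")


def read_summary_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"sample_id": str})
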