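"""Statistics of visualized pilus filaments.

Filaments are recorded per cell as (θ, L): the angle θ (degrees, measured
from the flow direction and wrapped to [0, 360)) and the visible length L
(μm).  The collection is carried as a tidy DataFrame with columns
``cell_id, strain, theta_deg, length_um`` — the same dialect as the
filament CSV files.

Angular convention: θ ∈ [0, 90] ∪ [270, 360) points *against* the flow
(upstream side), θ ∈ (90, 270) points with the flow.  The boundary angles
90° and 270° are counted on the against-flow side (closed intervals); the
choice is configurable where it matters.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidBinningError,
    InvalidSpecificationError,
    UndefinedRatioError,
)

__all__ = [
    "filament_frame", "orientation_ratio", "length_number_summary",
    "rose_histogram", "read_filaments_csv", "write_filaments_csv",
    "FILAMENT_CSV_COLUMNS",
]

FILAMENT_CSV_COLUMNS = ["cell_id", "strain", "theta_deg", "length_um"]


def filament_frame(records: Iterable[Mapping]) -> pd.DataFrame:
    """Build a validated filament table from per-filament records."""
    df = pd.DataFrame(list(records))
    missing = set(FILAMENT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidSpecificationError(f"filament table missing {missing}")
    df = df[FILAMENT_CSV_COLUMNS].copy()
    df["theta_deg"] = np.mod(df["theta_deg"].astype(float), 360.0)
    if (df["length_um"] <= 0).any():
        raise InvalidSpecificationError("filament lengths must be positive")
    return df


def _against_flow_mask(theta: np.ndarray, closed_boundaries: bool = True) -> np.ndarray:
    """True for angles on the against-flow (upstream) side."""
    if closed_boundaries:
        return (theta <= 90.0) | (theta >= 270.0)
    return (theta < 90.0) | (theta > 270.0)


def orientation_ratio(filaments, closed_boundaries: bool = True) -> float:
    """Against-flow / with-flow filament count ratio.

    Numerator: filaments with θ ∈ [0, 90] ∪ [270, 360); denominator:
    θ ∈ (90, 270).  ``filaments`` is a filament table or a sequence of
    angles in degrees.
    """
    theta = np.mod(np.asarray(
        filaments["theta_deg"] if isinstance(filaments, pd.DataFrame)
        else filaments, dtype=float), 360.0)
    against = _against_flow_mask(theta, closed_boundaries)
    n_with = int((~against).sum())
    if n_with == 0:
        raise UndefinedRatioError("no filaments in the with-flow (90–270°) range")
    return float(against.sum()) / n_with


def length_number_summary(filaments: pd.DataFrame) -> dict:
    """Population moments: filament length over filaments, count per cell.

    Returns mean ± SD length (μm, over all filaments) and mean ± SD visible
    filament count (over cells), as a plain dict.
    """
    if len(filaments) == 0:
        raise InsufficientDataError("no filaments supplied")
    lengths = filaments["length_um"].to_numpy(float)
    counts = filaments.groupby("cell_id", sort=False).size().to_numpy(float)
    return {
        "mean_length_um": float(lengths.mean()),
        "sd_length_um": float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0,
        "mean_count_per_cell": float(counts.mean()),
        "sd_count_per_cell": float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
        "n_cells": int(counts.size),
        "n_filaments": int(lengths.size),
    }


def rose_histogram(filaments, bin_width_deg: float = 30.0) -> pd.DataFrame:
    """Angular histogram (rose-plot binning) of filament directions.

    ``bin_width_deg`` must divide 360 exactly; bins are left-closed
    [k·w, (k+1)·w).  Total counts are conserved for every admissible width.
    Returns a frame with ``bin_left_deg, bin_right_deg, count``.
    """
    if bin_width_deg <= 0:
        raise InvalidBinningError("bin width must be positive")
    n_bins = 360.0 / bin_width_deg
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise InvalidBinningError(f"bin width {bin_width_deg}° does not divide 360°")
    n_bins = int(round(n_bins))
    theta = np.mod(np.asarray(
        filaments["theta_deg"] if isinstance(filaments, pd.DataFrame)
        else filaments, dtype=float), 360.0)
    idx = np.floor(theta / bin_width_deg).astype(int) % n_bins
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins) * bin_width_deg
    return pd.DataFrame({"bin_left_deg": edges,
                         "bin_right_deg": edges + bin_width_deg,
                         "count": counts})


def write_filaments_csv(filaments: pd.DataFrame, path) -> None:
    filaments[FILAMENT_CSV_COLUMNS].to_csv(path, index=False,
                                           float_format="%.17g")


def read_filaments_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    return filament_frame(df.to_dict("records"))
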