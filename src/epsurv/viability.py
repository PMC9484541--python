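"""Viability data model and I/O for electroporation dose-response experiments.

Cell survival after a burst of electroporation pulses is measured with a
colorimetric assay (CCK-8): the optical density of treated wells is
normalised against blank medium and untreated controls,

    viability% = 100 * (A_exp - A_blank) / (A_control - A_blank).

Viability may legitimately exceed 100% — weak fields can stimulate
proliferation — so values above 100 are retained, never clipped.

Datasets are tabular: one row per (cell line, pulse duration, pulse number,
field strength, replicate).  The table is held in a pandas DataFrame behind
a thin :class:`ViabilityDataset` wrapper that enforces the keying and
design-grid invariants the two-step model fit relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ODMeasurement",
    "ViabilityDataset",
    "ViabilityValidationError",
    "CELL_LINES",
    "ORGAN_OF_CELL_LINE",
    "compute_viability",
    "load_viability_table",
    "save_viability_table",
    "summarize_replicates",
    "DEFAULT_REPLICATES",
    "CUVETTE_GAP_CM",
]

#: electrode gap of the exposure cuvette, cm (EFS = voltage / gap)
CUVETTE_GAP_CM = 0.2

#: replicate count of the underlying assay design
DEFAULT_REPLICATES = 10

#: the 20 digestive-system cell lines and their organ of origin
ORGAN_OF_CELL_LINE: dict[str, str] = {
    "KYSE-150": "esophagus",
    "KYSE-410": "esophagus",
    "GES-1": "stomach",
    "MGC-823": "stomach",
    "SGC-7901": "stomach",
    "MKN-45": "stomach",
    "SW-620": "colon",
    "SW-480": "colon",
    "HCT-116": "colon",
    "LoVo": "colon",
    "HIBEpiC": "bile_duct",
    "HuCCT-1": "bile_duct",
    "QBC-939": "bile_duct",
    "HCCC-9810": "bile_duct",
    "L-02": "liver",
    "Huh-7": "liver",
    "Hep-3B": "liver",
    "Hep-G2": "liver",
    "PANC-1": "pancreas",
    "MIA PaCa-2": "pancreas",
}

CELL_LINES = tuple(ORGAN_OF_CELL_LINE)

#: accepted spelling variants -> canonical cell-line name
CELL_LINE_ALIASES = {"GSE-1": "GES-1"}

_RECORD_COLUMNS = [
    "cell_line",
    "organ",
    "pulse_duration_us",
    "pulse_number",
    "efs_v_cm",
    "replicate",
    "viability_pct",
]
_KEY_COLUMNS = ["cell_line", "pulse_duration_us", "pulse_number", "efs_v_cm", "replicate"]
_OD_COLUMNS = ["od_exp", "od_blank", "od_control"]


class ViabilityValidationError(ValueError):
    """Raised when a viability table violates the dataset invariants."""


@dataclass(frozen=True)
class ODMeasurement:
    """Mean optical densities (450 nm) of experimental, blank and control wells."""

    a_exp: float
    a_blank: float
    a_control: float

    def __post_init__(self) -> None:
        vals = (self.a_exp, self.a_blank, self.a_control)
        if not all(np.isfinite(vals)) or any(v < 0 for v in vals):
            raise ViabilityValidationError(f"OD values must be finite and >= 0, got {vals}")


def compute_viability(od: ODMeasurement) -> float:
    """Percent viability from an OD triplet.

    Returns ``100 * (a_exp - a_blank) / (a_control - a_blank)``.  The result
    can exceed 100 (proliferation) or fall below 0 is impossible for
    physically sensible ODs but is not clipped here.

    Raises
    ------
    ViabilityValidationError
        If the control does not exceed the blank (degenerate normalisation).
    """
    denom = od.a_control - od.a_blank
    if denom <= 0:
        raise ViabilityValidationError(
            f"degenerate control: a_control={od.a_control} <= a_blank={od.a_blank}"
        )
    return 100.0 * (od.a_exp - od.a_blank) / denom


@dataclass
class ViabilityDataset:
    """A validated table of viability measurements.

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns ``cell_line, organ, pulse_duration_us, pulse_number,
        efs_v_cm, replicate, viability_pct``; one row per replicate.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def design(self) -> pd.DataFrame:
        """The distinct (cell_line, duration, N, EFS) grid."""
        return (
            self.frame[["cell_line", "pulse_duration_us", "pulse_number", "efs_v_cm"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def subset(self, cell_line: str, pulse_duration_us: float | None = None) -> pd.DataFrame:
        sel = self.frame["cell_line"] == cell_line
        if pulse_duration_us is not None:
            sel &= self.frame["pulse_duration_us"] == pulse_duration_us
        return self.frame.loc[sel]


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _RECORD_COLUMNS if c not in frame.columns and c != "organ"]
    if missing:
        raise ViabilityValidationError(f"missing columns: {missing}")
    frame = frame.copy()
    frame["cell_line"] = frame["cell_line"].replace(CELL_LINE_ALIASES)

    unknown = sorted(set(frame["cell_line"]) - set(CELL_LINES))
    if unknown:
        rows = frame.index[frame["cell_line"].isin(unknown)].tolist()[:5]
        raise ViabilityValidationError(f"unknown cell line(s) {unknown} (rows {rows})")

    expected_organ = frame["cell_line"].map(ORGAN_OF_CELL_LINE)
    if "organ" in frame.columns:
        bad = frame.index[frame["organ"].astype(str) != expected_organ]
        if len(bad):
            raise ViabilityValidationError(
                f"cell line / organ mismatch at rows {bad.tolist()[:5]}"
            )
    frame["organ"] = expected_organ

    for col in ("pulse_duration_us", "efs_v_cm", "viability_pct"):
        frame[col] = pd.to_numeric(frame[col]).astype(np.float64)
    frame["pulse_number"] = frame["pulse_number"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)

    if (frame["pulse_duration_us"] <= 0).any():
        raise ViabilityValidationError("pulse_duration_us must be positive")
    if (frame["pulse_number"] < 0).any():
        raise ViabilityValidationError("pulse_number must be >= 0")
    if (frame["efs_v_cm"] < 0).any():
        raise ViabilityValidationError("efs_v_cm must be >= 0")
    if (frame["viability_pct"] < 0).any():
        rows = frame.index[frame["viability_pct"] < 0].tolist()[:5]
        raise ViabilityValidationError(f"negative viability at rows {rows}")

    dup = frame.duplicated(subset=_KEY_COLUMNS, keep=False)
    if dup.any():
        raise ViabilityValidationError(
            f"duplicate (cell_line, duration, N, EFS, replicate) keys at rows "
            f"{frame.index[dup].tolist()[:8]}"
        )
    return frame[_RECORD_COLUMNS].reset_index(drop=True)


def load_viability_table(path: str | Path) -> ViabilityDataset:
    """Load a viability CSV, converting OD-form rows if present.

    Two schemas are accepted: rows may carry a ``viability_pct`` column
    directly, or the OD triplet ``od_exp, od_blank, od_control`` from which
    viability is computed per well.
    """
    frame = pd.read_csv(path)
    if "viability_pct" not in frame.columns:
        missing = [c for c in _OD_COLUMNS if c not in frame.columns]
        if missing:
            raise ViabilityValidationError(
                f"need either viability_pct or OD columns; missing {missing}"
            )
        denom = frame["od_control"] - frame["od_blank"]
        bad = frame.index[denom <= 0].tolist()
        if bad:
            raise ViabilityValidationError(f"degenerate control (od_control <= od_blank) at rows {bad[:5]}")
        frame["viability_pct"] = 100.0 * (frame["od_exp"] - frame["od_blank"]) / denom
        frame = frame.drop(columns=_OD_COLUMNS)
    return ViabilityDataset(frame)


def save_viability_table(dataset: ViabilityDataset, path: str | Path) -> None:
    """Write the dataset back to CSV (the same schema ``load_viability_table`` reads)."""
    dataset.frame.to_csv(path, index=False, float_format="%.10g")


def summarize_replicates(dataset: ViabilityDataset) -> pd.DataFrame:
    """Mean +/- SD viability per experimental condition.

    Returns one row per (cell_line, organ, duration, N, EFS) with columns
    ``mean_viability_pct``, ``sd_viability_pct`` (sample SD, 0 when R = 1)
    and ``n_replicates``.
    """
    grouped = dataset.frame.groupby(
        ["cell_line", "organ", "pulse_duration_us", "pulse_number", "efs_v_cm"],
        as_index=False,
    )["viability_pct"]
    out = grouped.agg(
        mean_viability_pct="mean",
        sd_viability_pct=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
        n_replicates="size",
    )
    return out
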