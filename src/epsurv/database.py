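"""Bundled coefficient and tissue-property databases.

Two reference tables ship with the package:

* ``cell_coefficients.csv`` — the published cell-specific Peleg-Fermi
  coefficient sets (E0, k1, A0, k2 with stage-2 R² values and the derived
  Ec(100) threshold) for 20 digestive-system cell lines at pulse durations
  of 25, 50, 75 and 100 μs.  One entry (PANC-1 at 25 μs) is NA: those data
  required the double-exponential variant and its coefficients were not
  published.
* ``tissue_properties.csv`` — electrical conductivity and thermal constants
  per organ, used by the bioheat/injury simulator.

Coefficient databases produced by ``epsurv fit`` are round-tripped as JSON;
``load_coefficient_json``/``save_coefficient_json`` handle that format.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .models import PelegFermiCoefficients

__all__ = [
    "TissueProperties",
    "load_cell_coefficients",
    "builtin_coefficients",
    "coefficients_from_row",
    "load_tissue_properties",
    "tissue_properties",
    "save_coefficient_json",
    "load_coefficient_json",
    "ORGANS",
]

ORGANS = ("esophagus", "stomach", "colon", "bile_duct", "liver", "pancreas")


@dataclass(frozen=True)
class TissueProperties:
    """Electrical and thermal constants of one organ's tissue.

    Units: sigma S/m, rho kg/m³, c J/(kg·°C), k_th W/(m·°C),
    w_b ml/(min·kg) blood perfusion, q_met W/kg metabolic heat.
    """

    organ: str
    sigma: float
    rho: float
    c: float
    k_th: float
    w_b: float
    q_met: float

    def __post_init__(self) -> None:
        for name in ("sigma", "rho", "c", "k_th", "w_b", "q_met"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("epsurv.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_cell_coefficients(complete_only: bool = False) -> pd.DataFrame:
    """The bundled cell-coefficient table as a DataFrame (NA rows retained by default)."""
    df = _read_bundled("cell_coefficients.csv")
    if complete_only:
        df = df.dropna().reset_index(drop=True)
    return df


def coefficients_from_row(row: pd.Series | dict) -> PelegFermiCoefficients:
    return PelegFermiCoefficients(
        cell_line=str(row["cell_line"]),
        organ=str(row["organ"]),
        pulse_duration_us=float(row["pulse_duration_us"]),
        e0=float(row["e0"]),
        k1=float(row["k1"]),
        a0=float(row["a0"]),
        k2=float(row["k2"]),
        r2_e=float(row.get("r2_e", np.nan)),
        r2_a=float(row.get("r2_a", np.nan)),
    )


def builtin_coefficients(
    cell_line: str | None = None, pulse_duration_us: float | None = None
) -> list[PelegFermiCoefficients]:
    """Bundled coefficient sets, optionally filtered; NA entries are skipped."""
    df = load_cell_coefficients(complete_only=True)
    if cell_line is not None:
        df = df[df["cell_line"] == cell_line]
    if pulse_duration_us is not None:
        df = df[df["pulse_duration_us"] == pulse_duration_us]
    if df.empty:
        raise KeyError(
            f"no bundled coefficients for cell_line={cell_line!r}, "
            f"duration={pulse_duration_us!r}"
        )
    return [coefficients_from_row(r) for _, r in df.iterrows()]


def load_tissue_properties() -> pd.DataFrame:
    return _read_bundled("tissue_properties.csv")


def tissue_properties(organ: str) -> TissueProperties:
    """Tissue constants for one organ from the bundled table."""
    df = load_tissue_properties()
    match = df[df["organ"] == organ]
    if match.empty:
        raise KeyError(f"unknown organ {organ!r}; known: {sorted(df['organ'])}")
    r = match.iloc[0]
    return TissueProperties(
        organ=organ,
        sigma=float(r["sigma_s_m"]),
        rho=float(r["rho_kg_m3"]),
        c=float(r["c_j_kg_c"]),
        k_th=float(r["k_w_m_c"]),
        w_b=float(r["w_b_ml_min_kg"]),
        q_met=float(r["q_met_w_kg"]),
    )


def save_coefficient_json(coeffs: Iterable[PelegFermiCoefficients], path: str | Path) -> None:
    """Write a coefficient database as a JSON list of objects."""
    entries = []
    for c in coeffs:
        d = asdict(c)
        d["duration_us"] = d.pop("pulse_duration_us")
        d["model"] = "peleg_fermi"
        entries.append(d)
    Path(path).write_text(json.dumps(entries, indent=2) + "\n")


def load_coefficient_json(path: str | Path) -> list[PelegFermiCoefficients]:
    entries = json.loads(Path(path).read_text())
    out = []
    for d in entries:
        if d.get("model", "peleg_fermi") != "peleg_fermi":
            raise ValueError(f"unsupported model type {d.get('model')!r} in {path}")
        out.append(
            PelegFermiCoefficients(
                cell_line=d["cell_line"],
                organ=d["organ"],
                pulse_duration_us=float(d["duration_us"]),
                e0=float(d["e0"]),
                k1=float(d["k1"]),
                a0=float(d["a0"]),
                k2=float(d["k2"]),
                r2_e=float(d.get("r2_e", np.nan)),
                r2_a=float(d.get("r2_a", np.nan)),
            )
        )
    return out
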