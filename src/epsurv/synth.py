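"""Synthetic viability datasets with the statistical structure of the assay.

The generator draws replicate viabilities around the Peleg-Fermi survival
surface of a known ("truth") coefficient set on a rectangular
EFS × pulse-number design, mimicking the in vitro measurement:

* truth survival  S(E, N) = 1 / (1 + exp((E - Ec(N)) / Ac(N))),
* optional low-field stimulation  boost * exp(-E / cutoff)  — weak pulses
  can raise measured viability above 100%,
* additive Gaussian replicate noise on the viability fraction, truncated
  at zero (viability cannot be negative).

Defaults reproduce the assay design the coefficient database rests on:
nine field levels from 250 to 3000 V/cm, nine pulse numbers from 10 to 90,
ten replicates per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import PelegFermiCoefficients, survival_probability
from .viability import DEFAULT_REPLICATES, ViabilityDataset

__all__ = [
    "DEFAULT_EFS_GRID",
    "DEFAULT_N_GRID",
    "DEFAULT_DURATIONS_US",
    "DEFAULT_SEED",
    "StimulationConfig",
    "GeneratorConfig",
    "generate_dataset",
    "generate_od_dataset",
]

#: emulated assay design: field levels (V/cm), pulse numbers, durations (μs)
DEFAULT_EFS_GRID = (250.0, 500.0, 750.0, 1000.0, 1250.0, 1500.0, 2000.0, 2500.0, 3000.0)
DEFAULT_N_GRID = (10, 20, 30, 40, 50, 60, 70, 80, 90)
DEFAULT_DURATIONS_US = (25.0, 50.0, 75.0, 100.0)

DEFAULT_SEED = 20220905


@dataclass(frozen=True)
class StimulationConfig:
    """Low-field proliferation boost: adds boost * exp(-EFS/efs_cutoff) to S."""

    efs_cutoff: float = 500.0
    boost: float = 0.15


@dataclass
class GeneratorConfig:
    """Design and noise settings for one synthetic dataset.

    ``truths`` holds one coefficient set per pulse duration to emulate; the
    design grid applies to each.  ``noise_sd`` is the SD of the additive
    Gaussian noise on the viability *fraction* (0.03 ≈ 3 viability points).
    """

    truths: Sequence[PelegFermiCoefficients]
    efs_grid: Sequence[float] = DEFAULT_EFS_GRID
    n_grid: Sequence[int] = DEFAULT_N_GRID
    replicates: int = DEFAULT_REPLICATES
    noise_sd: float = 0.03
    stimulation: StimulationConfig | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.truths:
            raise ValueError("need at least one truth coefficient set")


def _true_survival(config: GeneratorConfig, truth: PelegFermiCoefficients,
                   efs: np.ndarray, n: np.ndarray) -> np.ndarray:
    s = np.asarray(survival_probability(efs, truth.ec(n), truth.ac(n)), dtype=float)
    if config.stimulation is not None:
        s = s + config.stimulation.boost * np.exp(-efs / config.stimulation.efs_cutoff)
    return s


def generate_dataset(config: GeneratorConfig) -> ViabilityDataset:
    """Draw a replicate-level viability dataset; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for truth in config.truths:
        efs, n, rep = np.meshgrid(
            np.asarray(config.efs_grid, dtype=float),
            np.asarray(config.n_grid, dtype=int),
            np.arange(1, config.replicates + 1),
            indexing="ij",
        )
        efs, n, rep = efs.ravel(), n.ravel(), rep.ravel()
        s = _true_survival(config, truth, efs, n.astype(float))
        noisy = s + rng.normal(0.0, config.noise_sd, size=s.shape) if config.noise_sd else s
        viability = np.maximum(noisy, 0.0) * 100.0
        frames.append(
            pd.DataFrame(
                {
                    "cell_line": truth.cell_line,
                    "organ": truth.organ,
                    "pulse_duration_us": truth.pulse_duration_us,
                    "pulse_number": n,
                    "efs_v_cm": efs,
                    "replicate": rep,
                    "viability_pct": viability,
                }
            )
        )
    return ViabilityDataset(pd.concat(frames, ignore_index=True))


def generate_od_dataset(
    config: GeneratorConfig, od_control: float = 1.1, od_blank: float = 0.1
) -> pd.DataFrame:
    """Same draw as :func:`generate_dataset` but emitted as raw OD triplets.

    Inverts the OD normalisation: ``od_exp = od_blank + S * (od_control -
    od_blank)``, so converting back yields the generated viability exactly.
    Returns a DataFrame in the OD CSV schema (no viability column).
    """
    if od_control <= od_blank:
        raise ValueError("od_control must exceed od_blank")
    ds = generate_dataset(config)
    frame = ds.frame.copy()
    s = frame.pop("viability_pct") / 100.0
    frame["od_exp"] = od_blank + s * (od_control - od_blank)
    frame["od_blank"] = od_blank
    frame["od_control"] = od_control
    return frame
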