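"""Seeded synthetic calibration plates, QC sets and study samples.

The generator emulates the statistical structure that surrogate-IS
quantitation relies on: peak-area ratios that are linear in nominal
concentration with multiplicative (lognormal) measurement noise, and a
per-sample digestion-efficiency factor.  Because a matrix (co-digested)
internal standard passes through digestion together with the analyte,
that factor multiplies *both* areas and cancels from their ratio; a
stable-isotope-labelled internal standard spiked after digestion does
not share it, so digestion variability propagates into SIL-IS
quantitation.  That asymmetry is the contrast the simulator exposes.

Defaults mirror the validation design used throughout the package's
examples: a nine-point calibration series (0.49 ... 1000 fmol on
column) measured in triplicate across four analyses, with QCs at 32,
125 and 600 fmol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .validation import AREA_COLUMNS

__all__ = [
    "DEFAULT_LEVELS",
    "DEFAULT_QC_LEVELS",
    "SimulationConfig",
    "make_qc_table",
    "simulate_calibration",
    "simulate_study_samples",
    "write_table",
]

#: Nine-point calibration series, fmol on column.
DEFAULT_LEVELS = (0.49, 0.98, 1.95, 3.91, 15.63, 62.50, 250.00, 500.00, 1000.00)

#: QC-low / QC-mid / QC-high, fmol on column.
DEFAULT_QC_LEVELS = (32.0, 125.0, 600.0)

#: Nominal constant IS peak area (arbitrary instrument counts).
IS_AREA = 1.0e5


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic assay.

    noise_cv is the SD of the lognormal multiplicative measurement noise
    on each peak-area ratio; digestion_cv is the SD (log scale) of the
    per-sample digestion-efficiency factor.  ``is_mode`` selects whether
    the internal standard is co-digested with the sample ("matrix") or
    spiked after digestion ("sil").  A seed is mandatory: every draw
    flows from it and reruns are byte-identical.
    """

    seed: int
    levels: tuple[float, ...] = DEFAULT_LEVELS
    replicates: int = 3
    analyses: int = 4
    true_slope: float = 0.005
    true_intercept: float = 0.01
    noise_cv: float = 0.05
    digestion_cv: float = 0.15
    is_mode: str = "matrix"

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.digestion_cv < 0:
            raise ValueError("noise_cv and digestion_cv must be >= 0")
        if len(set(self.levels)) != len(self.levels) or any(x <= 0 for x in self.levels):
            raise ValueError("levels must be strictly positive and distinct")
        if self.replicates < 1 or self.analyses < 1:
            raise ValueError("replicates and analyses must be >= 1")
        if self.is_mode not in ("sil", "matrix"):
            raise ValueError(f"is_mode must be 'sil' or 'matrix', got {self.is_mode!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _rows(analysis, sample_type, level_or_id, nominal, replicate, ratio):
    area_analyte = ratio * IS_AREA
    return {
        "analysis_id": analysis,
        "sample_type": sample_type,
        "level_or_id": level_or_id,
        "nominal": nominal,
        "replicate": replicate,
        "area_analyte": area_analyte,
        "area_is": IS_AREA,
    }


def simulate_calibration(config: SimulationConfig) -> pd.DataFrame:
    """Replicate calibration analyses in the validation-table dialect.

    Each observation is ratio = (true_slope*nominal + true_intercept) *
    exp(eps), eps ~ Normal(0, noise_cv), independently per analysis,
    level and replicate; areas are emitted with the IS area fixed at a
    nominal constant.
    """
    rng = config.rng()
    rows = []
    for a in range(1, config.analyses + 1):
        for level in config.levels:
            expected = config.true_slope * level + config.true_intercept
            for rep in range(1, config.replicates + 1):
                ratio = expected * np.exp(rng.normal(0.0, config.noise_cv))
                rows.append(
                    _rows(f"analysis_{a}", "calibrator", f"cal_{level:g}", level, rep, ratio)
                )
    return pd.DataFrame(rows, columns=AREA_COLUMNS)


def make_qc_table(
    config: SimulationConfig, qc_levels: tuple[float, ...] = DEFAULT_QC_LEVELS
) -> pd.DataFrame:
    """QC rows (``config.replicates`` per level per analysis), same noise model."""
    if any(q <= 0 for q in qc_levels):
        raise ValueError("QC levels must be positive")
    rng = np.random.default_rng(config.rng().integers(2**31))
    rows = []
    for a in range(1, config.analyses + 1):
        for level in qc_levels:
            expected = config.true_slope * level + config.true_intercept
            for rep in range(1, config.replicates + 1):
                ratio = expected * np.exp(rng.normal(0.0, config.noise_cv))
                rows.append(_rows(f"analysis_{a}", "qc", f"qc_{level:g}", level, rep, ratio))
    return pd.DataFrame(rows, columns=AREA_COLUMNS)


def simulate_study_samples(
    config: SimulationConfig,
    n_samples: int,
    true_concs: list[float] | tuple[float, ...],
) -> pd.DataFrame:
    """Study samples under both IS modes on the same underlying samples.

    One digestion-efficiency factor d_i ~ exp(Normal(0, digestion_cv)) is
    drawn per sample and shared between the two modes.  Under
    ``matrix`` both areas carry d_i (co-digestion) so it cancels from the
    ratio; under ``sil`` only the analyte area carries it.  Replicate
    measurement noise is independent per area, replicate and mode.  The
    returned table adds an ``is_mode`` column to the standard dialect.
    """
    if len(true_concs) != n_samples:
        raise ValueError(
            f"true_concs has {len(true_concs)} entries for n_samples={n_samples}"
        )
    rng = config.rng()
    efficiencies = np.exp(rng.normal(0.0, config.digestion_cv, size=n_samples))
    rows = []
    for mode in ("matrix", "sil"):
        for i, (conc, d) in enumerate(zip(true_concs, efficiencies), start=1):
            expected = config.true_slope * conc + config.true_intercept
            for rep in range(1, config.replicates + 1):
                eps_analyte = np.exp(rng.normal(0.0, config.noise_cv))
                eps_is = np.exp(rng.normal(0.0, config.noise_cv))
                area_analyte = IS_AREA * expected * d * eps_analyte
                area_is = IS_AREA * (d if mode == "matrix" else 1.0) * eps_is
                row = {
                    "analysis_id": "study",
                    "sample_type": "sample",
                    "level_or_id": f"sample_{i}",
                    "nominal": conc,
                    "replicate": rep,
                    "area_analyte": area_analyte,
                    "area_is": area_is,
                }
                row["is_mode"] = mode
                rows.append(row)
    return pd.DataFrame(rows, columns=AREA_COLUMNS + ["is_mode"])


def write_table(frame: pd.DataFrame, path: str | Path, config: SimulationConfig | None = None) -> None:
    """Write a simulated table as CSV, echoing the config as header comments."""
    with open(path, "w") as handle:
        if config is not None:
            for key, value in vars(config).items():
                handle.write(f"# {key} = {value}\n")
        frame.to_csv(handle, index=False)
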