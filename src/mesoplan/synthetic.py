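"""Synthetic assays and fixtures with the statistical structure the
analysis assumes.

The partition-assay generator runs the Nernst forward model (known true
K, sealed well, water = applied volume) and corrupts the supernatant
readings with multiplicative lognormal noise — the natural error model
for a photometric concentration measurement, parameterized by its
coefficient of variation and mean-one so that an undepleted assay reads
the sample concentration on average.  The calibration generator produces
(dilution factor, hydration) pairs from the forward hydration model,
optionally integer-rounded the way published figure captions are.

Seeds are explicit everywhere; no global random state is touched.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import InvalidSpecificationError
from .hydration import CalibrationParams, MesoSystem, round_half_up
from .partition import PartitionAssay, PartitionParams, fraction_incorporated
from .phasemap import PRACTICAL_DILUTION_GRID
from .screens import (
    Additive,
    PlateLayout,
    ProteinSample,
    ScreenSolution,
    build_grid_screen,
    plan_plate,
    with_additive,
)

__all__ = [
    "SyntheticAssaySpec",
    "simulate_partition_assay",
    "simulate_calibration_observations",
    "make_demo_plate",
    "assay_to_csv",
    "assay_from_csv",
]


class SyntheticAssaySpec(BaseModel):
    """Ground truth and noise model for one simulated depletion assay."""

    model_config = ConfigDict(frozen=True)

    k_true: float = Field(ge=0)
    sample_conc: float = Field(default=16.0, gt=0)  # µg/µl, typical BR prep
    applied_volume: float = Field(default=900.0, gt=0)  # nl
    mo_mass: float = Field(default=132.0, gt=0)  # µg
    n_replicates: int = Field(default=8, ge=1)
    noise_cv: float = Field(default=0.05, ge=0)
    seed: int = 0


def simulate_partition_assay(spec: SyntheticAssaySpec) -> PartitionAssay:
    """Forward-simulate a depletion assay from a known K.

    f follows from the partition model with W = applied volume × 1 µg/nl;
    each replicate's supernatant reading is (1−f)·C_0 times a mean-one
    lognormal factor with the requested CV.  Deterministic given the seed.
    """
    f = fraction_incorporated(
        PartitionParams(K=spec.k_true),
        MesoSystem(mo_mass=spec.mo_mass, water_mass=spec.applied_volume * 1.0),
    )
    c_clean = (1.0 - f) * spec.sample_conc
    if spec.noise_cv == 0:
        readings = np.full(spec.n_replicates, c_clean)
    else:
        rng = np.random.default_rng(spec.seed)
        sigma = math.sqrt(math.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=spec.n_replicates)
        readings = c_clean * noise
    return PartitionAssay(
        sample_conc=spec.sample_conc,
        applied_volume=spec.applied_volume,
        mo_mass=spec.mo_mass,
        supernatant_conc=tuple(float(c) for c in readings),
    )


def simulate_calibration_observations(
    true_phi: float,
    dilutions: Sequence[float],
    screen_volume: float,
    mo_mass: float,
    rounded: bool = True,
) -> list[tuple[float, float]]:
    """(d, hydration) pairs from the forward hydration model.

    With ``rounded`` the hydration is reported as an integer percent, the
    precision at which expected hydration levels are printed in figure
    captions; unrounded pairs invert exactly through ``calibrate_phi``.
    """
    if len(set(dilutions)) != len(dilutions):
        raise InvalidSpecificationError("dilution factors must be distinct")
    out = []
    for d in dilutions:
        if d < 1:
            raise InvalidSpecificationError(f"dilution factor {d} < 1")
        w = true_phi * screen_volume / d
        pct = 100.0 * w / (w + mo_mass)
        out.append((float(d), float(round_half_up(pct)) if rounded else pct))
    return out


_ASSAY_COLUMNS = [
    "well",
    "sample_conc_ug_ul",
    "applied_volume_nl",
    "mo_mass_ug",
    "supernatant_conc_ug_ul",
]


def assay_to_csv(assay: PartitionAssay) -> str:
    """Serialize an assay as replicate-per-row CSV (wells numbered A1..)."""
    lines = [",".join(_ASSAY_COLUMNS)]
    for i, c in enumerate(assay.supernatant_conc):
        well = f"{'ABCDEFGH'[i // 12]}{i % 12 + 1}"
        lines.append(
            f"{well},{assay.sample_conc!r},{assay.applied_volume!r},"
            f"{assay.mo_mass!r},{c!r}"
        )
    return "\n".join(lines) + "\n"


def assay_from_csv(text: str) -> PartitionAssay:
    """Parse a replicate-per-row assay CSV (inverse of :func:`assay_to_csv`).

    All rows must share the sample concentration, applied volume and
    monoolein mass — one assay per file.
    """
    import csv as _csv
    import io as _io

    rows = list(_csv.DictReader(_io.StringIO(text)))
    if not rows:
        raise InvalidSpecificationError("assay CSV has no data rows")
    missing = set(_ASSAY_COLUMNS) - set(rows[0])
    if missing:
        raise InvalidSpecificationError(f"assay CSV missing columns {sorted(missing)}")
    heads = {
        (r["sample_conc_ug_ul"], r["applied_volume_nl"], r["mo_mass_ug"]) for r in rows
    }
    if len(heads) != 1:
        raise InvalidSpecificationError(
            "assay CSV mixes multiple sample/volume/monoolein combinations"
        )
    return PartitionAssay(
        sample_conc=float(rows[0]["sample_conc_ug_ul"]),
        applied_volume=float(rows[0]["applied_volume_nl"]),
        mo_mass=float(rows[0]["mo_mass_ug"]),
        supernatant_conc=tuple(float(r["supernatant_conc_ug_ul"]) for r in rows),
    )


def make_demo_plate(
    seed: int = 0,
) -> tuple[PlateLayout, PlateLayout, PartitionAssay]:
    """Deterministic fixture bundle for tests and documentation.

    Returns a full 8 × 12 phosphate grid plate (pH 4.5–8.5, 0.5–4.0 M,
    undiluted), an additive plate mixing 10 % (v/v) sodium malonate into
    an ammonium sulfate screen across the practical dilution grid, and a
    synthetic depletion assay (K_true = 50, cv = 5 %, n = 8) whose
    estimate lands within a few percent of the truth.
    """
    sample = ProteinSample(name="demo-BR", concentration=16.0)
    grid = build_grid_screen(4.5, 8.5, 0.5, 4.0, 8, 12)
    grid_plate = plan_plate(
        sample, grid, "MO132", dilutions=(4.0,), metadata={"purpose": "grid"}
    )
    base = with_additive(
        ScreenSolution(precipitant="(NH4)2SO4", concentration=3.3),
        Additive(name="sodium malonate", concentration=0.5, unit="M"),
        0.10,
    )
    additive_plate = plan_plate(
        sample,
        [base],
        "MO132",
        dilutions=PRACTICAL_DILUTION_GRID,
        metadata={"purpose": "additive"},
    )
    assay = simulate_partition_assay(SyntheticAssaySpec(k_true=50.0, seed=seed))
    return grid_plate, additive_plate, assay
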