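"""Vapor-diffusion endpoint mass balance for in meso crystallization drops.

In a controlled in meso phase (CIMP) experiment a droplet of protein
solution plus (possibly diluted) screening solution sits on a monoolein
coating and equilibrates through the vapor phase against a reservoir of
undiluted screening solution.  Water leaves the droplet until the
precipitant concentration in the droplet matches the reservoir, so the
endpoint droplet volume is fixed by the amount of precipitant dispensed:

    V_f = V_s / d        (screen volume V_s, screen dilution factor d)

The water remaining at equilibrium hydrates the lipid.  The hydration
level of the condensed monoolein/water system,

    w = 100 * W / (W + M)      [wt% water]

selects the mesophase (see :mod:`mesoplan.phasemap`).  The single
calibration constant ``phi`` converts equilibrated droplet volume to water
mass (µg water per nl of droplet); it absorbs the solute mass fraction of
the equilibrated droplet and is recoverable from published expected
hydration levels via :func:`calibrate_phi`.

Units, package-wide: volumes in nl, masses in µg, water density 1 µg/nl,
precipitant concentrations in mol/l.
"""

from __future__ import annotations

import math
from typing import Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import minimize_scalar

from .errors import InvalidSpecificationError, UnderDeterminedError

__all__ = [
    "MesoSystem",
    "DropletSpec",
    "CalibrationParams",
    "EquilibriumResult",
    "CalibrationResult",
    "equilibrium_droplet_volume",
    "water_weight_fraction",
    "initial_hydration",
    "expected_final_hydration",
    "final_meso_system",
    "calibrate_phi",
    "round_half_up",
]

#: density of the pre-equilibration aqueous phase, µg per nl
WATER_DENSITY_UG_PER_NL = 1.0


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf.

    Python's builtin ``round`` is banker's rounding; reported hydration
    levels use the conventional half-up rule instead.
    """
    return int(math.floor(x + 0.5))


class MesoSystem(BaseModel):
    """A condensed monoolein/water system.

    Attributes
    ----------
    mo_mass:
        Monoolein mass M in µg (e.g. 132 µg per well on standard plates).
    water_mass:
        Total water mass W in µg, counting the water inside the mesophase
        and any coexisting excess aqueous phase.
    """

    model_config = ConfigDict(frozen=True)

    mo_mass: float = Field(gt=0)
    water_mass: float = Field(ge=0)


class DropletSpec(BaseModel):
    """One vapor-diffusion crystallization droplet before equilibration.

    ``protein_volume`` nl of sample plus ``screen_volume`` nl of screening
    solution diluted by ``dilution_factor`` relative to the reservoir
    (whose precipitant concentration is ``reservoir_conc`` mol/l).
    ``protein_buffer_conc`` optionally adds a precipitant contribution from
    the protein buffer itself; by default the protein solution is assumed
    to carry no precipitant.
    """

    model_config = ConfigDict(frozen=True)

    protein_volume: float = Field(gt=0)
    screen_volume: float = Field(gt=0)
    dilution_factor: float = Field(ge=1)
    reservoir_conc: float = Field(default=1.0, gt=0)
    protein_buffer_conc: float = Field(default=0.0, ge=0)


class CalibrationParams(BaseModel):
    """Constants linking droplet volumes to water masses.

    ``phi`` is the effective water mass per nl of *equilibrated* droplet
    (µg/nl); it is below 1 because the equilibrated droplet is concentrated
    precipitant solution, not pure water.  ``water_density_initial``
    applies to the dilute pre-equilibration droplet.
    """

    model_config = ConfigDict(frozen=True)

    phi: float = Field(default=0.88, gt=0, le=1.1)
    water_density_initial: float = Field(default=WATER_DENSITY_UG_PER_NL, gt=0)


class EquilibriumResult(BaseModel):
    """Endpoint state of one droplet after vapor-diffusion equilibration."""

    model_config = ConfigDict(frozen=True)

    final_droplet_volume: float = Field(ge=0)
    final_water_mass: float = Field(ge=0)
    hydration_pct: float = Field(ge=0, lt=100)
    rounded_hydration_pct: int

    @model_validator(mode="after")
    def _consistent_rounding(self) -> "EquilibriumResult":
        if self.rounded_hydration_pct != round_half_up(self.hydration_pct):
            raise ValueError("rounded_hydration_pct inconsistent with hydration_pct")
        return self


def equilibrium_droplet_volume(spec: DropletSpec) -> float:
    """Endpoint droplet volume in nl.

    Precipitant moles are conserved while water leaves through the vapor
    phase, and shrinking stops when the droplet concentration equals the
    reservoir concentration C_R.  Moles added: V_s·C_R/d from the screen
    aliquot (plus any protein-buffer term), hence

        V_f = V_s/d + V_p·C_pb/C_R

    which for the default C_pb = 0 is independent of the protein volume
    and of the absolute reservoir concentration.
    """
    v = spec.screen_volume / spec.dilution_factor
    if spec.protein_buffer_conc > 0:
        v += spec.protein_volume * spec.protein_buffer_conc / spec.reservoir_conc
    return v


def water_weight_fraction(system: MesoSystem) -> float:
    """Hydration level w = 100·W/(W+M) in wt% water."""
    return 100.0 * system.water_mass / (system.water_mass + system.mo_mass)


def initial_hydration(
    spec: DropletSpec,
    cal: CalibrationParams,
    mo_mass: float,
) -> float:
    """Hydration level right after dispensing, before any vapor loss.

    The full dispensed volume counts as water at the initial density
    (the droplet is dilute); e.g. 900 nl on 132 µg monoolein gives 87 %.
    """
    if mo_mass <= 0:
        raise InvalidSpecificationError("mo_mass must be positive")
    water = (spec.protein_volume + spec.screen_volume) * cal.water_density_initial
    return water_weight_fraction(MesoSystem(mo_mass=mo_mass, water_mass=water))


def expected_final_hydration(
    spec: DropletSpec,
    cal: CalibrationParams,
    mo_mass: float,
) -> EquilibriumResult:
    """Expected hydration level of the mesophase at the vapor-diffusion endpoint.

    Final water mass is φ·V_f with V_f from
    :func:`equilibrium_droplet_volume`; hydration is the weight fraction of
    that water in the water+monoolein system.  Strictly decreasing in the
    dilution factor and increasing in the screen volume.
    """
    if mo_mass <= 0:
        raise InvalidSpecificationError("mo_mass must be positive")
    v_f = equilibrium_droplet_volume(spec)
    w = cal.phi * v_f
    pct = water_weight_fraction(MesoSystem(mo_mass=mo_mass, water_mass=w))
    return EquilibriumResult(
        final_droplet_volume=v_f,
        final_water_mass=w,
        hydration_pct=pct,
        rounded_hydration_pct=round_half_up(pct),
    )


def final_meso_system(
    spec: DropletSpec,
    cal: CalibrationParams,
    mo_mass: float,
) -> MesoSystem:
    """The equilibrated monoolein/water system implied by a droplet spec."""
    if mo_mass <= 0:
        raise InvalidSpecificationError("mo_mass must be positive")
    return MesoSystem(
        mo_mass=mo_mass, water_mass=cal.phi * equilibrium_droplet_volume(spec)
    )


class CalibrationResult(BaseModel):
    """Output of :func:`calibrate_phi`: fitted constants plus fit report."""

    model_config = ConfigDict(frozen=True)

    params: CalibrationParams
    residuals: tuple[float, ...]  # model − observed, percentage points, per input
    max_abs_residual: float


def _model_hydration(phi: float, d: float, screen_volume: float, mo_mass: float) -> float:
    w = phi * screen_volume / d
    return 100.0 * w / (w + mo_mass)


def calibrate_phi(
    observations: Sequence[tuple[float, float]],
    screen_volume: float,
    mo_mass: float,
    bounds: tuple[float, float] = (0.5, 1.1),
) -> CalibrationResult:
    """Recover φ from (dilution factor, reported hydration wt%) pairs.

    Finds the φ minimizing the maximum absolute residual between the
    forward model and the reported levels (minimax, so a single outlying
    rounded caption value cannot dominate).  With a single observation the
    closed-form inversion φ = w·M·d / ((100−w)·V_s) is used.

    Raises
    ------
    UnderDeterminedError
        Fewer than one observation, or several observations all sharing
        one dilution factor (duplicate d cannot separate φ from noise).
    """
    if screen_volume <= 0 or mo_mass <= 0:
        raise InvalidSpecificationError("screen_volume and mo_mass must be positive")
    obs = [(float(d), float(w)) for d, w in observations]
    if not obs:
        raise UnderDeterminedError("at least one (dilution, hydration) pair required")
    for d, w in obs:
        if d < 1:
            raise InvalidSpecificationError(f"dilution factor {d} < 1")
        if not 0 < w < 100:
            raise InvalidSpecificationError(f"hydration {w} outside (0, 100)")

    if len(obs) > 1 and len({d for d, _ in obs}) == 1:
        raise UnderDeterminedError(
            "all observations share one dilution factor; phi is under-determined"
        )

    if len(obs) == 1:
        d, w = obs[0]
        phi = w * mo_mass * d / ((100.0 - w) * screen_volume)
    else:
        def worst(phi: float) -> float:
            return max(
                abs(_model_hydration(phi, d, screen_volume, mo_mass) - w)
                for d, w in obs
            )

        res = minimize_scalar(
            worst, bounds=bounds, method="bounded", options={"xatol": 1e-7}
        )
        phi = float(res.x)

    residuals = tuple(
        _model_hydration(phi, d, screen_volume, mo_mass) - w for d, w in obs
    )
    return CalibrationResult(
        params=CalibrationParams(phi=phi),
        residuals=residuals,
        max_abs_residual=max(abs(r) for r in residuals),
    )
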