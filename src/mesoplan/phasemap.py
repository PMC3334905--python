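"""Monoolein/water mesophase classification and dilution targeting at 22 °C.

With increasing water content monoolein passes through the crystalline
lamellar phase (Lc), fluid lamellar phase (Lα), the gyroid cubic phase
(Ia3d), the diamond cubic phase (Pn3m), and finally Pn3m coexisting with
excess aqueous phase.  The default interval bounds below are read off the
published 22 °C isotherm and tuned so that the hydration levels reachable
in the standard experiment land in the phases a crystallographer expects:
60–75 % is excess-water, 43 % is cubic (Pn3m), and 30 % sits on the
cubic/lamellar boundary.  Real screens shift these boundaries (salt,
detergent, protein all perturb the diagram), so the map is a configurable
value, not a constant.

The inverse problem — which screen dilution factor d targets a desired
hydration — has the closed form

    d = φ·V_s·(100 − w) / (w·M)

obtained by inverting the endpoint hydration model of
:mod:`mesoplan.hydration`.
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Sequence

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import InvalidSpecificationError, TargetUnreachableError
from .hydration import CalibrationParams

__all__ = [
    "PhaseMap",
    "PhaseCall",
    "DilutionRecommendation",
    "DEFAULT_PHASE_MAP",
    "PRACTICAL_DILUTION_GRID",
    "classify_phase",
    "dilution_for_hydration",
    "max_reachable_hydration",
    "dilution_series_for_phases",
]

#: dilutions routinely pipettable in a screening campaign
PRACTICAL_DILUTION_GRID: tuple[float, ...] = (1.0, 2.0, 4.0, 7.0)

#: human-readable names for the phase boundaries of the default map
_BOUNDARY_ALIASES = {
    frozenset({"Lc", "L_alpha"}): "Lc/L_alpha",
    frozenset({"L_alpha", "Ia3d"}): "cubic/lamellar",
    frozenset({"Ia3d", "Pn3m"}): "Ia3d/Pn3m",
    frozenset({"Pn3m", "Pn3m_excess_water"}): "cubic/excess water",
}


class PhaseMap(BaseModel):
    """Ordered partition of hydration [0, 100] wt% into mesophase labels.

    ``intervals`` is a list of (upper bound, label) pairs with strictly
    increasing bounds ending at 100; interval i covers
    (previous bound, bound] (the first covers [0, bound]).
    """

    model_config = ConfigDict(frozen=True)

    intervals: tuple[tuple[float, str], ...]
    temperature_c: float = 22.0

    @field_validator("intervals")
    @classmethod
    def _ordered_partition(cls, v):
        if not v:
            raise ValueError("phase map needs at least one interval")
        bounds = [b for b, _ in v]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"bounds must be strictly increasing, got {bounds}")
        if bounds[0] <= 0 or bounds[-1] != 100:
            raise ValueError("bounds must lie in (0, 100] and end at 100")
        if len({lab for _, lab in v}) != len(v):
            raise ValueError("phase labels must be unique")
        return v

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, lab in self.intervals)

    def interval_of(self, label: str) -> tuple[float, float]:
        """(lower, upper) hydration bounds of a phase label."""
        lower = 0.0
        for upper, lab in self.intervals:
            if lab == label:
                return lower, upper
            lower = upper
        raise KeyError(f"unknown phase label {label!r}")

    def boundaries(self) -> list[tuple[float, str]]:
        """Internal boundaries as (hydration, name) with field aliases."""
        out = []
        for (b, lab_lo), (_, lab_hi) in zip(self.intervals, self.intervals[1:]):
            name = _BOUNDARY_ALIASES.get(frozenset({lab_lo, lab_hi}), f"{lab_lo}/{lab_hi}")
            out.append((b, name))
        return out


DEFAULT_PHASE_MAP = PhaseMap(
    intervals=(
        (4.0, "Lc"),
        (30.0, "L_alpha"),
        (37.0, "Ia3d"),
        (45.0, "Pn3m"),
        (100.0, "Pn3m_excess_water"),
    )
)


class PhaseCall(BaseModel):
    """Result of classifying one hydration level.

    ``boundary`` is set when the hydration lies within the tagging
    tolerance of an internal phase boundary — conditions printed as e.g.
    "cubic/lamellar" are exactly such boundary conditions.
    """

    model_config = ConfigDict(frozen=True)

    hydration_pct: float
    label: str
    boundary: str | None = None


def classify_phase(
    hydration: float,
    phase_map: PhaseMap = DEFAULT_PHASE_MAP,
    boundary_tol: float = 1.5,
) -> PhaseCall:
    """Map a hydration level (wt% water) to a mesophase label.

    Values within ``boundary_tol`` percentage points of an internal
    boundary additionally carry that boundary's name.
    """
    if not 0 <= hydration <= 100:
        raise InvalidSpecificationError(
            f"hydration {hydration} outside [0, 100] wt%"
        )
    bounds = [b for b, _ in phase_map.intervals]
    idx = bisect_left(bounds, hydration)
    idx = min(idx, len(bounds) - 1)
    label = phase_map.intervals[idx][1]

    boundary = None
    best = boundary_tol
    for b, name in phase_map.boundaries():
        if abs(hydration - b) <= best:
            best = abs(hydration - b)
            boundary = name
    return PhaseCall(hydration_pct=hydration, label=label, boundary=boundary)


def max_reachable_hydration(
    screen_volume: float, mo_mass: float, cal: CalibrationParams
) -> float:
    """Highest expected hydration, attained with undiluted screen (d = 1)."""
    w = cal.phi * screen_volume
    return 100.0 * w / (w + mo_mass)


def dilution_for_hydration(
    target: float,
    screen_volume: float,
    mo_mass: float,
    cal: CalibrationParams,
) -> float:
    """Screen dilution factor that targets a hydration level.

    Exact inverse of the endpoint hydration model; raises
    :class:`TargetUnreachableError` when the target would require d < 1
    (i.e. a screen *more* concentrated than the reservoir).
    """
    if screen_volume <= 0 or mo_mass <= 0:
        raise InvalidSpecificationError("screen_volume and mo_mass must be positive")
    if not 0 < target < 100:
        raise InvalidSpecificationError(f"target hydration {target} outside (0, 100)")
    d = cal.phi * screen_volume * (100.0 - target) / (target * mo_mass)
    if d < 1.0:
        hi = max_reachable_hydration(screen_volume, mo_mass, cal)
        raise TargetUnreachableError(
            f"hydration {target:.1f}% needs dilution factor {d:.3f} < 1; "
            f"reachable range is (0, {hi:.1f}%] with this screen volume "
            f"({screen_volume} nl) and monoolein mass ({mo_mass} µg)"
        )
    return d


class DilutionRecommendation(BaseModel):
    """One row of a dilution series: which d targets which phase."""

    model_config = ConfigDict(frozen=True)

    phase: str
    target_hydration_pct: float
    dilution_factor: float
    snapped_dilution_factor: float | None = None
    predicted_hydration_pct: float
    predicted_label: str
    predicted_boundary: str | None = None


def _resolve_target(phase: str, phase_map: PhaseMap) -> float:
    """Hydration target for a phase label (interval midpoint) or a
    boundary name (the boundary hydration itself)."""
    if phase in phase_map.labels:
        lo, hi = phase_map.interval_of(phase)
        return (lo + hi) / 2.0
    for b, name in phase_map.boundaries():
        if phase == name:
            return b
    raise InvalidSpecificationError(
        f"unknown phase or boundary {phase!r}; known labels {phase_map.labels}, "
        f"boundaries {[n for _, n in phase_map.boundaries()]}"
    )


def dilution_series_for_phases(
    phases: Sequence[str],
    screen_volume: float,
    mo_mass: float,
    cal: CalibrationParams,
    phase_map: PhaseMap = DEFAULT_PHASE_MAP,
    snap_grid: Sequence[float] | None = None,
) -> tuple[list[DilutionRecommendation], list[tuple[str, str]]]:
    """Recommend one screen dilution per requested phase.

    ``phases`` may mix phase labels (targeted at their interval midpoint)
    and boundary names such as ``"cubic/lamellar"`` (targeted at the
    boundary).  With ``snap_grid`` set (e.g.
    :data:`PRACTICAL_DILUTION_GRID`) each exact d is additionally snapped
    to the nearest practical value.  Unreachable phases are skipped and
    returned in the second element as (phase, reason) records.
    """
    if not phases:
        raise InvalidSpecificationError("phases must be non-empty")
    recs: list[DilutionRecommendation] = []
    skipped: list[tuple[str, str]] = []
    for phase in phases:
        target = _resolve_target(phase, phase_map)
        try:
            d = dilution_for_hydration(target, screen_volume, mo_mass, cal)
        except TargetUnreachableError as err:
            skipped.append((phase, str(err)))
            continue
        snapped = min(snap_grid, key=lambda g: abs(g - d)) if snap_grid else None
        d_used = snapped if snapped is not None else d
        w_pred = cal.phi * screen_volume / d_used
        pred = 100.0 * w_pred / (w_pred + mo_mass)
        call = classify_phase(pred, phase_map)
        recs.append(
            DilutionRecommendation(
                phase=phase,
                target_hydration_pct=target,
                dilution_factor=d,
                snapped_dilution_factor=snapped,
                predicted_hydration_pct=pred,
                predicted_label=call.label,
                predicted_boundary=call.boundary,
            )
        )
    return recs, skipped
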