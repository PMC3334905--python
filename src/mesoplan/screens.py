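"""Screen composition, 96-well plate layouts and robot worklists.

Covers the bench side of a controlled in meso crystallization campaign:
grid screens (pH × precipitant concentration), additive mixing at a fixed
v/v fraction, screen dilution series, assembly of SBS 96-well plates on
monoolein-precoated formats, and a flat CSV worklist a liquid-handling
robot (or a patient human) can execute.

Plate formats mirror the commercial precoated consumables: 132 µg
monoolein per well with 450 + 450 nl droplets and a 75 µl reservoir, the
scaled-down 29 µg format with 100 + 100 nl, and a foil hanging-drop
variant with 100 µg spots, 300 + 300 nl and 50 µl reservoirs.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import (
    InvalidSpecificationError,
    PlateValidationError,
    WorklistParseError,
)
from .hydration import (
    CalibrationParams,
    DropletSpec,
    EquilibriumResult,
    expected_final_hydration,
)
from .phasemap import DEFAULT_PHASE_MAP, PhaseCall, PhaseMap, classify_phase

__all__ = [
    "Additive",
    "ScreenSolution",
    "ProteinSample",
    "Timeline",
    "WellCondition",
    "PlateFormat",
    "PLATE_FORMATS",
    "PlateLayout",
    "well_ids",
    "build_grid_screen",
    "with_additive",
    "dilute_screen",
    "plan_plate",
    "plan_plates",
    "export_worklist",
    "import_worklist",
    "write_worklist",
    "read_worklist",
]

ROWS = "ABCDEFGH"
N_COLS = 12


def well_ids() -> list[str]:
    """The 96 SBS well ids A1..H12 in row-major order."""
    return [f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1)]


_WELL_SET = frozenset(well_ids())


class Additive(BaseModel):
    """One additive component of a screening solution."""

    model_config = ConfigDict(frozen=True)

    name: str
    concentration: float = Field(ge=0)
    unit: str = "M"


class ScreenSolution(BaseModel):
    """A screening (precipitant) solution, possibly with additives.

    ``volume_fractions`` records the v/v makeup (base precipitant stock
    vs. additive stocks) and must sum to 1.
    """

    model_config = ConfigDict(frozen=True)

    precipitant: str
    concentration: float = Field(ge=0)  # mol/l
    ph: float | None = None
    additives: tuple[Additive, ...] = ()
    volume_fractions: tuple[tuple[str, float], ...] = (("base", 1.0),)

    @field_validator("volume_fractions")
    @classmethod
    def _sums_to_one(cls, v):
        total = sum(f for _, f in v)
        if any(f < 0 for _, f in v):
            raise ValueError("volume fractions must be >= 0")
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"volume fractions sum to {total}, expected 1")
        return v


class ProteinSample(BaseModel):
    """The protein solution dispensed onto the dry lipid."""

    model_config = ConfigDict(frozen=True)

    name: str = "protein"
    concentration: float = Field(gt=0)  # µg/µl


class Timeline(BaseModel):
    """Protocol timing constants (metadata; nothing is simulated)."""

    model_config = ConfigDict(frozen=True)

    swelling_hours: float = 3.0
    temperature_c: float = 22.0
    inspection_interval_days: float = 7.0


@dataclass(frozen=True)
class PlateFormat:
    """One monoolein-precoated consumable format."""

    name: str
    mo_mass_ug: float
    protein_volume_nl: int
    screen_volume_nl: int
    reservoir_volume_ul: float


PLATE_FORMATS: dict[str, PlateFormat] = {
    "MO132": PlateFormat("MO132", 132.0, 450, 450, 75.0),
    "MO29": PlateFormat("MO29", 29.0, 100, 100, 75.0),
    "FOIL100": PlateFormat("FOIL100", 100.0, 300, 300, 50.0),
}


def _get_format(fmt: "PlateFormat | str") -> PlateFormat:
    if isinstance(fmt, PlateFormat):
        return fmt
    try:
        return PLATE_FORMATS[fmt]
    except KeyError:
        raise InvalidSpecificationError(
            f"unknown plate format {fmt!r}; known: {sorted(PLATE_FORMATS)}"
        ) from None


class WellCondition(BaseModel):
    """One crystallization experiment on the plate."""

    model_config = ConfigDict(frozen=True)

    well: str
    protein_volume_nl: int = Field(gt=0)
    protein_conc_ug_ul: float = Field(gt=0)
    screen_volume_nl: int = Field(gt=0)
    screen: ScreenSolution  # the diluted aliquot added to the droplet
    dilution_factor: float = Field(ge=1)
    reservoir: ScreenSolution  # undiluted, in the reservoir well
    reservoir_volume_ul: float = Field(gt=0)
    mo_mass_ug: float = Field(gt=0)
    predicted: EquilibriumResult
    phase: PhaseCall
    timeline: Timeline = Timeline()

    @field_validator("well")
    @classmethod
    def _valid_well(cls, v):
        if v not in _WELL_SET:
            raise ValueError(f"well id {v!r} not in SBS A1–H12")
        return v

    @property
    def protein_mass_ug(self) -> float:
        """Protein consumed in this well: volume × concentration."""
        return self.protein_volume_nl * self.protein_conc_ug_ul / 1000.0


class PlateLayout(BaseModel):
    """A 96-well CIMP plate: format, occupied wells, free-form metadata."""

    model_config = ConfigDict(frozen=True)

    plate_format: str
    wells: tuple[WellCondition, ...] = ()
    metadata: tuple[tuple[str, str], ...] = ()

    @model_validator(mode="after")
    def _validate_plate(self) -> "PlateLayout":
        fmt = _get_format(self.plate_format)
        ids = [w.well for w in self.wells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PlateValidationError(f"duplicate well ids: {dupes}")
        bad = [
            w.well
            for w in self.wells
            if w.protein_volume_nl != fmt.protein_volume_nl
            or w.screen_volume_nl != fmt.screen_volume_nl
            or w.mo_mass_ug != fmt.mo_mass_ug
        ]
        if bad:
            raise PlateValidationError(
                f"wells {bad} have volumes/monoolein inconsistent with "
                f"format {fmt.name} "
                f"({fmt.protein_volume_nl}+{fmt.screen_volume_nl} nl, "
                f"{fmt.mo_mass_ug} µg)"
            )
        return self

    @property
    def total_protein_ug(self) -> float:
        return sum(w.protein_mass_ug for w in self.wells)

    def meta(self) -> dict[str, str]:
        return dict(self.metadata)


def build_grid_screen(
    ph_min: float,
    ph_max: float,
    conc_min: float,
    conc_max: float,
    n_ph: int,
    n_conc: int,
    precipitant: str = "Na/K phosphate",
) -> list[ScreenSolution]:
    """Uniform pH × concentration grid, endpoints included, row-major.

    Rows run over pH, columns over concentration, so an 8 × 12 grid fills
    one plate with pH constant along each row.  Grids larger than 96 are
    returned whole with a warning (``plan_plates`` splits them).
    """
    if ph_min >= ph_max or conc_min >= conc_max:
        raise InvalidSpecificationError("axis minima must be below maxima")
    if n_ph < 2 or n_conc < 2:
        raise InvalidSpecificationError(
            "each grid axis needs at least 2 points to include both endpoints"
        )
    if n_ph * n_conc > 96:
        warnings.warn(
            f"grid of {n_ph * n_conc} conditions exceeds one 96-well plate; "
            "split across plates with plan_plates()",
            stacklevel=2,
        )
    phs = np.linspace(ph_min, ph_max, n_ph)
    concs = np.linspace(conc_min, conc_max, n_conc)
    return [
        ScreenSolution(precipitant=precipitant, concentration=float(c), ph=float(p))
        for p in phs
        for c in concs
    ]


def with_additive(
    base: ScreenSolution, additive: Additive, fraction: float = 0.10
) -> ScreenSolution:
    """Mix an additive into a screen at a v/v fraction (default 10 %).

    Replacing ``fraction`` of the volume with additive stock dilutes the
    base precipitant (and any prior additives) by (1 − fraction); the new
    additive enters at its stock concentration × fraction.
    """
    if fraction == 0:
        return base
    if not 0 < fraction < 1:
        raise InvalidSpecificationError(f"fraction {fraction} outside (0, 1)")
    scaled = tuple(
        a.model_copy(update={"concentration": a.concentration * (1 - fraction)})
        for a in base.additives
    )
    new = additive.model_copy(
        update={"concentration": additive.concentration * fraction}
    )
    fractions = tuple(
        (name, f * (1 - fraction)) for name, f in base.volume_fractions
    ) + ((additive.name, fraction),)
    return base.model_copy(
        update={
            "concentration": base.concentration * (1 - fraction),
            "additives": scaled + (new,),
            "volume_fractions": fractions,
        }
    )


def dilute_screen(reservoir: ScreenSolution, d: float) -> ScreenSolution:
    """Dilute a reservoir solution by factor d (all solutes divided by d)."""
    if d < 1:
        raise InvalidSpecificationError(f"dilution factor {d} < 1")
    if d == 1:
        return reservoir
    return reservoir.model_copy(
        update={
            "concentration": reservoir.concentration / d,
            "additives": tuple(
                a.model_copy(update={"concentration": a.concentration / d})
                for a in reservoir.additives
            ),
        }
    )


def plan_plate(
    sample: ProteinSample,
    screens: Sequence[ScreenSolution],
    fmt: PlateFormat | str,
    dilutions: Sequence[float] = (1.0,),
    cal: CalibrationParams = CalibrationParams(),
    phase_map: PhaseMap = DEFAULT_PHASE_MAP,
    metadata: dict[str, str] | None = None,
) -> PlateLayout:
    """Lay out screens × dilutions on one 96-well plate.

    Conditions are assigned row-major (A1, A2, …); each well stores the
    diluted droplet aliquot, the undiluted reservoir, and the predicted
    endpoint hydration and mesophase from the forward model.  An empty
    screen list yields a valid empty layout.  Per-well failures are
    re-raised naming the offending well.
    """
    fmt = _get_format(fmt)
    conditions = [(s, float(d)) for s in screens for d in dilutions]
    if len(conditions) > 96:
        raise PlateValidationError(
            f"{len(conditions)} conditions exceed one plate; use plan_plates()"
        )
    meta = dict(metadata or {})
    meta.setdefault("protein", sample.name)
    meta.setdefault("phi", repr(cal.phi))
    wells = []
    for well_id, (screen, d) in zip(well_ids(), conditions):
        try:
            spec = DropletSpec(
                protein_volume=fmt.protein_volume_nl,
                screen_volume=fmt.screen_volume_nl,
                dilution_factor=d,
            )
            predicted = expected_final_hydration(spec, cal, fmt.mo_mass_ug)
            phase = classify_phase(predicted.hydration_pct, phase_map)
            wells.append(
                WellCondition(
                    well=well_id,
                    protein_volume_nl=fmt.protein_volume_nl,
                    protein_conc_ug_ul=sample.concentration,
                    screen_volume_nl=fmt.screen_volume_nl,
                    screen=dilute_screen(screen, d),
                    dilution_factor=d,
                    reservoir=screen,
                    reservoir_volume_ul=fmt.reservoir_volume_ul,
                    mo_mass_ug=fmt.mo_mass_ug,
                    predicted=predicted,
                    phase=phase,
                )
            )
        except (ValueError, InvalidSpecificationError) as err:
            raise PlateValidationError(f"well {well_id}: {err}") from err
    return PlateLayout(
        plate_format=fmt.name, wells=tuple(wells), metadata=tuple(sorted(meta.items()))
    )


def plan_plates(
    sample: ProteinSample,
    screens: Sequence[ScreenSolution],
    fmt: PlateFormat | str,
    dilutions: Sequence[float] = (1.0,),
    **kwargs,
) -> list[PlateLayout]:
    """Like :func:`plan_plate` but splits > 96 conditions across plates."""
    per_plate = max(1, 96 // max(1, len(dilutions)))
    chunks = [screens[i : i + per_plate] for i in range(0, len(screens), per_plate)]
    if len(chunks) > 1:
        warnings.warn(
            f"{len(screens) * len(dilutions)} conditions split across "
            f"{len(chunks)} plates",
            stacklevel=2,
        )
    layouts = []
    for i, chunk in enumerate(chunks or [[]]):
        meta = dict(kwargs.pop("metadata", {}) or {}) if i == 0 else {}
        meta["plate_index"] = str(i + 1)
        layouts.append(plan_plate(sample, chunk, fmt, dilutions, metadata=meta, **kwargs))
    return layouts


# ---------------------------------------------------------------------------
# Worklist CSV
#
# Three dispensing rows per well in protocol order: protein onto the dry
# lipid (step 1), then — after sealing and the 3 h swelling — the diluted
# screen into the droplet (step 2) and undiluted screen into the reservoir
# (step 3).  Volumes are integers in nl.  Solution compositions ride along
# as extra columns and layout-level facts as '#'-prefixed header lines, so
# the file is self-contained and import is an exact inverse.
# ---------------------------------------------------------------------------

_WL_VERSION = "mesoplan-worklist v1"
_WL_COLUMNS = [
    "step",
    "action",
    "source",
    "well",
    "volume_nl",
    "dilution_factor",
    "protein_conc_ug_ul",
    "precipitant",
    "conc_molar",
    "ph",
    "additives",
    "volume_fractions",
]


def _screen_cols(s: ScreenSolution) -> list[str]:
    return [
        s.precipitant,
        repr(s.concentration),
        "" if s.ph is None else repr(s.ph),
        json.dumps([a.model_dump() for a in s.additives], sort_keys=True)
        if s.additives
        else "",
        json.dumps(list(map(list, s.volume_fractions))),
    ]


def _screen_from_cols(
    precipitant: str, conc: str, ph: str, additives: str, fractions: str
) -> ScreenSolution:
    return ScreenSolution(
        precipitant=precipitant,
        concentration=float(conc),
        ph=None if ph == "" else float(ph),
        additives=tuple(Additive(**a) for a in json.loads(additives)) if additives else (),
        volume_fractions=tuple((n, f) for n, f in json.loads(fractions)),
    )


def export_worklist(layout: PlateLayout) -> str:
    """Serialize a plate layout to the worklist CSV text."""
    buf = io.StringIO()
    buf.write(f"# {_WL_VERSION}\n")
    buf.write(f"# plate_format={layout.plate_format}\n")
    buf.write(f"# metadata={json.dumps(layout.meta(), sort_keys=True)}\n")
    buf.write(",".join(_WL_COLUMNS) + "\n")
    for w in layout.wells:
        rows = [
            ["1", "dispense_protein", "protein_sample", w.well,
             str(w.protein_volume_nl), "", repr(w.protein_conc_ug_ul),
             "", "", "", "", ""],
            ["2", "dispense_screen", "screen_diluted", w.well,
             str(w.screen_volume_nl), repr(w.dilution_factor), ""]
            + _screen_cols(w.screen),
            ["3", "fill_reservoir", "screen_reservoir", w.well,
             str(int(round(w.reservoir_volume_ul * 1000))), "", ""]
            + _screen_cols(w.reservoir),
        ]
        for row in rows:
            buf.write(",".join(_csv_quote(c) for c in row) + "\n")
    return buf.getvalue()


def _csv_quote(cell: str) -> str:
    if any(ch in cell for ch in ',"\n'):
        return '"' + cell.replace('"', '""') + '"'
    return cell


def _csv_split(line: str, row: int) -> list[str]:
    import csv

    try:
        return next(csv.reader([line]))
    except (csv.Error, StopIteration) as err:
        raise WorklistParseError(str(err), row=row) from err


def import_worklist(
    text: str,
    cal: CalibrationParams | None = None,
    phase_map: PhaseMap = DEFAULT_PHASE_MAP,
) -> PlateLayout:
    """Rebuild a plate layout from worklist CSV text.

    Endpoint predictions are recomputed from the dispensing inputs using
    the φ stored in the file header (or ``cal`` if given), so
    ``import_worklist(export_worklist(layout)) == layout`` whenever the
    layout was planned with the same phase map.
    """
    lines = text.splitlines()
    if not lines or lines[0] != f"# {_WL_VERSION}":
        raise WorklistParseError(
            f"missing version line '# {_WL_VERSION}'", row=1
        )
    meta: dict[str, str] = {}
    plate_format = None
    body_start = None
    for i, line in enumerate(lines):
        if line.startswith("# plate_format="):
            plate_format = line.split("=", 1)[1]
        elif line.startswith("# metadata="):
            meta = json.loads(line.split("=", 1)[1])
        elif not line.startswith("#"):
            body_start = i
            break
    if plate_format is None or body_start is None:
        raise WorklistParseError("missing plate_format header or body")
    if lines[body_start] != ",".join(_WL_COLUMNS):
        raise WorklistParseError("unexpected column header", row=body_start + 1)
    if cal is None:
        cal = (
            CalibrationParams(phi=float(meta["phi"]))
            if "phi" in meta
            else CalibrationParams()
        )

    per_well: dict[str, dict[str, list[str]]] = {}
    order: list[str] = []
    for row_no, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        cells = _csv_split(line, row_no)
        if len(cells) != len(_WL_COLUMNS):
            raise WorklistParseError(
                f"expected {len(_WL_COLUMNS)} columns, got {len(cells)}", row=row_no
            )
        rec = dict(zip(_WL_COLUMNS, cells))
        well = rec["well"]
        if well not in per_well:
            per_well[well] = {}
            order.append(well)
        per_well[well][rec["action"]] = cells

    fmt = _get_format(plate_format)
    wells = []
    for well in order:
        recs = per_well[well]
        missing = {"dispense_protein", "dispense_screen", "fill_reservoir"} - set(recs)
        if missing:
            raise WorklistParseError(f"well {well} missing rows: {sorted(missing)}")
        prot = dict(zip(_WL_COLUMNS, recs["dispense_protein"]))
        scr = dict(zip(_WL_COLUMNS, recs["dispense_screen"]))
        res = dict(zip(_WL_COLUMNS, recs["fill_reservoir"]))
        d = float(scr["dilution_factor"])
        spec = DropletSpec(
            protein_volume=int(prot["volume_nl"]),
            screen_volume=int(scr["volume_nl"]),
            dilution_factor=d,
        )
        predicted = expected_final_hydration(spec, cal, fmt.mo_mass_ug)
        wells.append(
            WellCondition(
                well=well,
                protein_volume_nl=int(prot["volume_nl"]),
                protein_conc_ug_ul=float(prot["protein_conc_ug_ul"]),
                screen_volume_nl=int(scr["volume_nl"]),
                screen=_screen_from_cols(
                    scr["precipitant"], scr["conc_molar"], scr["ph"],
                    scr["additives"], scr["volume_fractions"],
                ),
                dilution_factor=d,
                reservoir=_screen_from_cols(
                    res["precipitant"], res["conc_molar"], res["ph"],
                    res["additives"], res["volume_fractions"],
                ),
                reservoir_volume_ul=int(res["volume_nl"]) / 1000.0,
                mo_mass_ug=fmt.mo_mass_ug,
                predicted=predicted,
                phase=classify_phase(predicted.hydration_pct, phase_map),
            )
        )
    return PlateLayout(
        plate_format=plate_format,
        wells=tuple(wells),
        metadata=tuple(sorted(meta.items())),
    )


def write_worklist(layout: PlateLayout, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(export_worklist(layout))


def read_worklist(path, **kwargs) -> PlateLayout:
    with open(path, encoding="utf-8") as fh:
        return import_worklist(fh.read(), **kwargs)
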