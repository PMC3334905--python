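"""End-to-end pipeline: plan → predict hydration/phase → optional K estimate.

Mirrors the standard bench workflow: dispense protein on the dry lipid,
let it swell 3 h, add diluted screen and fill the reservoir, equilibrate.
The pipeline runs the planning calculus over that workflow and emits a
JSON-serializable report with per-well predictions; identical config and
seed give an identical report (a timestamp is only included on request,
so reports are diffable by default).
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

from .config import RunConfig
from .errors import MesoplanError, PipelineError
from .partition import bootstrap_K_interval, estimate_K
from .screens import (
    PlateLayout,
    build_grid_screen,
    export_worklist,
    plan_plate,
    with_additive,
)
from .synthetic import assay_from_csv

__all__ = ["run_pipeline"]

log = logging.getLogger("mesoplan")


def _build_screens(config: RunConfig) -> list:
    spec = config.screens
    if not spec.is_valid():
        raise PipelineError(
            "screens", "exactly one of 'grid' or 'solutions' must be given"
        )
    if spec.grid is not None:
        g = spec.grid
        screens = build_grid_screen(
            g.ph_min, g.ph_max, g.conc_min, g.conc_max, g.n_ph, g.n_conc,
            precipitant=g.precipitant,
        )
    else:
        screens = list(spec.solutions)
    if spec.additive is not None:
        screens = [
            with_additive(s, spec.additive, spec.additive_fraction) for s in screens
        ]
    return screens


def _well_record(w) -> dict:
    return {
        "well": w.well,
        "dilution_factor": w.dilution_factor,
        "precipitant": w.reservoir.precipitant,
        "reservoir_conc_molar": w.reservoir.concentration,
        "droplet_conc_molar": w.screen.concentration,
        "ph": w.reservoir.ph,
        "protein_mass_ug": w.protein_mass_ug,
        "final_droplet_volume_nl": w.predicted.final_droplet_volume,
        "hydration_pct": w.predicted.hydration_pct,
        "rounded_hydration_pct": w.predicted.rounded_hydration_pct,
        "phase": w.phase.label,
        "phase_boundary": w.phase.boundary,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the planning pipeline; returns the report dict.

    Stages: screen construction, plate planning with per-well hydration
    and mesophase prediction, and — when ``assay_csv`` is set — apparent-K
    estimation with a bootstrap interval.  Any failure is re-raised as
    :class:`PipelineError` carrying the stage name; when planning fails
    the message names the offending well.  With ``out_dir`` set the
    layout JSON, worklist CSV and report JSON are written there.
    """
    screens = _build_screens(config)

    try:
        layout: PlateLayout = plan_plate(
            config.protein,
            screens,
            config.plate_format,
            config.dilutions,
            cal=config.calibration,
            phase_map=config.phase_map,
        )
    except MesoplanError as err:
        raise PipelineError("plan", str(err)) from err
    log.info("planned %d wells on %s", len(layout.wells), config.plate_format)

    report: dict = {
        "plate_format": config.plate_format,
        "n_wells": len(layout.wells),
        "total_protein_ug": layout.total_protein_ug,
        "phi": config.calibration.phi,
        "seed": config.seed,
        "wells": [_well_record(w) for w in layout.wells],
        "k_estimate": None,
    }
    if config.include_timestamp:
        report["generated_at"] = datetime.datetime.now(datetime.UTC).isoformat()

    if config.assay_csv is not None:
        try:
            assay = assay_from_csv(Path(config.assay_csv).read_text(encoding="utf-8"))
            est = estimate_K(assay)
            k_rec = {
                "k": est.k,
                "n_replicates": est.n,
                "replicate_k": [r.k_hat for r in est.replicates],
                "flags": [r.flag for r in est.replicates if r.flag],
            }
            if est.n >= 3:
                lo, hi = bootstrap_K_interval(
                    assay, config.bootstrap_resamples, seed=config.seed
                )
                k_rec["bootstrap_95ci"] = [lo, hi]
            report["k_estimate"] = k_rec
        except (OSError, MesoplanError, ValueError) as err:
            raise PipelineError("estimate-k", str(err)) from err

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "layout.json").write_text(
            layout.model_dump_json(indent=2), encoding="utf-8"
        )
        (out / "worklist.csv").write_text(export_worklist(layout), encoding="utf-8")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
        )
        log.info("wrote layout.json, worklist.csv, report.json to %s", out)
    return report
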