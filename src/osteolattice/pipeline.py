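"""End-to-end orchestration: curves -> calibration -> t/L -> geometry.

A :class:`RunConfig` collects every tunable of the workflow with its
documented default; :func:`run_pipeline` executes whichever stages the
config enables and returns a machine-readable report (fits, per-parameter
and mean t/L, mesh statistics).  Every default actually applied is
logged, and stage failures propagate tagged with the stage name.
Reports are deterministic for equal config + seed (no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import curves as _curves
from . import curvefit as _curvefit
from . import ctvol as _ctvol
from . import lattice as _lattice
from . import parametrize as _parametrize

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline tunables (units: mm, MPa, N, HU).

    Stages run only when their inputs are set: curve CSVs, an HU source
    (explicit value or a volume file), and optional mesh outputs.
    """

    seed: int = 0
    # -- curve analysis ----------------------------------------------------
    curve_csvs: list[str] = field(default_factory=list)
    specimen_diameter_mm: float = 6.0
    specimen_length_mm: float = 12.0
    modulus_window: float = 0.01  # strain span of the max-slope search
    # -- calibrations (bundled name or JSON path) --------------------------
    bone_calibration: str = "human_bone_vs_hu"
    lattice_calibration: str = "tough2000_vs_tl"
    # -- HU source ---------------------------------------------------------
    hu: Optional[float] = None
    volume_path: Optional[str] = None
    hemisphere: str = "left"  # which hemisphere feeds the inversion
    hu_threshold: float = _ctvol.DEFAULT_BONE_THRESHOLD_HU
    erode_radius_mm: float = _ctvol.DEFAULT_ERODE_RADIUS_MM
    # -- lattice geometry --------------------------------------------------
    strut_diameter_mm: float = _lattice.MIN_STRUT_MM
    mesh_pitch_mm: float = _lattice.DEFAULT_SPECIMEN_PITCH
    unit_cell_stl: Optional[str] = None
    specimen_stl: Optional[str] = None
    # -- whole-bone model --------------------------------------------------
    outer_stl: Optional[str] = None
    inner_stl: Optional[str] = None
    bone_model_stl: Optional[str] = None
    bone_pitch_mm: float = 0.2

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _load_cal(name_or_path: str) -> _parametrize.MaterialCalibration:
    from .synthetic import BUNDLED_CALIBRATIONS, load_bundled_calibration

    if name_or_path in BUNDLED_CALIBRATIONS:
        log.info("using bundled calibration %s", name_or_path)
        return load_bundled_calibration(name_or_path)
    return _parametrize.load_calibration(name_or_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the JSON-able report."""
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    if config.curve_csvs:
        try:
            spec = _curves.CompressionSpecimen(
                config.specimen_diameter_mm, config.specimen_length_mm
            )
            rows = []
            for path in config.curve_csvs:
                curve = _curves.read_curve_csv(path, spec, specimen_id=Path(path).stem)
                p = _curves.analyze_curve(curve, window=config.modulus_window)
                rows.append(
                    {
                        "id": p.specimen_id,
                        "E_MPa": p.E,
                        "sigma_y_MPa": p.sigma_y,
                        "sigma_p_MPa": p.sigma_p,
                        "warnings": p.warnings,
                    }
                )
            report["stages"]["curves"] = rows
        except Exception as exc:  # noqa: BLE001 - tagged and re-raised
            raise StageError("curves", exc) from exc

    try:
        bone_cal = _load_cal(config.bone_calibration)
        lattice_cal = _load_cal(config.lattice_calibration)
        report["stages"]["calibration"] = {
            "bone": {k: dataclasses.asdict(v) for k, v in bone_cal.laws.items()},
            "lattice": {k: dataclasses.asdict(v) for k, v in lattice_cal.laws.items()},
            "bone_label": bone_cal.label,
            "lattice_label": lattice_cal.label,
        }
    except Exception as exc:
        raise StageError("calibration", exc) from exc

    hu = config.hu
    if config.volume_path:
        try:
            vol = _ctvol.load_volume(config.volume_path)
            log.info(
                "HU extraction: threshold %.0f HU, erode %.1f mm",
                config.hu_threshold,
                config.erode_radius_mm,
            )
            mask = _ctvol.threshold_fill(vol, lo=config.hu_threshold)
            mask = _ctvol.erode(mask, config.erode_radius_mm)
            hemi = _ctvol.hemisphere_means(vol, mask)
            report["stages"]["ctvol"] = {
                "hu_left": hemi.hu_left,
                "hu_right": hemi.hu_right,
            }
            hu = hemi.hu_left if config.hemisphere == "left" else hemi.hu_right
        except Exception as exc:
            raise StageError("ctvol", exc) from exc

    spec_lat = None
    if hu is not None:
        try:
            res = _parametrize.parameterize(bone_cal, lattice_cal, hu)
            L = _parametrize.strut_length(config.strut_diameter_mm, res.t_over_L)
            spec_lat = _lattice.LatticeSpec(t=config.strut_diameter_mm, L=L)
            report["stages"]["parameterize"] = {
                "hu": hu,
                "per_parameter": res.per_parameter,
                "t_over_L": res.t_over_L,
                "clamped": res.clamped,
                "skipped": res.skipped,
                "t_mm": config.strut_diameter_mm,
                "L_mm": L,
                "relative_density": _lattice.relative_density(spec_lat),
            }
        except Exception as exc:
            raise StageError("parameterize", exc) from exc

    if spec_lat is not None and (config.unit_cell_stl or config.specimen_stl):
        try:
            meshes = {}
            if config.unit_cell_stl:
                m = _lattice.unit_cell(spec_lat)
                _lattice.export_stl(m, config.unit_cell_stl)
                meshes["unit_cell"] = _lattice.mesh_report(m, spec_lat)
            if config.specimen_stl:
                m = _lattice.specimen(spec_lat, pitch=config.mesh_pitch_mm)
                _lattice.export_stl(m, config.specimen_stl)
                meshes["specimen"] = _lattice.mesh_report(m, spec_lat)
            report["stages"]["lattice"] = meshes
        except Exception as exc:
            raise StageError("lattice", exc) from exc

    if config.outer_stl and config.inner_stl and config.bone_model_stl:
        if spec_lat is None:
            raise StageError(
                "bonemodel", ValueError("no t/L available: set hu or volume_path")
            )
        try:
            import trimesh

            from . import bonemodel as _bonemodel

            pair = _bonemodel.CorticalPair(
                outer=trimesh.load(config.outer_stl),
                inner=trimesh.load(config.inner_stl),
            )
            m = _bonemodel.fill_with_lattice(
                pair, spec_lat, pitch=config.bone_pitch_mm
            )
            _lattice.export_stl(m, config.bone_model_stl)
            report["stages"]["bonemodel"] = _lattice.mesh_report(m, spec_lat)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("bonemodel", exc) from exc

    return report
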