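"""Map a Hounsfield value to the lattice strut ratio t/L.

Two power-law calibrations exist for each mechanical parameter
(compressive modulus E, yield stress sigma_y, plateau stress sigma_p):

* bone:     property = a * HU**b
* lattice:  property = u * (t/L)**v

Equating the two and solving for the strut ratio gives the closed form

    t/L = (a * HU**b / u) ** (1/v)

which is evaluated per mechanical parameter; the final ratio is the
arithmetic mean over the parameters available in both calibrations.
Calibration entries whose constant is non-positive (e.g. printed as
0.000 after rounding) cannot be inverted and are skipped with a
warning.
"""

from __future__ import annotations

import json
import logging
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional

log = logging.getLogger(__name__)

__all__ = [
    "PowerLaw",
    "MaterialCalibration",
    "HemisphereHU",
    "ParameterizationResult",
    "invert_single",
    "parameterize",
    "strut_length",
    "load_calibration",
    "save_calibration",
    "CHARACTERIZED_RANGE",
    "PARAMETER_KEYS",
]

#: t/L span covered by the printed porosity series; results outside it
#: are extrapolations beyond what can be printed and are clamped.
CHARACTERIZED_RANGE = (0.1, 0.4)

PARAMETER_KEYS = ("E", "sigma_y", "sigma_p")


@dataclass(frozen=True)
class PowerLaw:
    """y = constant * x**exponent."""

    constant: float
    exponent: float

    def __call__(self, x: float) -> float:
        if x <= 0:
            raise ValueError("power law defined for x > 0")
        return self.constant * x**self.exponent

    @property
    def usable(self) -> bool:
        """Invertible: requires a strictly positive constant."""
        return self.constant > 0


@dataclass
class MaterialCalibration:
    """Per-parameter power laws for one material.

    ``laws`` maps parameter keys (any of ``E``, ``sigma_y``, ``sigma_p``)
    to :class:`PowerLaw`; ``label`` records provenance, e.g.
    ``human-bone-vs-HU`` or ``Tough2000-vs-tL``.
    """

    laws: dict[str, PowerLaw]
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.laws:
            raise ValueError("calibration needs at least one parameter law")
        unknown = set(self.laws) - set(PARAMETER_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")


@dataclass
class HemisphereHU:
    """Mean cancellous HU of the left/right halves of one vertebral body."""

    hu_left: float
    hu_right: float
    level: str = ""
    donor: str = ""


@dataclass
class ParameterizationResult:
    """Per-parameter t/L inversions and their mean for one HU value."""

    hu: float
    per_parameter: dict[str, float]
    t_over_L: float
    clamped: bool = False
    skipped: list = field(default_factory=list)


def invert_single(bone: PowerLaw, lattice: PowerLaw, hu: float) -> float:
    """Closed-form t/L for one mechanical parameter.

    Solves ``u * (t/L)**v = a * HU**b`` for t/L.
    """
    if hu <= 0:
        raise ValueError("HU must be positive for the power-law inversion")
    if not bone.usable or not lattice.usable:
        raise ValueError("both power laws need positive constants")
    return (bone(hu) / lattice.constant) ** (1.0 / lattice.exponent)


def parameterize(
    bone_cal: MaterialCalibration,
    lattice_cal: MaterialCalibration,
    hu: float,
    clamp: bool = True,
) -> ParameterizationResult:
    """Mean t/L over the mechanical parameters shared by both calibrations.

    Entries with a non-positive constant on either side are skipped with
    a warning (they cannot be inverted); the mean runs over the
    remaining parameters.  The mean is clamped to the characterized
    range (0.1-0.4 by default) with a warning, since ratios outside it
    were never printed or tested.
    """
    shared = [k for k in PARAMETER_KEYS if k in bone_cal.laws and k in lattice_cal.laws]
    if not shared:
        raise ValueError("calibrations share no mechanical parameter")
    per: dict[str, float] = {}
    skipped: list[str] = []
    for key in shared:
        b, l = bone_cal.laws[key], lattice_cal.laws[key]
        if not (b.usable and l.usable):
            skipped.append(key)
            log.warning(
                "skipping %s: non-invertible power law (constant <= 0)", key
            )
            continue
        per[key] = invert_single(b, l, hu)
    if not per:
        raise ValueError("no invertible parameter in the shared set")
    mean = sum(per.values()) / len(per)
    clamped = False
    lo, hi = CHARACTERIZED_RANGE
    if clamp and not (lo <= mean <= hi):
        clipped = min(max(mean, lo), hi)
        _warnings.warn(
            f"t/L = {mean:.4f} outside characterized range [{lo}, {hi}]; "
            f"clamped to {clipped:.4f}",
            stacklevel=2,
        )
        mean, clamped = clipped, True
    return ParameterizationResult(
        hu=hu, per_parameter=per, t_over_L=mean, clamped=clamped, skipped=skipped
    )


def strut_length(t_mm: float, t_over_L: float) -> float:
    """Strut length L (mm) from the printable strut diameter and the ratio."""
    if t_mm <= 0:
        raise ValueError("strut diameter must be positive")
    if t_over_L <= 0:
        raise ValueError("t/L must be positive")
    return t_mm / t_over_L


# ---------------------------------------------------------------------------
# JSON calibration files
#
# Format: {"label": ..., "laws": {"E": {"constant": ..., "exponent": ...,
#          "r_squared": ..., "p_value": ...}, ...}}


def load_calibration(path) -> MaterialCalibration:
    with open(path) as fh:
        doc = json.load(fh)
    laws = {
        key: PowerLaw(float(entry["constant"]), float(entry["exponent"]))
        for key, entry in doc["laws"].items()
    }
    meta = {
        key: {k: v for k, v in entry.items() if k not in ("constant", "exponent")}
        for key, entry in doc["laws"].items()
    }
    return MaterialCalibration(laws=laws, label=doc.get("label", ""), metadata=meta)


def save_calibration(path, cal: MaterialCalibration) -> None:
    doc = {
        "label": cal.label,
        "laws": {
            key: {
                "constant": law.constant,
                "exponent": law.exponent,
                **cal.metadata.get(key, {}),
            }
            for key, law in cal.laws.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
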