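"""Mechanical parameter extraction from uniaxial compression records.

A cancellous-bone (or printed-lattice) compression test yields a
stress-strain curve with a toe region, a quasilinear loading branch,
yield, post-yield softening and a long plateau.  Three scalar
parameters summarise such a curve:

* compressive modulus ``E`` -- the maximum slope of the quasilinear
  region (MPa),
* yield stress ``sigma_y`` -- the stress where the curve crosses a line
  of slope ``E`` offset by 0.2 % strain,
* plateau stress ``sigma_p`` -- the average stress over the 20-40 %
  strain range.

All compressive quantities are reported as positive magnitudes; strain
is dimensionless, stress in MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CompressionSpecimen",
    "StressStrainCurve",
    "MechanicalParameters",
    "to_stress_strain",
    "extract_modulus",
    "extract_offset_yield",
    "extract_plateau",
    "analyze_curve",
    "read_curve_csv",
    "write_parameters_csv",
    "PRECONDITION_LOWER_MPA",
    "PRECONDITION_UPPER_MPA",
]

# Preconditioning hysteresis bounds of the test protocol (MPa).  Records
# that include the preconditioning loop are trimmed to the final
# monotonic ramp using the lower bound.
PRECONDITION_LOWER_MPA = 0.16
PRECONDITION_UPPER_MPA = 0.33

#: default sliding-window span (strain) for the modulus search
DEFAULT_MODULUS_WINDOW = 0.01
#: upper strain bound of the quasilinear-region search
MODULUS_SEARCH_LIMIT = 0.20
#: offset strain of the yield construction
YIELD_OFFSET = 0.002
#: strain range over which the plateau stress is averaged
PLATEAU_RANGE = (0.20, 0.40)


@dataclass(frozen=True)
class CompressionSpecimen:
    """Cylindrical compression specimen (canonical bone core: Ø6 x 12 mm)."""

    diameter_mm: float
    length_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("specimen dimensions must be positive")

    @property
    def area_mm2(self) -> float:
        return math.pi * self.diameter_mm**2 / 4.0

    @property
    def aspect_ratio(self) -> float:
        """length / diameter; 2.0 for canonical specimens."""
        return self.length_mm / self.diameter_mm


@dataclass
class StressStrainCurve:
    """Ordered (strain, stress) samples of one compression test.

    ``strain`` must be strictly increasing (the final loading ramp);
    ``stress`` is in MPa, both as positive compressive magnitudes.
    """

    strain: np.ndarray
    stress: np.ndarray
    specimen_id: str = ""
    diameter_mm: Optional[float] = None
    length_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if self.strain.size < 2:
            raise ValueError("a curve needs at least two samples")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")

    @property
    def max_strain(self) -> float:
        return float(self.strain[-1])

    def reaches_plateau(self) -> bool:
        return self.max_strain >= PLATEAU_RANGE[1]


@dataclass
class MechanicalParameters:
    """The (E, sigma_y, sigma_p) triple of one specimen, in MPa.

    ``sigma_p`` is ``None`` when the record stops short of 40 % strain.
    """

    E: float
    sigma_y: float
    sigma_p: Optional[float] = None
    specimen_id: str = ""
    warnings: list = field(default_factory=list)


def _select_final_ramp(
    strain: np.ndarray,
    stress: np.ndarray,
    preload_level: float = PRECONDITION_LOWER_MPA,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop everything before the last downward crossing of the preload level.

    A downward crossing is a step from ``stress > level`` to
    ``stress <= level``; the final monotonic test ramp starts at the
    sample after the last such crossing.  Records without a
    preconditioning loop (never crossing downward) are kept whole.
    Strain is re-zeroed to the ramp start so the 20-40 % plateau window
    refers to deformation accumulated during the final ramp.
    """
    down = (stress[:-1] > preload_level) & (stress[1:] <= preload_level)
    idx = np.nonzero(down)[0]
    if idx.size == 0:
        return strain, stress
    start = int(idx[-1]) + 1
    return strain[start:] - strain[start], stress[start:]


def to_stress_strain(
    force_N: np.ndarray,
    displacement_mm: np.ndarray,
    spec: CompressionSpecimen,
    specimen_id: str = "",
    preload_level_mpa: float = PRECONDITION_LOWER_MPA,
) -> StressStrainCurve:
    """Engineering stress/strain from a force-displacement record.

    stress = force / cross-section area, strain = displacement / free
    length.  If the record contains the preconditioning hysteresis loop
    the final monotonic ramp is isolated (see :func:`_select_final_ramp`).
    """
    force = np.abs(np.asarray(force_N, dtype=float))
    disp = np.abs(np.asarray(displacement_mm, dtype=float))
    if force.shape != disp.shape:
        raise ValueError("force and displacement must have the same length")
    if spec.area_mm2 <= 0:
        raise ValueError("specimen area must be positive")
    stress = force / spec.area_mm2  # N / mm^2 = MPa
    strain = disp / spec.length_mm
    strain, stress = _select_final_ramp(strain, stress, preload_level_mpa)
    if np.any(np.diff(strain) <= 0):
        raise ValueError("strain not strictly increasing after ramp selection")
    return StressStrainCurve(
        strain,
        stress,
        specimen_id=specimen_id,
        diameter_mm=spec.diameter_mm,
        length_mm=spec.length_mm,
    )


def extract_modulus(
    curve: StressStrainCurve,
    window: float = DEFAULT_MODULUS_WINDOW,
    search_limit: float = MODULUS_SEARCH_LIMIT,
) -> float:
    """Maximum sliding-window least-squares slope below ``search_limit`` strain.

    The quasilinear region of a cellular-solid compression curve is not
    sharply delimited; the modulus is therefore taken as the maximum
    over all windows of span ``window`` (default 1 % strain) of the OLS
    slope of stress on strain, restricted to strain < ``search_limit``.
    """
    eps = curve.strain
    sig = curve.stress
    sel = eps < search_limit
    eps, sig = eps[sel], sig[sel]
    if eps.size < 3 or eps[-1] - eps[0] < window:
        raise ValueError(
            "curve has less than one window span of data below the search limit"
        )
    best = -np.inf
    n = eps.size
    j = 0
    for i in range(n):
        if i + 3 > n:
            break
        if j < i + 3:
            j = i + 3
        while j < n and eps[j - 1] - eps[i] < window:
            j += 1
        if eps[j - 1] - eps[i] < window:
            break  # no further full-span window fits
        x = eps[i:j]
        y = sig[i:j]
        if x.size < 3:
            continue
        xm = x - x.mean()
        denom = float(xm @ xm)
        if denom == 0.0:
            continue
        slope = float(xm @ (y - y.mean())) / denom
        if slope > best:
            best = slope
        if j == n and eps[-1] - eps[i] < window:
            break
    if not np.isfinite(best):
        raise ValueError("fewer than 3 points in every window")
    return max(best, 0.0)


def extract_offset_yield(
    curve: StressStrainCurve,
    E: float,
    offset: float = YIELD_OFFSET,
    search_limit: float = MODULUS_SEARCH_LIMIT,
) -> float:
    """Stress at the first crossing of the 0.2 %-offset line.

    The offset line is ``sigma = E * (strain - offset)``.  Both the
    curve and the line are treated as piecewise linear between samples;
    the first sign change of (stress - line) with strain > ``offset``
    is located and the intersection solved by linear interpolation.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    eps = curve.strain
    sig = curve.stress
    f = sig - E * (eps - offset)
    searchable = eps > offset
    # sign change between consecutive samples, restricted to the search range
    cross = (f[:-1] > 0) & (f[1:] <= 0) & searchable[1:] & (eps[1:] <= search_limit)
    idx = np.nonzero(cross)[0]
    if idx.size == 0:
        raise ValueError("no yield: curve does not cross the offset line before "
                         f"{search_limit:.0%} strain")
    i = int(idx[0])
    # linear interpolation of f between samples i and i+1
    t = f[i] / (f[i] - f[i + 1])
    return float(sig[i] + t * (sig[i + 1] - sig[i]))


def extract_plateau(
    curve: StressStrainCurve,
    strain_range: tuple[float, float] = PLATEAU_RANGE,
) -> float:
    """Trapezoidal average of stress over the plateau strain range.

    The strain-weighted (integral) mean is invariant to sampling
    density, unlike a raw sample mean.
    """
    lo, hi = strain_range
    if curve.max_strain < hi:
        raise ValueError(
            f"curve reaches only {curve.max_strain:.3f} strain; "
            f"plateau needs {hi:.2f}"
        )
    eps = curve.strain
    sig = curve.stress
    inner = (eps > lo) & (eps < hi)
    xs = np.concatenate(([lo], eps[inner], [hi]))
    ys = np.concatenate(
        ([np.interp(lo, eps, sig)], sig[inner], [np.interp(hi, eps, sig)])
    )
    return float(np.trapezoid(ys, xs) / (hi - lo))


def analyze_curve(
    curve: StressStrainCurve,
    window: float = DEFAULT_MODULUS_WINDOW,
) -> MechanicalParameters:
    """Extract (E, sigma_y, sigma_p) from one curve.

    The plateau stress is omitted (``None``) with a warning flag when
    the record stops before 40 % strain.
    """
    E = extract_modulus(curve, window=window)
    sigma_y = extract_offset_yield(curve, E)
    warnings: list[str] = []
    sigma_p: Optional[float] = None
    if curve.reaches_plateau():
        sigma_p = extract_plateau(curve)
    else:
        warnings.append(
            f"max strain {curve.max_strain:.3f} < 0.40; plateau stress omitted"
        )
    return MechanicalParameters(
        E=E,
        sigma_y=sigma_y,
        sigma_p=sigma_p,
        specimen_id=curve.specimen_id,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# CSV interface


def read_curve_csv(
    path,
    spec: Optional[CompressionSpecimen] = None,
    specimen_id: str = "",
) -> StressStrainCurve:
    """Read a curve from CSV with columns ``strain,stress`` or
    ``force_N,displacement_mm`` (header required; the latter needs ``spec``)."""
    df = pd.read_csv(path)
    cols = {c.strip().lower() for c in df.columns}
    df.columns = [c.strip().lower() for c in df.columns]
    if {"strain", "stress"} <= cols:
        return StressStrainCurve(
            df["strain"].to_numpy(), df["stress"].to_numpy(), specimen_id=specimen_id
        )
    if {"force_n", "displacement_mm"} <= cols:
        if spec is None:
            raise ValueError("force/displacement input needs specimen dimensions")
        return to_stress_strain(
            df["force_n"].to_numpy(),
            df["displacement_mm"].to_numpy(),
            spec,
            specimen_id=specimen_id,
        )
    raise ValueError(
        "CSV must have columns strain,stress or force_N,displacement_mm"
    )


def write_parameters_csv(path, params: list[MechanicalParameters]) -> None:
    """One row per specimen: ``id,E_MPa,sigma_y_MPa,sigma_p_MPa``."""
    rows = [
        {
            "id": p.specimen_id,
            "E_MPa": p.E,
            "sigma_y_MPa": p.sigma_y,
            "sigma_p_MPa": p.sigma_p if p.sigma_p is not None else "",
        }
        for p in params
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
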