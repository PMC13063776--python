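"""Seeded synthetic data with the statistical structure the pipeline assumes.

Every stage of the pipeline can be exercised without any measured data:

* :func:`gen_curve` -- compression stress-strain curves with toe,
  quasilinear branch of known modulus, yield vertex, softening and a
  20-40 % plateau (the morphology of cancellous-bone and printed-lattice
  tests), plus an optional preconditioning hysteresis prefix in
  force-displacement form;
* :func:`gen_hu_property` -- (HU, property) tables following a power law
  with multiplicative lognormal scatter;
* :func:`gen_phantom` -- an ellipsoid-shell CT phantom with a high-HU
  cortex and per-hemisphere interior means;
* :func:`gen_pullout` -- (HU, F_max) screw pull-out tables from a chosen
  regression law.

All generators take a mandatory seed and are byte-deterministic for
equal seeds.  Noise models: additive Gaussian for curves, multiplicative
lognormal (unit mean) for the positive-valued regression tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .curves import (
    PRECONDITION_LOWER_MPA,
    PRECONDITION_UPPER_MPA,
    CompressionSpecimen,
    MechanicalParameters,
    StressStrainCurve,
)
from .curvefit import CurveFit
from .parametrize import MaterialCalibration, PowerLaw, load_calibration
from .ctvol import VoxelVolume

__all__ = [
    "CurveParams",
    "gen_curve",
    "curve_truth",
    "gen_record",
    "gen_hu_property",
    "gen_phantom",
    "gen_pullout",
    "classify_tscore",
    "load_bundled_calibration",
    "load_donor_table",
    "load_printed_vertebrae",
    "load_pullout_fits",
    "BUNDLED_CALIBRATIONS",
]

# strain grid resolution and end point of generated curves
_STRAIN_STEP = 5.0e-4
_MAX_STRAIN = 0.45
_YIELD_OFFSET = 0.002


@dataclass(frozen=True)
class CurveParams:
    """Ground-truth parameters of one synthetic compression curve.

    ``E_true`` (MPa) is the slope of the quasilinear branch,
    ``sigma_y_true`` (MPa) the stress where the 0.2 %-offset line meets
    the curve, ``sigma_p_true`` (MPa) the plateau level over 20-40 %
    strain (softening to below yield is typical for bone).  ``toe_span``
    is the strain width of the initial toe; ``hardening`` an optional
    post-yield slope (MPa); ``ripple`` a zero-mean sinusoidal plateau
    modulation amplitude; ``noise_sd`` additive Gaussian stress noise.
    """

    E_true: float
    sigma_y_true: float
    sigma_p_true: float
    seed: int
    toe_span: float = 0.003
    hardening: float = 0.0
    ripple: float = 0.0
    ripple_periods: int = 5
    noise_sd: float = 0.0
    preconditioning: bool = False
    max_strain: float = _MAX_STRAIN

    def __post_init__(self) -> None:
        if self.E_true <= 0:
            raise ValueError("E_true must be positive")
        if self.sigma_y_true <= 0 or self.sigma_p_true <= 0:
            raise ValueError("stresses must be positive")
        if not (0.0 <= self.toe_span < 2 * _YIELD_OFFSET):
            raise ValueError(
                "toe_span must stay below 0.4 % strain so the offset "
                "construction hits the post-yield branch"
            )
        if self.hardening >= self.E_true:
            raise ValueError("hardening slope must be below E_true")
        if self.max_strain < 0.42:
            raise ValueError("curve must extend beyond 40 % strain")
        if self._vertex_stress() <= 0:
            raise ValueError("inconsistent yield/hardening parameters")
        if self._linear_span() < 0.011:
            raise ValueError(
                "quasilinear branch shorter than the 1 % modulus window; "
                "increase sigma_y_true/E_true or reduce toe_span"
            )

    # -- derived geometry of the noiseless curve ---------------------------

    def _vertex_stress(self) -> float:
        """Stress at the yield vertex such that the 0.2 %-offset line
        intersects the post-yield branch exactly at sigma_y_true."""
        E, h = self.E_true, self.hardening
        sy = self.sigma_y_true
        eps0 = self.toe_span / 2.0  # strain offset of the linear branch
        return (sy - h * (_YIELD_OFFSET - eps0) - h * sy / E) / (1.0 - h / E)

    def _vertex_strain(self) -> float:
        return self.toe_span / 2.0 + self._vertex_stress() / self.E_true

    def _linear_span(self) -> float:
        return self._vertex_strain() - self.toe_span

    def _soft_start(self) -> float:
        # post-yield branch long enough for the offset line to hit it
        return max(self._vertex_strain() + 0.02, _YIELD_OFFSET + self.sigma_y_true / self.E_true + 0.005)


def _noiseless_stress(p: CurveParams, eps: np.ndarray) -> np.ndarray:
    """Piecewise noiseless stress: toe, linear, hardening, softening, plateau."""
    E = p.E_true
    et = p.toe_span
    ev = p._vertex_strain()
    sv = p._vertex_stress()
    es = p._soft_start()
    ss = sv + p.hardening * (es - ev)
    sp = p.sigma_p_true
    out = np.empty_like(eps)

    toe = eps < et
    if et > 0:
        out[toe] = E * eps[toe] ** 2 / (2.0 * et)
    else:
        out[toe] = 0.0
    lin = (eps >= et) & (eps < ev)
    out[lin] = E * (eps[lin] - et / 2.0)
    hard = (eps >= ev) & (eps < es)
    out[hard] = sv + p.hardening * (eps[hard] - ev)
    # cubic-hermite softening with zero end slopes from (es, ss) to (0.20, sp)
    soft = (eps >= es) & (eps < 0.20)
    if es < 0.20:
        u = (eps[soft] - es) / (0.20 - es)
        out[soft] = ss + (sp - ss) * (3 * u**2 - 2 * u**3)
    plat = eps >= 0.20
    out[plat] = sp
    if p.ripple > 0:
        # integer number of periods across the 20-40 % window keeps the
        # integral mean at the plateau level
        w = 2 * np.pi * p.ripple_periods / 0.20
        out[plat] = sp + p.ripple * np.sin(w * (eps[plat] - 0.20))
    return out


def gen_curve(p: CurveParams, specimen_id: str = "synthetic") -> StressStrainCurve:
    """Synthetic stress-strain curve (final loading ramp only)."""
    rng = np.random.default_rng(p.seed)
    eps = np.arange(0.0, p.max_strain + _STRAIN_STEP / 2, _STRAIN_STEP)
    sig = _noiseless_stress(p, eps)
    if p.noise_sd > 0:
        sig = np.clip(sig + rng.normal(0.0, p.noise_sd, sig.shape), 0.0, None)
    return StressStrainCurve(eps, sig, specimen_id=specimen_id)


def curve_truth(p: CurveParams) -> MechanicalParameters:
    """The exact parameters the extraction should recover at zero noise."""
    return MechanicalParameters(
        E=p.E_true, sigma_y=p.sigma_y_true, sigma_p=p.sigma_p_true,
        specimen_id="truth",
    )


def gen_record(
    p: CurveParams,
    spec: CompressionSpecimen = CompressionSpecimen(6.0, 12.0),
    n_loops: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Force-displacement record, optionally with the preconditioning loop.

    With ``p.preconditioning`` the record starts with ``n_loops``
    hysteresis cycles between the preload bounds (0.16-0.33 MPa) before
    the final monotonic ramp; strain is not monotonic there, so the
    record form (force N, displacement mm) is returned for
    :func:`osteolattice.curves.to_stress_strain` to trim.
    """
    curve = gen_curve(p)
    eps, sig = curve.strain, curve.stress
    if p.preconditioning:
        lo, hi = PRECONDITION_LOWER_MPA, PRECONDITION_UPPER_MPA
        imax = int(sig.argmax())
        s_mono, e_mono = sig[: imax + 1], eps[: imax + 1]

        def strain_at(s):
            return np.interp(s, s_mono, e_mono)

        # cycles built in stress space so the loop bottoms land exactly
        # on the preload bound (the marker the ramp selection keys on)
        s_up = np.linspace(0.0, hi, 25)
        cyc_s, cyc_e = [s_up], [strain_at(s_up)]
        for _ in range(n_loops):
            s_down = np.linspace(hi, lo, 10)[1:]
            s_up2 = np.linspace(lo, hi, 10)[1:]
            cyc_s += [s_down, s_up2]
            cyc_e += [strain_at(s_down), strain_at(s_up2)]
        pre_s = np.concatenate(cyc_s)
        pre_e = np.concatenate(cyc_e)
        # final ramp re-starts from the loop's lower bound
        e_lo = float(strain_at(lo))
        tail = eps > e_lo
        eps = np.concatenate((pre_e, [e_lo], eps[tail]))
        sig = np.concatenate((pre_s, [lo], sig[tail]))
    force = sig * spec.area_mm2
    disp = eps * spec.length_mm
    return force, disp


def gen_hu_property(
    law: PowerLaw,
    n: int = 43,
    hu_range: tuple[float, float] = (61.0, 364.0),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """(HU, property) pairs from ``y = a * HU**b`` with lognormal scatter.

    ``noise_cv`` is the coefficient of variation of the unit-mean
    multiplicative noise; HU are uniform over ``hu_range`` (the span
    observed in elderly donor vertebrae).
    """
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    hu = rng.uniform(*hu_range, size=n)
    y = law.constant * hu**law.exponent
    if noise_cv > 0:
        s = np.sqrt(np.log1p(noise_cv**2))
        y = y * rng.lognormal(mean=-0.5 * s**2, sigma=s, size=n)
    return pd.DataFrame({"hu": hu, "y": y})


def gen_phantom(
    interior_means: tuple[float, float] = (90.0, 310.0),
    cortex_hu: float = 1500.0,
    cortical_thickness_mm: float = 2.0,
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
    semiaxes_mm: tuple[float, float, float] = (22.0, 16.0, 12.0),
    interior_sd: float = 20.0,
    background_hu: float = -1000.0,
    seed: int = 0,
) -> VoxelVolume:
    """Ellipsoid-shell CT phantom of a vertebral body.

    A cortical shell of uniform physical thickness at ``cortex_hu``
    surrounds a trabecular interior whose HU are Gaussian around a
    per-hemisphere mean (``interior_means`` = (left, right)); outside is
    air.  Array axis 0 runs left-right with code "R" (index increases
    toward the patient's right), so the left hemisphere is at low
    indices.
    """
    if cortical_thickness_mm < 0:
        raise ValueError("cortical thickness must be >= 0")
    if min(semiaxes_mm) <= cortical_thickness_mm:
        raise ValueError("cortex thicker than the ellipsoid semiaxes")
    rng = np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing)
    margin = 4.0  # mm of air around the shell
    half = np.asarray(semiaxes_mm) + margin
    shape = tuple(int(np.ceil(2 * h / s)) for h, s in zip(half, spacing))
    coords = [
        (np.arange(shape[k]) + 0.5) * spacing[k] - half[k] for k in range(3)
    ]
    xx = coords[0][:, None, None]
    yy = coords[1][None, :, None]
    zz = coords[2][None, None, :]
    a = np.asarray(semiaxes_mm, dtype=float)
    rho_out = np.sqrt((xx / a[0]) ** 2 + (yy / a[1]) ** 2 + (zz / a[2]) ** 2)
    ai = a - cortical_thickness_mm
    rho_in = np.sqrt((xx / ai[0]) ** 2 + (yy / ai[1]) ** 2 + (zz / ai[2]) ** 2)

    data = np.full(shape, background_hu, dtype=np.float32)
    interior = rho_in <= 1.0
    cortex = (rho_out <= 1.0) & ~interior
    data[cortex] = cortex_hu
    noise = rng.normal(0.0, interior_sd, size=shape).astype(np.float32)
    left = np.broadcast_to(xx < 0.0, shape)
    data[interior & left] = interior_means[0] + noise[interior & left]
    data[interior & ~left] = interior_means[1] + noise[interior & ~left]
    return VoxelVolume(data=data, spacing=spacing, orientation=("R", "A", "S"))


def gen_pullout(
    fit: CurveFit,
    n: int = 24,
    hu_range: tuple[float, float] = (58.0, 343.0),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """(HU, F_max) screw pull-out table from a fitted force-vs-HU law."""
    from .curvefit import predict

    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    hu = rng.uniform(*hu_range, size=n)
    f = np.asarray(predict(fit, hu), dtype=float)
    if noise_cv > 0:
        s = np.sqrt(np.log1p(noise_cv**2))
        f = f * rng.lognormal(mean=-0.5 * s**2, sigma=s, size=n)
    return pd.DataFrame({"hu": hu, "f_max": f})


def classify_tscore(t: float) -> str:
    """WHO DXA classification: normal / osteopenia / osteoporosis."""
    if t >= -1.0:
        return "normal"
    if t > -2.5:
        return "osteopenia"
    return "osteoporosis"


# ---------------------------------------------------------------------------
# Bundled reference tables (regression constants and donor roster)

BUNDLED_CALIBRATIONS = {
    "human_bone_vs_hu": "human_bone_vs_hu.json",
    "clear_v4_vs_tl": "clear_v4_vs_tl.json",
    "tough2000_vs_tl": "tough2000_vs_tl.json",
}


def _data_path(name: str):
    return resources.files("osteolattice.data").joinpath(name)


def load_bundled_calibration(name: str) -> MaterialCalibration:
    """One of ``human_bone_vs_hu``, ``clear_v4_vs_tl``, ``tough2000_vs_tl``."""
    if name not in BUNDLED_CALIBRATIONS:
        raise KeyError(f"unknown calibration {name!r}; have {sorted(BUNDLED_CALIBRATIONS)}")
    with resources.as_file(_data_path(BUNDLED_CALIBRATIONS[name])) as p:
        return load_calibration(p)


def load_donor_table() -> pd.DataFrame:
    """Donor roster: age, sex, DXA T-score and WHO classification."""
    with resources.as_file(_data_path("donors.csv")) as p:
        return pd.read_csv(p)


def load_printed_vertebrae() -> pd.DataFrame:
    """The three printed vertebrae: hemisphere HU and published t/L."""
    with resources.as_file(_data_path("printed_vertebrae.csv")) as p:
        return pd.read_csv(p)


def load_pullout_fits() -> dict[str, CurveFit]:
    """Published pull-out force regressions (linear, power, exponential)."""
    with resources.as_file(_data_path("pullout_fits.json")) as p:
        doc = json.loads(p.read_text())
    return {
        k: CurveFit(
            model=v["model"],
            constant=v["constant"],
            exponent=v["exponent"],
            r_squared=v["r_squared"],
            p_value=v["p_value"],
        )
        for k, v in doc["fits"].items()
    }
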