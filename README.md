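# osteolattice

Patient-specific, 3D-printable surrogates for vertebral cancellous
(spongious) bone.  The package turns the Hounsfield units (HU) of a
clinical CT scan into the single geometric parameter of a hexagonal
strut lattice — the ratio of strut diameter to strut length, t/L — and
generates watertight STL geometry: unit cells, compression test
specimens, and whole-bone models in which the cancellous interior is
replaced by the tuned lattice.  It is aimed at biomechanics groups and
labs building mechanically realistic bone replicas for surgical
training, implant testing (e.g. pedicle-screw anchorage) and method
development.

## The model

Uniaxial compression of cancellous bone or of an open-cell lattice gives
a stress–strain curve summarised by three parameters:

* **E** — compressive modulus, the maximum slope of the quasilinear
  region (MPa);
* **σ_y** — yield stress at the 0.2 %-offset construction (MPa);
* **σ_p** — plateau stress, the average stress over 20–40 % strain (MPa).

Two families of power laws calibrate these parameters, in the spirit of
Gibson–Ashby cellular-solid scaling:

```
bone:     y = a · HU^b          (property vs. CT attenuation)
lattice:  y = u · (t/L)^v       (property vs. strut ratio)
```

Both are estimated by ordinary least squares on log-transformed data
(the classic curve-estimation convention), with R² and the slope's
F-test p-value reported in the transformed space.  Setting the two laws
equal and solving for the strut ratio yields the closed-form inversion

```
t/L = ( a · HU^b / u )^(1/v)
```

evaluated once per mechanical parameter; the arithmetic mean over the
available parameters is the ratio used for the model.  With the fixed,
printable strut diameter t = 0.4 mm this fully determines the lattice
(L = t / (t/L)).  The hexagonal cell — planar regular hexagons of side L
whose corners are joined by vertical struts — has relative density
ρ ≈ (5π / 6√3)·(t/L)², so the ratio directly controls the solid
fraction and hence stiffness and strength.

## Worked example

Parameterize a lattice for a vertebral hemisphere with a mean cancellous
attenuation of 93 HU, using the bundled human-bone and Tough2000-resin
calibrations:

```
$ osteolattice parameterize --hu 93
{
  "hu": 93.0,
  "per_parameter": {
    "E": 0.15345668611819183,
    "sigma_y": 0.17743069281260396
  },
  "t_over_L": 0.1654436894653979,
  "clamped": false,
  "skipped": ["sigma_p"],
  "t_mm": 0.4,
  "L_mm": 2.4177410531192183
}
```

The modulus calibration asks for t/L ≈ 0.153, the yield-stress
calibration for ≈ 0.177; their mean, ≈ 0.165, is the ratio a print
would use (the plateau-stress law is skipped because its published
constant rounds to zero and cannot be inverted).  A strut diameter of
0.4 mm then implies struts of length ≈ 2.42 mm.

Export the corresponding unit cell as a watertight STL:

```
$ osteolattice lattice --tl 0.17 --unit-cell --out cell.stl
{
  "volume_mm3": 3.474920430042665,
  "watertight": true,
  "faces": 37676,
  "extents_mm": [5.105061334371567, 4.475402683019638, 2.752935194969177],
  "t_mm": 0.4,
  "L_mm": 2.3529411764705883,
  "t_over_L": 0.17,
  "relative_density": 0.03992891524207845
}
```

The cell's relative density of ≈ 4 % sits inside the 4–12 % range of
real vertebral cancellous bone.  Other subcommands: `curves` (extract
E, σ_y, σ_p from CSV records), `fit` (power/linear/exponential curve
estimation), `ctvol` (hemisphere HU from a NIfTI volume), `bonemodel`
(fill a segmented cortical shell with the lattice), `synth` (seeded
synthetic fixtures) and `pipeline` (config-driven end-to-end run).

The same workflow in Python:

```python
import osteolattice as ol
from osteolattice.synthetic import load_bundled_calibration

bone = load_bundled_calibration("human_bone_vs_hu")
resin = load_bundled_calibration("tough2000_vs_tl")
res = ol.parameterize(bone, resin, hu=93)      # -> t/L = 0.1654...
spec = ol.LatticeSpec.from_ratio(res.t_over_L) # t = 0.4 mm
mesh = ol.specimen(spec)                       # Ø: 10x lattice spacing, 1:2
```

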