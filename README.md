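# shrimpglass

Optics of cleaner-shrimp antennal ultrastructure: how layers of packed
high-refractive-index nanospheres and chitin multilayers beneath a
cuticle make signalling antennae white, and how to measure that
whiteness from calibrated photographs.

Obligate cleaner shrimps advertise their services to reef fish by waving
white antennae only ~150 µm across.  Inside the antennae of several
obligate cleaners sits either a 1–3 µm layer of ~300–400 nm spheres
(a "photonic glass") or a stack of ~0.27 µm chitin lamellae — structures
that strongly raise broadband (400–700 nm) reflectance over the bare
chitin cuticle.  This package provides the full modelling and
measurement pipeline for that claim:

- **geometry** — random close-ish packings of hard spheres/discs in a
  laterally periodic box; alternating high/low multilayer stacks.
- **thin_films** — exact transfer-matrix reflectance of planar stacks
  (the control cuticle and the lamellae model, and the oracle for FDTD).
- **em_solver** — a from-scratch 2-D FDTD solver (Yee grid, CPML,
  periodic lateral boundaries, broadband pulse + running DFT monitors)
  for scenes with sphere layers under a cuticle.
- **sweeps** — the three simulation experiments (sphere refractive
  index, layer thickness, sphere diameter), the antenna double-pass
  correction R + RT², and plateau detection.
- **photometry** — grey-standard exponential calibration and
  green-channel ROI reflectometry with two-stage aggregation.
- **stats** — exact two-sample Wilcoxon rank-sum tests (complete
  enumeration, midranks) and the linear-model/ANOVA comparison.
- **synthetic_data** — seed-deterministic generators for SEM-like
  packing images, calibration photographs and species reflectance
  datasets with known ground truth.

The model in brief: one antennal wall is a layer of spheres (index n_s,
diameters d, fill φ ≈ 0.55) in seawater-index matrix (n = 1.34) beneath
a 5 µm chitin layer (n = 1.57).  A broadband plane wave gives R(λ) and
T(λ); band averages are flat means over 400–700 nm, and antenna-level
reflectance accounts for the double wall of a cylinder:

    R_antenna = R + R·T²

## Worked example

```python
from shrimpglass.em_solver import SolverConfig
from shrimpglass.sweeps import control_reflectance, sphere_layer_scene, antenna_double_pass
from shrimpglass.em_solver import run_fdtd

# bare cuticle control (planar, exact)
control = control_reflectance(method="tmm")
print(f"control: single-layer {100*control['R']:.2f}%, "
      f"double-pass {100*control['R_antenna']:.2f}%")

# one packing realization: 2 µm of isoxanthopterin-index spheres under the cuticle
scene = sphere_layer_scene(lateral_um=2.0, layer_um=2.0,
                           diam_spec=("uniform", 300, 400),
                           n_sphere=1.78, seed=1)
spec = run_fdtd(scene, SolverConfig(resolution_nm=20.0, max_steps=30_000))
R, T = spec.band_average()
print(f"sphere layer: R={100*R:.1f}%, antenna R+RT² = {100*antenna_double_pass(R, T):.1f}%")
```

prints

```
control: single-layer 1.24%, double-pass 2.46%
sphere layer: R=15.6%, antenna R+RT² = 26.7%
```

i.e. the bare cuticle returns ~1–2 % of visible light, while adding a
2 µm layer of n = 1.78 spheres raises the antenna-level reflectance
more than tenfold — the optical basis of the white signal.  Replicate
packings scatter by a few percentage points; sweeps average several
seeds per point.

A command-line interface wraps the long-running pieces, e.g.

```
shrimpglass sweep-ri --replicates 3 --seed 0 --out ri.csv --plot ri.png
shrimpglass synth dataset --seed 0 --out dataset.csv
shrimpglass stats --dataset dataset.csv --contrast all
```

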