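# vfareg

Rigid surface registration of attributed 3-D point clouds by vector field
analysis (VFA), for image-guided surgery settings where a preoperative
surface model (e.g. a CT segmentation of the occiput) must be aligned with an
intraoperatively acquired surface (e.g. an A-mode ultrasound scan of the bone
through soft tissue). Plain closest-point registration of such data is
notoriously prone to local minima; this package implements a registration
energy that exploits manually labeled anatomical features — each point
carries an integer *form attribute* naming the suture arm or protuberance it
belongs to — together with an optimization pivot derived from analyzing the
force field the energy induces.

## The method

Both datasets are sets of 4-D points (x, y, z, a) with a ∈ ℕ₀ (0 =
unlabeled). Matching is *binary*: a moving point may only be matched to a
fixed point of the same attribute (the w → ∞ limit of the weighted distance
√(‖Δq‖² + w·Δa²)). With dₙ the closest same-class distance of moving point
qₙ, the registration energy in Gaussian scale space is

    E_σ = Σₙ (1 − exp(−dₙ²/σ²)),    σ = 10,

which is 0 at perfect alignment, saturates at N when all points are far, and
reduces to the quadratic spring energy Σ dₙ²/σ² near alignment. The negative
gradient of the per-point potential defines a force field Fₙ = −∇Uₙ pulling
the moving set onto the fixed one. The curl of this scattered field
(estimated by local moving-least-squares affine fits) identifies the *vortex*
— the attributed point of minimal curl magnitude within the active field —
which acts as the instant center of rotation (ICR): rotations during
optimization are parameterized about it, decoupling rotation from
translation. The six rigid parameters are minimized by a BFGS quasi-Newton
optimizer with Armijo backtracking, plus a bounded "stepping-out" stage that
escapes local minima via exploratory rotations about the ICR (committed only
when they end strictly below the departure energy).

The classic Gaussian-fields (GF) baseline is included for comparison: same
optimizer core, but a *soft* attribute distance over all point pairs and
rotation about the coordinate origin — its basin of convergence is markedly
narrower.

The package also provides a synthetic study-data generator (a skull-like
attributed surface and a polar-grid A-mode scan simulator with noise and
dropout), evaluation tools (target registration error, color-map distances,
basin-of-convergence sweeps, energy surfaces), PLY/CSV I/O, and a CLI.

## Worked example

```python
import numpy as np
from vfareg import (PhantomConfig, RigidTransform, ScanConfig, anterior_targets,
                    make_phantom, register_gf, register_vfa, simulate_amode_scan, tre)
from vfareg.synthetic import displace

# CT-like surface with labeled sutures + protuberance, and its A-mode scan
fixed = make_phantom(PhantomConfig(seed=1))
moving = simulate_amode_scan(fixed, ScanConfig(seed=3, center_O=PhantomConfig().center_mm))

# misalign the scan by a half-turn plus a shift, then register both ways
truth = RigidTransform(angles_deg=[0, 0, 180], translation_mm=[40, -25, 10],
                       pivot_mm=moving.centroid())
displaced = displace(moving, truth)

vfa = register_vfa(fixed, displaced)
gf = register_gf(fixed, displaced)
print(f"VFA : residual={vfa.residual:.3f}  iterations={vfa.iterations}")
print(f"GF  : residual={gf.residual:.3f}  iterations={gf.iterations}")

targets, labels = anterior_targets()
report = tre(targets, truth.apply(targets), vfa.transform, labels)
print(f"TRE at anterior targets (mm): min={report.min:.2f}  mean={report.mean:.2f}  max={report.max:.2f}")
```

Output:

```
VFA : residual=5.516  iterations=124
GF  : residual=415.261  iterations=48
TRE at anterior targets (mm): min=0.07  mean=0.12  max=0.17
```

The VFA method recovers the half-turn misalignment and reaches the global
minimum (residual 5.5 over the 1020 attributed scan points reflects the
0.3 mm sensor noise); the GF baseline stalls in a local minimum (residual
415, i.e. most points unmatched). Target registration error on the anterior
side of the skull — far from the scanned surface, where the lever-arm effect
is worst — stays well under the 1.5 mm margin commonly accepted for the head.

## Command line

```bash
vfareg simulate --seed 1 --out data/                     # phantom + scan (PLY)
vfareg register --fixed data/phantom.ply --moving data/scan.ply \
                --method vfa --out result.json
vfareg sweep    --fixed data/phantom.ply --moving data/scan.ply \
                --method gf --axis z --step 5 --out sweep.csv
vfareg surface  --fixed data/phantom.ply --moving data/phantom.ply \
                --pair phi-theta --grid 10 --out surface.csv
vfareg evaluate --targets targets.csv --transform result.json --out tre.csv
```

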