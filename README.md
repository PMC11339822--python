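# bmcpore

Structural and solvation analysis for **bacterial microcompartment (BMC)
shell-protein assemblies**, built to answer one question: do the central pores
of hexameric and trimeric shell tiles behave differently when the tiles sit in
a curved shell fragment versus a flat sheet?

BMC shells are protein-bounded bacterial organelles tiled by hexamers,
trimers, and pentamers; metabolites cross the shell through the tiles' central
pores. Simulating an intact shell is expensive, so a planar sheet of the same
tiles is an attractive surrogate — *if* pore geometry and water access are
unchanged by curvature. `bmcpore` provides the full analysis pipeline needed
to test that, and a synthetic-data module that generates inputs with
analytically known answers so every stage can be validated without large
trajectory downloads.

## What it computes

- **Pore-radius profiles** (HOLE-style): in each plane z along the channel
  axis, the largest sphere centred in that plane overlapping no vdW-inflated
  atom, i.e. `r(z) = max_p min_i (||p − x_i|| − R_i)`, located by an
  improvement-only Monte-Carlo search with shrinking step, marching plane by
  plane and following the channel centre. Trajectory-level per-z
  mean/median/min/max envelopes and per-frame bottleneck records.
- **Stability metrics**: Kabsch-superposed Cα RMSD series (whole assembly or
  per tile), trailing rolling-window smoothing, per-atom RMSF about the time
  mean after superposition onto the initial frame, explicit equilibration
  cuts.
- **Solvation metrics**: residue-wise Shrake–Rupley SASA (probe 1.4 Å, 960
  sphere points by default); unique-water contact counts within 5 Å; water
  residence times under a two-threshold hysteresis rule (association begins
  within 5 Å of a residue and ends only beyond 8 Å, so rattling between the
  thresholds does not split an event); hexamer-monomer segmentation into
  buried-interface vs solvent-exposed classes with mean ± SEM averaging over
  monomer copies.
- **XFMS dose–response analysis**: fraction unmodified from integrated peak
  areas, single-exponential fits `f(t) = A·exp(−k t)` yielding hydroxyl-radical
  modification rates k (s⁻¹) with standard errors, solution/shell k-ratios
  with first-order error propagation, and Pearson correlation of experimental
  ratios against structure-derived SASA or water-retention ratios (sites with
  undefined structural ratios are excluded and reported).
- **Rigid-body geometry**: Kabsch superposition, trimer pore normals,
  flattening of a curved tile assembly (each tile rotated rigidly so its pore
  normal aligns with a target axis and its centroid drops into a common
  plane), and Gaussian synthetic density maps (FWHM = nominal resolution) for
  downstream flexible fitting.
- **Synthetic data**: stacked-ring pore fixtures with exact radius profiles,
  scripted 3-site water tracks with ground-truth residence events, noisy
  exponential dose–response replicates, and rigid tile assemblies on a
  spherical cap with recorded true normals.

## Worked example

Profile a synthetic seven-ring channel whose radius shrinks linearly (exact
answer `ring_radius − vdw` at every ring plane), then recompute the published
hexamer solution/shell k-ratios from the bundled experimental table:

```python
import numpy as np
from bmcpore.synthetic_data import PoreGeometrySpec, make_pore_assembly
from bmcpore.pore import PoreParams, pore_profile
from bmcpore.xfms import reference_kvalues, k_ratio

rings = [(float(z), 6.0 - 0.3 * j, 12, 1.7) for j, z in enumerate(range(-3, 4))]
structure, analytic = make_pore_assembly(PoreGeometrySpec(rings=rings))
prof = pore_profile(structure, "all",
                    PoreParams(z_range=(-3, 3), z_step=1.0, seed=0,
                               seed_point=np.zeros(3)))
for z, r in zip(prof.z, prof.radius):
    print(f"z = {z:+.1f} A   pore radius = {r:.3f} A")
print(f"bottleneck: r = {prof.bottleneck()[0]:.3f} A at z = {prof.bottleneck()[1]:+.1f} A")

for sol, shell in reference_kvalues():
    r = k_ratio(sol, shell)
    print(f"{sol.site:<14s} solution/shell k-ratio = {r.value:.2f} +/- {r.stderr:.2f}")
```

prints

```
z = -3.0 A   pore radius = 4.058 A
z = -2.0 A   pore radius = 3.778 A
z = -1.0 A   pore radius = 3.497 A
z = +0.0 A   pore radius = 3.203 A
z = +1.0 A   pore radius = 2.910 A
z = +2.0 A   pore radius = 2.617 A
z = +3.0 A   pore radius = 2.500 A
bottleneck: r = 2.500 A at z = +3.0 A

M7             solution/shell k-ratio = 8.12 +/- 2.26
M16, M23       solution/shell k-ratio = 1.27 +/- 0.05
Y34            solution/shell k-ratio = 0.95 +/- 0.13
Y41            solution/shell k-ratio = 1.54 +/- 0.49
K54            solution/shell k-ratio = 2.15 +/- 0.17
P77, P79, P88  solution/shell k-ratio = 2.55 +/- 0.13
```

The bottleneck sits at the last (narrowest) ring, `6.0 − 0.3·6 − 1.7 =
2.5 Å`, exactly as constructed. Between the ring planes the profile
interpolates smoothly because the inscribed sphere touches atoms of the
nearest ring in 3D. The k-ratios quantify how much faster each site is
hydroxylated for tiles free in solution than assembled into a shell: M7's
ratio of 8.12 flags a dramatic loss of water access on assembly, while a
ratio near 1 (Y34, and nearly so for M16/M23) means the site's solvent
environment is indifferent to assembly state.

The end-to-end comparison (two conditions → stability, segmentation, solvent,
pore, XFMS correlation, one manifest) runs from a YAML config:

```bash
bmcpore make-fixture --kind demo --condition shell --out fixtures
bmcpore make-fixture --kind demo --condition sheet --out fixtures
bmcpore run-all --config analysis.yaml
```

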