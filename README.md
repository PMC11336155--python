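# dermakin

Multiscale kinematics of skin under uniaxial stretch: collagen microstructure
from multiphoton image volumes, tissue deformation from tracked features and
markers, and the measured-vs-affine fiber realignment comparison.

## The problem

The dermis bears load through a dense 3D network of collagen fibers. How that
network reorganizes under stretch — how much fibers realign, how much the
tissue thins and compacts, how stiffness develops along the stress-strain
curve — is central to understanding skin mechanics and how it changes with
age. Label-free multiphoton microscopy makes the network observable: second
harmonic generation (SHG) is specific to fibrillar collagen, and two-photon
excited fluorescence (TPEF) reports non-enzymatic crosslink
autofluorescence. Combining a uniaxial tester with a multiphoton microscope
yields, at every load increment, a 3D SHG/TPEF volume of the dermis
(micro-scale) and a wide-field image of inked fiduciary dots (macro-scale).

`dermakin` turns those raw observations into quantitative kinematics:

- **Microstructure** — collagen-positive masks (pluggable segmenter, Otsu
  threshold by default), fluorescein-referenced intensity normalization,
  voxel-wise 3D fiber orientation (θ, φ) from a windowed structure-tensor
  summation, and the scalar **3D directional variance**

  DV = (3/2)(1 − λ_max(⟨u uᵀ⟩)) ∈ [0, 1],

  0 for perfectly aligned axes, 1 for axes uniform on the sphere.
- **Micro-scale strain** — 3D SHG feature patches (20 × 20 × 5 voxels)
  detected by a corner score, tracked across increments by normalized
  cross-correlation over a 20 × 20 × 20 search window with sub-voxel
  refinement, gated by forward-backward consistency (every incremental error
  < 10 voxels, overall error < 1 voxel), then the largest tetrahedron of
  well-tracked points carries the deformation gradient **F**, Green strain
  ε = ½(FᵀF − I), principal strains and the volume ratio V/V₀ = det F.
- **Macro-scale mechanics** — fiduciary-dot tracking, isoparametric 2D F and
  Green strain, engineering stress σ = load/A₀, incremental modulus
  E_i = (σ_i − σ_{i−1})/(ε_xx,i − ε_xx,i−1) and incremental Poisson's ratio
  ν_i = −ε_yy,i/ε_xx,i, tabulated at 10 % ε_xx, 20 % ε_xx and the maximum
  modulus.
- **Affine comparison** — the measured F applied to the reference volume as a
  theoretical affine warp; ΔDV = DV_measured − DV_affine > 0 means fibers
  realign *less* than affine kinematics predict (non-affine behavior).
- **Statistics** — nested one-way ANOVA (sample as the error stratum for
  volume-level metrics), unpaired Student t-tests, one-sample test of
  ΔDV = 0, and box/whisker summaries.
- **Phantoms** — every stage is validated against synthetic data with known
  ground truth: fibrous SHG-like volumes with controlled axial orientation
  concentration (von Mises–Fisher, antipodally symmetrized), volumes warped
  by known affine maps, macro dot scenes under known 2D deformations, and
  toe/linear stress-strain traces.

## Worked example

Render a phantom with moderately aligned fibers (concentration κ = 8 about
the x axis), summarize its microstructure, then stretch it by a known
deformation and recover the strain from tracked SHG features:

```python
import numpy as np
from dermakin import (
    FiberPhantomSpec, generate_fiber_volume, collagen_mask, tissue_mask,
    summarize_microstructure, voxel_orientations, directional_variance,
    detect_features, track_features, forward_backward_gate,
    largest_tetrahedron, tetra_F3d, warp_volume_affine,
)

spec = FiberPhantomSpec(shape=(128, 128, 64), n_fibers=200,
                        concentration=8.0, seed=42)
shg, tpef, truth = generate_fiber_volume(spec)

collagen = collagen_mask(shg)
tissue = tissue_mask([shg, tpef])
field = voxel_orientations(shg, collagen.data)
summary = summarize_microstructure(shg, tpef, collagen, tissue, field)
print(f"collagen fraction : {summary.collagen_fraction:.1f} %")
print(f"directional variance: {summary.directional_variance:.3f}")

F = np.array([[1.095, 0.02, 0.0], [0.0, 0.913, 0.0], [0.0, 0.0, 0.960]])
stretched = warp_volume_affine(shg, F)
features = detect_features(shg, collagen.data, n_max=60, min_spacing=8)
tracks = forward_backward_gate(track_features([shg, stretched], features))
print(f"well-tracked features: {len(tracks)}/{len(features)}")

voxel = np.array(spec.voxel_size)
ref = np.array([t.ref_position for t in tracks]) * voxel
cur = np.array([t.positions[1] for t in tracks]) * voxel
tet = list(largest_tetrahedron(ref))
state = tetra_F3d(ref[tet], cur[tet])
print("recovered Green strain diag:", np.round(np.diag(state.green), 4))
print(f"volume ratio V/V0: {state.volume_ratio:.4f} (true {np.linalg.det(F):.4f})")
```

Output:

```
collagen fraction : 58.5 %
directional variance: 0.183
well-tracked features: 59/60
recovered Green strain diag: [ 0.095  -0.0866 -0.0477]
volume ratio V/V0: 0.9426 (true 0.9597)
```

The directional variance of 0.183 reflects the strong κ = 8 alignment (0
would be perfectly parallel fibers, 1 an isotropic network). All but one
detected feature survive the forward-backward gate, and the tetrahedron of
tracked features recovers the applied stretch: Green strain components match
the imposed deformation to better than 0.01 and the volume ratio to about
2 %.

A small command-line interface mirrors the library for shell use
(`dermakin phantom make-volume`, `dermakin segment`, `dermakin orient`,
`dermakin mech`; see `dermakin --help`).

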