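# fibramorph

Morphometry of fibrous biomaterials in 3D image volumes — the kind of data
produced by micro-CT of electrospun polymer scaffolds, cryogels and
particle-enriched hydrogels used in tissue engineering. The package
quantifies the structural parameters that drive cell response in such
materials: **fiber orientation**, **fiber diameter**, **porosity** and the
**number and size of particle inclusions** — and ships a synthetic fiber
phantom generator with exact ground truth so every estimator can be
validated without any external dataset.

## What it computes

A fiber axis is described by an azimuth θ ∈ (−90°, 90°] in the XY plane and
an elevation φ ∈ [0°, 90°] out of it, with unit direction
d(θ, φ) = (cos φ cos θ, cos φ sin θ, sin φ). Fibers are headless axes: *v*
and −*v* are the same orientation.

- **Local 3D orientation** (`estimate_tensor_orientation`): at every voxel
  of the medial axis (3D thinning of the segmented volume), the
  second-order structure tensor J = ⟨∇I ∇Iᵀ⟩ is averaged over a cubic
  window (default 32 voxels, Gaussian-derivative gradients at σ = 1); the
  fiber direction is the eigenvector of the smallest eigenvalue of J.
- **Global 2D orientation** (`estimate_fourier_orientation`): PCA of the
  Fourier power spectrum treated as point weights on frequency coordinates;
  the image orientation is perpendicular to the spectral major axis, with
  an anisotropy score 1 − λ₂/λ₁.
- **Fiber diameter** (`estimate_diameter`): from each oriented skeleton
  voxel, rays are cast in the plane perpendicular to the local axis
  (default 16 rays, 0.5-voxel steps); opposite rays are paired and the
  diameter is the mean chord length across pairs.
- **Porosity** (`calc_porosity`): exact background-voxel fraction of a
  labeled volume, plus per-material fractions.
- **Particle counting** (`object_counter`): connected-component analysis
  (6/18/26-connectivity) with voxel counts, centroids, bounding boxes and
  equivalent-sphere diameters, exportable as CSV.
- **Phantoms** (`simulate_fibers`): straight solid cylinders with sampled
  orientation/diameter/length/position, optional minimum gaps between
  fibers, Gaussian noise + smoothing contamination, and per-fiber ground
  truth records.
- **Validation protocol** (`fibramorph.evaluate`): wraparound-aware angular
  errors against ground truth, window-size sweeps, noise sweeps and an
  angular-range error scan.

## Worked example

```python
import numpy as np
import fibramorph as fm

# aligned phantom: every fiber at azimuth 27 deg, elevation 15 deg
cfg = fm.aligned_config(volume_shape=(128, 128, 128),
                        n_fibers_range=(8, 12), rng_seed=3)
phantom = fm.simulate_fibers(cfg)
skeleton = fm.skeletonize3d(phantom.volume)
field = fm.estimate_tensor_orientation(phantom.volume, skeleton, window_vox=32)
err = fm.angular_error(field, phantom)
print(f"{len(phantom.fibers)} fibers, {err.n_points} skeleton voxels")
print(f"azimuth error   {err.mean_azimuth_err_deg:.2f} +- {err.std_azimuth_err_deg:.2f} deg")
print(f"elevation error {err.mean_elevation_err_deg:.2f} +- {err.std_elevation_err_deg:.2f} deg")

diam = fm.estimate_diameter(phantom.volume, field)
true_mean = np.mean([f.diameter_vox for f in phantom.fibers])
print(f"diameter: estimated {diam.diameter_vox.mean():.1f} vox "
      f"(sampled fiber mean {true_mean:.1f} vox)")
```

prints

```
12 fibers, 492 skeleton voxels
azimuth error   0.59 +- 0.93 deg
elevation error 0.28 +- 0.34 deg
diameter: estimated 10.3 vox (sampled fiber mean 10.3 vox)
```

i.e. on a clean phantom the tensor estimator recovers the fiber axes to a
fraction of a degree and the ray-cast diameters track the sampled fiber
diameters within a voxel.

The same pipeline is available from the shell:

```sh
fibramorph simulate --shape 256,256,256 --azimuth 27 --elevation 15 \
    --seed 3 --out phantom/
fibramorph preprocess phantom/volume.tif work/pre --otsu --skeleton
fibramorph orient tensor phantom/volume.tif work/pre_skeleton.tif work/orient.csv --window 32
fibramorph diameter phantom/volume.tif work/orient.csv work/diameter.csv --voxel-size-um 1.8
fibramorph porosity phantom/labels.tif
fibramorph colorize work/orient.csv work/rgb.csv
```

All CSV outputs use 0-based x, y, z voxel coordinates; volumes are indexed
(z, y, x).

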