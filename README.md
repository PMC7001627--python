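# isospim

Isotropic reconstruction for tilted-scan, multi-view light-sheet
microscopy — with a full image-formation simulator, so the entire
pipeline is testable end to end without an instrument.

## The problem

Light-sheet microscopes sized for whole cleared organs compromise on
both axes: a thick Gaussian sheet (axial FWHM ~12 µm) and
low-magnification detection (lateral FWHM ~4.2 µm, 1.625 µm pixels).
This package recovers the lost resolution computationally, for people
building or analysing such instruments:

1. **Tilted continuous scanning.** The stage translates the sample along
   a direction S = R_y(θ₂)·R_x(θ₁)·ẑ tilted ~10° from the detection
   axis, with a step (280 nm) far below the sheet thickness. Each frame
   therefore carries sub-voxel shifts (≈48 nm lateral, ≈272 nm axial
   per step).
2. **Sub-voxel-resolving reconstruction (SVR).** Decimating the frame
   stream into M = round(Δz_target/dz) phase groups gives M mutually
   shifted low-resolution stacks y_j. On a grid finer by the
   enhancement factors (rx, ry, rz) = (4, 4, 2), the Poisson
   maximum-likelihood volume is iterated with the multiplicative
   multi-frame update

       x ← x · [Σⱼ Aⱼᵀ(yⱼ / Aⱼx)] / [Σⱼ Aⱼᵀ1],   Aⱼ = D Sⱼ H,

   (H sheared-PSF blur, Sⱼ sub-voxel shift, D block-average
   downsampling), followed by a shear realignment to Cartesian
   coordinates.
3. **Feature registration.** Views acquired under rotations about the
   vertical axis (8 views, 45° apart) are registered by detecting point
   features (beads or cell bodies), matching rotation-invariant
   constellation descriptors under a random-sample rigid consensus, and
   fitting the transform in closed form.
4. **Multiview deconvolution (MVD).** A weighted multiview
   Richardson–Lucy update fuses the registered views with per-view PSFs
   P_v and content weights w_v:

       ψ ← ψ · [Σᵥ (wᵥ·φᵥ/(ψ⊗Pᵥ)) ⊗ Pᵥ*] / [Σᵥ wᵥ ⊗ Pᵥ*],

   discarding attenuation-degraded content via the weights and yielding
   an isotropic estimate.

A synthetic module generates bead and filament phantoms and simulates
the whole acquisition chain (PSF blur, tilted scan, rotation, depth
attenuation, camera noise) with exact flux bookkeeping, and a metrics
module measures resolution as Gaussian-fit FWHM of bead profiles.

## Worked example

```python
import isospim as iso

config = iso.bead_characterization_config(
    phantom={"n_beads": 6, "size_um": 40.0, "min_separation_um": 11.0},
    svr={"max_iterations": 55, "exponent": 1.5},
    mvd={"max_iterations": 40},
    metrics={"expected_fwhm_um": (1.5, 1.5, 1.5), "isolation_um": 8.0},
    seed=20,
)
result = iso.run_pipeline(config)
print(result["report"].summary())
```

which simulates six 0.5 µm beads under the reference optics (4.2 µm
lateral / 12 µm axial PSF, 280 nm tilted steps, 4×4×2 enhancement,
8 views), reconstructs every view, registers and fuses them, and prints

```
{'n_beads': 6,
 'median_um': {'x': 0.746882747401659, 'y': 0.5973847876885257,
               'z': 0.7284985159297515},
 'iqr_um': {'x': 0.022898095244027417, 'y': 0.01914231078906714,
            'z': 0.019425018727751264},
 'median_lateral_um': 0.6721337675450924,
 'isotropy_ratio': 1.0838594207080627}
```

— the median bead FWHM per axis in µm over the measurable (isolated)
beads, the median lateral FWHM, and the axial/lateral isotropy ratio:
the fused volume resolves ~0.7 µm nearly isotropically (ratio 1.08),
versus 4.2/12 µm in the raw input. The intermediate single-view SVR
volumes of the same run measure ≈1.3/1.4/3.3 µm (x/y/z). Intermediate
artifacts (per-view SVR volumes, transforms, convergence logs,
manifest) are written when `out_dir` is set.

The same stages are scriptable from a shell:

```bash
isospim simulate --phantom phantom.json --geometry geom.json --out raw.tif
isospim svr --raw raw.tif --iters 55 --out view0_svr.tif
isospim register --ref view0_svr.tif --mov view1_svr.tif --out tf_1.json
isospim fuse --views v*.tif --transforms tf_*.json --out fused.tif
isospim metrics --volume fused.tif --beads beads.json --out report.csv
isospim pipeline --config run.json --out-dir out/
```

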