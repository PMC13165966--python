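# mdefov

Extended field-of-view lensless in-line digital holography: stitch laterally
scanned defocused holograms into an extended hologram at each of several
axial planes, run multi-depth amplitude-constrained phase retrieval, and
reconstruct the object plane. A full synthetic forward model makes every
stage testable without recorded data.

## What it does

1. **Simulate** (`mdefov.simulate`) — bar-target / phantom objects,
   plane-wave illumination, angular-spectrum propagation to each sensor
   plane, serpentine x-y scanning with a stage manifest, optional noise.
2. **Stitch** (`mdefov.stitching`) — grid topology from stage coordinates,
   overlap-ROI extraction with a ±10% search margin, patch-wise
   phase-correlation matching (pluggable matcher interface), median +
   2-D-histogram displacement voting, global least-squares alignment with
   loop closure, feathered weighted blending, auto-crop to full coverage.
   All planes of a dataset share the reference plane's layout and crop so
   the stack stays pixel-co-registered.
3. **Retrieve** (`mdefov.retrieval`) — multi-depth phase retrieval: zero
   phase at the reference plane, forward/backward propagation sweeps over
   all planes with the measured amplitude re-imposed at each, per-iteration
   RMSE/ΔRMSE convergence trace (default 10 iterations).
4. **Reconstruct & analyze** (`mdefov.analysis`) — back-propagation to the
   object plane; fringe contrast on three-bar elements (Michelson, MTF10
   resolution criterion); USAF-1951 chart law; system formulas (theoretical
   resolution λ√(4z²+L²)/(2L), effective NA, depth of field λ/NA², overlap
   ratio, area gain).
5. **Drive** (`mdefov.pipeline`, `mdefov.cli`) — end-to-end pipeline and a
   CLI; float-TIFF/CSV/JSON/YAML artifacts throughout.

The core wavefield engine (`mdefov.optics`) implements the exact
angular-spectrum transfer function with hard-zeroed evanescent waves and an
optional band-limited kernel for distances beyond the alias-free bound
`N·pitch²/λ`.

## CLI

```sh
# full demo pipeline: 3x3 scan, 256 px tiles, 5 axial planes (~10 s)
mdefov run --out runs/demo --seed 1

# or stage by stage
mdefov simulate --out runs/demo --seed 1
mdefov stitch --manifest runs/demo/manifest.csv --plane 3 --pitch-um 2 \
              --out runs/demo/stitched_z3.tif
mdefov retrieve --stack runs/demo/stitched_z0.tif ... --z 1.2,1.65,2.1,2.55,3.0 \
                --ref 3 --iters 10 --out runs/demo/field.tif
mdefov reconstruct --field runs/demo/field.tif --out runs/demo/recon
mdefov analyze --image runs/demo/recon_amplitude.tif --chart-map chart.json \
               --report runs/demo/report.json
```

A YAML config (see `mdefov.io.DEFAULT_CONFIG`) controls the geometry; an
empty config reproduces the full-scale acquisition defaults (632.8 nm, 2 µm
pitch, five planes from 114 mm at 1 mm spacing, reference plane 3). The
built-in demo configuration is desk-scaled (z = 1.2–3.0 mm) so the plain
angular-spectrum kernel stays alias-free at 256–480 px array sizes.

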