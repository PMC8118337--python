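# rbc3d — 3D red blood cell shape phenotyping

`rbc3d` turns 3D confocal z-stacks of membrane-stained red blood cells (or
synthetic cell meshes) into quantitative shape verdicts:

1. **Synthetic shapes** (`rbc3d.shapes`) — parametric canonical RBC meshes
   (biconcave discocytes, cup-shaped stomatocytes, spherocytes, spiculated
   echinocytes, trilobal knizocytes, acanthocytes, keratocytes, multilobate
   cells, fused cell clusters), continuous morphs between them, and
   confocal-like anisotropic voxel stacks with blur and noise — so every
   downstream stage is testable without real data.
2. **Stack preprocessing** (`rbc3d.preprocess`) — crop single cells,
   linearly interpolate z to the lateral pixel size (e.g. 68 planes at
   300 nm → 185 planes at 110 nm), binarize at a fixed threshold, and
   extract a marching-cubes isosurface centred at its bounding box.
3. **Shape descriptor** (`rbc3d.descriptor`) — a rotation- and
   translation-invariant spherical-harmonics descriptor: the cell is
   voxelized onto a 64³ grid, 32 concentric spheres are sampled and
   decomposed into 16 harmonic degrees; per radius the descriptor stores
   3 Euclidean scalars (eigenvalues of the degree-0+2 quadratic form) and
   14 band L2 norms, giving a 32 × (3 + 14) = 544-vector that is min-max
   normalized to [0, 1].
4. **Augmentation** (`rbc3d.augment`) — leakage-safe splitting before
   augmentation, then linear spectrum interpolation: within classes for
   the classifier, and within/between adjacent classes of the
   stomatocyte–discocyte–echinocyte (SDE) ladder for the regressor, with
   linearly interpolated scores.
5. **Dual-stage network** (`rbc3d.ann`) — a 544-54-7 softmax classifier
   (cross-entropy, Adam, 100 epochs, batches of 100) with a 75%
   confidence threshold routing uncertain cells to "unknown", followed by
   a 544-544-1 bounded regressor (tanh, MSE, 40 epochs) that scores SDE
   cells on the continuous scale from −1 (spherocyte) through 0
   (discocyte) to +1 (echinocyte III). Both stages support multi-restart
   selection by validation loss. Implemented in pure numpy for
   bit-reproducible training.
6. **Reporting** (`rbc3d.reporting`) — per-sample class fractions, SDE
   score densities with μ and the central 95% interval, and confusion
   matrices against manual labels using the ±0.17 score-matching rule
   (half the spacing between adjacent perfect shapes).

## CLI

```sh
rbc3d simulate --classes discocyte,spherocyte --n-per-class 10 --seed 1 --out-dir sim/ --stacks
rbc3d preprocess --in sim/discocyte_00000.tif --out-dir meshes/ --threshold-fraction 0.5
rbc3d describe --meshes meshes/ --out descriptors.tsv
rbc3d train --stage 1 --data descriptors.tsv --labels labels.tsv --restarts 3 --seed 1 --out stage1.npz
rbc3d predict --stage1 stage1.npz --stage2 stage2.npz --descriptors descriptors.tsv --out results.tsv
rbc3d report --results results.tsv --manual labels.tsv --out-dir report/
rbc3d run --out-dir run/ --seed 1          # full synthetic pipeline
```

Meshes are ASCII OBJ/PLY; stacks are multi-page TIFF with voxel size in
the image description and a JSON ground-truth sidecar; descriptors and
results are TSV.

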