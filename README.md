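# dvn — 3-D vessel segmentation toolkit

A tested library and CLI for segmenting vessels, predicting centerlines,
and detecting bifurcations in 3-D angiographic volumes, built from four
components:

- **Cross-hair convolution** (`dvn.crosshair`) — approximates a dense
  `(kx, ky, kz)` 3-D convolution by three 2-D kernels on the orthogonal
  planes through each voxel, cutting the per-voxel multiplication count
  from `kx·ky·kz` to `ky·kz + kx·kz + kx·ky`. Ships a dense reference
  implementation, a literal per-voxel form, the efficient slice-stack
  form, and the closed-form operation-count model relating them.
- **Class-imbalance losses** (`dvn.losses`) — standard cross entropy, the
  unstable sum-form class-balanced variant, a scale-stable per-class-mean
  variant (`l1_only`), and the full loss with false-prediction-rate
  correction (`deepvesselnet`), whose confidence weights γ1, γ2 ∈ [0.5, 1]
  grow with how far wrong predictions sit from the 0.5 threshold.
- **Synthetic vascular trees** (`dvn.synth`) — recursive geometric growth
  enforcing the radius power law `r_p^γ = r_l^γ + r_r^γ` and the
  minimum-volume branching-angle constraints at every bifurcation, plus
  capsule voxelization, 26-connected centerline rasterization, cube
  bifurcation labels, and noisy intensity rendering (vessels in
  [128, 255], background in [0, 100]). Default settings give ~2% vessel
  voxels per volume.
- **FCN and pipeline** (`dvn.models`, `dvn.pipeline`) — a 5-layer
  fully-convolutional network with no pooling/sub-sampling, same-size
  zero padding, per-layer cross-hair or full-3D mode, and sigmoid output
  (default width 1→5→10→20→50→1, 46,021 parameters in cross-hair mode vs
  58,521 dense). Training is plain SGD on non-overlapping 64³ boxes with
  a stepped learning-rate decay; inference runs on full volumes of any
  size. Evaluation includes precision/recall/Dice and the hit-or-miss
  bifurcation protocol (5×5×5 cube overlap).

The network is implemented directly on NumPy (strided sliding-window
views + `einsum`, hand-written adjoints verified against finite
differences), so no GPU framework is required.

## CLI

```sh
# operation-count model
dvn count-ops --kernel 5,5,5 --volume 128,128,128 --mode crosshair

# generate labeled synthetic volumes (NIfTI + tree JSON + manifest)
dvn synth --config cfg.yaml --n 10 --seed 1 --out data/

# train / predict / evaluate
dvn train --config cfg.yaml --data data/ --task vessel --seed 1 --out model.npz
dvn predict --model model.npz --in data/vol_000_image.nii.gz --out prob.nii.gz
dvn evaluate --pred prob.nii.gz --gt data/vol_000_vessel.nii.gz --task seg
dvn evaluate --pred prob.nii.gz --gt data/vol_000_tree_0.json --task bifurcation

# check simulator constraints on a tree document
dvn validate-tree --tree data/vol_000_tree_0.json --gamma 3
```

The YAML config has optional `synth`, `train`, and `model` sections;
missing keys take defaults and unknown keys are rejected. Example:

```yaml
synth:
  volume_shape: [64, 64, 64]
  gamma: 3.0
train:
  learning_rate: 0.01
  decay: 0.99
  iterations: 1000
  loss: deepvesselnet   # or: cross_entropy | balanced | l1_only
model:
  mode: crosshair       # or: full3d
```

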