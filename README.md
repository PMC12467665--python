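# flfsi

Feature-level fusion of paired ultrasound modalities by tri-channel 2DPCA
and swarm-selected feature reconstruction.

## The problem

Contrast-enhanced ultrasound (CEUS) shows blood perfusion that conventional
B-mode sonography cannot, but the two modalities are usually analysed
separately. This package fuses paired conventional/CEUS images in a learned
feature space so that downstream detectors see one image carrying both
tissue texture and perfusion cues. It is aimed at medical-imaging
researchers preparing fused training data, and ships a seeded synthetic
phantom generator so the entire pipeline runs and is testable without any
clinical data.

## The method

For a training stack of N color images `O_i ∈ R^{H×W×3}`, each channel `c`
gets its own 2DPCA decomposition: the column scatter matrix

    S_t^c = (1/N) Σ_i (O_i^c − Ō^c)^T (O_i^c − Ō^c)   (W×W, PSD)

is eigendecomposed; its eigenvectors `W_j^c` are projection axes and
`Y_j^c = O^c W_j^c` are projected feature vectors. An image is approximately
reconstructed from a subset S of components as `Õ^c = Σ_{j∈S} Y_j^c (W_j^c)^T`.

Which components to keep is a binary optimization over `{0,1}^{d×3}` masks
(d = image width), minimizing

    fitness(S) = mean_i Σ_c ‖O_i^c − Õ_i^c(S)‖_F + λ·|S|

with sparsity charge λ (default 0.001). Two binary PSO variants are
implemented: the **traditional** sigmoid-transfer BPSO, and an **improved**
variant that draws the cognitive/social factors r1, r2 as integers in
{0,1}, quantizes velocities with the sign function to {−1,0,1}, and moves
positions additively with clamping to {0,1}. The final component set is

    B = B1 ∪ B2

where B1 is the tri-channel consensus of the swarm's best mask (components
selected in all three channels) and B2 holds the top-m components by ℓ2
energy of their projected feature vectors (m = 100 at full scale,
proportionally smaller on small images). Each modality is reconstructed
from its own B, and the pair is fused at CEUS proportion x ∈ [0,1]:

    F = x·CEUS + (1−x)·conventional.

Top-k eigenvalue baselines (color `rgb_topk` and grayscale `gray_topk`,
k = 160 at full scale) are included for comparison.

## Worked example

```python
import numpy as np
from flfsi import (SyntheticParams, generate_dataset, fit_basis, BPSOConfig,
                   run_bpso, selection, rgb2dpca, fusion)

ds = generate_dataset(SyntheticParams(n_pairs=8, seed=7))          # 64x64 phantoms
basis = fit_basis(ds.conv)                                         # per-channel axes
result = run_bpso(ds.conv, basis, BPSOConfig(swarm_size=20, iterations=40, seed=1))
b1 = selection.consensus_indices(result.gbest)                     # tri-channel consensus
proj = np.stack([rgb2dpca.project(im, basis) for im in ds.conv])
b2 = selection.l2_rank(proj, 10)                                   # top-10 by l2 energy
b = selection.union_selection(b1, b2)
recon = selection.reconstruct_selected(proj[0], basis, b)
_, err_b = rgb2dpca.frobenius_error(ds.conv[0], recon)
top = selection.baseline_topk(basis, len(b))
_, err_top = rgb2dpca.frobenius_error(
    ds.conv[0], selection.reconstruct_selected(proj[0], basis, top))
print(f"swarm fitness {result.gbest_fitness:.4f} after {result.evaluations} evaluations")
print(f"|B1|={len(b1)}  |B2|={len(b2)}  |B|={len(b)}")
print(f"reconstruction error with B: {err_b:.4f}  (top-{len(b)} baseline: {err_top:.4f})")
fused = fusion.fuse(ds.conv[0], ds.ceus[0], fusion.FusionSpec(x=0.2))
print(f"fused image range: [{fused.min():.3f}, {fused.max():.3f}]")
```

prints

```
swarm fitness 11.2974 after 800 evaluations
|B1|=22  |B2|=10  |B|=25
reconstruction error with B: 15.1497  (top-25 baseline: 19.6826)
fused image range: [0.068, 0.788]
```

The swarm's fitness is the stack-mean reconstruction error plus the
sparsity charge. The selected set B (25 of 64 components) reconstructs the
first phantom with a lower Frobenius error than the top-25
largest-eigenvalue baseline — the swarm keeps components that carry
image-specific structure the global eigenvalue ranking underrates. The
fused image is a convex blend, so its intensities stay inside the range of
its two parents.

The same pipeline is available as a CLI:

```
flfsi synth --out data --n 16 --size 64 --seed 7
flfsi fuse --conv data/conv --ceus data/ceus --x 0.2 --out run \
           --sweep 0.1:0.9:0.1
flfsi benchmark --images data/conv
flfsi export-yolo --images run/fused --masks data/masks --out yolo
```

`fuse --sweep 0.1:0.9:0.1` writes one fused dataset per CEUS proportion,
plus the selection sets (JSON), the swarm trace (CSV) and a run manifest
from which every artifact is reproducible.

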