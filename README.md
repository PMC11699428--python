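# abmff — agent-based + firefly-clustering image segmentation

`abmff` implements a two-phase hybrid method for segmenting noisy 8-bit
grayscale images, aimed at workflows (e.g. biological imaging) where
impulse noise and within-region intensity variation break plain
clustering-based segmentation.

**Phase 1 — agent-based homogenization.** Every pixel is an agent holding
one of 256 intensity states. Each sweep, the agent `e0` computes the sign
consensus of its Moore neighbourhood `e1..e8`,

    S(e0) = sign( Σ_q sign(e_q − e0) ),

and updates `e0 ← e0 + S·Δ` (clamped to [0, 255]): it steps toward the
neighbourhood majority, stands still in uniform regions (`S = 0`) and on
perfectly balanced edges. Agents are processed sequentially along a raster
path (rows top-to-bottom, right-to-left within a row), so regions
homogenize while strong edges survive; after `iter1` sweeps the result is
the homogenized image `IH`.

**Phase 2 — firefly clustering with K-means refinement.** A "firefly" is a
set of k centroid intensities μ1..μk scored by the regularized objective

    J(C) = Σ_i Σ_{x∈C_i} ‖x − μ_i‖² − α Σ_{i<j} ‖μ_i − μ_j‖²,   α = 0.6,

under nearest-centroid assignment (computed exactly over the 256-bin
intensity histogram). The swarm moves toward brighter (lower-J) members
with distance-decaying attractiveness plus a shrinking random walk; the
best solution seeds a weighted K-means, and the better of the two under J
is kept. Labelling each pixel of `IH` with its nearest centroid gives the
segmentation `IS`.

The package also ships the synthetic ground-truthed image generator used
to evaluate the method (piecewise-Gaussian regions, salt-and-pepper and
additive Gaussian noise), the full-reference quality indices PSNR, global
SSIM and FSIM, a multilevel Otsu baseline, and a thin CLI
(`abmff synth | homogenize | cluster | segment | evaluate | experiment`).

## Worked example

Three heavily overlapping vertical bands (means 40/128/215, std 30) plus
10 % salt-and-pepper noise, segmented with k = 3
(`python examples/04_full_pipeline_vs_baselines.py`):

```
method  accuracy    psnr   ssim   fsim    rmse
abm-ff    0.8730 13.8137 0.7659 0.4159 51.9823
no-abm    0.8464 15.0669 0.8747 0.6176 44.9984
  otsu    0.8464 15.0669 0.8747 0.6176 44.9984
```

`accuracy` is the fraction of pixels assigned to the correct ground-truth
region (best label permutation); the other columns score the
centroid-rendered segmentation against the clean reference image. The
homogenization stage lifts pixel accuracy from 0.846 to 0.873 on this
input — that gap is what phase 1 contributes. (PSNR/SSIM/FSIM of the
rendering are computed against the *clean* image, so they also penalize
the homogenizer's intended smoothing, which is why they can favour the
ablation even when accuracy does not.)

On the clean two-region benchmark (regions N(50, 20) and N(200, 20)) the
pipeline recovers centroids (50.35, 200.38) and labels 99.98 % of pixels
correctly (`python examples/03_cluster_intensities.py`).

More narrative scripts live in `examples/`, one per capability.

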