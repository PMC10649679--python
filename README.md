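# vesiscope

Quantitative imaging of inhibitory-receptor traffic in T cells.

Inhibitory receptors (CTLA-4, PD-1, LAG3, TIM3, TIGIT) are largely held
in intracellular vesicles and only a small, regulated fraction reaches
the cell surface. Measuring that distribution — and catching the moments
when vesicles deliver receptor to the plasma membrane — takes several
bespoke image computations that this package implements as a tested,
reusable library:

* **Edge/interior statistics** for confocal midplanes: a distance-based
  split of each cell into an edge ring (a set share of the area) and an
  interior core, with the edge:interior intensity ratio, the Gini
  coefficient of pixel intensities (0 = even, 1 = one pixel holds all
  signal), and a greyscale Ripley's K — intensity-weighted pair mass
  within radius r, normalised so complete spatial randomness scores
  πr².
* **Membrane-associated fraction** from high-resolution z-stacks: 3D
  instance segmentation, central-slice selection, radial surface
  refinement (first crossing of 30%/50% of each ray's maximum, scanning
  from outside), membrane width from the smallest Gaussian cross-section
  σ's (×2 or ×3 by receptor class), and isotropic (ρ²-weighted) 3D
  extrapolation of the membrane/interior split.
* **TIRF insertion-event detection**: blur-frame exclusion by an SVM on
  focus measures; wavelet-smoothed particle detection validated by a
  one-sided Welch t-test of each candidate's brightest patch pixels —
  shifted down by 4 σ_local + 3 σ_global — against its three nearest
  local minima (p < 0.001); greedy nearest-neighbour tracking (linkage
  22 px, gap 3 frames); and per-time-point SVM classification of the
  log10 p-value series into abrupt-then-dispersing *insertion* events vs
  persistent *microclusters*, with rates per 100 frames and µm².
* **Interface line scans**: a 20 px band across the cell averaged into
  10 segments, normalised to the brightest.
* **Pearson colocalization** with two segmentation recipes — dual-colour
  TIRF cell segmentation/tracking (Sauvola thresholding, circularity and
  size filters) and confocal cytoplasm segmentation with or without a
  nuclear stain (Huang threshold, nearest-nucleus partition).
* **Synthetic scenes with exact ground truth** for every analysis:
  cells with a known edge/membrane signal share, TIRF movies with known
  insertion/microcluster events and defocused frames, and channel pairs
  with a known correlation, so the whole pipeline is testable without
  any imaging data.

See `docs/methods.md` for models, defaults and design decisions.

## A worked example

```python
from vesiscope.imgmodel import PipelineParams
from vesiscope.membrane import estimate_membrane_fraction
from vesiscope.synthetic import StackSceneSpec, generate_cell_stack

spec = StackSceneSpec(membrane_fraction=0.6, seed=3)   # truth: 60% at membrane
stack, truth = generate_cell_stack(spec)
params = PipelineParams.for_receptor_class("tim3")     # threshold 0.30, x3 width
est = estimate_membrane_fraction(stack, params)[0]
print(est.central_slice, round(est.membrane_width_px, 2),
      round(est.membrane_fraction, 3))
```

prints

```
24 3.34 0.579
```

— the central slice of the segmented cell, the apparent membrane width
in pixels (PSF-broadened), and the estimated share of the cell's
fluorescence at the membrane, within 0.03 of the constructed truth.
The scripts in `examples/` walk through each capability the same way
(`python examples/tirf_insertion_events.py` trains the event classifier
on synthetic movies and detects insertions in a fresh one).

A thin CLI wraps the same functions for shell use:

```bash
vesiscope simulate --kind stack --seed 3 --out-dir scratch/
vesiscope membrane --stack scratch/stack.tif --receptor-class tim3 --out-dir scratch/
```

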