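# vesiflow

Whole-cell visualization of intracellular vesicle transport from
single-channel fluorescence time-lapse microscopy.

Single-particle tracking resolves individual vesicle trajectories but
yields too few tracks per cell to describe transport at the whole-cell
level. `vesiflow` takes the complementary, dense approach: it computes
per-pixel optical flow over the entire cell, relates every flow vector to
the geometric cell center, and renders the result so that endocytic
(inward, dynein-like) and exocytic (outward, kinesin-like) traffic are
immediately visible as two contrasting colors.

## Method

Given an N-frame stack I_k(i, j):

1. **Dense Lucas–Kanade optical flow** between adjacent frames. Under
   brightness constancy, I_x V_x + I_y V_y + I_t = 0 at each pixel; the
   flow V is the weighted least-squares solution over a window Ω,

       [Σ W²I_x²   Σ W²I_xI_y] [V_x]   [−Σ W²I_xI_t]
       [Σ W²I_yI_x Σ W²I_y² ] [V_y] = [−Σ W²I_yI_t]

   Pixels whose structure tensor is near-singular (flat or 1-D texture,
   the aperture problem) are flagged invalid rather than solved.
2. **Cell-center estimation from temporal variability.** Vesicles funnel
   from the membrane toward the microtubule organizing center, so pixel
   intensity fluctuates least near the geometric center. Per-pixel
   temporal STD σ_ij is thresholded at σ̄ − σ_s (σ_s = STD of the σ
   distribution) and the center (C_x, C_y) is the centroid of the quiet
   region.
3. **Direction classification.** With α the angle of the pixel-to-center
   vector and β the flow angle, the wrapped difference |α − β| ∈ [0, π]
   classifies each vector: Inward if |α − β| ≤ π/2, Outward otherwise.
4. **Visualization.** A diverging red–white–blue colormap indexed by
   |α − β|/π (red = inward, blue = outward, neutral = tangential), the
   conventional HSV encoding for comparison, per-frame summary
   time-series, and a polar (R, θ) re-representation about the center,
   (x, y) = (C_x + R cos θ, C_y + R sin θ), which turns radial transport
   into vertical structure.

A seeded synthetic generator produces movies of Gaussian-PSF vesicle
spots on a dim cell body with inward/outward/diffusive motion and
Poisson–Gaussian noise, together with exact ground-truth trajectories, so
the whole pipeline is testable without real data.

## Worked example

```python
import vesiflow as vf

scene = vf.SceneConfig(seed=1, motion_modes="inward", n_vesicles=120,
                       initial_radius_range=(0.5, 1.0), n_frames=8,
                       diffusion_sigma=0.2)
stack, truth = vf.generate_movie(scene)

flows = vf.compute_flow_series(stack)          # N-1 dense flow fields
center = vf.estimate_center(stack)             # STD-map centroid
maps = [vf.direction_map(f, center) for f in flows]
summary = vf.summarize_series(maps)[0]

print(f"true center   : {tuple(map(float, truth.cell_center))}")
print(f"estimated     : ({center.center[0]:.2f}, {center.center[1]:.2f}) "
      f"from {center.mask_size} quiet pixels")
print(f"frame pair 0  : {summary.n_vectors} vectors classified, "
      f"{100*summary.prop_inward:.1f}% inward, "
      f"mean speed {summary.mean_magnitude:.2f} px/frame")
```

prints

```
true center   : (63.5, 63.5)
estimated     : (61.52, 59.90) from 1219 quiet pixels
frame pair 0  : 16298 vectors classified, 72.1% inward, mean speed 1.25 px/frame
```

The simulated scene is pure endocytosis (every vesicle moves inward at
1.5 px/frame); the center estimate lands ~4 px from the truth, and 72 %
of classified flow vectors in the first frame pair point inward — the
remainder are noise-floor flows in vesicle-free regions, which split
evenly between the two classes.

The same workflow runs from the shell:

```sh
vesiflow all -c config.yaml --seed 1     # full bundle into the output dir
vesiflow simulate|flow|center|classify|polar|render|sensitivity ...
```

Every run writes its effective configuration (`run_config.yaml`) and a
log beside the outputs, and identical configs reproduce byte-identical
results.

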