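# shellprint

Multiscale image analysis of the periodic growth patterns on scallop
shells: segmentation of the rib/ring line network, extraction and
matching of its cyclic structures, and their use for individual
re-identification, growth measurement, and species-level shape sorting.

## Who this is for

Shell surfaces record growth as concentric rings crossed by radial ribs
radiating from the umbo (the origin growth point). The crossings and
bifurcations of that network form a pattern that is stable for an
individual and variable between individuals — a natural marking usable
for photographic mark–recapture, growth-rate measurement, and
morphometric species sorting, without tagging or genotyping. This
package implements that workflow for grayscale or RGB shell images (CT
scans or camera photographs) and ships a synthetic phantom generator so
every stage is testable without any image collection.

## The method

1. **Enhancement (MFGK).** Matched filtering with a rotated Gaussian
   line kernel, `ker(x) = −exp(−(a⁻¹x)²/2σ²)` across the line and
   constant along it, zero-mean shifted; the response keeps the maximum
   over 17 orientations (10°–170°, step 10°, `a = 8`) and is globally
   z-scored: `f = (M_ker − μ)/σ`.
2. **Multiscale segmentation.** Hierarchical Rudin–Osher–Fatemi
   decomposition `J(g, λ) = λ‖v‖² + ‖u‖_BV` with the dyadic schedule
   λ_k = λ₀·2^k (λ₀ = 0.01), solved by Chambolle's projection; each
   line map u_k is binarized at 0, small components removed, line holes
   closed. `f = u₀ + … + u_K + v_K` holds exactly.
3. **Skeleton graph.** Thinning to 1-px centerlines; pixels with ≥ 3
   skeleton neighbors cluster into bifurcation/crossover feature
   points; centerline paths become edges; iterative degree-1 removal
   leaves the 2-core.
4. **Cyclic structures (SDFS).** A space-based depth-first search closes
   the smallest face-like cycles (3–6 points) by always taking the
   tightest turn, ordered by the cross product of incoming and outgoing
   edge vectors; on planar fixtures the result is a minimum cycle basis.
   Each structure gets a scale/rotation-invariant 6n-dimensional vector
   (normalized lengths L_i/ΣL_i, branch and corner angles θ/360°; 18,
   24, 30, 36 dimensions for n = 3..6) and structures are matched by
   minimizing s_ij = d(ṽ_i, ṽ_j), with `ms = min s_ij`.
5. **Registration and recognition.** Matched structures give point
   correspondences for a least-squares affine warp; the overlap ratio
   `ra` (fraction of warped skeleton pixels within 1 px of the
   template's) joins `ms` as the feature pair {ms, ra} feeding a small
   three-layer back-propagation classifier (10 hidden nodes, targets
   [1 0]/[0 1], error target 0.01, 500 iterations, 10 restarts).
6. **Anatomy and morphometrics.** Sector-restricted Hough transform for
   ribs and their common origin; neighborhood-suppressed radial
   profiling for rings; along-rib inter-ring distances as growth
   increments. Thin-plate-spline template correspondence, generalized
   Procrustes superimposition, and PCA sort species by shell shape.

## Worked example

```python
import numpy as np
from shellprint import synthetic, pipeline, recognition

cfg = pipeline.PipelineConfig(
    mfgk=pipeline.MFGKParams(a=8.0, sigma_kernel=0.25, polarity="bright")
)

# two captures of one individual, one capture of another
base = synthetic.ShellPhantomSpec(jitter_sigma=3.0, noise_sigma=0.03)
images = synthetic.generate_individual_set(base, 2, 2, master_seed=42)
art = [pipeline.extract_artifacts(ph.image, cfg, scale_index=5)
       for _, ph in images]

print("structures per image:", [len(a.structures) for a in art])
same = recognition.extract_features(art[0], art[1])
diff = recognition.extract_features(art[0], art[2])
print(f"same individual: ms={same.ms:.3f} ra={same.ra:.3f}")
print(f"different individual: ms={diff.ms:.3f} ra={diff.ra:.3f}")
```

prints

```
structures per image: [27, 29, 29, 31]
same individual: ms=0.042 ra=0.950
different individual: ms=0.077 ra=0.509
```

Each image yields ~30 cyclic structures at the finest scale. The two
captures of the same individual register almost perfectly — 95% of
skeleton pixels land within 1 px of the template (`ra`), against 51%
for the impostor — while the minimum descriptor distance `ms` is small
in both cases because a rib/ring lattice always contains some locally
similar cells; the classifier learns that `ra` carries most of the
discrimination and separates the two classes cleanly.

The same objects drive the command line:

```
shellprint synth --seed 3 --out work/
shellprint run work/phantom.png --out work/run/
shellprint compare work/phantom.png work/phantom.png --out work/cmp/
```

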