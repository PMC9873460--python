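# slns — self-learning brain-tumor MRI segmentation and impact analysis

`slns` is a desk-scale toolkit for identifying brain tumors on 2-D MRI
slices and quantifying their burden, aimed at researchers who want a fully
testable, dependency-light implementation of a self-learning segmentation
pipeline — including a synthetic phantom generator, so every stage can be
exercised and benchmarked without any clinical dataset.

The pipeline:

* **fuzzy-Gaussian denoising** — an edge-preserving hybrid kernel
  `out = pix − min(γ·f_z, 1)·(pix − G_σ(pix))` where
  `f_z = 1/(1 + ((v − t_max)/k_max)^{2u_max})` is a fuzzy membership of the
  pixel to its local segment;
* **GLCM texture features** — co-occurrence counts
  `C(x, y) = #{(p,q) : I_q(p,q) = x, I_q(p+d_p, q+d_q) = y}` and the
  Haralick statistics contrast, energy, homogeneity, entropy;
* **HARIS segmentation** — a heuristic two-objective loop: elbow-based
  segment-count estimation on the intensity histogram, Mahalanobis pixel
  assignment `d²(x) = (x−μ)ᵀ S⁻¹ (x−μ)`, the fitness
  `f = Σ_r α·N/n_r + Σ_r β·k/n_r` with `α` an intraclass-correlation
  coefficient and `β = Σ_r ω_r σ_r²`, fitness-gated split/merge of the
  segment count, and stochastic seed-point refinement
  `sp_i = rand·f_prev + rand·(GB − f_prev)` toward the global best;
* **fitness machinery** — Otsu between-class variance `ω₁ω₂(μ₁−μ₂)²`,
  fuzzy-entropy threshold selection (Shannon entropy of S-shaped class
  memberships, maximized over candidate levels), intraclass correlation
  `σ²_seg/(σ²_seg + σ²_img)`;
* **VAE augmentation** — a numpy variational autoencoder maximizing
  `ELBO = E_q[log p(x|z)] − KL(q(z|x) ‖ N(0, I))` to generate extra
  training slices;
* **bidirectional recurrent classifier** — sigmoid recurrences
  `ff_t = σ(W_x x_t + W_h ff_{t−1} + b)` over patch rows in both
  directions with a softmax readout, trained by BPTT under a decaying
  learning rate and class weights persisted in a cross-run
  **self-learning memory**;
* **impact analysis** — tumor core / enhanced / whole areas, the damage
  index `ln(1+area)·(1+contrast)` with bootstrap error bars, progression
  deltas and growth flags, and color overlays.

## Worked example

```python
from slns.phantom import PhantomSpec, generate_phantom
from slns.denoise import denoise_image
from slns.haris import HarisConfig, run_haris
from slns.metrics import confusion
from slns.impact import compute_report

img, truth = generate_phantom(PhantomSpec(seed=3))   # 228x228, noise sigma 5
den = denoise_image(img)
seg = run_haris(den, HarisConfig(seed=3))
print(seg.n_segments)                                 # -> 5

core = max(range(seg.n_segments),
           key=lambda s: confusion(seg.labels == s, truth.labels == 3).dice)
rep = confusion(seg.labels == core, truth.labels == 3)
print(round(rep.dice, 4), round(rep.sensitivity, 4)) # -> 1.0 1.0

imp = compute_report(truth, den, seed=0)
print(imp.core_area, imp.enhanced_area, imp.whole_area)
# -> 1517.0 936.0 2453.0
print(round(imp.core_index, 3), round(imp.erroneous_core, 3))
# -> 8.325 0.174
```

The phantom has five tissue classes (background, skull, brain, tumor core,
enhancing rim). HARIS starts from an elbow estimate of the segment count,
splits segments whose intensities prove bimodal, and here recovers all
five regions; the tumor core is segmented with Dice 1.0 against the exact
ground truth. The impact report gives the region areas in pixels (whole =
core + enhanced by construction) and a texture-weighted damage index with
a bootstrap error half-width.

The same flow is available from the shell:

```bash
slns simulate --out out/ --n 5 --seed 1        # phantoms + ground truth
slns denoise  --in out/image_000.png --out den.png
slns segment  --in den.png --out seg.png --seed 1
slns evaluate --pred seg.png --truth out/mask_000.png --out eval.json
slns run      --seed 5 --out run-out/          # full pipeline end to end
```

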