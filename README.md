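# pgrecon

Physics-guided synthetic phantoms and CNN image reconstruction for
biomedical imaging research.

Quantitative imaging methods are hard to validate on clinical data, where
ground truth is unknown and acquisition conditions vary. `pgrecon` provides
the controlled alternative: it simulates clean 2D/3D image fields from
parametric physical models, corrupts them with a known noise process, trains
a convolutional reconstructor whose loss embeds physical priors, and scores
the result with standard image-quality metrics. It is aimed at researchers
studying physics-guided learning — how much accuracy, robustness and
interpretability explicit physical constraints buy over purely data-driven
training — under fully reproducible conditions.

## Model

Clean image intensity is a parametric field u(x) = f(x; θ) on Ω = [−1, 1]²
(Gaussian activations, directional waves, step-quantised transitions),
optionally composed with geometric inclusions Ω_incl ⊂ Ω (lesions,
heterogeneous tissue) and, in 3D, an ellipsoidal brain phantom
x²/a² + y²/b² + z²/c² ≤ 1 carrying Gaussian activation blobs
u_B = exp(−α‖x − x₀‖²). Measurements follow ũ(x) = u(x) + η(x) with
η ~ N(0, σ²).

A small encoder–decoder CNN N_θ (7 conv layers, U-Net-style concatenation
skips, ~56k parameters, plain NumPy) maps ũ to a reconstruction and is
trained with the three-term physics-guided loss

    L(θ) = λ_d · mean‖N_θ(ũ) − u‖²        (data fidelity)
         + λ_p · mean‖R(N_θ(ũ))‖²         (physics residual)
         + λ_b · mean‖B(N_θ(ũ)) − g‖²     (boundary constraint)

where R is the discrete 5-point Laplacian on the grid interior (smoothness /
diffusion prior), B restricts to the domain frame ∂Ω and g are the clean
boundary values. Setting λ_p = λ_b = 0 recovers the unconstrained baseline
used for ablation comparisons. Evaluation covers RMSE, PSNR, SSIM and — for
3D volumes — activation-localization error, across six scenario sweeps
(inclusion size, inclusion geometry, field modality, noise level σ ∈
{0.01, 0.05, 0.10}, step surfaces, 3D brain volumes).

## Worked example

Denoise mixed Gaussian/wave/step fields at the moderate noise level
σ = 0.05 (32×32 grid for speed; the benchmark uses 64×64):

```python
import numpy as np
import pgrecon as pg

cfg = pg.ScenarioConfig(n_train=48, n_val=8, n_test=8,
                        grid=pg.GridSpec(32, 32), sigma_sweep=(0.05,))
ds = pg.generate_scenario("noise", cfg, seed=0)

noisy_psnr = np.mean([pg.psnr(ds.noisy[i], ds.clean[i]) for i in ds.test_idx])
print(f"noisy input PSNR : {noisy_psnr:.2f} dB")

model = pg.build_model(seed=0)
tcfg = pg.TrainConfig(max_epochs=120, patience=120, allow_override=True)
result = pg.train(model, ds, pg.LossWeights(), tcfg)
print(f"best val loss    : {result.best_val_total:.5f} (epoch {result.best_epoch})")

preds = pg.predict(model, ds.noisy[ds.test_idx])
psnr = np.mean([pg.psnr(p, ds.clean[i]) for p, i in zip(preds, ds.test_idx)])
ssim = np.mean([pg.ssim(p, ds.clean[i]) for p, i in zip(preds, ds.test_idx)])
print(f"reconstruction   : {psnr:.2f} dB PSNR, SSIM {ssim:.3f}")
```

Output:

```
noisy input PSNR : 25.92 dB
best val loss    : 0.00435 (epoch 119)
reconstruction   : 26.47 dB PSNR, SSIM 0.927
```

The noisy-input PSNR sits at the closed-form calibration value
10·log₁₀(1/σ²) ≈ 26 dB, and reconstruction lifts structural similarity from
0.779 (noisy) to 0.927. At the benchmark's full 64×64 scale the moderate-noise
PSNR reaches the low thirties with gains of 5–7 dB over the input.

A thin CLI mirrors the pipeline stages
(`pgrecon simulate|train|eval|report|repro-suite`), e.g.
`pgrecon simulate --scenario noise --seed 0 --out noise.npz`.

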