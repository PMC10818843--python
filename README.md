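# eit-smdr

Difference imaging for **electrical impedance tomography (EIT)** with
**sensitivity-matrix decomposition regularization (SMDR)** — a
reconstruction pipeline that uses posterior k-means clustering of a
first-pass regularized image to decompose the Jacobian into
cluster-aligned working areas, re-reconstructs differentially to cancel
blurred object boundaries, and removes residual artifacts by a second
clustering pass.

The package is aimed at people prototyping EIT reconstruction
algorithms at desk scale: it ships everything needed to exercise the
method end to end with no external data — a 2D P1 finite-element
forward solver for a circular multi-electrode sensor (gap electrode
model), the adjacent stimulation protocol, a phantom/noise simulator,
the Tikhonov baseline, and CC/RE evaluation metrics.

## The method

Difference EIT linearizes the forward map around a homogeneous
reference σ₀:

    ΔU ≈ S₀ Δσ,      S₀[i, e] = ∂U_i / ∂σ_e |_{σ₀}

and inverts it with Tikhonov regularization

    Δσ̃ = (S₀ᵀ S₀ + λ LᵀL)⁻¹ S₀ᵀ ΔU,   L = I.

SMDR then runs five stages:

1. **Initial image** Δσ̃ by Tikhonov (λ fixed or selected by GCV).
2. **Posterior clustering**: k-means (k = 4) on the pixel values;
   clusters relabelled by descending centre as *Object*,
   *Artifact–Object Mixture*, *Artifact*, *Background*.
3. **Decomposition**: S₀ = S₁ + S₂ + S₃ + S₄, where S_c keeps the
   columns of cluster c (exact column partition).
4. **Differential re-reconstruction**:
   Δσ̃′ = R(λ, S₁+S₂+S₃) ΔU − R(λ, S₃) ΔU — the artifact-only solve
   carries the blurred-boundary response but no object, so the
   difference suppresses the blur.
5. **Post-processing**: keep positive values, normalize to unit
   maximum, re-cluster, zero the Artifact/Background pixels.

Images live on a 64×64 pixel grid masked to the sensor disk;
reconstructions are scored against ground truth by the Pearson
correlation coefficient (CC) and relative image error
RE = ‖Δσ̃ − Δσ‖/‖Δσ‖ after location compensation
l(Δσ̃_i) = (r − d_i)·Δσ̃_i.

## Worked example

```python
import eit_smdr as es

# 1 m disk, 16 electrodes of 5 cm, ~2000 triangles, 64x64 grid;
# precomputes the reference frame and the pixel-basis Jacobian
model = es.build_model(n_elements=2000)

# two-phase phantom: 2 S/m inclusions on a 1 S/m background
phantom = es.make_case(2)
dU, truth = model.simulate(phantom, snr_db=50, seed=5)

tk = es.TikhonovReconstructor(lam="auto").fit(model.sensitivity)
x_tk = tk.transform(dU.values)

sm = es.SMDRReconstructor(lam="auto", random_state=5).fit(model.sensitivity)
x_sm = sm.reconstruct(dU.values).image

from eit_smdr.sweep import score_image
print("TK  : CC=%.3f RE=%.3f" % score_image(x_tk, truth, model, False))
print("SMDR: CC=%.3f RE=%.3f" % score_image(x_sm, truth, model, True))
```

Output:

```
TK  : CC=0.627 RE=0.869
SMDR: CC=0.683 RE=0.704
```

The CC/RE pair scores each location-compensated image against the
rasterized truth; the SMDR image correlates better with the phantom and
has the smaller relative error because the blurred halo and background
speckle of the Tikhonov image are removed.

The same workflow is available from the shell:

```sh
eit-smdr model --elements 2000 --out model.h5
eit-smdr simulate --model model.h5 --case 2 --snr 50 --seed 5 \
    --out frame.h5 --truth-out truth.csv
eit-smdr reconstruct --method smdr --model model.h5 --frame frame.h5 \
    --lambda auto --seed 5 --out img.csv
eit-smdr evaluate --image img.csv --truth truth.csv
```

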