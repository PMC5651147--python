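# cobbnet

Computer-aided Cobb angle measurement for scoliosis assessment from
posteroanterior (PA) spinal radiographs.

The Cobb angle — the angle between the upper endplate of the most tilted
vertebra at the top of a scoliotic curve and the lower endplate of the most
tilted vertebra at the bottom — is the clinical standard for grading curve
severity, and a change of 5° between visits can alter treatment. Manual
measurement varies by up to 5° within and 7° between observers, largely
because humans must judge endplate orientations by eye. `cobbnet` removes
that judgment: the user only clicks the vertebrae of the curve, a deep
regression network predicts each clicked vertebra's slope, and the Cobb
angle follows automatically. The package is aimed at researchers studying
measurement variability in scoliosis imaging and at anyone who needs a
fully synthetic, ground-truthed test bed for vertebral-slope estimators.

## The model

Each clicked vertebra is represented by a 150 × 150-pixel patch from the
height-standardized (1000 px) radiograph, reduced by 3 × 3 block averaging
to 50 × 50 and flattened to a vector *P* ∈ ℝ²⁵⁰⁰ of gray levels in [0, 1].
A four-layer network maps the patch to a slope in degrees:

```
A(P) = b₄ + W₄ tanh(b₃ + W₃ tanh(b₂ + W₂ (W₁ (P − b₁))))
```

* **h1 (linear, frozen):** the rows of W₁ are the first 100 eigenvectors of
  the patch covariance matrix (the PCA basis) and b₁ is the mean patch, so
  the first layer is a low-pass dimensionality reduction.
* **h2, h3 (tanh):** 500 and 50 neurons by default, initialized by
  layer-wise autoencoder pretraining (learning rate 0.1 per layer) and
  fine-tuned by mini-batch gradient-descent backpropagation on the squared
  slope error.
* **output (linear):** a single slope in degrees.

Given predicted slopes s₁ … s_k for the clicked vertebrae, the two
end-vertebrae are those with the maximum absolute slopes tilting in
opposite directions, and the Cobb angle is |s_upper| + |s_lower|.

Because no public radiograph set with per-vertebra slope ground truth
exists, the package ships a phantom generator that emulates radiographs of
a physical spine model: 17 vertebrae (T1–T12, L1–L5) along a smooth
laterally-deviated midline, slopes with maximum magnitude in 5°–50°
(mean |slope| ≈ 15°), and two bright pedicle markers per vertebra whose
connecting segment encodes the true slope — so marker detection, network
training, and reliability studies can all be validated against exact
ground truth. Reliability is quantified the way observer studies do it:
ICC(2,1) (two-way random effects, absolute agreement, single measure) with
a 95% CI, plus the mean absolute difference (MAD) of paired measurements.

## Worked example

```python
import cobbnet as cn

# train a small model on synthetic phantoms
train = cn.generate_dataset(40, seed=42)
patches = cn.sample_training_patches(train, patches_per_vertebra=12, seed=3)
results = cn.SlopeRegression(patches, cn.TrainingConfig(seed=2)).fit()
print(results.summary())

# measure a fresh phantom by "clicking" every vertebra center
spec = cn.generate_spine_spec(seed=301)
rad = cn.render_radiograph(spec, noise_level=5.0, seed=1)
record = cn.measure(rad.image, [v.center for v in spec.vertebrae], results.params)
print(f"predicted Cobb angle: {record.cobb_angle:.1f} deg "
      f"(ground truth {spec.cobb_angle_truth():.1f} deg)")

# simulated intra-observer reliability study (5-px click noise)
rep = cn.reliability_study(cn.generate_dataset(40, seed=7), results.params,
                           sessions=2, click_noise_sd=5.0, seed=11)
print(f"ICC {rep.icc:.3f} (95% CI {rep.ci_low:.3f}-{rep.ci_high:.3f}), "
      f"MAD {rep.mad:.2f} deg")
```

Output:

```
Vertebral Slope Regression Results
==============================================
Architecture:      2500 -> 100 (PCA) -> 500 -> 50 -> 1
Activations:       linear, tanh, tanh, linear
Parameters:        328101
Fine-tune epochs:  50 (lr 0.01, batch 128)
Final train MSE:   0.3311 deg^2
Final train RMSE:  0.575 deg
==============================================
predicted Cobb angle: 37.4 deg (ground truth 37.0 deg)
ICC 0.997 (95% CI 0.995-0.999), MAD 0.99 deg
```

The summary shows the fitted architecture and the training fit; the
measurement line shows that the automatic Cobb angle lands within a
fraction of a degree of the phantom's ground truth; the reliability line
says two simulated sessions that differ only in click placement agree
almost perfectly (ICC near 1) and differ by about a degree on average.

The same pipeline is available from the shell:

```bash
cobbnet generate --n-radiographs 40 --seed 42 --out phantoms/
cobbnet patches  --images phantoms/ --per-vertebra 12 --seed 3 --out train.npz
cobbnet train    --patches train.npz --h2 500 --h3 50 --seed 2 --out model.npz
cobbnet measure  --model model.npz --image phantoms/phantom-0000.png --clicks clicks.csv
cobbnet study    --model model.npz --phantoms phantoms/ --sessions 2 --click-noise 5 --report report.json
```

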