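# honeyspec

Detection of syrup adulteration in honey from hyperspectral transmission
microscopy, as a reusable, fully synthetic-testable pipeline.

Cheap sugar syrups (fructose, glucose, high-maltose) are the common
adulterants of monofloral honeys; at dilutions of 10–40 % by mass the
blend is indistinguishable by eye.  Under a transmission microscope with a
tunable bandpass filter, every sample yields a hypercube — one image per
wavelength over 420–730 nm — and every 4×4 pixel neighborhood yields a
transmittance spectrum

    tau(lambda) = P(lambda) / W(lambda),

sample power over white-reference power.  Each spectrum is compressed to a
24-number fingerprint by a sum-of-sines regression

    tau_hat(lambda) = sum_{n=1}^{8} a_n sin(b_n lambda + c_n),

fitted by nonlinear least squares (deterministic multistart
Levenberg–Marquardt, FFT- and harmonic-based initialization, RMSE < 1 % of
full scale), and the fingerprints feed cross-validated classifiers — LDA,
quadratic-kernel SVM and a 100-unit ReLU network — that assign the honey
mass fraction class (90/80/70/60 %).  Performance is reported per class as
precision, recall, specificity and F1 with macro averages and overall
accuracy.

Raw cubes for this instrument class are not publicly deposited, so the
package ships a first-class synthetic generator: seeded smooth endmember
spectra per material, mass-fraction mixing, a smooth multiplicative
illumination field (the effect of Koehler alignment) and per-band additive
white readout noise.  Every stage is a pure function of configuration and
seed; reruns are byte-identical.

See `docs/methods.md` for the model, its assumptions, and what the
synthetic benchmark does and does not demonstrate about real honey.

## Worked example

Fit one synthetic transmittance curve:

```python
import honeyspec as hs

grid = hs.WavelengthGrid.default()                      # 311 bands, 420-730 nm
lib = hs.generate_endmembers(["Q", "F"], grid, seed=0)  # honey Q, fructose syrup F
tau = hs.mixture_spectrum(lib, "Q", "F", 90.0)          # 90% honey by mass

sample, white = hs.simulate_cube_pair(
    tau, grid, dims=(16, 16), noise=hs.NoiseModel(sigma_read=0.002), seed=1
)
curves = hs.compute_transmittance(
    hs.average_neighborhoods(sample), hs.average_neighborhoods(white)
)
fit = hs.SumOfSinesModel(curves.curves[0], grid).fit()
print(fit.summary())
```

```
Sum-of-sines spectral fit
==========================================================
terms: 8   coefficients: 24   bands: 311
rmse: 0.000568563   converged: True   restarts used: 1
----------------------------------------------------------
term    amplitude  freq (rad/nm)  phase (rad)
   1     0.148239       0.001329     1.014227
   2     0.063592       0.011255    -2.535291
   3     0.081779       0.020291    -0.743047
   4     0.098064       0.029864    -2.762967
   5     0.075701       0.042740    -0.970802
   6     0.044048       0.053118     2.382671
   7     0.025868       0.063290    -0.255911
   8     0.010507       0.069609    -0.826258
==========================================================
```

The 311-sample spectrum is represented by 24 coefficients with a residual
of 0.057 % of full-scale transmittance — far below the 1 % benchmark for
this compression.  The near-DC first term (b₁ ≈ 0.0013 rad/nm) carries the
curve's mean level; the remaining terms encode its shape.

Run a small end-to-end analysis and summarize it:

```python
from honeyspec.pipeline import PipelineConfig, run_pipeline, report_summary

cfg = PipelineConfig(outdir="demo_out", seed=0, cube_rows=32, cube_cols=32,
                     n_per_class=40, k_folds=5, honeys=["Q"], syrups=["F"])
run_pipeline(cfg)
print(report_summary(cfg).to_string(index=False, float_format=lambda v: f"{v:.1f}"))
```

```
combination model  accuracy  macro_f1  macro_precision  macro_recall  macro_specificity
        Q+F   lda     100.0     100.0            100.0         100.0              100.0
        Q+F   svm     100.0     100.0            100.0         100.0              100.0
        Q+F    nn      99.4      99.4             99.4          99.4               99.8
```

Each honey×syrup directory under `demo_out/` holds the labeled curves,
feature matrix, out-of-fold predictions, confusion matrices and metric
tables (CSV + JSON), plus a run log with the resolved configuration and all
derived seeds.

## Command line

The same stages are available as a CLI:

```bash
honeyspec run-all --config config.yaml --seed 0 --outdir out
honeyspec simulate|preprocess|features|classify|evaluate --config config.yaml
honeyspec report --config config.yaml
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.  Any stage
re-run from the persisted artifact of the stage above reproduces its output
byte-for-byte.

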