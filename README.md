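# bsdr — hyperspectral band selection through discrete relaxation

Hyperspectral instruments measure hundreds to thousands of narrow spectral
bands per pixel, but for a given task (crop classification, soil organic
carbon estimation, land-cover mapping) only a handful of bands carry the
signal.  **Band selection** finds that subset while keeping the physical
interpretability of the original channels — unlike band *extraction*, which
forms composite features.

`bsdr` implements a gradient-based selector that treats the discrete subset
search as a continuous optimization problem.  Each of the `t` requested band
indices is a learnable parameter `c_p`, squashed through a sigmoid to a
normalized index `r_p ∈ (0, 1)`.  The denormalization map

    d(q) = ⌊q · (L − 1)⌋ + 1

takes a normalized index back to the 1-based band range, and the reflectance
"at" a fractional position is read off each sample's spectrum by
piecewise-linear interpolation

    B_i(q) = v_i[d(q)] + (v_i[d(q)+1] − v_i[d(q)]) · (q·(L−1) − ⌊q·(L−1)⌋).

Because adjacent hyperspectral bands are highly correlated
(quasi-continuity), these interpolated values are physically meaningful and
the objective

    argmin over θ, (r_1..r_t) of  (1/N) Σ_i loss(y_i, f_θ([B_i(r_1) … B_i(r_t)]))

is smooth in the band indices.  The inference network `f_θ` is deliberately
small — two hidden layers of 128 and 64 Leaky-ReLU units — and is trained
jointly with the band parameters by full-batch Adam (500 epochs, learning
rate 0.001).  After training, each `r_p` is rounded to its nearest integer
band and duplicates are removed, giving `t′ ≤ t` selected bands.  The total
learnable-parameter count is `129·t + 8384 + 65·K` (output width `K`) —
independent of the spectral dimension `L`, which is what makes the method
data-efficient even at thousands of bands.

The package also ships the full evaluation protocol (per-fold 90/10 splits
with an RBF-kernel SVM scoring the held-out half: C = 10⁵ for
classification, C = 100 for regression, γ = 1; overall accuracy and Cohen's
κ, or R² and RMSE), a brute-force subset-search oracle for tiny band
universes, and a synthetic-spectra generator with planted informative bands
for ground-truth validation.

## Worked example

Generate a smooth 2000 × 200 synthetic dataset whose continuous response is
a linear function of the reflectance at bands 55, 110 and 160 (plus noise),
then ask for three bands back:

```python
from bsdr import BSDR, SyntheticSpec, generate, make_split_plan, evaluate_bands_svm

spec = SyntheticSpec(n_samples=2000, n_bands=200, informative_bands=[55, 110, 160],
                     task="regression", smoothness=5, noise_sd=0.05, seed=0)
dataset, truth = generate(spec)

results = BSDR(dataset).fit(target_size=3, epochs=500, seed=0)
print(results.summary())

plan = make_split_plan(dataset.n_samples, fold_id=1, seed=0)
report = evaluate_bands_svm(dataset, results.bands, plan)
print(f"SVM on selected bands: R2 = {report.r2:.3f}, RMSE = {report.rmse:.3f}")
```

This prints:

```
BSDR band selection results
==============================================
Task:                       regression
Samples (N):                2000
Bands (L):                  200
Target size (t):            3
Selected bands (t'=3):      55, 110, 160
Learnable parameters:       8836
Epochs:                     500
Learning rate:              0.001
Final training loss:        0.00263413
Validation R²:              0.9976
Validation RMSE:            0.0531
==============================================
SVM on selected bands: R2 = 0.995, RMSE = 0.071
```

The selector recovers exactly the three planted bands.  The parameter count
is `129·3 + 8384 + 65·1 = 8836` learnable scalars — it would be identical
for a 4200-band spectrum.  The validation R² of 0.998 is the selector's own
monitoring metric; the independent SVM evaluation on the held-out split
confirms the three bands carry essentially all of the signal (R² = 0.995
against a noise floor set by `noise_sd = 0.05`).

Fitted results expose `results.bands` (sorted unique 1-based indices),
`results.trace` (per-epoch band positions, training loss and validation
metrics as a DataFrame), `results.plot_trace()`, and `results.predict()`.

## Command line

```bash
bsdr simulate --n 2000 --bands 200 --planted 55,110,160 --out synth.csv
bsdr select   --data synth.csv --target-col target --task reg --t 3 --seed 0 --out run/
bsdr evaluate --data synth.csv --target-col target --task reg --bands 55,110,160
bsdr benchmark --data synth.csv --target-col target --task reg --sizes 5,10,15,20,25,30
```

Every command writes its fully resolved configuration as JSON next to its
outputs, so runs are reproducible from their artifacts alone.

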