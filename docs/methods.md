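# Methods

## Model

The selector searches for `t` spectral bands out of `L` by relaxing the
integer band indices into continuous variables.  A raw parameter vector
`c = (c_1..c_t)` is mapped through a sigmoid to normalized indices
`r_p = σ(c_p) ∈ (0, 1)`; the denormalization `d(q) = ⌊q(L−1)⌋ + 1` maps the
unit interval bijectively onto the 1-based band range.  Reflectance at a
fractional index is obtained per sample by piecewise-linear interpolation
between the two bracketing bands, which makes the prediction loss smooth and
(almost everywhere) differentiable in the band indices.  The `t`
interpolated values feed a two-hidden-layer perceptron (128 and 64 units,
Leaky ReLU) whose output is a single value (regression, mean-squared-error
loss) or `K` unnormalized class scores (classification, cross-entropy).
Band parameters and network weights are updated jointly, full batch, for a
fixed number of epochs; no early stopping, shuffling, mini-batching or
weight decay.  Finally each `r_p` is rounded to the nearest integer band
(`round(r_p(L−1)) + 1`) and duplicates are removed, so the returned set may
be smaller than `t`.

The key assumption is quasi-continuity: adjacent bands must be strongly
correlated for interpolated mid-band values to be meaningful and for the
relaxed loss surface to be smooth.  Spectra with deleted band blocks violate
this at the seams — two spectrally distant channels become numerically
adjacent — and the selector's accuracy degrades there (this failure mode is
reproduced by `synthetic.missing_band_scenario` and its regression test).
A second consequence of gradient-based search is locality: each index tends
to converge to an optimum near its starting position, so initialization
matters (see below).

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `target_size` (t) | required, `1 ≤ t < L` | number of requested bands |
| `epochs` | 500 | enough for index migration; more mainly overfits the inference network without moving the indices |
| `learning_rate` | 0.001 | the selector is sensitive to this: larger overshoots band positions, smaller fails to migrate within the epoch budget |
| `hidden_sizes` | (128, 64) | deliberately small so performance reflects the chosen bands, not network capacity |
| `negative_slope` | 0.01 | Leaky-ReLU slope, the common default; avoids dead units |
| `optimizer` | `adam` | plain full-batch gradient descent at this learning rate cannot move both modules in 500 epochs; plain SGD remains available via `optimizer="sgd"` |
| `seed` | 0 | seeds the network weight init (uniform fan-in, `U(±1/√fan_in)`); band-parameter init is deterministic |

Band parameters initialize at `r_p = p/(t+1)`, i.e. linearly spaced across
the spectrum, strictly interior (so the inverse sigmoid is finite) and
strictly increasing (so the index vector emulates a set of distinct bands).

SVM evaluation uses an RBF kernel with the published hyperparameters:
`C = 1e5` (classification), `C = 100` (regression), `γ = 1`; all other SVM
settings follow scikit-learn defaults with a one-vs-rest decision function
fixed for multiclass.  These are exposed as module constants, not tuned here.

## Split protocol

Per fold: 10% of the samples are held out and halved into an SVM train and
an SVM test split; the remaining 90% trains the selector, with 10% of that
portion reserved as a validation set for per-epoch monitoring.  Across the
ten folds the held-out 10% splits partition the data (KFold with a seeded
shuffle).  Fold sizes are apportioned by largest remainder so they differ by
at most one sample.  For classification every sub-split is stratified by
class — the protocol leaves this open, but unstratified 5% splits on
imbalanced data risk empty classes in the SVM train half, which would make
the evaluation undefined; `make_split_plan` therefore requires each class to
have at least `2 × n_folds` samples and raises otherwise.

## Numerical choices

- **Boundary at q = 1.**  The interpolation formula indexes `v[d(q)+1]`,
  which is out of range when `d(q) = L`; the fractional multiplier is then
  exactly zero, so the second access is clamped to `v[L]`.  This preserves
  the formula's value everywhere while making evaluation total.  The batched
  implementation equivalently clamps the left bracket to `L−2`; the two
  forms agree identically, which a test asserts.
- **Grid points.**  An exact grid position takes the left segment's value
  (the floor convention); the derivative there uses the right-hand segment's
  slope (left-hand at q = 1), a valid subgradient either way.
- **Extraction rounding** is round-half-up on the continuous position
  `r(L−1)` before the `+1` shift.  The floor rule belongs to interpolation
  bracketing only; rounding only to extraction.  (Rounding the already
  floored integer would make the rounding step vacuous.)
- **Cross-entropy** is computed in log-sum-exp form from unnormalized
  scores; probabilities are never materialized outside the loss.
- **Divergence**: a non-finite training loss raises an error naming the
  epoch rather than continuing silently.
- All training is pure seeded NumPy, so identical inputs give bit-identical
  traces and band sets.

## Synthetic data

The generator emulates the one property the relaxation relies on:
smooth spectra with high adjacent-band correlation.  Spectra are sums of
random-amplitude Gaussian bumps (width = `smoothness` bands, one bump per
`smoothness`-spaced grid center, unit marginal variance) plus a gentle
random linear baseline, min-max rescaled to [0, 1].  At `smoothness = 5`
adjacent-band correlation is ≈ 0.99.  Because bump amplitudes are
independent across centers, bands far (≳ 4 × smoothness) from every planted
band are uninformative about the target, giving tests a ground-truth
"noise-only" region.  The target is a fixed random signed linear combination
(coefficients bounded away from zero) of the reflectance at the planted
bands, standardized to unit variance, plus Gaussian noise of sd `noise_sd`
(default 0.05, i.e. 5% of the signal scale); classification targets are the
rank-quantile binning of that score into `K` balanced classes.

What this does **not** emulate: radiative-transfer structure, wavelength-
dependent sensor noise, spatial correlation between pixels, class-dependent
spectral shapes, or collinearity patterns of real libraries.  Passing the
recovery tests therefore demonstrates that the optimization machinery finds
planted informative bands under the quasi-continuity premise — not that it
will match any particular field benchmark.

## Problem sizes used in validation

Parameter recovery uses N = 2000 samples, L = 200 bands, three planted bands
at 55/110/160 (pairwise ≥ 20 bands apart, offset from the deterministic
initialization previews at ≈ 51/100/150 so the indices must genuinely
migrate), smoothness 5, noise sd 0.05, t = 3, ten seeds.  The
near-optimality check uses a 10-band universe (t = 2, all 45 pairs
enumerated); downstream separation uses N = 2000, K = 3, noise sd 0.02.
These sizes keep each suite run in well under a minute per scenario while
leaving comfortable statistical margins.

## Known limitations

- Sensitivity to initialization: indices converge near their starting
  positions; an informative band far (≫ the spectral correlation length)
  from every initial index may never be reached.  Multiple seeded restarts
  are the practical mitigation (the CLI accepts a seed for scripting them).
- Duplicate convergence: two indices may settle on the same band, returning
  fewer than `t` bands by design.
- Gapped spectra (excluded band blocks) break the adjacency assumption; the
  selector does not currently model the seams.
- The evaluation SVM inherits scikit-learn's SVR epsilon (0.1), so reported
  regression R² depends on the response scale; targets standardized to unit
  variance (as the generator produces) are the intended regime.
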