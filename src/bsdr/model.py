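"""Band Selection through Discrete Relaxation (BSDR).

The selector treats the ``t`` requested band indices as continuous learnable
parameters.  Each raw parameter ``c_p`` is squashed through a sigmoid to a
normalized index ``r_p`` in (0, 1); the reflectance "at" that fractional
index is read off by piecewise-linear interpolation, and the ``t``
interpolated values feed a small two-hidden-layer network (128 and 64 Leaky
ReLU units) that predicts the target.  Both the band parameters and the
network weights are updated jointly by full-batch gradient descent (Adam by
default) for a fixed number of epochs; at the end the normalized indices are
rounded back to integer bands and deduplicated.

Because only the ``t`` selected positions are ever evaluated, the learnable
parameter count is ``129 t + 8384 + 65 K`` — independent of the spectral
dimension ``L`` — which is what makes the method data-efficient on
hyperspectral tables with hundreds or thousands of bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import CLASSIFICATION, REGRESSION, SpectralDataset, SplitPlan, make_split_plan
from .evaluation import cohens_kappa, confusion_from_labels, overall_accuracy, regression_metrics
from .exceptions import (
    ConfigurationError,
    DataValidationError,
    TrainingDivergenceError,
)
from .interpolation import interpolate_batch_with_slopes

HIDDEN_SIZES = (128, 64)


@dataclass
class BSDRConfig:
    """Hyperparameters of a BSDR fit.

    Defaults follow the reference protocol: 500 full-batch epochs at learning
    rate 0.001, hidden layers of 128 and 64 Leaky-ReLU units (negative slope
    0.01), Adam optimization.  ``seed`` controls the inference-network weight
    initialization only — the band parameters start deterministically at
    linearly spaced positions.
    """

    target_size: int
    task: str = REGRESSION
    epochs: int = 500
    learning_rate: float = 1e-3
    hidden_sizes: tuple[int, int] = HIDDEN_SIZES
    negative_slope: float = 0.01
    optimizer: str = "adam"  # or "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_size < 1:
            raise ConfigurationError(f"target_size must be >= 1, got {self.target_size}")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")


@dataclass
class BandSelectionState:
    """The relaxed band indices: raw parameters ``c`` and their sigmoid images."""

    raw_params: np.ndarray  # c, unconstrained reals, shape (t,)

    @property
    def normalized(self) -> np.ndarray:
        """``r = sigmoid(c)``, strictly inside (0, 1)."""
        return expit(self.raw_params)

    @property
    def target_size(self) -> int:
        return self.raw_params.shape[0]


@dataclass
class InferenceParams:
    """Weights and biases of the two-hidden-layer predictor."""

    W1: np.ndarray  # (t, 128)
    b1: np.ndarray  # (128,)
    W2: np.ndarray  # (128, 64)
    b2: np.ndarray  # (64,)
    W3: np.ndarray  # (64, K)
    b3: np.ndarray  # (K,)

    @property
    def n_parameters(self) -> int:
        return sum(a.size for a in (self.W1, self.b1, self.W2, self.b2, self.W3, self.b3))

    def arrays(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]


@dataclass
class SelectedBandSet:
    """Final unique 1-based band indices, sorted ascending; ``t_prime <= t``."""

    bands: np.ndarray

    def __post_init__(self) -> None:
        self.bands = np.unique(np.asarray(self.bands, dtype=np.int64))

    @property
    def t_prime(self) -> int:
        return self.bands.size

    def __iter__(self):
        return iter(self.bands.tolist())

    def __len__(self) -> int:
        return self.t_prime


def count_parameters(t: int, K: int) -> int:
    """Closed-form learnable-parameter count: ``129 t + 8384 + 65 K``.

    That is ``t`` band parameters, a ``t x 128`` layer with biases, a
    ``128 x 64`` layer with biases, and a ``64 x K`` output layer with
    biases.  Must (and does — see the tests) equal the number of learnable
    scalars in an instantiated model.
    """
    if t < 1 or K < 1:
        raise ConfigurationError("t and K must be >= 1")
    h1, h2 = HIDDEN_SIZES
    return t + (t * h1 + h1) + (h1 * h2 + h2) + (h2 * K + K)


def init_band_params(t: int, n_bands: int, seed: int = 0) -> BandSelectionState:
    """Initialize the relaxed indices linearly spaced across the spectrum.

    The normalized indices start at ``r_p = p / (t + 1)`` for ``p = 1..t`` —
    strictly interior (so the inverse sigmoid is finite), evenly spaced, and
    strictly increasing, which keeps the index vector emulating a set of
    distinct bands.  Deterministic regardless of ``seed``; the seed is
    reserved for the inference-network weights.
    """
    if not 1 <= t < n_bands:
        raise ConfigurationError(f"target size must satisfy 1 <= t < L, got t={t}, L={n_bands}")
    r0 = np.arange(1, t + 1, dtype=np.float64) / (t + 1)
    return BandSelectionState(raw_params=logit(r0))


def init_inference_params(t: int, K: int, seed: int, hidden_sizes=HIDDEN_SIZES) -> InferenceParams:
    """Uniform fan-in initialization, ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``."""
    rng = np.random.default_rng(seed)
    h1, h2 = hidden_sizes

    def layer(fan_in, fan_out):
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = rng.uniform(-bound, bound, size=fan_out)
        return W, b

    W1, b1 = layer(t, h1)
    W2, b2 = layer(h1, h2)
    W3, b3 = layer(h2, K)
    return InferenceParams(W1, b1, W2, b2, W3, b3)


def _leaky(a: np.ndarray, slope: float) -> np.ndarray:
    return np.where(a > 0, a, slope * a)


def forward(
    X: np.ndarray,
    state: BandSelectionState,
    params: InferenceParams,
    negative_slope: float = 0.01,
) -> np.ndarray:
    """Full forward pass: sigmoid -> interpolation -> MLP -> N x K scores.

    Classification outputs are unnormalized class scores; probabilities are
    formed only inside the loss (log-sum-exp form).
    """
    out, _ = _forward_cached(X, state.raw_params, params, negative_slope)
    return out


def _forward_cached(X, c, params, slope):
    r = expit(c)
    Z, dZdr = interpolate_batch_with_slopes(X, r)
    A1 = Z @ params.W1 + params.b1
    H1 = _leaky(A1, slope)
    A2 = H1 @ params.W2 + params.b2
    H2 = _leaky(A2, slope)
    out = H2 @ params.W3 + params.b3
    return out, (r, Z, dZdr, A1, H1, A2, H2)


def compute_loss(predictions: np.ndarray, targets: np.ndarray, task: str) -> float:
    """Mean squared error (regression) or mean cross-entropy (classification)."""
    predictions = np.asarray(predictions, dtype=np.float64)
    n = predictions.shape[0]
    if task == REGRESSION:
        y = np.asarray(targets, dtype=np.float64).reshape(n)
        return float(np.mean((y - predictions.reshape(n)) ** 2))
    y = np.asarray(targets)
    K = predictions.shape[1]
    if y.min() < 0 or y.max() >= K:
        raise DataValidationError(f"class labels must lie in 0..{K - 1}")
    shifted = predictions - predictions.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))
    return float(np.mean(log_z - shifted[np.arange(n), y]))


def _loss_and_grad(out, y, task):
    """Loss plus its gradient with respect to the output scores."""
    n = out.shape[0]
    if task == REGRESSION:
        yv = np.asarray(y, dtype=np.float64).reshape(n, 1)
        diff = out - yv
        return float(np.mean(diff**2)), (2.0 / n) * diff
    shifted = out - out.max(axis=1, keepdims=True)
    ez = np.exp(shifted)
    p = ez / ez.sum(axis=1, keepdims=True)
    idx = np.arange(n)
    loss = float(np.mean(np.log(ez.sum(axis=1)) - shifted[idx, y]))
    g = p.copy()
    g[idx, y] -= 1.0
    return loss, g / n


def _backward(X, c, params, slope, cache, dout):
    """Gradients of the loss w.r.t. every learnable array, matching forward."""
    r, Z, dZdr, A1, H1, A2, H2 = cache
    dW3 = H2.T @ dout
    db3 = dout.sum(axis=0)
    dH2 = dout @ params.W3.T
    dA2 = dH2 * np.where(A2 > 0, 1.0, slope)
    dW2 = H1.T @ dA2
    db2 = dA2.sum(axis=0)
    dH1 = dA2 @ params.W2.T
    dA1 = dH1 * np.where(A1 > 0, 1.0, slope)
    dW1 = Z.T @ dA1
    db1 = dA1.sum(axis=0)
    dZ = dA1 @ params.W1.T
    dr = (dZ * dZdr).sum(axis=0)
    dc = dr * r * (1.0 - r)
    return [dc, dW1, db1, dW2, db2, dW3, db3]


def extract_bands(state: BandSelectionState | np.ndarray, n_bands: int) -> SelectedBandSet:
    """Round each normalized index to its nearest integer band and deduplicate.

    ``band_p = round(r_p * (L - 1)) + 1`` (half-up); duplicates — which arise
    when two relaxed indices converge to the same band — are removed, so the
    result may hold fewer than ``t`` bands.
    """
    r = state.normalized if isinstance(state, BandSelectionState) else np.asarray(state, float)
    pos = r * (n_bands - 1)
    bands = np.floor(pos + 0.5).astype(np.int64) + 1
    return SelectedBandSet(bands=bands)


def _adam_update(arrays, grads, mstate, vstate, step, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    bc1 = 1.0 - beta1**step
    bc2 = 1.0 - beta2**step
    for a, g, m, v in zip(arrays, grads, mstate, vstate):
        m *= beta1
        m += (1 - beta1) * g
        v *= beta2
        v += (1 - beta2) * g * g
        a -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


def _validation_metrics(out, y, task):
    if task == REGRESSION:
        r2, rmse = regression_metrics(y, out.reshape(-1))
        return {"val_r2": r2, "val_rmse": rmse}
    pred = out.argmax(axis=1)
    conf = confusion_from_labels(y, pred, out.shape[1])
    return {"val_oa": overall_accuracy(conf), "val_kappa": cohens_kappa(conf)}


def _fit_arrays(X_train, y_train, X_val, y_val, K, config: BSDRConfig):
    """Run the full-batch joint optimization; returns (state, params, trace)."""
    L = X_train.shape[1]
    state = init_band_params(config.target_size, L)
    params = init_inference_params(config.target_size, K, config.seed, config.hidden_sizes)
    c = state.raw_params.astype(np.float64)
    arrays = [c] + params.arrays()
    mstate = [np.zeros_like(a) for a in arrays]
    vstate = [np.zeros_like(a) for a in arrays]
    slope = config.negative_slope
    records = []
    for epoch in range(1, config.epochs + 1):
        out, cache = _forward_cached(X_train, c, params, slope)
        loss, dout = _loss_and_grad(out, y_train, config.task)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(epoch)
        grads = _backward(X_train, c, params, slope, cache, dout)
        if config.optimizer == "adam":
            _adam_update(arrays, grads, mstate, vstate, epoch, config.learning_rate)
        else:
            for a, g in zip(arrays, grads):
                a -= config.learning_rate * g

        r = expit(c)
        assert (r > 0).all() and (r < 1).all()
        rec = {"epoch": epoch, "train_loss": loss}
        preview = extract_bands(r, L)
        pos = np.floor(r * (L - 1) + 0.5).astype(np.int64) + 1  # pre-dedup preview
        for p, band in enumerate(pos, start=1):
            rec[f"band_{p}"] = int(band)
        if X_val is not None and X_val.shape[0] > 0:
            val_out, _ = _forward_cached(X_val, c, params, slope)
            rec.update(_validation_metrics(val_out, y_val, config.task))
        rec["n_unique_bands"] = preview.t_prime
        records.append(rec)
    trace = pd.DataFrame.from_records(records)
    return BandSelectionState(raw_params=c), params, trace


def train(
    dataset: SpectralDataset,
    plan: SplitPlan,
    config: BSDRConfig,
):
    """Train BSDR on a fold's band-selection rows.

    Runs exactly ``config.epochs`` full-batch updates on the plan's
    ``bs_train`` rows, jointly updating the band parameters and the network
    weights; after each epoch the integer-band extraction preview and the
    validation metric on ``bs_validation`` rows are recorded.  No early
    stopping.  Fully reproducible given the config seed.

    Returns
    -------
    (BandSelectionState, InferenceParams, DataFrame)
    """
    if dataset.task != config.task:
        raise ConfigurationError(
            f"dataset task {dataset.task!r} does not match config task {config.task!r}"
        )
    if config.target_size >= dataset.n_bands:
        raise ConfigurationError(
            f"target size {config.target_size} must be < number of bands {dataset.n_bands}"
        )
    X, y = dataset.reflectance, dataset.targets
    tr, va = plan.bs_train_indices, plan.bs_validation_indices
    return _fit_arrays(X[tr], y[tr], X[va], y[va], dataset.output_size, config)


class BSDR:
    """Band-selection model over a single-pixel hyperspectral dataset.

    Parameters
    ----------
    reflectance : ndarray (n_samples, n_bands) or SpectralDataset
    targets : ndarray, optional (required unless a dataset is given)
    task : {"regression", "classification"}

    Examples
    --------
    >>> model = BSDR(X, y, task="regression")
    >>> res = model.fit(target_size=5, seed=0)
    >>> res.bands          # sorted unique 1-based band indices
    >>> print(res.summary())
    """

    def __init__(self, reflectance, targets=None, task: str = REGRESSION):
        if isinstance(reflectance, SpectralDataset):
            self.dataset = reflectance
        else:
            if targets is None:
                raise ConfigurationError("targets are required when passing a raw matrix")
            self.dataset = SpectralDataset(
                reflectance=np.asarray(reflectance, dtype=np.float64),
                targets=targets,
                task=task,
            )

    @classmethod
    def from_dataset(cls, dataset: SpectralDataset) -> "BSDR":
        return cls(dataset)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target_column: str, task: str) -> "BSDR":
        """Build a model from a DataFrame whose non-target columns are bands."""
        band_cols = [col for col in df.columns if col != target_column]
        X = df[band_cols].to_numpy(dtype=np.float64)
        y = df[target_column].to_numpy()
        if task == CLASSIFICATION and y.dtype.kind not in "iu":
            codes, uniques = pd.factorize(df[target_column], sort=True)
            ds = SpectralDataset(X, codes, task, label_names=[str(u) for u in uniques])
            return cls(ds)
        return cls(X, y, task=task)

    @property
    def n_bands(self) -> int:
        return self.dataset.n_bands

    def fit(
        self,
        target_size: int,
        *,
        epochs: int = 500,
        learning_rate: float = 1e-3,
        seed: int = 0,
        plan: SplitPlan | None = None,
        validation_fraction: float = 0.1,
        **config_kwargs,
    ) -> "BSDRResults":
        """Fit the selector and return a results object.

        When no ``plan`` is given, all rows train the model except a
        ``validation_fraction`` subset used only for the per-epoch monitoring
        metric.
        """
        config = BSDRConfig(
            target_size=target_size,
            task=self.dataset.task,
            epochs=epochs,
            learning_rate=learning_rate,
            seed=seed,
            **config_kwargs,
        )
        if config.target_size >= self.n_bands:
            raise ConfigurationError(
                f"target size {target_size} must be < number of bands {self.n_bands}"
            )
        ds = self.dataset
        if plan is not None:
            state, params, trace = train(ds, plan, config)
        else:
            rng = np.random.default_rng(seed)
            n = ds.n_samples
            perm = rng.permutation(n)
            n_val = int(round(validation_fraction * n))
            va, tr = perm[:n_val], perm[n_val:]
            state, params, trace = _fit_arrays(
                ds.reflectance[tr], ds.targets[tr],
                ds.reflectance[va], ds.targets[va],
                ds.output_size, config,
            )
        return BSDRResults(model=self, config=config, band_state=state,
                           inference_params=params, trace=trace)


@dataclass
class BSDRResults:
    """Fit results: selected bands, learned parameters, per-epoch trace."""

    model: BSDR
    config: BSDRConfig
    band_state: BandSelectionState
    inference_params: InferenceParams
    trace: pd.DataFrame

    @property
    def selected_bands(self) -> SelectedBandSet:
        return extract_bands(self.band_state, self.model.n_bands)

    @property
    def bands(self) -> np.ndarray:
        """Sorted unique 1-based selected band indices."""
        return self.selected_bands.bands

    @property
    def normalized_indices(self) -> np.ndarray:
        return self.band_state.normalized

    @property
    def n_parameters(self) -> int:
        """Learnable scalar count of the instantiated model."""
        return self.band_state.raw_params.size + self.inference_params.n_parameters

    @property
    def final_train_loss(self) -> float:
        return float(self.trace["train_loss"].iloc[-1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict with the learned inference network (labels or values)."""
        out = forward(X, self.band_state, self.inference_params, self.config.negative_slope)
        if self.config.task == CLASSIFICATION:
            return out.argmax(axis=1)
        return out.reshape(-1)

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "BSDR band selection results",
            "=" * 46,
            f"{'Task:':<28}{ds.task}",
            f"{'Samples (N):':<28}{ds.n_samples}",
            f"{'Bands (L):':<28}{ds.n_bands}",
            f"{'Target size (t):':<28}{self.config.target_size}",
            "{:<28}".format(f"Selected bands (t'={self.selected_bands.t_prime}):")
            + ", ".join(str(b) for b in self.bands),
            f"{'Learnable parameters:':<28}{self.n_parameters}",
            f"{'Epochs:':<28}{self.config.epochs}",
            f"{'Learning rate:':<28}{self.config.learning_rate}",
            f"{'Final training loss:':<28}{self.final_train_loss:.6g}",
        ]
        last = self.trace.iloc[-1]
        for col in ("val_oa", "val_kappa", "val_r2", "val_rmse"):
            if col in self.trace.columns:
                label = {"val_oa": "Validation OA", "val_kappa": "Validation κ",
                         "val_r2": "Validation R²", "val_rmse": "Validation RMSE"}[col]
                lines.append(f"{label + ':':<28}{last[col]:.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Plot the per-epoch band-index trajectories (one line per index)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        band_cols = [col for col in self.trace.columns if col.startswith("band_")]
        for col in band_cols:
            ax.plot(self.trace["epoch"], self.trace[col], lw=1)
        ax.set_xlabel("epoch")
        ax.set_ylabel("band index (1-based)")
        ax.set_title("Band-index trajectories during training")
        return ax

    def save(self, path) -> None:
        """Checkpoint config, band params, network weights and bands (.npz)."""
        import json

        p = self.inference_params
        np.savez(
            path,
            config=json.dumps({
                "target_size": self.config.target_size, "task": self.config.task,
                "epochs": self.config.epochs, "learning_rate": self.config.learning_rate,
                "hidden_sizes": list(self.config.hidden_sizes),
                "negative_slope": self.config.negative_slope,
                "optimizer": self.config.optimizer, "seed": self.config.seed,
            }),
            raw_params=self.band_state.raw_params,
            W1=p.W1, b1=p.b1, W2=p.W2, b2=p.b2, W3=p.W3, b3=p.b3,
            selected_bands=self.bands,
        )


def bsdr_selector(**fit_kwargs):
    """A selector callable for ``cross_validate``: fits BSDR on each fold.

    Returns a function ``(dataset, plan, target_size, seed) -> SelectedBandSet``.
    """

    def select(dataset: SpectralDataset, plan: SplitPlan, target_size: int,
               seed: int) -> SelectedBandSet:
        config = BSDRConfig(target_size=target_size, task=dataset.task, seed=seed, **fit_kwargs)
        state, _, _ = train(dataset, plan, config)
        return extract_bands(state, dataset.n_bands)

    return select


def all_bands_selector(dataset: SpectralDataset, plan: SplitPlan, target_size: int,
                       seed: int) -> np.ndarray:
    """Trivial selector returning every band (the no-reduction baseline)."""
    return np.arange(1, dataset.n_bands + 1)
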