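"""Synthetic quasi-continuous hyperspectral datasets with planted bands.

Real hyperspectral spectra are smooth: adjacent bands are highly correlated,
which is the property the relaxation exploits.  The generator emulates it by
summing random-amplitude Gaussian bumps (width = ``smoothness`` bands) placed
on a regular grid of centers, plus a gentle smooth baseline, then min-max
rescaling the whole matrix to [0, 1].  The target is a fixed random linear
combination of the reflectance at a small set of planted band indices
(standardized to unit variance) plus Gaussian noise; classification targets
are the quantile-binned version of that score.  Because bump amplitudes are
independent across centers, bands far from every planted band carry no
information about the target — giving tests a ground-truth notion of
"informative" versus "noise-only" spectral regions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import CLASSIFICATION, REGRESSION, SpectralDataset
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Parameters
    ----------
    n_samples, n_bands : int
    informative_bands : list of int
        Planted 1-based band indices the target depends on.
    task : {"regression", "classification"}
    n_classes : int
        Classes for quantile binning (classification only).
    smoothness : float
        Gaussian bump width in band units; controls adjacent-band
        correlation (width 5 gives adjacent correlation around 0.99).
    noise_sd : float
        Std of additive Gaussian noise on the standardized latent score.
    """

    n_samples: int
    n_bands: int
    informative_bands: list[int]
    task: str = REGRESSION
    n_classes: int = 3
    smoothness: float = 5.0
    noise_sd: float = 0.05
    seed: int = 0
    baseline_scale: float = 0.1

    def __post_init__(self) -> None:
        bands = list(self.informative_bands)
        if len(set(bands)) != len(bands):
            raise ConfigurationError("informative bands must be pairwise distinct")
        if any(not 1 <= b <= self.n_bands for b in bands):
            raise ConfigurationError(f"informative bands must lie in 1..{self.n_bands}")
        if self.smoothness < 1:
            raise ConfigurationError("smoothness must be >= 1 band")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.task == CLASSIFICATION and self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        srt = sorted(bands)
        if any(b2 - b1 < self.smoothness for b1, b2 in zip(srt, srt[1:])):
            warnings.warn(
                "planted bands closer together than the smoothness width; "
                "band recovery may be ambiguous",
                stacklevel=2,
            )


@dataclass
class GroundTruth:
    """What the generator planted: band indices, weights, and the clean score."""

    informative_bands: np.ndarray  # 1-based
    weights: np.ndarray
    latent: np.ndarray  # standardized noise-free score
    spec: SyntheticSpec

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative_bands": self.informative_bands.tolist(),
                "weights": self.weights.tolist(),
                "task": self.spec.task,
                "n_samples": self.spec.n_samples,
                "n_bands": self.spec.n_bands,
                "smoothness": self.spec.smoothness,
                "noise_sd": self.spec.noise_sd,
                "seed": self.spec.seed,
            },
            indent=2,
        )


def _smooth_spectra(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Random-amplitude Gaussian bumps on a center grid + smooth baseline."""
    L, sigma = spec.n_bands, spec.smoothness
    spacing = max(1, int(round(sigma)))
    centers = np.arange(0.0, L, spacing)
    j = np.arange(L, dtype=np.float64)
    kernel = np.exp(-((j[None, :] - centers[:, None]) ** 2) / (2.0 * sigma**2))
    amplitudes = rng.standard_normal((spec.n_samples, centers.size))
    X = amplitudes @ kernel
    # normalize so the bump field has unit marginal variance per band
    X /= np.sqrt(np.maximum((kernel**2).sum(axis=0), 1e-12))[None, :]
    a0 = rng.normal(0.0, spec.baseline_scale, size=(spec.n_samples, 1))
    a1 = rng.normal(0.0, spec.baseline_scale, size=(spec.n_samples, 1))
    X += a0 + a1 * (j[None, :] / max(L - 1, 1))
    lo, hi = X.min(), X.max()
    return (X - lo) / (hi - lo)


def generate(spec: SyntheticSpec) -> tuple[SpectralDataset, GroundTruth]:
    """Draw a dataset from the spec; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    X = _smooth_spectra(spec, rng)
    planted = np.asarray(sorted(spec.informative_bands), dtype=np.int64)
    # signed weights bounded away from zero so every planted band matters
    signs = rng.choice([-1.0, 1.0], size=planted.size)
    weights = signs * rng.uniform(0.5, 1.5, size=planted.size)
    raw = X[:, planted - 1] @ weights
    latent = (raw - raw.mean()) / raw.std()
    noisy = latent + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    if spec.task == REGRESSION:
        targets = noisy
    else:
        # rank-based quantile binning keeps class sizes balanced to +-1
        ranks = np.empty(spec.n_samples, dtype=np.int64)
        ranks[np.argsort(noisy, kind="stable")] = np.arange(spec.n_samples)
        targets = (ranks * spec.n_classes) // spec.n_samples
    dataset = SpectralDataset(reflectance=X, targets=targets, task=spec.task)
    truth = GroundTruth(informative_bands=planted, weights=weights, latent=latent, spec=spec)
    return dataset, truth


def missing_band_scenario(
    spec: SyntheticSpec, gap: tuple[int, int]
) -> tuple[SpectralDataset, GroundTruth]:
    """Delete a contiguous 1-based band range ``[gap_start, gap_end]``.

    Emulates datasets whose excluded bands make spectrally distant channels
    appear adjacent — the documented failure mode of index relaxation on
    gapped spectra.  Remaining columns are reindexed contiguously and the
    planted indices in the ground truth are shifted to match.
    """
    gap_start, gap_end = gap
    if gap_start > gap_end:  # empty gap -> identity
        return generate(spec)
    if not (1 <= gap_start <= gap_end <= spec.n_bands):
        raise ConfigurationError(f"gap must lie within 1..{spec.n_bands}")
    for b in spec.informative_bands:
        if gap_start <= b <= gap_end:
            raise ConfigurationError(f"gap {gap} covers planted band {b}")
    dataset, truth = generate(spec)
    keep = np.ones(spec.n_bands, dtype=bool)
    keep[gap_start - 1 : gap_end] = False
    X = dataset.reflectance[:, keep]
    width = gap_end - gap_start + 1
    shifted = np.array(
        [b - width if b > gap_end else b for b in truth.informative_bands], dtype=np.int64
    )
    gapped = SpectralDataset(reflectance=X, targets=dataset.targets, task=spec.task)
    truth_shifted = GroundTruth(
        informative_bands=shifted, weights=truth.weights, latent=truth.latent, spec=spec
    )
    return gapped, truth_shifted


def write_dataset(
    dataset: SpectralDataset, truth: GroundTruth, path: str | Path, target_column: str = "target"
) -> Path:
    """Write the table (CSV/TSV) plus a JSON ground-truth sidecar."""
    path = Path(path)
    dataset.to_csv(path, target_column=target_column)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    sidecar.write_text(truth.to_json())
    return sidecar
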