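"""Single-pixel hyperspectral datasets, file I/O and split bookkeeping.

A dataset is a plain ``N x L`` matrix of per-band reflectance values (one row
per sample, columns ordered by wavelength) plus a target vector — integer
class labels for classification or a continuous response (e.g. soil organic
carbon content) for regression.  Band indices are 1-based everywhere a user
sees them; internal array indexing is 0-based and every boundary crossing
converts explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ConfigurationError, DataValidationError, ParseError, StratificationError

logger = logging.getLogger(__name__)

CLASSIFICATION = "classification"
REGRESSION = "regression"
_TASKS = (CLASSIFICATION, REGRESSION)


@dataclass
class SpectralDataset:
    """A validated single-pixel hyperspectral dataset.

    Parameters
    ----------
    reflectance : ndarray of shape (n_samples, n_bands)
        Per-band reflectance (typically in [0, 1]); columns ordered by
        wavelength.  No missing values.
    targets : ndarray of shape (n_samples,)
        Integer class labels ``0..K-1`` (classification) or a float response
        (regression).
    task : {"classification", "regression"}
    label_names : list of str, optional
        Original class names, index ``k`` naming label ``k``.
    """

    reflectance: np.ndarray
    targets: np.ndarray
    task: str
    label_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        if self.task not in _TASKS:
            raise ConfigurationError(f"task must be one of {_TASKS}, got {self.task!r}")
        if self.reflectance.ndim != 2:
            raise DataValidationError("reflectance must be a 2-D matrix")
        if self.reflectance.shape[1] < 2:
            raise DataValidationError(
                f"need at least 2 bands for interpolation, got {self.reflectance.shape[1]}"
            )
        if not np.isfinite(self.reflectance).all():
            raise DataValidationError("reflectance contains missing or non-finite values")
        if self.task == CLASSIFICATION:
            self.targets = np.asarray(self.targets, dtype=np.int64)
        else:
            self.targets = np.asarray(self.targets, dtype=np.float64)
            if not np.isfinite(self.targets).all():
                raise DataValidationError("regression targets contain non-finite values")
        if self.targets.shape != (self.reflectance.shape[0],):
            raise DataValidationError("targets length must equal the number of samples")
        if self.task == CLASSIFICATION:
            labels = np.unique(self.targets)
            k = labels.size
            if k < 2:
                raise DataValidationError("classification needs at least 2 classes")
            if not np.array_equal(labels, np.arange(k)):
                raise DataValidationError(
                    "classification labels must be the contiguous set 0..K-1; "
                    "use load_spectra_table or encode labels first"
                )

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def n_classes(self) -> int | None:
        if self.task != CLASSIFICATION:
            return None
        return int(self.targets.max()) + 1

    @property
    def output_size(self) -> int:
        """Width of a predictor's output layer: K for classification, 1 for regression."""
        return self.n_classes if self.task == CLASSIFICATION else 1

    def to_dataframe(self, target_column: str = "target") -> pd.DataFrame:
        df = pd.DataFrame(
            self.reflectance,
            columns=[f"band_{j}" for j in range(1, self.n_bands + 1)],
        )
        if self.task == CLASSIFICATION and self.label_names is not None:
            df[target_column] = [self.label_names[k] for k in self.targets]
        else:
            df[target_column] = self.targets
        return df

    def to_csv(self, path: str | Path, target_column: str = "target") -> None:
        """Write the dataset as a delimited table round-trippable by ``load_spectra_table``."""
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        # 17 significant digits round-trip binary64 exactly
        self.to_dataframe(target_column).to_csv(path, sep=sep, index=False, float_format="%.17g")


def absorbance_to_reflectance(a):
    """Convert absorbance to reflectance, ``R = 1 / 10**A`` elementwise.

    Zero absorbance maps to full reflectance (1); the map is strictly
    decreasing.  Accepts scalars or arrays.
    """
    arr = np.asarray(a, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise DataValidationError("absorbance values must be finite")
    out = 10.0 ** (-arr)
    if np.isscalar(a) or arr.ndim == 0:
        return float(out)
    return out


def load_spectra_table(
    path: str | Path,
    target_column: str,
    task: str,
    *,
    absorbance: bool = False,
    drop_missing: bool = True,
) -> SpectralDataset:
    """Load a delimited spectra table (CSV/TSV autodetected by extension).

    All non-target columns are taken as band values ordered as in the file.
    String class labels are re-encoded to ``0..K-1`` in sorted order and the
    mapping is logged.  Rows with missing band cells are dropped (with a
    logged count) when ``drop_missing`` is true, otherwise rejected.

    Parameters
    ----------
    absorbance : bool
        If true, the band columns hold absorbance and are converted to
        reflectance via ``R = 10**(-A)``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if target_column not in df.columns:
        raise ConfigurationError(
            f"target column {target_column!r} not found in {path.name} "
            f"(columns: {list(df.columns)[:8]}...)"
        )
    band_cols = [c for c in df.columns if c != target_column]
    if len(band_cols) < 2:
        raise DataValidationError(f"{path.name}: found {len(band_cols)} band columns, need >= 2")

    bands = df[band_cols].apply(pd.to_numeric, errors="coerce")
    bad = bands.isna()
    if bad.to_numpy().any():
        raw_na = df[band_cols].isna()
        unparseable = bad & ~raw_na
        if unparseable.to_numpy().any():
            r, c = np.argwhere(unparseable.to_numpy())[0]
            raise ParseError(
                f"{path.name}: non-numeric band value at row {int(r)}, column {band_cols[int(c)]!r}"
            )
        if not drop_missing:
            raise DataValidationError(f"{path.name}: missing band values present")
        keep = ~bad.any(axis=1)
        logger.warning("%s: dropped %d row(s) with missing band values", path.name, int((~keep).sum()))
        bands = bands[keep]
        df = df[keep]

    targets = df[target_column]
    label_names = None
    if task == CLASSIFICATION:
        codes, uniques = pd.factorize(targets, sort=True)
        if (codes < 0).any():
            raise DataValidationError(f"{path.name}: missing values in target column")
        label_names = [str(u) for u in uniques]
        logger.info("label mapping: %s", {name: k for k, name in enumerate(label_names)})
        y = codes
    else:
        y = pd.to_numeric(targets, errors="coerce").to_numpy()
        if np.isnan(y).any():
            raise ParseError(f"{path.name}: non-numeric value in target column {target_column!r}")

    X = bands.to_numpy(dtype=np.float64)
    if absorbance:
        X = absorbance_to_reflectance(X)
    return SpectralDataset(reflectance=X, targets=y, task=task, label_names=label_names)


@dataclass
class SplitPlan:
    """Index bookkeeping for one cross-validation fold.

    The evaluation protocol per fold: 90% of the samples train the band
    selector (with a 10% validation subset carved out of that portion), and
    the held-out 10% is halved into an SVM train and an SVM test split.  All
    four lists are pairwise disjoint and together cover the fold's partition
    of ``0..n-1`` (0-based row indices).
    """

    bs_train_indices: np.ndarray
    bs_validation_indices: np.ndarray
    svm_train_indices: np.ndarray
    svm_test_indices: np.ndarray
    fold_id: int
    seed: int
    n: int = field(default=0)

    def __post_init__(self) -> None:
        parts = [
            np.asarray(p, dtype=np.int64)
            for p in (
                self.bs_train_indices,
                self.bs_validation_indices,
                self.svm_train_indices,
                self.svm_test_indices,
            )
        ]
        (
            self.bs_train_indices,
            self.bs_validation_indices,
            self.svm_train_indices,
            self.svm_test_indices,
        ) = parts
        total = sum(p.size for p in parts)
        union = np.concatenate(parts)
        if np.unique(union).size != total:
            raise DataValidationError("split plan index lists are not pairwise disjoint")
        if self.n:
            if union.min() < 0 or union.max() >= self.n:
                raise DataValidationError("split plan indices out of range")

    @property
    def evaluation_indices(self) -> np.ndarray:
        """The fold's held-out 10% (svm_train + svm_test)."""
        return np.sort(np.concatenate([self.svm_train_indices, self.svm_test_indices]))


def _halve_stratified(idx: np.ndarray, labels: np.ndarray | None, rng: np.random.Generator):
    """Split ``idx`` into two near-equal halves, stratified when labels given."""
    idx = np.asarray(idx)
    if labels is None:
        perm = rng.permutation(idx)
        h = perm.size // 2 + (perm.size % 2)
        return np.sort(perm[:h]), np.sort(perm[h:])
    first, second = [], []
    # per-class alternating assignment keeps both halves populated per class
    for cls in np.unique(labels[idx]):
        cls_idx = rng.permutation(idx[labels[idx] == cls])
        h = cls_idx.size // 2 + (cls_idx.size % 2)
        first.append(cls_idx[:h])
        second.append(cls_idx[h:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


def _carve_fraction(idx: np.ndarray, frac: float, labels: np.ndarray | None, rng: np.random.Generator):
    """Remove a ``frac`` subset from ``idx``; returns (rest, subset)."""
    idx = np.asarray(idx)
    if labels is None:
        perm = rng.permutation(idx)
        k = int(round(frac * idx.size))
        return np.sort(perm[k:]), np.sort(perm[:k])
    take, rest = [], []
    sizes = {}
    classes = np.unique(labels[idx])
    # largest-remainder apportionment of the subset size across classes
    quotas = {cls: frac * (labels[idx] == cls).sum() for cls in classes}
    base = {cls: int(np.floor(q)) for cls, q in quotas.items()}
    remainder = int(round(frac * idx.size)) - sum(base.values())
    order = sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True)
    for cls in classes:
        sizes[cls] = base[cls]
    for cls in order[:max(remainder, 0)]:
        sizes[cls] += 1
    for cls in classes:
        cls_idx = rng.permutation(idx[labels[idx] == cls])
        take.append(cls_idx[: sizes[cls]])
        rest.append(cls_idx[sizes[cls]:])
    return np.sort(np.concatenate(rest)), np.sort(np.concatenate(take))


def make_split_plan(
    n: int,
    fold_id: int,
    seed: int,
    labels: np.ndarray | None = None,
    n_folds: int = 10,
) -> SplitPlan:
    """Build the split plan for one fold of the evaluation protocol.

    Deterministic given ``(n, fold_id, seed)``; across ``fold_id`` 1..n_folds
    the held-out evaluation splits partition ``0..n-1``.  When ``labels`` is
    given every sub-split is stratified by class so no class is absent from
    the small SVM splits.

    Parameters
    ----------
    n : int
        Number of samples (must be >= 40 so every sub-split is non-empty).
    fold_id : int
        Fold number, 1-based, in ``1..n_folds``.
    labels : ndarray, optional
        Class labels for stratification (classification tasks only).
    """
    if n < 40:
        raise DataValidationError(f"need n >= 40 for a non-degenerate split plan, got {n}")
    if not 1 <= fold_id <= n_folds:
        raise ConfigurationError(f"fold_id must be in 1..{n_folds}, got {fold_id}")
    if labels is not None:
        labels = np.asarray(labels)
        counts = np.bincount(labels)
        if counts.min() < 2 * n_folds:
            raise StratificationError(
                f"smallest class has {counts.min()} samples; need >= {2 * n_folds} "
                "so each fold's SVM halves contain every class"
            )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))

    for k, (train_idx, eval_idx) in enumerate(split_iter, start=1):
        if k == fold_id:
            break
    rng = np.random.default_rng([seed, fold_id])
    svm_train, svm_test = _halve_stratified(eval_idx, labels, rng)
    bs_train, bs_val = _carve_fraction(train_idx, 0.1, labels, rng)
    return SplitPlan(
        bs_train_indices=bs_train,
        bs_validation_indices=bs_val,
        svm_train_indices=svm_train,
        svm_test_indices=svm_test,
        fold_id=fold_id,
        seed=seed,
        n=n,
    )
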