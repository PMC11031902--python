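"""Labeled binary datasets, label-noise injection and train/test splitting.

Label noise is modelled as uniform flips: a stated fraction of samples is
drawn without replacement and their binary labels are inverted.  The flip
mask and the original labels are kept alongside the data so downstream code
can always tell injected corruption apart from model error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

__all__ = ["Dataset", "NoiseConfig", "flip_labels", "split"]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class Dataset:
    """S samples of (binary feature vector, binary label).

    Attributes
    ----------
    X : (S, N) int array of {0, 1}
    y : (S,) int array of {0, 1}
        Possibly noisy labels — the labels a learner sees.
    y_clean : (S,) int array, optional
        Original labels before noise injection.
    flip_mask : (S,) bool array, optional
        True where the label was flipped; ``y = y_clean XOR flip_mask``.
    """

    X: NDArray[np.int64]
    y: NDArray[np.int64]
    y_clean: NDArray[np.int64] | None = None
    flip_mask: NDArray[np.bool_] | None = None

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=np.int64))
        y = np.asarray(self.y, dtype=np.int64).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if not np.isin(X, (0, 1)).all() or not np.isin(y, (0, 1)).all():
            raise ValueError("X and y must be binary")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if self.flip_mask is not None:
            mask = np.asarray(self.flip_mask, dtype=bool).ravel()
            clean = np.asarray(self.y_clean, dtype=np.int64).ravel()
            if mask.shape != y.shape or clean.shape != y.shape:
                raise ValueError("flip_mask/y_clean must match y in length")
            if not np.array_equal(y, clean ^ mask):
                raise ValueError("y must equal y_clean XOR flip_mask")
            object.__setattr__(self, "flip_mask", mask)
            object.__setattr__(self, "y_clean", clean)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def take(self, idx: NDArray[np.int64]) -> "Dataset":
        """Row subset, carrying noise provenance through."""
        return Dataset(
            self.X[idx],
            self.y[idx],
            None if self.y_clean is None else self.y_clean[idx],
            None if self.flip_mask is None else self.flip_mask[idx],
        )

    def to_frame(self, provenance: bool = False) -> pd.DataFrame:
        cols = {f"x{i + 1}": self.X[:, i] for i in range(self.n_features)}
        cols["y"] = self.y
        if provenance and self.flip_mask is not None:
            cols["y_clean"] = self.y_clean
            cols["flip"] = self.flip_mask.astype(int)
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path, provenance: bool = False) -> None:
        self.to_frame(provenance=provenance).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "y") -> "Dataset":
        feature_cols = [
            c for c in df.columns if c not in (label_col, "y_clean", "flip")
        ]
        y_clean = flip = None
        if "flip" in df.columns and "y_clean" in df.columns:
            y_clean = df["y_clean"].to_numpy()
            flip = df["flip"].to_numpy().astype(bool)
        return cls(df[feature_cols].to_numpy(), df[label_col].to_numpy(), y_clean, flip)

    @classmethod
    def from_csv(cls, path: str | Path, label_col: str = "y") -> "Dataset":
        return cls.from_frame(pd.read_csv(path), label_col=label_col)


@dataclass(frozen=True)
class NoiseConfig:
    """Noise intensity ``q`` (fraction of labels to flip) and RNG seed."""

    q: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("noise intensity q must lie in [0, 1]")


def flip_labels(data: Dataset, cfg: NoiseConfig) -> Dataset:
    """Flip the labels of ``round(q * S)`` uniformly chosen samples.

    Exactly ``floor(q*S + 0.5)`` distinct rows are selected without
    replacement and their labels inverted; features are untouched.  The
    returned dataset records the flip mask against the incoming labels.
    """
    rng = np.random.default_rng(cfg.seed)
    k = _round_half_up(cfg.q * data.n_samples)
    idx = rng.choice(data.n_samples, size=k, replace=False)
    mask = np.zeros(data.n_samples, dtype=bool)
    mask[idx] = True
    return Dataset(data.X, data.y ^ mask, y_clean=data.y, flip_mask=mask)


def split(
    data: Dataset, train_fraction: float, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Uniform random train/test partition.

    ``floor(train_fraction*S + 0.5)`` rows go to the training side; the rest
    to the test side.  Both sides must be non-empty.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = _round_half_up(train_fraction * data.n_samples)
    if n_train == 0 or n_train == data.n_samples:
        raise ValueError("split would leave an empty train or test set")
    perm = np.random.default_rng(seed).permutation(data.n_samples)
    return data.take(np.sort(perm[:n_train])), data.take(np.sort(perm[n_train:]))
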