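"""Tree-structured functional networks over binary inputs.

A functional network (FN) is a two-layer tree of Boolean lookup tables: M
first-layer boxes each read a disjoint, contiguous block of the binary
feature vector and emit one bit; an output box maps the M first-layer bits
to the final binary label.  Box inputs are addressed through a decimal
encoding that maps an n-bit vector to a code in {1..2^n}, with the first
column as the least-significant bit:

    code(b) = 1 + sum_i 2**(i-1) * b_i          (i = 1..n)

All truth tables in this package are indexed by that code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "FNStructure",
    "TruthTable",
    "FunctionalNetwork",
    "decimal_encode",
    "decimal_decode",
    "evaluate_fn",
]


def _as_binary_array(bits: ArrayLike, name: str = "bits") -> NDArray[np.int64]:
    arr = np.asarray(bits)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return arr.astype(np.int64)


def decimal_encode(bits: ArrayLike) -> int:
    """Encode a binary vector as its decimal code in ``{1..2**n}``.

    The first element is the least-significant bit, so ``[0, 1, 0] -> 3``.

    Parameters
    ----------
    bits : array-like of {0, 1}
        Binary vector of length ``n >= 1``.

    Returns
    -------
    int
        ``1 + sum(2**(i-1) * bits[i-1])``; a bijection onto ``{1..2**n}``.
    """
    arr = _as_binary_array(bits)
    if arr.ndim != 1:
        raise ValueError("bits must be one-dimensional")
    weights = 1 << np.arange(arr.size, dtype=np.int64)
    return int(1 + arr @ weights)


def decimal_decode(code: int, n: int) -> NDArray[np.int64]:
    """Invert :func:`decimal_encode`: recover the ``n``-bit vector of ``code``.

    Parameters
    ----------
    code : int
        Code in ``{1..2**n}``.
    n : int
        Number of bits.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= code <= (1 << n):
        raise ValueError(f"code {code} out of range 1..2**{n}")
    return (((code - 1) >> np.arange(n, dtype=np.int64)) & 1).astype(np.int64)


def encode_rows(bits: NDArray[np.int64]) -> NDArray[np.int64]:
    """Vectorised decimal code for each row of a binary matrix."""
    bits = np.atleast_2d(np.asarray(bits, dtype=np.int64))
    weights = 1 << np.arange(bits.shape[1], dtype=np.int64)
    return 1 + bits @ weights


@dataclass(frozen=True)
class FNStructure:
    """The prior knowledge of an FN: how features are grouped into boxes.

    Parameters
    ----------
    n_input_each_box : list of int
        Number of inputs per first-layer box, ``[n_1, ..., n_M]``.  Box 1
        reads the first ``n_1`` feature columns, box 2 the next ``n_2``,
        and so on.
    """

    n_input_each_box: tuple[int, ...]

    def __init__(self, n_input_each_box) -> None:
        sizes = tuple(int(n) for n in n_input_each_box)
        if len(sizes) < 1 or any(n < 1 for n in sizes):
            raise ValueError("n_input_each_box must list positive integers")
        object.__setattr__(self, "n_input_each_box", sizes)

    @property
    def n_boxes(self) -> int:
        """Number of first-layer boxes, M."""
        return len(self.n_input_each_box)

    @property
    def n_features(self) -> int:
        """Total feature width, N = sum of the per-box input counts."""
        return sum(self.n_input_each_box)

    @property
    def box_slices(self) -> tuple[slice, ...]:
        """Contiguous feature-column slice of each box, in order."""
        offsets = np.concatenate(([0], np.cumsum(self.n_input_each_box)))
        return tuple(slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:]))

    def box_codes(self, X: NDArray[np.int64]) -> NDArray[np.int64]:
        """Decimal code of every box's input slice, per row of ``X``.

        Returns an ``(S, M)`` integer array with codes in ``{1..2**n_m}``.
        """
        X = np.atleast_2d(np.asarray(X, dtype=np.int64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got {X.shape[1]}"
            )
        return np.column_stack([encode_rows(X[:, s]) for s in self.box_slices])


@dataclass(frozen=True)
class TruthTable:
    """A Boolean lookup table over ``n_inputs`` bits.

    ``table[k-1]`` is the output for decimal code ``k``; externally codes are
    1-based, storage is a 0-based numpy array of length ``2**n_inputs``.
    """

    n_inputs: int
    table: NDArray[np.int64] = field(compare=False)

    def __init__(self, n_inputs: int, table: ArrayLike) -> None:
        n_inputs = int(n_inputs)
        arr = _as_binary_array(table, "table")
        if arr.ndim != 1 or arr.size != (1 << n_inputs):
            raise ValueError(
                f"table must have 2**{n_inputs} = {1 << n_inputs} entries, "
                f"got {arr.size}"
            )
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "n_inputs", n_inputs)
        object.__setattr__(self, "table", arr)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TruthTable)
            and self.n_inputs == other.n_inputs
            and bool(np.array_equal(self.table, other.table))
        )

    def __getitem__(self, code: int) -> int:
        """Output bit for 1-based decimal ``code``."""
        if not 1 <= code <= self.table.size:
            raise KeyError(f"code {code} out of range 1..{self.table.size}")
        return int(self.table[code - 1])

    def lookup(self, codes: ArrayLike) -> NDArray[np.int64]:
        """Vectorised lookup of 1-based codes."""
        codes = np.asarray(codes, dtype=np.int64)
        if codes.size and (codes.min() < 1 or codes.max() > self.table.size):
            raise KeyError("codes out of range")
        return self.table[codes - 1]


@dataclass(frozen=True)
class FunctionalNetwork:
    """A two-layer tree FN: M first-layer tables plus an output-box table."""

    structure: FNStructure
    first_layer: tuple[TruthTable, ...]
    output_box: TruthTable

    def __init__(self, structure, first_layer, output_box) -> None:
        first_layer = tuple(first_layer)
        if len(first_layer) != structure.n_boxes:
            raise ValueError("one first-layer table per box is required")
        for m, (tt, n_m) in enumerate(zip(first_layer, structure.n_input_each_box)):
            if tt.n_inputs != n_m:
                raise ValueError(
                    f"box {m + 1} table has {tt.n_inputs} inputs, expected {n_m}"
                )
        if output_box.n_inputs != structure.n_boxes:
            raise ValueError("output box must take one input per first-layer box")
        object.__setattr__(self, "structure", structure)
        object.__setattr__(self, "first_layer", first_layer)
        object.__setattr__(self, "output_box", output_box)

    def evaluate(self, X: ArrayLike) -> NDArray[np.int64]:
        """Labels for each row of binary matrix ``X`` (shape ``(S, N)``)."""
        labels, _ = self.evaluate_with_intermediates(X)
        return labels

    def evaluate_with_intermediates(
        self, X: ArrayLike
    ) -> tuple[NDArray[np.int64], NDArray[np.int64]]:
        """Labels and the ``(S, M)`` matrix of first-layer output bits."""
        X = np.atleast_2d(_as_binary_array(X, "X"))
        codes = self.structure.box_codes(X)
        f = np.column_stack(
            [tt.lookup(codes[:, m]) for m, tt in enumerate(self.first_layer)]
        )
        labels = self.output_box.lookup(encode_rows(f))
        return labels, f

    def to_dict(self) -> dict:
        return {
            "n_input_each_box": list(self.structure.n_input_each_box),
            "first_layer": [tt.table.tolist() for tt in self.first_layer],
            "output_box": self.output_box.table.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FunctionalNetwork":
        structure = FNStructure(d["n_input_each_box"])
        first = tuple(
            TruthTable(n, t)
            for n, t in zip(structure.n_input_each_box, d["first_layer"])
        )
        out = TruthTable(structure.n_boxes, d["output_box"])
        return cls(structure, first, out)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FunctionalNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


def evaluate_fn(
    fn: FunctionalNetwork, x: ArrayLike
) -> tuple[int, NDArray[np.int64]]:
    """Evaluate an FN on a single binary input vector.

    Returns the final label and the length-M vector of first-layer outputs.
    """
    labels, f = fn.evaluate_with_intermediates(np.atleast_2d(x))
    return int(labels[0]), f[0]
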