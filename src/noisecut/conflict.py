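"""Conflict graphs: pairwise label disagreements attributed to single boxes.

For each first-layer box m, a conflict graph is built over the box's
2^{n_m} input codes.  Every unordered pair of training samples with
different labels whose inputs agree on all boxes except box m contributes
one unit of weight to the edge between the pair's two codes in box m.
Such a pair proves (in the noise-free case) that the box function must
differ on those two codes; under label noise the accumulated integer
weights measure how much evidence backs each disagreement.

The production builder groups rows by the codes of all *other* boxes (the
pair condition means the two rows share that context) and accumulates an
outer product of per-context label counts, which is equivalent to — and
much faster than — scanning all S-choose-2 pairs.  The naive pair scan is
kept as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

from .data import Dataset
from .fn_core import FNStructure

__all__ = [
    "ConflictGraph",
    "build_weight_matrices",
    "build_weight_matrices_naive",
    "total_conflict_mass",
]


@dataclass(frozen=True)
class ConflictGraph:
    """Symmetric nonnegative integer weight matrix of one box's graph."""

    box_index: int
    n_inputs: int
    W: NDArray[np.int64]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.int64)
        n = 1 << self.n_inputs
        if W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n} for a {self.n_inputs}-input box")
        if (W < 0).any() or not np.array_equal(W, W.T) or np.diag(W).any():
            raise ValueError("W must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "W", W)

    @property
    def n_vertices(self) -> int:
        return 1 << self.n_inputs

    def edge_list(self) -> list[tuple[int, int, int]]:
        """Positive-weight edges as (k, l, weight) with 1-based codes, k < l."""
        iu, jv = np.nonzero(np.triu(self.W, 1))
        return [
            (int(k) + 1, int(l) + 1, int(self.W[k, l])) for k, l in zip(iu, jv)
        ]

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{k}\t{l}\t{w}" for k, l, w in self.edge_list()]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _check(train: Dataset, structure: FNStructure) -> None:
    if train.n_samples == 0:
        raise ValueError("training set is empty")
    if train.n_features != structure.n_features:
        raise ValueError(
            f"feature width {train.n_features} != structure width "
            f"{structure.n_features}"
        )


def build_weight_matrices(
    train: Dataset, structure: FNStructure
) -> list[ConflictGraph]:
    """One conflict graph per box, by context grouping.

    For box m the "context" of a row is the tuple of decimal codes of all
    other boxes.  Rows sharing a context and differing in box m's code are
    exactly the pairs that disagree in box m alone, so within each context
    the label-0 and label-1 code counts contribute an outer product to W.
    Pairs with equal codes in box m (identical features) are excluded by
    zeroing the diagonal contribution.
    """
    _check(train, structure)
    codes = structure.box_codes(train.X)  # (S, M), 1-based
    y = train.y
    graphs = []
    for m, n_m in enumerate(structure.n_input_each_box):
        n = 1 << n_m
        others = [j for j in range(structure.n_boxes) if j != m]
        if others:
            _, ctx = np.unique(codes[:, others], axis=0, return_inverse=True)
        else:
            ctx = np.zeros(train.n_samples, dtype=np.int64)
        n_ctx = int(ctx.max()) + 1
        # per-context histograms of box-m codes, split by label
        c0 = np.zeros((n_ctx, n), dtype=np.int64)
        c1 = np.zeros((n_ctx, n), dtype=np.int64)
        np.add.at(c0, (ctx[y == 0], codes[y == 0, m] - 1), 1)
        np.add.at(c1, (ctx[y == 1], codes[y == 1, m] - 1), 1)
        W = c0.T @ c1
        W = W + W.T
        np.fill_diagonal(W, 0)  # identical-feature pairs carry no edge
        graphs.append(ConflictGraph(m, n_m, W))
    return graphs


def build_weight_matrices_naive(
    train: Dataset, structure: FNStructure
) -> list[ConflictGraph]:
    """Reference builder: explicit scan over all unordered sample pairs."""
    _check(train, structure)
    codes = structure.box_codes(train.X)
    y = train.y
    Ws = [
        np.zeros((1 << n_m, 1 << n_m), dtype=np.int64)
        for n_m in structure.n_input_each_box
    ]
    S = train.n_samples
    for a in range(S):
        for b in range(a + 1, S):
            if y[a] == y[b]:
                continue
            diff = np.nonzero(codes[a] != codes[b])[0]
            if diff.size != 1:
                continue
            m = int(diff[0])
            k, l = codes[a, m] - 1, codes[b, m] - 1
            Ws[m][k, l] += 1
            Ws[m][l, k] += 1
    return [
        ConflictGraph(m, n_m, W)
        for m, (n_m, W) in enumerate(zip(structure.n_input_each_box, Ws))
    ]


def total_conflict_mass(graphs: list[ConflictGraph]) -> int:
    """Number of label-discordant pairs attributed to exactly one box."""
    return int(sum(np.triu(g.W, 1).sum() for g in graphs))
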