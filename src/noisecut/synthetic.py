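"""Synthetic benchmark generator: random tree FNs and their enumerations.

The benchmark consists of random two-layer tree functional networks over
``d`` binary inputs (``d`` = 8..12 by default), each with three first-layer
boxes reading 2-6 inputs apiece.  Every truth-table entry is an independent
fair coin flip, and whole networks are rejected until the class-1 fraction
of the fully enumerated input space falls inside a balance window, so the
suite mixes balanced and imbalanced labelings.  Datasets are the complete
enumeration of {0,1}^d labeled by the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .fn_core import FNStructure, FunctionalNetwork, TruthTable

__all__ = [
    "GeneratorConfig",
    "random_structure",
    "random_network",
    "enumerate_dataset",
    "make_benchmark_suite",
]

#: class-1 fraction window: ratios between 0.1875:0.8125 and 0.8125:0.1875
DEFAULT_BALANCE_WINDOW = (0.1875, 0.8125)

_ENUMERATION_GUARD = 24  # 2**24 rows is the largest enumeration we allow


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for one random network draw."""

    d: int
    n_boxes: int = 3
    min_box_inputs: int = 2
    max_box_inputs: int = 6
    balance_window: tuple[float, float] = DEFAULT_BALANCE_WINDOW
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if not (
            self.n_boxes * self.min_box_inputs
            <= self.d
            <= self.n_boxes * self.max_box_inputs
        ):
            raise ValueError(
                f"d={self.d} admits no composition into {self.n_boxes} parts "
                f"within [{self.min_box_inputs}, {self.max_box_inputs}]"
            )
        lo, hi = self.balance_window
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("balance_window must satisfy 0 < lo <= hi < 1")


def random_structure(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> FNStructure:
    """Draw per-box input counts uniformly over valid compositions.

    Rejection sampling: parts are drawn i.i.d. uniform on the allowed range
    and the draw is kept once they sum to ``d``, which is uniform over the
    compositions of ``d`` into ``n_boxes`` bounded parts.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.min_box_inputs, cfg.max_box_inputs
    while True:
        parts = rng.integers(lo, hi + 1, size=cfg.n_boxes)
        if parts.sum() == cfg.d:
            return FNStructure(parts.tolist())


def _random_tables(
    structure: FNStructure, rng: np.random.Generator
) -> FunctionalNetwork:
    first = tuple(
        TruthTable(n, rng.integers(0, 2, size=1 << n))
        for n in structure.n_input_each_box
    )
    out = TruthTable(structure.n_boxes, rng.integers(0, 2, size=1 << structure.n_boxes))
    return FunctionalNetwork(structure, first, out)


def _enumerate_inputs(n: int) -> np.ndarray:
    """All 2**n binary rows in decimal-code order (row k-1 has code k)."""
    if n > _ENUMERATION_GUARD:
        raise ValueError(
            f"refusing to enumerate 2**{n} rows (guard 2**{_ENUMERATION_GUARD})"
        )
    codes = np.arange(1 << n, dtype=np.int64)
    return ((codes[:, None] >> np.arange(n, dtype=np.int64)) & 1).astype(np.int64)


def random_network(
    structure: FNStructure,
    balance_window: tuple[float, float] = DEFAULT_BALANCE_WINDOW,
    seed: int | np.random.Generator = 0,
    max_retries: int = 1000,
) -> FunctionalNetwork:
    """Fill truth tables with fair coin flips, rejecting unbalanced networks.

    A draw is accepted when the class-1 fraction of the full enumeration of
    the input space lies inside ``balance_window``; otherwise all tables are
    redrawn from the same stream, up to ``max_retries`` times.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    X = _enumerate_inputs(structure.n_features)
    last = None
    for _ in range(max_retries):
        fn = _random_tables(structure, rng)
        last = float(fn.evaluate(X).mean())
        if balance_window[0] <= last <= balance_window[1]:
            return fn
    raise RuntimeError(
        f"no network within balance window {balance_window} after "
        f"{max_retries} draws (last class-1 fraction {last})"
    )


def enumerate_dataset(fn: FunctionalNetwork) -> Dataset:
    """The full labeled enumeration of the network's input space.

    Rows are in decimal-code order, one per code 1..2^N; S = 2^N.
    """
    X = _enumerate_inputs(fn.structure.n_features)
    return Dataset(X, fn.evaluate(X))


def make_benchmark_suite(
    seed: int = 0,
    dims: tuple[int, ...] = (8, 9, 10, 11, 12),
    structures_per_dim: int = 6,
    **cfg_kwargs,
) -> list[tuple[FunctionalNetwork, Dataset]]:
    """The synthetic suite: ``structures_per_dim`` random networks per
    dimension with their enumerated datasets (defaults give 30 pairs).

    Deterministic in ``seed``; each network draws from an independent child
    stream so the suite is stable under reordering.
    """
    root = np.random.SeedSequence(seed)
    suite: list[tuple[FunctionalNetwork, Dataset]] = []
    for d, child in zip(
        np.repeat(dims, structures_per_dim),
        root.spawn(len(dims) * structures_per_dim),
    ):
        cfg = GeneratorConfig(d=int(d), **cfg_kwargs)
        rng = np.random.default_rng(child)
        structure = random_structure(cfg, rng=rng)
        fn = random_network(
            structure, cfg.balance_window, seed=rng, max_retries=cfg.max_retries
        )
        suite.append((fn, enumerate_dataset(fn)))
    return suite
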