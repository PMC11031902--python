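"""The NoiseCut estimator.

NoiseCut classifies binary feature vectors through a two-layer tree
functional network whose structure — how the features are grouped into
first-layer boxes — is supplied as prior knowledge (the sole hyperparameter
``n_input_each_box``).  Fitting decomposes into M independent subproblems
plus an aggregation step:

1. build one conflict graph per first-layer box from the training data;
2. solve an exact max-cut on each graph — the bipartition of the box's
   input codes that explains the largest number of label disagreements is
   the recovered Boolean box function (the cut deliberately leaves the
   lightest, typically noise-induced, disagreements unexplained, which is
   where the noise tolerance comes from);
3. route every training sample through the learned first layer and
   identify the output box by majority voting over the labels that arrive
   at each output-box input code.

The estimator follows the Model/Results convention: ``NoiseCutModel``
holds data and prior knowledge, ``fit()`` returns a ``NoiseCutResults``
with the learned tables, vote counts, predictions and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .conflict import ConflictGraph, build_weight_matrices, total_conflict_mass
from .data import Dataset
from .fn_core import FNStructure, FunctionalNetwork, TruthTable, encode_rows
from .maxcut import MaxCutProblem, MaxCutSolution, solve_maxcut

__all__ = ["NoiseCutModel", "NoiseCutResults", "fit", "predict", "predict_score"]


class NoiseCutModel:
    """Noise-tolerant Boolean classifier over a prior-knowledge tree network.

    Parameters
    ----------
    X : (S, N) array-like of {0, 1}
        Training features.
    y : (S,) array-like of {0, 1}
        Training labels (possibly noisy).
    n_input_each_box : sequence of int
        Inputs per first-layer box; box 1 reads the first columns, etc.
        The sum must equal the feature width.
    solver_time_budget : float, optional
        Seconds granted to each per-box exact max-cut solve.

    Examples
    --------
    >>> model = NoiseCutModel(X, y, n_input_each_box=[3, 2, 2])
    >>> res = model.fit()
    >>> res.predict(X_new)
    """

    def __init__(
        self,
        X: ArrayLike,
        y: ArrayLike,
        n_input_each_box,
        solver_time_budget: float = 120.0,
    ) -> None:
        self.data = Dataset(np.asarray(X), np.asarray(y))
        self.structure = FNStructure(n_input_each_box)
        if self.structure.n_features != self.data.n_features:
            raise ValueError(
                f"n_input_each_box sums to {self.structure.n_features} but X "
                f"has {self.data.n_features} columns"
            )
        self.solver_time_budget = solver_time_budget

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_input_each_box, label_col: str = "y", **kwargs
    ) -> "NoiseCutModel":
        """Build from a dataframe of 0/1 feature columns plus a label column."""
        data = Dataset.from_frame(df, label_col=label_col)
        return cls(data.X, data.y, n_input_each_box, **kwargs)

    @classmethod
    def from_dataset(
        cls, data: Dataset, n_input_each_box, **kwargs
    ) -> "NoiseCutModel":
        return cls(data.X, data.y, n_input_each_box, **kwargs)

    def fit(self) -> "NoiseCutResults":
        """Identify all box functions; returns the fitted results object."""
        graphs = build_weight_matrices(self.data, self.structure)
        first_layer: list[TruthTable] = []
        solutions: list[MaxCutSolution] = []
        for g in graphs:
            try:
                sol = solve_maxcut(
                    MaxCutProblem(g.W), time_budget=self.solver_time_budget
                )
            except Exception as err:
                raise type(err)(
                    f"box {g.box_index + 1}: {err}"
                ) from err
            solutions.append(sol)
            # the side holding code 1 (the all-zero input) is output 0
            first_layer.append(TruthTable(g.n_inputs, sol.assignment))

        y = self.data.y
        n_ones = int(y.sum())
        prior_1 = n_ones / y.size
        default_label = int(n_ones > y.size - n_ones)  # global majority, tie -> 0

        codes = self.structure.box_codes(self.data.X)
        f = np.column_stack(
            [tt.lookup(codes[:, m]) for m, tt in enumerate(first_layer)]
        )
        routed = encode_rows(f)  # output-box input code per training row
        n_cells = 1 << self.structure.n_boxes
        votes = np.zeros((n_cells, 2), dtype=np.int64)
        np.add.at(votes, (routed - 1, y), 1)

        out_table = np.where(
            votes[:, 1] > votes[:, 0],
            1,
            np.where(votes[:, 0] > votes[:, 1], 0, default_label),
        )
        network = FunctionalNetwork(
            self.structure,
            tuple(first_layer),
            TruthTable(self.structure.n_boxes, out_table),
        )
        return NoiseCutResults(
            model=self,
            network=network,
            output_votes=votes,
            default_label=default_label,
            prior_1=prior_1,
            conflict_graphs=graphs,
            maxcut_solutions=tuple(solutions),
        )


@dataclass(frozen=True)
class NoiseCutResults:
    """Fitted NoiseCut model: learned truth tables, votes and diagnostics.

    Attributes
    ----------
    network : FunctionalNetwork
        The learned first-layer tables and majority-vote output table.
    output_votes : (2**M, 2) int array
        Per output-box code: counts of training labels 0 and 1 routed there.
    default_label : int
        Label assigned to unseen or tied output cells (training majority).
    prior_1 : float
        Training prevalence of label 1 (score fallback for unseen cells).
    """

    model: NoiseCutModel | None
    network: FunctionalNetwork
    output_votes: NDArray[np.int64]
    default_label: int
    prior_1: float
    conflict_graphs: tuple[ConflictGraph, ...] | None = None
    maxcut_solutions: tuple[MaxCutSolution, ...] | None = None

    @property
    def structure(self) -> FNStructure:
        return self.network.structure

    def _route(self, X: ArrayLike) -> NDArray[np.int64]:
        X = np.atleast_2d(np.asarray(X, dtype=np.int64))
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X must be binary")
        codes = self.structure.box_codes(X)
        f = np.column_stack(
            [
                tt.lookup(codes[:, m])
                for m, tt in enumerate(self.network.first_layer)
            ]
        )
        return encode_rows(f)

    def predict(self, X: ArrayLike) -> NDArray[np.int64]:
        """Hard labels for each row of ``X``."""
        return self.network.output_box.lookup(self._route(X))

    def predict_score(self, X: ArrayLike) -> NDArray[np.float64]:
        """Vote-fraction scores in [0, 1].

        The score of a sample is the fraction of training votes for label 1
        at its routed output-box cell; cells no training sample reached
        fall back to the training prevalence of label 1.  Thresholding at
        0.5 (ties to the default label) reproduces :meth:`predict`.
        """
        routed = self._route(X) - 1
        totals = self.output_votes.sum(axis=1)[routed]
        ones = self.output_votes[routed, 1]
        with np.errstate(invalid="ignore"):
            score = np.where(totals > 0, ones / np.maximum(totals, 1), self.prior_1)
        return score.astype(np.float64)

    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels-style."""
        s = self.structure
        lines = [
            "NoiseCut fit",
            "=" * 44,
            f"boxes (n_input_each_box):  {list(s.n_input_each_box)}",
            f"features / samples:        {s.n_features} / "
            f"{self.output_votes.sum()}",
            f"training prevalence of 1:  {self.prior_1:.4f}",
            f"default label:             {self.default_label}",
        ]
        if self.conflict_graphs is not None:
            mass = total_conflict_mass(list(self.conflict_graphs))
            lines.append(f"total conflict mass:       {mass}")
        if self.maxcut_solutions is not None:
            for g, sol in zip(self.conflict_graphs, self.maxcut_solutions):
                uncut = int(np.triu(g.W, 1).sum()) - sol.cut_value
                lines.append(
                    f"  box {g.box_index + 1}: {g.n_vertices} vertices, "
                    f"cut {sol.cut_value}, uncut {uncut}"
                )
        lines.append("-" * 44)
        lines.append("output-box votes (code: zeros/ones -> label):")
        table = self.network.output_box.table
        for v in range(self.output_votes.shape[0]):
            n0, n1 = self.output_votes[v]
            lines.append(f"  {v + 1}: {n0}/{n1} -> {table[v]}")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "output_votes": self.output_votes.tolist(),
            "default_label": int(self.default_label),
            "prior_1": float(self.prior_1),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseCutResults":
        return cls(
            model=None,
            network=FunctionalNetwork.from_dict(d["network"]),
            output_votes=np.asarray(d["output_votes"], dtype=np.int64),
            default_label=int(d["default_label"]),
            prior_1=float(d["prior_1"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "NoiseCutResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- thin functional veneer over the Model/Results pair ----------------------


def fit(
    train: Dataset, n_input_each_box, **kwargs
) -> NoiseCutResults:
    """Fit NoiseCut on a dataset; see :class:`NoiseCutModel`."""
    return NoiseCutModel.from_dataset(train, n_input_each_box, **kwargs).fit()


def predict(results: NoiseCutResults, X: ArrayLike) -> NDArray[np.int64]:
    return results.predict(X)


def predict_score(results: NoiseCutResults, X: ArrayLike) -> NDArray[np.float64]:
    return results.predict_score(X)
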