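"""The NoiseCut estimator: fitting, prediction, scores, serialization."""

import numpy as np
import pytest

from noisecut import (
    Dataset,
    FunctionalNetwork,
    NoiseCutModel,
    NoiseCutResults,
    TruthTable,
    enumerate_dataset,
    random_network,
)
from noisecut.fn_core import FNStructure
from noisecut.model import fit as fit_fn


@pytest.fixture(scope="module")
def demo_fit(demo_enumeration):
    return NoiseCutModel(demo_enumeration.X, demo_enumeration.y, [3, 2, 2]).fit()


def test_noise_free_full_coverage_fit_recovers_all_labels(
    demo_enumeration, demo_fit
):
    """With full coverage and clean labels the fit is exact everywhere."""
    assert np.array_equal(demo_fit.predict(demo_enumeration.X), demo_enumeration.y)


def test_worked_example_prediction(demo_fit):
    assert demo_fit.predict([[0, 1, 0, 0, 1, 1, 0]]).tolist() == [0]


def test_exact_recovery_over_random_networks():
    """Noise-free enumerations of random small-box networks are learned
    exactly — behavioural form of the identifiability guarantee."""
    for seed in range(8):
        rng = np.random.default_rng(seed)
        sizes = rng.choice([2, 3, 4], size=3).tolist()
        fn = random_network(FNStructure(sizes), seed=seed)
        data = enumerate_dataset(fn)
        res = fit_fn(data, sizes)
        assert np.array_equal(res.predict(data.X), data.y)


def test_single_sample_degenerate_fit():
    data = Dataset([[1, 0, 1, 1]], [1])
    res = NoiseCutModel(data.X, data.y, [2, 2]).fit()
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, (16, 4))
    assert (res.predict(X) == 1).all()
    assert res.default_label == 1
    assert res.prior_1 == 1.0


def test_width_mismatch_rejected(demo_enumeration):
    with pytest.raises(ValueError):
        NoiseCutModel(demo_enumeration.X, demo_enumeration.y, [3, 3, 2])


def _complement_box(res: NoiseCutResults, m: int) -> NoiseCutResults:
    """Flip box m's table and remap the output-box cells accordingly."""
    first = list(res.network.first_layer)
    first[m] = TruthTable(first[m].n_inputs, 1 - first[m].table)
    n_cells = res.output_votes.shape[0]
    # flipping bit m of the output-box input XORs its (code-1) index with 2^m
    perm = np.arange(n_cells) ^ (1 << m)
    network = FunctionalNetwork(
        res.structure,
        tuple(first),
        TruthTable(res.structure.n_boxes, res.network.output_box.table[perm]),
    )
    return NoiseCutResults(
        model=None,
        network=network,
        output_votes=res.output_votes[perm],
        default_label=res.default_label,
        prior_1=res.prior_1,
    )


def test_orientation_invariance_absorbed_by_output_box(demo_enumeration, demo_fit):
    """Complementing any first-layer table while remapping the output box
    leaves predictions and scores unchanged."""
    X = demo_enumeration.X
    for m in range(3):
        flipped = _complement_box(demo_fit, m)
        assert np.array_equal(flipped.predict(X), demo_fit.predict(X))
        assert np.allclose(flipped.predict_score(X), demo_fit.predict_score(X))


def test_vote_fraction_scores():
    network = FunctionalNetwork(
        FNStructure([1, 1]),
        (TruthTable(1, [0, 1]), TruthTable(1, [0, 1])),
        TruthTable(2, [0, 0, 1, 1]),
    )
    votes = np.array([[0, 7], [5, 5], [0, 0], [2, 8]])
    res = NoiseCutResults(
        model=None, network=network, output_votes=votes,
        default_label=0, prior_1=0.4,
    )
    # routed cells for the four inputs of {0,1}^2 are codes 1..4
    X = [[0, 0], [1, 0], [0, 1], [1, 1]]
    assert res.predict_score(X).tolist() == [1.0, 0.5, 0.4, 0.8]


def test_scores_threshold_to_hard_predictions(demo_enumeration, demo_fit):
    X = demo_enumeration.X
    scores = demo_fit.predict_score(X)
    preds = demo_fit.predict(X)
    expected = np.where(
        scores > 0.5, 1, np.where(scores < 0.5, 0, demo_fit.default_label)
    )
    assert np.array_equal(preds, expected)


def test_fit_deterministic(demo_enumeration):
    a = NoiseCutModel(demo_enumeration.X, demo_enumeration.y, [3, 2, 2]).fit()
    b = NoiseCutModel(demo_enumeration.X, demo_enumeration.y, [3, 2, 2]).fit()
    assert a.to_dict() == b.to_dict()


def test_results_json_round_trip(tmp_path, demo_fit, demo_enumeration):
    path = tmp_path / "model.json"
    demo_fit.save(path)
    loaded = NoiseCutResults.load(path)
    X = demo_enumeration.X
    assert np.array_equal(loaded.predict(X), demo_fit.predict(X))
    assert np.allclose(loaded.predict_score(X), demo_fit.predict_score(X))
    assert loaded.default_label == demo_fit.default_label


def test_from_dataframe_constructor(demo_enumeration):
    df = demo_enumeration.to_frame()
    res = NoiseCutModel.from_dataframe(df, [3, 2, 2]).fit()
    assert np.array_equal(res.predict(demo_enumeration.X), demo_enumeration.y)


def test_summary_mentions_fit_facts(demo_fit):
    text = demo_fit.summary()
    assert "n_input_each_box" in text and "[3, 2, 2]" in text
    assert "cut" in text
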