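"""Conflict-graph construction from label-discordant sample pairs."""

import numpy as np
import pytest

from noisecut import (
    Dataset,
    FNStructure,
    NoiseConfig,
    build_weight_matrices,
    build_weight_matrices_naive,
    flip_labels,
    total_conflict_mass,
)

from conftest import random_dataset


def _graphs_equal(a, b):
    return all(np.array_equal(ga.W, gb.W) for ga, gb in zip(a, b))


def test_single_qualifying_pair_puts_one_edge_in_its_box():
    structure = FNStructure([2, 2])
    # rows agree on box 2, differ in box 1, labels differ
    data = Dataset([[0, 0, 1, 0], [1, 0, 1, 0]], [0, 1])
    g1, g2 = build_weight_matrices(data, structure)
    assert total_conflict_mass([g1, g2]) == 1
    assert g1.W[0, 1] == g1.W[1, 0] == 1  # codes 1 and 2 in box 1
    assert g1.W.sum() == 2
    assert not g2.W.any()


def test_equal_labels_contribute_nothing():
    structure = FNStructure([2, 2])
    data = Dataset([[0, 0, 1, 0], [1, 0, 1, 0]], [1, 1])
    graphs = build_weight_matrices(data, structure)
    assert total_conflict_mass(graphs) == 0


def test_pairs_differing_in_two_boxes_are_ignored():
    structure = FNStructure([2, 2])
    data = Dataset([[0, 0, 0, 0], [1, 0, 1, 0]], [0, 1])
    graphs = build_weight_matrices(data, structure)
    assert total_conflict_mass(graphs) == 0


def test_identical_features_with_discordant_labels_are_ignored():
    structure = FNStructure([2, 2])
    data = Dataset([[1, 0, 1, 0], [1, 0, 1, 0]], [0, 1])
    graphs = build_weight_matrices(data, structure)
    assert total_conflict_mass(graphs) == 0
    assert not any(np.diag(g.W).any() for g in graphs)


def test_demo_enumeration_matches_naive_pair_scan(demo_enumeration):
    """Grouped accumulation equals the brute-force pair scan on the
    noise-free 128-row enumeration."""
    structure = FNStructure([3, 2, 2])
    fast = build_weight_matrices(demo_enumeration, structure)
    slow = build_weight_matrices_naive(demo_enumeration, structure)
    assert _graphs_equal(fast, slow)
    assert total_conflict_mass(fast) == total_conflict_mass(slow)


@pytest.mark.parametrize("seed, n_samples, boxes", [
    (0, 60, (2, 2)),
    (1, 120, (3, 2, 2)),
    (2, 200, (2, 3, 3)),
])
def test_random_datasets_match_naive_pair_scan(seed, n_samples, boxes):
    rng = np.random.default_rng(seed)
    data, structure = random_dataset(rng, n_samples, boxes)
    assert _graphs_equal(
        build_weight_matrices(data, structure),
        build_weight_matrices_naive(data, structure),
    )


def test_noisy_demo_enumeration_matches_naive(demo_enumeration):
    structure = FNStructure([3, 2, 2])
    noisy = flip_labels(demo_enumeration, NoiseConfig(0.1, seed=0))
    assert _graphs_equal(
        build_weight_matrices(noisy, structure),
        build_weight_matrices_naive(noisy, structure),
    )


def test_symmetry_and_zero_diagonal_always_hold():
    for seed in range(5):
        data, structure = random_dataset(
            np.random.default_rng(seed), 150, (3, 2, 2)
        )
        for g in build_weight_matrices(data, structure):
            assert np.array_equal(g.W, g.W.T)
            assert not np.diag(g.W).any()
            assert (g.W >= 0).all()


def test_noise_increases_conflict_mass_on_average(demo_enumeration):
    """Flipping a few labels of a noise-free enumeration adds conflicts."""
    structure = FNStructure([3, 2, 2])
    base = total_conflict_mass(build_weight_matrices(demo_enumeration, structure))
    noisy_masses = [
        total_conflict_mass(
            build_weight_matrices(
                flip_labels(demo_enumeration, NoiseConfig(0.05, seed=s)), structure
            )
        )
        for s in range(10)
    ]
    assert np.mean(noisy_masses) > base


def test_width_mismatch_raises(demo_enumeration):
    with pytest.raises(ValueError):
        build_weight_matrices(demo_enumeration, FNStructure([3, 3, 2]))


def test_edge_list_dump_round_trips(tmp_path, demo_enumeration):
    structure = FNStructure([3, 2, 2])
    g = build_weight_matrices(demo_enumeration, structure)[0]
    path = tmp_path / "g1.tsv"
    g.to_tsv(path)
    lines = [ln.split("\t") for ln in path.read_text().splitlines()]
    assert len(lines) == len(g.edge_list())
    k, l, w = map(int, lines[0])
    assert g.W[k - 1, l - 1] == w
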