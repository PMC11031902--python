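"""Decimal encoding and functional-network evaluation."""

import itertools
import json

import numpy as np
import pytest

from noisecut import (
    FNStructure,
    FunctionalNetwork,
    TruthTable,
    decimal_decode,
    decimal_encode,
    evaluate_fn,
)

from conftest import DEMO_BOXES, DEMO_F1, DEMO_F2, DEMO_F3, DEMO_FO


@pytest.mark.parametrize(
    "bits, code",
    [
        ([0, 0, 0], 1),
        ([0, 1, 0], 3),
        ([1, 1, 1], 8),
        ([1], 2),
        ([0, 0, 0, 1], 9),
    ],
)
def test_decimal_encode_examples(bits, code):
    assert decimal_encode(bits) == code


@pytest.mark.parametrize(
    "code, n, bits",
    [(1, 3, [0, 0, 0]), (8, 3, [1, 1, 1]), (3, 2, [0, 1])],
)
def test_decimal_decode_examples(code, n, bits):
    assert decimal_decode(code, n).tolist() == bits


def test_encoding_bijection_exhaustive():
    """decode(encode(b)) round-trips over every bit vector up to 8 bits."""
    for n in range(1, 9):
        seen = set()
        for bits in itertools.product((0, 1), repeat=n):
            code = decimal_encode(list(bits))
            assert 1 <= code <= 2**n
            assert decimal_decode(code, n).tolist() == list(bits)
            seen.add(code)
        assert len(seen) == 2**n


@pytest.mark.parametrize("bad", [[], [0, 2, 1], [0.5, 0.5]])
def test_encode_rejects_invalid_input(bad):
    with pytest.raises(ValueError):
        decimal_encode(bad)


@pytest.mark.parametrize("code, n", [(0, 3), (9, 3), (-1, 2)])
def test_decode_rejects_out_of_range(code, n):
    with pytest.raises(ValueError):
        decimal_decode(code, n)


def test_structure_slices_partition_columns():
    s = FNStructure([3, 2, 2])
    assert s.n_boxes == 3 and s.n_features == 7
    assert s.box_slices == (slice(0, 3), slice(3, 5), slice(5, 7))


def test_structure_rejects_nonpositive_sizes():
    with pytest.raises(ValueError):
        FNStructure([3, 0, 2])
    with pytest.raises(ValueError):
        FNStructure([])


def test_truth_table_validation():
    with pytest.raises(ValueError):
        TruthTable(2, [0, 1, 1])  # wrong length
    with pytest.raises(ValueError):
        TruthTable(1, [0, 2])  # non-binary


def test_worked_example_intermediates_and_label(demo_network):
    """The worked-example input routes through [1, 1, 1] to label 0."""
    label, intermediates = evaluate_fn(demo_network, [0, 1, 0, 0, 1, 1, 0])
    assert intermediates.tolist() == [1, 1, 1]
    assert label == 0


def test_constant_zero_output_box_always_labels_zero(demo_network):
    fn = FunctionalNetwork(
        demo_network.structure,
        demo_network.first_layer,
        TruthTable(3, [0] * 8),
    )
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, size=(20, 7))
    assert not fn.evaluate(X).any()


def test_evaluate_rejects_wrong_width(demo_network):
    with pytest.raises(ValueError):
        demo_network.evaluate(np.zeros((2, 6), dtype=int))


def _reference_evaluate(x):
    """Independent oracle: direct table lookups with hand-rolled encoding."""
    tables = {0: DEMO_F1, 1: DEMO_F2, 2: DEMO_F3}
    slices = [(0, 3), (3, 5), (5, 7)]
    f = []
    for m, (a, b) in enumerate(slices):
        code = 1 + sum(2**i * x[a + i] for i in range(b - a))
        f.append(tables[m][code - 1])
    out_code = 1 + sum(2**i * f[i] for i in range(3))
    return DEMO_FO[out_code - 1]


def test_full_enumeration_matches_reference_oracle(demo_network, demo_enumeration):
    """All 2^7 labels agree bit-exactly with an independent lookup loop."""
    expected = [
        _reference_evaluate(list(row)) for row in demo_enumeration.X
    ]
    assert demo_enumeration.y.tolist() == expected
    # class-1 fraction of the enumeration, frozen from the oracle
    assert sum(expected) / 128 == pytest.approx(0.625)


def test_network_json_round_trip(tmp_path, demo_network):
    path = tmp_path / "net.json"
    demo_network.save(path)
    loaded = FunctionalNetwork.load(path)
    assert loaded.structure.n_input_each_box == DEMO_BOXES
    assert loaded.first_layer == demo_network.first_layer
    assert loaded.output_box == demo_network.output_box
    # serialized tables are plain 0/1 lists in code order
    raw = json.loads(path.read_text())
    assert raw["first_layer"][0] == list(DEMO_F1)
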