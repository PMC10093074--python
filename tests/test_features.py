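"""Feature fusion, mode ordering, entropy, NB fitness and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from securecnn import (
    DEFAULT_REGISTRY,
    FusedFeatureTable,
    GAConfig,
    build_toy_backbones,
    classify,
    extract_features,
    mode_order,
    nb_fitness,
    registry_fused_width,
    serial_fuse,
    shannon_entropy,
)
from securecnn.errors import ConfigError


# ---------------------------------------------------------------------------
# extraction and fusion
# ---------------------------------------------------------------------------

def test_extract_features_shape_and_determinism(images_labels):
    images, _ = images_labels
    model = build_toy_backbones(seed=0)["inceptionv3"]
    feats = extract_features(model, "avg pool", images[:10])
    assert feats.shape == (10, 32)
    again = extract_features(model, "avg pool", images[:10])
    assert np.array_equal(feats, again)
    # identical images give identical rows
    dup = extract_features(model, "avg pool", [images[0], images[0]])
    assert np.array_equal(dup[0], dup[1])


def test_extract_unknown_layer_lists_available_names(images_labels):
    images, _ = images_labels
    model = build_toy_backbones(seed=0)["googlenet"]
    with pytest.raises(ConfigError, match="global avg pool"):
        extract_features(model, "nope", images[:1])


def test_registry_dimensions_and_fused_width():
    assert DEFAULT_REGISTRY["inceptionv3"] == ("avg pool", 2048)
    assert DEFAULT_REGISTRY["googlenet"][1] == 1000
    assert DEFAULT_REGISTRY["densenet201"][1] == 1000
    assert registry_fused_width() == 4048


def test_serial_fuse_concatenates_rows():
    fused = serial_fuse(np.array([[1.0, 2.0]]), np.array([[3.0]]), np.array([[4.0]]))
    assert fused.features.tolist() == [[1.0, 2.0, 3.0, 4.0]]


def test_serial_fuse_width_is_sum_of_widths():
    rng = np.random.default_rng(0)
    f1, f2, f3 = rng.random((7, 9)), rng.random((7, 5)), rng.random((7, 0))
    assert serial_fuse(f1, f2, f3).n_features == 14
    with pytest.raises(ConfigError):
        serial_fuse(f1, f2[:5], f3)


def test_fused_table_csv_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    table = FusedFeatureTable(rng.random((6, 4)), np.array(["a", "b", "a", "b", "a", "b"]))
    path = tmp_path / "table.csv"
    table.to_csv(path)
    back = FusedFeatureTable.from_csv(path)
    assert np.allclose(back.features, table.features)
    assert list(back.labels) == list(table.labels)


# ---------------------------------------------------------------------------
# mode ordering
# ---------------------------------------------------------------------------

def test_mode_order_ranks_constant_features_by_value():
    table = FusedFeatureTable(
        np.column_stack([np.full(5, 3.0), np.full(5, 5.0)]), np.zeros(5, dtype=int)
    )
    ordered = mode_order(table)
    assert list(ordered.feature_order) == [1, 0]
    assert np.array_equal(ordered.features[:, 0], np.full(5, 5.0))


def test_mode_order_tie_keeps_original_index_order():
    table = FusedFeatureTable(np.ones((4, 3)), np.zeros(4, dtype=int))
    assert list(mode_order(table).feature_order) == [0, 1, 2]


def test_mode_order_matches_brute_force_histogram_oracle():
    """Column {1.0,1.0,2.0} has mode 1.0; {3.0,0.1,0.2} is all singletons
    at 1 decimal, so its mode is the smallest qualifying value 0.1."""
    table = FusedFeatureTable(
        np.column_stack([[1.0, 1.0, 2.0], [3.0, 0.1, 0.2]]), np.zeros(3, dtype=int)
    )
    ordered = mode_order(table, decimals=1)
    assert list(ordered.feature_order) == [0, 1]  # mode 1.0 ranks above 0.1

    def brute_mode(col, decimals):
        from collections import Counter

        rounded = [round(v, decimals) for v in col]
        counts = Counter(rounded)
        top = max(counts.values())
        return min(v for v, c in counts.items() if c == top)

    assert brute_mode([1.0, 1.0, 2.0], 1) == 1.0
    assert brute_mode([3.0, 0.1, 0.2], 1) == 0.1


@settings(derandomize=True, max_examples=30)
@given(seed=st.integers(0, 1000), n=st.integers(1, 8), m=st.integers(1, 10))
def test_mode_order_is_a_bijection(seed, n, m):
    rng = np.random.default_rng(seed)
    table = FusedFeatureTable(rng.normal(size=(m, n)), np.zeros(m, dtype=int))
    ordered = mode_order(table)
    assert sorted(ordered.feature_order) == list(range(n))
    # permuting columns loses no data
    back = ordered.features[:, np.argsort(ordered.feature_order)]
    assert np.array_equal(back, table.features)


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def test_entropy_closed_forms():
    assert shannon_entropy([1.0]) == 0.0
    assert abs(shannon_entropy([0.5, 0.5]) - np.log(2)) < 1e-12
    assert abs(shannon_entropy([0.25] * 4) - np.log(4)) < 1e-12
    for k in (3, 7, 10):
        assert abs(shannon_entropy([1.0 / k] * k) - np.log(k)) < 1e-12


def test_entropy_rejects_invalid_vectors():
    with pytest.raises(ConfigError):
        shannon_entropy([0.5, 0.6])
    with pytest.raises(ConfigError):
        shannon_entropy([-0.1, 1.1])


# ---------------------------------------------------------------------------
# NB fitness
# ---------------------------------------------------------------------------

def _two_class_table(n=60, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 5))
    X[:, 0] += sep * y  # single informative column
    return FusedFeatureTable(X, y)


def test_entropy_gate_zeroes_fitness():
    table = _two_class_table()
    cfg = GAConfig(population=10, elitism=2, entropy_threshold=1e-9)
    mask = np.array([True, True, False, False, False])
    assert nb_fitness(table, mask, cfg) == 0.0


def test_separated_classes_score_high_with_open_gate():
    table = _two_class_table(sep=5.0)
    cfg = GAConfig(population=10, elitism=2, entropy_threshold=np.inf)
    mask = np.array([True, False, False, False, False])
    assert nb_fitness(table, mask, cfg) >= 0.95


def test_shuffled_labels_score_near_chance():
    """With labels shuffled, fitness sits within 0.1 of 1/k over repeats."""
    rng = np.random.default_rng(5)
    accs = []
    for rep in range(20):
        table = _two_class_table(n=120, sep=4.0, seed=rep)
        shuffled = FusedFeatureTable(table.features, rng.permutation(table.labels))
        cfg = GAConfig(population=10, elitism=2, entropy_threshold=np.inf, seed=rep)
        accs.append(nb_fitness(shuffled, np.ones(5, dtype=bool), cfg))
    assert abs(np.mean(accs) - 0.5) < 0.1


def test_fitness_requires_two_classes_and_nonempty_mask():
    table = _two_class_table()
    single = FusedFeatureTable(table.features, np.zeros(len(table.labels), dtype=int))
    cfg = GAConfig(population=10, elitism=2)
    with pytest.raises(ConfigError):
        nb_fitness(single, np.ones(5, dtype=bool), cfg)
    with pytest.raises(ConfigError):
        nb_fitness(table, np.zeros(5, dtype=bool), cfg)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_perfectly_separable_table_classifies_perfectly():
    table = _two_class_table(n=80, sep=10.0)
    for name in ("gnb", "ld"):
        metrics = classify(table, [0], classifier_name=name)
        assert metrics["accuracy"] == 1.0
        assert metrics["f1"] == 1.0


def test_metrics_invariant_to_row_shuffling_before_split():
    table = _two_class_table(n=80, sep=2.0, seed=3)
    perm = np.random.default_rng(0).permutation(table.n_samples)
    shuffled = FusedFeatureTable(table.features[perm], table.labels[perm])
    m1 = classify(table, [0, 1, 2], seed=42)
    m2 = classify(shuffled, [0, 1, 2], seed=42)
    assert m1["accuracy"] == pytest.approx(m2["accuracy"])


def test_pure_noise_feature_scores_near_chance():
    rng = np.random.default_rng(0)
    accs = []
    for rep in range(10):
        X = rng.normal(size=(200, 1))
        y = np.repeat([0, 1], 100)
        accs.append(classify(FusedFeatureTable(X, y), [0], seed=rep)["accuracy"])
    assert abs(np.mean(accs) - 0.5) < 0.12


def test_unknown_classifier_lists_builtins():
    table = _two_class_table()
    with pytest.raises(ConfigError, match="gnb"):
        classify(table, [0], classifier_name="svm9000")
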