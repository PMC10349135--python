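"""Entropy scoring, maximum-entropy thresholding, and relevance maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epunet.interpret import (
    DegenerateMapError,
    RSSVector,
    compute_prm,
    entropic_threshold,
    explain,
    global_chart,
    select_informative,
    shannon_entropy,
)
from epunet.model import build_epu


def _brute_force_entropy(m, bins):
    """Explicit histogram + loop oracle."""
    m = np.asarray(m, dtype=float).ravel()
    lo, hi = m.min(), m.max()
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    h = 0.0
    for i in range(bins):
        if i < bins - 1:
            c = np.sum((m >= edges[i]) & (m < edges[i + 1]))
        else:
            c = np.sum((m >= edges[i]) & (m <= edges[i + 1]))
        p = c / m.size
        if p > 0:
            h -= p * np.log2(p)
    return h


class TestShannonEntropy:
    def test_constant_map_is_zero_bits(self):
        assert shannon_entropy(np.full((8, 8), 2.3)) == 0.0

    def test_two_level_map_is_one_bit(self):
        m = np.zeros((4, 4))
        m[:2] = 1.0
        assert shannon_entropy(m, bins=2) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            m = rng.normal(size=(12, 12))
            assert shannon_entropy(m, 64) == pytest.approx(
                _brute_force_entropy(m, 64), abs=1e-10
            )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 128))
    def test_entropy_bounded_by_log2_bins(self, seed, bins):
        m = np.random.default_rng(seed).uniform(size=(10, 10))
        h = shannon_entropy(m, bins)
        assert 0.0 <= h <= np.log2(bins) + 1e-12


class TestEntropicThreshold:
    def test_matches_exhaustive_oracle_on_random_maps(self):
        from tests_oracles import kapur_attains_oracle_max

        local_rng = np.random.default_rng(77)
        for _ in range(100):
            m = local_rng.integers(0, 256, size=(16, 16)).astype(float)
            # the returned level must be a global maximizer of the
            # exhaustively evaluated psi profile (exact ties allow several)
            assert kapur_attains_oracle_max(entropic_threshold(m), m)

    def test_bimodal_threshold_between_modes(self, rng):
        m = np.concatenate([rng.normal(0.2, 0.02, 500), rng.normal(0.8, 0.02, 500)])
        t = entropic_threshold(np.abs(m).reshape(40, 25))
        assert 0.2 < t < 0.8  # strictly between the two modes

    def test_affine_equivariant_mask(self, rng):
        m = rng.uniform(0, 1, size=(16, 16))
        t = entropic_threshold(m)
        c, d = 3.5, 2.0
        t2 = entropic_threshold(c * m + d)
        assert np.array_equal(m >= t, (c * m + d) >= t2)

    def test_constant_map_degenerate(self):
        with pytest.raises(DegenerateMapError):
            entropic_threshold(np.ones((8, 8)))


class TestSelection:
    def _maps_with_entropy_order(self):
        """Four 8x8 maps whose entropies order as (low, high, mid, mid-high)."""
        rng = np.random.default_rng(0)
        m1 = np.zeros((8, 8))                      # 0 bits
        m2 = rng.uniform(0, 1, (8, 8))             # ~max bits
        m3 = np.where(np.arange(64).reshape(8, 8) % 2, 1.0, 0.0)  # 1 bit
        m4 = (np.arange(64).reshape(8, 8) % 4) / 3.0              # 2 bits
        return np.stack([m1, m2, m3, m4])

    def test_top_half_selected_by_entropy_rank(self):
        selected, s = select_informative(self._maps_with_entropy_order())
        assert list(selected) == [1, 3]

    def test_aggregate_is_mean_of_selected(self):
        maps = self._maps_with_entropy_order()
        _, s = select_informative(maps)
        assert np.allclose(s, (maps[1] + maps[3]) / 2)

    def test_discarded_map_never_influences_aggregate(self):
        maps = self._maps_with_entropy_order()
        _, s1 = select_informative(maps)
        maps2 = maps.copy()
        maps2[0] += 0.25 * np.eye(8)[0]  # perturb, keeping it lowest-entropy
        _, s2 = select_informative(maps2)
        assert np.array_equal(s1, s2)

    def test_ties_break_stably_by_index(self):
        maps = np.tile(np.linspace(0, 1, 64).reshape(8, 8), (5, 1, 1))
        selected, s = select_informative(maps)
        assert list(selected) == [0, 1, 2]  # ceil(5/2) lowest indices
        assert np.allclose(s, maps[0])

    def test_keeps_ceil_half_for_odd_n(self, rng):
        maps = rng.uniform(size=(7, 6, 6))
        selected, _ = select_informative(maps)
        assert len(selected) == 4

    def test_hand_computed_mean_of_selected_toy_maps(self):
        # three 4x4 maps: constant (0 bits), 2-level (1 bit), 4-level
        # (2 bits); ceil(3/2) = 2 kept -> the aggregate is (m1 + m2) / 2
        m0 = np.zeros((4, 4))
        m1 = np.where(np.arange(16).reshape(4, 4) % 2, 1.0, 0.0)
        m2 = (np.arange(16, dtype=float).reshape(4, 4) % 4) / 3.0
        selected, s = select_informative(np.stack([m0, m1, m2]))
        assert list(selected) == [1, 2]
        assert np.allclose(s, (m1 + m2) / 2)


class TestComputePrm:
    def test_prm_shape_threshold_and_determinism(self, tiny_model, tiny_stacks):
        prm1 = compute_prm(tiny_model, tiny_stacks[0], subnet_index=2)
        prm2 = compute_prm(tiny_model, tiny_stacks[0], subnet_index=2)
        assert prm1.map.shape == tiny_stacks[0].shape[1:]
        assert prm1.mask.dtype == bool
        assert prm1.map.tobytes() == prm2.map.tobytes()
        assert prm1.source_layer == 5

    def test_threshold_refinement_idempotent(self, rng):
        # zeroing sub-threshold values and re-applying the same threshold
        # changes nothing: the mask is a fixed point
        s = rng.uniform(0.1, 1.0, size=(8, 8))
        t = entropic_threshold(s)
        refined = np.where(s >= t, s, 0.0)
        assert np.array_equal(refined >= t, s >= t)
        assert np.array_equal(np.where(refined >= t, refined, 0.0), refined)

    def test_invalid_indices_rejected(self, tiny_model, tiny_stacks):
        with pytest.raises(ValueError):
            compute_prm(tiny_model, tiny_stacks[0], subnet_index=9)
        with pytest.raises(ValueError):
            compute_prm(tiny_model, tiny_stacks[0], subnet_index=0, layer=99)


class TestExplain:
    def test_output_cardinality_and_consistency(self, tiny_model, tiny_stacks):
        res = explain(tiny_model, tiny_stacks[0])
        assert len(res.prms) == tiny_model.n
        assert res.rss.values.shape == (tiny_model.n,)
        p, _ = tiny_model.forward(tiny_stacks[0][None])
        assert res.prediction == p[0]  # bit-exact, same computation path

    def test_untrained_model_warns(self, tiny_stacks):
        fresh = build_epu("base_i", input_size=(16, 16), seed=0)
        with pytest.warns(UserWarning, match="untrained"):
            explain(fresh, tiny_stacks[0], with_prms=False)


class _StubModel:
    """Duck-typed model returning a fixed RSS table (for chart arithmetic)."""

    def __init__(self, rss):
        self._rss = np.asarray(rss, dtype=np.float64)
        self.pfm_names = tuple(f"pfm{i}" for i in range(self._rss.shape[1]))
        self.link = "sigmoid"

    def forward(self, stacks, train=False):
        return np.full(len(self._rss), 0.5), self._rss


class TestGlobalChart:
    def test_hand_computed_means_and_stds(self):
        rss = [[0.2, -0.4], [0.6, 0.0], [-0.1, 0.5]]
        labels = [0, 0, 1]
        chart = global_chart(_StubModel(rss), np.zeros((3, 2, 8, 8)), labels)
        assert chart.per_class_mean[0] == pytest.approx([0.4, -0.2])
        assert chart.per_class_std[0] == pytest.approx([0.2, 0.2])
        assert chart.per_class_mean[1] == pytest.approx([-0.1, 0.5])
        assert chart.per_class_std[1] == pytest.approx([0.0, 0.0])
        assert chart.n_per_class == {0: 2, 1: 1}

    def test_singleton_classes(self, tiny_model, tiny_stacks, tiny_dataset):
        idx = [0, len(tiny_dataset) - 1]  # one per class
        chart = global_chart(tiny_model, tiny_stacks[idx], tiny_dataset.labels[idx])
        _, rss = tiny_model.forward(tiny_stacks[idx])
        assert np.allclose(chart.per_class_mean[0], rss[0])
        assert np.allclose(chart.per_class_std[0], 0.0)

    def test_invariant_under_duplication(self, tiny_model, tiny_stacks, tiny_dataset):
        x, y = tiny_stacks[:4], tiny_dataset.labels[:4]
        c1 = global_chart(tiny_model, x, y)
        c2 = global_chart(tiny_model, np.concatenate([x, x]), np.concatenate([y, y]))
        for cls in c1.per_class_mean:
            assert np.allclose(c1.per_class_mean[cls], c2.per_class_mean[cls])
            assert np.allclose(c1.per_class_std[cls], c2.per_class_std[cls])


def test_rss_vector_validates_range():
    with pytest.raises(ValueError):
        RSSVector(values=[1.5, 0.0], pfm_names=("a", "b"), predicted_class=1)
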