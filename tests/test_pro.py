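"""Multi-scale convolutional head: oracles, pooling and motif invariance."""

import numpy as np
import pytest

from codonmoe import ProHeadConfig
from codonmoe.errors import ContractError, SequenceLengthError
from codonmoe.pro import (FeatureMap, conv_branch, init_pro_head,
                          max_over_time, motif_invariance_check, pro_predict)


def _conv_oracle(H, k, filters, biases):
    """Quadruple-loop sliding-window convolution with ReLU."""
    L, D = H.shape
    c_out = filters.shape[-1]
    out = np.zeros((L - k + 1, c_out))
    for i in range(L - k + 1):
        for f in range(c_out):
            acc = biases[f]
            for a in range(k):
                for b in range(D):
                    acc += H[i + a, b] * filters[a, b, f]
            out[i, f] = max(acc, 0.0)
    return out


class TestConvBranch:
    def test_all_ones_response(self):
        H = np.ones((5, 2))
        fm = conv_branch(H, 3, np.ones((3, 2, 1)), np.zeros(1))
        assert fm.values.shape == (3, 1) and np.allclose(fm.values, 6.0)

    def test_relu_clamps_negative_response(self):
        H = np.ones((5, 2))
        fm = conv_branch(H, 3, -np.ones((3, 2, 1)), np.zeros(1))
        assert np.allclose(fm.values, 0.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            H = rng.standard_normal((8, 3))
            filters = rng.standard_normal((4, 3, 2))
            biases = rng.standard_normal(2)
            fm = conv_branch(H, 4, filters, biases)
            assert np.allclose(fm.values, _conv_oracle(H, 4, filters, biases), atol=1e-6)

    def test_entries_nonnegative(self, rng):
        fm = conv_branch(rng.standard_normal((10, 4)), 3,
                         rng.standard_normal((3, 4, 5)), rng.standard_normal(5))
        assert np.all(fm.values >= 0.0)

    def test_short_input_raises(self, rng):
        with pytest.raises(SequenceLengthError, match="3"):
            conv_branch(rng.standard_normal((2, 4)), 3,
                        rng.standard_normal((3, 4, 1)), np.zeros(1))


class TestMaxOverTime:
    def test_single_channel(self):
        fm = FeatureMap(np.array([[0.0], [2.0], [1.0]]), 1)
        assert max_over_time(fm) == np.array([2.0])

    def test_permutation_invariant(self, rng):
        vals = np.abs(rng.standard_normal((10, 4)))
        perm = np.random.default_rng(1).permutation(10)
        assert np.array_equal(max_over_time(FeatureMap(vals, 3)),
                              max_over_time(FeatureMap(vals[perm], 3)))

    def test_matches_columnwise_loop(self, rng):
        vals = np.abs(rng.standard_normal((10, 4)))
        oracle = [max(vals[i, j] for i in range(10)) for j in range(4)]
        assert np.allclose(max_over_time(FeatureMap(vals, 3)), oracle)

    def test_empty_map_rejected(self):
        with pytest.raises(ContractError):
            max_over_time(FeatureMap(np.zeros((0, 4)), 3))


class TestProPredict:
    def test_zero_final_weights_return_bias(self, rng):
        cfg = ProHeadConfig(D=4, kernel_sizes=(2, 3), c_out=3)
        p = init_pro_head(cfg, rng)
        p["final_w"] = np.zeros_like(p["final_w"])
        p["final_b"] = np.array([1.25])
        assert pro_predict(rng.standard_normal((8, 4)), cfg, p) == 1.25

    def test_default_concat_dimension_is_300(self):
        assert ProHeadConfig(D=16).concat_dim == 300

    def test_matches_composed_oracles(self, rng):
        cfg = ProHeadConfig(D=8)
        p = init_pro_head(cfg, rng)
        H = rng.standard_normal((30, 8))
        pooled = []
        for k in cfg.kernel_sizes:
            fm = _conv_oracle(H, k, p[f"conv_W{k}"], p[f"conv_b{k}"])
            pooled.append(fm.max(axis=0))
        oracle = float(np.concatenate(pooled) @ p["final_w"] + p["final_b"][0])
        assert pro_predict(H, cfg, p) == pytest.approx(oracle, abs=1e-6)

    def test_final_weight_scaling_is_linear(self, rng):
        cfg = ProHeadConfig(D=4, kernel_sizes=(3,), c_out=5)
        p = init_pro_head(cfg, rng)
        H = rng.standard_normal((12, 4))
        bias = p["final_b"][0]
        y1 = pro_predict(H, cfg, p)
        p2 = dict(p, final_w=3.0 * p["final_w"])
        assert pro_predict(H, cfg, p2) - bias == pytest.approx(3.0 * (y1 - bias), rel=1e-9)


class TestMotifInvariance:
    @pytest.fixture
    def dominant_setup(self, rng):
        # Nonnegative filters, zero background, and a motif of identical
        # positive rows: for every kernel size the per-channel maximum is the
        # full-overlap response, attained at any placement (edges included).
        cfg = ProHeadConfig(D=3, kernel_sizes=(3, 4, 5), c_out=4, dropout_p=0.0)
        p = init_pro_head(cfg, rng)
        for k in cfg.kernel_sizes:
            p[f"conv_W{k}"] = np.abs(p[f"conv_W{k}"])
            p[f"conv_b{k}"] = np.zeros_like(p[f"conv_b{k}"])
        motif = np.tile(np.abs(rng.standard_normal(3)) + 0.5, (5, 1))
        background = np.zeros(3)
        return cfg, p, motif, background

    def test_invariant_across_placements(self, dominant_setup):
        cfg, p, motif, bg = dominant_setup
        assert motif_invariance_check(cfg, p, motif, bg, [0, 5, 12], L=20)

    def test_two_copies_equal_one(self, dominant_setup, rng):
        cfg, p, motif, bg = dominant_setup
        H1 = np.tile(bg, (20, 1))
        H1[3:8] = motif
        H2 = H1.copy()
        H2[12:17] = motif
        assert pro_predict(H1, cfg, p) == pytest.approx(pro_predict(H2, cfg, p), abs=1e-9)

    def test_dominant_background_also_invariant(self, rng):
        # background response strictly above the motif's: the pooled max is
        # the background response for every placement.
        cfg = ProHeadConfig(D=2, kernel_sizes=(3,), c_out=2, dropout_p=0.0)
        p = init_pro_head(cfg, rng)
        p["conv_W3"] = np.abs(p["conv_W3"])
        p["conv_b3"] = np.zeros(2)
        background = np.full(2, 5.0)
        motif = np.full((3, 2), 0.1)
        bg_resp = conv_branch(np.tile(background, (3, 1)), 3, p["conv_W3"], p["conv_b3"]).values[0]
        motif_resp = conv_branch(motif, 3, p["conv_W3"], p["conv_b3"]).values[0]
        assert np.all(bg_resp > motif_resp)
        assert motif_invariance_check(cfg, p, motif, background, [4, 9, 15], L=22)
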