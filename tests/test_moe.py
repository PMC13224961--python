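"""Mixture-of-codon-experts layer: oracle equivalence and invariants.

Oracles here are deliberately naive — explicit Python loops over codons,
experts and hidden units — and never call the library's vectorized paths.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codonmoe import MoEConfig, group_codons
from codonmoe.moe import (EnrichedRepresentation, base_head, enrich,
                          expert_forward, gate, init_base_head,
                          init_moe_params, moe_mix)
from codonmoe.errors import ContractError


def _gelu_scalar(x: float) -> float:
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + math.tanh(c * (x + 0.044715 * x**3)))


def _gate_oracle(c, W, b):
    scores = [sum(c[i] * W[i, k] for i in range(len(c))) + b[k] for k in range(W.shape[1])]
    exps = [math.exp(s - max(scores)) for s in scores]
    return np.array([e / sum(exps) for e in exps])


def _expert_oracle(c, k, params):
    W1, b1 = params["W1"][k], params["b1"][k]
    W2, b2 = params["W2"][k], params["b2"][k]
    hidden = [_gelu_scalar(sum(c[i] * W1[i, h] for i in range(len(c))) + b1[h])
              for h in range(W1.shape[1])]
    return np.array([sum(hidden[h] * W2[h, j] for h in range(len(hidden))) + b2[j]
                     for j in range(W2.shape[1])])


@pytest.fixture
def cfg_params(rng):
    cfg = MoEConfig(D=2, K=3, expert_hidden=4)
    return cfg, init_moe_params(cfg, rng)


class TestGate:
    def test_zero_params_give_uniform_weights(self):
        c = np.arange(6.0)
        g = gate(c, np.zeros((6, 4)), np.zeros(4))
        assert np.allclose(g, 0.25)

    def test_single_expert_gets_weight_one(self, rng):
        g = gate(rng.standard_normal(6), rng.standard_normal((6, 1)), rng.standard_normal(1))
        assert np.allclose(g, [1.0])

    def test_matches_exp_sum_oracle(self, rng):
        for _ in range(100):
            c = rng.standard_normal(6)
            W = rng.standard_normal((6, 4))
            b = rng.standard_normal(4)
            assert np.allclose(gate(c, W, b), _gate_oracle(c, W, b), atol=1e-9)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ContractError):
            gate(np.array([1.0, np.nan]), np.zeros((2, 2)), np.zeros(2))

    @given(seed=st.integers(0, 10_000))
    def test_rows_always_normalized(self, seed):
        r = np.random.default_rng(seed)
        g = gate(10 * r.standard_normal(12), r.standard_normal((12, 5)), r.standard_normal(5))
        assert np.all(g >= 0) and abs(g.sum() - 1.0) < 1e-6


class TestExpert:
    def test_all_zero_params_give_zero(self, cfg_params):
        cfg, p = cfg_params
        zero = {k: np.zeros_like(v) for k, v in p.items()}
        assert np.allclose(expert_forward(np.ones(cfg.codon_dim), 0, zero), 0.0)

    def test_identity_construction_on_positive_inputs(self):
        # First layer embeds the input into the (nearly linear) positive
        # region with a large bias; second layer inverts the affine map.
        cd, hidden, shift = 3, 3, 30.0
        params = {
            "W1": np.eye(cd)[None],
            "b1": np.full((1, hidden), shift),
            "W2": np.eye(cd)[None],
            "b2": np.full((1, cd), -shift),
        }
        c = np.array([0.5, 1.0, 2.0])
        out = expert_forward(c, 0, params)
        assert np.allclose(out, c, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        cfg = MoEConfig(D=1, K=2, expert_hidden=2)
        for _ in range(100):
            p = init_moe_params(cfg, rng)
            c = rng.standard_normal(cfg.codon_dim)
            k = int(rng.integers(cfg.K))
            assert np.allclose(expert_forward(c, k, p), _expert_oracle(c, k, p), atol=1e-9)


class TestMoEMix:
    def test_single_expert_reduces_to_that_expert(self, rng):
        cfg = MoEConfig(D=2, K=1, expert_hidden=5)
        p = init_moe_params(cfg, rng)
        X = rng.standard_normal((4, cfg.codon_dim))
        direct = np.stack([expert_forward(x, 0, p) for x in X])
        assert np.allclose(moe_mix(X, cfg, p), direct, atol=1e-12)

    def test_identical_experts_collapse_to_one(self, rng):
        cfg = MoEConfig(D=2, K=3, expert_hidden=4)
        p = init_moe_params(cfg, rng)
        for key in ("W1", "b1", "W2", "b2"):
            p[key] = np.repeat(p[key][:1], cfg.K, axis=0)
        X = rng.standard_normal((5, cfg.codon_dim))
        single = np.stack([expert_forward(x, 0, p) for x in X])
        assert np.allclose(moe_mix(X, cfg, p), single, atol=1e-9)

    def test_matches_nested_loop_oracle(self, rng):
        cfg = MoEConfig(D=1, K=2, expert_hidden=2)
        for _ in range(100):
            p = init_moe_params(cfg, rng)
            X = rng.standard_normal((3, cfg.codon_dim))
            oracle = np.zeros_like(X)
            for j in range(3):
                g = _gate_oracle(X[j], p["gate_W"], p["gate_b"])
                for k in range(cfg.K):
                    oracle[j] += g[k] * _expert_oracle(X[j], k, p)
            assert np.allclose(moe_mix(X, cfg, p), oracle, atol=1e-9)

    def test_output_in_convex_hull_of_expert_outputs(self, rng):
        # K=2: each mixed row must lie on the segment between the two
        # expert outputs for that codon.
        cfg = MoEConfig(D=2, K=2, expert_hidden=4)
        p = init_moe_params(cfg, rng)
        X = rng.standard_normal((6, cfg.codon_dim))
        mixed = moe_mix(X, cfg, p)
        for j in range(6):
            e0 = expert_forward(X[j], 0, p)
            e1 = expert_forward(X[j], 1, p)
            span = e1 - e0
            denom = float(span @ span)
            t = float((mixed[j] - e0) @ span) / denom
            assert -1e-9 <= t <= 1 + 1e-9
            assert np.allclose(mixed[j], e0 + t * span, atol=1e-8)


class TestEnrich:
    def test_zero_mix_reduces_to_gelu_layernorm(self, cfg_params, rng):
        cfg, p = cfg_params
        E = rng.standard_normal((6, cfg.D))
        H = enrich(E, np.zeros((2, cfg.codon_dim)), cfg, p, mode="evaluation")
        from codonmoe.nnops import gelu, layer_norm
        expected = gelu(layer_norm(E, p["ln_gamma"], p["ln_beta"])[0])
        assert np.allclose(H.values, expected, atol=1e-12)

    def test_constant_rows_normalize_to_zero(self, cfg_params):
        cfg, p = cfg_params
        E = np.full((6, cfg.D), 3.3)
        H = enrich(E, np.zeros((2, cfg.codon_dim)), cfg, p)
        assert np.allclose(H.values, 0.0, atol=1e-3)  # LN(const)=0, GELU(0)=0

    def test_matches_step_by_step_oracle(self, rng):
        cfg = MoEConfig(D=4, K=2)
        p = init_moe_params(cfg, rng)
        E = rng.standard_normal((6, 4))
        mixed = moe_mix(group_codons(E), cfg, p)
        H = enrich(E, mixed, cfg, p, mode="evaluation")
        # independent recomposition: residual, then per-row LN, then GELU
        Y = E + mixed.reshape(6, 4)
        oracle = np.empty_like(Y)
        for i in range(6):
            row = Y[i]
            xhat = (row - row.mean()) / np.sqrt(row.var() + 1e-5)
            z = p["ln_gamma"] * xhat + p["ln_beta"]
            oracle[i] = [_gelu_scalar(v) for v in z]
        assert np.allclose(H.values, oracle, atol=1e-6)

    def test_shape_mismatch_is_contract_error(self, cfg_params, rng):
        cfg, p = cfg_params
        with pytest.raises(ContractError):
            enrich(rng.standard_normal((6, cfg.D)),
                   rng.standard_normal((5, cfg.codon_dim)), cfg, p)


class TestBaseHead:
    def test_zero_weights_return_bias(self, rng):
        H = EnrichedRepresentation(rng.standard_normal((6, 2)), "evaluation", 0, 2)
        assert base_head(H, {"head_w": np.zeros(12), "head_b": np.array([0.7])}) == 0.7

    def test_all_ones_sum(self):
        H = EnrichedRepresentation(np.ones((6, 2)), "evaluation", 0, 2)
        out = base_head(H, {"head_w": np.ones(12), "head_b": np.zeros(1)})
        assert out == pytest.approx(12.0)

    def test_matches_dot_product_oracle(self, rng):
        for _ in range(100):
            vals = rng.standard_normal((6, 3))
            H = EnrichedRepresentation(vals, "evaluation", 0, 2)
            p = init_base_head(18, rng)
            oracle = sum(vals[i, j] * p["head_w"][i * 3 + j]
                         for i in range(6) for j in range(3)) + p["head_b"][0]
            assert base_head(H, p) == pytest.approx(oracle, abs=1e-9)

    def test_length_mismatch_is_contract_error(self, rng):
        H = EnrichedRepresentation(rng.standard_normal((6, 2)), "evaluation", 0, 2)
        with pytest.raises(ContractError):
            base_head(H, {"head_w": np.zeros(10), "head_b": np.zeros(1)})
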