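"""Trainable adapters over a frozen backbone: batched forward/backward.

Four adapter kinds, mirroring the design progression from global averaging
to local context modeling:

``mean``
    Codon-averaging baseline: per-codon arithmetic mean of nucleotide rows,
    then LayerNorm → GELU → dropout → linear flatten head.
``base``
    Mixture-of-codon-experts enrichment (see :mod:`codonmoe.moe`) with the
    linear flatten head.
``pro``
    The same enrichment followed by the multi-scale convolutional head
    (see :mod:`codonmoe.pro`).
``dense``
    Parameter-matched control: a plain two-hidden-layer perceptron on the
    flattened raw embeddings, with no codon structure at all.

All four share one interface — ``init_params``, ``forward``, ``backward``,
``predict`` — over float64 parameter dicts, so the training loop and the
checkpoint container are adapter-agnostic. Evaluation-mode forward passes
are deterministic and agree with the single-sequence reference ops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nnops
from .errors import ContractError, ValidationError
from .moe import MoEConfig, init_base_head, init_moe_params
from .nnops import ParamDict, gelu, gelu_grad, layer_norm, layer_norm_backward, softmax, softmax_backward
from .pro import ProHeadConfig, init_pro_head

__all__ = [
    "Adapter",
    "MeanAdapter",
    "BaseMoEAdapter",
    "ProMoEAdapter",
    "DenseAdapter",
    "make_adapter",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# shared enrichment engine (mean / base / pro)
# ---------------------------------------------------------------------------

def _codon_geometry(L: int, frame_offset: int) -> tuple[int, slice]:
    M = (L - frame_offset) // 3
    if M < 1:
        raise ValidationError(f"length {L} at offset {frame_offset} has no complete codon")
    return M, slice(frame_offset, frame_offset + 3 * M)


def _moe_enrich_forward(E, params, cfg: MoEConfig, frame_offset, mode, rng):
    """Batched MoE mixing + residual + LayerNorm + GELU + dropout.

    Expert contractions are phrased as stacked matmuls (BLAS) rather than
    general tensor contractions; shapes are (B, K, M, ·) with K the expert
    axis broadcast against the (K, ·, ·) parameter stacks.
    """
    B, L, D = E.shape
    M, cov = _codon_geometry(L, frame_offset)
    X = E[:, cov, :].reshape(B, M, 3 * D)
    G = softmax(X @ params["gate_W"] + params["gate_b"])  # (B, M, K)
    H1 = X[:, None] @ params["W1"] + params["b1"][None, :, None, :]  # (B, K, M, h)
    A1 = gelu(H1)
    O = A1 @ params["W2"] + params["b2"][None, :, None, :]  # (B, K, M, 3D)
    Gk = G.transpose(0, 2, 1)[..., None]  # (B, K, M, 1)
    Mix = (Gk * O).sum(axis=1)  # (B, M, 3D)
    Y = E.copy()
    Y[:, cov, :] += Mix.reshape(B, 3 * M, D)
    Z, ln_cache = layer_norm(Y, params["ln_gamma"], params["ln_beta"])
    A = gelu(Z)
    mask = None
    if mode == "training" and cfg.dropout_p > 0.0:
        mask = nnops.dropout_mask(A.shape, cfg.dropout_p, rng)
        A = A * mask
    cache = (X, G, H1, A1, O, Z, ln_cache, mask, cov, M)
    return A, cache


def _moe_enrich_backward(dH, cache, params):
    X, G, H1, A1, O, Z, ln_cache, mask, cov, M = cache
    B, L, D = dH.shape
    K = G.shape[-1]
    dA = dH * mask if mask is not None else dH
    dZ = dA * gelu_grad(Z)
    dY, dgamma, dbeta = layer_norm_backward(dZ, ln_cache)
    dMix = dY[:, cov, :].reshape(B, M, 3 * D)
    dG = (dMix[:, None] * O).sum(axis=-1).transpose(0, 2, 1)  # (B, M, K)
    dO = G.transpose(0, 2, 1)[..., None] * dMix[:, None]  # (B, K, M, 3D)
    # fold the batch axis into the per-expert matmuls: (K, B*M, ·)
    A1k = A1.transpose(1, 0, 2, 3).reshape(K, B * M, -1)
    dOk = dO.transpose(1, 0, 2, 3).reshape(K, B * M, -1)
    dW2 = A1k.transpose(0, 2, 1) @ dOk
    db2 = dOk.sum(axis=1)
    dA1 = dO @ params["W2"].transpose(0, 2, 1)  # (B, K, M, h)
    dH1 = dA1 * gelu_grad(H1)
    Xf = X.reshape(B * M, -1)
    dH1k = dH1.transpose(1, 0, 2, 3).reshape(K, B * M, -1)
    dW1 = Xf.T[None] @ dH1k
    db1 = dH1k.sum(axis=1)
    dZg = softmax_backward(dG, G)
    dgate_W = Xf.T @ dZg.reshape(B * M, -1)
    dgate_b = dZg.sum(axis=(0, 1))
    return {
        "gate_W": dgate_W, "gate_b": dgate_b,
        "W1": dW1, "b1": db1, "W2": dW2, "b2": db2,
        "ln_gamma": dgamma, "ln_beta": dbeta,
    }


# ---------------------------------------------------------------------------
# adapters
# ---------------------------------------------------------------------------

class Adapter:
    """Common adapter interface. Subclasses set ``kind``."""

    kind: str = "?"

    def __init__(self, L: int, D: int, frame_offset: int = 0):
        self.L = int(L)
        self.D = int(D)
        self.frame_offset = int(frame_offset)

    # subclasses implement init_params / forward / backward
    def init_params(self, rng: np.random.Generator) -> ParamDict:
        raise NotImplementedError

    def forward(self, params, E, mode="evaluation", rng=None):
        raise NotImplementedError

    def backward(self, params, cache, dy) -> ParamDict:
        raise NotImplementedError

    def predict(self, params: ParamDict, E: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode predictions for a (B, L, D) batch."""
        y, _ = self.forward(params, E, mode="evaluation")
        return y

    def _check_batch(self, E: np.ndarray) -> None:
        if E.ndim != 3 or E.shape[1] != self.L or E.shape[2] != self.D:
            raise ContractError(
                f"expected batch of shape (B, {self.L}, {self.D}), got {E.shape}"
            )

    def config_dict(self) -> dict:
        return {"kind": self.kind, "L": self.L, "D": self.D,
                "frame_offset": self.frame_offset}


class MeanAdapter(Adapter):
    """Codon-averaging baseline with the linear flatten head."""

    kind = "mean"

    def __init__(self, L, D, frame_offset=0, dropout_p=0.1):
        super().__init__(L, D, frame_offset)
        self.dropout_p = float(dropout_p)
        self.M, self.cov = _codon_geometry(L, frame_offset)

    def init_params(self, rng):
        params = {"ln_gamma": np.ones(self.D), "ln_beta": np.zeros(self.D)}
        params.update(init_base_head(3 * self.M * self.D, rng))
        return params

    def forward(self, params, E, mode="evaluation", rng=None):
        self._check_batch(E)
        B = E.shape[0]
        T = E.copy()
        block = E[:, self.cov, :].reshape(B, self.M, 3, self.D)
        T[:, self.cov, :] = np.repeat(block.mean(axis=2), 3, axis=1)
        Z, ln_cache = layer_norm(T, params["ln_gamma"], params["ln_beta"])
        A = gelu(Z)
        mask = None
        if mode == "training" and self.dropout_p > 0.0:
            mask = nnops.dropout_mask(A.shape, self.dropout_p, rng)
            A = A * mask
        flat = A[:, self.cov, :].reshape(B, -1)
        y = flat @ params["head_w"] + params["head_b"][0]
        return y, (Z, ln_cache, mask, flat)

    def backward(self, params, cache, dy):
        Z, ln_cache, mask, flat = cache
        B = flat.shape[0]
        dflat = dy[:, None] * params["head_w"][None, :]
        dA = np.zeros_like(Z)
        dA[:, self.cov, :] = dflat.reshape(B, 3 * self.M, self.D)
        if mask is not None:
            dA = dA * mask
        dZ = dA * gelu_grad(Z)
        _, dgamma, dbeta = layer_norm_backward(dZ, ln_cache)
        return {
            "ln_gamma": dgamma, "ln_beta": dbeta,
            "head_w": flat.T @ dy, "head_b": np.array([dy.sum()]),
        }

    def config_dict(self):
        return {**super().config_dict(), "dropout_p": self.dropout_p}


class BaseMoEAdapter(Adapter):
    """Mixture-of-codon-experts enrichment + linear flatten head."""

    kind = "base"

    def __init__(self, L, D, frame_offset=0, moe_config: MoEConfig | None = None):
        super().__init__(L, D, frame_offset)
        self.moe_config = moe_config or MoEConfig(D=D)
        if self.moe_config.D != D:
            raise ContractError("MoEConfig.D does not match adapter D")
        self.M, self.cov = _codon_geometry(L, frame_offset)

    def init_params(self, rng):
        params = init_moe_params(self.moe_config, rng)
        params.update(init_base_head(3 * self.M * self.D, rng))
        return params

    def forward(self, params, E, mode="evaluation", rng=None):
        self._check_batch(E)
        H, cache = _moe_enrich_forward(E, params, self.moe_config,
                                       self.frame_offset, mode, rng)
        B = E.shape[0]
        flat = H[:, self.cov, :].reshape(B, -1)
        y = flat @ params["head_w"] + params["head_b"][0]
        return y, (cache, flat, H.shape)

    def backward(self, params, cache, dy):
        enrich_cache, flat, H_shape = cache
        B = flat.shape[0]
        dH = np.zeros(H_shape)
        dH[:, self.cov, :] = (dy[:, None] * params["head_w"][None, :]).reshape(
            B, 3 * self.M, self.D)
        grads = _moe_enrich_backward(dH, enrich_cache, params)
        grads["head_w"] = flat.T @ dy
        grads["head_b"] = np.array([dy.sum()])
        return grads

    def config_dict(self):
        c = self.moe_config
        return {**super().config_dict(), "K": c.K,
                "expert_hidden": c.expert_hidden, "dropout_p": c.dropout_p}


class ProMoEAdapter(Adapter):
    """MoE enrichment + hierarchical multi-scale convolutional head."""

    kind = "pro"

    def __init__(self, L, D, frame_offset=0,
                 moe_config: MoEConfig | None = None,
                 pro_config: ProHeadConfig | None = None):
        super().__init__(L, D, frame_offset)
        self.moe_config = moe_config or MoEConfig(D=D)
        self.pro_config = pro_config or ProHeadConfig(D=D)
        if self.moe_config.D != D or self.pro_config.D != D:
            raise ContractError("config D does not match adapter D")
        if max(self.pro_config.kernel_sizes) > L:
            raise ValidationError("kernel height exceeds sequence length")
        self.M, self.cov = _codon_geometry(L, frame_offset)

    def init_params(self, rng):
        params = init_moe_params(self.moe_config, rng)
        params.update(init_pro_head(self.pro_config, rng))
        return params

    def forward(self, params, E, mode="evaluation", rng=None):
        self._check_batch(E)
        H, enrich_cache = _moe_enrich_forward(E, params, self.moe_config,
                                              self.frame_offset, mode, rng)
        B, L, D = H.shape
        conv_caches = []
        pooled = []
        for k in self.pro_config.kernel_sizes:
            Wk = params[f"conv_W{k}"].reshape(k * D, -1)
            windows = np.lib.stride_tricks.sliding_window_view(H, k, axis=1)
            # (B, P, D, k) -> (B, P, k*D) with rows in (position-in-window, D) order
            Xu = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(
                B, L - k + 1, k * D)
            F = Xu @ Wk + params[f"conv_b{k}"]
            R = np.maximum(F, 0.0)
            idx = R.argmax(axis=1)  # (B, c_out)
            pooled.append(np.take_along_axis(R, idx[:, None, :], axis=1)[:, 0, :])
            conv_caches.append((Xu, F, idx))
        c = np.concatenate(pooled, axis=1)
        mask = None
        if mode == "training" and self.pro_config.dropout_p > 0.0:
            mask = nnops.dropout_mask(c.shape, self.pro_config.dropout_p, rng)
            c = c * mask
        y = c @ params["final_w"] + params["final_b"][0]
        return y, (enrich_cache, conv_caches, c, mask, H.shape)

    def backward(self, params, cache, dy):
        enrich_cache, conv_caches, c, mask, H_shape = cache
        B, L, D = H_shape
        grads: ParamDict = {"final_w": c.T @ dy, "final_b": np.array([dy.sum()])}
        dc = dy[:, None] * params["final_w"][None, :]
        if mask is not None:
            dc = dc * mask
        dH = np.zeros(H_shape)
        c_out = self.pro_config.c_out
        for branch, k in enumerate(self.pro_config.kernel_sizes):
            Xu, F, idx = conv_caches[branch]
            dm = dc[:, branch * c_out : (branch + 1) * c_out]
            dR = np.zeros_like(F)
            np.put_along_axis(dR, idx[:, None, :], dm[:, None, :], axis=1)
            dF = dR * (F > 0.0)
            grads[f"conv_W{k}"] = (
                Xu.reshape(-1, k * D).T @ dF.reshape(-1, c_out)
            ).reshape(k, D, c_out)
            grads[f"conv_b{k}"] = dF.sum(axis=(0, 1))
            dXu = dF @ params[f"conv_W{k}"].reshape(k * D, -1).T
            dXu = dXu.reshape(B, L - k + 1, k, D)
            for a in range(k):
                dH[:, a : a + L - k + 1, :] += dXu[:, :, a, :]
        grads.update(_moe_enrich_backward(dH, enrich_cache, params))
        return grads

    def config_dict(self):
        m, p = self.moe_config, self.pro_config
        return {**super().config_dict(), "K": m.K, "expert_hidden": m.expert_hidden,
                "moe_dropout_p": m.dropout_p, "kernel_sizes": list(p.kernel_sizes),
                "c_out": p.c_out, "head_dropout_p": p.dropout_p}


class DenseAdapter(Adapter):
    """Structure-free control: MLP (L·D) → h → h → 1 with GELU activations."""

    kind = "dense"

    def __init__(self, L, D, hidden: int, frame_offset=0):
        super().__init__(L, D, frame_offset)
        if hidden < 1:
            raise ValidationError("hidden width must be >= 1")
        self.hidden = int(hidden)

    def init_params(self, rng):
        W1, b1 = nnops.affine_init(rng, self.L * self.D, self.hidden)
        W2, b2 = nnops.affine_init(rng, self.hidden, self.hidden)
        w3, b3 = nnops.affine_init(rng, self.hidden, 1)
        return {"d_W1": W1, "d_b1": b1, "d_W2": W2, "d_b2": b2,
                "d_w3": w3[:, 0], "d_b3": b3}

    def forward(self, params, E, mode="evaluation", rng=None):
        self._check_batch(E)
        B = E.shape[0]
        flat = E.reshape(B, -1)
        Z1 = flat @ params["d_W1"] + params["d_b1"]
        A1 = gelu(Z1)
        Z2 = A1 @ params["d_W2"] + params["d_b2"]
        A2 = gelu(Z2)
        y = A2 @ params["d_w3"] + params["d_b3"][0]
        return y, (flat, Z1, A1, Z2, A2)

    def backward(self, params, cache, dy):
        flat, Z1, A1, Z2, A2 = cache
        dA2 = dy[:, None] * params["d_w3"][None, :]
        dZ2 = dA2 * gelu_grad(Z2)
        dA1 = dZ2 @ params["d_W2"].T
        dZ1 = dA1 * gelu_grad(Z1)
        return {
            "d_w3": A2.T @ dy, "d_b3": np.array([dy.sum()]),
            "d_W2": A1.T @ dZ2, "d_b2": dZ2.sum(axis=0),
            "d_W1": flat.T @ dZ1, "d_b1": dZ1.sum(axis=0),
        }

    def config_dict(self):
        return {**super().config_dict(), "hidden": self.hidden}


# ---------------------------------------------------------------------------
# factory and checkpointing
# ---------------------------------------------------------------------------

def make_adapter(kind: str, L: int, D: int, frame_offset: int = 0,
                 moe_config: MoEConfig | None = None,
                 pro_config: ProHeadConfig | None = None,
                 dense_hidden: int | None = None) -> Adapter:
    if kind == "mean":
        return MeanAdapter(L, D, frame_offset)
    if kind == "base":
        return BaseMoEAdapter(L, D, frame_offset, moe_config)
    if kind == "pro":
        return ProMoEAdapter(L, D, frame_offset, moe_config, pro_config)
    if kind == "dense":
        if dense_hidden is None:
            raise ValidationError("dense adapter requires dense_hidden (or use "
                                  "baselines.build_dense_baseline for budget parity)")
        return DenseAdapter(L, D, dense_hidden, frame_offset)
    raise ValidationError(f"unknown adapter kind {kind!r} "
                          "(expected mean | base | pro | dense)")


def adapter_from_config(cfg: dict) -> Adapter:
    kind = cfg["kind"]
    if kind == "mean":
        return MeanAdapter(cfg["L"], cfg["D"], cfg["frame_offset"], cfg["dropout_p"])
    if kind == "base":
        mc = MoEConfig(D=cfg["D"], K=cfg["K"], expert_hidden=cfg["expert_hidden"],
                       dropout_p=cfg["dropout_p"])
        return BaseMoEAdapter(cfg["L"], cfg["D"], cfg["frame_offset"], mc)
    if kind == "pro":
        mc = MoEConfig(D=cfg["D"], K=cfg["K"], expert_hidden=cfg["expert_hidden"],
                       dropout_p=cfg["moe_dropout_p"])
        pc = ProHeadConfig(D=cfg["D"], kernel_sizes=tuple(cfg["kernel_sizes"]),
                           c_out=cfg["c_out"], dropout_p=cfg["head_dropout_p"])
        return ProMoEAdapter(cfg["L"], cfg["D"], cfg["frame_offset"], mc, pc)
    if kind == "dense":
        return DenseAdapter(cfg["L"], cfg["D"], cfg["hidden"], cfg["frame_offset"])
    raise ValidationError(f"unknown adapter kind {kind!r} in checkpoint")


def save_checkpoint(path: str | Path, adapter: Adapter, params: ParamDict) -> None:
    """Self-describing single-file checkpoint (config JSON + parameter arrays)."""
    meta = {"version": CHECKPOINT_VERSION, "config": adapter.config_dict()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **params)


def load_checkpoint(path: str | Path) -> tuple[Adapter, ParamDict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValidationError(f"unsupported checkpoint version {meta.get('version')}")
        params = {k: npz[k].copy() for k in npz.files if k != "__meta__"}
    return adapter_from_config(meta["config"]), params
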