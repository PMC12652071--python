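"""Prunable transformer encoders for DNA sequence classification.

The unit of model surgery throughout this toolkit is one encoder layer
(self-attention block + feed-forward block). Any model exposing an
ordered, removable layer stack can be profiled; this module provides

* :class:`TinyEncoder` — a self-contained pre-LayerNorm transformer
  encoder over single-nucleotide tokens, implemented in numpy with
  hand-derived backpropagation so the whole ablation pipeline runs on a
  single CPU with no deep-learning framework. It is small by design
  (tens of thousands of parameters) and is the reference implementation
  used for testing and desk-scale experiments.
* :func:`remove_layers` / :func:`clone_model` / :func:`count_parameters`
  — the layer-surgery operations. Surgery never mutates its input model;
  surviving layers keep their weights and relative order, are re-indexed
  densely, and the mapping back to original indices is kept in metadata.
* :func:`load_external_encoder` — the adapter contract for pretrained
  checkpoints (DNABERT-2, Nucleotide Transformer); it requires torch and
  transformers at call time and only demands an enumerable encoder-layer
  stack of the checkpoint.

Layer index 0 always denotes the first encoder block; embeddings are not
removable.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import (
    InvalidArgumentError,
    InvalidDataError,
    ResourceError,
    UnsupportedArchitectureError,
)

# single-nucleotide vocabulary; a leading classification token is prepended
TOKENS = {"PAD": 0, "CLS": 1, "A": 2, "C": 3, "G": 4, "T": 5, "N": 6}
VOCAB_SIZE = len(TOKENS)
_LN_EPS = 1e-5
_NEG_INF = -1e9


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of a tiny reference encoder.

    ``head_dims`` describes the classification head applied to the pooled
    representation: a chain of linear layers with ReLU between, whose
    final width must be 2 (the binary logits). ``(2,)`` is a single
    linear layer.
    """

    n_layers: int = 4
    d_model: int = 32
    n_heads: int = 4
    d_ff: int = 64
    max_len: int = 128
    pooling: str = "first-token"
    head_dims: tuple[int, ...] = (2,)
    vocab: str = "ACGTN"

    def __post_init__(self):
        if self.n_layers < 1:
            raise InvalidArgumentError("n_layers must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise InvalidArgumentError(
                f"d_model={self.d_model} is not divisible by n_heads={self.n_heads}"
            )
        if self.pooling not in ("first-token", "mean"):
            raise InvalidArgumentError("pooling must be 'first-token' or 'mean'")
        if not self.head_dims or self.head_dims[-1] != 2:
            raise InvalidArgumentError("head_dims must end in 2 logits")
        if self.max_len < 2:
            raise InvalidArgumentError("max_len must be >= 2")


# ---------------------------------------------------------------------------
# parameter tree helpers

_LAYER_KEYS = (
    "ln1_g", "ln1_b", "Wq", "bq", "Wk", "bk", "Wv", "bv", "Wo", "bo",
    "ln2_g", "ln2_b", "W1", "b1", "W2", "b2",
)


def _init_layer(rng: np.random.Generator, d: int, d_ff: int) -> dict:
    s = 0.02
    return {
        "ln1_g": np.ones(d), "ln1_b": np.zeros(d),
        "Wq": rng.normal(0, s, (d, d)), "bq": np.zeros(d),
        "Wk": rng.normal(0, s, (d, d)), "bk": np.zeros(d),
        "Wv": rng.normal(0, s, (d, d)), "bv": np.zeros(d),
        "Wo": rng.normal(0, s, (d, d)), "bo": np.zeros(d),
        "ln2_g": np.ones(d), "ln2_b": np.zeros(d),
        "W1": rng.normal(0, s, (d, d_ff)), "b1": np.zeros(d_ff),
        "W2": rng.normal(0, s, (d_ff, d)), "b2": np.zeros(d),
    }


def _init_head(rng: np.random.Generator, d_model: int, head_dims: tuple[int, ...]) -> list[dict]:
    layers = []
    d_in = d_model
    for d_out in head_dims:
        layers.append({"W": rng.normal(0, 0.02, (d_in, d_out)), "b": np.zeros(d_out)})
        d_in = d_out
    return layers


def iter_params(params: dict) -> Iterable[tuple[str, np.ndarray]]:
    """Deterministic (path, array) iteration over a parameter tree."""
    yield "tok_emb", params["tok_emb"]
    yield "pos_emb", params["pos_emb"]
    for i, layer in enumerate(params["layers"]):
        for k in _LAYER_KEYS:
            yield f"layers.{i}.{k}", layer[k]
    yield "lnf_g", params["lnf_g"]
    yield "lnf_b", params["lnf_b"]
    for j, lin in enumerate(params["head"]):
        yield f"head.{j}.W", lin["W"]
        yield f"head.{j}.b", lin["b"]


# ---------------------------------------------------------------------------
# numerical primitives (forward + backward)


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _split_heads(x, n_heads):
    B, T, D = x.shape
    return x.reshape(B, T, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, H, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)


def _attn_fwd(xn, layer, n_heads, mask):
    q = xn @ layer["Wq"] + layer["bq"]
    k = xn @ layer["Wk"] + layer["bk"]
    v = xn @ layer["Wv"] + layer["bv"]
    qh, kh, vh = (_split_heads(t, n_heads) for t in (q, k, v))
    dh = qh.shape[-1]
    scale = 1.0 / np.sqrt(dh)
    scores = qh @ kh.transpose(0, 1, 3, 2) * scale + mask
    attn = _softmax(scores)
    ctx = _merge_heads(attn @ vh)
    out = ctx @ layer["Wo"] + layer["bo"]
    cache = (xn, qh, kh, vh, attn, ctx, scale)
    return out, cache


def _attn_bwd(dout, layer, cache, n_heads):
    xn, qh, kh, vh, attn, ctx, scale = cache
    grads = {}
    B, T, D = xn.shape
    ctx2 = ctx.reshape(-1, D)
    dout2 = dout.reshape(-1, D)
    grads["Wo"] = ctx2.T @ dout2
    grads["bo"] = dout2.sum(0)
    dctx = (dout @ layer["Wo"].T)
    dctx_h = _split_heads(dctx, n_heads)
    dattn = dctx_h @ vh.transpose(0, 1, 3, 2)
    dvh = attn.transpose(0, 1, 3, 2) @ dctx_h
    # softmax backward (rows sum to 1)
    dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
    dscores *= scale
    dqh = dscores @ kh
    dkh = dscores.transpose(0, 1, 3, 2) @ qh
    dq, dk, dv = (_merge_heads(t) for t in (dqh, dkh, dvh))
    xn2 = xn.reshape(-1, D)
    dxn = np.zeros_like(xn)
    for name, dt in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
        dt2 = dt.reshape(-1, D)
        grads[name] = xn2.T @ dt2
        grads["b" + name[1].lower()] = dt2.sum(0)
        dxn += dt @ layer[name].T
    return dxn, grads


def _ffn_fwd(xn, layer):
    pre = xn @ layer["W1"] + layer["b1"]
    h = np.maximum(pre, 0.0)
    out = h @ layer["W2"] + layer["b2"]
    return out, (xn, pre, h)


def _ffn_bwd(dout, layer, cache):
    xn, pre, h = cache
    B, T, D = xn.shape
    d_ff = h.shape[-1]
    dout2 = dout.reshape(-1, D)
    h2 = h.reshape(-1, d_ff)
    grads = {"W2": h2.T @ dout2, "b2": dout2.sum(0)}
    dh = (dout @ layer["W2"].T) * (pre > 0)
    dh2 = dh.reshape(-1, d_ff)
    xn2 = xn.reshape(-1, xn.shape[-1])
    grads["W1"] = xn2.T @ dh2
    grads["b1"] = dh2.sum(0)
    dxn = dh @ layer["W1"].T
    return dxn, grads


# ---------------------------------------------------------------------------
# the tiny encoder


class TinyEncoder:
    """Pre-LN transformer encoder classifier over single-nucleotide tokens.

    Sequences are tokenized one base per token with a leading CLS token;
    pooling is either the CLS position ("first-token") or a padding-aware
    mean. All arithmetic is float64 numpy, which keeps runs bit-reproducible
    for a given seed on a given platform.
    """

    def __init__(self, config: EncoderConfig, params: dict, metadata: dict):
        self.config = config
        self.params = params
        self.metadata = metadata

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, config: EncoderConfig, seed: int = 0) -> "TinyEncoder":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE11C]))
        d, d_ff = config.d_model, config.d_ff
        params = {
            "tok_emb": rng.normal(0, 0.02, (VOCAB_SIZE, d)),
            "pos_emb": rng.normal(0, 0.02, (config.max_len, d)),
            "layers": [_init_layer(rng, d, d_ff) for _ in range(config.n_layers)],
            "lnf_g": np.ones(d),
            "lnf_b": np.zeros(d),
            "head": _init_head(rng, d, config.head_dims),
        }
        metadata = {
            "provenance": "reference-tiny",
            "seed": int(seed),
            "original_indices": list(range(config.n_layers)),
            "removed_history": [],
        }
        return cls(config, params, metadata)

    @property
    def n_layers(self) -> int:
        return len(self.params["layers"])

    @property
    def layers(self) -> list[int]:
        """Current 0-based layer indices (dense)."""
        return list(range(self.n_layers))

    @property
    def original_indices(self) -> list[int]:
        return list(self.metadata["original_indices"])

    # -- tokenization ------------------------------------------------------

    def tokenize(self, sequences: Sequence[str]) -> np.ndarray:
        if not sequences:
            raise InvalidDataError("cannot tokenize an empty batch")
        T = max(len(s) for s in sequences) + 1  # leading CLS
        if T > self.config.max_len:
            raise InvalidDataError(
                f"sequence of length {T - 1} exceeds max_len={self.config.max_len} "
                "(one position is reserved for the classification token)"
            )
        out = np.full((len(sequences), T), TOKENS["PAD"], dtype=np.int64)
        out[:, 0] = TOKENS["CLS"]
        for i, s in enumerate(sequences):
            try:
                out[i, 1 : len(s) + 1] = [TOKENS[c] for c in s]
            except KeyError as exc:
                raise InvalidDataError(f"sequence {i}: unknown base {exc}") from exc
        return out

    # -- forward / backward ------------------------------------------------

    def _embed(self, tokens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        B, T = tokens.shape
        x = self.params["tok_emb"][tokens] + self.params["pos_emb"][:T]
        key_mask = np.where(tokens == TOKENS["PAD"], _NEG_INF, 0.0)
        return x, key_mask[:, None, None, :]

    def forward_logits(
        self,
        tokens: np.ndarray,
        layer_hook: Callable[[int, np.ndarray], None] | None = None,
    ) -> np.ndarray:
        """Forward pass to logits. ``layer_hook(original_index, hidden)``
        is invoked after each surviving encoder layer, in execution order."""
        x, mask = self._embed(tokens)
        cfg = self.config
        for li, layer in enumerate(self.params["layers"]):
            xn, _ = _layernorm_fwd(x, layer["ln1_g"], layer["ln1_b"])
            a, _ = _attn_fwd(xn, layer, cfg.n_heads, mask)
            x = x + a
            xn2, _ = _layernorm_fwd(x, layer["ln2_g"], layer["ln2_b"])
            f, _ = _ffn_fwd(xn2, layer)
            x = x + f
            if layer_hook is not None:
                layer_hook(self.metadata["original_indices"][li], x)
        h, _ = _layernorm_fwd(x, self.params["lnf_g"], self.params["lnf_b"])
        pooled = self._pool(h, tokens)
        z = pooled
        for j, lin in enumerate(self.params["head"]):
            z = z @ lin["W"] + lin["b"]
            if j < len(self.params["head"]) - 1:
                z = np.maximum(z, 0.0)
        return z

    def _pool(self, h: np.ndarray, tokens: np.ndarray) -> np.ndarray:
        if self.config.pooling == "first-token":
            return h[:, 0, :]
        valid = (tokens != TOKENS["PAD"])[:, :, None]
        return (h * valid).sum(1) / valid.sum(1)

    def loss_and_grads(
        self, tokens: np.ndarray, labels: np.ndarray
    ) -> tuple[float, dict]:
        """Mean softmax cross-entropy and gradients for every parameter."""
        cfg = self.config
        params = self.params
        x, mask = self._embed(tokens)
        caches = []
        for layer in params["layers"]:
            xn, c_ln1 = _layernorm_fwd(x, layer["ln1_g"], layer["ln1_b"])
            a, c_att = _attn_fwd(xn, layer, cfg.n_heads, mask)
            x = x + a
            xn2, c_ln2 = _layernorm_fwd(x, layer["ln2_g"], layer["ln2_b"])
            f, c_ffn = _ffn_fwd(xn2, layer)
            x = x + f
            caches.append((c_ln1, c_att, c_ln2, c_ffn))
        h, c_lnf = _layernorm_fwd(x, params["lnf_g"], params["lnf_b"])
        pooled = self._pool(h, tokens)

        head_caches = []
        z = pooled
        for j, lin in enumerate(params["head"]):
            pre = z @ lin["W"] + lin["b"]
            act = np.maximum(pre, 0.0) if j < len(params["head"]) - 1 else pre
            head_caches.append((z, pre))
            z = act
        logits = z

        B = tokens.shape[0]
        probs = _softmax(logits)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(B), labels] + eps)))

        # ---- backward
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B

        grads: dict = {"layers": [dict() for _ in params["layers"]], "head": []}
        dz = dlogits
        head_grads: list[dict] = [None] * len(params["head"])
        for j in range(len(params["head"]) - 1, -1, -1):
            z_in, pre = head_caches[j]
            if j < len(params["head"]) - 1:
                dz = dz * (pre > 0)
            head_grads[j] = {"W": z_in.T @ dz, "b": dz.sum(0)}
            dz = dz @ params["head"][j]["W"].T
        grads["head"] = head_grads
        dpooled = dz

        if cfg.pooling == "first-token":
            dh = np.zeros_like(h)
            dh[:, 0, :] = dpooled
        else:
            valid = (tokens != TOKENS["PAD"])[:, :, None]
            dh = np.where(valid, 1.0, 0.0) * (dpooled[:, None, :] / valid.sum(1)[:, None, :])
        dx, dgf, dbf = _layernorm_bwd(dh, c_lnf)
        grads["lnf_g"], grads["lnf_b"] = dgf, dbf

        for li in range(len(params["layers"]) - 1, -1, -1):
            layer = params["layers"][li]
            c_ln1, c_att, c_ln2, c_ffn = caches[li]
            lg = grads["layers"][li]
            dxn2, g_ffn = _ffn_bwd(dx, layer, c_ffn)
            lg.update(g_ffn)
            dres, dg2, db2 = _layernorm_bwd(dxn2, c_ln2)
            lg["ln2_g"], lg["ln2_b"] = dg2, db2
            dx = dx + dres
            dxn, g_att = _attn_bwd(dx, layer, c_att, cfg.n_heads)
            lg.update(g_att)
            dres1, dg1, db1 = _layernorm_bwd(dxn, c_ln1)
            lg["ln1_g"], lg["ln1_b"] = dg1, db1
            dx = dx + dres1

        dtok = np.zeros_like(params["tok_emb"])
        np.add.at(dtok, tokens, dx)
        dpos = np.zeros_like(params["pos_emb"])
        dpos[: tokens.shape[1]] = dx.sum(0)
        grads["tok_emb"], grads["pos_emb"] = dtok, dpos
        return loss, grads

    # -- inference ---------------------------------------------------------

    def predict_proba(self, sequences: Sequence[str], batch_size: int = 128) -> np.ndarray:
        """Class probabilities, shape (n, 2)."""
        out = []
        for i in range(0, len(sequences), batch_size):
            tokens = self.tokenize(sequences[i : i + batch_size])
            out.append(_softmax(self.forward_logits(tokens)))
        return np.concatenate(out, axis=0)

    # -- surgery & bookkeeping --------------------------------------------

    def clone(self) -> "TinyEncoder":
        return TinyEncoder(
            self.config, copy.deepcopy(self.params), copy.deepcopy(self.metadata)
        )

    def layer_param_count(self, index: int) -> int:
        if not 0 <= index < self.n_layers:
            raise InvalidArgumentError(f"layer index {index} out of range")
        return sum(arr.size for arr in self.params["layers"][index].values())

    def count_parameters(self) -> int:
        return sum(arr.size for _, arr in iter_params(self.params))

    def reinit_head(self, seed: int) -> None:
        """Draw a fresh classification head (used at fine-tuning time)."""
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4EAD]))
        self.params["head"] = _init_head(rng, self.config.d_model, self.config.head_dims)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for path, arr in iter_params(self.params):
            h.update(path.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def describe(self) -> dict:
        """JSON-ready metadata report."""
        return {
            "provenance": self.metadata["provenance"],
            "n_layers": self.n_layers,
            "parameter_count": self.count_parameters(),
            "original_indices": self.original_indices,
            "removed_history": list(self.metadata["removed_history"]),
        }

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {p: a for p, a in iter_params(self.params)}
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config.__dict__, default=list).encode(), dtype=np.uint8
        )
        arrays["__metadata__"] = np.frombuffer(
            json.dumps(self.metadata).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TinyEncoder":
        with np.load(Path(path)) as npz:
            cfg_d = json.loads(bytes(npz["__config__"]).decode())
            cfg_d["head_dims"] = tuple(cfg_d["head_dims"])
            config = EncoderConfig(**cfg_d)
            metadata = json.loads(bytes(npz["__metadata__"]).decode())
            params = {
                "tok_emb": npz["tok_emb"],
                "pos_emb": npz["pos_emb"],
                "layers": [
                    {k: npz[f"layers.{i}.{k}"] for k in _LAYER_KEYS}
                    for i in range(len(metadata["original_indices"]))
                ],
                "lnf_g": npz["lnf_g"],
                "lnf_b": npz["lnf_b"],
                "head": [],
            }
            j = 0
            while f"head.{j}.W" in npz:
                params["head"].append({"W": npz[f"head.{j}.W"], "b": npz[f"head.{j}.b"]})
                j += 1
        return cls(config, params, metadata)


# ---------------------------------------------------------------------------
# module-level surgery API (works on any PrunableModel-shaped object)


def build_tiny_encoder(config: EncoderConfig | None = None, seed: int = 0) -> TinyEncoder:
    """Construct a reproducible randomly initialized tiny encoder."""
    return TinyEncoder.build(config if config is not None else EncoderConfig(), seed)


def clone_model(model: TinyEncoder) -> TinyEncoder:
    """Deep, independent copy; mutating either side never affects the other."""
    return model.clone()


def remove_layers(model: TinyEncoder, indices: Iterable[int]) -> TinyEncoder:
    """Return a copy of ``model`` with the given layers removed.

    ``indices`` are 0-based positions in the *current* stack. Surviving
    layers keep their weights and relative order and are re-indexed
    densely; their original indices are retained in metadata. At least
    one layer must remain.
    """
    idx = list(indices)
    if len(set(idx)) != len(idx):
        raise InvalidArgumentError(f"duplicate layer indices in {idx}")
    idx_set = set(idx)
    n = model.n_layers
    for i in idx_set:
        if not isinstance(i, (int, np.integer)) or not 0 <= i < n:
            raise InvalidArgumentError(f"layer index {i!r} out of range 0..{n - 1}")
    if len(idx_set) >= n:
        raise InvalidArgumentError("cannot remove every encoder layer")
    out = model.clone()
    survivors = [i for i in range(n) if i not in idx_set]
    out.params["layers"] = [out.params["layers"][i] for i in survivors]
    originals = model.metadata["original_indices"]
    out.metadata["original_indices"] = [originals[i] for i in survivors]
    removed_orig = sorted(originals[i] for i in idx_set)
    out.metadata["removed_history"] = list(model.metadata["removed_history"]) + (
        [removed_orig] if removed_orig else []
    )
    out.config = EncoderConfig(
        **{**model.config.__dict__, "n_layers": len(survivors)}
    )
    return out


def count_parameters(model: TinyEncoder) -> int:
    """Exact count of trainable parameters."""
    return model.count_parameters()


def layer_param_count(model: TinyEncoder, index: int) -> int:
    """Parameter count of one encoder layer, from the model structure."""
    return model.layer_param_count(index)


def tiny_param_count_closed_form(config: EncoderConfig) -> int:
    """Closed-form parameter census for :class:`TinyEncoder`.

    embedding: V·d + max_len·d
    per layer: 4·(d² + d) attention + (d·f + f + f·d + d) feed-forward + 4·d norms
    final norm: 2·d;  head: chained linears with biases.
    """
    d, f = config.d_model, config.d_ff
    per_layer = 4 * (d * d + d) + (d * f + f + f * d + d) + 4 * d
    head = 0
    d_in = d
    for d_out in config.head_dims:
        head += d_in * d_out + d_out
        d_in = d_out
    return VOCAB_SIZE * d + config.max_len * d + config.n_layers * per_layer + 2 * d + head


# ---------------------------------------------------------------------------
# external checkpoint adapter


def load_external_encoder(checkpoint_ref: str):
    """Load a pretrained encoder-only transformer behind the surgery contract.

    Requires ``torch`` and ``transformers`` (and, for hub identifiers,
    network access or a local cache). The checkpoint must expose an
    enumerable stack of encoder layers; anything else raises
    :class:`UnsupportedArchitectureError`. Retrieval problems — including
    the hosting libraries being unavailable — raise :class:`ResourceError`.
    """
    if not isinstance(checkpoint_ref, str) or not checkpoint_ref:
        raise InvalidArgumentError("checkpoint_ref must be a non-empty string")
    try:
        import torch  # noqa: F401
        from transformers import AutoModel
    except ImportError as exc:
        raise ResourceError(
            f"loading checkpoint {checkpoint_ref!r} requires torch and "
            "transformers, which are not installed in this environment"
        ) from exc
    try:
        hf_model = AutoModel.from_pretrained(checkpoint_ref, trust_remote_code=True)
    except Exception as exc:
        raise ResourceError(
            f"could not retrieve checkpoint {checkpoint_ref!r}: {exc}"
        ) from exc
    stack = _find_layer_stack(hf_model)
    if stack is None:
        raise UnsupportedArchitectureError(
            f"checkpoint {checkpoint_ref!r} does not expose an enumerable "
            "encoder layer stack (encoder-only transformers are supported)"
        )
    return ExternalEncoder(hf_model, stack, checkpoint_ref)


def _find_layer_stack(hf_model):
    """Locate the ModuleList of encoder blocks in a transformers model."""
    candidates = ("encoder.layer", "encoder.layers", "layers", "blocks",
                  "esm.encoder.layer", "transformer.layer")
    for dotted in candidates:
        obj = hf_model
        ok = True
        for part in dotted.split("."):
            if not hasattr(obj, part):
                ok = False
                break
            obj = getattr(obj, part)
        if ok and hasattr(obj, "__len__") and len(obj) >= 1:
            return obj
    return None


class ExternalEncoder:
    """Thin wrapper giving external checkpoints the prunable-model surface.

    Only the structural operations (layer enumeration, removal, parameter
    counts, cloning) are provided here; fine-tuning an external model goes
    through the same training loop contract but requires torch.
    """

    def __init__(self, hf_model, stack, checkpoint_ref: str):
        self._model = hf_model
        self._stack = stack
        self.metadata = {
            "provenance": f"adapter:{checkpoint_ref}",
            "original_indices": list(range(len(stack))),
            "removed_history": [],
        }

    @property
    def n_layers(self) -> int:
        return len(self._stack)

    def count_parameters(self) -> int:
        return sum(p.numel() for p in self._model.parameters() if p.requires_grad)

    def layer_param_count(self, index: int) -> int:
        return sum(p.numel() for p in self._stack[index].parameters())

    def clone(self) -> "ExternalEncoder":
        out = copy.deepcopy(self)
        return out

    def remove_layers_inplace(self, indices: Iterable[int]) -> None:
        idx = set(indices)
        n = self.n_layers
        if any(not 0 <= i < n for i in idx) or len(idx) >= n:
            raise InvalidArgumentError("invalid layer index set")
        survivors = [i for i in range(n) if i not in idx]
        originals = self.metadata["original_indices"]
        for pos in sorted(idx, reverse=True):
            del self._stack[pos]
        self.metadata["removed_history"].append(sorted(originals[i] for i in idx))
        self.metadata["original_indices"] = [originals[i] for i in survivors]
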