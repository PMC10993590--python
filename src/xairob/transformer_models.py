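"""Instrumented transformer encoders for SMILES toxicity modelling.

The encoder exposes everything the attribution methods need from one
forward pass: per-layer, per-head attention matrices (row-stochastic
softmax outputs) and per-layer attention-block outputs after the W^O
projection.  Gradients of a class logit with respect to those stored
intermediates are exact tape gradients, not finite differences.

Two architectures are provided: encoder-only (pre-trained with a
per-position MLP emitting canonical SMILES) and encoder-decoder (a causal
transformer decoder with cross attention, greedy-decoded for sequence
accuracy).  Transfer learning freezes the encoder — verified by weight
digest — and trains a max-pool MLP or TextCNN-highway head on top.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import autograd as ag
from .autograd import AdamW, Parameter, Tensor, no_grad
from .chem_data import MoleculeRecord, TokenSequence, enumerate_smiles, mask_tokens, tokenize
from .vocab import DEFAULT_VOCAB

PRETRAIN_REGIMENS = ("C2C", "R2C", "E2C", "MC2C", "MR2C", "ME2C")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Architecture and optimisation hyperparameters.

    Defaults are standard choices for character-level SMILES transformers:
    sequence length 175, vocabulary 68, embedding 512, Xavier init, AdamW
    with weight decay 0.01, dropout 0.1 (pre-training) / 0.3 (transfer),
    learning rates 1e-4 / 5e-5, batch 128.  Depth and head count are kept
    small (L=3, h=8 at full width) so the default model stays well under a
    16.5 M parameter budget.
    """

    max_len: int = 175
    embed_dim: int = 512
    heads: int = 8
    layers: int = 3
    ff_mult: int = 4
    vocab_size: int = 68
    dropout_pretrain: float = 0.1
    dropout_transfer: float = 0.3
    lr_pretrain: float = 1e-4
    lr_transfer: float = 5e-5
    weight_decay: float = 0.01
    batch_size: int = 128
    head_type: str = "maxpool_mlp"  # or "textcnn"
    architecture: str = "encoder_only"  # or "encoder_decoder"
    param_budget: int = 16_500_000
    force_uniform_attention: bool = False  # diagnostic: constant 1/S attention

    def __post_init__(self):
        if self.embed_dim % self.heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by heads {self.heads}"
            )
        for name in ("max_len", "embed_dim", "heads", "layers", "ff_mult", "vocab_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.head_type not in ("maxpool_mlp", "textcnn"):
            raise ValueError(f"unknown head_type {self.head_type!r}")
        if self.architecture not in ("encoder_only", "encoder_decoder"):
            raise ValueError(f"unknown architecture {self.architecture!r}")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads

    @property
    def full_length(self) -> int:
        return self.max_len + 2  # BOS + SMILES + EOS, PAD up to this


# ---------------------------------------------------------------------------
# traces


@dataclass
class AttentionTrace:
    """Stored intermediates of one forward pass (single sequence)."""

    alpha: np.ndarray  # (L, h, S, S), rows stochastic
    h_out: np.ndarray  # (L, S, E), attention-block outputs after W^O
    logits: np.ndarray  # (2,)

    @property
    def layers(self) -> int:
        return self.alpha.shape[0]


@dataclass
class GradientTrace:
    """Gradients of one class logit w.r.t. the stored intermediates."""

    d_alpha: np.ndarray  # (L, h, S, S)
    d_hout: np.ndarray  # (L, S, E)
    class_index: int


# ---------------------------------------------------------------------------
# building blocks


class Linear:
    def __init__(self, rng, fan_in: int, fan_out: int):
        self.W = Parameter(ag.xavier_uniform(rng, fan_in, fan_out))
        self.b = Parameter(np.zeros(fan_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gain + self.bias

    def parameters(self) -> list[Parameter]:
        return [self.gain, self.bias]


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or p <= 0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * keep


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class MultiHeadAttention:
    """Scaled dot-product multi-head attention with trace capture."""

    def __init__(self, rng, cfg: ModelConfig):
        E = cfg.embed_dim
        self.cfg = cfg
        self.wq = Linear(rng, E, E)
        self.wk = Linear(rng, E, E)
        self.wv = Linear(rng, E, E)
        self.wo = Linear(rng, E, E)

    def __call__(
        self,
        query: Tensor,
        memory: Tensor,
        key_mask: np.ndarray,
        causal: bool = False,
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (output after W^O, alpha, h_out) — alpha/h_out are tape nodes."""
        cfg = self.cfg
        B, Sq, E = query.shape
        Sk = memory.shape[1]
        h, d = cfg.heads, cfg.head_dim
        q = self.wq(query).reshape(B, Sq, h, d).transpose(0, 2, 1, 3)
        k = self.wk(memory).reshape(B, Sk, h, d).transpose(0, 2, 1, 3)
        v = self.wv(memory).reshape(B, Sk, h, d).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        if cfg.force_uniform_attention:
            scores = scores * 0.0
        bias = np.where(key_mask[:, None, None, :], 0.0, -1e9)
        if causal:
            tri = np.triu(np.full((Sq, Sk), -1e9), k=1)
            bias = bias + tri[None, None, :, :]
        alpha = (scores + bias).softmax(axis=-1)  # (B, h, Sq, Sk)
        ctx = (alpha @ v).transpose(0, 2, 1, 3).reshape(B, Sq, E)
        h_out = self.wo(ctx)
        return h_out, alpha, h_out

    def parameters(self) -> list[Parameter]:
        return self.wq.parameters() + self.wk.parameters() + self.wv.parameters() + self.wo.parameters()


class EncoderLayer:
    def __init__(self, rng, cfg: ModelConfig):
        E = cfg.embed_dim
        self.attn = MultiHeadAttention(rng, cfg)
        self.ln1 = LayerNorm(E)
        self.ln2 = LayerNorm(E)
        self.ff1 = Linear(rng, E, cfg.ff_mult * E)
        self.ff2 = Linear(rng, cfg.ff_mult * E, E)

    def __call__(self, x, key_mask, dropout_p=0.0, rng=None):
        h_out, alpha, _ = self.attn(x, x, key_mask)
        x = self.ln1(x + _dropout(h_out, dropout_p, rng))
        ff = self.ff2(self.ff1(x).relu())
        x = self.ln2(x + _dropout(ff, dropout_p, rng))
        return x, alpha, h_out

    def parameters(self):
        return (
            self.attn.parameters()
            + self.ln1.parameters()
            + self.ln2.parameters()
            + self.ff1.parameters()
            + self.ff2.parameters()
        )


class DecoderLayer:
    def __init__(self, rng, cfg: ModelConfig):
        E = cfg.embed_dim
        self.self_attn = MultiHeadAttention(rng, cfg)
        self.cross_attn = MultiHeadAttention(rng, cfg)
        self.ln1 = LayerNorm(E)
        self.ln2 = LayerNorm(E)
        self.ln3 = LayerNorm(E)
        self.ff1 = Linear(rng, E, cfg.ff_mult * E)
        self.ff2 = Linear(rng, cfg.ff_mult * E, E)

    def __call__(self, x, memory, self_mask, memory_mask, dropout_p=0.0, rng=None):
        sa, _, _ = self.self_attn(x, x, self_mask, causal=True)
        x = self.ln1(x + _dropout(sa, dropout_p, rng))
        ca, _, _ = self.cross_attn(x, memory, memory_mask)
        x = self.ln2(x + _dropout(ca, dropout_p, rng))
        ff = self.ff2(self.ff1(x).relu())
        x = self.ln3(x + _dropout(ff, dropout_p, rng))
        return x

    def parameters(self):
        return (
            self.self_attn.parameters()
            + self.cross_attn.parameters()
            + self.ln1.parameters()
            + self.ln2.parameters()
            + self.ln3.parameters()
            + self.ff1.parameters()
            + self.ff2.parameters()
        )


# ---------------------------------------------------------------------------
# encoder, heads, models


class TransformerEncoder:
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.embedding = Parameter(
            ag.xavier_uniform(rng, cfg.vocab_size, cfg.embed_dim)
        )
        self.positional = sinusoidal_positions(cfg.full_length, cfg.embed_dim)
        self.layers = [EncoderLayer(rng, cfg) for _ in range(cfg.layers)]
        self.pad_id = DEFAULT_VOCAB.pad_id

    def embed(self, ids: np.ndarray) -> Tensor:
        """Input representation: token embedding + sinusoidal position."""
        ids = np.atleast_2d(ids)
        x = ag.embedding_lookup(self.embedding, ids)
        return x * np.sqrt(self.cfg.embed_dim) + self.positional[: ids.shape[1]]

    def __call__(
        self,
        ids: np.ndarray | None = None,
        inputs: Tensor | None = None,
        key_mask: np.ndarray | None = None,
        dropout_p: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Returns (hidden (B,S,E), list of alpha nodes, list of h_out nodes)."""
        if inputs is None:
            if ids is None:
                raise ValueError("provide ids or inputs")
            ids = np.atleast_2d(ids)
            if ids.shape[1] > self.cfg.full_length:
                raise ValueError(
                    f"sequence length {ids.shape[1]} exceeds {self.cfg.full_length}"
                )
            inputs = self.embed(ids)
            if key_mask is None:
                key_mask = ids != self.pad_id
        if key_mask is None:
            key_mask = np.ones(inputs.shape[:2], dtype=bool)
        x = inputs
        alphas, houts = [], []
        for layer in self.layers:
            x, alpha, h_out = layer(x, key_mask, dropout_p, rng)
            alphas.append(alpha)
            houts.append(h_out)
        return x, alphas, houts

    def parameters(self) -> list[Parameter]:
        out = [self.embedding]
        for layer in self.layers:
            out += layer.parameters()
        return out


class MaxPoolMLPHead:
    """Masked max pooling over the sequence followed by a two-layer MLP."""

    def __init__(self, rng, cfg: ModelConfig, hidden: int | None = None):
        E = cfg.embed_dim
        hidden = hidden or E
        self.l1 = Linear(rng, E, hidden)
        self.l2 = Linear(rng, hidden, 2)

    def __call__(self, hidden: Tensor, key_mask: np.ndarray,
                 dropout_p: float = 0.0, rng=None) -> Tensor:
        neg = np.where(key_mask[:, :, None], 0.0, -1e9)
        pooled = (hidden + neg).max(axis=1)
        return self.l2(_dropout(self.l1(pooled).relu(), dropout_p, rng))

    def parameters(self):
        return self.l1.parameters() + self.l2.parameters()


class TextCNNHead:
    """TextCNN over token states: kernels {3,4,5} x 100 filters + one highway unit."""

    KERNELS = (3, 4, 5)
    FILTERS = 100

    def __init__(self, rng, cfg: ModelConfig):
        E = cfg.embed_dim
        self.convs = []
        for k in self.KERNELS:
            W = Parameter(ag.xavier_uniform(rng, k * E, self.FILTERS, shape=(k, E, self.FILTERS)))
            b = Parameter(np.zeros(self.FILTERS))
            self.convs.append((W, b))
        total = self.FILTERS * len(self.KERNELS)
        self.highway_t = Linear(rng, total, total)
        self.highway_h = Linear(rng, total, total)
        self.out = Linear(rng, total, 2)

    def __call__(self, hidden: Tensor, key_mask: np.ndarray,
                 dropout_p: float = 0.0, rng=None) -> Tensor:
        feats = []
        for (W, b), k in zip(self.convs, self.KERNELS):
            conv = ag.conv1d(hidden, W, b).relu()
            feats.append(conv.max(axis=1))
        x = ag.concatenate(feats, axis=-1)
        t = self.highway_t(x).sigmoid()
        h = self.highway_h(x).relu()
        x = t * h + (1.0 - t) * x
        return self.out(_dropout(x, dropout_p, rng))

    def parameters(self):
        out = []
        for W, b in self.convs:
            out += [W, b]
        return out + self.highway_t.parameters() + self.highway_h.parameters() + self.out.parameters()


class ToxicityClassifier:
    """Encoder + classification head; logits y in R^2 (non-toxic, toxic)."""

    def __init__(self, cfg: ModelConfig, seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = TransformerEncoder(cfg, rng)
        self.head = (
            TextCNNHead(rng, cfg) if cfg.head_type == "textcnn"
            else MaxPoolMLPHead(rng, cfg)
        )
        self.seed = seed
        self.trained = False

    # -- forward paths ---------------------------------------------------
    def forward_tensors(
        self,
        ids: np.ndarray | None = None,
        inputs: Tensor | None = None,
        key_mask: np.ndarray | None = None,
        dropout_p: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Full tape forward: returns (logits, alphas, houts, key_mask)."""
        if ids is not None:
            ids = np.atleast_2d(ids)
            if key_mask is None:
                key_mask = ids != self.encoder.pad_id
        hidden, alphas, houts = self.encoder(
            ids=ids, inputs=inputs, key_mask=key_mask, dropout_p=dropout_p, rng=rng
        )
        if key_mask is None:
            key_mask = np.ones(hidden.shape[:2], dtype=bool)
        logits = self.head(hidden, key_mask, dropout_p, rng)
        return logits, alphas, houts, key_mask

    def logits(self, ids: np.ndarray) -> np.ndarray:
        """Forward-only class scores, shape (B, 2) (no tape)."""
        with no_grad():
            logits, _, _, _ = self.forward_tensors(ids=np.atleast_2d(ids))
        return logits.data

    def predict_proba(self, ids: np.ndarray) -> np.ndarray:
        z = self.logits(ids)
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def parameters(self) -> list[Parameter]:
        return self.encoder.parameters() + self.head.parameters()

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Seq2SeqModel:
    """Pre-training model: encoder plus decoder (or per-position MLP)."""

    def __init__(self, cfg: ModelConfig, seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = TransformerEncoder(cfg, rng)
        if cfg.architecture == "encoder_decoder":
            self.dec_embedding = Parameter(
                ag.xavier_uniform(rng, cfg.vocab_size, cfg.embed_dim)
            )
            self.dec_layers = [DecoderLayer(rng, cfg) for _ in range(cfg.layers)]
        else:
            self.mlp1 = Linear(rng, cfg.embed_dim, cfg.embed_dim)
        self.out_proj = Linear(rng, cfg.embed_dim, cfg.vocab_size)
        self.seed = seed

    def parameters(self) -> list[Parameter]:
        out = self.encoder.parameters()
        if self.cfg.architecture == "encoder_decoder":
            out.append(self.dec_embedding)
            for layer in self.dec_layers:
                out += layer.parameters()
        else:
            out += self.mlp1.parameters()
        return out + self.out_proj.parameters()

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _decode_states(self, tgt_ids: np.ndarray, memory: Tensor,
                       memory_mask: np.ndarray, dropout_p=0.0, rng=None) -> Tensor:
        x = ag.embedding_lookup(self.dec_embedding, tgt_ids) * np.sqrt(
            self.cfg.embed_dim
        ) + self.encoder.positional[: tgt_ids.shape[1]]
        self_mask = tgt_ids != self.encoder.pad_id
        for layer in self.dec_layers:
            x = layer(x, memory, self_mask, memory_mask, dropout_p, rng)
        return x

    def token_logits(self, src_ids: np.ndarray, tgt_in_ids: np.ndarray | None,
                     dropout_p: float = 0.0, rng=None) -> Tensor:
        """(B, S, V) next-token logits (teacher forcing for the decoder)."""
        src_ids = np.atleast_2d(src_ids)
        memory, _, _ = self.encoder(ids=src_ids, dropout_p=dropout_p, rng=rng)
        memory_mask = src_ids != self.encoder.pad_id
        if self.cfg.architecture == "encoder_decoder":
            states = self._decode_states(
                np.atleast_2d(tgt_in_ids), memory, memory_mask, dropout_p, rng
            )
        else:
            states = self.mlp1(memory).relu()
        return self.out_proj(states)

    def greedy_decode(self, src_ids: np.ndarray, max_len: int | None = None) -> np.ndarray:
        """Greedy autoregressive decoding (encoder-decoder only)."""
        vocab = DEFAULT_VOCAB
        src_ids = np.atleast_2d(src_ids)
        max_len = max_len or src_ids.shape[1]
        with no_grad():
            memory, _, _ = self.encoder(ids=src_ids)
            memory_mask = src_ids != self.encoder.pad_id
            B = src_ids.shape[0]
            out = np.full((B, 1), vocab.bos_id, dtype=np.intp)
            done = np.zeros(B, dtype=bool)
            for _ in range(max_len - 1):
                states = self._decode_states(out, memory, memory_mask)
                nxt = self.out_proj(states).data[:, -1, :].argmax(axis=-1)
                nxt = np.where(done, vocab.pad_id, nxt)
                out = np.concatenate([out, nxt[:, None]], axis=1)
                done |= nxt == vocab.eos_id
                if done.all():
                    break
        return out


# ---------------------------------------------------------------------------
# factories & digests


def build_model(config: ModelConfig, seed: int) -> ToxicityClassifier:
    """Xavier-initialised classifier; deterministic under `seed`."""
    model = ToxicityClassifier(config, seed)
    if model.parameter_count() > config.param_budget:
        raise ValueError(
            f"{model.parameter_count()} parameters exceed budget {config.param_budget}"
        )
    return model


def randomize_model(config: ModelConfig, seed: int) -> ToxicityClassifier:
    """Randomly initialised, never-trained control model."""
    return build_model(config, seed)


def weight_digest(params: Iterable[Parameter]) -> str:
    hasher = hashlib.sha256()
    for p in params:
        hasher.update(np.ascontiguousarray(p.data).tobytes())
    return hasher.hexdigest()


def save_checkpoint(model, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "config": asdict(model.cfg),
        "seed": model.seed,
        "digest": weight_digest(model.parameters()),
        "kind": type(model).__name__,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path) -> "ToxicityClassifier | Seq2SeqModel":
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**meta["config"])
    cls = ToxicityClassifier if meta["kind"] == "ToxicityClassifier" else Seq2SeqModel
    model = cls(cfg, meta["seed"])
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.parameters()):
        p.data = data[f"p{i}"]
    if weight_digest(model.parameters()) != meta["digest"]:
        raise ValueError("checkpoint digest mismatch")
    return model


# ---------------------------------------------------------------------------
# tracing API


def forward_with_trace(
    model: ToxicityClassifier, seq: TokenSequence
) -> tuple[dict, AttentionTrace]:
    """Evaluation-mode forward returning logits plus the full trace."""
    ids = np.asarray(seq.ids, dtype=np.intp)
    with no_grad():
        logits, alphas, houts, _ = model.forward_tensors(ids=ids)
    trace = AttentionTrace(
        alpha=np.stack([a.data[0] for a in alphas]),
        h_out=np.stack([h.data[0] for h in houts]),
        logits=logits.data[0],
    )
    z = trace.logits - trace.logits.max()
    probs = np.exp(z) / np.exp(z).sum()
    prediction = {
        "logits": trace.logits,
        "probs": probs,
        "class_index": int(trace.logits.argmax()),
    }
    return prediction, trace


def class_gradients(
    model: ToxicityClassifier, seq: TokenSequence, class_index: int
) -> GradientTrace:
    """Exact gradients of logit `class_index` w.r.t. attention and h_out."""
    if class_index not in (0, 1):
        raise ValueError("class_index must be 0 or 1")
    ids = np.asarray(seq.ids, dtype=np.intp)
    logits, alphas, houts, _ = model.forward_tensors(ids=ids)
    logits[0, class_index].backward()
    d_alpha, d_hout = [], []
    for layer_idx, (a, h) in enumerate(zip(alphas, houts)):
        ga = np.zeros_like(a.data[0]) if a.grad is None else a.grad[0]
        gh = np.zeros_like(h.data[0]) if h.grad is None else h.grad[0]
        if not (np.isfinite(ga).all() and np.isfinite(gh).all()):
            raise FloatingPointError(f"non-finite gradients at layer {layer_idx}")
        d_alpha.append(ga)
        d_hout.append(gh)
    return GradientTrace(
        d_alpha=np.stack(d_alpha), d_hout=np.stack(d_hout), class_index=class_index
    )


# ---------------------------------------------------------------------------
# training


def _cross_entropy(logits: Tensor, targets: np.ndarray, weight: np.ndarray) -> Tensor:
    """Mean masked token cross-entropy. logits (B,S,V), targets (B,S)."""
    shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    logz = shifted.exp().sum(axis=-1, keepdims=True).log()
    logp = shifted - logz
    B, S = targets.shape
    picked = logp[np.arange(B)[:, None], np.arange(S)[None, :], targets]
    total = float(weight.sum())
    return -(picked * weight).sum() / max(total, 1.0)


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **kwargs):
        self.epochs.append(kwargs)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.epochs:
                fh.write(json.dumps(row) + "\n")


def _pad_batch(seqs: list[TokenSequence], length: int) -> np.ndarray:
    pad = DEFAULT_VOCAB.pad_id
    out = np.full((len(seqs), length), pad, dtype=np.intp)
    for i, s in enumerate(seqs):
        out[i, : s.length] = s.ids
    return out


def _regimen_pairs(
    records: Sequence[MoleculeRecord], regimen: str, seed: int, epoch: int
) -> list[tuple[str, str]]:
    """(input SMILES, target canonical SMILES) pairs for one epoch."""
    masked = regimen.startswith("M")
    base = regimen[1:] if masked else regimen
    pairs: list[tuple[str, str]] = []
    for i, rec in enumerate(records):
        can = rec.smiles_canonical
        if base == "C2C":
            pairs.append((can, can))
        elif base == "R2C":
            rand = enumerate_smiles(can, 1, seed + 1009 * epoch + i)[0]
            pairs.append((rand, can))
        elif base == "E2C":
            for rand in enumerate_smiles(can, 10, seed + 1009 * epoch + i):
                pairs.append((rand, can))
            pairs.append((can, can))
        else:
            raise ValueError(f"unknown regimen {regimen!r}")
    return pairs


def pretrain(
    model: Seq2SeqModel,
    corpus: Sequence[MoleculeRecord],
    regimen: str,
    seed: int = 0,
    epochs: int = 50,
    patience: int = 5,
    valid_fraction: float = 0.2,
    batch_size: int | None = None,
    lr: float | None = None,
) -> tuple[Seq2SeqModel, TrainingHistory]:
    """Auto-translation pre-training to canonical SMILES.

    The regimen selects the input form — canonical (C2C), one randomized
    SMILES per epoch (R2C) or up to ten randomized plus the canonical
    (E2C) — with an M prefix adding 15% token masking on the input.  Early
    stopping monitors validation cross-entropy with the given patience.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if regimen not in PRETRAIN_REGIMENS:
        raise ValueError(f"regimen must be one of {PRETRAIN_REGIMENS}")
    cfg = model.cfg
    rng = np.random.default_rng(seed)
    n_valid = (
        max(1, int(valid_fraction * len(corpus)))
        if valid_fraction > 0 and len(corpus) > 1
        else 0
    )
    order = rng.permutation(len(corpus))
    valid_recs = [corpus[i] for i in order[:n_valid]]
    train_recs = [corpus[i] for i in order[n_valid:]] or list(corpus)
    masked = regimen.startswith("M")
    vocab = DEFAULT_VOCAB
    optimizer = AdamW(
        model.parameters(),
        lr=cfg.lr_pretrain if lr is None else lr,
        weight_decay=cfg.weight_decay,
    )
    history = TrainingHistory()
    best_val = np.inf
    best_state = [p.data.copy() for p in model.parameters()]
    stale = 0
    batch_size = batch_size or cfg.batch_size

    def epoch_batches(records, epoch, train):
        pairs = _regimen_pairs(records, regimen, seed if train else seed + 7, epoch if train else 0)
        length = min(
            cfg.full_length,
            max(max(len(vocab.split(s)) for s, _ in pairs),
                max(len(vocab.split(t)) for _, t in pairs)) + 2,
        )
        seq_in, seq_out = [], []
        for j, (s, t) in enumerate(pairs):
            sin = tokenize(s)
            if masked and train:
                sin, _ = mask_tokens(sin, seed + 31 * epoch + j)
            seq_in.append(sin)
            seq_out.append(tokenize(t))
        src = _pad_batch(seq_in, length)
        tgt = _pad_batch(seq_out, length)
        idx = rng.permutation(len(src)) if train else np.arange(len(src))
        for start in range(0, len(src), batch_size):
            sel = idx[start : start + batch_size]
            yield src[sel], tgt[sel]

    def step(src, tgt, train: bool):
        pad = vocab.pad_id
        if cfg.architecture == "encoder_decoder":
            tgt_in, tgt_out = tgt[:, :-1], tgt[:, 1:]
        else:
            tgt_in, tgt_out = None, tgt
        weight = (tgt_out != pad).astype(np.float64)
        drop = cfg.dropout_pretrain if train else 0.0
        logits = model.token_logits(src, tgt_in, dropout_p=drop, rng=rng if train else None)
        loss = _cross_entropy(logits, tgt_out, weight)
        if train:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        pred = logits.data.argmax(axis=-1)
        hits = (pred == tgt_out) & (weight > 0)
        char_acc = hits.sum() / max(weight.sum(), 1.0)
        seq_acc = ((hits.sum(axis=1) == weight.sum(axis=1))).mean()
        return float(loss.data), float(char_acc), float(seq_acc)

    for epoch in range(epochs):
        train_stats = [step(src, tgt, True) for src, tgt in epoch_batches(train_recs, epoch, True)]
        with_valid = valid_recs or train_recs
        with no_grad():
            val_stats = [step(src, tgt, False) for src, tgt in epoch_batches(with_valid, epoch, False)]
        train_loss = float(np.mean([s[0] for s in train_stats]))
        val_loss = float(np.mean([s[0] for s in val_stats]))
        history.append(
            epoch=epoch,
            train_loss=train_loss,
            val_loss=val_loss,
            char_accuracy=float(np.mean([s[1] for s in val_stats])),
            sequence_accuracy=float(np.mean([s[2] for s in val_stats])),
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = [p.data.copy() for p in model.parameters()]
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                history.epochs[-1]["early_stopped"] = True
                break
    for p, data in zip(model.parameters(), best_state):
        p.data = data
    return model, history


def training_accuracy(model: Seq2SeqModel, corpus: Sequence[MoleculeRecord],
                      greedy: bool = False) -> dict:
    """Teacher-forced (or greedy) reconstruction accuracy on a corpus."""
    vocab = DEFAULT_VOCAB
    seqs = [tokenize(rec.smiles_canonical) for rec in corpus]
    length = max(s.length for s in seqs)
    ids = _pad_batch(seqs, length)
    if greedy and model.cfg.architecture == "encoder_decoder":
        out = model.greedy_decode(ids, max_len=length)
        hits = []
        for i, s in enumerate(seqs):
            target = np.asarray(s.ids[1:], dtype=np.intp)
            got = out[i, 1 : 1 + len(target)] if out.shape[1] > len(target) else out[i, 1:]
            hits.append(len(got) == len(target) and bool((got == target).all()))
        return {"sequence_accuracy": float(np.mean(hits))}
    tgt_in = ids[:, :-1] if model.cfg.architecture == "encoder_decoder" else None
    tgt_out = ids[:, 1:] if model.cfg.architecture == "encoder_decoder" else ids
    with no_grad():
        logits = model.token_logits(ids, tgt_in)
    weight = (tgt_out != vocab.pad_id).astype(np.float64)
    pred = logits.data.argmax(axis=-1)
    hits = (pred == tgt_out) & (weight > 0)
    return {
        "character_accuracy": float(hits.sum() / weight.sum()),
        "sequence_accuracy": float((hits.sum(axis=1) == weight.sum(axis=1)).mean()),
    }


def transfer_learn(
    encoder_model: ToxicityClassifier,
    data: Sequence[MoleculeRecord],
    freeze: bool = True,
    split: str = "scaffold",
    seed: int = 0,
    epochs: int = 60,
    patience: int = 5,
    lr: float | None = None,
    head_epochs_batch: int | None = None,
) -> tuple[ToxicityClassifier, dict]:
    """Train the classification head on binary labels with a frozen encoder.

    With `freeze=True` (the default, and the only supported mode) encoder
    weights are bitwise unchanged — checked by digest — and the head is
    trained on cached encoder features, which is mathematically identical
    to backpropagating through frozen weights.  Returns the classifier and
    held-out metrics (AUROC, accuracy, F1, MCC, precision, recall).
    """
    from .analysis_stats import classification_metrics
    from .chem_data import random_split as _random_split, scaffold_split as _scaffold_split

    labels_all = [rec.label for rec in data]
    if any(l is None for l in labels_all):
        raise ValueError("all records need binary labels")
    if len(set(labels_all)) < 2:
        raise ValueError("training data contains a single class")
    if not freeze:
        raise NotImplementedError("only frozen-encoder transfer is supported")
    splitter = _scaffold_split if split == "scaffold" else _random_split
    train, valid, test = splitter(list(data), seed=seed)
    if not valid:
        valid = train[-max(1, len(train) // 10):]
    if not test:
        test = valid
    cfg = encoder_model.cfg
    rng = np.random.default_rng(seed)
    digest_before = weight_digest(encoder_model.encoder.parameters())

    def featurize(records):
        seqs = [tokenize(r.smiles_canonical) for r in records]
        length = min(cfg.full_length, max(s.length for s in seqs))
        ids = _pad_batch(seqs, length)
        mask = ids != encoder_model.encoder.pad_id
        feats = []
        for start in range(0, len(ids), cfg.batch_size):
            with no_grad():
                hidden, _, _ = encoder_model.encoder(ids=ids[start : start + cfg.batch_size])
            feats.append(hidden.data)
        return np.concatenate(feats, axis=0), mask, np.array(
            [r.label for r in records], dtype=np.intp
        )

    x_train, m_train, y_train = featurize(train)
    x_valid, m_valid, y_valid = featurize(valid)
    x_test, m_test, y_test = featurize(test)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training split contains a single class")

    head = encoder_model.head
    optimizer = AdamW(
        head.parameters(),
        lr=cfg.lr_transfer if lr is None else lr,
        weight_decay=cfg.weight_decay,
    )

    def head_loss(x, m, y, train_mode: bool):
        drop = cfg.dropout_transfer if train_mode else 0.0
        logits = head(Tensor(x), m, drop, rng if train_mode else None)
        weight = np.ones((len(y), 1))
        return _cross_entropy(
            logits.reshape(len(y), 1, 2), y[:, None], weight
        ), logits

    best_val = np.inf
    best_state = [p.data.copy() for p in head.parameters()]
    stale = 0
    batch = cfg.batch_size
    for epoch in range(epochs):
        order = rng.permutation(len(y_train))
        for start in range(0, len(y_train), batch):
            sel = order[start : start + batch]
            loss, _ = head_loss(x_train[sel], m_train[sel], y_train[sel], True)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        with no_grad():
            val_loss, _ = head_loss(x_valid, m_valid, y_valid, False)
        if val_loss.data < best_val:
            best_val = float(val_loss.data)
            best_state = [p.data.copy() for p in head.parameters()]
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    for p, data_ in zip(head.parameters(), best_state):
        p.data = data_
    digest_after = weight_digest(encoder_model.encoder.parameters())
    assert digest_before == digest_after, "frozen encoder was modified"
    with no_grad():
        _, logits = head_loss(x_test, m_test, y_test, False)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    probs = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
    metrics = classification_metrics(probs[:, 1], y_test)
    metrics["encoder_digest"] = digest_after
    encoder_model.trained = True
    return encoder_model, metrics
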