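"""BERT-style transformer encoder over gene-token cell sentences.

Post-layer-norm encoder blocks with learned absolute position embeddings,
SiLU feed-forward activation, an untied masked-token (MLM) projection head
and an optional [CLS] classification head. Inference helpers (masked-token
prediction, cell embedding extraction, classification) run with dropout
disabled and no autodiff graph.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .encoding import CLS, MASK, PAD, N_SPECIALS, CellSentence
from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale settings (2048 positions, 6 blocks, 4 heads,
    256 embedding dimensions, SiLU, dropout 0.02); :meth:`tiny` gives a
    desk-scale preset.
    """

    vocab_size: int
    max_input: int = 2048
    n_blocks: int = 6
    n_heads: int = 4
    embed_dim: int = 256
    activation: str = "silu"
    dropout: float = 0.02
    n_classes: int | None = None
    ffn_dim: int | None = None  # default 4 * embed_dim (BERT convention)
    tie_mlm: bool = False

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ConfigurationError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if not (0 <= self.dropout < 1):
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.vocab_size <= N_SPECIALS:
            raise ConfigurationError("vocabulary has no gene tokens")
        if self.activation != "silu":
            raise ConfigurationError("only SiLU activation is supported")
        if self.n_blocks < 1 or self.max_input < 2:
            raise ConfigurationError("need n_blocks >= 1 and max_input >= 2")

    @property
    def ffn(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.embed_dim

    @classmethod
    def tiny(cls, vocab_size: int, n_classes: int | None = None,
             max_input: int = 256) -> "EncoderConfig":
        """Reduced preset for desk-scale experiments: 2 blocks, 2 heads,
        64 embedding dimensions."""
        return cls(vocab_size=vocab_size, max_input=max_input, n_blocks=2,
                   n_heads=2, embed_dim=64, n_classes=n_classes)


class EncoderModel:
    """Encoder parameters plus training provenance (the model state)."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        self.provenance: dict = {"init_seed": int(seed)}
        rng = np.random.default_rng(seed)
        d, v, p = config.embed_dim, config.vocab_size, config.max_input
        f = config.ffn

        def w(*shape):
            return Tensor(rng.normal(0.0, 0.02, size=shape).astype(np.float32),
                          requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)

        self.params: dict[str, Tensor] = {
            "tok_emb": w(v, d), "pos_emb": w(p, d),
            "emb_ln_g": ones(d), "emb_ln_b": zeros(d),
        }
        for b in range(config.n_blocks):
            pre = f"b{b}."
            self.params.update({
                pre + "q_w": w(d, d), pre + "q_b": zeros(d),
                pre + "k_w": w(d, d), pre + "k_b": zeros(d),
                pre + "v_w": w(d, d), pre + "v_b": zeros(d),
                pre + "o_w": w(d, d), pre + "o_b": zeros(d),
                pre + "ln1_g": ones(d), pre + "ln1_b": zeros(d),
                pre + "f1_w": w(d, f), pre + "f1_b": zeros(f),
                pre + "f2_w": w(f, d), pre + "f2_b": zeros(d),
                pre + "ln2_g": ones(d), pre + "ln2_b": zeros(d),
            })
        if not config.tie_mlm:
            self.params["mlm_w"] = w(d, v)
        self.params["mlm_b"] = zeros(v)
        if config.n_classes is not None:
            self.params["cls_w"] = w(d, config.n_classes)
            self.params["cls_b"] = zeros(config.n_classes)

    # ------------------------------------------------------------------
    def block_param_names(self, block: int) -> list[str]:
        return [k for k in self.params if k.startswith(f"b{block}.")]

    def add_classification_head(self, n_classes: int, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        d = self.config.embed_dim
        self.params["cls_w"] = Tensor(
            rng.normal(0.0, 0.02, size=(d, n_classes)).astype(np.float32),
            requires_grad=True)
        self.params["cls_b"] = Tensor(np.zeros(n_classes, dtype=np.float32),
                                      requires_grad=True)
        self.config = replace(self.config, n_classes=n_classes)

    # ------------------------------------------------------------------
    def forward(self, tokens: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> list[Tensor]:
        """Hidden states after every encoder block for padded ``tokens``
        (batch, length); returns a list of (B, T, D) tensors, one per block."""
        tokens = np.asarray(tokens)
        if tokens.ndim != 2:
            raise DataError("tokens must be a (batch, length) array")
        B, T = tokens.shape
        if T > self.config.max_input:
            raise DataError(
                f"sequence length {T} exceeds max_input {self.config.max_input}"
            )
        p = self.config.dropout if training else 0.0
        if p and rng is None:
            raise ConfigurationError("training-mode forward needs an rng for dropout")

        x = ag.add(ag.embedding(self.params["tok_emb"], tokens),
                   ag.embedding(self.params["pos_emb"], np.arange(T)))
        x = ag.layer_norm(x, self.params["emb_ln_g"], self.params["emb_ln_b"])
        if p:
            x = ag.dropout(x, p, rng)

        # additive attention mask: PAD keys get -inf-like logits
        attn_bias = np.where(tokens == PAD, np.float32(-1e9), np.float32(0.0))
        attn_bias = attn_bias[:, None, None, :]  # (B, 1, 1, T)

        H = self.config.n_heads
        d = self.config.embed_dim
        dh = d // H
        scale = 1.0 / np.sqrt(dh)
        layers: list[Tensor] = []
        for b in range(self.config.n_blocks):
            pr = self.params
            pre = f"b{b}."

            def heads(t: Tensor) -> Tensor:
                return ag.transpose(ag.reshape(t, (B, T, H, dh)), (0, 2, 1, 3))

            q = heads(ag.add(ag.matmul(x, pr[pre + "q_w"]), pr[pre + "q_b"]))
            k = heads(ag.add(ag.matmul(x, pr[pre + "k_w"]), pr[pre + "k_b"]))
            v = heads(ag.add(ag.matmul(x, pr[pre + "v_w"]), pr[pre + "v_b"]))
            att = ag.add(ag.mul(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), scale),
                         attn_bias)
            att = ag.softmax(att)
            if p:
                att = ag.dropout(att, p, rng)
            ctx = ag.reshape(ag.transpose(ag.matmul(att, v), (0, 2, 1, 3)), (B, T, d))
            ctx = ag.add(ag.matmul(ctx, pr[pre + "o_w"]), pr[pre + "o_b"])
            if p:
                ctx = ag.dropout(ctx, p, rng)
            x = ag.layer_norm(ag.add(x, ctx), pr[pre + "ln1_g"], pr[pre + "ln1_b"])
            h = ag.silu(ag.add(ag.matmul(x, pr[pre + "f1_w"]), pr[pre + "f1_b"]))
            h = ag.add(ag.matmul(h, pr[pre + "f2_w"]), pr[pre + "f2_b"])
            if p:
                h = ag.dropout(h, p, rng)
            x = ag.layer_norm(ag.add(x, h), pr[pre + "ln2_g"], pr[pre + "ln2_b"])
            layers.append(x)
        return layers

    def mlm_logits(self, hidden: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
        """MLM head applied at selected (batch, position) indices."""
        states = ag.take_rows(hidden, rows, cols)
        w = (ag.transpose(self.params["tok_emb"], (1, 0))
             if self.config.tie_mlm else self.params["mlm_w"])
        return ag.add(ag.matmul(states, w), self.params["mlm_b"])

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        (path / "config.json").write_text(json.dumps(
            {"config": cfg, "provenance": self.provenance}, indent=1))
        np.savez(path / "weights.npz",
                 **{k: t.data for k, t in self.params.items()})

    @classmethod
    def load(cls, path) -> "EncoderModel":
        path = Path(path)
        blob = json.loads((path / "config.json").read_text())
        config = EncoderConfig(**blob["config"])
        model = cls(config, seed=0)
        with np.load(path / "weights.npz") as z:
            for k in model.params:
                model.params[k].data = z[k].astype(np.float32)
        model.provenance = blob.get("provenance", {})
        return model


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def build_model(config: EncoderConfig, seed: int = 0) -> EncoderModel:
    """Randomly initialized encoder; deterministic under ``seed``."""
    return EncoderModel(config, seed=seed)


def pad_batch(sentences: Sequence[CellSentence] | Sequence[np.ndarray],
              max_input: int | None = None) -> np.ndarray:
    """Stack sentences into a (batch, max_len) array padded with [PAD]."""
    arrs = [s.tokens if isinstance(s, CellSentence) else np.asarray(s)
            for s in sentences]
    if max_input is not None:
        for a in arrs:
            if len(a) > max_input:
                raise DataError(f"sentence length {len(a)} > max_input {max_input}")
    T = max(len(a) for a in arrs)
    out = np.full((len(arrs), T), PAD, dtype=np.int64)
    for i, a in enumerate(arrs):
        out[i, : len(a)] = a
    return out


def predict_masked(model: EncoderModel, sentence: CellSentence) -> np.ndarray:
    """Probability distribution over the vocabulary at each [MASK] position
    of ``sentence``; rows ordered by position."""
    toks = sentence.tokens
    if len(toks) > model.config.max_input:
        raise DataError("sentence exceeds max_input")
    pos = np.flatnonzero(toks == MASK)
    with ag.no_grad():
        hidden = model.forward(toks[None, :])[-1]
        logits = model.mlm_logits(hidden, np.zeros(len(pos), dtype=int), pos)
        return ag.softmax(logits).data


def _batched_hidden(model: EncoderModel, sentences, layer: int,
                    batch_size: int = 32):
    """Yield (tokens, hidden.data) per batch at 1-based ``layer``."""
    for i in range(0, len(sentences), batch_size):
        chunk = sentences[i: i + batch_size]
        toks = pad_batch(chunk, model.config.max_input)
        with ag.no_grad():
            hidden = model.forward(toks)[layer - 1]
        yield toks, hidden.data


def embed_cells(model: EncoderModel, sentences: Sequence[CellSentence],
                layer: int | None = None, pooling: str = "mean",
                batch_size: int = 32) -> tuple[np.ndarray, dict]:
    """Cell embeddings: mean over gene-token positions (default) or the
    [CLS] state, at the given 1-based encoder layer (default: final)."""
    if pooling not in ("mean", "cls"):
        raise ConfigurationError("pooling must be 'mean' or 'cls'")
    layer = model.config.n_blocks if layer is None else int(layer)
    if not (1 <= layer <= model.config.n_blocks):
        raise ConfigurationError(f"layer must be in [1, {model.config.n_blocks}]")
    out = np.empty((len(sentences), model.config.embed_dim), dtype=np.float32)
    row = 0
    for toks, hid in _batched_hidden(model, list(sentences), layer, batch_size):
        if pooling == "cls":
            out[row: row + len(toks)] = hid[:, 0, :]
        else:
            genes = toks >= N_SPECIALS
            for i in range(len(toks)):
                m = genes[i]
                if not m.any():
                    warnings.warn("sentence has no gene tokens; using [CLS] state",
                                  stacklevel=2)
                    out[row + i] = hid[i, 0, :]
                else:
                    out[row + i] = hid[i, m, :].mean(axis=0)
        row += len(toks)
    provenance = {"layer": layer, "pooling": pooling}
    return out, provenance


def classify(model: EncoderModel, sentences: Sequence[CellSentence],
             batch_size: int = 32) -> np.ndarray:
    """Per-cell class probabilities from the [CLS] state at the final layer."""
    if model.config.n_classes is None or "cls_w" not in model.params:
        raise ConfigurationError("model has no classification head")
    probs = np.empty((len(sentences), model.config.n_classes), dtype=np.float32)
    row = 0
    for toks, hid in _batched_hidden(model, list(sentences),
                                     model.config.n_blocks, batch_size):
        logits = hid[:, 0, :] @ model.params["cls_w"].data + model.params["cls_b"].data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs[row: row + len(toks)] = e / e.sum(axis=1, keepdims=True)
        row += len(toks)
    return probs
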