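"""Selection-factor models: amino-acid sequence -> per-site factor f_j >= 0.

A selection factor multiplies the neutral probability of nonsynonymous
substitution at a codon site: f_j > 1 is diversifying selection, f_j < 1
purifying, and 0 the strongest possible purifying selection.  Three model
families share one contract:

* ``single``       — one global factor (repertoire-wide selection pressure);
* ``per_position`` — one factor per alignment position, sequence-blind;
* ``transformer``  — a transformer encoder over the amino-acid sequence with
  a per-site linear head, so factors depend on the whole sequence context.

All families emit a raw per-site score that passes through the "wiggle"
activation, ``exp(wiggle(x, beta)) = exp(beta (x-1))`` for ``x < 1`` and
``x**beta`` for ``x >= 1``: positive, increasing, equal to 1 at ``x = 1``,
and sub-linear above 1 so factors cannot run away.  ``beta = 0.3`` is the
operating default and is not trained.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Tensor
from .seqcodec import AA_INDEX, AMINO_ACIDS

PAD = len(AMINO_ACIDS)  # padding token index (vocabulary: 20 aa + PAD)
AMBIGUOUS_AA = "X"


# ---------------------------------------------------------------------------
# Wiggle activation
# ---------------------------------------------------------------------------

def wiggle(x, beta: float = 0.3):
    """Log selection factor: ``beta*(x-1)`` below 1, ``beta*log(x)`` above."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(x < 1.0, beta * (x - 1.0), beta * np.log(np.maximum(x, 1.0)))
    return out if out.ndim else float(out)


def exp_wiggle(x, beta: float = 0.3):
    """Selection factor: ``exp(beta*(x-1))`` below 1, ``x**beta`` above."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(x < 1.0, np.exp(beta * (x - 1.0)), np.power(np.maximum(x, 1.0), beta))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Configuration and tokenization
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SelectionModelConfig:
    family: str = "transformer"  # single | per_position | transformer
    heads: int = 8
    dims_per_head: int = 16
    layers: int = 5
    ff_width: int | None = None  # default 4 x embedding width
    dropout: float = 0.1
    max_len: int = 512
    beta: float = 0.3

    def __post_init__(self):
        if self.family not in ("single", "per_position", "transformer"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.family == "transformer":
            if self.heads < 1 or self.dims_per_head < 1 or self.layers < 1:
                raise ValueError("heads, dims_per_head and layers must be positive")
        if self.ff_width is None:
            self.ff_width = 4 * self.embed_dim

    @property
    def embed_dim(self) -> int:
        return self.heads * self.dims_per_head

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionModelConfig":
        return cls(**d)


def tokenize(aa_seq: str, max_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Map an amino-acid string to (token ids, usable-site mask).

    Ambiguous sites (``X``) become PAD tokens with mask False; any other
    non-canonical symbol is an error.  Overlong sequences are an error.
    """
    if len(aa_seq) > max_len:
        raise ValueError(f"sequence length {len(aa_seq)} exceeds maximum {max_len}")
    tokens = np.empty(len(aa_seq), dtype=np.int64)
    mask = np.ones(len(aa_seq), dtype=bool)
    for i, a in enumerate(aa_seq):
        if a == AMBIGUOUS_AA:
            tokens[i] = PAD
            mask[i] = False
        elif a in AA_INDEX:
            tokens[i] = AA_INDEX[a]
        else:
            raise ValueError(f"unknown amino-acid symbol {a!r} at position {i}")
    return tokens, mask


def pad_token_batch(seqs: list[str], max_len: int):
    """Stack variable-length sequences into (tokens, site_mask) arrays."""
    L = max(len(s) for s in seqs)
    tokens = np.full((len(seqs), L), PAD, dtype=np.int64)
    mask = np.zeros((len(seqs), L), dtype=bool)
    for i, s in enumerate(seqs):
        tok, m = tokenize(s, max_len)
        tokens[i, : len(s)] = tok
        mask[i, : len(s)] = m
    return tokens, mask


def sinusoidal_positions(max_len: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding (max_len, dim)."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(np.float32)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class SelectionModel:
    """Shared surface: named parameters plus a batched differentiable forward."""

    config: SelectionModelConfig

    def parameters(self) -> list[Tensor]:
        return [t for _, t in sorted(self._params.items())]

    def named_parameters(self) -> dict[str, Tensor]:
        return dict(self._params)

    @property
    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, tokens: np.ndarray, key_mask: np.ndarray,
                train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError

    def factors_batch(self, seqs: list[str]) -> np.ndarray:
        """Evaluation-mode factors, (B, Lmax) with NaN at masked/padded sites."""
        tokens, mask = pad_token_batch(seqs, self.config.max_len)
        with _nn.no_grad():
            f = self.forward(tokens, mask, train=False).data.astype(np.float64)
        f = np.where(mask, f, np.nan)
        return f

    def factors(self, aa_seq: str) -> np.ndarray:
        """Per-site selection factors for one sequence (NaN at ambiguous sites)."""
        return self.factors_batch([aa_seq])[0, : len(aa_seq)]


def predict_selection(model: SelectionModel, parent_aa_seq: str) -> np.ndarray:
    """SelectionProfile for one parent amino-acid sequence.

    Deterministic in evaluation mode; one nonnegative factor per site, NaN at
    ambiguous (masked) sites.
    """
    return model.factors(parent_aa_seq)


class SingleFactorModel(SelectionModel):
    """One trainable factor applied to every site of every sequence."""

    def __init__(self, config: SelectionModelConfig, seed: int = 0):
        self.config = config
        self._params = {"theta": Tensor(np.array([1.0], dtype=np.float64), requires_grad=True)}

    def forward(self, tokens, key_mask, train=False, rng=None) -> Tensor:
        f1 = _nn.exp_wiggle_op(self._params["theta"], self.config.beta)  # (1,)
        ones = Tensor(np.ones(tokens.shape, dtype=np.float64))
        return _nn.mul(ones, f1)

    @property
    def factor(self) -> float:
        return float(exp_wiggle(self._params["theta"].data[0], self.config.beta))


class PerPositionModel(SelectionModel):
    """One trainable factor per alignment position, independent of content."""

    def __init__(self, config: SelectionModelConfig, seed: int = 0):
        self.config = config
        init = np.ones(config.max_len, dtype=np.float64)
        self._params = {"theta": Tensor(init, requires_grad=True)}

    def forward(self, tokens, key_mask, train=False, rng=None) -> Tensor:
        L = tokens.shape[1]
        theta_l = _nn.embedding(self._params["theta"], np.arange(L))  # (L,)
        f = _nn.exp_wiggle_op(theta_l, self.config.beta)
        ones = Tensor(np.ones(tokens.shape, dtype=np.float64))
        return _nn.mul(ones, f)


class TransformerModel(SelectionModel):
    """Pre-norm transformer encoder with a per-site scalar head and wiggle.

    Amino-acid embedding + fixed sinusoidal positions, ``layers`` encoder
    blocks (multi-head self-attention with key-padding masking, then a ReLU
    feed-forward), a final layer norm, and a linear head emitting one raw
    score per site.  The head bias starts at 1 so a fresh model predicts
    factors near 1 (neutrality).
    """

    def __init__(self, config: SelectionModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        D, F = config.embed_dim, config.ff_width
        p: dict[str, Tensor] = {}

        def weight(name, shape, std):
            p[name] = Tensor(rng.normal(0.0, std, size=shape).astype(np.float32),
                             requires_grad=True)

        def zeros(name, shape):
            p[name] = Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)

        def ones(name, shape):
            p[name] = Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)

        weight("embed", (PAD + 1, D), 0.02)
        for l in range(config.layers):
            for nm in ("wq", "wk", "wv", "wo"):
                weight(f"l{l}.{nm}", (D, D), D ** -0.5)
            zeros(f"l{l}.bo", (D,))
            weight(f"l{l}.ff1", (D, F), D ** -0.5)
            zeros(f"l{l}.bff1", (F,))
            weight(f"l{l}.ff2", (F, D), F ** -0.5)
            zeros(f"l{l}.bff2", (D,))
            for nm in ("ln1", "ln2"):
                ones(f"l{l}.{nm}.g", (D,))
                zeros(f"l{l}.{nm}.b", (D,))
        ones("lnf.g", (D,))
        zeros("lnf.b", (D,))
        weight("head.w", (D, 1), D ** -0.5)
        p["head.b"] = Tensor(np.array([1.0], dtype=np.float32), requires_grad=True)
        self._params = p
        self._pe = sinusoidal_positions(config.max_len, D)

    def forward(self, tokens, key_mask, train=False, rng=None) -> Tensor:
        cfg = self.config
        p = self._params
        B, L = tokens.shape
        H, dh = cfg.heads, cfg.dims_per_head
        D = cfg.embed_dim
        drop = cfg.dropout if train else 0.0
        if drop > 0 and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")

        h = _nn.add(_nn.embedding(p["embed"], tokens), Tensor(self._pe[None, :L, :]))
        # keys at padded positions are unreachable for attention; the bias add
        # is skipped entirely when nothing is padded (saves a (B,H,L,L) node)
        any_pad = not key_mask.all()
        bias = np.where(key_mask, 0.0, -1e9).astype(np.float32)[:, None, None, :]

        def lin(x, w, b=None):
            y = _nn.matmul(x, p[w])
            return _nn.add(y, p[b]) if b else y

        for l in range(cfg.layers):
            a = _nn.layer_norm(h, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])
            # 1/sqrt(dh) applied to q (B,L,D) rather than scores (B,H,L,L)
            q_flat = _nn.mul(lin(a, f"l{l}.wq"), Tensor(np.float32(dh ** -0.5)))
            q = _split_heads(q_flat, B, L, H, dh)
            k = _split_heads(lin(a, f"l{l}.wk"), B, L, H, dh)
            v = _split_heads(lin(a, f"l{l}.wv"), B, L, H, dh)
            scores = _nn.matmul(q, _nn.transpose(k, (0, 1, 3, 2)))
            if any_pad:
                scores = _nn.add(scores, Tensor(bias))
            attn = _nn.softmax(scores, axis=-1)
            if drop > 0:
                attn = _nn.dropout(attn, drop, rng)
            ctx = _nn.matmul(attn, v)  # (B, H, L, dh)
            ctx = _nn.reshape(_nn.transpose(ctx, (0, 2, 1, 3)), (B, L, D))
            ctx = lin(ctx, f"l{l}.wo", f"l{l}.bo")
            if drop > 0:
                ctx = _nn.dropout(ctx, drop, rng)
            h = _nn.add(h, ctx)

            a2 = _nn.layer_norm(h, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])
            ff = _nn.relu(lin(a2, f"l{l}.ff1", f"l{l}.bff1"))
            ff = lin(ff, f"l{l}.ff2", f"l{l}.bff2")
            if drop > 0:
                ff = _nn.dropout(ff, drop, rng)
            h = _nn.add(h, ff)

        h = _nn.layer_norm(h, p["lnf.g"], p["lnf.b"])
        z = _nn.reshape(lin(h, "head.w", "head.b"), (B, L))
        return _nn.exp_wiggle_op(z, cfg.beta)


def _split_heads(x, B, L, H, dh):
    return _nn.transpose(_nn.reshape(x, (B, L, H, dh)), (0, 2, 1, 3))


_FAMILIES = {
    "single": SingleFactorModel,
    "per_position": PerPositionModel,
    "transformer": TransformerModel,
}


def build_selection_model(config: SelectionModelConfig, seed: int = 0) -> SelectionModel:
    """Instantiate a selection model with reproducible seeded initialization."""
    return _FAMILIES[config.family](config, seed=seed)


# ---------------------------------------------------------------------------
# Checkpoints: single weights file + JSON config sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(model: SelectionModel, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(str(prefix) + ".npz",
             **{name: t.data for name, t in model.named_parameters().items()})
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(model.config.to_dict(), fh, indent=1)


def load_checkpoint(prefix) -> SelectionModel:
    prefix = str(prefix)
    with open(prefix + ".json") as fh:
        config = SelectionModelConfig.from_dict(json.load(fh))
    model = build_selection_model(config, seed=0)
    with np.load(prefix + ".npz") as npz:
        for name, t in model.named_parameters().items():
            t.data = npz[name].astype(t.data.dtype)
    return model
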