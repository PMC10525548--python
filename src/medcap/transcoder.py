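"""The generative caption model: a transformer encoder block over image
feature tokens and a transformer decoder block producing the word sequence.

Encoder block (no positional information — image tokens are treated as a
set): layer-normalise the feature sequence, project each token through a
ReLU dense layer to the model width, run multi-head self-attention, add the
attention output back to its input, and layer-normalise again.

Decoder block: token embedding plus learned positional embedding, causally
masked self-attention, cross-attention over the encoder output, a two-layer
feed-forward net (each sub-layer with residual + layer norm), and a softmax
over the vocabulary. Captions are produced by greedy decoding from START,
stopping at END or at the position limit; argmax ties resolve to the lowest
index.

Targets are the fixed-order slot sequence START exam body problem END.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from ._tensor import Tensor
from .errors import ValidationError

__all__ = [
    "Vocabulary",
    "TranscoderConfig",
    "EncoderState",
    "build_vocabulary",
    "EncoderBlock",
    "DecoderBlock",
    "CaptionModel",
    "generate_caption",
    "encode_targets",
    "save_checkpoint",
    "load_checkpoint",
]

PAD, UNK, START, END = "<pad>", "<unk>", "<start>", "<end>"
SPECIALS = (PAD, UNK, START, END)


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> index map; PAD=0, UNK=1, START=2, END=3."""

    tokens: tuple

    def __post_init__(self):
        if tuple(self.tokens[:4]) != SPECIALS:
            raise ValidationError("vocabulary must start with the reserved specials")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValidationError("vocabulary tokens must be unique")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self):
        return len(self.tokens)

    @property
    def pad_id(self):
        return 0

    @property
    def unk_id(self):
        return 1

    @property
    def start_id(self):
        return 2

    @property
    def end_id(self):
        return 3

    def encode(self, words) -> list[int]:
        return [self._index.get(w, self.unk_id) for w in words]

    def decode(self, indices) -> list[str]:
        out = []
        for i in indices:
            if not 0 <= i < len(self.tokens):
                raise ValidationError(f"token index {i} out of range")
            out.append(self.tokens[i])
        return out


def build_vocabulary(captions) -> Vocabulary:
    """Vocabulary from word sequences: specials first, then words by
    descending frequency with lexicographic tie-breaking."""
    freq = Counter(w for cap in captions for w in cap)
    words = sorted(freq, key=lambda w: (-freq[w], w))
    return Vocabulary(SPECIALS + tuple(words))


@dataclass(frozen=True)
class TranscoderConfig:
    vocab_size: int
    feature_dim: int
    embed_dim: int = 128
    n_heads: int = 2
    ff_dim: int = 256
    max_len: int = 8  # token positions incl. START and END
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValidationError("embed_dim must be divisible by n_heads")
        if self.max_len < 5:
            raise ValidationError("max_len must fit START + three slots + END")


@dataclass
class EncoderState:
    encoded: Tensor  # (..., n_tokens, embed_dim)


class EncoderBlock(nn.Module):
    def __init__(self, config: TranscoderConfig, rng: np.random.Generator):
        super().__init__()
        self.dense = nn.Dense(config.feature_dim, config.embed_dim, rng)
        self.attn = nn.MultiHeadAttention(config.embed_dim, config.n_heads, rng)

    def __call__(self, features) -> Tensor:
        x = features if isinstance(features, Tensor) else Tensor(features)
        if not np.isfinite(x.data).all():
            raise ValidationError("encoder input must be finite")
        h = self.dense(x.layer_norm()).relu()
        return (h + self.attn(h, h, h)).layer_norm()


class DecoderBlock(nn.Module):
    def __init__(self, config: TranscoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.embed_dim
        self.tok_embed = nn.Embedding(config.vocab_size, d, rng)
        self.pos_embed = nn.Embedding(config.max_len, d, rng)
        self.self_attn = nn.MultiHeadAttention(d, config.n_heads, rng)
        self.norm1 = nn.LayerNorm(d)
        self.cross_attn = nn.MultiHeadAttention(d, config.n_heads, rng)
        self.norm2 = nn.LayerNorm(d)
        self.ff1 = nn.Dense(d, config.ff_dim, rng)
        self.ff2 = nn.Dense(config.ff_dim, d, rng)
        self.norm3 = nn.LayerNorm(d)
        self.out = nn.Dense(d, config.vocab_size, rng)

    def logits(self, tokens, encoded: Tensor) -> Tensor:
        tokens = np.asarray(tokens)
        L = tokens.shape[-1]
        if L > self.config.max_len:
            raise ValidationError(f"sequence length {L} exceeds max_len")
        if tokens.min() < 0 or tokens.max() >= self.config.vocab_size:
            raise ValidationError("token index out of vocabulary range")
        x = self.tok_embed(tokens) + self.pos_embed(np.arange(L))
        causal = np.triu(np.full((L, L), -1e9), k=1)
        x = self.norm1(x + self.self_attn(x, x, x, mask=causal))
        x = self.norm2(x + self.cross_attn(x, encoded, encoded))
        x = self.norm3(x + self.ff2(self.ff1(x).relu()))
        return self.out(x)

    def __call__(self, tokens, encoder_state) -> Tensor:
        enc = encoder_state.encoded if isinstance(encoder_state, EncoderState) else encoder_state
        if not isinstance(enc, Tensor):
            enc = Tensor(enc)
        return self.logits(tokens, enc).softmax()


class CaptionModel(nn.Module):
    """Encoder + decoder over a fixed vocabulary."""

    def __init__(self, config: TranscoderConfig, vocabulary: Vocabulary):
        super().__init__()
        if len(vocabulary) != config.vocab_size:
            raise ValidationError("config.vocab_size must match the vocabulary")
        self.config = config
        self.vocabulary = vocabulary
        rng = np.random.default_rng(config.seed)
        self.encoder = EncoderBlock(config, rng)
        self.decoder = DecoderBlock(config, rng)

    def encode(self, features) -> EncoderState:
        return EncoderState(self.encoder(features))

    def logits(self, features, tokens) -> Tensor:
        return self.decoder.logits(tokens, self.encoder(features))


def generate_caption(features, model: CaptionModel, max_len: int | None = None) -> list[str]:
    """Greedy decode one image's feature sequence into caption words.

    Starts from START, appends the argmax token at each step (ties to the
    lowest index), stops at END or after max_len - 1 generated tokens.
    Returns the words without special tokens.
    """
    vocab = model.vocabulary
    cfg = model.config
    limit = cfg.max_len if max_len is None else min(max_len, cfg.max_len)
    feats = np.asarray(features, dtype=np.float64)
    if feats.ndim != 2:
        raise ValidationError("generate_caption expects a single (n_tokens, dim) sequence")
    state = model.encode(feats)
    seq = [vocab.start_id]
    while len(seq) < limit:
        probs = model.decoder(np.array(seq), state).data
        nxt = int(np.argmax(probs[-1]))
        if nxt == vocab.end_id:
            break
        seq.append(nxt)
    return [w for w in vocab.decode(seq[1:]) if w not in SPECIALS]


def encode_targets(vocabulary: Vocabulary, triples, max_len: int) -> np.ndarray:
    """Padded target matrix: each row is START, the slot words, END, PAD..."""
    rows = []
    for t in triples:
        ids = [vocabulary.start_id] + vocabulary.encode(list(t)) + [vocabulary.end_id]
        if len(ids) > max_len:
            raise ValidationError("target longer than max_len")
        rows.append(ids + [vocabulary.pad_id] * (max_len - len(ids)))
    return np.array(rows, dtype=np.int64)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: CaptionModel, path) -> None:
    """Single-file archive: versioned JSON header + weight arrays."""
    header = {
        "format": "medcap-checkpoint",
        "version": 1,
        "config": asdict(model.config),
        "vocabulary": list(model.vocabulary.tokens),
    }
    arrays = {k.replace(".", "__"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> CaptionModel:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__meta__"]).decode())
        if header.get("format") != "medcap-checkpoint":
            raise ValidationError("not a caption-model checkpoint")
        config = TranscoderConfig(**header["config"])
        model = CaptionModel(config, Vocabulary(tuple(header["vocabulary"])))
        state = {
            k.replace("__", "."): archive[k] for k in archive.files if k != "__meta__"
        }
        model.load_state_dict(state)
    return model
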