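"""Scaffold- and property-conditioned SMILES transformers.

Two models share one stack: a causal (autoregressive) decoder used for
conditional molecular generation, and a bidirectional encoder trained by
masked-token prediction whose [CLS]-position penultimate state is the
256-dimensional molecular feature vector consumed by the activity
predictors.

Architecture: token + learned position embeddings (decoder additionally
adds a scaffold-token embedding per position and a linear projection of the
ten normalized physicochemical properties, broadcast over positions), all
summed and passed through 10% dropout; eight pre-norm blocks (LayerNorm →
8-head scaled-dot-product attention → residual; LayerNorm → GeLU MLP with
10% dropout → residual) at embedding dimension 256; a final LayerNorm; and
a linear projection onto the vocabulary.  The encoder's feature vector is
taken after the final LayerNorm, immediately before that projection.

Defaults mirror the full-scale recipe (100 epochs, batch 512, lr 3e-4,
weight decay 0.1); every dimension and the optimizer budget scale down via
:class:`TransformerConfig` / :class:`TransformerTrainSettings` so the models
train on a desk-scale corpus on one CPU.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import features
from .nn import AdamW, Dropout, Embedding, LayerNorm, Linear, Module, Tensor, TransformerBlock
from .tokenizer import (
    MaskingPlan,
    TokenSequence,
    Vocabulary,
    apply_masking,
    encode_single,
    tokenize,
)

__all__ = [
    "TransformerConfig",
    "TransformerTrainSettings",
    "ConditioningBundle",
    "SmilesTransformer",
    "Checkpoint",
    "GenTrainExample",
    "prepare_generator_corpus",
    "train_autoregressive",
    "train_generator",
    "train_bidirectional",
    "extract_feature",
    "sample",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransformerConfig:
    vocab_size: int
    block_len: int = 135
    n_blocks: int = 8
    n_heads: int = 8
    embed_dim: int = 256
    dropout: float = 0.10
    n_properties: int = 10
    conditioned: bool = False

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if min(self.vocab_size, self.block_len, self.n_blocks, self.embed_dim) <= 0:
            raise ValueError("all transformer dimensions must be positive")


@dataclass
class ConditioningBundle:
    """Decoder conditioning: tokenized scaffold + raw 10-property vector."""

    scaffold_ids: np.ndarray      # (block_len,) int64
    property_values: np.ndarray   # (10,) raw scale; normalized inside the model


class SmilesTransformer(Module):
    def __init__(self, config: TransformerConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.embed_dim
        self.token_emb = Embedding(config.vocab_size, d, rng)
        self.pos_emb = Embedding(config.block_len, d, rng)
        if config.conditioned:
            self.scaffold_emb = Embedding(config.vocab_size, d, rng)
            self.prop_proj = Linear(config.n_properties, d, rng, init="transformer")
        self.emb_drop = Dropout(config.dropout)
        self.blocks = [
            TransformerBlock(d, config.n_heads, config.dropout, rng)
            for _ in range(config.n_blocks)
        ]
        self.ln_f = LayerNorm(d)
        self.head = Linear(d, config.vocab_size, rng, init="transformer")
        # property normalization statistics; set by the training loop
        self.prop_mean = np.zeros(config.n_properties)
        self.prop_std = np.ones(config.n_properties)

    # -- forward -----------------------------------------------------------
    def embed_inputs(self, ids: np.ndarray, scaffold_ids: np.ndarray | None = None,
                     properties: np.ndarray | None = None,
                     rng: np.random.Generator | None = None) -> Tensor:
        """Sum token, position and (optionally) conditioning embeddings."""
        ids = np.atleast_2d(np.asarray(ids, dtype=np.int64))
        b, t = ids.shape
        if t > self.config.block_len:
            raise ValueError(f"sequence length {t} exceeds block length {self.config.block_len}")
        x = self.token_emb(ids) + self.pos_emb(np.tile(np.arange(t), (b, 1)))
        if self.config.conditioned:
            if scaffold_ids is None or properties is None:
                raise ValueError("conditioned model requires scaffold_ids and properties")
            scaffold_ids = np.atleast_2d(np.asarray(scaffold_ids, dtype=np.int64))[:, :t]
            props = np.atleast_2d(np.asarray(properties, dtype=np.float64))
            normed = (props - self.prop_mean) / self.prop_std
            x = x + self.scaffold_emb(scaffold_ids)
            x = x + self.prop_proj(Tensor(normed)).reshape(b, 1, self.config.embed_dim)
        return self.emb_drop(x, rng)

    def forward_embedded(self, x: Tensor, causal: bool,
                         rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Run the block stack; returns (logits, penultimate states)."""
        for block in self.blocks:
            x = block(x, causal=causal, rng=rng)
        penult = self.ln_f(x)
        return self.head(penult), penult

    def forward(self, ids: np.ndarray, scaffold_ids: np.ndarray | None = None,
                properties: np.ndarray | None = None, causal: bool = True,
                rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        x = self.embed_inputs(ids, scaffold_ids, properties, rng)
        return self.forward_embedded(x, causal=causal, rng=rng)


# ---------------------------------------------------------------------------
# Checkpoints: a single self-contained archive (weights + config + vocabulary
# + property-normalization statistics + training metadata).

@dataclass
class Checkpoint:
    model: SmilesTransformer
    vocab: Vocabulary
    max_content_len: int
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        state = self.model.state_dict()
        meta = {
            "config": asdict(self.model.config),
            "vocab": {"token_to_id": self.vocab.token_to_id,
                      "min_count": self.vocab.min_count,
                      "dropped": list(self.vocab.dropped)},
            "max_content_len": self.max_content_len,
            "prop_mean": self.model.prop_mean.tolist(),
            "prop_std": self.model.prop_std.tolist(),
            "meta": self.meta,
        }
        arrays = {f"w::{k}": v for k, v in state.items()}
        np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        blob = np.load(Path(path))
        meta = json.loads(bytes(blob["__meta__"]).decode())
        config = TransformerConfig(**meta["config"])
        vocab = Vocabulary(token_to_id=meta["vocab"]["token_to_id"],
                           min_count=meta["vocab"]["min_count"],
                           dropped=tuple(meta["vocab"]["dropped"]))
        model = SmilesTransformer(config)
        model.load_state_dict({k[len("w::"):]: blob[k] for k in blob.files if k.startswith("w::")})
        model.prop_mean = np.array(meta["prop_mean"])
        model.prop_std = np.array(meta["prop_std"])
        model.eval()
        return cls(model=model, vocab=vocab, max_content_len=meta["max_content_len"],
                   meta=meta["meta"])


# ---------------------------------------------------------------------------
# Training.

@dataclass(frozen=True)
class TransformerTrainSettings:
    epochs: int = 100
    batch_size: int = 512
    lr: float = 3e-4
    weight_decay: float = 0.1
    seed: int = 0


@dataclass(frozen=True)
class GenTrainExample:
    seq: TokenSequence
    scaffold: TokenSequence
    properties: np.ndarray  # raw 10-property vector


def prepare_generator_corpus(smiles_list: Sequence[str], vocab: Vocabulary,
                             max_content_len: int = 133) -> list[GenTrainExample]:
    """Pair each encodable molecule with its scaffold block and properties."""
    out = []
    dropped = 0
    for smi in smiles_list:
        try:
            seq = encode_single(smi, vocab, max_content_len)
            scaffold = encode_single(features.murcko_scaffold(smi), vocab, max_content_len)
            props = features.physchem_properties(smi).as_array()
        except (ValueError, KeyError, features.ParseError):
            dropped += 1
            continue
        out.append(GenTrainExample(seq=seq, scaffold=scaffold, properties=props))
    if dropped:
        logger.info("prepare_generator_corpus: dropped %d molecules", dropped)
    return out


def _ce_loss(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean cross entropy over masked positions."""
    b, t, _ = logits.shape
    lp = logits.log_softmax(axis=-1)
    picked = lp[np.arange(b)[:, None], np.arange(t)[None, :], targets]
    weights = mask.astype(np.float64)
    return -(picked * Tensor(weights)).sum() / float(weights.sum())


def train_autoregressive(corpus: Sequence[GenTrainExample], vocab: Vocabulary,
                         config: TransformerConfig,
                         settings: TransformerTrainSettings = TransformerTrainSettings(),
                         ) -> tuple[Checkpoint, list[float]]:
    """Train the conditioned decoder for next-token prediction.

    The loss is cross entropy on targets shifted one position left, with pad
    targets excluded.  Property-normalization statistics (per-property mean
    and standard deviation over the training corpus) are computed here and
    stored in the checkpoint.  Returns the final-epoch checkpoint and the
    per-epoch mean training loss.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    if not config.conditioned:
        raise ValueError("the generator config must have conditioned=True")
    rng = np.random.default_rng(settings.seed)
    model = SmilesTransformer(config, seed=settings.seed)
    props = np.stack([ex.properties for ex in corpus])
    model.prop_mean = props.mean(axis=0)
    std = props.std(axis=0)
    model.prop_std = np.where(std > 0, std, 1.0)

    ids = np.stack([ex.seq.ids for ex in corpus])
    scaffold_ids = np.stack([ex.scaffold.ids for ex in corpus])
    inputs, targets = ids[:, :-1], ids[:, 1:]
    loss_mask = targets != vocab.pad_id

    optimizer = AdamW(model.parameters(), lr=settings.lr, weight_decay=settings.weight_decay)
    history = _run_epochs(
        model, optimizer, rng, settings,
        n_examples=len(corpus),
        step=lambda idx, step_rng: _ar_step(model, inputs[idx], scaffold_ids[idx],
                                            props[idx], targets[idx], loss_mask[idx], step_rng),
    )
    model.eval()
    ckpt = Checkpoint(model=model, vocab=vocab, max_content_len=ids.shape[1] - 2,
                      meta={"kind": "autoregressive", "epochs": settings.epochs,
                            "loss_history": history})
    return ckpt, history


def train_generator(smiles_list: Sequence[str], vocab: Vocabulary,
                    config: TransformerConfig,
                    settings: TransformerTrainSettings = TransformerTrainSettings(),
                    max_content_len: int = 133) -> tuple[Checkpoint, list[float]]:
    """Convenience wrapper: prepare conditioning, then train the generator."""
    corpus = prepare_generator_corpus(smiles_list, vocab, max_content_len)
    return train_autoregressive(corpus, vocab, config, settings)


def _ar_step(model, inp, scaf, props, tgt, mask, rng):
    logits, _ = model.forward(inp, scaf, props, causal=True, rng=rng)
    return _ce_loss(logits, tgt, mask)


def train_bidirectional(sequences: Sequence[TokenSequence], vocab: Vocabulary,
                        config: TransformerConfig,
                        settings: TransformerTrainSettings = TransformerTrainSettings(),
                        plan: MaskingPlan = MaskingPlan(),
                        ) -> tuple[Checkpoint, list[float]]:
    """Train the unconditioned encoder for masked-token prediction."""
    if not sequences:
        raise ValueError("empty training corpus")
    if config.conditioned:
        raise ValueError("the featurizer config must have conditioned=False")
    if plan.select_prob <= 0.0:
        raise ValueError("masked-token training requires select_prob > 0")
    rng = np.random.default_rng(settings.seed)
    model = SmilesTransformer(config, seed=settings.seed)
    optimizer = AdamW(model.parameters(), lr=settings.lr, weight_decay=settings.weight_decay)

    def step(idx, step_rng):
        batch = [sequences[i] for i in idx]
        corrupted, targets, masks = [], [], []
        for seq in batch:
            c, t, m = apply_masking(seq, vocab, step_rng, plan)
            corrupted.append(c)
            targets.append(t)
            masks.append(m)
        mask = np.stack(masks)
        if not mask.any():  # rare at tiny select_prob; skip batch
            return None
        logits, _ = model.forward(np.stack(corrupted), causal=False, rng=step_rng)
        return _ce_loss(logits, np.stack(targets), mask)

    history = _run_epochs(model, optimizer, rng, settings, n_examples=len(sequences), step=step)
    model.eval()
    ckpt = Checkpoint(model=model, vocab=vocab, max_content_len=sequences[0].block_len - 2,
                      meta={"kind": "bidirectional", "epochs": settings.epochs,
                            "loss_history": history})
    return ckpt, history


def _run_epochs(model, optimizer, rng, settings, n_examples, step) -> list[float]:
    history = []
    model.train()
    for epoch in range(settings.epochs):
        order = rng.permutation(n_examples)
        losses = []
        for start in range(0, n_examples, settings.batch_size):
            idx = order[start:start + settings.batch_size]
            loss = step(idx, rng)
            if loss is None:
                continue
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        logger.debug("epoch %d: loss %.4f", epoch, history[-1])
    return history


# ---------------------------------------------------------------------------
# Inference.

def extract_feature(checkpoint: Checkpoint, smiles: str) -> np.ndarray:
    """The [CLS]-position penultimate encoder state for one molecule.

    Deterministic: the model runs in eval mode (dropout disabled).
    """
    model = checkpoint.model
    if model.config.conditioned:
        raise ValueError("feature extraction requires the bidirectional (unconditioned) model")
    tokens = tokenize(smiles)
    oov = [t for t in tokens if t not in checkpoint.vocab.token_to_id]
    if oov:
        raise KeyError(f"tokens not in the featurizer vocabulary: {sorted(set(oov))}")
    seq = encode_single(smiles, checkpoint.vocab, checkpoint.max_content_len)
    model.eval()
    _, penult = model.forward(seq.ids[None, :], causal=False)
    return penult.data[0, 0].copy()


def sample(checkpoint: Checkpoint, scaffold_smiles: str, properties,
           n: int, rng: np.random.Generator, temperature: float = 1.0,
           top_k: int | None = None) -> list[str]:
    """Draw ``n`` sequences from the conditioned decoder; keep the valid ones.

    Sampling is autoregressive from [CLS] until [EOS] or the block limit;
    a string is kept when RDKit parses it.  The validity rate is logged.
    Fewer than ``n`` strings may be returned; callers loop as needed.
    """
    model = checkpoint.model
    vocab = checkpoint.vocab
    if not model.config.conditioned:
        raise ValueError("sampling requires the conditioned generator checkpoint")
    if hasattr(properties, "as_array"):
        properties = properties.as_array()
    properties = np.asarray(properties, dtype=np.float64)
    scaffold = encode_single(scaffold_smiles, vocab, checkpoint.max_content_len)
    model.eval()

    t_max = model.config.block_len - 1  # decoder input length (shifted by one)
    ids = np.full((n, t_max), vocab.pad_id, dtype=np.int64)
    ids[:, 0] = vocab.cls_id
    scaf = np.tile(scaffold.ids[:t_max], (n, 1))
    props = np.tile(properties, (n, 1))
    finished = np.zeros(n, dtype=bool)
    lengths = np.full(n, t_max, dtype=np.int64)
    for t in range(1, t_max):
        logits, _ = model.forward(ids, scaf, props, causal=True)
        step_logits = logits.data[:, t - 1, :]
        if temperature <= 1e-6:
            nxt = step_logits.argmax(axis=-1)
        else:
            z = step_logits / temperature
            if top_k is not None:
                kth = np.partition(z, -top_k, axis=-1)[:, -top_k][:, None]
                z = np.where(z < kth, -np.inf, z)
            z = z - z.max(axis=-1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=-1, keepdims=True)
            nxt = np.array([rng.choice(len(row), p=row) for row in p])
        newly_done = (~finished) & (nxt == vocab.eos_id)
        lengths[newly_done] = t
        still = ~finished & ~newly_done
        ids[still, t] = nxt[still]
        finished |= newly_done
        if finished.all():
            break
    id_to_token = vocab.id_to_token
    out = []
    n_valid = 0
    for row, ln, done in zip(ids, lengths, finished):
        content = row[1:ln] if done else row[1:]
        content = content[content != vocab.pad_id]
        smi = "".join(id_to_token[int(i)] for i in content)
        if not smi:
            continue
        try:
            out.append(features.canonicalize(smi))
            n_valid += 1
        except features.ParseError:
            continue
    logger.info("sample: %d/%d generated strings were valid SMILES", n_valid, n)
    return out
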