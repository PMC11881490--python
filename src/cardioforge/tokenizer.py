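"""SMILES tokenization, vocabulary construction and corpus preprocessing.

A SMILES string is split into chemically meaningful tokens: bracket atoms
(``[nH]``, ``[N+]``, ``[C@@H]``) and two-letter organic-subset elements
(``Cl``, ``Br``) are single tokens, as are ``%nn`` two-digit ring-bond
labels; every other character stands alone.  Joining the tokens always
reproduces the input string exactly.

A corpus is reduced to sequences of integer ids over a vocabulary built
from token counts (tokens rarer than ``min_count`` are dropped together
with the molecules containing them).  Each surviving molecule is laid out
as ``[CLS] <content> [EOS] <pad>...`` in a constant-length block: content
is padded to ``max_content_len`` (default 133) slots, so the default total
block length is 135.  Masked-token corruption for bidirectional training
selects each content token independently (default probability 0.15) and
replaces it with the mask token, a random vocabulary token, or leaves it
unchanged (0.8 / 0.1 / 0.1).
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PAD", "CLS", "EOS", "MASK",
    "TokenizationError",
    "tokenize", "detokenize",
    "Vocabulary", "build_vocabulary",
    "TokenSequence", "preprocess_corpus", "encode_single",
    "split_corpus",
    "MaskingPlan", "apply_masking",
    "read_smiles_file",
]

logger = logging.getLogger(__name__)

PAD, CLS, EOS, MASK = "<pad>", "[CLS]", "[EOS]", "<MASK>"
SPECIALS = (PAD, CLS, EOS, MASK)

# Bracket atoms first, then two-letter elements, then %nn ring closures,
# then any single SMILES character.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOPSFIbcnops]|[0-9]|[=#$:/\\.\-+()@*~])"
)


class TokenizationError(ValueError):
    """Raised when a SMILES string contains an unrecognizable character."""


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens whose concatenation reproduces it."""
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"unparseable character {smiles[pos]!r} at offset {pos} in {smiles!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


@dataclass(frozen=True)
class Vocabulary:
    """Token↔id mapping with four reserved special tokens at ids 0–3."""

    token_to_id: dict[str, int]
    min_count: int = 1
    dropped: tuple[str, ...] = ()

    def __post_init__(self):
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("vocabulary ids must be contiguous from 0")
        for s in SPECIALS:
            if s not in self.token_to_id:
                raise ValueError(f"special token {s} missing from vocabulary")

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    @property
    def content_ids(self) -> list[int]:
        special_ids = {self.token_to_id[s] for s in SPECIALS}
        return [i for i in self.token_to_id.values() if i not in special_ids]

    def encode_tokens(self, tokens: list[str]) -> list[int]:
        try:
            return [self.token_to_id[t] for t in tokens]
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "token_to_id": self.token_to_id,
            "min_count": self.min_count,
            "dropped": list(self.dropped),
            "specials": {"pad": PAD, "cls": CLS, "eos": EOS, "mask": MASK},
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        blob = json.loads(Path(path).read_text())
        return cls(token_to_id=blob["token_to_id"], min_count=blob["min_count"],
                   dropped=tuple(blob.get("dropped", ())))


def build_vocabulary(corpus: list[str], min_count: int = 1) -> Vocabulary:
    """Count tokens over ``corpus`` and keep those occurring >= ``min_count``.

    The four specials occupy ids 0–3; surviving tokens follow in order of
    decreasing frequency (ties broken lexicographically) so ids are stable
    across runs.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for smi in corpus:
        counts.update(tokenize(smi))
    kept = sorted((t for t, c in counts.items() if c >= min_count),
                  key=lambda t: (-counts[t], t))
    dropped = tuple(sorted(t for t, c in counts.items() if c < min_count))
    if not kept:
        raise ValueError(
            f"no token occurs >= {min_count} times; vocabulary would be empty"
        )
    if dropped:
        logger.info("vocabulary: dropped %d rare tokens: %s", len(dropped), dropped)
    token_to_id = {s: i for i, s in enumerate(SPECIALS)}
    for t in kept:
        token_to_id[t] = len(token_to_id)
    return Vocabulary(token_to_id=token_to_id, min_count=min_count, dropped=dropped)


@dataclass(frozen=True)
class TokenSequence:
    """A fixed-length id block: ``[CLS] content [EOS] pads``."""

    ids: np.ndarray  # (block_len,) int64
    content_len: int
    smiles: str = ""

    @property
    def block_len(self) -> int:
        return len(self.ids)


def encode_single(smiles: str, vocab: Vocabulary, max_content_len: int = 133) -> TokenSequence:
    """Encode one SMILES into a block, raising on OOV or over-length input.

    The empty string (an acyclic molecule's scaffold) encodes to a block
    with no content tokens.
    """
    tokens = tokenize(smiles) if smiles else []
    if len(tokens) > max_content_len:
        raise ValueError(f"{smiles!r} has {len(tokens)} tokens (> {max_content_len})")
    ids = vocab.encode_tokens(tokens)
    block = np.full(max_content_len + 2, vocab.pad_id, dtype=np.int64)
    block[0] = vocab.cls_id
    block[1:1 + len(ids)] = ids
    block[1 + len(ids)] = vocab.eos_id
    return TokenSequence(ids=block, content_len=len(ids), smiles=smiles)


def preprocess_corpus(corpus: list[str], vocab: Vocabulary,
                      max_content_len: int = 133) -> list[TokenSequence]:
    """Encode every in-vocabulary, in-length molecule; drop (and count) the rest."""
    out: list[TokenSequence] = []
    n_oov = n_long = 0
    for smi in corpus:
        try:
            tokens = tokenize(smi)
        except TokenizationError:
            n_oov += 1
            continue
        if len(tokens) > max_content_len:
            n_long += 1
            continue
        if any(t not in vocab.token_to_id for t in tokens):
            n_oov += 1
            continue
        out.append(encode_single(smi, vocab, max_content_len))
    if n_oov or n_long:
        logger.info("preprocess_corpus: dropped %d out-of-vocabulary and %d over-length molecules",
                    n_oov, n_long)
    return out


def split_corpus(sequences: list, train_frac: float = 0.95,
                 seed: int | None = 0) -> tuple[list, list]:
    """Random disjoint train/validation partition, deterministic per seed."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sequences))
    n_train = int(round(train_frac * len(sequences)))
    n_train = min(max(n_train, 1), len(sequences) - 1)
    train_idx = sorted(order[:n_train])
    val_idx = sorted(order[n_train:])
    return [sequences[i] for i in train_idx], [sequences[i] for i in val_idx]


@dataclass(frozen=True)
class MaskingPlan:
    """Per-token Bernoulli selection followed by a mask/random/keep draw."""

    select_prob: float = 0.15
    mask_frac: float = 0.8
    random_frac: float = 0.1
    keep_frac: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.select_prob <= 1.0:
            raise ValueError("select_prob must be a probability")
        total = self.mask_frac + self.random_frac + self.keep_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mask/random/keep fractions must sum to 1, got {total}")


def apply_masking(seq: TokenSequence, vocab: Vocabulary, rng: np.random.Generator,
                  plan: MaskingPlan = MaskingPlan()) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Corrupt a sequence for masked-token training.

    Returns ``(corrupted_ids, target_ids, loss_mask)``; the loss mask marks
    exactly the selected content positions.  Specials and pads are never
    selected.
    """
    ids = seq.ids.copy()
    target = seq.ids.copy()
    loss_mask = np.zeros(len(ids), dtype=bool)
    if seq.content_len == 0 or plan.select_prob == 0.0:
        return ids, target, loss_mask
    content_slice = slice(1, 1 + seq.content_len)
    selected = rng.random(seq.content_len) < plan.select_prob
    positions = np.flatnonzero(selected) + content_slice.start
    loss_mask[positions] = True
    if len(positions) == 0:
        return ids, target, loss_mask
    action = rng.choice(3, size=len(positions),
                        p=[plan.mask_frac, plan.random_frac, plan.keep_frac])
    content_pool = np.array(vocab.content_ids, dtype=np.int64)
    for pos, act in zip(positions, action):
        if act == 0:
            ids[pos] = vocab.mask_id
        elif act == 1:
            ids[pos] = content_pool[rng.integers(len(content_pool))]
        # act == 2: keep unchanged
    return ids, target, loss_mask


def read_smiles_file(path: str | Path) -> list[str]:
    """Read a .smi (one SMILES per line) or CSV with a ``smiles`` column."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        import pandas as pd

        frame = pd.read_csv(path)
        if "smiles" not in frame.columns:
            raise ValueError(f"{path} has no 'smiles' column")
        return frame["smiles"].astype(str).tolist()
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]
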