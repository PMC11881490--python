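"""Tri-modal cardiac ion-channel activity predictors.

One architecture serves both blocker classification and pIC50 regression
for each channel (hERG, NaV1.5, CaV1.2).  Three encodings of a molecule are
produced and fused:

* the 256-d feature vector from the pretrained bidirectional SMILES
  transformer, through a two-layer feed-forward branch
  (linear → batch-norm → ReLU → 50% dropout, twice);
* the 1024-bit ECFP4 fingerprint, through an identical branch;
* the 14-feature molecular graph, through two graph-attention convolutions
  (self-loops added, ReLU between, softmax attention over each atom's
  neighborhood) followed by global add pooling.

Branch outputs are concatenated and passed through a final feed-forward
head (linear → batch-norm → ReLU → 50% dropout → linear) onto one output:
a blocker logit (classification) or a predicted pIC50 (regression).

Training uses AdamW (lr 3e-4, weight decay 1e-4) with an L1 penalty
(coefficient 1e-4), gradient clipping at global norm 5.0, learning-rate
halving after 10 epochs without validation improvement, and snapshot
selection by best validation accuracy (classification) or Pearson r
(regression).  A compound measured several times is labeled with the mean
of its replicate pIC50 values after discarding those above the replicate
set's 95th percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import features, metrics
from .nn import (
    AdamW,
    BatchNorm1d,
    Dropout,
    GATConv,
    Linear,
    Module,
    ReduceLROnPlateau,
    Tensor,
    clip_grad_norm,
    concat,
    segment_sum,
)
from .transformer import Checkpoint, extract_feature

__all__ = [
    "BLOCKER_THRESHOLD",
    "PredictorConfig",
    "TrainRecipe",
    "ActivityRecord",
    "aggregate_labels",
    "TriModalFeatures",
    "featurize",
    "CardiacActivityPredictor",
    "train_predictor",
    "TrainedPredictor",
    "predict",
    "classify",
]

logger = logging.getLogger(__name__)

# pIC50 >= 5.0 (IC50 <= 10 uM) defines a channel blocker.
BLOCKER_THRESHOLD = 5.0

Channel = Literal["hERG", "NaV1.5", "CaV1.2"]


@dataclass(frozen=True)
class PredictorConfig:
    task: Literal["classification", "regression"] = "classification"
    channel: Channel = "hERG"
    use_transformer_branch: bool = True
    use_fingerprint_branch: bool = True
    use_graph_branch: bool = True
    transformer_dim: int = 256
    branch_hidden: int = 128
    gat_hidden: int = 64
    gat_heads: int = 8
    fused_hidden: int = 256
    dropout: float = 0.5

    def __post_init__(self):
        if not (self.use_transformer_branch or self.use_fingerprint_branch
                or self.use_graph_branch):
            raise ValueError("at least one branch must be enabled")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainRecipe:
    epochs: int = 200               # 200 classification / 100 regression
    batch_size: int = 32
    lr: float = 3e-4
    weight_decay: float = 1e-4
    l1_coeff: float = 1e-4
    plateau_patience: int = 10
    grad_clip_norm: float = 5.0
    val_frac: float = 0.2           # used when no validation set is supplied

    def __post_init__(self):
        if min(self.epochs, self.batch_size) <= 0 or self.lr <= 0:
            raise ValueError("epochs, batch size and learning rate must be positive")


@dataclass(frozen=True)
class ActivityRecord:
    smiles: str
    pic50: float | None = None
    label: int | None = None        # 1 = blocker
    channel: Channel = "hERG"

    def resolved_label(self) -> int:
        if self.label is not None:
            return int(self.label)
        if self.pic50 is None:
            raise ValueError(f"record {self.smiles} has neither pIC50 nor label")
        return int(self.pic50 >= BLOCKER_THRESHOLD)


def aggregate_labels(replicates: Sequence[float]) -> float:
    """Replicate pIC50 aggregation: trim above the 95th percentile, then mean.

    High outliers dominate replicate IC50 measurements, so the trim is
    one-sided (upper).  A single replicate is returned unchanged.
    """
    reps = np.asarray(list(replicates), dtype=np.float64)
    if reps.size == 0:
        raise ValueError("no replicates to aggregate")
    if reps.size == 1:
        return float(reps[0])
    cutoff = np.percentile(reps, 95)
    kept = reps[reps <= cutoff]
    return float(kept.mean())


# ---------------------------------------------------------------------------
# Featurization.

@dataclass
class TriModalFeatures:
    transformer_vec: np.ndarray | None
    fingerprint: np.ndarray | None
    graph: features.MolGraph | None
    smiles: str = ""


def featurize(smiles: str, featurizer: Checkpoint | None,
              config: PredictorConfig) -> TriModalFeatures:
    """Compute the enabled molecular representations (cached per featurizer).

    The cache lives on the featurizer checkpoint object, so feature vectors
    are reused across epochs and across predictors sharing one featurizer.
    """
    key = (smiles, config.use_transformer_branch, config.use_fingerprint_branch,
           config.use_graph_branch)
    cache = featurizer.__dict__.setdefault("_feature_cache", {}) if featurizer is not None else None
    if cache is not None and key in cache:
        return cache[key]
    try:
        result = TriModalFeatures(
            transformer_vec=(extract_feature(featurizer, smiles)
                             if config.use_transformer_branch else None),
            fingerprint=features.ecfp4(smiles) if config.use_fingerprint_branch else None,
            graph=features.build_graph(smiles) if config.use_graph_branch else None,
            smiles=smiles,
        )
    except Exception as exc:
        raise features.FeaturizationError(f"featurization failed for {smiles!r}: {exc}") from exc
    if cache is not None:
        cache[key] = result
    return result


def _batch_graphs(graphs: Sequence[features.MolGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge graphs into one block-diagonal graph: (nodes, edge_index, graph_ids)."""
    feats, edges, gids = [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        feats.append(g.node_features)
        edges.append(g.directed_edge_index(self_loops=True) + offset)
        gids.append(np.full(g.n_nodes, gi, dtype=np.int64))
        offset += g.n_nodes
    return (np.concatenate(feats), np.concatenate(edges, axis=1), np.concatenate(gids))


# ---------------------------------------------------------------------------
# Model.

class _BranchMLP(Module):
    """Two (linear → batch-norm → ReLU → dropout) layers."""

    def __init__(self, in_dim: int, hidden: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_dim, hidden, rng)
        self.bn1 = BatchNorm1d(hidden)
        self.fc2 = Linear(hidden, hidden, rng)
        self.bn2 = BatchNorm1d(hidden)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = self.drop(self.bn1(self.fc1(x)).relu(), rng)
        x = self.drop(self.bn2(self.fc2(x)).relu(), rng)
        return x


class _GraphBranch(Module):
    """Two GAT convolutions with ReLU between, then global add pooling."""

    def __init__(self, in_dim: int, hidden: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = GATConv(in_dim, hidden, heads, rng, concat=True)
        self.conv2 = GATConv(hidden * heads, hidden, heads, rng, concat=False)
        self.out_dim = hidden

    def __call__(self, node_feats: np.ndarray, edge_index: np.ndarray,
                 graph_ids: np.ndarray, n_graphs: int) -> Tensor:
        if len(node_feats) == 0:
            raise ValueError("empty graph batch")
        h = self.conv1(Tensor(node_feats), edge_index).relu()
        h = self.conv2(h, edge_index)
        return segment_sum(h, graph_ids, n_graphs)


class CardiacActivityPredictor(Module):
    def __init__(self, config: PredictorConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        fused_in = 0
        if config.use_transformer_branch:
            self.transformer_branch = _BranchMLP(config.transformer_dim, config.branch_hidden,
                                                 config.dropout, rng)
            fused_in += config.branch_hidden
        if config.use_fingerprint_branch:
            self.fingerprint_branch = _BranchMLP(features.FINGERPRINT_BITS, config.branch_hidden,
                                                 config.dropout, rng)
            fused_in += config.branch_hidden
        if config.use_graph_branch:
            self.graph_branch = _GraphBranch(len(features.NODE_FEATURE_NAMES),
                                             config.gat_hidden, config.gat_heads, rng)
            fused_in += self.graph_branch.out_dim
        self.fused_in = fused_in
        self.head_fc = Linear(fused_in, config.fused_hidden, rng)
        self.head_bn = BatchNorm1d(config.fused_hidden)
        self.head_drop = Dropout(config.dropout)
        self.head_out = Linear(config.fused_hidden, 1, rng)

    def forward(self, batch: Sequence[TriModalFeatures],
                rng: np.random.Generator | None = None) -> Tensor:
        parts = []
        if self.config.use_transformer_branch:
            tv = np.stack([f.transformer_vec for f in batch])
            parts.append(self.transformer_branch(Tensor(tv), rng))
        if self.config.use_fingerprint_branch:
            fp = np.stack([f.fingerprint for f in batch])
            parts.append(self.fingerprint_branch(Tensor(fp), rng))
        if self.config.use_graph_branch:
            nodes, edge_index, gids = _batch_graphs([f.graph for f in batch])
            parts.append(self.graph_branch(nodes, edge_index, gids, len(batch)))
        fused = parts[0] if len(parts) == 1 else concat(parts, axis=-1)
        h = self.head_drop(self.head_bn(self.head_fc(fused)).relu(), rng)
        return self.head_out(h).reshape(len(batch))


# ---------------------------------------------------------------------------
# Training.

@dataclass
class TrainedPredictor:
    model: CardiacActivityPredictor
    config: PredictorConfig
    best_metric: float
    history: dict = field(default_factory=dict)


def _l1_penalty(model: Module, coeff: float) -> Tensor | float:
    if coeff == 0.0:
        return 0.0
    total = None
    for _, p in model.named_parameters():
        term = p.abs().sum()
        total = term if total is None else total + term
    return total * coeff


def train_predictor(records: Sequence[ActivityRecord], featurizer: Checkpoint | None,
                    config: PredictorConfig, recipe: TrainRecipe | None = None,
                    seed: int = 0,
                    val_records: Sequence[ActivityRecord] | None = None) -> TrainedPredictor:
    """Train a channel predictor; returns the best-validation-epoch snapshot."""
    if recipe is None:
        recipe = TrainRecipe(epochs=200 if config.task == "classification" else 100)
    rng = np.random.default_rng(seed)
    records = list(records)
    if val_records is None:
        order = rng.permutation(len(records))
        n_val = max(1, int(round(recipe.val_frac * len(records))))
        val_records = [records[i] for i in order[:n_val]]
        records = [records[i] for i in order[n_val:]]
    if config.task == "classification":
        train_labels = {r.resolved_label() for r in records}
        if len(train_labels) < 2:
            raise ValueError("classification training set contains a single class")

    def targets_of(recs):
        if config.task == "classification":
            return np.array([r.resolved_label() for r in recs], dtype=np.float64)
        missing = [r.smiles for r in recs if r.pic50 is None]
        if missing:
            raise ValueError(f"regression requires pIC50 labels; missing for {missing[:3]}")
        return np.array([r.pic50 for r in recs], dtype=np.float64)

    x_train = [featurize(r.smiles, featurizer, config) for r in records]
    x_val = [featurize(r.smiles, featurizer, config) for r in val_records]
    y_train = targets_of(records)
    y_val = targets_of(val_records)

    model = CardiacActivityPredictor(config, seed=seed)
    optimizer = AdamW(model.parameters(), lr=recipe.lr, weight_decay=recipe.weight_decay)
    scheduler = ReduceLROnPlateau(optimizer, patience=recipe.plateau_patience)
    best_metric = -np.inf
    best_state = model.state_dict()
    history = {"train_loss": [], "val_loss": [], "val_metric": []}

    for epoch in range(recipe.epochs):
        model.train()
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for start in range(0, len(order), recipe.batch_size):
            idx = order[start:start + recipe.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs more than one sample
            batch = [x_train[i] for i in idx]
            out = model.forward(batch, rng)
            y = Tensor(y_train[idx])
            if config.task == "classification":
                # stable BCE-with-logits: softplus(z) - y*z
                loss = (out.softplus() - y * out).mean()
            else:
                diff = out - y
                loss = (diff * diff).mean()
            loss = loss + _l1_penalty(model, recipe.l1_coeff)
            optimizer.zero_grad()
            loss.backward()
            clip_grad_norm(model.parameters(), recipe.grad_clip_norm)
            optimizer.step()
            epoch_losses.append(float(loss.data))

        model.eval()
        val_out = model.forward(x_val).data
        if config.task == "classification":
            val_loss = float(np.mean(np.logaddexp(0.0, val_out) - y_val * val_out))
            val_metric = float(np.mean((val_out >= 0.0) == (y_val > 0.5)))
        else:
            val_loss = float(np.mean((val_out - y_val) ** 2))
            val_metric = (metrics.pearson(y_val, val_out)
                          if np.std(val_out) > 0 and np.std(y_val) > 0 else -1.0)
        scheduler.step(val_loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["val_metric"].append(val_metric)
        if val_metric > best_metric:
            best_metric = val_metric
            best_state = model.state_dict()
        logger.debug("epoch %d loss %.4f val %.4f metric %.4f",
                     epoch, history["train_loss"][-1], val_loss, val_metric)

    model.load_state_dict(best_state)
    model.eval()
    return TrainedPredictor(model=model, config=config, best_metric=best_metric,
                            history=history)


# ---------------------------------------------------------------------------
# Inference.

def predict(trained: TrainedPredictor, smiles: str,
            featurizer: Checkpoint | None) -> float:
    """Blocker probability (classification) or predicted pIC50 (regression)."""
    return predict_batch(trained, [smiles], featurizer)[0]


def predict_batch(trained: TrainedPredictor, smiles_list: Sequence[str],
                  featurizer: Checkpoint | None) -> np.ndarray:
    model = trained.model
    model.eval()
    batch = [featurize(s, featurizer, trained.config) for s in smiles_list]
    out = model.forward(batch).data
    if trained.config.task == "classification":
        return 1.0 / (1.0 + np.exp(-out))
    return out


def classify(trained: TrainedPredictor, smiles: str, featurizer: Checkpoint | None,
             threshold: float = BLOCKER_THRESHOLD) -> str:
    """Label a molecule ``"blocker"`` / ``"non-blocker"``.

    Regressors compare predicted pIC50 to ``threshold`` (>= is a blocker);
    classifiers compare the blocker probability to 0.5.
    """
    score = predict(trained, smiles, featurizer)
    if trained.config.task == "regression":
        return "blocker" if score >= threshold else "non-blocker"
    return "blocker" if score >= 0.5 else "non-blocker"
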