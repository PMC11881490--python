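"""The end-to-end re-engineering workflow.

Given a channel-active input molecule, the pipeline

1. computes the input's Murcko scaffold and ten physicochemical properties,
2. samples the conditioned generator in batches, keeping valid, unique
   molecules (the input itself is excluded),
3. scores every candidate with the requested channel predictors and keeps
   those satisfying all constraints (e.g. predicted hERG pIC50 below 6.0,
   or a one-log-unit improvement over the input's predicted value),
4. repeats until the requested number of candidates is accepted (or an
   attempt cap is reached), and
5. ranks the accepted candidates by cosine similarity between z-scored,
   mutual-information-pruned wide descriptor vectors of the input and each
   candidate.

A PCA projection of the ten conditioning properties over {input ∪
candidates ∪ background corpus} supports chemical-space visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import features
from .predictors import TrainedPredictor, predict_batch
from .transformer import Checkpoint, sample

__all__ = [
    "ChannelConstraint",
    "Candidate",
    "CandidateSet",
    "apply_constraints",
    "reengineer",
    "rank_candidates",
    "chem_space_projection",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChannelConstraint:
    """Acceptance rule for one channel's predicted activity.

    ``classify-nonblocker`` accepts predicted non-blockers (classifier
    probability < 0.5).  ``pIC50-range`` accepts predicted pIC50 in
    [low, high); an upper-bound-only filter is ``low=-inf``.
    """

    channel: str
    mode: Literal["classify-nonblocker", "pIC50-range"] = "pIC50-range"
    low: float = -np.inf
    high: float = np.inf

    def __post_init__(self):
        if self.mode == "pIC50-range" and not self.low < self.high:
            raise ValueError(f"constraint bounds must satisfy low < high, got [{self.low}, {self.high})")

    def accepts(self, prediction: float) -> bool:
        if self.mode == "classify-nonblocker":
            return prediction < 0.5
        return self.low <= prediction < self.high


def apply_constraints(predictions: dict[str, float],
                      constraints: Sequence[ChannelConstraint]) -> bool:
    """Conjunction of all constraints; missing channel predictions are errors."""
    for c in constraints:
        if c.channel not in predictions:
            raise KeyError(f"no prediction available for constrained channel {c.channel}")
        if not c.accepts(predictions[c.channel]):
            return False
    return True


@dataclass(frozen=True)
class Candidate:
    smiles: str
    predictions: dict[str, float]
    similarity: float


@dataclass
class CandidateSet:
    input_smiles: str
    input_scaffold: str
    input_properties: np.ndarray
    candidates: list[Candidate]
    n_sampled: int = 0
    n_valid: int = 0
    n_unique: int = 0
    n_accepted: int = 0

    @property
    def validity_rate(self) -> float:
        return self.n_valid / self.n_sampled if self.n_sampled else float("nan")

    @property
    def filter_pass_rate(self) -> float:
        return self.n_accepted / self.n_unique if self.n_unique else float("nan")


def reengineer(input_smiles: str, constraints: Sequence[ChannelConstraint],
               n_candidates: int, generator: Checkpoint,
               predictors: dict[str, TrainedPredictor],
               featurizer: Checkpoint | None, rng: np.random.Generator,
               batch_size: int = 64, max_attempts: int | None = None,
               temperature: float = 1.0,
               mi_threshold: float = 0.9) -> CandidateSet:
    """Generate, filter and rank analogues of ``input_smiles``.

    Returns candidates sorted by descending descriptor-space cosine
    similarity to the input.  If the attempt cap is hit first, a partial
    set is returned with a warning.
    """
    constraints = list(constraints)
    if not constraints:
        raise ValueError("at least one channel constraint is required")
    for c in constraints:
        if c.channel not in predictors:
            raise KeyError(f"no predictor supplied for constrained channel {c.channel}")
    canon_input = features.canonicalize(input_smiles)
    scaffold = features.murcko_scaffold(canon_input)
    props = features.physchem_properties(canon_input)
    if max_attempts is None:
        max_attempts = max(1000 * n_candidates, 1000)

    result = CandidateSet(input_smiles=canon_input, input_scaffold=scaffold,
                          input_properties=props.as_array(), candidates=[])
    accepted: dict[str, dict[str, float]] = {}
    seen: set[str] = {canon_input}
    while len(accepted) < n_candidates and result.n_sampled < max_attempts:
        n_draw = min(batch_size, max_attempts - result.n_sampled)
        batch = sample(generator, scaffold, props, n_draw, rng, temperature=temperature)
        result.n_sampled += n_draw
        result.n_valid += len(batch)
        fresh = []
        for smi in batch:
            if smi not in seen:
                seen.add(smi)
                fresh.append(smi)
        result.n_unique += len(fresh)
        if not fresh:
            continue
        channel_preds = {}
        for channel in {c.channel for c in constraints}:
            channel_preds[channel] = predict_batch(predictors[channel], fresh, featurizer)
        for i, smi in enumerate(fresh):
            preds = {ch: float(v[i]) for ch, v in channel_preds.items()}
            if apply_constraints(preds, constraints):
                accepted[smi] = preds
                if len(accepted) >= n_candidates:
                    break
    result.n_accepted = len(accepted)
    if len(accepted) < n_candidates:
        logger.warning("reengineer: attempt cap %d reached with %d/%d candidates",
                       max_attempts, len(accepted), n_candidates)
    if accepted:
        order, sims = rank_candidates(canon_input, list(accepted), mi_threshold=mi_threshold)
        result.candidates = [
            Candidate(smiles=smi, predictions=accepted[smi], similarity=sim)
            for smi, sim in zip(order, sims)
        ]
    return result


def rank_candidates(input_smiles: str, candidate_smiles: Sequence[str],
                    mi_threshold: float = 0.9) -> tuple[list[str], list[float]]:
    """Rank candidates by cosine similarity of processed descriptor vectors.

    The wide descriptor matrix over {input ∪ candidates} is z-scored per
    column, pruned of mutually redundant columns (normalized MI above
    ``mi_threshold``), and candidates are sorted by descending cosine
    similarity to the input's processed vector.  Ties break by canonical
    SMILES order.
    """
    all_smiles = [input_smiles, *candidate_smiles]
    matrix = features.descriptor_matrix(all_smiles)
    std = matrix.std(axis=0)
    mean = matrix.mean(axis=0)
    scaled = (matrix - mean) / np.where(std > 0, std, 1.0)
    keep = features.prune_redundant(scaled, mi_threshold=mi_threshold)
    pruned = scaled[:, keep]
    sims = []
    for i, smi in enumerate(candidate_smiles, start=1):
        sims.append(features.cosine_similarity(pruned[0], pruned[i]))
    order = sorted(range(len(candidate_smiles)),
                   key=lambda i: (-sims[i], candidate_smiles[i]))
    return [candidate_smiles[i] for i in order], [sims[i] for i in order]


def chem_space_projection(smiles_groups: dict[str, Sequence[str]],
                          ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Project molecules into the top-2 PCA plane of the ten properties.

    ``smiles_groups`` maps a group name (e.g. ``"input"``, ``"candidates"``,
    ``"background"``) to SMILES lists; the PCA basis is fitted on all
    molecules pooled, on standardized property columns (constant columns
    dropped with a warning).  Returns per-group coordinate arrays and the
    two explained-variance fractions.
    """
    from sklearn.decomposition import PCA

    names, all_smiles = [], []
    for name, group in smiles_groups.items():
        for smi in group:
            names.append(name)
            all_smiles.append(smi)
    if len(all_smiles) < 3:
        raise ValueError("need at least 3 molecules for a 2-component projection")
    props = np.stack([features.physchem_properties(s).as_array() for s in all_smiles])
    std = props.std(axis=0)
    constant = std == 0
    if constant.any():
        logger.warning("chem_space_projection: dropping %d constant property columns",
                       int(constant.sum()))
    props = props[:, ~constant]
    scaled = (props - props.mean(axis=0)) / props.std(axis=0)
    pca = PCA(n_components=2)
    coords = pca.fit_transform(scaled)
    out: dict[str, np.ndarray] = {}
    names_arr = np.array(names)
    for name in smiles_groups:
        out[name] = coords[names_arr == name]
    return out, pca.explained_variance_ratio_.copy()
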