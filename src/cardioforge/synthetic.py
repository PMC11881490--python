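"""Synthetic corpora and planted-signal activity labels.

The corpus generator assembles SMILES from a fragment grammar — ring cores
(aromatic and saturated, N/O/S-containing), short linkers, and prefix /
suffix substituents (including halogens, amides, sulfonamides, a charged
quaternary nitrogen and a stereocenter) — so every emitted string parses by
construction (and is verified with RDKit anyway).  The grammar yields
drug-fragment-like molecules whose ten conditioning properties all vary
across the corpus and whose molecular weights span roughly 90–600 g/mol.

Planted activity labels follow the correlation structure observed in real
cardiac ion-channel data: pIC50 increases with lipophilicity (LogP),
decreases with polarity (TPSA) and increases when a basic (aromatic or
protonated) nitrogen is present, plus Gaussian noise:

    pIC50 = intercept + b_logp * LogP - b_tpsa * TPSA/100 + b_basicN * 1[basic N] + eps

Default coefficients are chosen so that labels straddle the pIC50 = 5
blocker threshold with roughly balanced classes, which maximizes the power
of the recovery tests that train predictors on these fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from . import features
from .predictors import ActivityRecord, BLOCKER_THRESHOLD

__all__ = [
    "SyntheticCorpusSpec",
    "make_corpus",
    "PlantedActivitySpec",
    "make_labeled_set",
    "has_basic_nitrogen",
]

logger = logging.getLogger(__name__)

# Ring cores; each is a valid standalone SMILES that accepts a prefix on its
# first atom and a suffix on its last atom.
_RINGS = (
    "c1ccccc1", "c1ccncc1", "c1ccnnc1", "c1ccsc1", "c1ccoc1", "c1cnccn1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "C1CNCCN1", "C1COCCN1", "C1CCCC1",
)
_LINKERS = ("", "C", "CC", "CCC", "O", "N", "OC", "CN", "C(=O)", "C(=O)N", "S(=O)(=O)")
_PREFIXES = (
    "", "C", "CC", "CCC", "CCCC", "CO", "CN", "OC", "NC", "CC(C)", "CC(=O)N",
    "COC(=O)", "CN(C)", "FC(F)(F)", "C[N+](C)(C)C", "C[C@H](N)", "CC(O)",
    "CCCCCC", "c1ccccc1C",
)
_SUFFIXES = (
    "", "C", "CC", "O", "N", "F", "Cl", "Br", "I", "C(=O)O", "C(=O)N",
    "C(=O)OC", "S(=O)(=O)N", "C#N", "OC", "CCO", "CCN", "C(F)(F)F",
    "CCCC", "[N+](C)(C)C",
)


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    n_molecules: int = 500
    max_rings: int = 3
    max_heavy_atoms: int = 45
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1 or self.max_rings < 1:
            raise ValueError("n_molecules and max_rings must be positive")


def make_corpus(spec: SyntheticCorpusSpec) -> list[str]:
    """Assemble ``n_molecules`` unique, parseable SMILES; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    cap = 200 * spec.n_molecules
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"fragment grammar exhausted after {cap} attempts "
                f"({len(out)}/{spec.n_molecules} unique molecules); enlarge the grammar"
            )
        n_rings = int(rng.integers(1, spec.max_rings + 1))
        parts = [str(rng.choice(_PREFIXES))]
        for i in range(n_rings):
            if i > 0:
                parts.append(str(rng.choice(_LINKERS)))
            parts.append(str(rng.choice(_RINGS)))
        parts.append(str(rng.choice(_SUFFIXES)))
        smi = _renumber_rings(parts)
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() > spec.max_heavy_atoms:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    logger.info("make_corpus: %d molecules from %d attempts", len(out), attempts)
    return out


def _renumber_rings(parts: list[str]) -> str:
    """Concatenate fragments, renumbering ring-closure digits to avoid clashes."""
    out = []
    next_label = 1
    for frag in parts:
        mapping: dict[str, str] = {}
        chars = []
        i = 0
        while i < len(frag):
            ch = frag[i]
            if ch.isdigit():
                if ch not in mapping:
                    mapping[ch] = str(next_label) if next_label < 10 else f"%{next_label}"
                    next_label += 1
                chars.append(mapping[ch])
            elif ch == "[":
                j = frag.index("]", i)
                chars.append(frag[i:j + 1])
                i = j
            else:
                chars.append(ch)
            i += 1
        out.append("".join(chars))
    return "".join(out)


_BASIC_N = Chem.MolFromSmarts("[n,#7+]")


def has_basic_nitrogen(smiles: str) -> bool:
    """Aromatic or positively charged nitrogen — the planted hERG pharmacophore."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise features.ParseError(f"invalid SMILES: {smiles!r}")
    return mol.HasSubstructMatch(_BASIC_N)


@dataclass(frozen=True)
class PlantedActivitySpec:
    channel: str = "hERG"
    intercept: float = 4.4
    b_logp: float = 0.45
    b_tpsa: float = 0.9
    b_basic_n: float = 0.8
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def make_labeled_set(corpus: list[str], spec: PlantedActivitySpec = PlantedActivitySpec(),
                     ) -> list[ActivityRecord]:
    """Label every molecule with a planted-structure pIC50 and a blocker flag."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for smi in corpus:
        props = features.physchem_properties(smi)
        pic50 = (spec.intercept
                 + spec.b_logp * props.logp
                 - spec.b_tpsa * props.tpsa / 100.0
                 + spec.b_basic_n * float(has_basic_nitrogen(smi))
                 + rng.normal(0.0, spec.noise_sd))
        records.append(ActivityRecord(smiles=smi, pic50=float(pic50),
                                      label=int(pic50 >= BLOCKER_THRESHOLD),
                                      channel=spec.channel))
    return records
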