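"""Molecular featurization on RDKit.

Four representations of a molecule are produced here:

* ten physicochemical properties (the generator's conditioning vector, in a
  fixed documented order),
* a 1024-bit ECFP4 (Morgan, radius 2) fingerprint,
* a molecular graph with a 14-feature node vector per heavy atom and
  bond-order-labeled edges,
* a wide 2D descriptor vector over a descriptor list pinned in
  ``data/descriptors_2d.json`` (209 names), used for candidate ranking
  after mutual-information pruning and z-scoring.

Plus the two structural reductions the pipeline needs: canonical SMILES and
the Bemis–Murcko scaffold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.metrics import normalized_mutual_info_score

__all__ = [
    "ParseError", "FeaturizationError",
    "canonicalize", "murcko_scaffold",
    "PROPERTY_NAMES", "PropertyVector", "physchem_properties",
    "ecfp4", "FINGERPRINT_BITS",
    "MolGraph", "build_graph", "NODE_FEATURE_NAMES",
    "load_descriptor_names", "descriptor_vector", "descriptor_matrix",
    "prune_redundant", "cosine_similarity",
]

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

FINGERPRINT_BITS = 1024


class ParseError(ValueError):
    """A SMILES string that RDKit cannot parse."""


class FeaturizationError(RuntimeError):
    """A parseable molecule whose features could not be computed."""


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Canonical SMILES; two encodings of one molecule map to one string."""
    return Chem.MolToSmiles(_mol(smiles))


def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko scaffold: ring systems plus linkers, side chains removed.

    Acyclic molecules have the empty scaffold ``""``.
    """
    mol = _mol(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


# ---------------------------------------------------------------------------
# Ten conditioning properties.  The field order is load-bearing: it defines
# the layout of the generator's property-conditioning vector.
PROPERTY_NAMES = (
    "molecular_weight",
    "n_rings",
    "n_rotatable_bonds",
    "n_hbd",
    "n_hba",
    "tpsa",
    "n_heteroatoms",
    "logp",
    "n_stereocenters",
    "formal_charge",
)


@dataclass(frozen=True)
class PropertyVector:
    molecular_weight: float
    n_rings: int
    n_rotatable_bonds: int
    n_hbd: int
    n_hba: int
    tpsa: float
    n_heteroatoms: int
    logp: float
    n_stereocenters: int
    formal_charge: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PROPERTY_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PropertyVector":
        values = list(values)
        if len(values) != len(PROPERTY_NAMES):
            raise ValueError(f"expected {len(PROPERTY_NAMES)} values, got {len(values)}")
        kwargs = dict(zip(PROPERTY_NAMES, values))
        for key in ("n_rings", "n_rotatable_bonds", "n_hbd", "n_hba",
                    "n_heteroatoms", "n_stereocenters", "formal_charge"):
            kwargs[key] = int(round(kwargs[key]))
        return cls(**kwargs)


def physchem_properties(smiles: str) -> PropertyVector:
    mol = _mol(smiles)
    stereo = Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    return PropertyVector(
        molecular_weight=Descriptors.MolWt(mol),
        n_rings=rdMolDescriptors.CalcNumRings(mol),
        n_rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        n_hbd=Lipinski.NumHDonors(mol),
        n_hba=Lipinski.NumHAcceptors(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        n_heteroatoms=rdMolDescriptors.CalcNumHeteroatoms(mol),
        logp=Crippen.MolLogP(mol),
        n_stereocenters=len(stereo),
        formal_charge=Chem.GetFormalCharge(mol),
    )


_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=FINGERPRINT_BITS)


def ecfp4(smiles: str) -> np.ndarray:
    """1024-bit extended-connectivity fingerprint, diameter 4 (radius 2)."""
    fp = _morgan.GetFingerprintAsNumPy(_mol(smiles))
    return fp.astype(np.float64)


# ---------------------------------------------------------------------------
# Graph featurization: 14 per-atom features in this order.
NODE_FEATURE_NAMES = (
    "is_carbon", "is_nitrogen", "is_oxygen", "is_phosphorus", "is_sulfur",
    "is_hydrophobic", "is_aromatic", "is_hba", "is_hbd", "in_ring",
    "n_heavy_neighbors", "n_hetero_neighbors", "partial_charge", "atomic_mass",
)


@dataclass(frozen=True)
class MolGraph:
    """Heavy-atom graph: (n, 14) node features, undirected edges, bond orders."""

    node_features: np.ndarray  # (n_atoms, 14)
    edges: np.ndarray          # (n_edges, 2) undirected pairs
    edge_orders: np.ndarray    # (n_edges,) bond order (1, 1.5, 2, 3)
    smiles: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.node_features)

    def directed_edge_index(self, self_loops: bool = True) -> np.ndarray:
        """(2, E) source→target index with both directions (+ self-loops)."""
        if len(self.edges):
            src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
            dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        else:
            src = dst = np.array([], dtype=np.int64)
        if self_loops:
            loops = np.arange(self.n_nodes, dtype=np.int64)
            src = np.concatenate([src, loops])
            dst = np.concatenate([dst, loops])
        return np.stack([src.astype(np.int64), dst.astype(np.int64)])


def build_graph(smiles: str) -> MolGraph:
    """Featurize the heavy-atom graph of a molecule.

    The hydrophobicity indicator marks carbon atoms with no bonded
    heteroatom; hydrogen-bond donor/acceptor membership follows the
    Lipinski SMARTS definitions; partial charges are Gasteiger.
    """
    mol = _mol(smiles)
    from rdkit.Chem import AllChem

    AllChem.ComputeGasteigerCharges(mol)
    hba_atoms = {m[0] for m in mol.GetSubstructMatches(Lipinski.HAcceptorSmarts)}
    hbd_atoms = {m[0] for m in mol.GetSubstructMatches(Lipinski.HDonorSmarts)}
    feats = np.zeros((mol.GetNumAtoms(), len(NODE_FEATURE_NAMES)))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        heavy = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1]
        hetero = [nb for nb in heavy if nb.GetSymbol() not in ("C", "H")]
        charge = atom.GetDoubleProp("_GasteigerCharge")
        if not np.isfinite(charge):
            raise FeaturizationError(f"partial charge failed for atom {i} of {smiles!r}")
        feats[i] = [
            sym == "C", sym == "N", sym == "O", sym == "P", sym == "S",
            sym == "C" and not hetero,
            atom.GetIsAromatic(),
            i in hba_atoms,
            i in hbd_atoms,
            atom.IsInRing(),
            len(heavy),
            len(hetero),
            charge,
            atom.GetMass(),
        ]
    edges, orders = [], []
    for bond in mol.GetBonds():
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        orders.append(bond.GetBondTypeAsDouble())
    return MolGraph(
        node_features=feats,
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        edge_orders=np.array(orders, dtype=np.float64),
        smiles=smiles,
    )


# ---------------------------------------------------------------------------
# Wide 2D descriptor vectors for candidate ranking.

def load_descriptor_names() -> list[str]:
    """The pinned 2D descriptor list shipped with the package."""
    blob = json.loads(
        resources.files("cardioforge.data").joinpath("descriptors_2d.json").read_text()
    )
    return list(blob["descriptors"])


_DESC_FUNCS = dict(Descriptors._descList)


def descriptor_vector(smiles: str, descriptor_names: Sequence[str] | None = None) -> np.ndarray:
    """Evaluate the pinned descriptors; non-finite values become 0 (warned)."""
    names = list(descriptor_names) if descriptor_names is not None else load_descriptor_names()
    mol = _mol(smiles)
    values = np.empty(len(names))
    bad = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(names):
            try:
                v = float(_DESC_FUNCS[name](mol))
            except Exception:
                v = np.nan
            if not np.isfinite(v):
                bad.append(name)
                v = 0.0
            values[j] = v
    if bad:
        logger.warning("descriptor_vector(%s): non-finite %s replaced by 0", smiles, bad)
    return values


def descriptor_matrix(smiles_list: Sequence[str],
                      descriptor_names: Sequence[str] | None = None) -> np.ndarray:
    names = list(descriptor_names) if descriptor_names is not None else load_descriptor_names()
    return np.stack([descriptor_vector(s, names) for s in smiles_list])


def _bin_column(col: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization (quantile bins, duplicates merged)."""
    qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, col, side="right")


def prune_redundant(matrix: np.ndarray, mi_threshold: float = 0.9,
                    n_bins: int = 32) -> np.ndarray:
    """Greedy removal of mutually redundant descriptor columns.

    Columns are scanned in index order; a column whose normalized mutual
    information with any already-kept column exceeds ``mi_threshold`` is
    dropped (the later-indexed member of an offending pair is always the
    one removed).  Constant columns are dropped first with a warning.
    Values are discretized into equal-frequency bins; the bin count is
    capped at sqrt(n_rows) so tiny candidate sets do not degenerate into
    one-sample bins (which would make every pair look maximally informative).

    Returns a boolean keep-mask over columns.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 molecules")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("descriptor matrix must be finite")
    n, d = matrix.shape
    keep = np.ones(d, dtype=bool)
    constant = matrix.std(axis=0) == 0.0
    if constant.any():
        logger.warning("prune_redundant: dropping %d constant columns", int(constant.sum()))
        keep[constant] = False
    bins = max(2, min(n_bins, int(np.floor(np.sqrt(n)))))
    discretized = {j: _bin_column(matrix[:, j], bins) for j in np.flatnonzero(keep)}
    kept: list[int] = []
    for j in np.flatnonzero(keep):
        redundant = False
        for i in kept:
            nmi = normalized_mutual_info_score(discretized[i], discretized[j])
            if nmi > mi_threshold:
                redundant = True
                break
        if redundant:
            keep[j] = False
        else:
            kept.append(j)
    return keep


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (||a|| ||b||); raises on zero vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))
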