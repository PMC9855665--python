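"""Molecular featurization: directed graphs, global descriptors, fingerprints.

A molecule becomes a :class:`MolGraph` whose hidden states will live on
*directed* bonds (each undirected bond contributes two directed edges), plus
a 200-dimensional global descriptor vector computed with RDKit and pinned by
name in a shipped manifest. ECFP4 (Morgan radius 2, 2048 bits) Tanimoto
similarity supports low-similarity test-set construction.
"""

from __future__ import annotations

import functools
import json
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, rdFingerprintGenerator

logger = logging.getLogger(__name__)

_ELEMENTS = ("C", "H", "O", "N", "P", "S", "Cl", "Br", "I", "F")
_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)

#: atom feature length: element(11) + degree(6) + charge(1) + hybrid(6)
#: + aromatic(1) + numH(5) + mass(1)
ATOM_FDIM = len(_ELEMENTS) + 1 + 6 + 1 + len(_HYBRIDIZATIONS) + 1 + 1 + 5 + 1
#: bond feature length: order(4) + conjugated(1) + in-ring(1)
BOND_FDIM = 6

N_DESCRIPTORS = 200


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    feats = _one_hot(atom.GetSymbol(), list(_ELEMENTS))
    feats += _one_hot(atom.GetDegree(), [0, 1, 2, 3, 4, 5])[:-1]  # degree 0-5
    feats += [float(atom.GetFormalCharge())]
    feats += _one_hot(atom.GetHybridization(), list(_HYBRIDIZATIONS))
    feats += [1.0 if atom.GetIsAromatic() else 0.0]
    feats += _one_hot(atom.GetTotalNumHs(), [0, 1, 2, 3, 4])[:-1]
    feats += [atom.GetMass() / 100.0]
    return np.asarray(feats, dtype=np.float64)


def bond_features(bond: Chem.Bond) -> np.ndarray:
    bt = bond.GetBondType()
    feats = [
        1.0 if bt == Chem.BondType.SINGLE else 0.0,
        1.0 if bt == Chem.BondType.DOUBLE else 0.0,
        1.0 if bt == Chem.BondType.TRIPLE else 0.0,
        1.0 if bt == Chem.BondType.AROMATIC else 0.0,
        1.0 if bond.GetIsConjugated() else 0.0,
        1.0 if bond.IsInRing() else 0.0,
    ]
    return np.asarray(feats, dtype=np.float64)


@dataclass
class MolGraph:
    """Directed molecular graph with per-atom and per-directed-bond features.

    ``src[e]``/``dst[e]`` give the source/destination atom of directed bond
    ``e``; ``reverse_index[e]`` is the opposite direction of the same bond
    (an involution with no fixed points). ``incoming[a]`` lists the directed
    bonds arriving at atom ``a``.
    """

    smiles: str
    atom_feats: np.ndarray  # (n_atoms, ATOM_FDIM)
    bond_feats: np.ndarray  # (n_bonds_directed, BOND_FDIM)
    src: np.ndarray  # (n_bonds_directed,) int
    dst: np.ndarray  # (n_bonds_directed,) int
    reverse_index: np.ndarray  # (n_bonds_directed,) int

    @property
    def n_atoms(self) -> int:
        return self.atom_feats.shape[0]

    @property
    def n_directed_bonds(self) -> int:
        return self.bond_feats.shape[0]

    @property
    def incoming(self) -> list[list[int]]:
        inc: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for e in range(self.n_directed_bonds):
            inc[int(self.dst[e])].append(e)
        return inc


def smiles_to_graph(smiles: str) -> MolGraph:
    """Build the directed graph for one SMILES (hydrogens implicit)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    afeats = np.zeros((n, ATOM_FDIM))
    for atom in mol.GetAtoms():
        afeats[atom.GetIdx()] = atom_features(atom)

    src, dst, bfeats, rev = [], [], [], []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = bond_features(bond)
        e = len(src)
        src += [a, b]
        dst += [b, a]
        bfeats += [f, f]
        rev += [e + 1, e]

    return MolGraph(
        smiles=smiles,
        atom_feats=afeats,
        bond_feats=np.asarray(bfeats).reshape(len(src), BOND_FDIM),
        src=np.asarray(src, dtype=np.int64),
        dst=np.asarray(dst, dtype=np.int64),
        reverse_index=np.asarray(rev, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Global descriptors


@functools.lru_cache(maxsize=1)
def descriptor_manifest() -> dict:
    """The pinned 200-descriptor manifest shipped with the package."""
    text = resources.files("molactive.data").joinpath("descriptor_manifest.json").read_text()
    manifest = json.loads(text)
    assert len(manifest["names"]) == N_DESCRIPTORS
    return manifest


@functools.lru_cache(maxsize=1)
def _descriptor_functions():
    registry = dict(Descriptors._descList)
    return [(name, registry[name]) for name in descriptor_manifest()["names"]]


@dataclass(frozen=True)
class DescriptorVector:
    values: np.ndarray  # (200,), NaN marks a failed descriptor pre-imputation
    manifest_version: str


@functools.lru_cache(maxsize=200_000)
def _descriptors_cached(canonical_smiles: str) -> tuple:
    mol = Chem.MolFromSmiles(canonical_smiles)
    values = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, fn in _descriptor_functions():
            try:
                v = float(fn(mol))
            except Exception:
                v = math.nan
            if math.isnan(v) or math.isinf(v):
                v = math.nan
                n_failed += 1
            values.append(v)
    if n_failed > 0.1 * N_DESCRIPTORS:
        logger.warning(
            "%d/%d descriptors failed for %s", n_failed, N_DESCRIPTORS, canonical_smiles
        )
    return tuple(values)


def compute_global_descriptors(smiles: str) -> DescriptorVector:
    """Compute the 200 manifest descriptors; failures become NaN (imputed later)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    canon = Chem.MolToSmiles(mol)
    values = np.asarray(_descriptors_cached(canon), dtype=np.float64)
    return DescriptorVector(values=values, manifest_version=descriptor_manifest()["version"])


class DescriptorScaler:
    """Per-descriptor z-scoring with training-set mean/SD (population SD).

    NaNs are imputed to the training mean before scaling; a zero-variance
    descriptor scales to 0.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, vectors: np.ndarray) -> "DescriptorScaler":
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] < 2:
            raise ValueError("need >= 2 training vectors")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.mean_ = np.nanmean(vectors, axis=0)
        self.mean_ = np.nan_to_num(self.mean_, nan=0.0)
        filled = np.where(np.isnan(vectors), self.mean_, vectors)
        self.std_ = filled.std(axis=0)
        return self

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fit")
        vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
        filled = np.where(np.isnan(vectors), self.mean_, vectors)
        out = np.zeros_like(filled)
        nz = self.std_ > 0
        out[:, nz] = (filled[:, nz] - self.mean_[nz]) / self.std_[nz]
        return out

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "std": self.std_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorScaler":
        s = cls()
        s.mean_ = np.asarray(d["mean"], dtype=np.float64)
        s.std_ = np.asarray(d["std"], dtype=np.float64)
        return s


def fit_descriptor_scaler(vectors: np.ndarray) -> DescriptorScaler:
    return DescriptorScaler().fit(vectors)


def apply_scaler(scaler: DescriptorScaler, vector: np.ndarray) -> np.ndarray:
    return scaler.transform(vector)


# ---------------------------------------------------------------------------
# Fingerprints

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@functools.lru_cache(maxsize=200_000)
def _fingerprint(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return _MORGAN.GetFingerprint(mol)


def ecfp4_fingerprint(smiles: str):
    """Hashed circular fingerprint, radius 2 / 2048 bits (ECFP4)."""
    return _fingerprint(smiles)


def tanimoto_similarity(smiles_a: str, smiles_b: str) -> float:
    """Tanimoto coefficient on ECFP4 fingerprints, in [0, 1]."""
    return DataStructs.TanimotoSimilarity(_fingerprint(smiles_a), _fingerprint(smiles_b))
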