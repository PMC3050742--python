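"""The seven 2D descriptor sets and the similarity function built on them.

Descriptor sets
---------------
ECFP4
    Extended-connectivity circular fingerprint of diameter 4 bonds
    (radius 2): the sparse set of hashed atom-environment identifiers
    produced by iterative neighbourhood hashing with deduplication of
    identical environments.  Unfolded integer ids are kept (no fixed bit
    length), so Tanimoto similarity is computed on feature sets without
    folding collisions.
PROPERTY
    Eight whole-molecule properties, in this order: AlogP (atom-contribution
    octanol/water logP), molecular weight, H-bond acceptors, H-bond donors,
    heavy-atom count, rotatable bonds, rings (SSSR), aromatic rings.
BCUT
    For each atom-weight scheme (mass, Gasteiger partial charge, atomic
    polarizability) the lowest and highest eigenvalue of the heavy-atom
    bond-order adjacency matrix (aromatic bonds count 1.5) with the atom
    weights on the diagonal.
GCUT
    As BCUT, but off-diagonal entries are topological (bond-count) graph
    distances; disconnected fragments form a block matrix (cross-fragment
    entries zero).
ECFP4_PROPERTY, BCUT_GCUT, GCUT_PROPERTY
    Combinations; their similarity is the unweighted mean of the component
    similarities.

Similarity
----------
Fingerprints compare by Tanimoto |A∩B|/|A∪B|.  Continuous blocks compare
by ``1 − mean |Δ|`` after per-component min–max scaling whose bounds are
fitted on the *training* library only (:class:`ContinuousScaler`) and
frozen for query scoring; out-of-range query values clamp into [0, 1].
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator, rdmolops


class DescriptorSet(enum.Enum):
    ECFP4 = "ECFP4"
    PROPERTY = "PROPERTY"
    ECFP4_PROPERTY = "ECFP4_PROPERTY"
    BCUT = "BCUT"
    GCUT = "GCUT"
    BCUT_GCUT = "BCUT_GCUT"
    GCUT_PROPERTY = "GCUT_PROPERTY"


PROPERTY_NAMES = (
    "alogp",
    "mol_weight",
    "hbond_acceptors",
    "hbond_donors",
    "n_atoms",
    "rotatable_bonds",
    "n_rings",
    "n_aromatic_rings",
)

#: Atom-weight schemes used on the BCUT/GCUT diagonal, in output order.
DEFAULT_WEIGHT_SCHEMES = ("mass", "gasteiger", "polarizability")

# Static atomic dipole polarizabilities (Å^3) for elements common in
# drug-like molecules; elements outside the table fall back to 2.0.
_POLARIZABILITY = {
    "H": 0.667, "B": 3.03, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
    "Si": 5.38, "P": 3.63, "S": 2.90, "Cl": 2.18, "Se": 3.77, "Br": 3.05,
    "I": 5.35, "Li": 24.33, "Na": 24.11, "K": 43.4, "Mg": 10.6, "Ca": 22.8,
    "Fe": 8.4, "Zn": 5.75,
}
_POLARIZABILITY_DEFAULT = 2.0


@dataclass(frozen=True)
class DescriptorVector:
    """A compound's representation under one descriptor set.

    ``fingerprint`` holds sparse feature ids (fingerprint sets only);
    ``blocks`` holds named continuous blocks (e.g. ``property``, ``bcut``)
    whose similarities are averaged for combined sets.
    """

    set_id: DescriptorSet
    fingerprint: frozenset[int] | None = None
    blocks: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.fingerprint is None and not self.blocks:
            raise ValueError("descriptor vector needs a fingerprint or blocks")
        for name, vec in self.blocks.items():
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite values in block {name!r}")


@dataclass
class SimilarityMatrix:
    """Symmetric all-pairs similarity over an ordered compound list."""

    ids: tuple[str, ...]
    values: np.ndarray
    set_id: DescriptorSet

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")
        self._index = {cid: i for i, cid in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate compound ids in similarity matrix")

    def index(self, compound_id: str) -> int:
        return self._index[compound_id]

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def n(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# individual descriptor computations


def property_descriptors(mol: Chem.Mol) -> np.ndarray:
    """The 8-component whole-molecule property vector (see module docs)."""
    return np.array(
        [
            Crippen.MolLogP(mol),
            Descriptors.MolWt(mol),
            Lipinski.NumHAcceptors(mol),
            Lipinski.NumHDonors(mol),
            mol.GetNumHeavyAtoms(),
            Lipinski.NumRotatableBonds(mol),
            rdMolDescriptors.CalcNumRings(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
        ],
        dtype=float,
    )


def circular_fingerprint(mol: Chem.Mol, radius: int = 2) -> frozenset[int]:
    """Sparse circular-fingerprint feature set (default ECFP4, radius 2)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    return frozenset(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


WeightScheme = str | Callable[[Chem.Mol], np.ndarray]


def atom_weights(mol: Chem.Mol, scheme: WeightScheme) -> np.ndarray:
    """Per-heavy-atom diagonal weights for one BCUT/GCUT scheme.

    Gasteiger charges fold the implicit-hydrogen contribution into their
    heavy atom so the weight reflects the whole group; NaN charges (exotic
    atoms) become 0.
    """
    if callable(scheme):
        w = np.asarray(scheme(mol), dtype=float)
        if w.shape != (mol.GetNumAtoms(),):
            raise ValueError("weight callable returned wrong length")
        return w
    if scheme == "mass":
        return np.array([a.GetMass() for a in mol.GetAtoms()], dtype=float)
    if scheme == "gasteiger":
        AllChem.ComputeGasteigerCharges(mol)
        w = np.array(
            [
                a.GetDoubleProp("_GasteigerCharge")
                + a.GetDoubleProp("_GasteigerHCharge")
                for a in mol.GetAtoms()
            ],
            dtype=float,
        )
        return np.nan_to_num(w, nan=0.0, posinf=0.0, neginf=0.0)
    if scheme == "polarizability":
        return np.array(
            [
                _POLARIZABILITY.get(a.GetSymbol(), _POLARIZABILITY_DEFAULT)
                for a in mol.GetAtoms()
            ],
            dtype=float,
        )
    raise ValueError(f"unknown weight scheme {scheme!r}")


def _bond_order_adjacency(mol: Chem.Mol) -> np.ndarray:
    n = mol.GetNumAtoms()
    adj = np.zeros((n, n), dtype=float)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = bond.GetBondTypeAsDouble()  # aromatic -> 1.5
        adj[i, j] = adj[j, i] = order
    return adj


def _topological_distance(mol: Chem.Mol) -> np.ndarray:
    # RDKit marks cross-fragment distances with a 1e8 sentinel; the GCUT
    # matrix treats fragments as blocks, so those entries become 0.
    dist = np.array(rdmolops.GetDistanceMatrix(mol), dtype=float)
    dist[dist > mol.GetNumAtoms()] = 0.0
    return dist


def _cut_eigen_extremes(off_diag: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    mat = off_diag.copy()
    np.fill_diagonal(mat, weights)
    eig = np.linalg.eigvalsh(mat)
    return float(eig[0]), float(eig[-1])


def bcut_descriptors(
    mol: Chem.Mol, weight_schemes: Sequence[WeightScheme] = DEFAULT_WEIGHT_SCHEMES
) -> np.ndarray:
    """(lowest, highest) eigenvalue of the weighted bond-order adjacency
    matrix, for each weight scheme — 2×|schemes| values."""
    if mol.GetNumAtoms() < 1:
        raise ValueError("molecule has no heavy atoms")
    adj = _bond_order_adjacency(mol)
    out = []
    for scheme in weight_schemes:
        out.extend(_cut_eigen_extremes(adj, atom_weights(mol, scheme)))
    return np.array(out, dtype=float)


def gcut_descriptors(
    mol: Chem.Mol, weight_schemes: Sequence[WeightScheme] = DEFAULT_WEIGHT_SCHEMES
) -> np.ndarray:
    """As :func:`bcut_descriptors` but on the topological-distance matrix."""
    if mol.GetNumAtoms() < 1:
        raise ValueError("molecule has no heavy atoms")
    dist = _topological_distance(mol)
    out = []
    for scheme in weight_schemes:
        out.extend(_cut_eigen_extremes(dist, atom_weights(mol, scheme)))
    return np.array(out, dtype=float)


_SET_BLOCKS: dict[DescriptorSet, tuple[bool, tuple[str, ...]]] = {
    # set_id -> (has fingerprint, continuous block names)
    DescriptorSet.ECFP4: (True, ()),
    DescriptorSet.PROPERTY: (False, ("property",)),
    DescriptorSet.ECFP4_PROPERTY: (True, ("property",)),
    DescriptorSet.BCUT: (False, ("bcut",)),
    DescriptorSet.GCUT: (False, ("gcut",)),
    DescriptorSet.BCUT_GCUT: (False, ("bcut", "gcut")),
    DescriptorSet.GCUT_PROPERTY: (False, ("gcut", "property")),
}


def compute_vector(mol: Chem.Mol, set_id: DescriptorSet) -> DescriptorVector:
    """Compute one compound's :class:`DescriptorVector` for ``set_id``."""
    has_fp, block_names = _SET_BLOCKS[set_id]
    blocks: dict[str, np.ndarray] = {}
    for name in block_names:
        if name == "property":
            blocks[name] = property_descriptors(mol)
        elif name == "bcut":
            blocks[name] = bcut_descriptors(mol)
        elif name == "gcut":
            blocks[name] = gcut_descriptors(mol)
    return DescriptorVector(
        set_id=set_id,
        fingerprint=circular_fingerprint(mol) if has_fp else None,
        blocks=blocks,
    )


def compute_vectors(
    mols: Mapping[str, Chem.Mol], set_id: DescriptorSet
) -> dict[str, DescriptorVector]:
    return {cid: compute_vector(mol, set_id) for cid, mol in mols.items()}


# ---------------------------------------------------------------------------
# similarity


def tanimoto(a: frozenset[int], b: frozenset[int]) -> float:
    """|A∩B| / |A∪B|;  two empty sets are identical, hence 1 by convention."""
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


class ContinuousScaler:
    """Per-component min–max bounds for the continuous blocks.

    Fitted on the training library only and frozen afterwards, so query
    compounds are scored against the training value ranges; scaled values
    clamp into [0, 1].  Zero-range components scale to a constant 0.5 and
    therefore contribute zero difference.
    """

    def __init__(self):
        self._lo: dict[str, np.ndarray] = {}
        self._hi: dict[str, np.ndarray] = {}

    def fit(self, vectors: Iterable[DescriptorVector]) -> "ContinuousScaler":
        stacked: dict[str, list[np.ndarray]] = {}
        for vec in vectors:
            for name, block in vec.blocks.items():
                stacked.setdefault(name, []).append(block)
        for name, blocks in stacked.items():
            arr = np.vstack(blocks)
            self._lo[name] = arr.min(axis=0)
            self._hi[name] = arr.max(axis=0)
        return self

    @property
    def is_fitted(self) -> bool:
        return bool(self._lo)

    def scale(self, name: str, block: np.ndarray) -> np.ndarray:
        if name not in self._lo:
            raise ValueError(f"scaler was not fitted for block {name!r}")
        lo, hi = self._lo[name], self._hi[name]
        span = hi - lo
        out = np.full_like(block, 0.5, dtype=float)
        nz = span > 0
        out[nz] = (block[nz] - lo[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0)


def _block_similarity(
    name: str, a: np.ndarray, b: np.ndarray, scaler: ContinuousScaler
) -> float:
    sa, sb = scaler.scale(name, a), scaler.scale(name, b)
    return 1.0 - float(np.mean(np.abs(sa - sb)))


def similarity(
    a: DescriptorVector, b: DescriptorVector, scaler: ContinuousScaler | None = None
) -> float:
    """Similarity in [0, 1] between two vectors of the same descriptor set.

    Component similarities (fingerprint Tanimoto and/or per-block scaled
    mean-absolute-difference similarities) are averaged with equal weight.
    Continuous blocks require a fitted :class:`ContinuousScaler`.
    """
    if a.set_id != b.set_id:
        raise ValueError(
            f"descriptor set mismatch: {a.set_id.value} vs {b.set_id.value}"
        )
    parts: list[float] = []
    if a.fingerprint is not None or b.fingerprint is not None:
        parts.append(tanimoto(a.fingerprint or frozenset(), b.fingerprint or frozenset()))
    if a.blocks:
        if scaler is None:
            raise ValueError("continuous blocks require a fitted ContinuousScaler")
        for name in a.blocks:
            parts.append(_block_similarity(name, a.blocks[name], b.blocks[name], scaler))
    return float(np.clip(np.mean(parts), 0.0, 1.0))


def _pairwise_block(
    name: str, blocks: list[np.ndarray], scaler: ContinuousScaler
) -> np.ndarray:
    scaled = np.vstack([scaler.scale(name, b) for b in blocks])
    diff = np.abs(scaled[:, None, :] - scaled[None, :, :]).mean(axis=2)
    return 1.0 - diff


def similarity_matrix(
    vectors: Mapping[str, DescriptorVector],
    scaler: ContinuousScaler | None = None,
    ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """All-pairs similarity matrix over ``ids`` (default: mapping order)."""
    if ids is None:
        ids = list(vectors)
    ids = tuple(ids)
    vecs = [vectors[cid] for cid in ids]
    if not vecs:
        raise ValueError("empty library")
    set_id = vecs[0].set_id
    n = len(ids)
    parts: list[np.ndarray] = []
    if vecs[0].fingerprint is not None:
        fps = [v.fingerprint for v in vecs]
        tan = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                tan[i, j] = tan[j, i] = tanimoto(fps[i], fps[j])
        parts.append(tan)
    if vecs[0].blocks:
        if scaler is None:
            raise ValueError("continuous blocks require a fitted ContinuousScaler")
        for name in vecs[0].blocks:
            parts.append(_pairwise_block(name, [v.blocks[name] for v in vecs], scaler))
    values = np.clip(np.mean(parts, axis=0), 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=ids, values=values, set_id=set_id)


def cross_similarities(
    queries: Mapping[str, DescriptorVector],
    training: Mapping[str, DescriptorVector],
    scaler: ContinuousScaler | None = None,
) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Query × training similarity matrix (rows: queries, cols: training)."""
    qids, tids = tuple(queries), tuple(training)
    out = np.empty((len(qids), len(tids)))
    for i, q in enumerate(qids):
        for j, t in enumerate(tids):
            out[i, j] = similarity(queries[q], training[t], scaler)
    return qids, tids, out


def export_descriptor_csv(
    vectors: Mapping[str, DescriptorVector], path
) -> None:
    """Continuous blocks as CSV (one row per compound, named columns)."""
    import pandas as pd

    rows = {}
    for cid, vec in vectors.items():
        row: dict[str, float] = {}
        for name, block in vec.blocks.items():
            if name == "property":
                cols = [f"property_{p}" for p in PROPERTY_NAMES]
            else:
                cols = [
                    f"{name}_{scheme}_{end}"
                    for scheme in DEFAULT_WEIGHT_SCHEMES
                    for end in ("low", "high")
                ]
            row.update(zip(cols, block))
        rows[cid] = row
    pd.DataFrame.from_dict(rows, orient="index").rename_axis("compound_id").to_csv(path)


def export_fingerprints(vectors: Mapping[str, DescriptorVector], path) -> None:
    """Sparse fingerprints as ``compound_id<TAB>sorted feature ids``."""
    with open(path, "w", encoding="utf-8") as fh:
        for cid, vec in vectors.items():
            if vec.fingerprint is None:
                continue
            feats = " ".join(str(f) for f in sorted(vec.fingerprint))
            fh.write(f"{cid}\t{feats}\n")
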