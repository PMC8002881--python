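"""Window encoding: candidate sites -> fixed-size numeric matrices.

Each candidate cleavage site is represented by the 8 residues surrounding
the scissile bond (P4..P1 upstream, P1'..P4' downstream) as an 8 x 30
matrix.  Per residue the 30 features are:

* cols 0-19: one-hot amino acid (alphabetical, A..Y); all-zero for
  positions outside the protein and for non-standard letters,
* cols 20-22: one-hot secondary structure (coil, strand, helix),
* cols 23-24: one-hot solvent exposure (exposed, buried),
* cols 25-26: one-hot disorder flag (disordered, ordered),
* cols 27-29: the (x, y, z) coordinate triple, z-scored per protein and
  per axis (zero for padding).

Structural tracks come from a pluggable :class:`FeatureProvider`; when no
structure is available the structural columns are zero and only the
sequence one-hot carries signal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .core import (
    EXPOSURE_CLASSES,
    SS_CLASSES,
    STANDARD_AA,
    CleavageAnnotation,
    ProteinRecord,
    StructuralFeatures,
    ValidationError,
)
from .synthetic import StructureParams, simulate_structure

WINDOW_SIZE = 8  # P4..P1 + P1'..P4'
UPSTREAM = 4
DOWNSTREAM = 4

AA_BLOCK = slice(0, 20)
SS_BLOCK = slice(20, 23)
EXPOSURE_BLOCK = slice(23, 25)
DISORDER_BLOCK = slice(25, 27)
COORD_BLOCK = slice(27, 30)
N_FEATURES = 30

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
_SS_INDEX = {name: i for i, name in enumerate(SS_CLASSES)}
_EXP_INDEX = {name: i for i, name in enumerate(EXPOSURE_CLASSES)}

ROW_NAMES = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")


@dataclass(frozen=True)
class EncodedWindow:
    """One labelled candidate site: 8 x 30 matrix plus provenance."""

    matrix: np.ndarray
    label: int
    protein_id: str
    p1: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float32)
        if m.shape != (WINDOW_SIZE, N_FEATURES):
            raise ValidationError(f"window matrix must be {WINDOW_SIZE}x{N_FEATURES}")
        object.__setattr__(self, "matrix", m)
        if self.label not in (0, 1):
            raise ValidationError("label must be 0 or 1")


class FeatureProvider(Protocol):
    """Contract: map a protein to per-residue structural features.

    Returning ``None`` means "no structure known"; the encoder then leaves
    all structural blocks zero.
    """

    def __call__(self, protein: ProteinRecord) -> StructuralFeatures | None: ...


class ZeroFeatureProvider:
    """Provider for sequence-only encoding: all structural blocks zero."""

    def __call__(self, protein: ProteinRecord) -> StructuralFeatures | None:
        return None


class SimulatedFeatureProvider:
    """Deterministic simulated structure, seeded per protein id.

    The per-protein seed mixes the provider seed with a CRC of the protein
    id, so features depend only on (seed, params, id, sequence length) and
    are stable across processes.
    """

    def __init__(self, seed: int = 0, params: StructureParams | None = None):
        self.seed = seed
        self.params = params or StructureParams()
        self._cache: dict[str, StructuralFeatures] = {}

    def _protein_seed(self, protein_id: str) -> int:
        return (self.seed * 0x9E3779B1 + zlib.crc32(protein_id.encode())) % (2**31 - 1)

    def __call__(self, protein: ProteinRecord) -> StructuralFeatures:
        if protein.id not in self._cache:
            self._cache[protein.id] = simulate_structure(
                protein, self._protein_seed(protein.id), self.params
            )
        return self._cache[protein.id]


class PrecomputedFeatureProvider:
    """Features from an in-memory mapping (e.g. a generated dataset)."""

    def __init__(self, features: Mapping[str, StructuralFeatures]):
        self.features = features

    def __call__(self, protein: ProteinRecord) -> StructuralFeatures | None:
        return self.features.get(protein.id)


class FileFeatureProvider:
    """Features from a per-residue TSV.

    Expected columns: ``protein_id``, ``pos`` (1-based), ``ss`` (coil /
    strand / helix), ``exposure`` (exposed / buried), ``disorder`` (0/1),
    ``x``, ``y``, ``z`` - the shape written by external structure
    predictors or by :func:`cleavesite.synthetic.write_feature_table`.
    """

    def __init__(self, path: str | Path):
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
        self._groups = {pid: g.sort_values("pos") for pid, g in df.groupby("protein_id")}

    def __call__(self, protein: ProteinRecord) -> StructuralFeatures | None:
        g = self._groups.get(protein.id)
        if g is None:
            return None
        if len(g) != protein.length or list(g["pos"]) != list(range(1, protein.length + 1)):
            raise ValidationError(
                f"{protein.id}: feature table does not cover every residue"
            )
        return StructuralFeatures(
            ss_class=tuple(g["ss"]),
            exposure=tuple(g["exposure"]),
            disorder=tuple(bool(int(d)) for d in g["disorder"]),
            coords=g[["x", "y", "z"]].to_numpy(dtype=float),
        )


def residue_feature_matrix(
    protein: ProteinRecord, features: StructuralFeatures | None
) -> np.ndarray:
    """Per-residue (L, 30) feature matrix with coordinates z-scored."""
    L = protein.length
    mat = np.zeros((L, N_FEATURES), dtype=np.float32)
    for i, aa in enumerate(protein.sequence):
        j = _AA_INDEX.get(aa)
        if j is not None:
            mat[i, j] = 1.0
    if features is not None:
        if len(features) != L:
            raise ValidationError(f"{protein.id}: features do not cover every residue")
        for i in range(L):
            mat[i, 20 + _SS_INDEX[features.ss_class[i]]] = 1.0
            mat[i, 23 + _EXP_INDEX[features.exposure[i]]] = 1.0
            mat[i, 25 + (0 if features.disorder[i] else 1)] = 1.0
        coords = np.asarray(features.coords, dtype=np.float64)
        mean = coords.mean(axis=0)
        std = coords.std(axis=0)
        std[std == 0] = 1.0
        mat[:, COORD_BLOCK] = ((coords - mean) / std).astype(np.float32)
    return mat


def _window_from_padded(padded: np.ndarray, p1: int) -> np.ndarray:
    # padded has UPSTREAM leading zero rows; window rows are residues
    # p1-3..p1+4 (1-based) = padded[p1 : p1+8].
    return padded[p1 : p1 + WINDOW_SIZE]


def encode_site(
    protein: ProteinRecord,
    p1: int,
    provider: FeatureProvider,
    label: int = 0,
) -> EncodedWindow:
    """Encode one candidate site as an :class:`EncodedWindow`.

    Rows map to residues ``p1-3 .. p1`` and ``p1+1 .. p1+4``; positions
    outside ``[1, L]`` (near the termini) are all-zero rows.
    """
    if not (1 <= p1 <= protein.length - 1):
        raise ValidationError(
            f"{protein.id}: p1={p1} outside [1, {protein.length - 1}]"
        )
    mat = residue_feature_matrix(protein, provider(protein))
    padded = np.zeros((protein.length + WINDOW_SIZE, N_FEATURES), dtype=np.float32)
    padded[UPSTREAM : UPSTREAM + protein.length] = mat
    return EncodedWindow(
        matrix=_window_from_padded(padded, p1), label=label, protein_id=protein.id, p1=p1
    )


class WindowDataset(Sequence[EncodedWindow]):
    """All candidate windows of a protein set, as dense arrays.

    Behaves as a sequence of :class:`EncodedWindow` while storing the
    matrices in one ``(n, 8, 30)`` float32 array ``X`` with labels ``y``,
    protein ids and p1 positions as parallel arrays - the shape the
    training code consumes directly.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, protein_ids: np.ndarray, p1: np.ndarray):
        self.X = np.asarray(X, dtype=np.float32)
        self.y = np.asarray(y, dtype=np.int8)
        self.protein_ids = np.asarray(protein_ids)
        self.p1 = np.asarray(p1, dtype=np.int64)
        n = len(self.X)
        if not (len(self.y) == len(self.protein_ids) == len(self.p1) == n):
            raise ValidationError("window arrays must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return WindowDataset(self.X[idx], self.y[idx], self.protein_ids[idx], self.p1[idx])
        return EncodedWindow(
            matrix=self.X[idx],
            label=int(self.y[idx]),
            protein_id=str(self.protein_ids[idx]),
            p1=int(self.p1[idx]),
        )

    def subset(self, mask: np.ndarray) -> "WindowDataset":
        return WindowDataset(self.X[mask], self.y[mask], self.protein_ids[mask], self.p1[mask])

    def for_proteins(self, ids: Iterable[str]) -> "WindowDataset":
        ids = set(ids)
        mask = np.array([pid in ids for pid in self.protein_ids])
        return self.subset(mask)

    def relabel(self, positives: set[tuple[str, int]]) -> "WindowDataset":
        """Same windows, labels replaced by membership in ``positives``."""
        y = np.array(
            [(pid, int(p)) in positives for pid, p in zip(self.protein_ids, self.p1)],
            dtype=np.int8,
        )
        return WindowDataset(self.X, y, self.protein_ids, self.p1)


def encode_dataset(
    proteins: Sequence[ProteinRecord],
    annotations: Iterable[CleavageAnnotation],
    protease: str,
    provider: FeatureProvider,
    registry=None,
) -> WindowDataset:
    """Encode every candidate site of every protein, labelled for ``protease``.

    Label is 1 iff (protease, protein, p1) is annotated.  Ordering is
    deterministic: proteins sorted by id, sites by p1.
    """
    if registry is not None and protease not in registry:
        raise ValidationError(f"protease '{protease}' not in registry")
    positives = {
        (a.protein_id, a.p1) for a in annotations if a.protease == protease
    }
    Xs, ys, pids, p1s = [], [], [], []
    for protein in sorted(proteins, key=lambda p: p.id):
        if protein.length < 2:
            continue
        mat = residue_feature_matrix(protein, provider(protein))
        padded = np.zeros((protein.length + WINDOW_SIZE, N_FEATURES), dtype=np.float32)
        padded[UPSTREAM : UPSTREAM + protein.length] = mat
        sites = np.arange(1, protein.length)
        idx = sites[:, None] + np.arange(WINDOW_SIZE)[None, :]
        Xs.append(padded[idx])
        ys.append(
            np.array([(protein.id, int(p1)) in positives for p1 in sites], dtype=np.int8)
        )
        pids.append(np.array([protein.id] * len(sites)))
        p1s.append(sites)
    if not Xs:
        return WindowDataset(
            np.empty((0, WINDOW_SIZE, N_FEATURES), dtype=np.float32),
            np.empty(0, dtype=np.int8),
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
        )
    return WindowDataset(
        np.concatenate(Xs), np.concatenate(ys), np.concatenate(pids), np.concatenate(p1s)
    )
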