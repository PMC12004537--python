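"""Minimum-distance embeddings of receptor conformations and ligand poses.

A structure of *n* residues becomes an *n* × *n* symmetric matrix whose
(i, j) entry is the minimum heavy-atom distance between residues i and j —
a superposition-free representation that captures combined backbone and
side-chain motion. A bound ligand becomes a length-*n* vector of minimum
residue–ligand heavy-atom distances. Matrices flatten to the n(n−1)/2
upper-triangle features for dimensionality reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .structio import Ligand, ResidueKey, StructureRecord

__all__ = [
    "MinDistanceMatrix",
    "LigandDistanceVector",
    "FeatureMatrix",
    "min_distance_matrix",
    "ligand_distance_vector",
    "flatten_ensemble",
    "unflatten",
    "pair_labels",
]


@dataclass
class MinDistanceMatrix:
    """n × n matrix of minimum inter-residue distances (Å), zero diagonal."""

    keys: list[ResidueKey]
    D: np.ndarray
    structure_id: str
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        n = len(self.keys)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match key count")

    def pair(self, i: ResidueKey, j: ResidueKey) -> float:
        a, b = self.keys.index(i), self.keys.index(j)
        return float(self.D[a, b])


@dataclass
class LigandDistanceVector:
    """Length-n vector of minimum residue–ligand distances (Å)."""

    keys: list[ResidueKey]
    v: np.ndarray
    structure_id: str
    ligand_identity: tuple[str, str, int]


@dataclass
class FeatureMatrix:
    """Structures (or ligand entries) × distance features, in Å."""

    ids: list[str]
    labels: list[str]
    X: np.ndarray
    kind: str  # "receptor" or "ligand"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.ids, columns=self.labels)


def _residue_coords(record: StructureRecord, keys: Sequence[ResidueKey],
                    include_hydrogens: bool) -> list[np.ndarray]:
    rmap = record.residue_map()
    coords = []
    for k in keys:
        res = rmap.get(k)
        if res is None:
            raise KeyError(f"residue key {k} absent from {record.id}")
        coords.append(res.coords(include_hydrogens=include_hydrogens))
    return coords


def min_distance_matrix(record: StructureRecord, keys: Sequence[ResidueKey],
                        include_hydrogens: bool = False) -> MinDistanceMatrix:
    """Minimum residue–residue distance matrix over the given keys.

    D[i, j] = min over atom pairs (a in residue i, b in residue j) of the
    Euclidean distance; D[i, i] = 0. Heavy atoms only unless
    ``include_hydrogens``.
    """
    keys = list(keys)
    coords = _residue_coords(record, keys, include_hydrogens)
    n = len(keys)
    D = np.zeros((n, n))
    # minimum taken over squared distances; the single final sqrt keeps the
    # entry bit-identical to min over per-pair Euclidean norms
    for i in range(n):
        for j in range(i + 1, n):
            diff = coords[i][:, None, :] - coords[j][None, :, :]
            D[i, j] = D[j, i] = np.sqrt((diff ** 2).sum(axis=-1).min())
    return MinDistanceMatrix(keys=keys, D=D, structure_id=record.id,
                             include_hydrogens=include_hydrogens)


def ligand_distance_vector(record: StructureRecord, ligand: Ligand,
                           keys: Sequence[ResidueKey],
                           include_hydrogens: bool = False) -> LigandDistanceVector:
    """Minimum residue–ligand distance per residue key.

    A zero entry (ligand atom coincident with a residue atom) is reported
    as a clash warning but retained.
    """
    keys = list(keys)
    coords = _residue_coords(record, keys, include_hydrogens)
    lxyz = ligand.coords(include_hydrogens=include_hydrogens)
    v = np.array([np.sqrt(((c[:, None, :] - lxyz[None, :, :]) ** 2)
                          .sum(axis=-1).min()) for c in coords])
    if np.any(v == 0.0):
        clashing = [keys[i] for i in np.flatnonzero(v == 0.0)]
        warnings.warn(f"{record.id}/{ligand.identity}: zero residue-ligand "
                      f"distance (clash) at {clashing}")
    return LigandDistanceVector(keys=keys, v=v, structure_id=record.id,
                                ligand_identity=ligand.identity)


def _key_label(k: ResidueKey) -> str:
    chain, num, icode = k
    return f"{chain}{num}{icode}"


def pair_labels(keys: Sequence[ResidueKey]) -> list[str]:
    """Upper-triangle (i < j) pair labels in the given key order."""
    keys = list(keys)
    return [f"{_key_label(keys[i])}-{_key_label(keys[j])}"
            for i in range(len(keys)) for j in range(i + 1, len(keys))]


def flatten_ensemble(items: Sequence[MinDistanceMatrix] | Sequence[LigandDistanceVector],
                     ) -> FeatureMatrix:
    """Stack an ensemble into a feature matrix.

    Receptor matrices flatten to their n(n−1)/2 upper-triangle entries in
    (i < j) lexicographic key order; ligand vectors stack as rows indexed by
    residue key. All items must share identical keys.
    """
    if not items:
        raise ValueError("no items to flatten")
    ref_keys = items[0].keys
    bad = [getattr(it, "structure_id", "?") for it in items if it.keys != ref_keys]
    if bad:
        raise ValueError(f"residue keys differ from first item for: {bad}")

    if isinstance(items[0], MinDistanceMatrix):
        n = len(ref_keys)
        iu = np.triu_indices(n, k=1)
        X = np.array([it.D[iu] for it in items])
        return FeatureMatrix(ids=[it.structure_id for it in items],
                             labels=pair_labels(ref_keys), X=X, kind="receptor")
    X = np.array([it.v for it in items])
    ids = [f"{it.structure_id}:{it.ligand_identity[0]}_{it.ligand_identity[2]}"
           for it in items]
    return FeatureMatrix(ids=ids, labels=[_key_label(k) for k in ref_keys],
                         X=X, kind="ligand")


def unflatten(row: np.ndarray, keys: Sequence[ResidueKey],
              structure_id: str = "") -> MinDistanceMatrix:
    """Inverse of receptor flattening: rebuild the symmetric matrix."""
    n = len(keys)
    if row.shape != (n * (n - 1) // 2,):
        raise ValueError("feature row length does not match n(n-1)/2")
    D = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    D[iu] = row
    D += D.T
    return MinDistanceMatrix(keys=list(keys), D=D, structure_id=structure_id)
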