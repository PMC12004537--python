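"""Docking-pose evaluation metrics and benchmark aggregation.

Two success rules are supported:

* **self-docking** — a pose succeeds when its heavy-atom,
  symmetry-corrected RMSD to the crystal ligand is below 2 Å (no
  realignment: docking and crystal share a frame);
* **cross-docking** — the docked receptor is superposed onto the reference
  receptor over their shared Cα atoms (Kabsch least squares), the pose is
  carried along, and success is a ligand heavy-atom centroid within 5 Å of
  the crystal ligand centroid. The looser rule acknowledges that a
  rigid-receptor pose in a different conformation cannot reproduce the
  crystal contacts atom-for-atom but can still find the right pocket.

A complex succeeds when at least one pose (optionally restricted to the
top-k ranked) passes; per-binding-mode success fractions aggregate the
complexes. ΔPop/ΔRank diagnostics compare the population and rank of the
correct pose cluster against the best false-positive cluster. Butina
sphere-exclusion clustering deduplicates ligand conformers by pairwise
aligned RMSD.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Pose",
    "PoseSet",
    "load_benchmark_dir",
    "EvalResult",
    "RankDiagnostic",
    "kabsch_align",
    "pose_rmsd",
    "centroid_metric",
    "evaluate_complexes",
    "rank_diagnostics",
    "butina_dedup",
    "SELF_RMSD_THRESHOLD",
    "CROSS_CENTROID_THRESHOLD",
]

SELF_RMSD_THRESHOLD = 2.0       # Å, strict <
CROSS_CENTROID_THRESHOLD = 5.0  # Å, strict <

# single-bond covalent radii (Å) for bond perception in symmetry RMSD
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "B": 0.84, "SE": 1.20,
}
_BOND_TOLERANCE = 0.45  # Å added to radii sum
_MAX_AUTOMORPHISMS = 10000


@dataclass
class Pose:
    """One docked pose: heavy-atom elements + coordinates, score, rank."""

    elements: list[str]
    coords: np.ndarray
    score: float
    rank: int


@dataclass
class PoseSet:
    """All poses for one receptor–ligand complex plus references."""

    complex_id: str
    receptor_id: str
    ligand_id: str
    binding_mode: str
    poses: list[Pose]
    ref_elements: list[str]
    ref_coords: np.ndarray
    ref_receptor_ca: Mapping[tuple, np.ndarray] = field(default_factory=dict)
    docked_receptor_ca: Mapping[tuple, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = sorted(p.rank for p in self.poses)
        if ranks != list(range(1, len(self.poses) + 1)):
            raise ValueError(f"{self.complex_id}: ranks must be 1..P without gaps")


@dataclass
class EvalResult:
    """Per-complex metrics and per-binding-mode success fractions."""

    rule: str
    top_k: Optional[int]
    per_complex: dict[str, dict] = field(default_factory=dict)
    group_fractions: dict[str, float] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def overall_fraction(self) -> float:
        flags = [v["success"] for v in self.per_complex.values()]
        return float(np.mean(flags)) if flags else float("nan")


@dataclass
class RankDiagnostic:
    complex_id: str
    delta_pop: int
    delta_rank: int


def kabsch_align(mobile: np.ndarray, target: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation R, translation t, fit RMSD) with the proper rotation
    (det +1) such that ``mobile @ R.T + t ≈ target``. Requires ≥3
    non-collinear points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3 or P.shape[1] != 3:
        raise ValueError("need matching (m>=3, 3) point sets")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(np.vstack([P0, Q0]), tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


def _bond_graph(elements: Sequence[str], coords: np.ndarray) -> nx.Graph:
    """Perceive bonds from covalent radii; nodes labeled by element."""
    g = nx.Graph()
    els = [e.upper() for e in elements]
    for i, e in enumerate(els):
        g.add_node(i, element=e)
    n = len(els)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        ri = _COVALENT_RADII.get(els[i], 0.77)
        for j in range(i + 1, n):
            rj = _COVALENT_RADII.get(els[j], 0.77)
            if d[i, j] < ri + rj + _BOND_TOLERANCE:
                g.add_edge(i, j)
    return g


def _automorphisms(g: nx.Graph):
    """Element-preserving graph automorphisms, identity first."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    count = 0
    yield {i: i for i in g.nodes}
    for mapping in gm.isomorphisms_iter():
        count += 1
        if count > _MAX_AUTOMORPHISMS:
            warnings.warn("automorphism enumeration truncated")
            return
        yield mapping


def _check_formula(a: Sequence[str], b: Sequence[str]) -> None:
    fa = sorted(e.upper() for e in a)
    fb = sorted(e.upper() for e in b)
    if fa != fb:
        raise ValueError(f"heavy-atom formula mismatch: {fa} vs {fb}")


def pose_rmsd(pose_elements: Sequence[str], pose_coords: np.ndarray,
              ref_elements: Sequence[str], ref_coords: np.ndarray,
              symmetry: bool = True) -> float:
    """Heavy-atom RMSD of a pose to the reference, in the shared frame.

    With ``symmetry`` on, the minimum RMSD over chemically equivalent atom
    mappings (element-preserving automorphisms of the reference bond
    graph) is returned; otherwise the naive atom-order RMSD. No
    realignment is performed.
    """
    _check_formula(pose_elements, ref_elements)
    P = np.asarray(pose_coords, dtype=float)
    Q = np.asarray(ref_coords, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("pose and reference atom counts differ")

    def _rmsd(perm: Sequence[int]) -> float:
        return float(np.sqrt(np.mean(np.sum((P[list(perm)] - Q) ** 2, axis=1))))

    if not symmetry:
        return _rmsd(range(len(P)))
    g = _bond_graph(ref_elements, Q)
    best = np.inf
    for mapping in _automorphisms(g):
        perm = [mapping[i] for i in range(len(P))]
        best = min(best, _rmsd(perm))
    return best


def centroid_metric(pose_coords: np.ndarray, ref_pose_coords: np.ndarray,
                    docked_receptor_ca: Mapping, ref_receptor_ca: Mapping,
                    ) -> float:
    """Ligand-centroid distance after all-Cα receptor alignment.

    The docked receptor is superposed onto the reference over the
    intersection of their Cα keys; the same transform carries the pose.
    Returns the Euclidean distance between heavy-atom centroids of the
    transformed pose and the reference ligand. A warning is attached when
    fewer than half the reference Cα are shared.
    """
    shared = sorted(set(docked_receptor_ca) & set(ref_receptor_ca))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared Cα keys for alignment")
    if len(shared) < 0.5 * len(ref_receptor_ca):
        warnings.warn(f"only {len(shared)}/{len(ref_receptor_ca)} reference "
                      "Cα shared for alignment")
    mobile = np.array([docked_receptor_ca[k] for k in shared])
    target = np.array([ref_receptor_ca[k] for k in shared])
    R, t, _ = kabsch_align(mobile, target)
    moved = np.asarray(pose_coords, dtype=float) @ R.T + t
    return float(np.linalg.norm(moved.mean(axis=0)
                                - np.asarray(ref_pose_coords).mean(axis=0)))


def _pose_metric(ps: PoseSet, pose: Pose, rule: str) -> float:
    if rule == "self":
        return pose_rmsd(pose.elements, pose.coords, ps.ref_elements,
                         ps.ref_coords)
    if rule == "cross":
        return centroid_metric(pose.coords, ps.ref_coords,
                               ps.docked_receptor_ca, ps.ref_receptor_ca)
    raise ValueError(f"unknown rule {rule!r}")


def _threshold(rule: str) -> float:
    return SELF_RMSD_THRESHOLD if rule == "self" else CROSS_CENTROID_THRESHOLD


def evaluate_complexes(pose_sets: Sequence[PoseSet], rule: str = "self",
                       top_k: Optional[int] = None) -> EvalResult:
    """Success fractions per binding mode under the chosen rule.

    A complex succeeds when any considered pose (rank ≤ ``top_k`` if given)
    beats the rule's threshold (strict <). Empty groups are reported as
    absent, not as zero.
    """
    res = EvalResult(rule=rule, top_k=top_k)
    by_mode: dict[str, list[bool]] = {}
    for ps in pose_sets:
        considered = [p for p in ps.poses
                      if top_k is None or p.rank <= top_k]
        metrics = {p.rank: _pose_metric(ps, p, rule) for p in considered}
        best_rank = None
        if metrics:
            ok = {r: m for r, m in metrics.items() if m < _threshold(rule)}
            if ok:
                best_rank = min(ok)
        success = best_rank is not None
        best_metric = min(metrics.values()) if metrics else float("nan")
        res.per_complex[ps.complex_id] = {
            "binding_mode": ps.binding_mode,
            "best_metric": best_metric,
            "success": success,
            "best_success_rank": best_rank,
        }
        by_mode.setdefault(ps.binding_mode, []).append(success)
    for mode, flags in by_mode.items():
        res.group_fractions[mode] = float(np.mean(flags))
        res.group_sizes[mode] = len(flags)
    return res


def rank_diagnostics(pose_set: PoseSet, cluster_threshold: float = 2.0,
                     rule: str = "self") -> Optional[RankDiagnostic]:
    """ΔPop/ΔRank of the correct pose cluster versus false positives.

    Poses are clustered by pairwise symmetry-corrected RMSD with complete
    linkage cut at ``cluster_threshold``. A cluster is correct when any
    member passes the active success rule. ΔPop = population of the
    correct cluster (the one holding the best-ranked correct pose) minus
    the largest incorrect-cluster population. ΔRank = best rank among
    incorrect clusters minus best rank in the correct cluster: positive
    means the correct pose outranks every false positive. Absent when all
    poses are correct or all incorrect.
    """
    poses = pose_set.poses
    if len(poses) < 2:
        raise ValueError("need at least 2 poses")
    m = len(poses)
    dm = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        dm[i, j] = dm[j, i] = pose_rmsd(poses[i].elements, poses[i].coords,
                                        poses[j].elements, poses[j].coords)
    labels = fcluster(linkage(squareform(dm), method="complete"),
                      t=cluster_threshold, criterion="distance")
    passes = np.array([_pose_metric(pose_set, p, rule) < _threshold(rule)
                       for p in poses])
    correct_clusters = {int(c) for c, ok in zip(labels, passes) if ok}
    incorrect_clusters = set(int(c) for c in labels) - correct_clusters
    if not correct_clusters or not incorrect_clusters:
        return None
    ranks = np.array([p.rank for p in poses])
    best_correct_rank = ranks[passes].min()
    chosen = int(labels[np.flatnonzero(passes & (ranks == best_correct_rank))[0]])
    pop_correct = int(np.sum(labels == chosen))
    pop_incorrect = max(int(np.sum(labels == c)) for c in incorrect_clusters)
    best_incorrect_rank = min(int(ranks[labels == c].min())
                              for c in incorrect_clusters)
    return RankDiagnostic(
        complex_id=pose_set.complex_id,
        delta_pop=pop_correct - pop_incorrect,
        delta_rank=best_incorrect_rank - int(best_correct_rank),
    )


def butina_dedup(conformers: Sequence[np.ndarray], threshold: float = 2.0,
                 elements: Optional[Sequence[str]] = None,
                 ) -> tuple[list[int], list[list[int]]]:
    """Butina sphere-exclusion clustering of conformers by aligned RMSD.

    The pairwise matrix holds the RMSD after optimal superposition of each
    conformer pair. Clustering follows the neighbor-count definition:
    repeatedly take the unassigned conformer with the most unassigned
    neighbors within ``threshold`` (ties → lowest index) as a centroid and
    assign its neighbors to it. Returns (centroid indices, clusters as
    index lists).
    """
    confs = [np.asarray(c, dtype=float) for c in conformers]
    if not confs:
        raise ValueError("no conformers")
    shape = confs[0].shape
    if any(c.shape != shape for c in confs):
        raise ValueError("conformers differ in atom count")
    n = len(confs)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        _, _, rmsd = kabsch_align(confs[i], confs[j])
        dm[i, j] = dm[j, i] = rmsd

    unassigned = set(range(n))
    reps: list[int] = []
    clusters: list[list[int]] = []
    while unassigned:
        counts = {i: sum(1 for j in unassigned
                         if j != i and dm[i, j] <= threshold)
                  for i in unassigned}
        centroid = min(counts, key=lambda i: (-counts[i], i))
        members = [centroid] + sorted(j for j in unassigned
                                      if j != centroid and dm[centroid, j] <= threshold)
        reps.append(centroid)
        clusters.append(members)
        unassigned -= set(members)
    return reps, clusters


# --- benchmark directory layout -------------------------------------------

def _read_ligand_pdb(path) -> tuple[list[str], np.ndarray]:
    """Read elements + coordinates from a ligand-only PDB (HETATM lines)."""
    elements, coords = [], []
    for line in open(path):
        if line.startswith(("HETATM", "ATOM")):
            elements.append(line[76:78].strip() or line[12:16].strip()[0])
            coords.append([float(line[30:38]), float(line[38:46]),
                           float(line[46:54])])
    if not elements:
        raise ValueError(f"no atoms in {path}")
    return elements, np.array(coords)


def load_benchmark_dir(bench_dir) -> list[PoseSet]:
    """Load a benchmark directory (scores.csv + poses/ + refs/ +
    receptor_ca.csv) written by :func:`mdmr.synthgen.write_benchmark_dir`
    or prepared by hand in the same layout."""
    import pandas as pd
    from pathlib import Path

    bench_dir = Path(bench_dir)
    scores = pd.read_csv(bench_dir / "scores.csv", comment="#")
    ca_df = pd.read_csv(bench_dir / "receptor_ca.csv", comment="#")
    ca_by_role: dict[str, dict] = {}
    for role, grp in ca_df.groupby("role"):
        ca_by_role[role] = {
            (row.chain, int(row.resnum), str(row.icode) if pd.notna(row.icode) else ""):
            np.array([row.x, row.y, row.z]) for row in grp.itertuples()}
    pose_sets = []
    for cid, grp in scores.groupby("complex_id", sort=True):
        grp = grp.sort_values("rank")
        ref_el, ref_xyz = _read_ligand_pdb(bench_dir / "refs" / f"{cid}.pdb")
        poses = []
        for row in grp.itertuples():
            el, xyz = _read_ligand_pdb(bench_dir / row.pose_file)
            poses.append(Pose(elements=el, coords=xyz, score=float(row.score),
                              rank=int(row.rank)))
        pose_sets.append(PoseSet(
            complex_id=str(cid), receptor_id="receptor",
            ligand_id=str(cid), binding_mode=str(grp["binding_mode"].iloc[0]),
            poses=poses, ref_elements=ref_el, ref_coords=ref_xyz,
            ref_receptor_ca=ca_by_role.get("ref", {}),
            docked_receptor_ca=ca_by_role.get("docked",
                                              ca_by_role.get("ref", {})),
        ))
    return pose_sets
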