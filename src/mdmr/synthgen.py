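"""Synthetic multi-state ensembles and docking benchmarks with ground truth.

The ensemble generator emulates the one feature of real conformational
ensembles that the downstream statistics depend on: designated residue
pairs toggling between an "interaction formed" state (minimum distance
around 2.8 Å, hydrogen-bond/salt-bridge range) and a "broken" state
(around 8 Å), with Gaussian noise on the realized distance. Backbone
pseudo-atoms (CA) are laid on a ring with ~6 Å spacing so that untoggled
residue pairs keep large, nearly constant separations; each planted pair
is realized by a side-chain pseudo-atom (SG) of the second residue placed
along the first residue's outward normal at the state's distance from its
CB. The geometry is deliberately not protein-like — only the distance
statistics matter.

The benchmark generator builds complexes whose poses are pure translations
of the reference ligand, so every success metric is known analytically
from the planted displacement magnitudes.

All randomness flows from the single seed in each spec; identical specs
produce identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .benchmark import Pose, PoseSet
from .structio import Atom, Ligand, Residue, StructureRecord, write_record

__all__ = [
    "StateSpec",
    "EnsembleSpec",
    "EnsembleManifest",
    "BenchmarkSpec",
    "BenchmarkManifest",
    "generate_ensemble",
    "generate_benchmark",
    "write_benchmark_dir",
]


@dataclass
class StateSpec:
    """One conformational state: its ensemble fraction and which planted
    residue pairs (author numbers, i < j) are formed in it."""

    id: str
    fraction: float
    formed_pairs: list[tuple[int, int]] = field(default_factory=list)
    ligand_pocket: Optional[int] = None  # residue number hosting a toy ligand


@dataclass
class EnsembleSpec:
    n_residues: int = 40
    states: list[StateSpec] = field(default_factory=lambda: [
        StateSpec("inactive", 0.5, [(5, 15), (9, 21)]),
        StateSpec("active", 0.5, [(13, 25), (17, 29)]),
    ])
    n_structures: int = 40
    mu_formed: float = 2.8      # Å, formed-pair minimum distance
    mu_broken: float = 8.0      # Å, broken-pair minimum distance
    sigma: float = 0.26         # Å, noise on realized pair distances
    coord_jitter: float = 0.02  # Å, isotropic jitter on backbone atoms
    spacing: float = 6.0        # Å between consecutive CA pseudo-atoms
    chain_id: str = "S"
    seed: int = 0
    #: structure index -> internal (start, end) residue runs to delete
    deletions: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(s.fraction for s in self.states) - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")
        if self.mu_formed < 1.8:
            raise ValueError("infeasible geometry: mu_formed < 1.8 Å")
        used: set[int] = set()
        for s in self.states:
            for i, j in s.formed_pairs:
                if not (1 <= i < j <= self.n_residues):
                    raise ValueError(f"pair {(i, j)} outside 1..{self.n_residues}")
                if j - i < 4:
                    raise ValueError(f"pair {(i, j)} too close in sequence (need |i-j| >= 4)")
        for pair in self.all_pairs():
            if used & set(pair):
                raise ValueError(f"residue reused across planted pairs: {pair}")
            used |= set(pair)

    def all_pairs(self) -> list[tuple[int, int]]:
        seen: list[tuple[int, int]] = []
        for s in self.states:
            for p in s.formed_pairs:
                if p not in seen:
                    seen.append(p)
        return seen

    @property
    def separation_ratio(self) -> float:
        """Inter-state distance gap over noise; >= 4 counts as separable."""
        return (self.mu_broken - self.mu_formed) / self.sigma


@dataclass
class EnsembleManifest:
    """Ground truth for a generated ensemble."""

    spec: EnsembleSpec
    structure_states: dict[str, str]            # record id -> state id
    formed_pairs: dict[str, list[str]]          # state id -> pair labels
    deleted: dict[str, list[tuple[int, int]]]   # record id -> deleted runs

    def planted_sets(self, x_state: str, y_state: str) -> tuple[set[str], set[str]]:
        """(R1, R3) pair labels for the comparison x = ``x_state`` vs
        y = ``y_state``: R3 formed only in y, R1 formed only in x."""
        fx = set(self.formed_pairs[x_state])
        fy = set(self.formed_pairs[y_state])
        return fx - fy, fy - fx

    def state_labels(self, ids: Sequence[str]) -> list[str]:
        return [self.structure_states[i] for i in ids]


def _pair_label(chain: str, i: int, j: int) -> str:
    return f"{chain}{i}-{chain}{j}"


def generate_ensemble(spec: EnsembleSpec, out_dir: Optional[str | Path] = None,
                      ) -> tuple[list[StructureRecord], EnsembleManifest]:
    """Generate a multi-state ensemble with a ground-truth manifest.

    Structures are assigned to states by the spec fractions (largest
    remainders fill rounding slack), in an order shuffled by the seed.
    When ``out_dir`` is given, each record is also written as a PDB file
    named after its stem.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    radius = spec.spacing / (2.0 * math.sin(math.pi / n))
    angles = 2.0 * math.pi * np.arange(n) / n
    normals = np.stack([np.cos(angles), np.sin(angles), np.zeros(n)], axis=1)
    ca = radius * normals
    cb = (radius + 1.5) * normals

    # deterministic state assignment honoring fractions
    counts = [int(math.floor(s.fraction * spec.n_structures)) for s in spec.states]
    k = 0
    while sum(counts) < spec.n_structures:
        counts[k % len(counts)] += 1
        k += 1
    state_seq = [s for s, c in zip(spec.states, counts) for _ in range(c)]
    rng.shuffle(state_seq)

    donors = {j: i for i, j in spec.all_pairs()}  # residue j hosts SG near i
    records: list[StructureRecord] = []
    manifest = EnsembleManifest(
        spec=spec,
        structure_states={},
        formed_pairs={s.id: [_pair_label(spec.chain_id, i, j)
                             for i, j in s.formed_pairs] for s in spec.states},
        deleted={},
    )

    for idx, state in enumerate(state_seq):
        stem = f"s{idx:03d}"
        rec_id = f"{stem}_{spec.chain_id}"
        formed = set(state.formed_pairs)
        residues = []
        for r in range(1, n + 1):
            i0 = r - 1
            atoms = [
                Atom("C", "CA", *(ca[i0] + rng.normal(0, spec.coord_jitter, 3))),
                Atom("C", "CB", *(cb[i0] + rng.normal(0, spec.coord_jitter, 3))),
            ]
            if r in donors:
                partner = donors[r]
                pair = (partner, r)
                mu = spec.mu_formed if pair in formed else spec.mu_broken
                dist = mu + rng.normal(0, spec.sigma)
                pos = cb[partner - 1] + dist * normals[partner - 1]
                atoms.append(Atom("S", "SG", *pos))
            name = "CYS" if r in donors else "ALA"
            residues.append(Residue(key=(spec.chain_id, r, ""), name=name,
                                    atoms=atoms))
        deleted_runs = spec.deletions.get(idx, [])
        drop = {num for a, b in deleted_runs for num in range(a, b + 1)}
        residues = [res for res in residues if res.key[1] not in drop]

        ligands = []
        if state.ligand_pocket is not None:
            p = state.ligand_pocket - 1
            base = cb[p] + (3.5 + rng.normal(0, spec.sigma)) * normals[p]
            tangent = np.array([-normals[p][1], normals[p][0], 0.0])
            ligands.append(Ligand(identity=("LIG", spec.chain_id, 900), atoms=[
                Atom("C", "C1", *base),
                Atom("C", "C2", *(base + 1.4 * tangent)),
                Atom("O", "O1", *(base + 1.4 * np.array([0.0, 0.0, 1.0]))),
            ]))

        rec = StructureRecord(id=rec_id, residues=residues, ligands=ligands,
                              resolution=round(1.5 + 1.5 * rng.random(), 2))
        records.append(rec)
        manifest.structure_states[rec_id] = state.id
        if deleted_runs:
            manifest.deleted[rec_id] = list(deleted_runs)
        if out_dir is not None:
            write_record(rec, Path(out_dir) / f"{stem}.pdb")
    return records, manifest


# --- docking benchmarks ----------------------------------------------------

#: asymmetric 5-heavy-atom toy ligand (local frame, Å)
_TOY_LIGAND = np.array([
    [0.0, 0.0, 0.0],
    [1.5, 0.0, 0.0],
    [2.3, 1.2, 0.0],
    [1.5, 2.4, 0.3],
    [-0.7, -1.1, 0.6],
])
_TOY_ELEMENTS = ["C", "C", "N", "O", "C"]


@dataclass
class BenchmarkSpec:
    n_complexes: int = 20
    n_decoys: int = 8
    displacement_range: tuple[float, float] = (1.0, 12.0)  # Å, uniform draw
    binding_modes: tuple[str, ...] = ("orthosteric", "allosteric")
    true_rank: Optional[int] = None  # None -> uniform random in 1..P
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.displacement_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid displacement range")


@dataclass
class BenchmarkManifest:
    """Planted displacements; success is analytic from them."""

    spec: BenchmarkSpec
    displacements: dict[str, list[float]]  # complex id -> by rank (1..P)
    true_rank: dict[str, int]
    binding_mode: dict[str, str]

    def predicted_fraction(self, threshold: float,
                           top_k: Optional[int] = None,
                           mode: Optional[str] = None) -> float:
        flags = []
        for cid, disp in self.displacements.items():
            if mode is not None and self.binding_mode[cid] != mode:
                continue
            considered = disp if top_k is None else disp[:top_k]
            flags.append(any(d < threshold for d in considered))
        return float(np.mean(flags)) if flags else float("nan")


def _helix_ca(n: int = 20) -> dict[tuple, np.ndarray]:
    t = np.arange(n)
    pts = np.stack([2.3 * np.cos(t * 1.75), 2.3 * np.sin(t * 1.75), 1.5 * t],
                   axis=1)
    return {("R", int(i + 1), ""): pts[i] for i in range(n)}


def generate_benchmark(spec: BenchmarkSpec,
                       ) -> tuple[list[PoseSet], BenchmarkManifest]:
    """Generate pose sets whose metrics are known from construction.

    Every pose is the reference ligand translated rigidly by a planted
    displacement (the designated true pose by 0 Å), so both the
    self-docking RMSD and the cross-docking centroid distance of a pose
    equal its displacement exactly. Docked and reference receptors share a
    frame.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.displacement_range
    receptor_ca = _helix_ca()
    pose_sets: list[PoseSet] = []
    manifest = BenchmarkManifest(spec=spec, displacements={}, true_rank={},
                                 binding_mode={})
    for c in range(spec.n_complexes):
        cid = f"cplx{c:03d}"
        mode = spec.binding_modes[c % len(spec.binding_modes)]
        anchor = np.array([6.0, 0.0, 3.0 + 1.1 * c]) + rng.normal(0, 0.5, 3)
        ref = _TOY_LIGAND + anchor
        n_poses = spec.n_decoys + 1
        t_rank = (spec.true_rank if spec.true_rank is not None
                  else int(rng.integers(1, n_poses + 1)))
        decoy_disp = rng.uniform(lo, hi, spec.n_decoys)
        disp_by_rank: list[float] = []
        poses: list[Pose] = []
        di = 0
        for rank in range(1, n_poses + 1):
            if rank == t_rank:
                d = 0.0
            else:
                d = float(decoy_disp[di])
                di += 1
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords = ref + d * direction
            poses.append(Pose(elements=list(_TOY_ELEMENTS), coords=coords,
                              score=float(n_poses - rank), rank=rank))
            disp_by_rank.append(d)
        pose_sets.append(PoseSet(
            complex_id=cid, receptor_id="R0", ligand_id=f"lig{c:03d}",
            binding_mode=mode, poses=poses,
            ref_elements=list(_TOY_ELEMENTS), ref_coords=ref,
            ref_receptor_ca=receptor_ca, docked_receptor_ca=receptor_ca,
        ))
        manifest.displacements[cid] = disp_by_rank
        manifest.true_rank[cid] = t_rank
        manifest.binding_mode[cid] = mode
    return pose_sets, manifest


def _write_ligand_pdb(elements: Sequence[str], coords: np.ndarray,
                      path: Path, resname: str = "LIG") -> None:
    from .structio import _pdb_atom_line

    lines = []
    for i, (el, xyz) in enumerate(zip(elements, coords), start=1):
        atom = Atom(el, f"{el}{i}", float(xyz[0]), float(xyz[1]), float(xyz[2]))
        lines.append(_pdb_atom_line("HETATM", i, atom, resname, ("L", 1, "")))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_benchmark_dir(pose_sets: Sequence[PoseSet],
                        manifest: BenchmarkManifest,
                        out_dir: str | Path) -> Path:
    """Serialize pose sets as the on-disk benchmark layout.

    Layout: ``scores.csv`` (complex_id, rank, score, binding_mode,
    pose_file), per-pose PDB files under ``poses/``, reference ligands
    under ``refs/``, shared Cα coordinates in ``receptor_ca.csv``, and the
    ground-truth ``manifest.json``.
    """
    import json

    out = Path(out_dir)
    (out / "poses").mkdir(parents=True, exist_ok=True)
    (out / "refs").mkdir(exist_ok=True)
    rows = ["complex_id,rank,score,binding_mode,pose_file"]
    for ps in pose_sets:
        _write_ligand_pdb(ps.ref_elements, ps.ref_coords,
                          out / "refs" / f"{ps.complex_id}.pdb")
        for p in sorted(ps.poses, key=lambda p: p.rank):
            rel = f"poses/{ps.complex_id}_r{p.rank}.pdb"
            _write_ligand_pdb(p.elements, p.coords, out / rel)
            rows.append(f"{ps.complex_id},{p.rank},{p.score},"
                        f"{ps.binding_mode},{rel}")
    (out / "scores.csv").write_text("\n".join(rows) + "\n")

    ca_rows = ["role,chain,resnum,icode,x,y,z"]
    first = pose_sets[0]
    for role, mapping in (("ref", first.ref_receptor_ca),
                          ("docked", first.docked_receptor_ca)):
        for (ch, num, icode), xyz in sorted(mapping.items()):
            ca_rows.append(f"{role},{ch},{num},{icode},"
                           f"{xyz[0]:.3f},{xyz[1]:.3f},{xyz[2]:.3f}")
    (out / "receptor_ca.csv").write_text("\n".join(ca_rows) + "\n")

    (out / "manifest.json").write_text(json.dumps({
        "seed": manifest.spec.seed,
        "displacements": manifest.displacements,
        "true_rank": manifest.true_rank,
        "binding_mode": manifest.binding_mode,
    }, indent=2, sort_keys=True) + "\n")
    return out
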