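"""Structure input/output and the shared residue key system.

Residues are identified by ``(chain id, author residue number, insertion
code)`` — the author numbering published with each structure, not a
sequential index — so that the same residue can be compared across every
member of a conformational ensemble. All downstream matrices and vectors
are indexed by an ordered list of these keys.

Hydrogens are parsed but flagged; distance computations downstream exclude
them by default because they are usually absent from X-ray models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Ligand",
    "StructureRecord",
    "ResidueKey",
    "DEFAULT_EXCLUDED_HET",
    "ParseError",
    "parse_structures",
    "common_residue_keys",
    "write_record",
]

#: (chain id, author residue number, insertion code)
ResidueKey = tuple[str, int, str]

#: Heteroatom component codes never treated as ligands: water, common
#: mono-/di-valent ions, cryoprotectants and buffer components. Editable:
#: pass a custom set to :func:`parse_structures`.
DEFAULT_EXCLUDED_HET: frozenset[str] = frozenset({
    "HOH", "DOD", "WAT",
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "FE2", "NI", "CU",
    "CO", "CD", "BR", "IOD", "F", "CS", "LI", "SR", "BA", "RB", "HG",
    "SO4", "PO4", "NO3", "ACT", "FMT", "CO3", "AZI", "NH4",
    "GOL", "EDO", "PEG", "PGE", "PG4", "MPD", "DMS", "BME", "MRD",
    "EOH", "MOH", "IPA", "ACY", "TRS", "EPE", "MES", "BCT", "CAC",
})

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


class ParseError(ValueError):
    """Raised when a structure file cannot be read or yields no residues."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, name, coordinates in Å, occupancy, altloc."""

    element: str
    name: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""
    is_hydrogen: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    """A polymer residue with at least one heavy atom."""

    key: ResidueKey
    name: str
    atoms: list[Atom]

    def coords(self, include_hydrogens: bool = False) -> np.ndarray:
        """(m, 3) coordinate array; heavy atoms only unless requested."""
        sel = self.atoms if include_hydrogens else [a for a in self.atoms if not a.is_hydrogen]
        if not sel:
            raise ValueError(f"residue {self.key} has no heavy atoms")
        return np.array([[a.x, a.y, a.z] for a in sel], dtype=float)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Ligand:
    """A bound small molecule: (component code, chain, residue number)."""

    identity: tuple[str, str, int]
    atoms: list[Atom]

    @property
    def code(self) -> str:
        return self.identity[0]

    def coords(self, include_hydrogens: bool = False) -> np.ndarray:
        sel = self.atoms if include_hydrogens else [a for a in self.atoms if not a.is_hydrogen]
        if not sel:
            raise ValueError(f"ligand {self.identity} has no heavy atoms")
        return np.array([[a.x, a.y, a.z] for a in sel], dtype=float)


@dataclass
class StructureRecord:
    """One protein copy: ordered residues, assigned ligands, provenance."""

    id: str
    residues: list[Residue]
    ligands: list[Ligand] = field(default_factory=list)
    resolution: Optional[float] = None
    source: Optional[Path] = None

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"{self.id}: duplicate residue keys")
        self.residues = sorted(self.residues, key=lambda r: r.key)

    def keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues}

    def ca_coords(self, keys: Optional[Sequence[ResidueKey]] = None) -> dict[ResidueKey, np.ndarray]:
        """Cα coordinates keyed by residue; residues without a CA are skipped."""
        out: dict[ResidueKey, np.ndarray] = {}
        rmap = self.residue_map()
        for k in (keys if keys is not None else self.keys()):
            res = rmap.get(k)
            if res is None:
                continue
            ca = res.atom("CA")
            if ca is not None and not ca.is_hydrogen:
                out[k] = ca.xyz
        return out


def _is_hydrogen(element: str) -> bool:
    return element.upper() in _HYDROGEN_ELEMENTS


def _filter_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one altloc per atom name: highest occupancy, ties alphabetical."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            kept.append(group[0])
        else:
            kept.append(min(group, key=lambda a: (-a.occupancy, a.altloc)))
    return kept


def _convert_atoms(res: gemmi.Residue) -> list[Atom]:
    atoms = []
    for at in res:
        el = at.element.name if at.element else "X"
        atoms.append(Atom(
            element=el,
            name=at.name,
            x=at.pos.x, y=at.pos.y, z=at.pos.z,
            occupancy=at.occ,
            altloc=at.altloc if at.altloc else "",
            is_hydrogen=_is_hydrogen(el),
        ))
    return _filter_altlocs(atoms)


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def parse_structures(
    path: str | Path,
    chain: Optional[str] = None,
    exclusion: Iterable[str] = DEFAULT_EXCLUDED_HET,
    per_model: bool = False,
) -> list[StructureRecord]:
    """Parse a PDB or mmCIF file into one record per protein copy.

    Each protein chain (per model, if ``per_model``) becomes its own
    :class:`StructureRecord`. For atoms with alternate locations only the
    highest-occupancy altloc is kept (ties broken alphabetically). Waters
    and components on the exclusion list are dropped; remaining heteroatom
    groups become :class:`Ligand` objects assigned to the protein copy with
    the smallest minimum heavy-atom distance.

    Multi-model files default to the first model; ``per_model=True`` emits
    one set of records per model (NMR-style ensembles).
    """
    path = Path(path)
    excluded = {c.upper() for c in exclusion}
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    models = list(st) if per_model else list(st)[:1]
    if not models:
        raise ParseError(f"{path}: file contains no models")

    records: list[StructureRecord] = []
    for model in models:
        chain_records: list[StructureRecord] = []
        pending_ligands: list[Ligand] = []
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            residues: list[Residue] = []
            for res in ch:
                icode = res.seqid.icode.strip()
                if _is_amino_acid(res.name):
                    atoms = _convert_atoms(res)
                    if not any(not a.is_hydrogen for a in atoms):
                        continue
                    residues.append(Residue(
                        key=(ch.name, res.seqid.num, icode),
                        name=res.name,
                        atoms=atoms,
                    ))
                else:
                    if res.name.upper() in excluded or res.is_water():
                        continue
                    atoms = _convert_atoms(res)
                    if not any(not a.is_hydrogen for a in atoms):
                        continue
                    pending_ligands.append(Ligand(
                        identity=(res.name, ch.name, res.seqid.num),
                        atoms=atoms,
                    ))
            if residues:
                model_tag = f"_m{model.num}" if per_model and len(models) > 1 else ""
                chain_records.append(StructureRecord(
                    id=f"{path.stem}{model_tag}_{ch.name}",
                    residues=residues,
                    resolution=resolution,
                    source=path,
                ))
        if not chain_records:
            raise ParseError(f"{path}: no residues found"
                             + (f" in chain {chain}" if chain else ""))
        for lig in pending_ligands:
            _assign_ligand(lig, chain_records)
        records.extend(chain_records)
    return records


def _assign_ligand(lig: Ligand, records: list[StructureRecord]) -> None:
    """Attach a ligand to the protein copy it sits closest to."""
    from scipy.spatial.distance import cdist

    lxyz = lig.coords()
    best, best_d = None, np.inf
    for rec in records:
        pts = np.vstack([r.coords() for r in rec.residues])
        d = cdist(pts, lxyz).min()
        if d < best_d:
            best, best_d = rec, d
    assert best is not None
    best.ligands.append(lig)


def common_residue_keys(records: Sequence[StructureRecord]) -> list[ResidueKey]:
    """Sorted intersection of residue keys present in every record.

    This implements the ensemble cleaning step: residues not resolved in
    every structure are dropped so all matrices share one index.
    """
    if not records:
        raise ValueError("no records given")
    common = set(records[0].keys())
    for rec in records[1:]:
        common &= set(rec.keys())
    if not common:
        raise ValueError("no residue keys shared by all records; ensemble unalignable")
    return sorted(common)


def write_record(record: StructureRecord, path: str | Path) -> Path:
    """Write a record as a standard PDB file (ATOM/HETATM fixed columns)."""
    path = Path(path)
    lines = []
    if record.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.  {record.resolution:6.2f} ANGSTROMS.")
    serial = 1
    for res in record.residues:
        for a in res.atoms:
            lines.append(_pdb_atom_line("ATOM", serial, a, res.name, res.key))
            serial += 1
    for lig in record.ligands:
        code, ch, num = lig.identity
        for a in lig.atoms:
            lines.append(_pdb_atom_line("HETATM", serial, a, code, (ch, num, "")))
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def _pdb_atom_line(kind: str, serial: int, a: Atom, resname: str, key: ResidueKey) -> str:
    chain, num, icode = key
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"{kind:<6s}{serial:>5d} {name:<4s}{a.altloc or ' '}{resname:<3s} "
        f"{chain[:1]}{num:>4d}{icode or ' ':1s}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )
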