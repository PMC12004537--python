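"""Gap detection and conformation-based loop-template assignment.

Crystal structures commonly lack density for flexible loops. Rather than
rebuilding missing segments against an arbitrary template, templates are
chosen from the ensemble itself: candidate structures that resolve the
whole segment are ranked by (1) sharing the target's conformational
cluster, (2) proximity in retained principal-component space, and
(3) crystallographic resolution. The actual rebuilding is delegated to an
external comparative-modeling engine; this module emits the alignment and
a job manifest describing the protocol (rebuild missing segments only,
revert noncanonical residues to the reference amino acid, generate five
models, keep the lowest-DOPE one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .ensemble import ClusterAssignment, EnsembleProjection
from .structio import StructureRecord

__all__ = [
    "GapReport",
    "TemplateAssignment",
    "RankedTemplate",
    "detect_gaps",
    "assign_templates",
    "emit_modeling_job",
    "load_modeling_job",
    "THREE_TO_ONE",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class GapReport:
    """Missing-residue runs for one structure against the reference.

    ``segments`` are internal (modelable) runs as inclusive
    (start number, end number); ``terminal_segments`` touch a terminus and
    are excluded from modeling.
    """

    structure_id: str
    segments: list[tuple[int, int]] = field(default_factory=list)
    terminal_segments: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RankedTemplate:
    template_id: str
    pca_distance: float
    same_cluster: bool
    resolution: Optional[float]


@dataclass
class TemplateAssignment:
    """Ranked template structures per modelable segment."""

    structure_id: str
    per_segment: dict[tuple[int, int], list[RankedTemplate]] = field(default_factory=dict)
    unmodelable: list[tuple[int, int]] = field(default_factory=list)


def _runs(numbers: Sequence[int]) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    for n in sorted(numbers):
        if runs and n == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], n)
        else:
            runs.append((n, n))
    return runs


def detect_gaps(record: StructureRecord,
                reference_numbers: Sequence[int]) -> GapReport:
    """Find runs of reference residues unresolved in the record.

    ``reference_numbers`` is the author numbering of the full-length
    reference sequence. Runs touching either end of the reference are
    terminal and flagged excluded; record residues outside the reference
    numbering are an error.
    """
    ref = sorted(set(int(n) for n in reference_numbers))
    present = {k[1] for k in record.keys()}
    outside = present - set(ref)
    if outside:
        raise ValueError(
            f"{record.id}: residues {sorted(outside)} outside reference numbering")
    missing = [n for n in ref if n not in present]
    report = GapReport(structure_id=record.id)
    lo, hi = ref[0], ref[-1]
    for run in _runs(missing):
        if run[0] == lo or run[1] == hi:
            report.terminal_segments.append(run)
        else:
            report.segments.append(run)
    return report


def _covers(coverage: set[int], segment: tuple[int, int]) -> bool:
    return all(n in coverage for n in range(segment[0], segment[1] + 1))


def assign_templates(gaps: GapReport, projection: EnsembleProjection,
                     clusters: ClusterAssignment,
                     coverage: Mapping[str, set[int]],
                     resolutions: Optional[Mapping[str, Optional[float]]] = None,
                     top_n: int = 5) -> TemplateAssignment:
    """Rank template candidates for each modelable segment.

    ``coverage`` maps structure id → set of resolved residue numbers; a
    candidate must resolve every residue of the segment and is never the
    target itself. Ranking is lexicographic: same cluster as the target
    first, then ascending Euclidean distance in retained PC space, then
    ascending resolution (unknown resolution last), then structure id for
    determinism.
    """
    target = gaps.structure_id
    resolutions = resolutions or {}
    t_score = projection.score_of(target)
    t_label = clusters.label_of(target)
    out = TemplateAssignment(structure_id=target)
    for seg in gaps.segments:
        ranked = []
        for cand in projection.ids:
            if cand == target or cand not in coverage:
                continue
            if not _covers(coverage[cand], seg):
                continue
            dist = float(np.linalg.norm(projection.score_of(cand) - t_score))
            same = clusters.label_of(cand) == t_label and t_label >= 0
            ranked.append(RankedTemplate(cand, dist, same,
                                         resolutions.get(cand)))
        if not ranked:
            out.unmodelable.append(seg)
            continue
        ranked.sort(key=lambda r: (
            0 if r.same_cluster else 1,
            r.pca_distance,
            r.resolution if r.resolution is not None else float("inf"),
            r.template_id,
        ))
        out.per_segment[seg] = ranked[:top_n]
    return out


def _sequence_line(numbers: Sequence[int], resolved: Mapping[int, str]) -> str:
    return "".join(resolved.get(n, "-") for n in numbers)


def emit_modeling_job(assignment: TemplateAssignment, record: StructureRecord,
                      templates: Sequence[StructureRecord],
                      reference: Mapping[int, str],
                      out_dir: str | Path,
                      n_models: int = 5) -> tuple[Path, Path]:
    """Write a PIR alignment and a JSON control manifest for the external
    modeling engine.

    The target row carries the full reference sequence (noncanonical
    residues reverted to the reference amino acid); template rows show only
    their resolved residues. The manifest declares: rebuild the assigned
    missing segments only, generate ``n_models`` models, and keep the one
    with the lowest DOPE score.
    """
    if not assignment.per_segment:
        raise ValueError(f"{assignment.structure_id}: empty assignment")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    numbers = sorted(reference)

    ali = out_dir / f"{assignment.structure_id}.ali"
    lines = [f">P1;{assignment.structure_id}",
             f"sequence:{assignment.structure_id}:{numbers[0]}: :{numbers[-1]}: ::: :",
             _sequence_line(numbers, reference) + "*"]
    tmap = {t.id: t for t in templates}
    for seg, ranked in sorted(assignment.per_segment.items()):
        for rt in ranked:
            t = tmap.get(rt.template_id)
            if t is None:
                continue
            resolved = {k[1]: THREE_TO_ONE.get(r.name, "X")
                        for k, r in zip(t.keys(), t.residues)}
            lines += [f">P1;{t.id}",
                      f"structureX:{t.id}:{min(resolved)}: :{max(resolved)}: ::: :",
                      _sequence_line(numbers, resolved) + "*"]
            break  # top-ranked template per segment in the alignment
    ali.write_text("\n".join(lines) + "\n")

    manifest = out_dir / f"{assignment.structure_id}.job.json"
    manifest.write_text(json.dumps({
        "target": assignment.structure_id,
        "rebuild_segments": [list(s) for s in sorted(assignment.per_segment)],
        "unmodelable_segments": [list(s) for s in assignment.unmodelable],
        "templates": {f"{s[0]}-{s[1]}": [
            {"id": rt.template_id, "pca_distance": rt.pca_distance,
             "same_cluster": rt.same_cluster, "resolution": rt.resolution}
            for rt in ranked]
            for s, ranked in sorted(assignment.per_segment.items())},
        "noncanonical_policy": "convert to reference amino acid",
        "n_models": n_models,
        "model_selection": "lowest DOPE score",
        "alignment": ali.name,
    }, indent=2) + "\n")
    return ali, manifest


def load_modeling_job(manifest_path: str | Path) -> TemplateAssignment:
    """Parse a job manifest back into a :class:`TemplateAssignment`."""
    data = json.loads(Path(manifest_path).read_text())
    out = TemplateAssignment(structure_id=data["target"])
    out.unmodelable = [tuple(s) for s in data["unmodelable_segments"]]
    for seg_key, ranked in data["templates"].items():
        a, b = seg_key.split("-")
        out.per_segment[(int(a), int(b))] = [
            RankedTemplate(r["id"], r["pca_distance"], r["same_cluster"],
                           r["resolution"]) for r in ranked]
    return out
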