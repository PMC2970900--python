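"""Readers and writers: shift lists (TSV / NMR-STAR), PDB coordinates, reports.

The native shift dialect is a 5-column TSV (chain, seq_pos, residue, atom,
value_ppm).  NMR-STAR reading covers the standard assigned-chemical-shift
loop.  The report format is a sectioned plain-text table that round-trips
through :func:`write_report` / :func:`read_report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .core import (
    GroupCorrection,
    NucleusGroup,
    SecondaryStructure,
    ShiftClass,
    ShiftRecord,
    STANDARD_RESIDUES,
    THREE_TO_ONE,
    UnknownAtomError,
    VascoError,
    canonicalize_atom_name,
)


class ParseError(VascoError):
    pass


@dataclass
class ParseReport:
    """Bookkeeping for a parsed shift file: rows_in = kept + dropped."""

    rows_total: int = 0
    rows_kept: int = 0
    dropped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def rows_dropped(self) -> int:
        return len(self.dropped)


@dataclass
class ShiftTable:
    """An ordered, key-unique collection of assigned chemical shifts."""

    entry_id: str
    records: list[ShiftRecord]
    parse_report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.key in seen:
                raise ParseError(f"duplicate shift for {rec.key}")
            seen.add(rec.key)

    def chains(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.chain_id not in out:
                out.append(rec.chain_id)
        return out

    def residues(self, chain_id: str) -> list[tuple[int, str]]:
        """Sorted (seq_pos, residue_type) pairs present in one chain."""
        seen: dict[int, str] = {}
        for rec in self.records:
            if rec.chain_id == chain_id:
                seen.setdefault(rec.seq_pos, rec.residue_type)
        return sorted(seen.items())

    def sequence(self, chain_id: str) -> tuple[int, str]:
        """One-letter sequence for a chain with 'X' at unassigned positions.

        Returns (start_seq_pos, sequence).
        """
        res = self.residues(chain_id)
        if not res:
            return (1, "")
        start = res[0][0]
        seq = ["X"] * (res[-1][0] - start + 1)
        for pos, rtype in res:
            seq[pos - start] = THREE_TO_ONE.get(rtype, "X")
        return (start, "".join(seq))


def _make_record(chain: str, pos: str, residue: str, atom: str, value: str,
                 lineno: int, report: ParseReport) -> Optional[ShiftRecord]:
    residue = residue.upper()
    if residue not in STANDARD_RESIDUES:
        report.dropped.append((lineno, f"non-standard residue {residue!r}"))
        return None
    try:
        seq_pos = int(pos)
        value_ppm = float(value)
    except ValueError:
        report.dropped.append((lineno, f"unparseable row: {pos!r}/{value!r}"))
        return None
    if not math.isfinite(value_ppm):
        report.dropped.append((lineno, "non-finite shift value"))
        return None
    try:
        atom_name = canonicalize_atom_name(residue, atom)
    except UnknownAtomError as exc:
        report.dropped.append((lineno, str(exc)))
        return None
    return ShiftRecord(chain, seq_pos, residue, atom_name, value_ppm)


def read_shift_table(source: Union[str, Path], dialect: str = "tsv",
                     entry_id: Optional[str] = None,
                     on_duplicate: str = "reject") -> ShiftTable:
    """Read an assigned chemical-shift list.

    dialect ``tsv``: header ``chain seq_pos residue atom value_ppm``;
    dialect ``nmrstar``: the ``_Atom_chem_shift`` loop of an NMR-STAR v3
    file.  Rows with non-standard residues or unparseable values are
    dropped and counted in the parse report.
    """
    path = Path(source)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if dialect == "tsv":
        rows = _read_tsv_rows(path)
    elif dialect == "nmrstar":
        rows = _read_nmrstar_rows(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    report = ParseReport()
    records: list[ShiftRecord] = []
    index: dict[tuple, int] = {}
    for lineno, (chain, pos, residue, atom, value) in rows:
        report.rows_total += 1
        rec = _make_record(chain, pos, residue, atom, value, lineno, report)
        if rec is None:
            continue
        if rec.key in index:
            if on_duplicate == "last":
                records[index[rec.key]] = rec
                report.dropped.append((lineno, f"duplicate {rec.key} (replaced)"))
                continue
            raise ParseError(f"line {lineno}: duplicate shift for {rec.key}")
        index[rec.key] = len(records)
        records.append(rec)
    report.rows_kept = len(records)
    if not records:
        raise ParseError(f"{path}: no usable shift rows")
    return ShiftTable(entry_id or path.stem, records, report)


def _read_tsv_rows(path: Path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if [p.strip().lower() for p in parts[:2]] == ["chain", "seq_pos"]:
                continue
            if len(parts) != 5:
                raise ParseError(f"{path} line {lineno}: expected 5 columns, got {len(parts)}")
            rows.append((lineno, tuple(p.strip() for p in parts)))
    return rows


# NMR-STAR assigned chemical shift loop tags -> row fields
_STAR_TAGS = {
    "_atom_chem_shift.auth_asym_id": "chain",
    "_atom_chem_shift.entity_assembly_id": "chain_fallback",
    "_atom_chem_shift.comp_index_id": "pos",
    "_atom_chem_shift.seq_id": "pos",
    "_atom_chem_shift.comp_id": "residue",
    "_atom_chem_shift.atom_id": "atom",
    "_atom_chem_shift.val": "value",
}


def _read_nmrstar_rows(path: Path):
    """Minimal reader for the ``_Atom_chem_shift`` loop of NMR-STAR v3."""
    rows = []
    tags: list[str] = []
    state = "scan"  # scan -> tags -> data
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if state == "scan":
                if line == "loop_":
                    tags = []
                    state = "tags"
                continue
            if state == "tags":
                if line.lower().startswith("_atom_chem_shift."):
                    tags.append(line.lower())
                    continue
                if line.startswith("_"):  # some other loop
                    state = "scan"
                    continue
                if not tags:
                    state = "scan"
                    continue
                state = "data"
            if state == "data":
                if line == "stop_":
                    state = "done"
                    break
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != len(tags):
                    raise ParseError(f"{path} line {lineno}: {len(fields)} fields "
                                     f"for {len(tags)} loop tags")
                rec = dict(zip(tags, fields))
                chain = rec.get("_atom_chem_shift.auth_asym_id", ".")
                if chain in (".", "?"):
                    chain = rec.get("_atom_chem_shift.entity_assembly_id", "A")
                if chain in (".", "?"):
                    chain = "A"
                pos = rec.get("_atom_chem_shift.comp_index_id") or rec.get("_atom_chem_shift.seq_id")
                residue = rec.get("_atom_chem_shift.comp_id", "")
                atom = rec.get("_atom_chem_shift.atom_id", "")
                value = rec.get("_atom_chem_shift.val", "")
                if pos is None:
                    raise ParseError(f"{path}: missing sequence tag in shift loop")
                rows.append((lineno, (chain, pos, residue, atom, value)))
    if not rows:
        raise ParseError(f"{path}: no assigned chemical shift loop found")
    return rows


def write_shift_table(table: ShiftTable, dest: Union[str, Path]) -> None:
    with open(dest, "w") as fh:
        fh.write("chain\tseq_pos\tresidue\tatom\tvalue_ppm\n")
        for rec in table.records:
            fh.write(f"{rec.chain_id}\t{rec.seq_pos}\t{rec.residue_type}\t"
                     f"{rec.atom_name}\t{rec.value_ppm!r}\n")


# ---------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class StructureAtom:
    chain_id: str
    seq_pos: int
    residue_type: str
    atom_name: str
    x: float
    y: float
    z: float
    element: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_pos, self.atom_name)


@dataclass
class StructureModel:
    entry_id: str
    atoms: list[StructureAtom]
    model_index: int = 0

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self, chain_id: str) -> list[tuple[int, str]]:
        seen: dict[int, str] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.seq_pos, a.residue_type)
        return sorted(seen.items())


def read_structure(source: Union[str, Path], model_index: int = 0) -> StructureModel:
    """Read one model from a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first encountered).  Hydrogens are retained when present.
    """
    path = Path(source)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure.get_models())
    if not models:
        raise ParseError(f"{path}: no models")
    if not 0 <= model_index < len(models):
        raise ParseError(f"{path}: model_index {model_index} out of range; "
                         f"available models: 0..{len(models) - 1}")
    model = models[model_index]
    atoms: list[StructureAtom] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            if hetflag.strip():  # skip waters / heteroatoms
                continue
            for atom in _select_altloc(residue):
                x, y, z = (float(v) for v in atom.coord)
                if not all(math.isfinite(v) for v in (x, y, z)):
                    raise ParseError(f"{path}: non-finite coordinates for {atom}")
                element = (atom.element or "").strip().upper() or atom.get_name()[0]
                atoms.append(StructureAtom(chain.id.strip() or "A", int(resseq),
                                           residue.get_resname().strip().upper(),
                                           atom.get_name().strip().upper(),
                                           x, y, z, element))
    if not atoms:
        raise ParseError(f"{path}: model {model_index} contains no atoms")
    return StructureModel(path.stem, atoms, model_index)


def _select_altloc(residue):
    """One atom per name: highest occupancy wins, ties keep the first."""
    by_name: dict[str, object] = {}
    for atom in residue.get_unpacked_list():
        name = atom.get_name()
        prev = by_name.get(name)
        occ = atom.get_occupancy() or 0.0
        if prev is None or occ > (prev.get_occupancy() or 0.0):
            by_name[name] = atom
    return list(by_name.values())


def write_structure(model: StructureModel, dest: Union[str, Path]) -> None:
    """Write a minimal single-model PDB file."""
    with open(dest, "w") as fh:
        fh.write("MODEL        1\n")
        for i, a in enumerate(model.atoms, 1):
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            fh.write(f"ATOM  {i:5d} {name:<4s} {a.residue_type:<3s} "
                     f"{a.chain_id:1s}{a.seq_pos:4d}    "
                     f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                     f"          {a.element:>2s}\n")
        fh.write("ENDMDL\nEND\n")


# ---------------------------------------------------------------------------
# reports


@dataclass(frozen=True)
class ReportShift:
    """One atom row of a correction/validation report."""

    chain_id: str
    seq_pos: int
    residue_type: str
    atom_name: str
    original_ppm: float
    corrected_ppm: float
    shift_class: ShiftClass
    z: float


@dataclass
class Report:
    entry_id: str
    corrections: list[GroupCorrection]
    shifts: list[ReportShift]


_GROUP_HEADER = ("group", "n_shifts", "mean_ppm", "uncertainty_ppm",
                 "total_precision", "retained", "low_confidence")
_SHIFT_HEADER = ("chain", "seq_pos", "residue", "atom", "original_ppm",
                 "corrected_ppm", "class_residue", "class_atom", "ss_state",
                 "asa_bin", "z")


def write_report(report: Report, dest: Union[str, Path]) -> None:
    """Write the per-entry report: five group rows plus per-atom rows.

    Absent groups are emitted with ``n_shifts = 0`` and ``retained = false``.
    Floats are written with full precision so the reader is an exact inverse.
    """
    by_group = {c.group: c for c in report.corrections}
    with open(dest, "w") as fh:
        fh.write("# vasco-report 1\n")
        fh.write(f"entry\t{report.entry_id}\n")
        fh.write("[corrections]\n")
        fh.write("\t".join(_GROUP_HEADER) + "\n")
        for group in NucleusGroup:
            c = by_group.get(group) or GroupCorrection(
                group=group, mean_ppm=0.0, uncertainty_ppm=math.inf,
                total_precision=0.0, n_shifts_used=0, retained=False,
                low_confidence=True)
            fh.write(f"{c.group.value}\t{c.n_shifts_used}\t{c.mean_ppm!r}\t"
                     f"{c.uncertainty_ppm!r}\t{c.total_precision!r}\t"
                     f"{int(c.retained)}\t{int(c.low_confidence)}\n")
        fh.write("[shifts]\n")
        fh.write("\t".join(_SHIFT_HEADER) + "\n")
        for s in report.shifts:
            sc = s.shift_class
            fh.write(f"{s.chain_id}\t{s.seq_pos}\t{s.residue_type}\t{s.atom_name}\t"
                     f"{s.original_ppm!r}\t{s.corrected_ppm!r}\t"
                     f"{sc.atom_type[0]}\t{sc.atom_type[1]}\t{sc.ss_state.value}\t"
                     f"{sc.asa_bin_index}\t{s.z!r}\n")


def read_report(source: Union[str, Path]) -> Report:
    path = Path(source)
    entry_id = ""
    corrections: list[GroupCorrection] = []
    shifts: list[ReportShift] = []
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("entry\t"):
                entry_id = line.split("\t", 1)[1]
                continue
            if line == "[corrections]":
                section = "corrections"
                continue
            if line == "[shifts]":
                section = "shifts"
                continue
            parts = line.split("\t")
            if section == "corrections":
                if parts[0] == "group":
                    continue
                g, n, mean, unc, prec, ret, low = parts
                corrections.append(GroupCorrection(
                    group=NucleusGroup(g), mean_ppm=float(mean),
                    uncertainty_ppm=float(unc), total_precision=float(prec),
                    n_shifts_used=int(n), retained=bool(int(ret)),
                    low_confidence=bool(int(low))))
            elif section == "shifts":
                if parts[0] == "chain":
                    continue
                (chain, pos, res, atom, orig, corr, cres, catom, ss, abin, z) = parts
                shifts.append(ReportShift(
                    chain_id=chain, seq_pos=int(pos), residue_type=res,
                    atom_name=atom, original_ppm=float(orig),
                    corrected_ppm=float(corr),
                    shift_class=ShiftClass((cres, catom), SecondaryStructure(ss),
                                           int(abin)),
                    z=float(z)))
    if not corrections:
        raise ParseError(f"{path}: not a vasco report")
    return Report(entry_id, corrections, shifts)
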