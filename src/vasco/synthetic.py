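"""Synthetic fixtures: reference databases, entries with known injected
offsets, and toy coordinate sets.

The shift generator runs the statistical model forward
(value = s_alpha + offset_group + noise), so inference can be checked
against known ground truth without any archive data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotate import ResidueMapping
from .core import (
    AtomAnnotation,
    ClassStat,
    NucleusGroup,
    SecondaryStructure,
    ShiftClass,
    ShiftRecord,
    VascoError,
    assign_group,
    topology,
)
from .io import ShiftTable, StructureAtom, StructureModel
from .refdb import (
    AnnotatedEntry,
    BinningScheme,
    Observation,
    ReferenceDB,
    build_reference_db,
)


@dataclass(frozen=True)
class ClassSpec:
    """Ground-truth Gaussian for one synthetic class."""

    atom_type: tuple[str, str]
    ss_state: SecondaryStructure
    mean_ppm: float
    precision: float
    count: int = 200


#: one atom type per nucleus group, coil state — the smallest layout that
#: exercises all five correction factors
def default_layout(counts: int = 200,
                   ss_states: Sequence[SecondaryStructure] = (SecondaryStructure.coil,),
                   ) -> list[ClassSpec]:
    base = [
        (("ALA", "HA"), 4.3, 1.0 / 0.5 ** 2),
        (("ALA", "N"), 123.0, 1.0 / 4.0 ** 2),
        (("ALA", "CA"), 53.0, 1.0 / 2.0 ** 2),
        (("PHE", "CD1"), 131.5, 1.0 / 2.0 ** 2),
        (("ALA", "C"), 177.5, 1.0 / 1.5 ** 2),
    ]
    return [ClassSpec(at, ss, mean, prec, counts)
            for ss in ss_states for at, mean, prec in base]


def make_refdb(layout: Optional[Sequence[ClassSpec]] = None,
               seed: int = 0, mode: str = "direct") -> ReferenceDB:
    """Reference database from a synthetic class layout.

    ``direct`` writes the specified statistics verbatim; ``fit`` simulates
    ``count`` draws per class and runs the regular build pipeline (classes
    below the smallest count threshold then drop out per the usual rules).
    Each (atom type, secondary structure) stratum is a single ASA bin
    covering [0, 1].
    """
    layout = list(layout) if layout is not None else default_layout()
    if not layout:
        raise VascoError("empty class layout")
    min_count = min(spec.count for spec in layout)
    if mode == "direct":
        scheme = BinningScheme(target_bin_count=min_count)
        stats = []
        for spec in layout:
            scheme.cuts[(spec.atom_type, spec.ss_state)] = [0.0]
            sc = ShiftClass(spec.atom_type, spec.ss_state, 0)
            stats.append(ClassStat(sc, spec.mean_ppm, spec.precision, spec.count))
        return ReferenceDB.from_stats(scheme, stats,
                                      {"synthetic": "direct", "seed": seed})
    if mode == "fit":
        rng = np.random.default_rng(seed)
        obs = []
        for spec in layout:
            sd = spec.precision ** -0.5
            values = rng.normal(spec.mean_ppm, sd, size=spec.count)
            # zero ASA keeps every stratum a single zero-bin
            obs.extend(Observation(spec.atom_type, spec.ss_state, 0.0, float(v))
                       for v in values)
        entry = AnnotatedEntry("synthetic-fit", obs)
        db = build_reference_db([entry], target_bin_count=min_count)
        db.metadata.update(synthetic="fit", seed=seed)
        return db
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class SyntheticEntry:
    """A generated entry plus its ground truth."""

    table: ShiftTable
    annotations: list[AtomAnnotation]
    mapping: ResidueMapping
    offsets: dict[NucleusGroup, float]
    classes: list[ClassStat] = field(default_factory=list)  # per record

    def to_annotated_entry(self) -> AnnotatedEntry:
        ann = {a.atom_key: a for a in self.annotations}
        topo = topology()
        obs = []
        for rec in self.table.records:
            heavy = topo.heavy_parent(rec.residue_type, rec.atom_name)
            a = ann[(rec.chain_id, rec.seq_pos, heavy)]
            obs.append(Observation((rec.residue_type, rec.atom_name),
                                   a.ss_state, a.asa_fraction, rec.value_ppm))
        return AnnotatedEntry(self.table.entry_id, obs)


def make_entry(refdb: ReferenceDB, n_shifts: int,
               offsets: Optional[dict[NucleusGroup, float]] = None,
               noise_scale: float = 1.0, seed: int = 0,
               entry_id: str = "synthetic", chain_id: str = "A",
               ) -> SyntheticEntry:
    """Sample an entry whose shifts carry known per-group offsets.

    Each shift is drawn from a uniformly chosen reference class as
    mean + offset_group + noise_scale * N(0, 1/k); one atom per residue
    position keeps keys unique.  ``noise_scale = 1`` is the model-matched
    case; larger values emulate added random scatter.
    """
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    if not len(refdb):
        raise VascoError("empty reference database")
    offsets = dict(offsets or {})
    rng = np.random.default_rng(seed)
    stats = sorted(refdb.stats.values(),
                   key=lambda s: (s.shift_class.atom_type,
                                  s.shift_class.ss_state.value,
                                  s.shift_class.asa_bin_index))
    topo = topology()
    records, annotations, classes = [], [], []
    pairs = []
    for i in range(n_shifts):
        stat = stats[int(rng.integers(len(stats)))]
        residue, atom = stat.shift_class.atom_type
        if residue == "*":
            raise VascoError("make_entry needs residue_atom class mode")
        group = assign_group(residue, atom)
        noise = noise_scale * rng.standard_normal() / math.sqrt(stat.precision)
        value = stat.mean_ppm + offsets.get(group, 0.0) + noise
        pos = i + 1
        records.append(ShiftRecord(chain_id, pos, residue, atom, value))
        cuts = refdb.scheme.cuts[(stat.shift_class.atom_type,
                                  stat.shift_class.ss_state)]
        asa = cuts[stat.shift_class.asa_bin_index]
        heavy = topo.heavy_parent(residue, atom)
        annotations.append(AtomAnnotation((chain_id, pos, heavy), asa,
                                          stat.shift_class.ss_state))
        classes.append(stat)
        pairs.append((pos, pos))
    table = ShiftTable(entry_id, records)
    mapping = ResidueMapping(tuple(pairs), 1.0)
    return SyntheticEntry(table, annotations, mapping, offsets, classes)


def make_entries(refdb: ReferenceDB, n_entries: int, n_shifts: int,
                 offset_for: Optional[dict[int, dict[NucleusGroup, float]]] = None,
                 noise_scale: float = 1.0, seed: int = 0) -> list[AnnotatedEntry]:
    """A synthetic population for database-build experiments."""
    offset_for = offset_for or {}
    out = []
    for i in range(n_entries):
        entry = make_entry(refdb, n_shifts, offset_for.get(i), noise_scale,
                           seed=seed + 7919 * i, entry_id=f"synthetic-{i}")
        out.append(entry.to_annotated_entry())
    return out


# ---------------------------------------------------------------------------
# toy coordinates

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = math.radians(111.2)
_ANGLE_CA_C_N = math.radians(116.2)
_ANGLE_C_N_CA = math.radians(121.7)
_ANGLE_CA_C_O = math.radians(120.8)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position d with |c-d| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(angle),
                  bond * math.sin(angle) * math.cos(torsion),
                  bond * math.sin(angle) * math.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _backbone_chain(n_residues: int, phi: float, psi: float,
                    residue_type: str = "ALA") -> list[StructureAtom]:
    """Poly-amino-acid backbone (N, CA, C, O) with fixed dihedrals."""
    phi, psi = math.radians(phi), math.radians(psi)
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND_N_CA, 0.0, 0.0])
    theta = math.pi - _ANGLE_N_CA_C
    c = ca + _BOND_CA_C * np.array([math.cos(theta), math.sin(theta), 0.0])
    atoms: list[StructureAtom] = []

    def emit(pos: int, name: str, coord: np.ndarray, element: str) -> None:
        atoms.append(StructureAtom("A", pos, residue_type, name,
                                   float(coord[0]), float(coord[1]),
                                   float(coord[2]), element))

    for i in range(n_residues):
        pos = i + 1
        emit(pos, "N", n, "N")
        emit(pos, "CA", ca, "C")
        emit(pos, "C", c, "C")
        o = _place(n, ca, c, _BOND_C_O, _ANGLE_CA_C_O, psi + math.pi)
        emit(pos, "O", o, "O")
        if i == n_residues - 1:
            break
        n_next = _place(n, ca, c, _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_next = _place(ca, c, n_next, _BOND_N_CA, _ANGLE_C_N_CA, math.pi)
        c_next = _place(c, n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        n, ca, c = n_next, ca_next, c_next
    return atoms


def _sphere_shell(n_points: int, radius: float) -> np.ndarray:
    i = np.arange(n_points, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n_points
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_toy_structure(kind: str, n_residues: int = 12,
                       separation: float = 10.0, seed: int = 0,
                       ) -> StructureModel:
    """Deterministic toy coordinate sets for annotation tests.

    kinds: ``ideal_helix`` (poly-ALA, phi=-57 psi=-47), ``extended``
    (phi=psi=180), ``single_atom``, ``two_atoms`` (two carbons
    ``separation`` apart) and ``buried_shell`` (one carbon enclosed in a
    dense occluding shell).
    """
    if kind == "ideal_helix":
        return StructureModel("ideal_helix", _backbone_chain(n_residues, -57.0, -47.0))
    if kind == "extended":
        return StructureModel("extended", _backbone_chain(n_residues, 180.0, 180.0))
    if kind == "single_atom":
        return StructureModel("single_atom", [
            StructureAtom("A", 1, "GLY", "CA", 0.0, 0.0, 0.0, "C")])
    if kind == "two_atoms":
        return StructureModel("two_atoms", [
            StructureAtom("A", 1, "GLY", "CA", 0.0, 0.0, 0.0, "C"),
            StructureAtom("A", 2, "GLY", "CA", separation, 0.0, 0.0, "C")])
    if kind == "buried_shell":
        atoms = [StructureAtom("A", 1, "GLY", "CA", 0.0, 0.0, 0.0, "C")]
        for i, (x, y, z) in enumerate(_sphere_shell(240, 3.0), start=2):
            atoms.append(StructureAtom("A", i, "GLY", "CA",
                                       float(x), float(y), float(z), "C"))
        return StructureModel("buried_shell", atoms)
    raise ValueError(f"unknown toy structure kind {kind!r}")


# ---------------------------------------------------------------------------
# structure-matched fixtures (end-to-end pipeline)

_GROUP_BASE = {
    NucleusGroup.H: (4.5, 0.6),
    NucleusGroup.N: (119.0, 4.0),
    NucleusGroup.C_ali: (45.0, 3.0),
    NucleusGroup.C_aro: (130.0, 3.0),
    NucleusGroup.C_noH: (177.0, 2.0),
}


def make_refdb_for_structure(annotations: Iterable[AtomAnnotation],
                             structure: StructureModel,
                             count: int = 200, seed: int = 0) -> ReferenceDB:
    """A direct-mode reference database covering every annotated atom type
    (plus attached protons) of a structure, so an end-to-end run classifies
    every shift regardless of the computed ASA values."""
    rng = np.random.default_rng(seed)
    restype = {(a.chain_id, a.seq_pos): a.residue_type for a in structure.atoms}
    topo = topology()
    layout: dict[tuple, ClassSpec] = {}
    for ann in annotations:
        chain, pos, atom = ann.atom_key
        residue = restype[(chain, pos)]
        names = [atom] + topo.hydrogens_of(residue, atom)
        for name in names:
            try:
                group = assign_group(residue, name)
            except VascoError:
                continue
            key = ((residue, name), ann.ss_state)
            if key in layout:
                continue
            base_mean, base_sd = _GROUP_BASE[group]
            mean = base_mean + float(rng.normal(0.0, base_sd))
            layout[key] = ClassSpec((residue, name), ann.ss_state, mean,
                                    1.0 / base_sd ** 2, count)
    return make_refdb(list(layout.values()), seed=seed, mode="direct")


def make_entry_for_structure(refdb: ReferenceDB, structure: StructureModel,
                             annotations: Iterable[AtomAnnotation],
                             offsets: Optional[dict[NucleusGroup, float]] = None,
                             noise_scale: float = 1.0, seed: int = 0,
                             entry_id: str = "synthetic") -> ShiftTable:
    """Sample a shift table for a structure's atoms from a matching refdb."""
    offsets = dict(offsets or {})
    rng = np.random.default_rng(seed)
    restype = {(a.chain_id, a.seq_pos): a.residue_type for a in structure.atoms}
    topo = topology()
    records = []
    for ann in annotations:
        chain, pos, atom = ann.atom_key
        residue = restype[(chain, pos)]
        for name in [atom] + topo.hydrogens_of(residue, atom):
            try:
                group = assign_group(residue, name)
            except VascoError:
                continue
            stat = refdb.lookup((residue, name), ann.ss_state, ann.asa_fraction)
            if stat is None:
                continue
            noise = noise_scale * rng.standard_normal() / math.sqrt(stat.precision)
            value = stat.mean_ppm + offsets.get(group, 0.0) + noise
            records.append(ShiftRecord(chain, pos, residue, name, value))
    if not records:
        raise VascoError("no records generated: refdb does not cover structure")
    return ShiftTable(entry_id, records)
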