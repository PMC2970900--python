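"""Core domain types: nucleus groups, shift records, classes, corrections.

The statistical model treats each measured shift as

    delta_i = s_alpha(i) + c_g(i) + eps_alpha(i)

where ``s_alpha`` is the reference mean of the atom's class (atom type x
secondary structure x solvent-accessibility bin), ``c_g`` a per-entry offset
shared by all atoms of the nucleus group g, and ``eps_alpha`` zero-mean
Gaussian noise with precision ``k_alpha``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional


class VascoError(Exception):
    """Base error for this package."""


class UnknownAtomError(VascoError):
    """Atom name not found in the residue topology."""


class GroupAssignmentError(VascoError):
    """Atom exists but has no nucleus group (e.g. oxygen, sulfur)."""


class NucleusGroup(enum.Enum):
    """The five nucleus groups carrying independent correction factors."""

    H = "H"
    N = "N"
    C_ali = "C_ali"
    C_aro = "C_aro"
    C_noH = "C_noH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SecondaryStructure(enum.Enum):
    """Six-state secondary structure of the parent residue."""

    alpha_helix = "alpha_helix"
    helix_310 = "helix_310"
    helix_pi = "helix_pi"
    beta_strand = "beta_strand"
    turn = "turn"
    coil = "coil"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: single-letter codes used by precomputed secondary-structure files
SS_LETTER = {
    "H": SecondaryStructure.alpha_helix,
    "G": SecondaryStructure.helix_310,
    "I": SecondaryStructure.helix_pi,
    "E": SecondaryStructure.beta_strand,
    "T": SecondaryStructure.turn,
    "C": SecondaryStructure.coil,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned chemical shift tied to a residue/atom identity."""

    chain_id: str
    seq_pos: int
    residue_type: str
    atom_name: str
    value_ppm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value_ppm):
            raise ValueError(f"non-finite shift for {self.key}")
        if not self.atom_name:
            raise ValueError("empty atom name")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_pos, self.atom_name)


@dataclass(frozen=True)
class AtomAnnotation:
    """Per-atom solvent exposure plus the parent residue's secondary structure.

    ``asa_fraction`` is the fraction of the atom's in-vacuum (probe-inflated)
    sphere surface that is solvent accessible, discretized upstream.
    """

    atom_key: tuple[str, int, str]
    asa_fraction: float
    ss_state: SecondaryStructure

    def __post_init__(self) -> None:
        if not 0.0 <= self.asa_fraction <= 1.0:
            raise ValueError(f"asa_fraction {self.asa_fraction} outside [0, 1]")


@dataclass(frozen=True)
class ShiftClass:
    """Class index alpha: atom type x secondary structure x ASA bin."""

    atom_type: tuple[str, str]  # (residue_type, atom_name); residue "*" = coarse
    ss_state: SecondaryStructure
    asa_bin_index: int

    def __post_init__(self) -> None:
        if self.asa_bin_index < 0:
            raise ValueError("negative ASA bin index")


@dataclass(frozen=True)
class ClassStat:
    """Reference Gaussian of one class: mean s_alpha, precision k_alpha."""

    shift_class: ShiftClass
    mean_ppm: float
    precision: float  # ppm^-2, inverse variance
    count: int

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError("precision must be positive")

    @property
    def sd_ppm(self) -> float:
        return self.precision ** -0.5


@dataclass(frozen=True)
class GroupCorrection:
    """Posterior correction factor for one nucleus group of one entry.

    ``mean_ppm`` is the posterior mean offset contained in the measured
    shifts; applying the correction subtracts it. ``total_precision`` is
    K = sum_alpha n_alpha * k_alpha; the uncertainty is K**-0.5. A
    correction is retained only when |mean| >= 3 x uncertainty.
    """

    group: NucleusGroup
    mean_ppm: float
    uncertainty_ppm: float
    total_precision: float
    n_shifts_used: int
    retained: bool
    low_confidence: bool = False

    @property
    def applied_ppm(self) -> float:
        """Offset actually subtracted from shifts (0 when not retained)."""
        return self.mean_ppm if self.retained else 0.0


@dataclass(frozen=True)
class ShiftZScore:
    """Standardized deviation of a corrected shift from its class."""

    atom_key: tuple[str, int, str]
    corrected_ppm: float
    z: float


# ---------------------------------------------------------------------------
# residue topology


@dataclass(frozen=True)
class TopologyAtom:
    residue: str
    atom: str
    element: str
    n_h: int
    aromatic: bool
    parent: Optional[str]  # bonded heavy atom, hydrogens only


class Topology:
    """Static amino-acid connectivity table backing group assignment."""

    def __init__(self, atoms: Iterable[TopologyAtom]):
        self._atoms: dict[tuple[str, str], TopologyAtom] = {}
        self._children: dict[tuple[str, str], list[str]] = {}
        for a in atoms:
            self._atoms[(a.residue, a.atom)] = a
            if a.parent is not None:
                self._children.setdefault((a.residue, a.parent), []).append(a.atom)

    def get(self, residue: str, atom: str) -> Optional[TopologyAtom]:
        return self._atoms.get((residue.upper(), atom.upper()))

    def atoms_of(self, residue: str) -> list[TopologyAtom]:
        res = residue.upper()
        return [a for (r, _), a in self._atoms.items() if r == res]

    def hydrogens_of(self, residue: str, heavy_atom: str) -> list[str]:
        """Hydrogen names bonded to ``heavy_atom``, in table order."""
        return list(self._children.get((residue.upper(), heavy_atom.upper()), []))

    def heavy_parent(self, residue: str, atom: str) -> str:
        """The atom itself if heavy, else its bonded heavy atom."""
        entry = self.get(residue, atom)
        if entry is None:
            raise UnknownAtomError(f"unknown atom {residue} {atom}")
        if entry.element != "H":
            return entry.atom
        assert entry.parent is not None
        return entry.parent


def _load_topology() -> Topology:
    text = resources.files("vasco.data").joinpath("topology.tsv").read_text()
    atoms = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("residue\t"):
            continue
        res, atom, element, n_h, aromatic, parent = line.split("\t")
        atoms.append(TopologyAtom(
            residue=res, atom=atom, element=element, n_h=int(n_h),
            aromatic=aromatic == "1", parent=None if parent == "-" else parent,
        ))
    return Topology(atoms)


_TOPOLOGY: Optional[Topology] = None


def topology() -> Topology:
    global _TOPOLOGY
    if _TOPOLOGY is None:
        _TOPOLOGY = _load_topology()
    return _TOPOLOGY


def canonicalize_atom_name(residue_type: str, atom_name: str) -> str:
    """Normalize an atom name to the fixed IUPAC dialect of the topology.

    Handles ``HN``, alternatives (``HB2|HB3``), PDB digit-prefix names
    (``1HB`` -> ``HB1``), wildcard suffixes (``HB#``, ``HB%``, ``HB*``) and
    pseudo-atoms (``QB``, ``MB``) which collapse onto the first hydrogen of
    the implied heavy atom.
    """
    res = residue_type.upper()
    name = atom_name.strip().upper()
    if "|" in name:
        name = name.split("|", 1)[0].strip()
    if name == "HN":
        name = "H"
    if name and name[0].isdigit():
        name = name[1:] + name[0]
    topo = topology()
    if topo.get(res, name) is not None:
        return topo.get(res, name).atom
    if name.endswith(("#", "%", "*", "+")):
        stem = name.rstrip("#%*+")
        cands = sorted(a.atom for a in topo.atoms_of(res)
                       if a.element == "H" and a.atom.startswith(stem))
        if cands:
            return cands[0]
    if name[:1] in ("Q", "M") and len(name) > 1:
        stem = name[1:]
        for el in ("C", "N", "O", "S"):
            heavy = topo.get(res, el + stem)
            if heavy is not None:
                hydros = topo.hydrogens_of(res, heavy.atom)
                if hydros:
                    return hydros[0]
    raise UnknownAtomError(f"unknown atom name {atom_name!r} for residue {residue_type!r}")


def assign_group(residue_type: str, atom_name: str,
                 aromatic_no_h_to_aro: bool = True) -> NucleusGroup:
    """Deterministically map a (residue, atom) pair to its nucleus group.

    All hydrogens map to H and all nitrogens to N.  Carbons split three
    ways: members of an aromatic ring are C_aro, other carbons without
    attached hydrogens (carbonyl/carboxyl C, Asp/Asn CG, Glu/Gln CD,
    Arg CZ) are C_noH, everything else is C_ali.  Aromaticity takes
    precedence for ring carbons lacking protons (Phe/Tyr/Trp CG, Tyr CZ);
    set ``aromatic_no_h_to_aro=False`` to send those to C_noH instead.

    Raises :class:`UnknownAtomError` for names outside the topology and
    :class:`GroupAssignmentError` for atoms with no NMR group (O, S).
    """
    res = residue_type.upper()
    if res not in STANDARD_RESIDUES:
        raise UnknownAtomError(f"non-standard residue {residue_type!r}")
    name = canonicalize_atom_name(res, atom_name)
    entry = topology().get(res, name)
    assert entry is not None
    if entry.element == "H":
        return NucleusGroup.H
    if entry.element == "N":
        return NucleusGroup.N
    if entry.element == "C":
        if entry.aromatic and (entry.n_h > 0 or aromatic_no_h_to_aro):
            return NucleusGroup.C_aro
        if entry.n_h == 0:
            return NucleusGroup.C_noH
        return NucleusGroup.C_ali
    raise GroupAssignmentError(
        f"no nucleus group for {residue_type} {atom_name} (element {entry.element})")
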