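"""Structure-derived annotations: per-atom solvent exposure, per-residue
secondary structure, and the shift-table-to-structure residue mapping."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    AtomAnnotation,
    SecondaryStructure,
    SS_LETTER,
    VascoError,
)
from .io import StructureModel

log = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Angstrom
DEFAULT_SPHERE_POINTS = 960
DEFAULT_ASA_STEP = 0.0043  # discretization of the exposed-surface fraction
DEFAULT_RADIUS = 1.8


class MappingError(VascoError):
    """Shift and structure sequences do not correspond."""


def _load_radii() -> dict[str, float]:
    text = resources.files("vasco.data").joinpath("radii.tsv").read_text()
    radii = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        element, radius = line.split("\t")
        radii[element] = float(radius)
    return radii


_RADII: Optional[dict[str, float]] = None


def vdw_radius(element: str) -> float:
    global _RADII
    if _RADII is None:
        _RADII = _load_radii()
    r = _RADII.get(element.upper())
    if r is None:
        log.warning("unknown element %r: using default radius %.2f A",
                    element, DEFAULT_RADIUS)
        return DEFAULT_RADIUS
    return r


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def discretize_asa(fraction: float, step: float = DEFAULT_ASA_STEP) -> float:
    """Snap an exposed-surface fraction to the nearest multiple of ``step``."""
    return min(1.0, round(fraction / step) * step)


def compute_asa(structure: StructureModel,
                probe_radius: float = DEFAULT_PROBE_RADIUS,
                n_sphere_points: int = DEFAULT_SPHERE_POINTS,
                step: Optional[float] = DEFAULT_ASA_STEP,
                heavy_only: bool = True) -> dict[tuple[str, int, str], float]:
    """Shrake-Rupley solvent accessibility as a fraction of the sphere surface.

    For every atom, test points are placed on its probe-inflated sphere and
    counted as buried when they fall inside any neighbour's inflated sphere.
    The returned value is exposed_points / total_points, i.e. exposed_area
    over 4*pi*(r+probe)^2, optionally discretized to multiples of ``step``
    (pass ``step=None`` for the raw quadrature value).
    """
    atoms = [a for a in structure.atoms
             if not (heavy_only and a.element.upper() == "H")]
    if not atoms:
        raise VascoError("structure has no atoms to compute ASA for")
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.array([vdw_radius(a.element) + probe_radius for a in atoms])
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    out: dict[tuple[str, int, str], float] = {}
    for i, atom in enumerate(atoms):
        pts = coords[i] + radii[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                 if j != i]
        if neigh:
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            exposed = np.all(d2 >= (radii[neigh] ** 2)[None, :] - 1e-12, axis=1)
            frac = float(np.count_nonzero(exposed)) / n_sphere_points
        else:
            frac = 1.0
        out[atom.key] = discretize_asa(frac, step) if step else frac
    return out


# ---------------------------------------------------------------------------
# secondary structure

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q1Q2_F = 0.084 * 332.0


@dataclass
class _Residue:
    seq_pos: int
    n: Optional[np.ndarray] = None
    ca: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None
    o: Optional[np.ndarray] = None
    h: Optional[np.ndarray] = None
    is_pro: bool = False

    @property
    def complete(self) -> bool:
        return all(v is not None for v in (self.n, self.ca, self.c, self.o))


def _hbond_energy(donor: _Residue, acceptor: _Residue) -> float:
    """Kabsch-Sander electrostatic N-H...O=C energy, kcal/mol."""
    if donor.h is None or donor.is_pro:
        return 0.0
    r_on = np.linalg.norm(acceptor.o - donor.n)
    r_ch = np.linalg.norm(acceptor.c - donor.h)
    r_oh = np.linalg.norm(acceptor.o - donor.h)
    r_cn = np.linalg.norm(acceptor.c - donor.n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9
    return _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _collect_backbone(structure: StructureModel, chain_id: str) -> list[_Residue]:
    by_pos: dict[int, _Residue] = {}
    for a in structure.atoms:
        if a.chain_id != chain_id:
            continue
        res = by_pos.setdefault(a.seq_pos, _Residue(a.seq_pos))
        coord = np.array([a.x, a.y, a.z])
        if a.atom_name == "N":
            res.n = coord
        elif a.atom_name == "CA":
            res.ca = coord
        elif a.atom_name == "C":
            res.c = coord
        elif a.atom_name == "O":
            res.o = coord
        elif a.atom_name == "H":
            res.h = coord
        if a.residue_type == "PRO":
            res.is_pro = True
    residues = [by_pos[p] for p in sorted(by_pos)]
    # place missing amide protons from the preceding carbonyl (N-H roughly
    # anti-parallel to the C=O bond)
    for prev, res in zip(residues, residues[1:]):
        if res.h is None and not res.is_pro and res.complete and prev.complete \
                and res.seq_pos == prev.seq_pos + 1:
            co = prev.c - prev.o
            norm = np.linalg.norm(co)
            if norm > 0:
                res.h = res.n + co / norm * 1.01
    return residues


def assign_secondary_structure(
        structure: StructureModel,
        backend: str = "builtin",
        precomputed: Optional[Union[str, Path]] = None,
) -> dict[tuple[str, int], SecondaryStructure]:
    """Six-state secondary structure for every residue of the model.

    The builtin backend evaluates Kabsch-Sander hydrogen-bond energies and
    applies pattern rules: two consecutive i->i+4 turns make an alpha helix,
    i->i+3 a 3-10 helix, i->i+5 a pi helix; bridge patterns make strands;
    remaining hydrogen-bonded turns are 'turn'; everything else is coil.
    The precomputed backend reads whitespace-separated
    ``chain seq_pos letter`` rows with letters H/G/I/E/T/C.
    """
    if backend == "precomputed":
        if precomputed is None:
            raise ValueError("precomputed backend needs a state file")
        return _read_precomputed_ss(precomputed, structure)
    if backend != "builtin":
        raise ValueError(f"unknown backend {backend!r}")

    out: dict[tuple[str, int], SecondaryStructure] = {}
    for chain_id in structure.chains():
        residues = _collect_backbone(structure, chain_id)
        states = _assign_chain_ss(residues)
        for res, state in zip(residues, states):
            out[(chain_id, res.seq_pos)] = state
    return out


def _assign_chain_ss(residues: list[_Residue]) -> list[SecondaryStructure]:
    n = len(residues)
    if n < 3:
        return [SecondaryStructure.coil] * n
    pos = {r.seq_pos: i for i, r in enumerate(residues)}

    # hbond[i][j]: N-H of residue i donates to C=O of residue j
    hbond = np.zeros((n, n), dtype=bool)
    for i, donor in enumerate(residues):
        if donor.h is None or not donor.complete:
            continue
        for j, acceptor in enumerate(residues):
            if not acceptor.complete or abs(i - j) < 2:
                continue
            if _hbond_energy(donor, acceptor) < _HB_ENERGY_CUTOFF:
                hbond[i, j] = True

    def seq_gap_ok(i: int, j: int) -> bool:
        return residues[j].seq_pos - residues[i].seq_pos == j - i

    # n-turn at i: C=O of i accepts from N-H of i+k
    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if seq_gap_ok(i, i + k) and hbond[i + k, i]:
                turn[k][i] = True

    states: list[Optional[SecondaryStructure]] = [None] * n

    def mark(lo: int, hi: int, state: SecondaryStructure) -> None:
        for i in range(lo, hi + 1):
            if states[i] is None:
                states[i] = state

    # helices: two consecutive k-turns starting at i-1 and i cover i..i+k-1
    for k, state in ((4, SecondaryStructure.alpha_helix),
                     (3, SecondaryStructure.helix_310),
                     (5, SecondaryStructure.helix_pi)):
        for i in range(1, n - k):
            if turn[k][i - 1] and turn[k][i]:
                mark(i, i + k - 1, state)
        if k == 4:
            _mark_bridges(n, hbond, states)  # strands outrank 3-10/pi

    # any remaining residue inside an n-turn span -> turn
    for k in (3, 4, 5):
        for i in range(n - k):
            if turn[k][i]:
                for j in range(i + 1, i + k):
                    if states[j] is None:
                        states[j] = SecondaryStructure.turn

    return [s if s is not None else SecondaryStructure.coil for s in states]


def _mark_bridges(n: int, hbond: np.ndarray, states: list) -> None:
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hbond[i, j - 1] and hbond[j + 1, i]) or \
                   (hbond[j, i - 1] and hbond[i + 1, j])
            anti = (hbond[i, j] and hbond[j, i]) or \
                   (hbond[i - 1, j + 1] and hbond[j - 1, i + 1])
            if para or anti:
                for k in (i, j):
                    if states[k] is None:
                        states[k] = SecondaryStructure.beta_strand


def _read_precomputed_ss(path: Union[str, Path], structure: StructureModel):
    table: dict[tuple[str, int], SecondaryStructure] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise VascoError(f"{path} line {lineno}: expected 'chain pos letter'")
            chain, pos, letter = parts
            state = SS_LETTER.get(letter.upper())
            if state is None:
                raise VascoError(f"{path} line {lineno}: unknown state {letter!r}")
            table[(chain, int(pos))] = state
    out = {}
    for chain_id in structure.chains():
        for pos, _ in structure.residues(chain_id):
            out[(chain_id, pos)] = table.get((chain_id, pos), SecondaryStructure.coil)
    return out


def annotate_structure(structure: StructureModel,
                       ss_backend: str = "builtin",
                       precomputed_ss: Optional[Union[str, Path]] = None,
                       probe_radius: float = DEFAULT_PROBE_RADIUS,
                       n_sphere_points: int = DEFAULT_SPHERE_POINTS,
                       step: float = DEFAULT_ASA_STEP) -> list[AtomAnnotation]:
    """Per-heavy-atom annotations combining ASA fraction and residue SS."""
    asa = compute_asa(structure, probe_radius, n_sphere_points, step)
    ss = assign_secondary_structure(structure, ss_backend, precomputed_ss)
    annotations = []
    for atom in structure.atoms:
        if atom.key not in asa:
            continue
        state = ss.get((atom.chain_id, atom.seq_pos), SecondaryStructure.coil)
        annotations.append(AtomAnnotation(atom.key, asa[atom.key], state))
    return annotations


def write_annotations(annotations: list[AtomAnnotation],
                      dest: Union[str, Path]) -> None:
    with open(dest, "w") as fh:
        fh.write("chain\tseq_pos\tatom\tasa_fraction\tss_state\n")
        for a in annotations:
            chain, pos, atom = a.atom_key
            fh.write(f"{chain}\t{pos}\t{atom}\t{a.asa_fraction!r}\t{a.ss_state.value}\n")


def read_annotations(source: Union[str, Path]) -> list[AtomAnnotation]:
    out = []
    with open(source) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chain\t"):
                continue
            chain, pos, atom, asa, ss = line.split("\t")
            out.append(AtomAnnotation((chain, int(pos), atom), float(asa),
                                      SecondaryStructure(ss)))
    if not out:
        raise VascoError(f"{source}: no annotations")
    return out


# ---------------------------------------------------------------------------
# sequence mapping

NW_MATCH = 1.0
NW_MISMATCH = -1.0
NW_GAP = -2.0
DEFAULT_IDENTITY_FLOOR = 0.8


@dataclass(frozen=True)
class ResidueMapping:
    """One-to-one, strictly increasing pairing of shift and structure positions."""

    pairs: tuple[tuple[int, int], ...]
    aligned_identity: float

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)


def _global_alignment(a: str, b: str):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = NW_MATCH
    aligner.mismatch_score = NW_MISMATCH
    aligner.open_gap_score = NW_GAP
    aligner.extend_gap_score = NW_GAP
    return aligner.align(a, b)[0]


def map_sequences(shift_seq: str, structure_seq: str,
                  shift_positions: Optional[list[int]] = None,
                  structure_positions: Optional[list[int]] = None,
                  identity_floor: float = DEFAULT_IDENTITY_FLOOR) -> ResidueMapping:
    """Needleman-Wunsch global alignment of the two residue sequences.

    Only aligned columns with identical residue letters become mapping
    pairs; mismatches and gaps are excluded.  'X' marks an unassigned
    position and never pairs.  The identity is computed over aligned
    non-'X' columns and must reach ``identity_floor``.
    """
    if not shift_seq or not structure_seq:
        raise MappingError("empty sequence")
    if shift_positions is None:
        shift_positions = list(range(1, len(shift_seq) + 1))
    if structure_positions is None:
        structure_positions = list(range(1, len(structure_seq) + 1))
    if len(shift_positions) != len(shift_seq) or \
            len(structure_positions) != len(structure_seq):
        raise ValueError("positions must parallel the sequences")

    aln = _global_alignment(shift_seq, structure_seq)
    pairs: list[tuple[int, int]] = []
    n_aligned = n_identical = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            ia, ib = a0 + off, b0 + off
            ra, rb = shift_seq[ia], structure_seq[ib]
            if ra == "X" or rb == "X":
                continue
            n_aligned += 1
            if ra == rb:
                n_identical += 1
                pairs.append((shift_positions[ia], structure_positions[ib]))
    if n_aligned == 0:
        raise MappingError("sequences share no aligned residues")
    identity = n_identical / n_aligned
    if identity < identity_floor:
        raise MappingError(
            f"sequences do not correspond: identity {identity:.3f} "
            f"below floor {identity_floor:.3f}")
    return ResidueMapping(tuple(pairs), identity)


def map_shift_table_to_structure(table, structure: StructureModel,
                                 chain_id: Optional[str] = None,
                                 structure_chain_id: Optional[str] = None,
                                 identity_floor: float = DEFAULT_IDENTITY_FLOOR,
                                 ) -> ResidueMapping:
    """Align one shift-table chain onto one structure chain by residue type."""
    from .core import THREE_TO_ONE

    chain_id = chain_id or table.chains()[0]
    structure_chain_id = structure_chain_id or (
        chain_id if chain_id in structure.chains() else structure.chains()[0])
    shift_res = table.residues(chain_id)
    struct_res = structure.residues(structure_chain_id)
    if not shift_res or not struct_res:
        raise MappingError("no residues to align")
    shift_seq = "".join(THREE_TO_ONE.get(r, "X") for _, r in shift_res)
    struct_seq = "".join(THREE_TO_ONE.get(r, "X") for _, r in struct_res)
    return map_sequences(shift_seq, struct_seq,
                         [p for p, _ in shift_res], [p for p, _ in struct_res],
                         identity_floor)
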