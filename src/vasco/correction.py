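"""Per-entry inference: posterior correction factors, retention, Z-scores.

With a flat prior on the group offset c_g, the posterior given the
classified shifts of group g is Gaussian with

    K      = sum_alpha n_alpha * k_alpha            (total precision)
    c_bar  = sum_alpha n_alpha * k_alpha * r_alpha / K
    sigma  = K ** -0.5

where r_alpha is the mean residual (observed minus class mean) of the
n_alpha shifts in class alpha.  A correction is retained only when
|c_bar| >= 3 sigma; otherwise the applied correction is zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .core import (
    AtomAnnotation,
    ClassStat,
    GroupAssignmentError,
    GroupCorrection,
    NucleusGroup,
    ShiftRecord,
    ShiftZScore,
    UnknownAtomError,
    VascoError,
    assign_group,
    topology,
)
from .io import ShiftTable
from .annotate import ResidueMapping
from .refdb import Observation, ReferenceDB

log = logging.getLogger(__name__)

RETENTION_SIGMA = 3.0
LOW_CONFIDENCE_FLOOR = 5


@dataclass(frozen=True)
class ClassifiedShift:
    """A shift paired with its reference class and nucleus group."""

    record: ShiftRecord
    stat: ClassStat
    group: NucleusGroup

    @property
    def residual_ppm(self) -> float:
        return self.record.value_ppm - self.stat.mean_ppm


@dataclass
class ClassifyReport:
    n_input: int = 0
    n_classified: int = 0
    n_unmapped: int = 0
    n_no_annotation: int = 0
    n_no_class: int = 0
    n_no_group: int = 0


def classify_shifts(table: ShiftTable,
                    annotations: Iterable[AtomAnnotation],
                    mapping: Union[ResidueMapping, dict[str, ResidueMapping]],
                    refdb: ReferenceDB,
                    ) -> tuple[list[ClassifiedShift], ClassifyReport]:
    """Pair each shift with its reference-class statistics.

    Shifts on residues excluded by the alignment, or whose class is absent
    from the reference database (too few observations), are dropped and
    counted.  Protons inherit the annotation of their bonded heavy atom.
    """
    ann_by_key = {a.atom_key: a for a in annotations}
    if isinstance(mapping, ResidueMapping):
        chain_maps = {c: mapping for c in table.chains()}
    else:
        chain_maps = mapping

    report = ClassifyReport(n_input=len(table.records))
    topo = topology()
    out: list[ClassifiedShift] = []
    for rec in table.records:
        cmap = chain_maps.get(rec.chain_id)
        pos = cmap.as_dict().get(rec.seq_pos) if cmap else None
        if pos is None:
            report.n_unmapped += 1
            continue
        try:
            group = assign_group(rec.residue_type, rec.atom_name)
            heavy = topo.heavy_parent(rec.residue_type, rec.atom_name)
        except (UnknownAtomError, GroupAssignmentError):
            report.n_no_group += 1
            continue
        ann = ann_by_key.get((rec.chain_id, pos, heavy))
        if ann is None and rec.chain_id not in {k[0] for k in ann_by_key}:
            # single-chain structure annotated under another chain id
            cands = [a for k, a in ann_by_key.items()
                     if k[1] == pos and k[2] == heavy]
            ann = cands[0] if len(cands) == 1 else None
        if ann is None:
            report.n_no_annotation += 1
            continue
        stat = refdb.lookup((rec.residue_type, rec.atom_name), ann.ss_state,
                            ann.asa_fraction)
        if stat is None:
            report.n_no_class += 1
            continue
        out.append(ClassifiedShift(rec, stat, group))
    report.n_classified = len(out)
    if not out:
        raise VascoError("no classifiable shifts: empty intersection of "
                         "shift table, mapping and reference database")
    return out, report


def annotate_entry(table: ShiftTable,
                   annotations: Iterable[AtomAnnotation],
                   mapping: Union[ResidueMapping, dict[str, ResidueMapping]],
                   ) -> "AnnotatedEntry":
    """Convert a shift table into database-build observations (no refdb
    lookup: used when assembling the reference population itself)."""
    from .refdb import AnnotatedEntry

    ann_by_key = {a.atom_key: a for a in annotations}
    if isinstance(mapping, ResidueMapping):
        chain_maps = {c: mapping for c in table.chains()}
    else:
        chain_maps = mapping
    topo = topology()
    obs = []
    for rec in table.records:
        cmap = chain_maps.get(rec.chain_id)
        pos = cmap.as_dict().get(rec.seq_pos) if cmap else None
        if pos is None:
            continue
        try:
            heavy = topo.heavy_parent(rec.residue_type, rec.atom_name)
            assign_group(rec.residue_type, rec.atom_name)
        except (UnknownAtomError, GroupAssignmentError):
            continue
        ann = ann_by_key.get((rec.chain_id, pos, heavy))
        if ann is None:
            cands = [a for key, a in ann_by_key.items()
                     if key[1] == pos and key[2] == heavy]
            ann = cands[0] if len(cands) == 1 else None
        if ann is None:
            continue
        obs.append(Observation((rec.residue_type, rec.atom_name),
                               ann.ss_state, ann.asa_fraction, rec.value_ppm))
    return AnnotatedEntry(table.entry_id, obs)


def _posterior_from_arrays(group: NucleusGroup, k: np.ndarray, resid: np.ndarray,
                           retention_sigma: float = RETENTION_SIGMA,
                           low_confidence_floor: int = LOW_CONFIDENCE_FLOOR,
                           ) -> GroupCorrection:
    n = int(k.size)
    if n == 0:
        return GroupCorrection(group=group, mean_ppm=0.0,
                               uncertainty_ppm=math.inf, total_precision=0.0,
                               n_shifts_used=0, retained=False,
                               low_confidence=True)
    total_precision = float(np.sum(k))
    mean = float(np.sum(k * resid) / total_precision)
    uncertainty = total_precision ** -0.5
    retained = abs(mean) >= retention_sigma * uncertainty
    return GroupCorrection(group=group, mean_ppm=mean,
                           uncertainty_ppm=uncertainty,
                           total_precision=total_precision,
                           n_shifts_used=n, retained=retained,
                           low_confidence=n < low_confidence_floor)


def posterior_correction(classified: Sequence[ClassifiedShift],
                         group: NucleusGroup,
                         retention_sigma: float = RETENTION_SIGMA,
                         low_confidence_floor: int = LOW_CONFIDENCE_FLOOR,
                         ) -> GroupCorrection:
    """Closed-form Gaussian posterior for one nucleus group's offset."""
    members = [c for c in classified if c.group == group]
    k = np.array([c.stat.precision for c in members])
    resid = np.array([c.residual_ppm for c in members])
    return _posterior_from_arrays(group, k, resid, retention_sigma,
                                  low_confidence_floor)


def compute_corrections(classified: Sequence[ClassifiedShift],
                        retention_sigma: float = RETENTION_SIGMA,
                        low_confidence_floor: int = LOW_CONFIDENCE_FLOOR,
                        ) -> dict[NucleusGroup, GroupCorrection]:
    """Exactly five corrections, one per nucleus group."""
    return {g: posterior_correction(classified, g, retention_sigma,
                                    low_confidence_floor)
            for g in NucleusGroup}


def corrections_for_observations(observations: Iterable[Observation],
                                 refdb: ReferenceDB,
                                 retention_sigma: float = RETENTION_SIGMA,
                                 ) -> dict[NucleusGroup, GroupCorrection]:
    """Group corrections straight from annotated observations (database
    build path, no shift-table plumbing)."""
    ks: dict[NucleusGroup, list[float]] = {g: [] for g in NucleusGroup}
    rs: dict[NucleusGroup, list[float]] = {g: [] for g in NucleusGroup}
    for o in observations:
        stat = refdb.lookup(o.atom_type, o.ss_state, o.asa_fraction)
        if stat is None:
            continue
        try:
            g = assign_group(*o.atom_type)
        except (UnknownAtomError, GroupAssignmentError):
            continue
        ks[g].append(stat.precision)
        rs[g].append(o.value_ppm - stat.mean_ppm)
    return {g: _posterior_from_arrays(g, np.array(ks[g]), np.array(rs[g]),
                                      retention_sigma)
            for g in NucleusGroup}


def apply_corrections(table: ShiftTable,
                      corrections: dict[NucleusGroup, GroupCorrection],
                      ) -> ShiftTable:
    """Subtract each retained group correction from that group's shifts.

    Shifts whose group correction was not retained, and shifts that cannot
    be assigned a group, pass through unchanged.  The input table is not
    modified.
    """
    new_records = []
    for rec in table.records:
        try:
            group = assign_group(rec.residue_type, rec.atom_name)
        except (UnknownAtomError, GroupAssignmentError):
            new_records.append(rec)
            continue
        applied = corrections[group].applied_ppm if group in corrections else 0.0
        new_records.append(ShiftRecord(rec.chain_id, rec.seq_pos,
                                       rec.residue_type, rec.atom_name,
                                       rec.value_ppm - applied))
    return ShiftTable(table.entry_id, new_records, table.parse_report)


def zscore_shifts(classified: Sequence[ClassifiedShift],
                  corrections: dict[NucleusGroup, GroupCorrection],
                  ) -> list[ShiftZScore]:
    """Standardized deviation of each corrected shift from its class:
    z = (corrected - s_alpha) * sqrt(k_alpha)."""
    out = []
    for c in classified:
        corrected = c.record.value_ppm - corrections[c.group].applied_ppm
        z = (corrected - c.stat.mean_ppm) * math.sqrt(c.stat.precision)
        out.append(ShiftZScore(c.record.key, corrected, z))
    return out


# ---------------------------------------------------------------------------
# stability experiment


@dataclass(frozen=True)
class StabilityRow:
    fraction: float
    group: NucleusGroup
    n_samples: int
    n_retained: int
    n_samples_min: int  # samples with >= min_shifts remaining in the group
    n_retained_min: int


def stability_experiment(classified: Sequence[ClassifiedShift],
                         removal_fractions: Sequence[float],
                         n_samples: int,
                         seed: int,
                         retention_sigma: float = RETENTION_SIGMA,
                         min_shifts: int = 0) -> list[StabilityRow]:
    """Random-deletion robustness test.

    For each removal fraction, ``n_samples`` random subsets are drawn by
    deleting that fraction of shifts uniformly at random; corrections are
    recomputed on each subset and retained ('erroneously found')
    corrections counted per group.  Deterministic under ``seed``.
    """
    for f in removal_fractions:
        if not 0.0 <= f < 1.0:
            raise ValueError(f"removal fraction {f} outside [0, 1)")
    if not classified:
        raise VascoError("no classified shifts")
    rng = np.random.default_rng(seed)
    n = len(classified)
    groups = list(NucleusGroup)
    group_idx = np.array([groups.index(c.group) for c in classified])
    k = np.array([c.stat.precision for c in classified])
    resid = np.array([c.residual_ppm for c in classified])

    rows = []
    for fraction in removal_fractions:
        n_keep = n - int(round(fraction * n))
        retained = np.zeros(len(groups), dtype=int)
        eligible = np.zeros(len(groups), dtype=int)
        retained_min = np.zeros(len(groups), dtype=int)
        for _ in range(n_samples):
            keep = rng.choice(n, size=n_keep, replace=False)
            gi, ki, ri = group_idx[keep], k[keep], resid[keep]
            for g in range(len(groups)):
                mask = gi == g
                m = int(np.count_nonzero(mask))
                if m == 0:
                    continue
                total = float(np.sum(ki[mask]))
                mean = float(np.sum(ki[mask] * ri[mask])) / total
                hit = abs(mean) >= retention_sigma * total ** -0.5
                retained[g] += hit
                if m >= min_shifts:
                    eligible[g] += 1
                    retained_min[g] += hit
        for g, group in enumerate(groups):
            rows.append(StabilityRow(fraction, group, n_samples,
                                     int(retained[g]), int(eligible[g]),
                                     int(retained_min[g])))
    return rows


# ---------------------------------------------------------------------------
# numerical-integration oracle (test use)


def posterior_numerical(n_alpha: Sequence[int], k_alpha: Sequence[float],
                        r_alpha: Sequence[float], n_grid: int = 20001,
                        half_width_sigma: float = 10.0,
                        ) -> tuple[float, float]:
    """Mean and sd of the group-offset posterior by trapezoidal quadrature.

    Multiplies the per-shift Gaussian likelihoods under a flat prior on a
    +/- ``half_width_sigma`` grid around the closed-form mean.  Exists as an
    independent oracle for the closed form; not a runtime path.
    """
    n_alpha = np.asarray(n_alpha, dtype=float)
    k_alpha = np.asarray(k_alpha, dtype=float)
    r_alpha = np.asarray(r_alpha, dtype=float)
    total = float(np.sum(n_alpha * k_alpha))
    sd = total ** -0.5
    # the posterior mean is a convex combination of the r_alpha, so this
    # bracket provably contains all the mass
    grid = np.linspace(float(np.min(r_alpha)) - half_width_sigma * sd,
                       float(np.max(r_alpha)) + half_width_sigma * sd, n_grid)
    # log product of likelihoods: sum_alpha n_alpha * k_alpha * (r_alpha-c)^2 / -2
    logp = -0.5 * np.sum(
        n_alpha[:, None] * k_alpha[:, None] * (r_alpha[:, None] - grid[None, :]) ** 2,
        axis=0)
    logp -= logp.max()
    p = np.exp(logp)
    norm = np.trapezoid(p, grid)
    mean = float(np.trapezoid(p * grid, grid) / norm)
    var = float(np.trapezoid(p * (grid - mean) ** 2, grid) / norm)
    return mean, math.sqrt(var)
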