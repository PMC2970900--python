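"""Class-conditional Gaussian reference statistics.

Observations are stratified by atom type and secondary structure; within a
stratum they are binned by discretized solvent accessibility so that each
interior bin holds a fixed number of points (default 200).  The zero-ASA
bin may hold more, the highest-ASA bin fewer; classes below the target
count are excluded from inference.  The database is built twice: once from
the raw shifts, then again after subtracting per-entry corrections, so that
wrongly referenced entries have minimal effect on the statistics.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Union

import numpy as np

from .core import (
    ClassStat,
    SecondaryStructure,
    ShiftClass,
    VascoError,
    assign_group,
)

log = logging.getLogger(__name__)

DEFAULT_BIN_COUNT = 200
REFDB_FORMAT_VERSION = 1


class Observation(NamedTuple):
    """One annotated database observation."""

    atom_type: tuple[str, str]  # (residue_type, atom_name)
    ss_state: SecondaryStructure
    asa_fraction: float
    value_ppm: float


@dataclass
class AnnotatedEntry:
    """All classifiable observations of one archive entry."""

    entry_id: str
    observations: list[Observation]


def _stratum_key(atom_type: tuple[str, str], atom_mode: str) -> tuple[str, str]:
    if atom_mode == "atom":
        return ("*", atom_type[1])
    return atom_type


@dataclass
class BinningScheme:
    """Per-stratum ASA cut points.

    ``cuts[stratum]`` is an ascending list of lower bin edges starting at
    0.0; bin i covers [cuts[i], cuts[i+1]) and the last bin is closed above.
    An ASA of exactly 0 always lands in bin 0.
    """

    target_bin_count: int = DEFAULT_BIN_COUNT
    atom_mode: str = "residue_atom"  # or "atom"
    cuts: dict[tuple[tuple[str, str], SecondaryStructure], list[float]] = \
        field(default_factory=dict)

    def bin_index(self, atom_type: tuple[str, str], ss_state: SecondaryStructure,
                  asa_fraction: float) -> Optional[int]:
        key = (_stratum_key(atom_type, self.atom_mode), ss_state)
        cuts = self.cuts.get(key)
        if cuts is None:
            return None
        return max(0, bisect_right(cuts, asa_fraction) - 1)

    def shift_class(self, atom_type: tuple[str, str], ss_state: SecondaryStructure,
                    asa_fraction: float) -> Optional[ShiftClass]:
        idx = self.bin_index(atom_type, ss_state, asa_fraction)
        if idx is None:
            return None
        return ShiftClass(_stratum_key(atom_type, self.atom_mode), ss_state, idx)


def build_binning(observations: Iterable[Observation],
                  target_bin_count: int = DEFAULT_BIN_COUNT,
                  atom_mode: str = "residue_atom") -> BinningScheme:
    """Partition each stratum's ASA axis into consecutive equal-count bins.

    All zero-ASA observations form bin 0.  The remaining observations are
    split, in ascending ASA order, into runs of ``target_bin_count``;
    observations sharing one discretized ASA value are never split across
    bins, and the highest bin keeps the remainder.
    """
    obs = list(observations)
    if not obs:
        raise VascoError("no observations to bin")
    strata: dict[tuple, list[float]] = {}
    for o in obs:
        key = (_stratum_key(o.atom_type, atom_mode), o.ss_state)
        strata.setdefault(key, []).append(o.asa_fraction)

    scheme = BinningScheme(target_bin_count=target_bin_count, atom_mode=atom_mode)
    for key, values in strata.items():
        values.sort()
        positive = [v for v in values if v > 0.0]
        cuts = [0.0]
        has_zero_bin = len(positive) < len(values)
        if has_zero_bin and positive:
            cuts.append(positive[0])  # zero-ASA observations stay in bin 0
        i = 0
        while i < len(positive):
            j = _advance_run(positive, i, target_bin_count)
            if j >= len(positive):
                break
            cuts.append(positive[j])
            i = j
        scheme.cuts[key] = cuts
    return scheme


def _advance_run(values: list[float], start: int, target: int) -> int:
    """End index of a bin starting at ``start``: at least ``target`` points,
    extended so a run of tied values is never split."""
    j = start + target
    if j >= len(values):
        return len(values)
    while j < len(values) and values[j] == values[j - 1]:
        j += 1
    return j


def bin_sizes(observations: Iterable[Observation], scheme: BinningScheme,
              ) -> dict[tuple, list[int]]:
    """Observation count per bin, per stratum (diagnostics / invariants)."""
    counts: dict[tuple, dict[int, int]] = {}
    for o in observations:
        sc = scheme.shift_class(o.atom_type, o.ss_state, o.asa_fraction)
        if sc is None:
            continue
        d = counts.setdefault((sc.atom_type, sc.ss_state), {})
        d[sc.asa_bin_index] = d.get(sc.asa_bin_index, 0) + 1
    return {key: [d.get(i, 0) for i in range(max(d) + 1)]
            for key, d in counts.items()}


def fit_class_stats(observations: Iterable[Observation], scheme: BinningScheme,
                    ) -> list[ClassStat]:
    """Gaussian (mean, precision) per class; classes with fewer than two
    distinct values are excluded."""
    groups: dict[ShiftClass, list[float]] = {}
    for o in observations:
        sc = scheme.shift_class(o.atom_type, o.ss_state, o.asa_fraction)
        if sc is None:
            continue
        groups.setdefault(sc, []).append(o.value_ppm)
    stats = []
    for sc, values in groups.items():
        arr = np.asarray(values)
        if arr.size < 2 or np.all(arr == arr[0]):
            log.debug("class %s excluded: zero variance (%d values)", sc, arr.size)
            continue
        var = float(np.var(arr, ddof=1))
        stats.append(ClassStat(sc, float(arr.mean()), 1.0 / var, int(arr.size)))
    return stats


@dataclass
class ReferenceDB:
    """Lookup table of class-conditional Gaussians.

    Only classes whose build count reaches the target bin count are kept;
    lookups for other classes return None and the shift is excluded from
    inference.
    """

    scheme: BinningScheme
    stats: dict[ShiftClass, ClassStat]
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_stats(cls, scheme: BinningScheme, stats: Iterable[ClassStat],
                   metadata: Optional[dict] = None,
                   min_count: Optional[int] = None) -> "ReferenceDB":
        threshold = scheme.target_bin_count if min_count is None else min_count
        kept = {s.shift_class: s for s in stats if s.count >= threshold}
        return cls(scheme, kept, metadata or {})

    def lookup(self, atom_type: tuple[str, str], ss_state: SecondaryStructure,
               asa_fraction: float) -> Optional[ClassStat]:
        sc = self.scheme.shift_class(atom_type, ss_state, asa_fraction)
        if sc is None:
            return None
        return self.stats.get(sc)

    def __len__(self) -> int:
        return len(self.stats)

    # -- serialization ------------------------------------------------------

    def to_path(self, dest: Union[str, Path]) -> None:
        lines = [f"# vasco-refdb {REFDB_FORMAT_VERSION}",
                 f"#meta target_bin_count {self.scheme.target_bin_count}",
                 f"#meta atom_mode {self.scheme.atom_mode}"]
        for k, v in sorted(self.metadata.items()):
            lines.append(f"#meta {k} {v}")
        lines.append("residue\tatom\tss_state\tbin_index\tbin_low\tbin_high\t"
                     "count\tmean_ppm\tvariance_ppm2")
        for sc in sorted(self.stats, key=lambda c: (c.atom_type, c.ss_state.value,
                                                    c.asa_bin_index)):
            st = self.stats[sc]
            cuts = self.scheme.cuts[(sc.atom_type, sc.ss_state)]
            low = cuts[sc.asa_bin_index]
            high = cuts[sc.asa_bin_index + 1] if sc.asa_bin_index + 1 < len(cuts) else 1.0
            lines.append(
                f"{sc.atom_type[0]}\t{sc.atom_type[1]}\t{sc.ss_state.value}\t"
                f"{sc.asa_bin_index}\t{low!r}\t{high!r}\t{st.count}\t"
                f"{st.mean_ppm!r}\t{1.0 / st.precision!r}")
        Path(dest).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_path(cls, source: Union[str, Path]) -> "ReferenceDB":
        path = Path(source)
        if not path.exists():
            raise VascoError(f"no such refdb file: {path}")
        meta: dict[str, str] = {}
        rows = []
        for line in path.read_text().splitlines():
            if line.startswith("#meta "):
                _, k, v = line.split(" ", 2)
                meta[k] = v
            elif line.startswith("#") or line.startswith("residue\t") or not line:
                continue
            else:
                rows.append(line.split("\t"))
        if not rows:
            raise VascoError(f"{path}: empty reference database")
        target = int(meta.pop("target_bin_count", DEFAULT_BIN_COUNT))
        atom_mode = meta.pop("atom_mode", "residue_atom")
        scheme = BinningScheme(target_bin_count=target, atom_mode=atom_mode)
        stats: dict[ShiftClass, ClassStat] = {}
        strata_cuts: dict[tuple, dict[int, float]] = {}
        for res, atom, ss, idx, low, high, count, mean, var in rows:
            sc = ShiftClass((res, atom), SecondaryStructure(ss), int(idx))
            stats[sc] = ClassStat(sc, float(mean), 1.0 / float(var), int(count))
            strata_cuts.setdefault(((res, atom), sc.ss_state), {})[int(idx)] = float(low)
        for key, by_idx in strata_cuts.items():
            n_bins = max(by_idx) + 1
            cuts = [by_idx.get(i, 0.0) for i in range(n_bins)]
            scheme.cuts[key] = cuts
        db = cls(scheme, stats, dict(meta))
        return db


def collect_observations(entries: Iterable[AnnotatedEntry]) -> list[Observation]:
    out: list[Observation] = []
    for entry in entries:
        out.extend(entry.observations)
    return out


def build_reference_db(entries: Iterable[AnnotatedEntry],
                       target_bin_count: int = DEFAULT_BIN_COUNT,
                       atom_mode: str = "residue_atom",
                       metadata: Optional[dict] = None) -> ReferenceDB:
    """One build pass: binning scheme plus class statistics."""
    obs = collect_observations(entries)
    scheme = build_binning(obs, target_bin_count, atom_mode)
    stats = fit_class_stats(obs, scheme)
    return ReferenceDB.from_stats(scheme, stats, metadata)


def iterative_build(entries: list[AnnotatedEntry],
                    n_iterations: int = 2,
                    target_bin_count: int = DEFAULT_BIN_COUNT,
                    atom_mode: str = "residue_atom",
                    retention_sigma: float = 3.0) -> ReferenceDB:
    """Self-consistent database build.

    Iteration 0 fits the statistics on the raw shifts.  Every further
    iteration computes per-entry group corrections against the current
    statistics, subtracts the retained ones from that entry's shifts, and
    refits.  Two iterations (initial + one repeat) are the default; more
    have no significant effect.
    """
    from .correction import corrections_for_observations

    if len(entries) < 2:
        raise VascoError("iterative build needs at least two entries")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    current = [AnnotatedEntry(e.entry_id, list(e.observations)) for e in entries]
    db = build_reference_db(current, target_bin_count, atom_mode)
    for _ in range(n_iterations - 1):
        corrected: list[AnnotatedEntry] = []
        for entry in current:
            corr = corrections_for_observations(entry.observations, db,
                                                retention_sigma=retention_sigma)
            new_obs = []
            for o in entry.observations:
                applied = corr[assign_group(*o.atom_type)].applied_ppm
                new_obs.append(o._replace(value_ppm=o.value_ppm - applied))
            corrected.append(AnnotatedEntry(entry.entry_id, new_obs))
        current = corrected
        db = build_reference_db(current, target_bin_count, atom_mode)
    db.metadata.update(n_entries=len(entries), n_iterations=n_iterations)
    return db
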