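import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasco.core import (
    ClassStat,
    NucleusGroup,
    SecondaryStructure,
    ShiftClass,
    ShiftRecord,
    VascoError,
)
from vasco.correction import (
    ClassifiedShift,
    apply_corrections,
    classify_shifts,
    compute_corrections,
    posterior_correction,
    posterior_numerical,
    stability_experiment,
    zscore_shifts,
)
from vasco.io import ShiftTable
from vasco.synthetic import make_entry, make_refdb

COIL = SecondaryStructure.coil


def _classified(values, precisions, mean=50.0, group=NucleusGroup.C_ali,
                residue="ALA", atom="CA", counts=None):
    """Hand-built classified shifts, one class per distinct precision."""
    out = []
    for i, (v, k) in enumerate(zip(values, precisions)):
        sc = ShiftClass((residue, atom), COIL, 0)
        stat = ClassStat(sc, mean, k, counts or 200)
        rec = ShiftRecord("A", i + 1, residue, atom, mean + v)
        out.append(ClassifiedShift(rec, stat, group))
    return out


class TestPosteriorCorrection:
    def test_single_class_four_shifts(self):
        # four shifts at exactly s + 2.0, k = 1 -> c = 2, sigma = 1/sqrt(4)
        cl = _classified([2.0] * 4, [1.0] * 4)
        c = posterior_correction(cl, NucleusGroup.C_ali)
        assert c.mean_ppm == pytest.approx(2.0)
        assert c.uncertainty_ppm == pytest.approx(0.5)
        assert c.total_precision == pytest.approx(4.0)
        assert c.retained  # 2.0 >= 3 * 0.5

    def test_two_class_precision_weighting(self):
        # (n=2, k=4, r=1) and (n=2, k=1, r=2): c = (8 + 4)/10 = 1.2
        cl = _classified([1.0, 1.0], [4.0, 4.0]) + \
            _classified([2.0, 2.0], [1.0, 1.0])
        c = posterior_correction(cl, NucleusGroup.C_ali)
        assert c.mean_ppm == pytest.approx(1.2)
        assert c.uncertainty_ppm == pytest.approx(10 ** -0.5)
        assert c.retained

    def test_retention_boundary_not_retained(self):
        c = posterior_correction(_classified([2.0], [1.0]), NucleusGroup.C_ali)
        assert c.mean_ppm == pytest.approx(2.0)
        assert c.uncertainty_ppm == pytest.approx(1.0)
        assert not c.retained  # 2.0 < 3.0

    def test_retention_at_exactly_three_sigma(self):
        c = posterior_correction(_classified([3.0], [1.0]), NucleusGroup.C_ali)
        assert c.mean_ppm == pytest.approx(3.0)
        assert c.retained  # >= comparison: 3.0 counts

    def test_empty_group_zero_correction(self):
        c = posterior_correction([], NucleusGroup.C_aro)
        assert c.n_shifts_used == 0
        assert c.mean_ppm == 0.0
        assert not c.retained
        assert c.applied_ppm == 0.0
        assert c.total_precision == 0.0

    def test_uncertainty_is_inverse_root_precision(self):
        cl = _classified([0.5] * 7, [2.0] * 7)
        c = posterior_correction(cl, NucleusGroup.C_ali)
        assert c.uncertainty_ppm == pytest.approx(c.total_precision ** -0.5)

    @given(st.floats(-50, 50), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_translation_equivariance_exact(self, delta, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, size=8).tolist()
        ks = rng.uniform(0.1, 10, size=8).tolist()
        base = posterior_correction(_classified(values, ks), NucleusGroup.C_ali)
        shifted = posterior_correction(
            _classified([v + delta for v in values], ks), NucleusGroup.C_ali)
        assert shifted.mean_ppm - base.mean_ppm == pytest.approx(delta, abs=1e-9)
        assert shifted.uncertainty_ppm == base.uncertainty_ppm

    def test_agrees_with_numerical_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n_classes = int(rng.integers(1, 6))
            n = rng.integers(1, 11, size=n_classes)
            k = rng.uniform(0.05, 20.0, size=n_classes)
            r = rng.normal(0, 3, size=n_classes)
            cl = []
            for nc, kc, rc in zip(n, k, r):
                cl += _classified([rc] * int(nc), [kc] * int(nc))
            closed = posterior_correction(cl, NucleusGroup.C_ali)
            mean, sd = posterior_numerical(n, k, r)
            assert closed.mean_ppm == pytest.approx(mean, rel=1e-6, abs=1e-9)
            assert closed.uncertainty_ppm == pytest.approx(sd, rel=1e-6)


class TestComputeCorrections:
    def test_always_five_groups(self, refdb, offset_entry):
        classified, _ = classify_shifts(offset_entry.table,
                                        offset_entry.annotations,
                                        offset_entry.mapping, refdb)
        corrections = compute_corrections(classified)
        assert set(corrections) == set(NucleusGroup)
        assert sum(c.n_shifts_used for c in corrections.values()) == len(classified)

    def test_recovers_injected_offset(self, refdb, offset_entry):
        classified, _ = classify_shifts(offset_entry.table,
                                        offset_entry.annotations,
                                        offset_entry.mapping, refdb)
        corrections = compute_corrections(classified)
        c = corrections[NucleusGroup.C_ali]
        assert c.retained
        assert abs(c.mean_ppm - 2.0) <= 3 * c.uncertainty_ppm

    def test_low_confidence_flag(self):
        cl = _classified([0.1] * 3, [1.0] * 3)
        c = posterior_correction(cl, NucleusGroup.C_ali)
        assert c.low_confidence  # fewer than 5 shifts


class TestClassifyShifts:
    def test_all_mappable_count_preserved(self, refdb, offset_entry):
        classified, report = classify_shifts(offset_entry.table,
                                             offset_entry.annotations,
                                             offset_entry.mapping, refdb)
        assert report.n_classified == report.n_input == len(classified)

    def test_unmapped_residue_excluded(self, refdb, offset_entry):
        from vasco.annotate import ResidueMapping

        pairs = tuple(p for p in offset_entry.mapping.pairs if p[0] > 10)
        mapping = ResidueMapping(pairs, 1.0)
        classified, report = classify_shifts(offset_entry.table,
                                             offset_entry.annotations,
                                             mapping, refdb)
        assert report.n_unmapped == 10
        assert report.n_classified == report.n_input - 10

    def test_absent_class_excluded(self, refdb, offset_entry):
        from vasco.refdb import ReferenceDB

        pruned = ReferenceDB(refdb.scheme,
                             {k: v for k, v in refdb.stats.items()
                              if k.atom_type != ("ALA", "CA")},
                             refdb.metadata)
        classified, report = classify_shifts(offset_entry.table,
                                             offset_entry.annotations,
                                             offset_entry.mapping, pruned)
        assert report.n_no_class > 0
        assert all(c.stat.shift_class.atom_type != ("ALA", "CA")
                   for c in classified)

    def test_empty_intersection_errors(self, refdb, offset_entry):
        from vasco.annotate import ResidueMapping

        with pytest.raises(VascoError, match="no classifiable"):
            classify_shifts(offset_entry.table, offset_entry.annotations,
                            ResidueMapping((), 1.0), refdb)


class TestApplyCorrections:
    def test_retained_subtracted_from_group(self, refdb, offset_entry):
        classified, _ = classify_shifts(offset_entry.table,
                                        offset_entry.annotations,
                                        offset_entry.mapping, refdb)
        corrections = compute_corrections(classified)
        assert corrections[NucleusGroup.C_ali].retained
        corrected = apply_corrections(offset_entry.table, corrections)
        applied = corrections[NucleusGroup.C_ali].mean_ppm
        for before, after in zip(offset_entry.table.records, corrected.records):
            from vasco.core import assign_group

            if assign_group(before.residue_type, before.atom_name) is \
                    NucleusGroup.C_ali:
                assert after.value_ppm == pytest.approx(
                    before.value_ppm - applied, abs=1e-12)

    def test_non_retained_groups_unchanged(self, refdb, offset_entry):
        from vasco.core import assign_group

        classified, _ = classify_shifts(offset_entry.table,
                                        offset_entry.annotations,
                                        offset_entry.mapping, refdb)
        corrections = compute_corrections(classified)
        corrected = apply_corrections(offset_entry.table, corrections)
        for before, after in zip(offset_entry.table.records, corrected.records):
            group = assign_group(before.residue_type, before.atom_name)
            if not corrections[group].retained:
                assert after.value_ppm == before.value_ppm

    def test_second_pass_near_zero(self, refdb, offset_entry):
        classified, _ = classify_shifts(offset_entry.table,
                                        offset_entry.annotations,
                                        offset_entry.mapping, refdb)
        corrections = compute_corrections(classified)
        corrected = apply_corrections(offset_entry.table, corrections)
        classified2, _ = classify_shifts(corrected, offset_entry.annotations,
                                         offset_entry.mapping, refdb)
        corrections2 = compute_corrections(classified2)
        for g in NucleusGroup:
            if corrections[g].retained:
                assert abs(corrections2[g].mean_ppm) <= \
                    corrections2[g].uncertainty_ppm


class TestZScores:
    def test_direct_formula_cases(self):
        cl = _classified([0.0, 1.0, 1.5], [1.0, 1.0, 4.0])
        corrections = compute_corrections(cl)
        assert not corrections[NucleusGroup.C_ali].retained
        zs = zscore_shifts(cl, corrections)
        assert zs[0].z == pytest.approx(0.0)  # corrected == class mean
        assert zs[1].z == pytest.approx(1.0)  # one sd above
        assert zs[2].z == pytest.approx(3.0)  # k=4, residual 1.5

    def test_standardization_at_scale(self, refdb):
        n = 10_000
        entry = make_entry(refdb, n, {}, noise_scale=1.0, seed=21)
        classified, _ = classify_shifts(entry.table, entry.annotations,
                                        entry.mapping, refdb)
        corrections = compute_corrections(classified)
        z = np.array([s.z for s in zscore_shifts(classified, corrections)])
        assert abs(z.mean()) <= 3.0 / math.sqrt(n)
        # sample variance of a standard normal: se = sqrt(2/n)
        assert abs(z.var(ddof=1) - 1.0) <= 3.0 * math.sqrt(2.0 / n)


class TestNoiseScatter:
    def test_scatter_only_increases_error_margin(self):
        """Adding zero-mean scatter leaves the expected correction at the
        truth and widens the class distributions the refit database sees."""
        from vasco.refdb import Observation, build_reference_db, AnnotatedEntry
        from vasco.correction import corrections_for_observations
        from vasco.synthetic import default_layout

        rng = np.random.default_rng(17)
        layout = default_layout(counts=400)
        means = []
        base_db = make_refdb(layout, seed=0)
        for noise in (1.0, 3.0):
            obs = []
            for spec in layout:
                sd = noise * spec.precision ** -0.5
                values = rng.normal(spec.mean_ppm, sd, size=spec.count)
                obs.extend(Observation(spec.atom_type, spec.ss_state, 0.0,
                                       float(v)) for v in values)
            db = build_reference_db([AnnotatedEntry("x", obs)],
                                    target_bin_count=300)
            entry_obs = obs[:200]
            c = corrections_for_observations(entry_obs, db)
            means.append(c)
            for g in NucleusGroup:
                if c[g].n_shifts_used:
                    assert abs(c[g].mean_ppm) < 3 * c[g].uncertainty_ppm
        for g in NucleusGroup:
            if means[0][g].n_shifts_used and means[1][g].n_shifts_used:
                assert means[1][g].uncertainty_ppm > means[0][g].uncertainty_ppm


@pytest.fixture(scope="module")
def classified(refdb, clean_entry):
    cl, _ = classify_shifts(clean_entry.table, clean_entry.annotations,
                            clean_entry.mapping, refdb)
    return cl


class TestStabilityExperiment:

    def test_deterministic_under_seed(self, classified):
        a = stability_experiment(classified, [0.3, 0.6], 50, seed=9)
        b = stability_experiment(classified, [0.3, 0.6], 50, seed=9)
        assert a == b

    def test_different_seed_differs(self, classified):
        a = stability_experiment(classified, [0.9], 100, seed=1)
        b = stability_experiment(classified, [0.9], 100, seed=2)
        # same shape, (almost surely) different draws; counts may coincide,
        # so only check structure
        assert [(r.fraction, r.group) for r in a] == \
            [(r.fraction, r.group) for r in b]

    def test_fraction_zero_no_false_positives(self, refdb, clean_entry, classified):
        corrections = compute_corrections(classified)
        assert not any(c.retained for c in corrections.values())
        rows = stability_experiment(classified, [0.0], 20, seed=3)
        assert all(r.n_retained == 0 for r in rows)

    def test_invalid_fraction_errors(self, classified):
        with pytest.raises(ValueError):
            stability_experiment(classified, [1.5], 10, seed=0)

    def test_counts_stay_small(self, classified):
        rows = stability_experiment(classified, [0.1, 0.5, 0.9], 200, seed=4)
        for row in rows:
            assert row.n_retained <= 0.05 * row.n_samples
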