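import numpy as np
import pytest

from pscdkit.clinical import classify_decliner, records_to_frame, rank_correlation
from pscdkit.cohort import (
    CohortSpec,
    OutcomeCoefs,
    build_generating_matrix,
    compact_partition,
    generate_block_bold,
    generate_cohort,
    generate_labeled_volumes,
    psd_repair,
)
from pscdkit.connectivity import compute_fc, fisher_z
from pscdkit.imaging import regional_suvr, wmh_volume_fraction
from pscdkit.segregation import CanonicalPartition, system_segregation


TWO_NET = (("VN", 10), ("SMN", 10))


def _sample_sysseg(ts, partition_spec):
    assignment = {}
    i = 0
    for name, cnt in partition_spec:
        for _ in range(cnt):
            assignment[i] = name
            i += 1
    nets = tuple(dict.fromkeys(n for n, _ in partition_spec))
    part = CanonicalPartition(assignment, nets)
    return system_segregation(fisher_z(compute_fc(ts)), part).overall["sysseg"]


class TestBlockBold:
    def test_empirical_correlations_converge_to_targets(self):
        ts = generate_block_bold((("A", 3), ("B", 3)), 5000, 0.6, 0.0, seed=0)
        fc = compute_fc(ts).values
        within = [fc[i, j] for b in (0, 3) for i in range(b, b + 3) for j in range(i + 1, b + 3)]
        between = [fc[i, j] for i in range(3) for j in range(3, 6)]
        assert np.mean(within) == pytest.approx(0.6, abs=0.05)
        assert np.mean(between) == pytest.approx(0.0, abs=0.05)

    def test_no_modular_structure_gives_zero_sysseg(self):
        ts = generate_block_bold(TWO_NET, 5000, 0.3, 0.3, seed=1)
        assert abs(_sample_sysseg(ts, TWO_NET)) < 0.05

    def test_full_mixing_does_not_increase_sysseg(self):
        kwargs = dict(timepoints=2000, r_within=0.6, r_between=0.1, seed=2)
        s_mixed = _sample_sysseg(
            generate_block_bold(TWO_NET, mixing_fraction=1.0, **kwargs), TWO_NET
        )
        s_intact = _sample_sysseg(
            generate_block_bold(TWO_NET, mixing_fraction=0.0, **kwargs), TWO_NET
        )
        assert s_mixed <= s_intact

    def test_invalid_correlations_rejected(self):
        with pytest.raises(ValueError):
            generate_block_bold(TWO_NET, 100, 1.0, 0.1)
        with pytest.raises(ValueError):
            generate_block_bold(TWO_NET, 100, 0.3, 0.5)

    def test_short_series_warns(self):
        with pytest.warns(UserWarning, match="timepoints"):
            generate_block_bold(TWO_NET, 10, 0.5, 0.1, seed=0)


class TestGeneratingMatrix:
    def test_psd_repair_contract(self):
        # a chain-attenuated block matrix needs (and survives) repair
        c, _ = build_generating_matrix([5, 5, 5, 5], 0.6, 0.4, 0.0, 0.05)
        assert np.allclose(np.diag(c), 1.0)
        assert np.linalg.eigvalsh(c).min() >= -1e-10

    def test_psd_repair_fixes_indefinite_matrix(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < 0
        fixed = psd_repair(bad)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-12
        assert np.allclose(np.diag(fixed), 1.0)

    def test_segregation_monotone_in_shift(self):
        # same seed streams, growing shift => non-increasing decliner
        # generating segregation
        means = []
        for shift in (0.0, 0.05, 0.1, 0.15, 0.2):
            spec = CohortSpec(
                n_decliners=3, n_nondecliners=0, partition_spec=compact_partition(),
                segregation_shift=shift, mixing_fraction=0.0,
                long_range_attenuation=1.0, r_within_sd=0.0, seed=11,
            )
            co = generate_cohort(spec, include_bold=False, include_volumes=False,
                                 enforce_label_consistency=False)
            means.append(np.mean([s.generating_segregation for s in co.subjects]))
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))


class TestGenerateCohort:
    def test_null_configuration_groups_identical(self):
        spec = CohortSpec(
            n_decliners=4, n_nondecliners=4, partition_spec=compact_partition(),
            segregation_shift=0.0, mixing_fraction=0.0, long_range_attenuation=1.0,
            outcome_coefs=OutcomeCoefs.zero(), seed=5,
        )
        co = generate_cohort(spec, include_bold=False, include_volumes=False,
                             enforce_label_consistency=False)
        dec = [s.generating_segregation for s in co.by_group("decliner")]
        non = [s.generating_segregation for s in co.by_group("non_decliner")]
        assert dec == non  # same per-subject covariance streams

    def test_segregation_couples_to_mmse_change(self):
        coefs = OutcomeCoefs(
            intercept_decliner=0.0, intercept_nondecliner=0.0, segregation=8.0,
            wmh_decliner=0.0, wmh_nondecliner=0.0, suvr=0.0, seg_ref=0.3,
        )
        spec = CohortSpec(
            n_decliners=25, n_nondecliners=25, partition_spec=compact_partition(),
            outcome_coefs=coefs, noise_sd=0.3, seed=7,
        )
        co = generate_cohort(spec, include_bold=False, include_volumes=False,
                             enforce_label_consistency=False)
        seg = [s.generating_segregation for s in co.subjects]
        change = [s.record.mmse_change for s in co.subjects]
        assert rank_correlation(seg, change).estimate > 0.5

    def test_same_seed_bit_identical_records(self):
        spec = CohortSpec(n_decliners=3, n_nondecliners=3,
                          partition_spec=compact_partition(), seed=9)
        df1 = records_to_frame(generate_cohort(spec, include_bold=False,
                                               include_volumes=False).records())
        df2 = records_to_frame(generate_cohort(spec, include_bold=False,
                                               include_volumes=False).records())
        assert df1.equals(df2)

    def test_group_labels_match_classification_rule(self):
        spec = CohortSpec(partition_spec=compact_partition(), seed=0)
        co = generate_cohort(spec, include_bold=False, include_volumes=False)
        agree = [
            classify_decliner(s.record.mmse_baseline, s.record.mmse_final,
                              s.record.interval_months) == s.record.group
            for s in co.subjects
        ]
        assert np.mean(agree) >= 0.9

    def test_volumes_consistent_with_records(self):
        spec = CohortSpec(n_decliners=2, n_nondecliners=2,
                          partition_spec=compact_partition(),
                          grid_shape=(24, 24, 24), seed=13)
        co = generate_cohort(spec, include_bold=False, include_volumes=True)
        from pscdkit.cohort import COMPOSITE_MAP, REFERENCE_LABEL
        from pscdkit.imaging import global_suvr

        for s in co.subjects:
            assert s.lesion_mask is not None
            # lesions inside the brain, recorded fraction from the mask
            assert not np.any((s.lesion_mask.data > 0) & (s.brain_mask.data == 0))
            frac = wmh_volume_fraction(s.lesion_mask, s.brain_mask)
            assert frac == pytest.approx(s.record.wmh_fraction_pct)
            res = regional_suvr(s.pet_volume, s.label_volume, REFERENCE_LABEL)
            g = global_suvr(res, COMPOSITE_MAP)
            assert g == pytest.approx(s.record.global_suvr, abs=0.05)

    def test_write_manifest(self, tmp_path):
        spec = CohortSpec(n_decliners=1, n_nondecliners=1,
                          partition_spec=compact_partition(),
                          grid_shape=(16, 16, 16), timepoints=40, seed=1)
        co = generate_cohort(spec)
        manifest = co.write(tmp_path / "cohort")
        import json

        data = json.loads(manifest.read_text())
        assert len(data["subjects"]) == 2
        for entry in data["subjects"].values():
            for key in ("bold", "pet", "labels", "lesion", "brain"):
                assert (manifest.parent / entry[key]).exists()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(r_within=1.2)
        with pytest.raises(ValueError):
            CohortSpec(r_within=0.3, r_between=0.5)
        with pytest.raises(ValueError):
            CohortSpec(mixing_fraction=1.5)

    def test_spec_round_trip(self, tmp_path):
        spec = CohortSpec(n_decliners=4, seed=42, mixing_fraction=0.25)
        spec.to_file(tmp_path / "spec.yaml")
        back = CohortSpec.from_file(tmp_path / "spec.yaml")
        assert back == spec


class TestLabeledVolumeGeneration:
    def test_known_suvr_by_construction(self):
        pet, labels, lesion, brain = generate_labeled_volumes(
            (16, 16, 16), {1: 2.6}, reference_label=9, reference_mean=2.0,
            lesion_count=0, seed=0,
        )
        res = regional_suvr(pet, labels, 9)
        assert res.per_region[1] == pytest.approx(1.3)
        assert lesion.data.sum() == 0
        assert wmh_volume_fraction(lesion, brain) == 0.0

    def test_overlapping_blobs_union_below_sum(self):
        _, _, lesion, _ = generate_labeled_volumes(
            (10, 10, 10), {1: 1.0}, reference_label=9, reference_mean=1.0,
            lesion_count=40, seed=3, lesion_edge=3,
        )
        assert 0 < lesion.data.sum() < 40 * 27

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_labeled_volumes(
                (4, 4, 4), {1: 1.0}, reference_label=9, reference_mean=1.0,
                lesion_count=3, seed=0, lesion_edge=4,
            )
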