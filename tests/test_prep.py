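"""Within-study marker averaging and point-group pooling."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ratedecay import (
    CalibrationType,
    ValidationError,
    average_markers_within_study,
    pool_point_group,
    selector_from_mapping,
)

from conftest import make_dataset, make_record


class TestAverageMarkersWithinStudy:
    def test_single_record_passes_through(self):
        ds = make_dataset(make_record())
        out = average_markers_within_study(ds)
        assert out.records == ds.records

    def test_two_markers_same_study_become_arithmetic_mean(self):
        ds = make_dataset(
            make_record(rate=2e-8, marker_name="COI"),
            make_record(rate=4e-8, marker_name="cytb"),
        )
        out = average_markers_within_study(ds)
        assert len(out) == 1
        assert out[0].rate == pytest.approx(3e-8)
        assert "COI" in out[0].marker_name and "cytb" in out[0].marker_name

    def test_geometric_mean_variant(self):
        ds = make_dataset(make_record(rate=1e-8), make_record(rate=1e-6))
        out = average_markers_within_study(ds, mean="geometric")
        assert out[0].rate == pytest.approx(1e-7)

    def test_mixed_marker_classes_are_not_merged(self):
        ds = make_dataset(
            make_record(marker_class="coding"),
            make_record(marker_class="noncoding"),
        )
        out = average_markers_within_study(ds)
        assert len(out) == 2

    def test_unequal_calibration_times_are_ambiguous(self):
        ds = make_dataset(
            make_record(calibration_time=1e6),
            make_record(calibration_time=2e6),
        )
        with pytest.raises(ValidationError, match="unequal calibration times"):
            average_markers_within_study(ds)

    def test_idempotent(self):
        ds = make_dataset(
            make_record(rate=2e-8),
            make_record(rate=4e-8),
            make_record(study_id="other"),
        )
        once = average_markers_within_study(ds)
        twice = average_markers_within_study(once)
        assert once.records == twice.records

    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.floats(1e-10, 1e-6)),
            min_size=1,
            max_size=20,
        )
    )
    def test_record_count_matches_brute_force_grouping(self, spec):
        """Output count = input - sum(k_i - 1) over multi-member groups."""
        ds = make_dataset(
            *[make_record(rate=r, study_id=f"s{g}") for g, r in spec]
        )
        out = average_markers_within_study(ds)
        from collections import Counter

        sizes = Counter(g for g, _ in spec)
        expected = len(spec) - sum(k - 1 for k in sizes.values())
        assert len(out) == expected


class TestPoolPointGroup:
    def test_three_records_pool_to_componentwise_means(self):
        ds = make_dataset(
            make_record(rate=1e-8, calibration_time=10.0, calibration_type="pedigree",
                        study_id="a"),
            make_record(rate=3e-8, calibration_time=20.0, calibration_type="pedigree",
                        study_id="b"),
            make_record(rate=5e-8, calibration_time=60.0, calibration_type="pedigree",
                        study_id="c"),
        )
        out = pool_point_group(ds, {"calibration_type": "pedigree"}, "human pedigree")
        assert len(out) == 1
        assert out[0].rate == pytest.approx(3e-8)
        assert out[0].calibration_time == pytest.approx(30.0)
        assert out[0].species == "human pedigree"
        assert out[0].calibration_type is CalibrationType.PEDIGREE

    def test_single_match_leaves_dataset_unchanged(self):
        ds = make_dataset(make_record(), make_record(species="Other species"))
        out = pool_point_group(ds, {"species": "Other species"}, "solo")
        assert out.records == ds.records
        assert any("single match" in p for p in out.provenance)

    def test_unmatched_records_untouched_and_order_kept(self):
        ds = make_dataset(
            make_record(study_id="keep1", species="A"),
            make_record(study_id="p1", species="pooled sp", rate=1e-8),
            make_record(study_id="keep2", species="B"),
            make_record(study_id="p2", species="pooled sp", rate=3e-8),
        )
        out = pool_point_group(ds, {"species": "pooled sp"}, "pool")
        assert [r.study_id for r in out] == ["keep1", "pool", "keep2"]

    def test_cross_class_pooling_is_rejected(self):
        ds = make_dataset(
            make_record(marker_class="coding", species="X"),
            make_record(marker_class="noncoding", species="X"),
        )
        with pytest.raises(ValidationError, match="both marker classes"):
            pool_point_group(ds, {"species": "X"}, "bad")

    def test_mixed_calibration_types_become_mixed(self):
        ds = make_dataset(
            make_record(species="X", calibration_type="pedigree"),
            make_record(species="X", calibration_type="ancient_dna"),
        )
        out = pool_point_group(ds, {"species": "X"}, "x")
        assert out[0].calibration_type is CalibrationType.MIXED

    def test_no_match_is_an_error(self):
        ds = make_dataset(make_record())
        with pytest.raises(ValidationError, match="matched no records"):
            pool_point_group(ds, {"species": "Nobody"}, "none")

    def test_idempotent_when_pooled_record_still_matches(self):
        ds = make_dataset(
            make_record(calibration_type="pedigree", rate=1e-8, calibration_time=5),
            make_record(calibration_type="pedigree", rate=2e-8, calibration_time=7),
        )
        sel = {"calibration_type": "pedigree"}
        once = pool_point_group(ds, sel, "ped")
        twice = pool_point_group(once, sel, "ped")
        assert once.records == twice.records

    def test_selector_unknown_field_rejected(self):
        with pytest.raises(ValidationError, match="unknown field"):
            selector_from_mapping({"colour": "blue"})

    def test_geometric_mean_pooling(self):
        ds = make_dataset(
            make_record(species="X", rate=1e-9, calibration_time=10.0),
            make_record(species="X", rate=1e-5, calibration_time=1000.0),
        )
        out = pool_point_group(ds, {"species": "X"}, "x", mean="geometric")
        assert out[0].rate == pytest.approx(1e-7)
        assert out[0].calibration_time == pytest.approx(100.0)
        assert math.isclose(out[0].genetic_distance, 1e-5)
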