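import numpy as np
import pytest

from corridorprobe import (
    AnalysisConfig,
    HUVolume,
    LandmarkPair,
    OutOfBoundsError,
    PerforationEvent,
    ProbeProfile,
    StationSample,
    WorldPoint,
    assess_accessibility,
    classify_perforation_site,
    find_cortical_runs,
    make_phantom,
    sample_bore_probe,
)
from corridorprobe.corridor_probe import (
    ArcIntervalRegions,
    LabelVolumeRegions,
    UnclassifiableError,
)
from corridorprobe.phantom_gen import PhantomSpec

from ._oracles import voxel_cylinder_verdict
from .conftest import make_empty_volume, noise_free


def profile_from_pattern(pattern, step=1.0):
    """Synthetic profile with a prescribed cortical True/False pattern."""
    stations = [
        StationSample(index=i, arc_mm=i * step, center_hu=0.0, mean_hu=0.0,
                      max_hu=800.0 if c else 0.0, is_cortical=bool(c))
        for i, c in enumerate(pattern)
    ]
    return ProbeProfile(specimen_id="pat", side="left", stations=stations,
                        length_mm=(len(pattern) - 1) * step, config=AnalysisConfig())


class TestSampleBoreProbe:
    def test_constant_zero_volume(self):
        vol = make_empty_volume([60, 40, 40], spacing=2.0)
        lm = LandmarkPair(WorldPoint(0, 0, 0), WorldPoint(30, 0, 0))
        profile = sample_bore_probe(vol, lm)
        assert not profile.is_cortical.any()
        assert profile.max_hu.max() == 0.0
        assert profile.length_mm == pytest.approx(30.0)

    def test_reference_length_corridor(self):
        vol = make_empty_volume([180, 40, 40], spacing=2.0)
        lm = LandmarkPair(WorldPoint(0, 0, 0), WorldPoint(0, 0, 131.7))
        # reorient the volume extent to cover the z corridor
        vol = make_empty_volume([40, 40, 180], spacing=2.0)
        profile = sample_bore_probe(vol, lm)
        assert profile.length_mm == pytest.approx(131.7)
        assert profile.stations[-1].arc_mm == pytest.approx(131.7)

    def test_straight_tube_cortical_only_at_ends(self, straight_tube_spec):
        phantom = make_phantom(straight_tube_spec)
        profile = sample_bore_probe(phantom.volume, phantom.landmarks)
        runs = find_cortical_runs(profile)
        assert len(runs) == 2
        assert runs[0].is_entry and not runs[0].is_exit
        assert runs[1].is_exit and not runs[1].is_entry
        # agreement with the brute-force voxel-in-cylinder oracle
        accessible, _ = voxel_cylinder_verdict(
            phantom.volume, phantom.landmarks, probe_radius_mm=3.75)
        assert accessible

    def test_station_invariants(self, straight_tube_spec):
        phantom = make_phantom(straight_tube_spec)
        profile = sample_bore_probe(phantom.volume, phantom.landmarks)
        for s in profile.stations:
            assert s.center_hu <= s.max_hu + 1e-9
            assert s.mean_hu <= s.max_hu + 1e-9
        assert np.all(np.diff(profile.arc_mm) > 0)

    def test_out_of_bounds_names_station(self):
        vol = make_empty_volume([20, 20, 20], spacing=1.0, origin=[0, -10, -10])
        lm = LandmarkPair(WorldPoint(5, 0, 0), WorldPoint(40, 0, 0),
                          specimen_id="oob", side="right")
        with pytest.raises(OutOfBoundsError, match=r"station \d+.*oob"):
            sample_bore_probe(vol, lm)

    def test_threshold_is_strict(self):
        vol = make_empty_volume([40, 30, 30], spacing=1.0, value=400.0)
        lm = LandmarkPair(WorldPoint(0, 0, 0), WorldPoint(20, 0, 0))
        profile = sample_bore_probe(vol, lm)
        assert not profile.is_cortical.any()  # exactly 400 HU is not cortical


class TestCorticalRuns:
    def test_hand_enumerated_pattern(self):
        runs = find_cortical_runs(profile_from_pattern([1, 1, 0, 0, 1, 0, 1]))
        assert [(r.start, r.end, r.is_entry, r.is_exit) for r in runs] == [
            (0, 1, True, False), (4, 4, False, False), (6, 6, False, True)]

    def test_all_false(self):
        assert find_cortical_runs(profile_from_pattern([0, 0, 0, 0])) == []

    def test_all_true_single_run_both_flags(self):
        runs = find_cortical_runs(profile_from_pattern([1, 1, 1, 1]))
        assert len(runs) == 1
        assert runs[0].is_entry and runs[0].is_exit


class TestAssessAccessibility:
    def test_constant_zero_accessible(self):
        vol = make_empty_volume([60, 40, 40], spacing=2.0)
        lm = LandmarkPair(WorldPoint(0, 0, 0), WorldPoint(30, 0, 0))
        res = assess_accessibility(sample_bore_probe(vol, lm))
        assert res.accessible
        assert res.length_mm == pytest.approx(30.0)
        assert res.events == []

    def test_arc_tube_with_clearance(self):
        # inner radius 6, sagitta 1: min chord clearance 5 >= probe radius
        spec = noise_free(PhantomSpec(chord_length_mm=60, sagitta_mm=1.0,
                                      inner_radius_mm=6.0))
        phantom = make_phantom(spec)
        res = assess_accessibility(sample_bore_probe(phantom.volume, phantom.landmarks))
        assert res.accessible
        assert phantom.ground_truth.accessible_expected

    def test_arc_tube_too_narrow(self):
        # inner radius 5, sagitta 2: clearance 3 < 3.75 -> interior event mid-corridor
        spec = noise_free(PhantomSpec(chord_length_mm=60, sagitta_mm=2.0,
                                      inner_radius_mm=5.0))
        phantom = make_phantom(spec)
        profile = sample_bore_probe(phantom.volume, phantom.landmarks)
        res = assess_accessibility(profile, regions=phantom.regions,
                                   landmarks=phantom.landmarks)
        assert not res.accessible
        assert res.length_mm is None
        assert len(res.events) >= 1
        mid = 0.5 * (res.events[0].arc_start_mm + res.events[0].arc_end_mm)
        assert abs(mid - 30.0) < 15.0
        assert not phantom.ground_truth.accessible_expected

    def test_fully_cortical_not_accessible(self):
        vol = make_empty_volume([40, 30, 30], spacing=1.0, value=900.0)
        lm = LandmarkPair(WorldPoint(0, 0, 0), WorldPoint(20, 0, 0))
        res = assess_accessibility(sample_bore_probe(vol, lm))
        assert not res.accessible

    def test_monotone_in_diameter(self):
        spec = noise_free(PhantomSpec(chord_length_mm=60, sagitta_mm=1.5,
                                      inner_radius_mm=5.5))
        phantom = make_phantom(spec)
        verdicts = []
        for d in (9.5, 8.5, 7.5, 6.5, 5.5, 4.5):
            cfg = AnalysisConfig(probe_diameter_mm=d)
            res = assess_accessibility(sample_bore_probe(phantom.volume,
                                                         phantom.landmarks, cfg))
            verdicts.append(res.accessible)
        # once accessible at some diameter, accessible at every smaller one
        assert verdicts == sorted(verdicts)

    def test_monotone_in_threshold(self):
        spec = noise_free(PhantomSpec(chord_length_mm=60, sagitta_mm=2.0,
                                      inner_radius_mm=5.0))
        phantom = make_phantom(spec)
        verdicts = []
        for thr in (100.0, 400.0, 700.0, 1000.0, 1500.0):
            cfg = AnalysisConfig(cortical_threshold_hu=thr)
            res = assess_accessibility(sample_bore_probe(phantom.volume,
                                                         phantom.landmarks, cfg))
            verdicts.append(res.accessible)
        assert verdicts == sorted(verdicts)  # non-decreasing in threshold

    def test_length_matches_ground_truth_exactly(self):
        spec = noise_free(PhantomSpec(chord_length_mm=57.3, sagitta_mm=0.5,
                                      inner_radius_mm=6.5))
        phantom = make_phantom(spec)
        profile = sample_bore_probe(phantom.volume, phantom.landmarks)
        res = assess_accessibility(profile)
        assert res.accessible
        assert res.length_mm == phantom.ground_truth.length_mm


class TestRegionsAndGroups:
    def test_classify_single_regions(self):
        ev = lambda region: PerforationEvent(1, 2, 1.0, 2.0, region)
        assert classify_perforation_site([ev("ramus")]) == 1
        assert classify_perforation_site([ev("acetabulum"), ev("acetabulum")]) == 2
        assert classify_perforation_site([ev("ramus"), ev("acetabulum")]) == 3

    def test_classify_ignores_other(self):
        ev = lambda region: PerforationEvent(1, 2, 1.0, 2.0, region)
        assert classify_perforation_site([ev("ramus"), ev("other")]) == 1

    def test_classify_errors(self):
        with pytest.raises(ValueError):
            classify_perforation_site([])
        with pytest.raises(UnclassifiableError):
            classify_perforation_site(
                [PerforationEvent(1, 2, 1.0, 2.0, "unassigned")])

    def test_arc_interval_lookup(self):
        regions = ArcIntervalRegions([(0, 30, "ramus"), (30, 45, "acetabulum"),
                                      (45, 60, "other")])
        assert regions.lookup(10.0) == "ramus"
        assert regions.lookup(30.0) == "acetabulum"
        assert regions.lookup(59.0) == "other"
        assert regions.lookup(99.0) == "unassigned"

    def test_arc_interval_yaml_round_trip(self, tmp_path):
        regions = ArcIntervalRegions([(0, 30, "ramus"), (30, 60, "acetabulum")])
        regions.to_yaml(tmp_path / "r.yaml")
        back = ArcIntervalRegions.from_yaml(tmp_path / "r.yaml")
        assert back.intervals == regions.intervals

    def test_label_volume_lookup(self):
        labels = np.zeros((10, 4, 4))
        labels[6:, :, :] = 2
        labels[:6, :, :] = 1
        lv = LabelVolumeRegions(HUVolume(values=labels, affine=np.eye(4)),
                                {1: "ramus", 2: "acetabulum"})
        assert lv.lookup(0.0, point=[2.0, 1.0, 1.0]) == "ramus"
        assert lv.lookup(0.0, point=[8.0, 1.0, 1.0]) == "acetabulum"
        assert lv.lookup(0.0, point=[50.0, 1.0, 1.0]) == "unassigned"

    def test_group_assignment_via_phantom_regions(self):
        spec = noise_free(PhantomSpec(chord_length_mm=60, sagitta_mm=2.0,
                                      inner_radius_mm=5.0))
        phantom = make_phantom(spec)
        profile = sample_bore_probe(phantom.volume, phantom.landmarks)
        res = assess_accessibility(profile, regions=phantom.regions,
                                   landmarks=phantom.landmarks)
        assert res.group == 1  # mid-corridor narrowing perforates the ramus

    def test_acetabular_wall_gives_group_2(self):
        spec = noise_free(PhantomSpec(chord_length_mm=60, sagitta_mm=0.5,
                                      inner_radius_mm=6.5,
                                      acetabular_wall_offset_mm=10.0))
        phantom = make_phantom(spec)
        profile = sample_bore_probe(phantom.volume, phantom.landmarks)
        res = assess_accessibility(profile, regions=phantom.regions,
                                   landmarks=phantom.landmarks)
        assert not res.accessible
        assert res.group == 2


class TestResultInvariants:
    def test_accessible_excludes_events(self):
        with pytest.raises(ValueError):
            from corridorprobe import AccessibilityResult

            AccessibilityResult(accessible=True, length_mm=10.0,
                                events=[PerforationEvent(1, 2, 1.0, 2.0)])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnalysisConfig(probe_diameter_mm=0)
        with pytest.raises(ValueError):
            AnalysisConfig(step_mm=-1)
        with pytest.raises(ValueError):
            AnalysisConfig(cortical_threshold_hu=float("nan"))
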