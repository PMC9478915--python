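"""Distance cube, within-window clustering, and sliding-window assembly."""

import numpy as np
import pytest

import reference
from conftest import make_detection, random_calibration, random_detections
from eodtrack import (
    DistanceConfig,
    ErrorCalibration,
    TrackingConfig,
    build_distance_cube,
    cluster_window,
    track,
)

CFG = TrackingConfig()
FLAT_CAL = ErrorCalibration(np.linspace(0.01, 2.0, 40))


def partition(traces):
    return {frozenset(tr.indices) for tr in traces}


class TestDistanceCube:
    def test_frequency_threshold_excludes_pair(self):
        dets = [make_detection(0, 700.0, [-50, -60, -70]),
                make_detection(1, 703.0, [-50, -60, -70])]
        cube = build_distance_cube(dets, FLAT_CAL, CFG)
        assert list(cube.iter_pairs()) == []

    def test_time_threshold_excludes_pair(self):
        dets = [make_detection(0, 700.0, [-50, -60, -70], step=11.0),
                make_detection(1, 700.1, [-50, -60, -70], step=11.0)]
        cube = build_distance_cube(dets, FLAT_CAL, CFG)
        assert list(cube.iter_pairs()) == []

    def test_forward_pairs_only_and_bounded(self):
        dets = [make_detection(i, 700.0 + 0.1 * i, [-50 - i, -60, -70])
                for i in range(4)]
        cube = build_distance_cube(dets, FLAT_CAL, CFG)
        for a, b, eps in cube.iter_pairs():
            assert dets[b].time > dets[a].time
            assert 0.0 <= eps <= 1.0

    def test_each_detection_owns_one_alpha_row(self, rng):
        dets = random_detections(rng, 12)
        cube = build_distance_cube(dets, FLAT_CAL, CFG)
        assert cube.detection_indices() == list(range(len(dets)))

    def test_entry_set_matches_loop_oracle(self, rng):
        dets = random_detections(rng, 5)
        cal = random_calibration(rng)
        cube = build_distance_cube(dets, cal, CFG)
        got = {(a, b): eps for a, b, eps in cube.iter_pairs()}
        expected = {(i, j): eps for i, j, eps in
                    reference.pair_distances_ref(dets, cal.sorted_differences)}
        assert got.keys() == expected.keys()
        for key in got:
            assert got[key] == pytest.approx(expected[key], rel=1e-9)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError, match="alibration"):
            build_distance_cube([make_detection(0, 700.0, [-50, -60])], None, CFG)


class TestClusterWindow:
    def test_single_detection_is_a_singleton_identity(self):
        dets = [make_detection(0, 700.0, [-50, -60, -70])]
        traces = cluster_window(build_distance_cube(dets, FLAT_CAL, CFG), dets)
        assert partition(traces) == {frozenset({0})}

    def test_two_fish_cluster_by_frequency(self, two_fish_detections):
        dets = two_fish_detections
        traces = cluster_window(build_distance_cube(dets, FLAT_CAL, CFG), dets)
        assert len(traces) == 2
        for tr in traces:
            freqs = [d.eodf for d in tr.detections]
            assert max(freqs) - min(freqs) < 0.5
            assert len(tr.detections) == 6

    def test_identity_has_one_detection_per_time_step(self, rng):
        dets = random_detections(rng, 18)
        traces = cluster_window(build_distance_cube(dets, FLAT_CAL, CFG), dets)
        for tr in traces:
            steps = [d.time_index for d in tr.detections]
            assert len(steps) == len(set(steps))
            assert steps == sorted(steps)

    def test_crossing_resolved_by_spatial_profiles(self):
        # two traces crossing in frequency but anchored to opposite electrodes
        dets = []
        for i in range(7):
            fa = 700.0 + 0.3 * i   # rising fish, strongest on electrode 0
            fb = 701.0             # steady fish, strongest on electrode 3
            dets.append(make_detection(i, fa, [-45, -60, -75, -90]))
            dets.append(make_detection(i, fb, [-90, -75, -60, -45]))
        cal = ErrorCalibration(np.linspace(0.01, 1.5, 60))
        traces = cluster_window(build_distance_cube(dets, cal, CFG), dets)
        assert len(traces) == 2
        for tr in traces:
            best = {int(np.argmax(d.powers)) for d in tr.detections}
            assert len(best) == 1  # never switches electrode side

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_ascending_order_replay_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_detections(rng, int(rng.integers(2, 21)))
        cal = random_calibration(rng)
        traces = cluster_window(build_distance_cube(dets, cal, CFG), dets)
        expected = reference.cluster_replay_ref(
            dets, reference.pair_distances_ref(dets, cal.sorted_differences))
        assert partition(traces) == expected


def synth_detections(freq_traces, n_steps, step=0.3, n_electrodes=6,
                     dropout=None, seed=0):
    """Detection stream from analytic frequency traces + fixed fish positions.

    ``freq_traces``: list of (freq_fn, electrode_gains).  Gaussian jitter on
    powers keeps profiles realistic but distinct.
    """
    rng = np.random.default_rng(seed)
    dets, labels = [], []
    for i in range(n_steps):
        t = i * step
        for fid, (freq_fn, gains) in enumerate(freq_traces):
            if dropout is not None and rng.random() < dropout:
                continue
            powers = np.asarray(gains) + rng.normal(0, 0.5, size=len(gains))
            dets.append(make_detection(i, float(freq_fn(t)), powers, step=step))
            labels.append(fid)
    order = sorted(range(len(dets)), key=lambda i: (dets[i].time, dets[i].eodf))
    return [dets[i] for i in order], [labels[i] for i in order]


def trace_label_accuracy(traces, dets, labels):
    correct = total = 0
    for tr in traces:
        labs = [labels[i] for i in tr.indices]
        majority = max(set(labs), key=labs.count)
        correct += sum(1 for l in labs if l == majority)
        total += len(labs)
    return correct / total


class TestTrack:
    gains_a = [-45, -55, -65, -75, -85, -90]
    gains_b = [-90, -85, -75, -65, -55, -45]
    gains_c = [-70, -50, -80, -70, -50, -80]

    def test_empty_detections_empty_output(self):
        assert track([]) == []

    def test_short_recording_single_window_pass(self):
        dets, labels = synth_detections(
            [(lambda t: 700.0, self.gains_a), (lambda t: 710.0, self.gains_b)],
            n_steps=20)
        traces = track(dets)
        assert len(traces) == 2
        assert trace_label_accuracy(traces, dets, labels) == 1.0

    def test_three_fish_long_recording_fully_recovered(self):
        fns = [(lambda t: 700.0, self.gains_a),
               (lambda t: 707.0, self.gains_b),
               (lambda t: 715.0, self.gains_c)]
        dets, labels = synth_detections(fns, n_steps=400)  # 120 s
        traces = track(dets)
        assert len(traces) == 3
        assert trace_label_accuracy(traces, dets, labels) == 1.0

    def test_dropout_tolerated_via_extended_windows(self):
        fns = [(lambda t: 700.0, self.gains_a),
               (lambda t: 707.0, self.gains_b)]
        dets, labels = synth_detections(fns, n_steps=400, dropout=0.2, seed=5)
        traces = track(dets)
        assert len(traces) == 2
        assert trace_label_accuracy(traces, dets, labels) == 1.0

    def test_partition_property(self, rng):
        fns = [(lambda t: 700.0 + 0.5 * np.sin(t / 7), self.gains_a),
               (lambda t: 702.0, self.gains_b)]
        dets, _ = synth_detections(fns, n_steps=300, dropout=0.1, seed=2)
        traces = track(dets)
        all_indices = sorted(i for tr in traces for i in tr.indices)
        assert all_indices == list(range(len(dets)))
        for tr in traces:
            steps = [d.time_index for d in tr.detections]
            assert len(steps) == len(set(steps))

    def test_threshold_soundness_between_consecutive_detections(self):
        fns = [(lambda t: 700.0, self.gains_a), (lambda t: 701.5, self.gains_b)]
        dets, _ = synth_detections(fns, n_steps=300, dropout=0.15, seed=9)
        cfg = TrackingConfig()
        for tr in track(dets, cfg):
            times = np.array([d.time for d in tr.detections])
            freqs = np.array([d.eodf for d in tr.detections])
            assert np.all(np.diff(times) <= cfg.distance.dt_thresh + 1e-9)
            assert np.all(np.abs(np.diff(freqs)) <= cfg.distance.df_thresh + 1e-9)

    def test_gap_beyond_threshold_splits_identities(self):
        dets_a, _ = synth_detections([(lambda t: 700.0, self.gains_a)], n_steps=40)
        late = [make_detection(200 + i, 700.0, self.gains_a, step=0.3)
                for i in range(40)]  # 60 s - 12 s = 48 s gap
        dets = dets_a + late
        traces = track(dets)
        assert len(traces) == 2

    def test_assembly_prefers_smaller_distance(self):
        # established trace at 700.0; two later traces at 700.1 and 702.2
        dets = []
        for i in range(60):  # 0..17.7 s
            dets.append(make_detection(i, 700.0, self.gains_a, step=0.3))
        for i in range(60, 160):
            dets.append(make_detection(i, 700.1, self.gains_a, step=0.3))
            dets.append(make_detection(i, 702.2, self.gains_a, step=0.3))
        traces = track(dets)
        assert len(traces) == 2
        joined = next(tr for tr in traces if tr.detections[0].eodf == 700.0)
        assert {round(d.eodf, 1) for d in joined.detections} == {700.0, 700.1}

    def test_determinism_identical_runs(self, rng):
        fns = [(lambda t: 700.0 + np.sin(t / 5), self.gains_a),
               (lambda t: 701.0, self.gains_b)]
        dets, _ = synth_detections(fns, n_steps=250, dropout=0.1, seed=3)
        t1 = track(dets)
        t2 = track(dets)
        assert [(tr.identity_id, tr.indices) for tr in t1] == \
               [(tr.identity_id, tr.indices) for tr in t2]

    def test_window_layout_validated(self):
        with pytest.raises(ValueError):
            TrackingConfig(window_shift=15.0, central_length=10.0)
        with pytest.raises(ValueError):
            TrackingConfig(window_length=15.0)
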