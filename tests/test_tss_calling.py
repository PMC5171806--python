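import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cappswitch.genome_io import StartCountTrack
from cappswitch.tss_calling import (attach_subthreshold_rpm, call_tss,
                                    cluster_read_starts,
                                    merge_tss_across_conditions, normalize_rpm)
from conftest import oracle_cluster, random_track


class TestNormalizeRpm:
    @pytest.mark.parametrize("count,lib,expected", [
        (10, 1_000_000, 10.0),
        (7, 700_000, 10.0),
    ])
    def test_definition(self, track_factory, count, lib, expected):
        track = normalize_rpm(track_factory({("+", 5): count}, library_size=lib))
        assert track.counts[("+", 5)] == pytest.approx(expected)

    def test_total_rpm_equals_counted_fraction_of_a_million(self, track_factory, rng):
        counts = {("+", int(p)): int(c)
                  for p, c in zip(rng.integers(1, 1000, 50),
                                  rng.integers(1, 30, 50))}
        raw = track_factory(counts, library_size=200_000)
        norm = normalize_rpm(raw)
        assert sum(norm.counts.values()) == pytest.approx(
            1e6 * raw.total() / raw.library_size)

    def test_zero_library_rejected(self, track_factory):
        with pytest.raises(ValueError):
            normalize_rpm(track_factory({("+", 1): 1}, library_size=0))


class TestClusterReadStarts:
    def test_worked_example(self, track_factory):
        track = track_factory({("+", 100): 5, ("+", 101): 9, ("+", 103): 3,
                               ("+", 110): 2})
        clusters = cluster_read_starts(track, window=5)
        assert [(c.peak_position, c.cluster_count, c.member_positions)
                for c in clusters] == [(101, 17, [100, 101, 103]), (110, 2, [110])]

    def test_single_position_identity(self, track_factory):
        (c,) = cluster_read_starts(track_factory({("+", 42): 8}))
        assert (c.peak_position, c.cluster_count, c.peak_count) == (42, 8, 8)

    @pytest.mark.parametrize("strand,expected_peak", [("+", 100), ("-", 101)])
    def test_tie_breaks_five_prime_most(self, track_factory, strand, expected_peak):
        track = track_factory({(strand, 100): 5, (strand, 101): 5})
        (c,) = cluster_read_starts(track)
        assert c.peak_position == expected_peak and c.cluster_count == 10

    def test_empty_track_empty_list(self, track_factory):
        assert cluster_read_starts(track_factory({})) == []

    def test_even_window_rejected(self, track_factory):
        with pytest.raises(ValueError):
            cluster_read_starts(track_factory({("+", 1): 1}), window=4)

    def test_count_conservation_per_strand(self, rng):
        track = random_track(rng, n_positions=500)
        clusters = cluster_read_starts(track)
        for strand in "+-":
            total = sum(c for (s, _), c in track.counts.items() if s == strand)
            assert sum(c.cluster_count for c in clusters
                       if c.strand == strand) == total

    def test_matches_bruteforce_oracle_on_random_tracks(self, rng):
        for _ in range(25):
            track = random_track(rng, n_positions=int(rng.integers(5, 300)))
            got = sorted((c.strand, c.peak_position, tuple(c.member_positions),
                          c.cluster_count)
                         for c in cluster_read_starts(track))
            assert got == oracle_cluster(track.counts, 5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(window=st.sampled_from([1, 3, 5, 7]),
           entries=st.lists(
               st.tuples(st.sampled_from("+-"), st.integers(1, 120),
                         st.integers(1, 40)),
               min_size=1, max_size=60))
    def test_oracle_equivalence_property(self, window, entries):
        counts = {}
        for s, p, c in entries:
            counts[(s, p)] = counts.get((s, p), 0) + c
        track = StartCountTrack(counts=counts, library_size=10_000)
        got = sorted((c.strand, c.peak_position, tuple(c.member_positions),
                      c.cluster_count)
                     for c in cluster_read_starts(track, window=window))
        assert got == oracle_cluster(counts, window)

    def test_members_within_window_and_peak_maximal(self, rng):
        track = random_track(rng, n_positions=300)
        for c in cluster_read_starts(track, window=5):
            assert all(abs(m - c.peak_position) <= 2 for m in c.member_positions)
            assert all(track.counts[(c.strand, m)] <= c.peak_count
                       for m in c.member_positions)


class TestCallTss:
    def _tracks(self, rpm1, rpm2, pos1=500, pos2=500, lib=1_000_000):
        t1 = StartCountTrack({("+", pos1): rpm1 * lib / 1e6}, lib, "c/r1")
        t2 = StartCountTrack({("+", pos2): rpm2 * lib / 1e6}, lib, "c/r2")
        return [t1, t2]

    def test_called_when_both_replicates_above_threshold(self):
        tss = call_tss(self._tracks(11, 12, pos2=501), "glucose")
        assert len(tss) == 1
        assert tss[0].detected_conditions == {"glucose"}
        assert tss[0].rpm_by_condition_replicate == {
            ("glucose", "rep1"): pytest.approx(11.0),
            ("glucose", "rep2"): pytest.approx(12.0)}

    def test_threshold_is_strict_in_both_replicates(self):
        assert call_tss(self._tracks(11, 9), "glucose") == []
        # exactly 10 in one replicate fails the strict rule
        assert call_tss(self._tracks(11, 10), "glucose") == []

    def test_replicate_peaks_outside_match_window_not_called(self):
        assert call_tss(self._tracks(11, 12, pos1=500, pos2=504), "glucose") == []
        assert len(call_tss(self._tracks(11, 12, pos1=500, pos2=502),
                            "glucose")) == 1

    def test_position_is_pooled_profile_peak(self):
        lib = 1_000_000
        t1 = StartCountTrack({("+", 500): 20, ("+", 501): 5}, lib, "c/r1")
        t2 = StartCountTrack({("+", 501): 30}, lib, "c/r2")
        (tss,) = call_tss([t1, t2], "glucose")
        assert tss.position == 501  # pooled 35 at 501 vs 20 at 500
        assert tss.pooled_count == 55

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            call_tss([StartCountTrack({("+", 1): 20}, 1_000_000)], "c")

    def test_mismatched_genome_lengths_rejected(self):
        t1 = StartCountTrack({("+", 1): 20}, 1_000_000, genome_length=100)
        t2 = StartCountTrack({("+", 1): 20}, 1_000_000, genome_length=200)
        with pytest.raises(ValueError, match="genome length"):
            call_tss([t1, t2], "c")

    def test_peak_only_mode_thresholds_peak_count(self):
        lib = 1_000_000
        # cluster sum 12 RPM but peak itself only 7 RPM
        t = {("+", 500): 7, ("+", 501): 5}
        tracks = [StartCountTrack(dict(t), lib, "c/r1"),
                  StartCountTrack(dict(t), lib, "c/r2")]
        assert len(call_tss(tracks, "c", count_mode="cluster_sum")) == 1
        assert call_tss(tracks, "c", count_mode="peak_only") == []

    def test_raising_threshold_never_adds_tss(self, rng):
        tracks = [random_track(rng, 200, span=2000, library_size=50_000)
                  for _ in range(2)]
        sizes = [len(call_tss(tracks, "c", threshold_rpm=thr))
                 for thr in (5, 10, 20, 50, 100)]
        assert sizes == sorted(sizes, reverse=True)

    def test_determinism(self, rng):
        tracks = [random_track(rng, 300, span=3000, library_size=50_000)
                  for _ in range(2)]
        a = call_tss(tracks, "c")
        b = call_tss(tracks, "c")
        assert [(t.strand, t.position, t.mean_rpm_by_condition) for t in a] == \
               [(t.strand, t.position, t.mean_rpm_by_condition) for t in b]


class TestMergeAcrossConditions:
    def test_nearby_positions_merge_with_union_of_conditions(self, tss_factory):
        glu = tss_factory("+", 500, {"glucose": 20.0})
        glu.pooled_count = 40
        xyl = tss_factory("+", 501, {"xylan": 15.0})
        xyl.pooled_count = 30
        (m,) = merge_tss_across_conditions({"glucose": [glu], "xylan": [xyl]})
        assert m.position == 500  # stronger member's position wins
        assert m.detected_conditions == {"glucose", "xylan"}
        assert m.mean_rpm_by_condition == {"glucose": 20.0, "xylan": 15.0}

    def test_single_condition_passthrough_with_zero_fill(self, tss_factory):
        t = tss_factory("+", 500, {"glucose": 20.0})
        (m,) = merge_tss_across_conditions({"glucose": [t], "xylan": []})
        assert m.detected_conditions == {"glucose"}
        assert m.mean_rpm_by_condition == {"glucose": 20.0, "xylan": 0.0}

    def test_opposite_strands_never_merge(self, tss_factory):
        a = tss_factory("+", 500, {"glucose": 20.0})
        b = tss_factory("-", 500, {"xylan": 20.0})
        merged = merge_tss_across_conditions({"glucose": [a], "xylan": [b]})
        assert len(merged) == 2

    def test_distant_positions_stay_separate(self, tss_factory):
        a = tss_factory("+", 500, {"glucose": 20.0})
        b = tss_factory("+", 506, {"xylan": 20.0})
        assert len(merge_tss_across_conditions(
            {"glucose": [a], "xylan": [b]})) == 2

    def test_subthreshold_signal_recorded_for_undetected_conditions(
            self, tss_factory, track_factory):
        t = tss_factory("+", 500, {"glucose": 20.0})
        (m,) = merge_tss_across_conditions({"glucose": [t], "xylan": []})
        assert m.mean_rpm_by_condition["xylan"] == 0.0
        # xylan replicates carry 3 and 5 sub-threshold reads near the site
        xyl1 = track_factory({("+", 499): 2, ("+", 501): 1}, 1_000_000)
        xyl2 = track_factory({("+", 500): 5}, 1_000_000)
        attach_subthreshold_rpm([m], {"xylan": [xyl1, xyl2]})
        assert m.mean_rpm_by_condition["xylan"] == pytest.approx(4.0)
        # detected condition keeps its called value
        assert m.mean_rpm_by_condition["glucose"] == 20.0
        assert m.detected_conditions == {"glucose"}
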