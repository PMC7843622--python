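import itertools

import numpy as np
import pandas as pd
import pytest

from betaplus import (
    DamageSummary,
    ScoringRules,
    StrandBreak,
    backbone_point,
    relative_difference,
    score_dsbs,
    score_event_arrays,
    score_ssbs,
    summarize_campaign,
)
from betaplus.track import KIND_IONIZATION, TrackResult


def track_from(points, energies, pid=0):
    n = len(energies)
    return TrackResult(
        species="electron",
        initial_energy_ev=float(np.sum(energies)),
        primary_id=pid,
        positions=np.asarray(points, dtype=float).reshape(-1, 3),
        energies=np.asarray(energies, dtype=float),
        kinds=np.full(n, KIND_IONIZATION, dtype=np.int8),
        path_length_nm=1.0,
    )


def exhaustive_max_pairing(breaks, rules):
    """Maximum-cardinality DSB pairing by brute-force search."""
    def compatible(a, b):
        if rules.dsb_requires_opposite_strands and a.strand == b.strand:
            return False
        return abs(a.base_index - b.base_index) <= rules.dsb_max_base_separation

    best = 0
    n = len(breaks)

    def rec(avail, count):
        nonlocal best
        best = max(best, count)
        if not avail:
            return
        first, rest = avail[0], avail[1:]
        # skip first
        rec(rest, count)
        for j, other in enumerate(rest):
            if compatible(first, other):
                rec(rest[:j] + rest[j + 1 :], count + 1)

    rec(list(breaks), 0)
    return best


class TestScoreSSBs:
    def test_threshold_inclusive_at_17p5(self, geom):
        p = backbone_point(geom, 0, 5)
        assert len(score_ssbs(track_from([p], [17.5]), geom)) == 1
        assert len(score_ssbs(track_from([p], [17.4]), geom)) == 0

    def test_per_volume_accumulation(self, geom):
        p = backbone_point(geom, 0, 5)
        q = backbone_point(geom, 0, 6)
        # two sub-threshold hits in the same volume accumulate to an SSB
        assert len(score_ssbs(track_from([p, p], [10.0, 10.0]), geom)) == 1
        # in different volumes they do not
        assert len(score_ssbs(track_from([p, q], [10.0, 10.0]), geom)) == 0

    def test_per_event_mode(self, geom):
        p = backbone_point(geom, 0, 5)
        rules = ScoringRules(accumulation="per_event")
        assert len(score_ssbs(track_from([p, p], [10.0, 10.0]), geom, rules)) == 0
        assert len(score_ssbs(track_from([p], [20.0]), geom, rules)) == 1

    def test_base_hits_never_break(self, geom):
        axis_point = np.array([0.0, 0.0, 5.1])
        assert score_ssbs(track_from([axis_point], [500.0]), geom) == []

    def test_raising_threshold_cannot_increase_breaks(self, geom, rng):
        pts = rng.uniform([-1.2, -1.2, 0], [1.2, 1.2, 34], size=(300, 3))
        es = rng.uniform(5, 40, size=300)
        tr = track_from(pts, es)
        counts = [
            len(score_ssbs(tr, geom, ScoringRules(ssb_threshold_ev=t)))
            for t in (10.0, 17.5, 25.0, 40.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestScoreDSBs:
    def test_separation_boundary(self):
        rules = ScoringRules()
        assert score_dsbs([StrandBreak(0, 10, 20.0), StrandBreak(1, 20, 20.0)], rules) == 1
        assert score_dsbs([StrandBreak(0, 10, 20.0), StrandBreak(1, 21, 20.0)], rules) == 0

    def test_same_strand_excluded_by_default(self):
        breaks = [StrandBreak(0, 10, 20.0), StrandBreak(0, 12, 20.0)]
        assert score_dsbs(breaks) == 0
        relaxed = ScoringRules(dsb_requires_opposite_strands=False)
        assert score_dsbs(breaks, relaxed) == 1

    def test_zero_separation_requires_equal_base(self):
        rules = ScoringRules(dsb_max_base_separation=0)
        assert score_dsbs([StrandBreak(0, 7, 20.0), StrandBreak(1, 7, 20.0)], rules) == 1
        assert score_dsbs([StrandBreak(0, 7, 20.0), StrandBreak(1, 8, 20.0)], rules) == 0

    def test_each_break_used_once(self):
        breaks = [
            StrandBreak(0, 0, 20.0),
            StrandBreak(1, 5, 20.0),
            StrandBreak(0, 9, 20.0),
        ]
        assert score_dsbs(breaks) == 1

    def test_greedy_equals_exhaustive_matching(self, rng):
        # random break sets: greedy sweep must attain the maximum
        # cardinality pairing found by brute force
        rules = ScoringRules()
        for _ in range(2000):
            n = int(rng.integers(0, 11))
            breaks = [
                StrandBreak(int(rng.integers(0, 2)), int(rng.integers(0, 40)), 20.0)
                for _ in range(n)
            ]
            # unique volumes only (one SSB per volume)
            seen = set()
            uniq = []
            for b in breaks:
                if (b.strand, b.base_index) not in seen:
                    seen.add((b.strand, b.base_index))
                    uniq.append(b)
            assert score_dsbs(uniq, rules) == exhaustive_max_pairing(uniq, rules)

    def test_dsb_bounded_by_half_ssb(self, rng):
        for _ in range(300):
            n = int(rng.integers(0, 12))
            seen = set()
            breaks = []
            for _ in range(n):
                key = (int(rng.integers(0, 2)), int(rng.integers(0, 30)))
                if key not in seen:
                    seen.add(key)
                    breaks.append(StrandBreak(key[0], key[1], 20.0))
            assert score_dsbs(breaks) <= len(breaks) // 2


class TestVectorizedScoring:
    def test_matches_naive_on_random_batches(self, geom, rng):
        from betaplus.synthetic import EventSimSpec, make_event_stream

        for seed in range(50):
            spec = EventSimSpec(n_primaries=40, seed=seed)
            pos, es, pid, truth = make_event_stream(spec, geom)
            ssb, dsb = score_event_arrays(pos, es, pid, geom)
            assert (ssb, dsb) == (truth["ssb_count"], truth["dsb_count"])

    def test_empty_batch(self, geom):
        ssb, dsb = score_event_arrays(
            np.zeros((0, 3)), np.zeros(0), np.zeros(0, dtype=int), geom
        )
        assert (ssb, dsb) == (0, 0)


class TestSummaries:
    def test_frequency_scaling(self):
        s = DamageSummary("electron", 400.0, 1, 10_000, ssb_count=7, dsb_count=1)
        assert s.ssb_per_1e6 == pytest.approx(700.0)
        assert s.dsb_per_1e6 == pytest.approx(100.0)

    def test_zero_events_all_zero(self):
        s = DamageSummary("electron", 400.0, 1, 1000, 0, 0)
        assert s.ssb_per_1e6 == 0.0 and s.dsb_per_1e6 == 0.0

    def test_aggregate_mean_and_spread(self):
        seeds = [
            DamageSummary("electron", 400.0, s, 1000, ssb, 0)
            for s, ssb in [(1, 10), (2, 14), (3, 12)]
        ]
        agg = summarize_campaign(seeds)
        row = agg.iloc[0]
        assert row["ssb_per_1e6_mean"] == pytest.approx(12_000.0)
        assert row["ssb_per_1e6_spread"] == pytest.approx(4000.0)
        assert row["n_seeds"] == 3

    def test_pooled_two_equal_seeds_is_mean(self):
        seeds = [
            DamageSummary("e", 1.0, 1, 1000, 10, 2),
            DamageSummary("e", 1.0, 2, 1000, 20, 4),
        ]
        pooled_freq = (10 + 20) * 1e6 / 2000
        agg = summarize_campaign(seeds)
        assert agg.iloc[0]["ssb_per_1e6_mean"] == pytest.approx(pooled_freq)


class TestRelativeDifference:
    def frame(self, energies, freqs):
        return pd.DataFrame({"energy_ev": energies, "ssb_per_1e6_mean": freqs})

    def test_identical_is_zero(self):
        a = self.frame([250, 500, 750], [10.0, 8.0, 6.0])
        table, integral = relative_difference(a, a)
        assert np.allclose(table["pct_difference"], 0.0)
        assert integral == 0.0

    def test_double_is_hundred_percent(self):
        b = self.frame([250, 500], [10.0, 6.0])
        a = self.frame([250, 500], [20.0, 12.0])
        table, integral = relative_difference(a, b)
        assert np.allclose(table["pct_difference"], 100.0)
        assert integral == pytest.approx(100.0)

    def test_hand_computed_trapezoid(self):
        a = self.frame([0.0, 1.0, 2.0], [2.0, 4.0, 2.0])
        b = self.frame([0.0, 1.0, 2.0], [2.0, 2.0, 2.0])
        # int a = 6, int b = 4 -> 50%
        _, integral = relative_difference(a, b)
        assert integral == pytest.approx(50.0)

    def test_zero_denominator_flagged(self):
        a = self.frame([0.0, 1.0], [1.0, 1.0])
        b = self.frame([0.0, 1.0], [0.0, 2.0])
        table, _ = relative_difference(a, b)
        assert np.isnan(table["pct_difference"].iloc[0])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(self.frame([1.0], [1.0]), self.frame([2.0], [1.0]))


class TestRules:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScoringRules(ssb_threshold_ev=0.0)
        with pytest.raises(ValueError):
            ScoringRules(dsb_max_base_separation=-1)
        with pytest.raises(ValueError):
            ScoringRules(accumulation="weird")

    def test_round_trip(self):
        r = ScoringRules(ssb_threshold_ev=20.0)
        assert ScoringRules.from_dict(r.to_dict()) == r
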