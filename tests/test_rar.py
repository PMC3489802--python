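"""Cohort-level recurrent-region delineation, event timing, high-level regions."""

import numpy as np
import pandas as pd
import pytest

from rarseek.call import CallSet, call_cohort, call_segment
from rarseek.core import ProbeMap, Segment
from rarseek.rar import (EventRule, carrier_percent, classify_event,
                         detect_high_level, detect_rars, marker_matrix,
                         probe_frequency)
from rarseek.segment import SegmentationParams, segment_matrix
from rarseek.simulate import default_config, simulate_cohort


def _probe_map(n=200, chrom="1", step=200_000):
    return ProbeMap(
        probe_id=np.array([f"{chrom}_{i}" for i in range(n)], dtype=object),
        chromosome=np.array([chrom] * n, dtype=object),
        position=np.array([(i + 1) * step for i in range(n)]),
    )


def _flat_callset(sample, probes, regions):
    """CallSet tiling the map: `regions` is a list of (first, last, mean)."""
    calls = []
    cursor = 0
    bounds = sorted(regions)
    segs = []
    for first, last, mean in bounds:
        if first > cursor:
            segs.append((cursor, first - 1, 0.0))
        segs.append((first, last, mean))
        cursor = last + 1
    if cursor < len(probes):
        segs.append((cursor, len(probes) - 1, 0.0))
    for first, last, mean in segs:
        seg = Segment(sample, str(probes.chromosome[first]),
                      int(probes.position[first]), int(probes.position[last]),
                      first, last, last - first + 1, mean)
        calls.append(call_segment(seg))
    return CallSet(sample, calls)


class TestClassifyEvent:
    @pytest.mark.parametrize("fI,fII,expected", [
        (0.36, 0.54, "earlier"),
        (0.09, 0.46, "later"),
        (0.27, 0.41, "unclassified"),
        (0.30, 0.30, "earlier"),         # boundary: >= 30% both stages
        (0.10, 0.46, "unclassified"),    # boundary: later needs stage I < 10%
        (0.09, 0.40, "unclassified"),    # boundary: later needs stage II > 40%
    ])
    def test_rule_boundaries(self, fI, fII, expected):
        assert classify_event(fI, fII) == expected

    def test_rejects_non_proportions(self):
        with pytest.raises(ValueError):
            classify_event(1.2, 0.5)

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            EventRule(earlier_min_freq=0.05)


class TestProbeFrequency:
    def test_single_carrier_frequency(self):
        pm = _probe_map(50)
        carrier = _flat_callset("S1", pm, [(10, 19, 0.6)])
        others = [_flat_callset(f"N{i}", pm, []) for i in range(9)]
        freq = probe_frequency([carrier] + others, "gain", pm)
        assert freq[15] == pytest.approx(0.1)
        assert freq[5] == 0.0

    def test_gain_and_loss_frequencies_disjoint(self):
        pm = _probe_map(50)
        rng = np.random.default_rng(0)
        cohort = []
        for i in range(12):
            first = int(rng.integers(0, 30))
            mean = float(rng.choice([-0.8, 0.6]))
            cohort.append(_flat_callset(f"S{i}", pm, [(first, first + 9, mean)]))
        g = probe_frequency(cohort, "gain", pm)
        l = probe_frequency(cohort, "loss", pm)
        assert np.all(g >= 0) and np.all(l >= 0)
        assert np.all(g + l <= 1 + 1e-12)


class TestDetectRars:
    def _cohort(self, pm, n=20, carriers=10, first=40, last=79, mean=0.6):
        cohort = [_flat_callset(f"C{i}", pm, [(first, last, mean)])
                  for i in range(carriers)]
        cohort += [_flat_callset(f"N{i}", pm, []) for i in range(n - carriers)]
        return cohort

    def test_frequency_just_below_threshold_not_reported(self):
        pm = _probe_map(200)
        cohort = self._cohort(pm, n=100, carriers=29)  # 29% < 30%
        rars, _ = detect_rars(cohort, pm, n_perm=200, seed=0)
        assert rars == []

    def test_planted_region_recovered_with_significance(self):
        pm = _probe_map(200)
        cohort = self._cohort(pm, n=20, carriers=10)
        rars, markers = detect_rars(cohort, pm, n_perm=500, seed=0)
        assert len(rars) == 1
        r = rars[0]
        assert (r.first_probe, r.last_probe) == (40, 79)
        assert r.p_value < 0.05
        assert r.freq_total == pytest.approx(0.5)
        assert markers[r.name].sum() == 10

    def test_min_freq_monotonicity(self):
        pm = _probe_map(200)
        cohort = self._cohort(pm, n=20, carriers=10)
        low, _ = detect_rars(cohort, pm, min_freq=0.3, n_perm=200, seed=0)
        high, _ = detect_rars(cohort, pm, min_freq=0.6, n_perm=200, seed=0)
        assert len(high) <= len(low)

    def test_reported_frequencies_equal_marker_recounts(self, small_cohort):
        cfg, probes, matrix, clinical, truth = small_cohort
        segsets = segment_matrix(matrix, SegmentationParams(seed=42))
        callsets = call_cohort(segsets)
        rars, markers = detect_rars(callsets, probes, clinical=clinical,
                                    n_perm=200, seed=42)
        assert rars, "expected planted regions to be recovered"
        for r in rars:
            assert r.freq_total == pytest.approx(markers[r.name].mean())

    def test_null_cohort_rarely_reports_regions(self):
        hits = 0
        for seed in range(10):
            cfg = default_config(seed=seed, chromosomes=("16",), implants=(),
                                 interactions=())
            probes, matrix, _cl, _tr = simulate_cohort(cfg)
            segsets = segment_matrix(matrix, SegmentationParams(seed=seed))
            callsets = call_cohort(segsets)
            rars, _ = detect_rars(callsets, probes, n_perm=200, seed=seed)
            hits += bool(rars)
        assert hits == 0


class TestMarkerMatrix:
    def test_overlap_rule(self):
        pm = _probe_map(100)
        # RAR spans probes 20..59 (positions 4.2M..12.0M)
        full = _flat_callset("full", pm, [(20, 59, 0.6)])
        partial = _flat_callset("part", pm, [(20, 31, 0.6)])   # 30% of span
        none = _flat_callset("none", pm, [])
        rars, _ = detect_rars([full] * 10 + [none] * 10, pm, n_perm=200, seed=0)
        m = marker_matrix(rars, [full, partial, none])
        col = m[rars[0].name]
        assert col["full"] == 1
        assert col["part"] == 0
        assert col["none"] == 0


class TestHighLevel:
    @pytest.mark.parametrize("carriers,n,expected_pct", [(14, 48, 29), (6, 48, 13)])
    def test_carrier_percent_rounding(self, carriers, n, expected_pct):
        assert carrier_percent(carriers, n) == expected_pct

    def test_detection_above_and_below_cutoff(self):
        pm = _probe_map(100)
        def cohort(k):
            amp = [_flat_callset(f"A{i}", pm, [(10, 29, 1.8)]) for i in range(k)]
            rest = [_flat_callset(f"N{i}", pm, []) for i in range(48 - k)]
            return amp + rest
        found = detect_high_level(cohort(6), pm)
        assert len(found) == 1
        assert found[0].carrier_count == 6
        assert found[0].carrier_percent == 13
        assert detect_high_level(cohort(4), pm) == []  # 8.3% below the 10% cutoff
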