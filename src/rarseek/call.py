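"""Categorical copy-number calls from segment means.

A segment is a gain when its mean log2 ratio exceeds +0.2 (exclusive), a
loss below -0.3 (exclusive), neutral otherwise. High-level events sit on
top of the state: amplification at mean >= +1.5 (inclusive), homozygous
deletion at mean <= -1.5 (inclusive). The asymmetric strictness tracks the
thresholds' published phrasing exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ProbeMap, Segment, SegmentSet

GAIN, NEUTRAL, LOSS = "gain", "neutral", "loss"
AMP, HD, NONE = "amplification", "homozygous_deletion", "none"


@dataclass(frozen=True)
class CallThresholds:
    gain_min: float = 0.2       # exclusive
    loss_max: float = -0.3      # exclusive
    amp_min: float = 1.5        # inclusive
    hd_max: float = -1.5        # inclusive

    def __post_init__(self):
        if not (self.hd_max < self.loss_max < 0 < self.gain_min < self.amp_min):
            raise ValueError("thresholds must satisfy hd_max < loss_max < 0 < gain_min < amp_min")


@dataclass(frozen=True)
class CNACall:
    segment: Segment
    state: str        # gain | loss | neutral
    high_level: str   # none | amplification | homozygous_deletion

    def __post_init__(self):
        if self.high_level == AMP and self.state != GAIN:
            raise ValueError("amplification implies gain")
        if self.high_level == HD and self.state != LOSS:
            raise ValueError("homozygous deletion implies loss")


@dataclass
class CallSet:
    """All calls of one sample, tiling its probe runs."""

    sample_id: str
    calls: list[CNACall]

    def __iter__(self):
        return iter(self.calls)

    def __len__(self):
        return len(self.calls)


def call_segment(seg: Segment, th: CallThresholds = CallThresholds()) -> CNACall:
    m = seg.mean_log2
    if not math.isfinite(m):
        raise ValueError(f"non-finite segment mean for sample {seg.sample_id!r}")
    if m > th.gain_min:
        state = GAIN
        high = AMP if m >= th.amp_min else NONE
    elif m < th.loss_max:
        state = LOSS
        high = HD if m <= th.hd_max else NONE
    else:
        state, high = NEUTRAL, NONE
    return CNACall(segment=seg, state=state, high_level=high)


def call_sample(segset: SegmentSet, th: CallThresholds = CallThresholds()) -> CallSet:
    calls = []
    for seg in segset:
        if seg.flag == "missing":  # no informative probes: force neutral
            calls.append(CNACall(segment=seg, state=NEUTRAL, high_level=NONE))
        else:
            calls.append(call_segment(seg, th))
    return CallSet(sample_id=segset.sample_id, calls=calls)


def call_cohort(segsets: list[SegmentSet], th: CallThresholds = CallThresholds()) -> list[CallSet]:
    return [call_sample(ss, th) for ss in segsets]


def sample_summary(callset: CallSet, probes: ProbeMap) -> tuple[int, float, float]:
    """(n_cna, altered_mb, altered_fraction) for one sample.

    altered_fraction uses the probe-covered genome span as denominator; the
    published 13%-of-genome figure leaves its denominator unstated, so the
    mapped length is the only self-consistent choice.
    """
    altered_bp = 0
    n_cna = 0
    for c in callset:
        if c.state != NEUTRAL:
            n_cna += 1
            altered_bp += c.segment.length_bp
    total = probes.mapped_length()
    return n_cna, altered_bp / 1e6, altered_bp / total


def cohort_cna_stats(callsets: list[CallSet], probes: ProbeMap) -> dict:
    """Cohort-level CNA burden: median/range of per-sample CNA counts, mean altered Mb."""
    if not callsets:
        raise ValueError("empty cohort")
    summaries = [sample_summary(cs, probes) for cs in callsets]
    counts = np.array([s[0] for s in summaries])
    mbs = np.array([s[1] for s in summaries])
    fracs = np.array([s[2] for s in summaries])
    return {
        "median_n_cna": float(np.median(counts)),
        "min_n_cna": int(counts.min()),
        "max_n_cna": int(counts.max()),
        "mean_altered_mb": float(mbs.mean()),
        "mean_altered_fraction": float(fracs.mean()),
    }


_STATE_CODE = {GAIN: 1, NEUTRAL: 0, LOSS: -1}
_HIGH_CODE = {AMP: 1, NONE: 0, HD: -1}


def state_matrix(callsets: list[CallSet], probes: ProbeMap) -> np.ndarray:
    """samples x probes int8 matrix: +1 gain, -1 loss, 0 neutral."""
    out = np.zeros((len(callsets), len(probes)), dtype=np.int8)
    for i, cs in enumerate(callsets):
        for c in cs:
            if c.segment.first_probe < 0:
                raise ValueError("state_matrix needs probe-indexed segments")
            out[i, c.segment.first_probe : c.segment.last_probe + 1] = _STATE_CODE[c.state]
    return out


def highlevel_matrix(callsets: list[CallSet], probes: ProbeMap) -> np.ndarray:
    """samples x probes int8 matrix: +1 amplification, -1 homozygous deletion."""
    out = np.zeros((len(callsets), len(probes)), dtype=np.int8)
    for i, cs in enumerate(callsets):
        for c in cs:
            if c.high_level != NONE:
                out[i, c.segment.first_probe : c.segment.last_probe + 1] = _HIGH_CODE[c.high_level]
    return out
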