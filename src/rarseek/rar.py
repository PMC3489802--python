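"""Recurrently altered regions (RARs) across a cohort.

A RAR is a maximal probe run where the cohort frequency of same-direction
CNA calls is at least ``min_freq`` (default 30%), kept when a positional
permutation null assigns it p < alpha (default 0.05). The null circularly
shifts each sample's per-probe call states within each chromosome,
preserving that sample's segment-length spectrum and alteration burden —
the key confounder — and asks how often the shifted cohort reaches the
observed peak frequency over the region's span. Gains and losses are
detected in fully independent passes and named RAR-G1.. / RAR-L1.. in
genomic order.

Stage-stratified frequencies classify each RAR as an earlier event
(frequent in both stage I and II), a later event (rare in stage I, frequent
in stage II) or unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .call import GAIN, LOSS, NEUTRAL, CallSet, highlevel_matrix, state_matrix
from .core import ClinicalTable, ProbeMap

EARLIER, LATER, UNCLASSIFIED = "earlier", "later", "unclassified"


@dataclass(frozen=True)
class EventRule:
    """Stage-stratified event-timing rule.

    later: stage-I frequency < later_max_stageI AND stage-II > later_min_stageII;
    earlier: both stage frequencies >= earlier_min_freq; otherwise unclassified.
    """

    earlier_min_freq: float = 0.30
    later_max_stageI: float = 0.10   # exclusive
    later_min_stageII: float = 0.40  # exclusive

    def __post_init__(self):
        if not self.later_max_stageI < self.earlier_min_freq:
            raise ValueError("later_max_stageI must be below earlier_min_freq")


def classify_event(freq_stageI: float, freq_stageII: float,
                   rule: EventRule = EventRule()) -> str:
    """Classify a RAR as an earlier/later event from stage-stratified frequencies."""
    for f in (freq_stageI, freq_stageII):
        if not (0.0 <= f <= 1.0):
            raise ValueError("frequencies must be proportions in [0, 1]")
    if freq_stageI < rule.later_max_stageI and freq_stageII > rule.later_min_stageII:
        return LATER
    if freq_stageI >= rule.earlier_min_freq and freq_stageII >= rule.earlier_min_freq:
        return EARLIER
    return UNCLASSIFIED


@dataclass
class RAR:
    name: str
    chromosome: str
    start_bp: int
    end_bp: int
    type: str  # gain | loss
    freq_total: float
    freq_stageI: float  # NaN when no stage information
    freq_stageII: float
    p_value: float
    event_class: str
    first_probe: int
    last_probe: int

    @property
    def size_mb(self) -> float:
        return round((self.end_bp - self.start_bp + 1) / 1e6, 2)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class HighLevelRegion:
    name: str
    chromosome: str
    start_bp: int
    end_bp: int
    type: str  # amplification | homozygous_deletion
    carrier_count: int
    carrier_percent: int
    first_probe: int
    last_probe: int


def probe_frequency(callsets: list[CallSet], state: str, probes: ProbeMap) -> np.ndarray:
    """Per-probe cohort frequency of the given call state (gain or loss)."""
    if state not in (GAIN, LOSS):
        raise ValueError("state must be 'gain' or 'loss'")
    sm = state_matrix(callsets, probes)
    code = 1 if state == GAIN else -1
    return (sm == code).mean(axis=0)


def _candidate_runs(freq: np.ndarray, min_freq: float, probes: ProbeMap) -> list[tuple[int, int]]:
    """Maximal runs of probes with freq >= min_freq, within chromosomes (half-open)."""
    runs = []
    for sl in probes.chrom_slices().values():
        above = freq[sl] >= min_freq
        start = None
        for i, a in enumerate(above):
            if a and start is None:
                start = i
            elif not a and start is not None:
                runs.append((sl.start + start, sl.start + i))
                start = None
        if start is not None:
            runs.append((sl.start + start, sl.stop))
    return runs


def _region_null_pvalues(
    indicator: np.ndarray,
    regions: list[tuple[int, int]],
    probes: ProbeMap,
    n_perm: int,
    rng: np.random.Generator,
) -> list[float]:
    """Permutation p per region under per-sample within-chromosome circular shifts.

    indicator: samples x probes boolean (sample has the state at that probe).
    p = (b+1)/(n_perm+1) where b counts permutations whose maximum frequency
    over the region's span reaches the observed maximum.
    """
    n_samples = indicator.shape[0]
    obs = [indicator[:, a:b].mean(axis=0).max() for a, b in regions]
    exceed = np.zeros(len(regions), dtype=int)
    slices = probes.chrom_slices()
    # group regions by chromosome so shifts are drawn once per sample/chrom/perm
    by_chrom: dict[str, list[int]] = {}
    for ri, (a, _b) in enumerate(regions):
        by_chrom.setdefault(str(probes.chromosome[a]), []).append(ri)
    for chrom, ridx in by_chrom.items():
        sl = slices[chrom]
        L = sl.stop - sl.start
        sub = indicator[:, sl]  # samples x L
        cols = np.concatenate([np.arange(regions[r][0] - sl.start, regions[r][1] - sl.start)
                               for r in ridx])
        bounds = np.cumsum([0] + [regions[r][1] - regions[r][0] for r in ridx])
        counts = np.zeros((n_perm, len(cols)), dtype=np.int32)
        for s in range(n_samples):
            offsets = rng.integers(0, L, size=n_perm)
            counts += sub[s, (cols[None, :] - offsets[:, None]) % L]
        tol = 1e-9
        for j, r in enumerate(ridx):
            region_max = counts[:, bounds[j]:bounds[j + 1]].max(axis=1) / n_samples
            exceed[r] = int(np.sum(region_max >= obs[r] - tol))
    return [(e + 1) / (n_perm + 1) for e in exceed]


def detect_rars(
    callsets: list[CallSet],
    probes: ProbeMap,
    clinical: ClinicalTable | None = None,
    min_freq: float = 0.30,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    event_rule: EventRule = EventRule(),
    overlap_frac: float = 0.5,
) -> tuple[list[RAR], pd.DataFrame]:
    """Delineate cohort RARs; returns (rars, marker matrix samples x RAR).

    Reported frequency columns are carrier fractions recomputed from the
    marker matrix (50% span-overlap rule), so the table is internally
    consistent with downstream marker analyses.
    """
    if len(callsets) < 2:
        raise ValueError("RAR detection needs at least 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sm = state_matrix(callsets, probes)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5A5]))
    accepted: list[RAR] = []
    for state, code, prefix in ((GAIN, 1, "RAR-G"), (LOSS, -1, "RAR-L")):
        indicator = sm == code
        freq = indicator.mean(axis=0)
        regions = _candidate_runs(freq, min_freq, probes)
        if not regions:
            continue
        pvals = _region_null_pvalues(indicator, regions, probes, n_perm, rng)
        k = 0
        for (a, b), p in zip(regions, pvals):
            if p < alpha:
                k += 1
                accepted.append(RAR(
                    name=f"{prefix}{k}",
                    chromosome=str(probes.chromosome[a]),
                    start_bp=int(probes.position[a]),
                    end_bp=int(probes.position[b - 1]),
                    type=state,
                    freq_total=float("nan"),
                    freq_stageI=float("nan"),
                    freq_stageII=float("nan"),
                    p_value=p,
                    event_class=UNCLASSIFIED,
                    first_probe=a,
                    last_probe=b - 1,
                ))
    markers = marker_matrix(accepted, callsets, overlap_frac=overlap_frac)
    for r in accepted:
        col = markers[r.name].to_numpy()
        r.freq_total = float(col.mean()) if len(col) else float("nan")
        if clinical is not None:
            cl = clinical.aligned_to([cs.sample_id for cs in callsets])
            stages = cl.stage_collapsed().to_numpy()
            for stage, attr in (("I", "freq_stageI"), ("II", "freq_stageII")):
                mask = stages == stage
                setattr(r, attr, float(col[mask].mean()) if mask.any() else float("nan"))
            if math.isfinite(r.freq_stageI) and math.isfinite(r.freq_stageII):
                r.event_class = classify_event(r.freq_stageI, r.freq_stageII, event_rule)
    return accepted, markers


def marker_matrix(rars: list[RAR], callsets: list[CallSet],
                  overlap_frac: float = 0.5) -> pd.DataFrame:
    """Binary samples x RAR matrix: 1 iff the sample's same-type non-neutral
    calls cover at least ``overlap_frac`` of the RAR's bp span."""
    sample_ids = [cs.sample_id for cs in callsets]
    data = {}
    for r in rars:
        col = np.zeros(len(callsets), dtype=np.int8)
        for i, cs in enumerate(callsets):
            covered = 0
            for c in cs:
                if c.state != r.type or c.segment.chromosome != r.chromosome:
                    continue
                lo = max(c.segment.start_bp, r.start_bp)
                hi = min(c.segment.end_bp, r.end_bp)
                if hi >= lo:
                    covered += hi - lo + 1
            if covered >= overlap_frac * r.length_bp:
                col[i] = 1
        data[r.name] = col
    return pd.DataFrame(data, index=sample_ids)


def detect_high_level(
    callsets: list[CallSet],
    probes: ProbeMap,
    min_carrier_frac: float = 0.10,
) -> list[HighLevelRegion]:
    """Common high-level regions: maximal runs of probes with >= 1 flagged
    sample, reported when the carrier fraction exceeds ``min_carrier_frac``
    (strict, matching the 'over 10%' phrasing)."""
    hm = highlevel_matrix(callsets, probes)
    n = len(callsets)
    out: list[HighLevelRegion] = []
    for code, typ, prefix in ((1, "amplification", "AMP"), (-1, "homozygous_deletion", "HD")):
        indicator = hm == code
        counts = indicator.sum(axis=0)
        regions = _candidate_runs((counts >= 1).astype(float), 0.5, probes)
        k = 0
        for a, b in regions:
            carriers = int(indicator[:, a:b].any(axis=1).sum())
            if carriers / n > min_carrier_frac:
                k += 1
                out.append(HighLevelRegion(
                    name=f"{prefix}{k}",
                    chromosome=str(probes.chromosome[a]),
                    start_bp=int(probes.position[a]),
                    end_bp=int(probes.position[b - 1]),
                    type=typ,
                    carrier_count=carriers,
                    carrier_percent=carrier_percent(carriers, n),
                    first_probe=a,
                    last_probe=b - 1,
                ))
    return out


def carrier_percent(carriers: int, n_samples: int) -> int:
    """Integer percent, half-up (6/48 -> 13)."""
    return int(math.floor(100.0 * carriers / n_samples + 0.5))
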