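"""Rank-based recursive segmentation of log2 ratio profiles.

Each sample's probe-ordered profile is partitioned into constant-mean
segments by recursive binary splitting on the two-sample Wilcoxon rank-sum
statistic. A candidate split is the position maximizing the standardized
rank-sum statistic between the left and right halves of the current run; it
is accepted iff a within-run label-permutation p-value falls below the
significance threshold AND both children keep the minimum probe count.
Runs break at chromosome boundaries and wherever adjacent probes are
further apart than the maximum contiguous probe spacing.

This is an original, fully reproducible re-specification of the
"rank segmentation" family implemented in commercial CNA callers, honoring
the four published parameters (significance threshold, maximum probe
spacing, minimum probes per segment, permutation budget); the internal
stopping rule of the proprietary implementation is undisclosed and is not
cloned. Ties take midranks; argmax ties break leftmost; permutation
p-values are the add-one estimate (b+1)/(B+1) under a seeded generator.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import ProbeMap, RatioMatrix, Segment, SegmentSet


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the rank-segmentation procedure.

    significance_threshold: permutation p-value below which a split is kept.
    max_probe_spacing_kbp: adjacent probes further apart than this start a new run.
    min_probes: minimum probes per emitted segment (terminal remainders are flagged).
    max_permutations: permutation budget per split test.
    seed: base seed; per-sample/per-split streams are derived deterministically.
    """

    significance_threshold: float = 5.0e-4
    max_probe_spacing_kbp: float = 1000.0
    min_probes: int = 5
    max_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.significance_threshold < 1.0:
            raise ValueError("significance_threshold must be in (0, 1)")
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if self.max_permutations < 1:
            raise ValueError("max_permutations must be >= 1")
        if self.max_probe_spacing_kbp <= 0:
            raise ValueError("max_probe_spacing_kbp must be positive")


def split_runs(probes: ProbeMap, params: SegmentationParams) -> list[tuple[int, int]]:
    """Half-open probe-index runs: contiguous stretches segmentable as one unit.

    Runs break at chromosome boundaries and at gaps > max_probe_spacing_kbp.
    Their union is the whole probe map.
    """
    max_gap_bp = params.max_probe_spacing_kbp * 1000.0
    runs: list[tuple[int, int]] = []
    for sl in probes.chrom_slices().values():
        start = sl.start
        for i in range(sl.start + 1, sl.stop):
            if probes.position[i] - probes.position[i - 1] > max_gap_bp:
                runs.append((start, i))
                start = i
        runs.append((start, sl.stop))
    return runs


def best_split(ranks: np.ndarray, min_probes: int) -> tuple[int, float]:
    """Best single split of a rank vector: (split index k, max |Z|).

    k splits the run into [0,k) and [k,n); only splits leaving >= min_probes
    on each side are eligible. Z standardizes the left-side rank sum against
    its permutation moments (midranks make this exact under ties). Returns
    (-1, 0.0) when no split is eligible. Leftmost argmax on ties.
    """
    n = len(ranks)
    if n < 2 * min_probes:
        return -1, 0.0
    k = np.arange(min_probes, n - min_probes + 1)
    left_sums = np.cumsum(ranks)[k - 1]
    rbar = ranks.mean()
    s2 = np.mean((ranks - rbar) ** 2)
    if s2 <= 0:  # constant data: no information to split on
        return -1, 0.0
    var = k * (n - k) / (n - 1) * s2
    z = np.abs(left_sums - k * rbar) / np.sqrt(var)
    j = int(np.argmax(z))
    return int(k[j]), float(z[j])


class _NullCache:
    """Lazily grown null distributions of the max-|Z| split statistic.

    The permutation null depends only on the rank multiset (and min_probes),
    not on the probe order, so draws are shared across samples and recursion
    nodes with the same run length and tie structure — in a cohort the same
    chromosome-run sizes recur in every sample. Draws are generated in
    doubling chunks from a stream seeded by (seed, key), which makes
    p-values deterministic and independent of the traversal order.
    """

    def __init__(self):
        self._store: dict[tuple, np.ndarray] = {}

    def _key(self, ranks: np.ndarray, min_probes: int, seed: int) -> tuple:
        tie_sig = zlib.crc32(np.sort(ranks).tobytes())
        return (len(ranks), min_probes, tie_sig, seed & 0x7FFFFFFF)

    def draws(self, ranks: np.ndarray, min_probes: int, seed: int,
              n_needed: int) -> np.ndarray:
        key = self._key(ranks, min_probes, seed)
        have = self._store.get(key, np.empty(0))
        while len(have) < n_needed:
            chunk = max(64, min(len(have), 4096))
            rng = np.random.default_rng(np.random.SeedSequence(
                [*key, len(have)]))
            have = np.concatenate([have, _max_stat_draws(ranks, min_probes, chunk, rng)])
            self._store[key] = have
        return have

    def clear(self):
        self._store.clear()


_null_cache = _NullCache()


def _max_stat_draws(ranks: np.ndarray, min_probes: int, m: int,
                    rng: np.random.Generator) -> np.ndarray:
    """m permutation draws of max |Z| over eligible splits of the rank vector."""
    n = len(ranks)
    k = np.arange(min_probes, n - min_probes + 1)
    rbar = ranks.mean()
    s2 = np.mean((ranks - rbar) ** 2)
    sd = np.sqrt(k * (n - k) / (n - 1) * s2)
    mean = k * rbar
    perm = rng.permuted(np.broadcast_to(ranks, (m, n)).copy(), axis=1)
    cs = np.cumsum(perm, axis=1)[:, k - 1]
    return (np.abs(cs - mean) / sd).max(axis=1)


def _split_pvalue(ranks: np.ndarray, observed: float,
                  params: SegmentationParams) -> float:
    """Permutation p-value of the best-split statistic, (b+1)/(B+1).

    Uses the shared null cache; consumes draws incrementally and stops as
    soon as the estimate can no longer fall below the significance
    threshold — the accept/reject decision is identical to the full-budget
    decision.
    """
    B = params.max_permutations
    tol = 1e-9
    done = 0
    while done < B:
        done = min(B, max(64, done * 4))
        draws = _null_cache.draws(ranks, params.min_probes, params.seed, done)
        b = int(np.sum(draws[:done] >= observed - tol))
        if (b + 1) / (B + 1) >= params.significance_threshold:
            return (b + 1) / (done + 1)
    return (b + 1) / (B + 1)


def segment_sample(
    values: np.ndarray,
    probes: ProbeMap,
    params: SegmentationParams,
    sample_id: str = "sample",
) -> SegmentSet:
    """Segment one sample's per-probe log2 ratios into a SegmentSet.

    Missing (NaN) probes are excluded from the statistics but inherit the
    enclosing segment for reporting (a split boundary is placed immediately
    before the right child's first informative probe). Runs shorter than
    min_probes yield a single segment flagged 'short'.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(probes),):
        raise ValueError("values must align with the probe map")
    segset = SegmentSet(sample_id=str(sample_id))

    for run_start, run_stop in split_runs(probes, params):
        idx = np.arange(run_start, run_stop)
        finite = idx[np.isfinite(values[idx])]
        if len(finite) == 0:
            # run with no informative probes: one NaN-mean segment
            segset.segments.append(_make_segment(
                sample_id, probes, run_start, run_stop - 1, float("nan"), flag="missing"))
            continue
        boundaries: list[int] = []  # positions in `finite` where a new segment starts

        def recurse(lo: int, hi: int) -> None:
            vals = values[finite[lo:hi]]
            n = hi - lo
            if n < 2 * params.min_probes:
                return
            ranks = rankdata(vals, method="average")
            k, obs = best_split(ranks, params.min_probes)
            if k < 0:
                return
            p = _split_pvalue(ranks, obs, params)
            if p < params.significance_threshold:
                boundaries.append(lo + k)
                recurse(lo, lo + k)
                recurse(lo + k, hi)

        recurse(0, len(finite))
        cuts = [0] + sorted(boundaries) + [len(finite)]
        short_run = len(finite) < params.min_probes
        for a, b in zip(cuts, cuts[1:]):
            # segment spans all probes (incl. missing) from the previous
            # boundary up to just before the next informative probe
            first = run_start if a == 0 else int(finite[a])
            last = (run_stop - 1) if b == len(finite) else int(finite[b] - 1)
            mean = float(np.mean(values[finite[a:b]]))
            flag = "short" if short_run else ""
            segset.segments.append(_make_segment(sample_id, probes, first, last, mean, flag))
    return segset


def _make_segment(sample_id, probes: ProbeMap, first: int, last: int,
                  mean: float, flag: str = "") -> Segment:
    return Segment(
        sample_id=str(sample_id),
        chromosome=str(probes.chromosome[first]),
        start_bp=int(probes.position[first]),
        end_bp=int(probes.position[last]),
        first_probe=first,
        last_probe=last,
        n_probes=last - first + 1,
        mean_log2=mean,
        flag=flag,
    )


def segment_matrix(matrix: RatioMatrix, params: SegmentationParams) -> list[SegmentSet]:
    """Segment every sample of a ratio matrix."""
    return [
        segment_sample(matrix.values[i], matrix.probes, params, sample_id=sid)
        for i, sid in enumerate(matrix.sample_ids)
    ]
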