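"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive base pairs throughout. The probe map is the
spatial backbone: every per-probe array in the package is aligned to its
(chromosome, position) order, chromosomes ranked 1..22 then X.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("rarseek")

CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

STAGES = ("I", "IIA", "IIB")
SUBTYPES = ("LuminalA", "LuminalB", "HER2", "TNBC")


class RarseekError(Exception):
    """Base class for all package errors."""


class ParseError(RarseekError):
    """Raised when an on-disk table cannot be parsed."""


def normalize_chromosome(chrom) -> str:
    """Canonical chromosome label: '1'..'22', 'X' (a leading 'chr' is stripped)."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper() if c.lower() == "x" else c
    if c not in _CHROM_RANK:
        raise ParseError(f"unsupported chromosome label: {chrom!r}")
    return c


def chromosome_rank(chrom: str) -> int:
    return _CHROM_RANK[normalize_chromosome(chrom)]


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic probe coordinates.

    Invariants: probe ids unique; probes sorted by (chromosome, position) with
    strictly positive 1-based positions. Positions may tie (duplicate
    coordinates are permitted); ids may not.
    """

    probe_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        pid = np.asarray(self.probe_id, dtype=object)
        chrom = np.asarray([normalize_chromosome(c) for c in self.chromosome], dtype=object)
        pos = np.asarray(self.position, dtype=np.int64)
        if not (len(pid) == len(chrom) == len(pos)):
            raise ValueError("probe map arrays must have equal length")
        if len(pid) == 0:
            raise ValueError("probe map must contain at least one probe")
        if np.any(pos < 1):
            raise ValueError("probe positions must be positive 1-based coordinates")
        ids, counts = np.unique(pid, return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate probe_id: {dup!r}")
        ranks = np.array([_CHROM_RANK[c] for c in chrom])
        order = np.lexsort((pos, ranks))
        if not np.array_equal(order, np.arange(len(pid))):
            logger.info("probe map was not coordinate-sorted; sorting")
            pid, chrom, pos = pid[order], chrom[order], pos[order]
        object.__setattr__(self, "probe_id", pid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)

    def __len__(self) -> int:
        return len(self.probe_id)

    @property
    def n_probes(self) -> int:
        return len(self.probe_id)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice of each chromosome present, in genomic order."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chromosome[i] != self.chromosome[start]:
                out[self.chromosome[start]] = slice(start, i)
                start = i
        return out

    def mapped_length(self) -> int:
        """Total bp spanned by probes, summed per chromosome (first to last probe)."""
        total = 0
        for sl in self.chrom_slices().values():
            total += int(self.position[sl.stop - 1] - self.position[sl.start] + 1)
        return total

    def index_of(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_id)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe_id": self.probe_id, "chromosome": self.chromosome, "position": self.position}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeMap":
        return cls(
            probe_id=df["probe_id"].to_numpy(dtype=object),
            chromosome=df["chromosome"].to_numpy(dtype=object),
            position=df["position"].to_numpy(),
        )


@dataclass
class RatioMatrix:
    """Per-sample normalized log2 tumor/reference ratios, samples x probes.

    Columns are keyed to a ProbeMap; missing values are NaN and are excluded
    probe-wise by downstream segmentation.
    """

    sample_ids: list[str]
    values: np.ndarray
    probes: ProbeMap

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratio matrix must be 2-D (samples x probes)")
        if self.values.shape != (len(self.sample_ids), len(self.probes)):
            raise ValueError(
                f"ratio matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probes)} probes"
            )
        present = self.values[~np.isnan(self.values)]
        if present.size and not np.all(np.isfinite(present)):
            raise ValueError("ratio matrix contains non-finite (inf) values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in ratio matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.probes.probe_id))
        df.insert(0, "sample", self.sample_ids)
        return df


@dataclass(frozen=True)
class Segment:
    """A constant-mean run of probes in one sample.

    n_probes counts probes spanned (including missing-value probes that
    inherit the segment). ``flag`` marks degenerate cases: 'short' for
    terminal remainders below the minimum probe count.
    """

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    first_probe: int
    last_probe: int
    n_probes: int
    mean_log2: float
    flag: str = ""

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("segment start_bp > end_bp")
        if self.n_probes < 1:
            raise ValueError("segment must span at least one probe")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SegmentSet:
    """All segments of one sample, in genomic order."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


CLINICAL_COLUMNS = ["sample", "age_group", "stage", "er", "pr", "her2",
                    "survival_years", "event"]


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and survival outcome.

    age_group in {'<50', '>=50'}; stage in {I, IIA, IIB}; er/pr/her2 in
    {'positive', 'negative'}; event 1 = dead, 0 = alive/censored.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if df["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        bad = ~df["stage"].isin(STAGES)
        if bad.any():
            raise ValueError(f"invalid stage values: {sorted(df.loc[bad, 'stage'].unique())}")
        for col in ("er", "pr", "her2"):
            badm = ~df[col].isin(["positive", "negative"])
            if badm.any():
                raise ValueError(f"invalid {col} values: {sorted(df.loc[badm, col].unique())}")
        if (df["survival_years"] < 0).any():
            raise ValueError("negative survival_years")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")
        if "subtype" not in df.columns:
            from .clinical import classify_subtype  # deferred: avoids import cycle

            df["subtype"] = [
                classify_subtype(e, p, h)
                for e, p, h in zip(df["er"], df["pr"], df["her2"])
            ]
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample"])

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def stage_collapsed(self) -> pd.Series:
        """Stage I vs II: IIA/IIB collapse to 'II' for stratified frequencies."""
        return self.data["stage"].map(lambda s: "I" if s == "I" else "II")

    def aligned_to(self, sample_ids: list[str]) -> "ClinicalTable":
        df = self.data.set_index("sample").loc[list(sample_ids)].reset_index()
        return ClinicalTable(df)
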