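"""Readers and writers for every on-disk artifact the pipeline touches.

All tables are tab-separated UTF-8 with a header row. Segment interchange
uses a SEG-style layout (sample, chromosome, start, end, n_probes, mean),
the de-facto standard for copy-number segments. Every reader/writer pair is
the identity on valid in-memory objects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    ParseError,
    ProbeMap,
    RatioMatrix,
    Segment,
    SegmentSet,
    normalize_chromosome,
)

logger = logging.getLogger("rarseek")

_PROBE_COLS = {"probe_id", "chromosome", "position"}
SEG_COLUMNS = ["sample", "chromosome", "start_bp", "end_bp", "n_probes", "mean_log2", "flag"]


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                           na_values=["", "NA", "NaN", "nan"])
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"{path}: {exc}") from exc


def read_probe_map(path) -> ProbeMap:
    """Read a probe annotation TSV (probe_id, chromosome, position).

    Out-of-order rows are sorted silently (with a logged notice, handled by
    ProbeMap itself); duplicate probe ids raise naming the offending id;
    malformed positions raise naming the 1-based data line.
    """
    df = _read_tsv(path)
    missing = _PROBE_COLS - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = np.flatnonzero(pos.isna().to_numpy())
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ParseError(
            f"{path}: non-numeric position {df['position'].iloc[bad[0]]!r} "
            f"on line {bad[0] + 2}"
        )
    try:
        return ProbeMap(
            probe_id=df["probe_id"].to_numpy(dtype=object),
            chromosome=df["chromosome"].to_numpy(dtype=object),
            position=pos.to_numpy(dtype=np.int64),
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_probe_map(probes: ProbeMap, path) -> None:
    probes.to_frame().to_csv(path, sep="\t", index=False)


def read_ratio_matrix(path, probes: ProbeMap) -> RatioMatrix:
    """Read a samples x probes log2-ratio TSV and realign columns to the map order.

    The first column is the sample id; remaining column names must all be
    probe ids known to ``probes`` (alien columns are an error, as is any
    probe of the map absent from the matrix). Non-numeric cells raise with
    (sample, probe) coordinates.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a sample column plus probe columns")
    sample_col = df.columns[0]
    sample_ids = [str(s) for s in df[sample_col]]
    matrix_probes = list(df.columns[1:])
    known = set(probes.probe_id)
    alien = [p for p in matrix_probes if p not in known]
    if alien:
        raise ParseError(f"{path}: probe column(s) absent from probe map: {alien[:5]}")
    absent = known - set(matrix_probes)
    if absent:
        raise ParseError(
            f"{path}: {len(absent)} probe(s) of the probe map missing from the matrix, "
            f"e.g. {sorted(absent)[:5]}"
        )
    values = np.empty((len(sample_ids), len(probes)), dtype=float)
    for j, pid in enumerate(probes.probe_id):
        col = pd.to_numeric(df[pid], errors="coerce")
        raw_na = df[pid].isna()
        bad = np.flatnonzero((col.isna() & ~raw_na).to_numpy())
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric ratio {df[pid].iloc[bad[0]]!r} at "
                f"sample {sample_ids[bad[0]]!r}, probe {pid!r}"
            )
        values[:, j] = col.to_numpy(dtype=float)
    return RatioMatrix(sample_ids=sample_ids, values=values, probes=probes)


def write_ratio_matrix(matrix: RatioMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_segments(segsets: list[SegmentSet], path) -> None:
    rows = []
    for ss in segsets:
        for s in ss:
            rows.append(
                (s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.n_probes,
                 repr(float(s.mean_log2)), s.flag)
            )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[SegmentSet]:
    """Read a SEG-style table back into per-sample SegmentSets.

    Overlapping segments within one sample+chromosome are rejected. Probe
    index bookkeeping (first/last probe) is not serialized; round-trip
    preserves coordinates, probe counts, means and flags.
    """
    df = _read_tsv(path)
    missing = set(SEG_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if "flag" not in df.columns:
        df["flag"] = ""
    out: dict[str, SegmentSet] = {}
    for _, row in df.iterrows():
        seg = Segment(
            sample_id=str(row["sample"]),
            chromosome=normalize_chromosome(row["chromosome"]),
            start_bp=int(row["start_bp"]),
            end_bp=int(row["end_bp"]),
            first_probe=-1,
            last_probe=-1,
            n_probes=int(row["n_probes"]),
            mean_log2=float(row["mean_log2"]),
            flag="" if pd.isna(row["flag"]) else str(row["flag"]),
        )
        out.setdefault(seg.sample_id, SegmentSet(seg.sample_id)).segments.append(seg)
    for ss in out.values():
        by_chrom: dict[str, list[Segment]] = {}
        for s in ss:
            by_chrom.setdefault(s.chromosome, []).append(s)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start_bp)
            for a, b in zip(segs, segs[1:]):
                if b.start_bp <= a.end_bp:
                    raise ParseError(
                        f"{path}: overlapping segments for sample {ss.sample_id!r} "
                        f"chromosome {chrom}: [{a.start_bp},{a.end_bp}] and "
                        f"[{b.start_bp},{b.end_bp}]"
                    )
    return list(out.values())


def read_clinical(path) -> ClinicalTable:
    df = _read_tsv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["survival_years"] = pd.to_numeric(df["survival_years"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise").astype(int)
    try:
        return ClinicalTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct TSV: sample, locus, template, replicate, ct."""
    df = _read_tsv(path)
    required = {"sample", "locus", "template", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    bad = ~df["template"].isin(["tumor", "reference"])
    if bad.any():
        raise ParseError(f"{path}: template must be tumor/reference")
    if (df["ct"] <= 0).any():
        raise ParseError(f"{path}: Ct values must be positive")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def format_mb(bp: int) -> str:
    """Report a bp coordinate in megabases with 2 decimals ('148.12' style)."""
    return f"{bp / 1e6:.2f}"
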