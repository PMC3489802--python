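"""Relative copy-number quantification from genomic qPCR by the ddCT method.

ddCT contrasts the target locus against a diploid internal-control locus,
in tumor DNA against normal reference DNA:

    ddCT = (Ct_target,tumor - Ct_control,tumor)
         - (Ct_target,ref   - Ct_control,ref)

dosage_ratio = 2^(-ddCT) (amplification efficiency fixed at 2 per cycle;
an ``efficiency`` parameter exists for sensitivity checks). Replicates are
aggregated as the arithmetic mean of Ct before differencing. A locus is
called a copy-number gain when the dosage ratio is strictly above the
cutoff (default 2.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clinical import (
    SurvivalResult,
    combined_marker,
    km_estimate,
    logrank_test,
    logrank_trend_test,
    marker_survival,
    three_level_groups,
)
from .core import ClinicalTable


@dataclass(frozen=True)
class DosageCall:
    sample: str
    locus: str
    delta_delta_ct: float
    dosage_ratio: float
    gain: bool
    flagged: bool = False  # replicate spread above the Ct-SD limit


def _mean_ct(ct: pd.DataFrame, sample: str, locus: str, template: str,
             sd_limit: float) -> tuple[float, bool]:
    sub = ct[(ct["sample"] == sample) & (ct["locus"] == locus) & (ct["template"] == template)]
    if sub.empty:
        raise ValueError(f"missing Ct values: sample={sample!r} locus={locus!r} "
                         f"template={template!r}")
    vals = sub["ct"].to_numpy(dtype=float)
    flagged = len(vals) > 1 and float(np.std(vals, ddof=1)) > sd_limit
    return float(vals.mean()), flagged


def ddct_call(ct: pd.DataFrame, sample: str, locus: str, control_locus: str,
              gain_cutoff: float = 2.0, efficiency: float = 2.0,
              sd_limit: float = 0.5) -> DosageCall:
    """ddCT dosage call for one sample x target locus.

    Requires target and control Cts for both tumor and reference templates.
    High replicate spread (sample SD above ``sd_limit`` cycles) flags the
    call but never drops it.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    means = {}
    flagged = False
    for loc, tmpl in ((locus, "tumor"), (control_locus, "tumor"),
                      (locus, "reference"), (control_locus, "reference")):
        means[(loc, tmpl)], f = _mean_ct(ct, sample, loc, tmpl, sd_limit)
        flagged |= f
    ddct = ((means[(locus, "tumor")] - means[(control_locus, "tumor")])
            - (means[(locus, "reference")] - means[(control_locus, "reference")]))
    ratio = float(efficiency ** (-ddct))
    return DosageCall(sample=str(sample), locus=str(locus), delta_delta_ct=float(ddct),
                      dosage_ratio=ratio, gain=ratio > gain_cutoff, flagged=flagged)


def call_all(ct: pd.DataFrame, control_locus: str, gain_cutoff: float = 2.0,
             efficiency: float = 2.0, sd_limit: float = 0.5) -> pd.DataFrame:
    """Dosage calls for every (sample, target locus) pair in a Ct table."""
    loci = [l for l in ct["locus"].unique() if l != control_locus]
    rows = []
    for sample in pd.unique(ct["sample"]):
        for locus in loci:
            c = ddct_call(ct, sample, locus, control_locus, gain_cutoff,
                          efficiency, sd_limit)
            rows.append({"sample": c.sample, "locus": c.locus,
                         "delta_delta_ct": c.delta_delta_ct,
                         "dosage_ratio": c.dosage_ratio,
                         "gain": int(c.gain), "flagged": int(c.flagged)})
    return pd.DataFrame(rows)


def dosage_marker_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """samples x locus binary gain matrix from a call table."""
    return (calls.pivot(index="sample", columns="locus", values="gain")
            .fillna(0).astype(int))


def replicate_survival(calls: pd.DataFrame, clinical: ClinicalTable,
                       loci: list[str] | None = None,
                       horizon_years: float = 10.0) -> dict[str, SurvivalResult]:
    """Survival analysis of qPCR gain markers in a replication cohort.

    Runs KM/log-rank/adjusted Cox for each single locus marker, for the AND
    (double-positive) marker, and a log-rank trend over the
    {neither, either, both} grouping when exactly two loci are analyzed.
    """
    markers = dosage_marker_matrix(calls)
    if loci is None:
        loci = list(markers.columns)
    cl = clinical.aligned_to(list(markers.index))
    df = cl.data
    out: dict[str, SurvivalResult] = {}
    for locus in loci:
        m = markers[locus].to_numpy()
        if m.sum() == 0 or m.sum() == len(m):
            res = SurvivalResult(km_curves=km_estimate(
                *_capped(df, horizon_years), np.where(m == 1, "positive", "negative")))
            res.notes.append(f"{locus}: single group; log-rank skipped")
            warnings.warn(res.notes[-1], stacklevel=2)
            out[locus] = res
        else:
            out[locus] = marker_survival(m, df, horizon_years, marker_name=locus)
    if len(loci) == 2:
        both = combined_marker(markers, loci)
        name = f"{loci[0]}*{loci[1]}"
        if 0 < both.sum() < len(both):
            out[name] = marker_survival(both, df, horizon_years, marker_name=name)
            levels = three_level_groups(markers, loci)
            t, e = _capped(df, horizon_years)
            chi2, p = logrank_trend_test(t, e, levels)
            out[name].notes.append(f"trend chi2={chi2:.4f} p={p:.4g}")
            out["trend"] = SurvivalResult(
                km_curves=km_estimate(t, e, levels),
                logrank_statistic=chi2, logrank_p=p,
                notes=["log-rank test for trend over {neither, either, both}"])
    return out


def _capped(df: pd.DataFrame, horizon_years: float):
    from .clinical import apply_horizon

    return apply_horizon(df["survival_years"], df["event"], horizon_years)
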