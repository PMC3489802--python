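"""End-to-end orchestration: discovery and replication runs from one config.

Discovery: segment -> call -> RAR delineation -> rule mining -> survival.
Replication: qPCR dosage calls -> survival of single/combined markers.
Every report is recomputable from inputs + config + seed; the seed and a
config hash are stamped into each output file's header line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .call import CallSet, CallThresholds, call_cohort, cohort_cna_stats, sample_summary
from .clinical import SurvivalResult, combined_marker, marker_survival
from .core import ClinicalTable, ProbeMap, RatioMatrix, RarseekError
from .mine import CparParams, mine_rules, report_death_rules, rules_table
from .qpcr import call_all, replicate_survival
from .rar import EventRule, detect_high_level, detect_rars
from .segment import SegmentationParams, segment_matrix
from .simulate import CohortConfig, ImplantSpec, InteractionSpec, default_config, simulate_cohort

logger = logging.getLogger("rarseek")


class StageError(RarseekError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    mode: str = "discovery"  # discovery | replication | simulate
    seed: int = 0
    out_dir: str | None = None
    # input paths (discovery: probes/ratios/clinical; replication: ct/clinical)
    probes: str | None = None
    ratios: str | None = None
    clinical: str | None = None
    ct: str | None = None
    # simulation settings (used when input paths are absent)
    simulate: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    rar: dict = field(default_factory=dict)
    mining: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant config (where outputs go is excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    rar_table: pd.DataFrame
    highlevel_table: pd.DataFrame
    rules_table: pd.DataFrame
    survival_table: pd.DataFrame
    sample_table: pd.DataFrame
    cohort_stats: dict
    provenance: dict
    survival_results: dict[str, SurvivalResult] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = "# rarseek seed={seed} config={config_hash}\n".format(**self.provenance)
        for name, df in (("rars.tsv", self.rar_table),
                         ("high_level.tsv", self.highlevel_table),
                         ("rules.tsv", self.rules_table),
                         ("survival.tsv", self.survival_table),
                         ("samples.tsv", self.sample_table)):
            path = out / name
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        with open(out / "provenance.json", "w") as fh:
            json.dump({**self.provenance, "cohort_stats": self.cohort_stats},
                      fh, indent=2, sort_keys=True, default=str)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"{name}: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrapped
    return deco


def _load_inputs(config: RunConfig) -> tuple[ProbeMap, RatioMatrix, ClinicalTable]:
    if config.probes and config.ratios and config.clinical:
        probes = rio.read_probe_map(config.probes)
        matrix = rio.read_ratio_matrix(config.ratios, probes)
        clinical = rio.read_clinical(config.clinical)
        return probes, matrix, clinical
    cohort = _cohort_config(config)
    probes, matrix, clinical, _truth = simulate_cohort(cohort)
    return probes, matrix, clinical


def _cohort_config(config: RunConfig) -> CohortConfig:
    opts = dict(config.simulate)
    if opts.pop("defaults", True):
        base = default_config(seed=config.seed)
    else:
        base = CohortConfig(seed=config.seed)
    if "implants" in opts:
        opts["implants"] = tuple(ImplantSpec(**d) for d in opts["implants"])
    if "interactions" in opts:
        opts["interactions"] = tuple(
            InteractionSpec(implants=tuple(d["implants"]),
                            hazard_multiplier=d.get("hazard_multiplier", 1.0))
            for d in opts["interactions"])
    opts.setdefault("seed", config.seed)
    return base.with_(**opts)


def rar_report_table(rars) -> pd.DataFrame:
    """RAR report in the published shape (positions in Mb, 2 decimals)."""
    rows = []
    for r in rars:
        rows.append({
            "RAR": r.name,
            "chromosome": r.chromosome,
            "map_position_mb": f"{rio.format_mb(r.start_bp)}-{rio.format_mb(r.end_bp)}",
            "size_mb": f"{r.size_mb:.2f}",
            "type": r.type,
            "p_value": round(r.p_value, 4),
            "freq_total": round(r.freq_total, 4),
            "freq_stageI": round(r.freq_stageI, 4) if np.isfinite(r.freq_stageI) else "",
            "freq_stageII": round(r.freq_stageII, 4) if np.isfinite(r.freq_stageII) else "",
            "event": r.event_class,
        })
    return pd.DataFrame(rows, columns=["RAR", "chromosome", "map_position_mb", "size_mb",
                                       "type", "p_value", "freq_total", "freq_stageI",
                                       "freq_stageII", "event"])


def highlevel_report_table(regions) -> pd.DataFrame:
    rows = [{
        "region": hl.name,
        "chromosome": hl.chromosome,
        "position_mb": f"{rio.format_mb(hl.start_bp)}-{rio.format_mb(hl.end_bp)}",
        "size_mb": f"{(hl.end_bp - hl.start_bp + 1) / 1e6:.2f}",
        "type": hl.type,
        "carrier_count": hl.carrier_count,
        "carrier_percent": hl.carrier_percent,
    } for hl in regions]
    return pd.DataFrame(rows, columns=["region", "chromosome", "position_mb", "size_mb",
                                       "type", "carrier_count", "carrier_percent"])


def survival_report_table(results: dict[str, SurvivalResult]) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        base = {"analysis": name,
                "logrank_statistic": round(res.logrank_statistic, 4)
                if np.isfinite(res.logrank_statistic) else "",
                "logrank_p": res.logrank_p if np.isfinite(res.logrank_p) else ""}
        if res.cox:
            for row in res.cox:
                rows.append({**base, "covariate": row.covariate,
                             "hazard_ratio": round(row.hazard_ratio, 2),
                             "ci_low": round(row.ci_low, 2),
                             "ci_high": round(row.ci_high, 2),
                             "p": float(f"{row.p:.4g}")})
        else:
            rows.append({**base, "covariate": "", "hazard_ratio": "", "ci_low": "",
                         "ci_high": "", "p": ""})
    return pd.DataFrame(rows, columns=["analysis", "covariate", "hazard_ratio",
                                       "ci_low", "ci_high", "p",
                                       "logrank_statistic", "logrank_p"])


@_stage("discovery")
def run_discovery(config: RunConfig) -> RunReport:
    """Full discovery pipeline on real or simulated inputs."""
    seg_params = SegmentationParams(**{"seed": config.seed, **config.segmentation})
    thresholds = CallThresholds(**config.thresholds)
    rar_opts = dict(config.rar)
    mining_opts = dict(config.mining)
    horizon = float(config.survival.get("horizon_years", 10.0))
    combine = config.survival.get("combine")

    probes, matrix, clinical = _load_inputs(config)
    logger.info("inputs: %d samples x %d probes", matrix.n_samples, len(probes))

    segsets = segment_matrix(matrix, seg_params)
    logger.info("segmentation: %d segments", sum(len(s) for s in segsets))
    callsets = call_cohort(segsets, thresholds)
    stats = cohort_cna_stats(callsets, probes)
    logger.info("calling: median %.0f CNAs/sample", stats["median_n_cna"])

    rars, markers = detect_rars(
        callsets, probes, clinical=clinical,
        min_freq=float(rar_opts.get("min_freq", 0.30)),
        alpha=float(rar_opts.get("alpha", 0.05)),
        n_perm=int(rar_opts.get("n_perm", 1000)),
        seed=config.seed,
        event_rule=EventRule(),
    )
    logger.info("RARs: %d", len(rars))
    high = detect_high_level(callsets, probes,
                             min_carrier_frac=float(rar_opts.get("min_carrier_frac", 0.10)))

    # survival-status class: 1 = alive at the horizon, 0 = dead within it
    from .clinical import apply_horizon

    _t, ev10 = apply_horizon(clinical.data["survival_years"], clinical.data["event"],
                             horizon)
    rules_df = pd.DataFrame(columns=["rule", "predicted_class", "n_total", "n_c", "laplace"])
    death_rules = []
    if len(rars) and len(set(ev10.tolist())) == 2:
        params = CparParams(**mining_opts) if mining_opts else CparParams()
        rules = mine_rules(markers, 1 - ev10, params)
        death_rules = report_death_rules(rules, params)
        rules_df = rules_table(death_rules)
    logger.info("mining: %d death rules", len(death_rules))

    results: dict[str, SurvivalResult] = {}
    for r in rars:
        m = markers[r.name].to_numpy()
        if 0 < m.sum() < len(m):
            results[r.name] = marker_survival(m, clinical.data, horizon,
                                              marker_name=r.name)
    if combine is None and death_rules:
        # default to the pair of markers shared by every reported death rule
        common = set.intersection(*({mk for mk, v in dr.antecedent if v == 1}
                                    for dr in death_rules))
        if len(common) >= 2:
            combine = sorted(common)[:2]
    if combine:
        both = combined_marker(markers, list(combine))
        if 0 < both.sum() < len(both):
            name = "*".join(combine)
            results[name] = marker_survival(both, clinical.data, horizon,
                                            marker_name=name)

    sample_rows = []
    for cs in callsets:
        n_cna, mb, frac = sample_summary(cs, probes)
        sample_rows.append({"sample": cs.sample_id, "n_cna": n_cna,
                            "altered_mb": round(mb, 2),
                            "altered_fraction": round(frac, 4)})

    report = RunReport(
        rar_table=rar_report_table(rars),
        highlevel_table=highlevel_report_table(high),
        rules_table=rules_df,
        survival_table=survival_report_table(results),
        sample_table=pd.DataFrame(sample_rows),
        cohort_stats=stats,
        provenance={"mode": "discovery", "seed": config.seed,
                    "config_hash": config.config_hash(),
                    "n_samples": matrix.n_samples, "n_probes": len(probes),
                    "segmentation": dataclasses.asdict(seg_params),
                    "thresholds": dataclasses.asdict(thresholds)},
        survival_results=results,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


@_stage("replication")
def run_replication(config: RunConfig) -> RunReport:
    """qPCR-based replication pipeline: dosage calls -> marker survival."""
    if not (config.ct and config.clinical):
        raise ValueError("replication mode needs 'ct' and 'clinical' input paths")
    ct = rio.read_ct_table(config.ct)
    clinical = rio.read_clinical(config.clinical)
    control = config.qpcr.get("control_locus", "chr13q32.1")
    cutoff = float(config.qpcr.get("gain_cutoff", 2.0))
    horizon = float(config.survival.get("horizon_years", 10.0))
    calls = call_all(ct, control_locus=control, gain_cutoff=cutoff)
    results = replicate_survival(calls, clinical, horizon_years=horizon)
    empty = pd.DataFrame()
    report = RunReport(
        rar_table=empty, highlevel_table=empty,
        rules_table=empty,
        survival_table=survival_report_table(results),
        sample_table=calls,
        cohort_stats={"n_samples": int(calls["sample"].nunique()),
                      "n_gain_calls": int(calls["gain"].sum())},
        provenance={"mode": "replication", "seed": config.seed,
                    "config_hash": config.config_hash(),
                    "control_locus": control, "gain_cutoff": cutoff},
        survival_results=results,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def run(config: RunConfig) -> RunReport:
    if config.mode in ("discovery", "simulate"):
        return run_discovery(config)
    if config.mode == "replication":
        return run_replication(config)
    raise ValueError(f"unknown mode {config.mode!r}")
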