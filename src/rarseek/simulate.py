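"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: ~24,000 probes
laid over 22 autosomes + X, per-probe Gaussian noise around segment-level
means, implanted recurrent gains/losses with stage-stratified carrier
frequencies, high-level amplifications, exponential survival with
multiplicative hazards for marker carriers, administrative censoring, and
qPCR Ct values consistent with carrier dosage.

The generator's defaults mirror the study design the pipeline targets:
48 samples of which 11 are stage I, 24,107 probes, 10-year censoring.
Everything is reproducible from the config seed (same seed => byte-identical
outputs). Carrier assignment supports a ``binomial`` mode (each sample is a
carrier with the stage's frequency) and an ``exact`` quota mode
(round(freq x n) carriers per stage stratum) so frequency-threshold tests
can be exercised deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CHROMOSOMES, ClinicalTable, ProbeMap, RatioMatrix

logger = logging.getLogger("rarseek")

# Approximate chromosome lengths (Mb) for 1..22, X; only relative sizes matter.
_CHROM_MB = {
    "1": 247, "2": 243, "3": 199, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 140, "10": 135, "11": 134, "12": 132, "13": 114, "14": 106,
    "15": 100, "16": 89, "17": 79, "18": 76, "19": 64, "20": 62, "21": 47,
    "22": 50, "X": 155,
}

DEFAULT_MEAN_LOG2 = {
    "gain": 0.58,
    "loss": -1.0,
    "amplification": 1.8,
    "homozygous_deletion": -1.8,
}

IMPLANT_TYPES = tuple(DEFAULT_MEAN_LOG2)


@dataclass(frozen=True)
class ImplantSpec:
    """One recurrent alteration implanted into carrier samples.

    mean_log2 defaults by type (gain +0.58, loss -1.0, amplification +1.8,
    homozygous deletion -1.8); its sign must be consistent with the type.
    hazard_multiplier multiplies the event hazard of carriers.
    """

    name: str
    chromosome: str
    start_bp: int
    end_bp: int
    type: str
    carrier_freq_stageI: float = 0.0
    carrier_freq_stageII: float = 0.0
    mean_log2: float | None = None
    hazard_multiplier: float = 1.0

    def __post_init__(self):
        if self.type not in IMPLANT_TYPES:
            raise ValueError(f"unknown implant type {self.type!r}")
        if not self.start_bp < self.end_bp:
            raise ValueError("implant start must precede end")
        for f in (self.carrier_freq_stageI, self.carrier_freq_stageII):
            if not 0.0 <= f <= 1.0:
                raise ValueError("carrier frequencies must be in [0, 1]")
        if self.hazard_multiplier < 0:
            raise ValueError("hazard_multiplier must be >= 0")
        if self.mean_log2 is None:
            object.__setattr__(self, "mean_log2", DEFAULT_MEAN_LOG2[self.type])
        expected_sign = 1.0 if self.type in ("gain", "amplification") else -1.0
        if np.sign(self.mean_log2) != expected_sign:
            raise ValueError(
                f"mean_log2 {self.mean_log2} inconsistent with type {self.type!r}"
            )

    @property
    def sign(self) -> int:
        return 1 if self.mean_log2 > 0 else -1


@dataclass(frozen=True)
class InteractionSpec:
    """Extra hazard applied only to samples carrying every named implant."""

    implants: tuple[str, ...]
    hazard_multiplier: float = 1.0

    def __post_init__(self):
        if len(self.implants) < 2:
            raise ValueError("an interaction needs at least two implants")
        if self.hazard_multiplier < 0:
            raise ValueError("hazard_multiplier must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a simulated cohort."""

    n_samples: int = 48
    n_stageI: int = 11
    probe_count: int = 24_107
    noise_sd: float = 0.15
    implants: tuple[ImplantSpec, ...] = ()
    interactions: tuple[InteractionSpec, ...] = ()
    baseline_hazard: float = 0.03       # events / year in non-carriers
    censoring_years: float = 10.0       # administrative censoring window
    carrier_mode: str = "binomial"      # binomial | exact
    chromosomes: tuple[str, ...] | None = None  # None = whole genome
    frac_stageIIB: float = 0.3          # of stage II, mirroring 11/37
    p_age_ge50: float = 0.458
    p_er_positive: float = 0.521
    p_pr_positive: float = 0.729
    p_her2_positive: float = 0.229
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_stageI <= self.n_samples:
            raise ValueError("need 0 < n_stageI <= n_samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.carrier_mode not in ("binomial", "exact"):
            raise ValueError("carrier_mode must be 'binomial' or 'exact'")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if isinstance(self.implants, list):
            object.__setattr__(self, "implants", tuple(self.implants))
        if isinstance(self.interactions, list):
            object.__setattr__(self, "interactions", tuple(self.interactions))
        if isinstance(self.chromosomes, list):
            object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated cohort (the parameter-recovery oracle)."""

    carriers: pd.DataFrame           # samples x implant names, 0/1
    stage: pd.Series                 # collapsed I/II per sample
    survival_years: pd.Series
    event: pd.Series
    hazard: pd.Series                # per-sample realized hazard (events/yr)
    implant_probes: dict[str, tuple[int, int]]  # implant -> (first, last) probe idx

    def marker_vector(self, name: str) -> np.ndarray:
        return self.carriers[name].to_numpy()

    def and_marker(self, names: list[str]) -> np.ndarray:
        return self.carriers[list(names)].all(axis=1).astype(int).to_numpy()


def build_probe_map(probe_count: int,
                    chromosomes: tuple[str, ...] | None = None) -> ProbeMap:
    """Evenly spaced probes over 22 autosomes + X, proportional to length.

    ``probe_count`` is the whole-genome array size and fixes the probe
    density (24,107 probes ~ one per 129 kb). Restricting ``chromosomes``
    instantiates only those chromosomes at that same density — the honest
    way to scale a simulation down without opening artificial probe gaps.
    """
    total_mb = sum(_CHROM_MB.values())
    counts = {c: max(2, int(round(probe_count * _CHROM_MB[c] / total_mb)))
              for c in CHROMOSOMES}
    use = CHROMOSOMES if chromosomes is None else tuple(chromosomes)
    ids, chroms, positions = [], [], []
    for c in use:
        n = counts[c]
        length_bp = _CHROM_MB[c] * 1_000_000
        step = length_bp // (n + 1)
        for i in range(n):
            ids.append(f"P{c}_{i}")
            chroms.append(c)
            positions.append((i + 1) * step)
    return ProbeMap(probe_id=np.array(ids, dtype=object),
                    chromosome=np.array(chroms, dtype=object),
                    position=np.array(positions, dtype=np.int64))


def _implant_probe_bounds(implant: ImplantSpec, probes: ProbeMap) -> tuple[int, int]:
    sl = probes.chrom_slices().get(implant.chromosome)
    if sl is None:
        raise ValueError(f"implant {implant.name}: chromosome {implant.chromosome} "
                         "not in probe map")
    pos = probes.position[sl]
    inside = np.flatnonzero((pos >= implant.start_bp) & (pos <= implant.end_bp))
    if inside.size == 0:
        raise ValueError(f"implant {implant.name} covers no probes")
    return sl.start + int(inside[0]), sl.start + int(inside[-1])


def _draw_carriers(config: CohortConfig, stage: np.ndarray,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    cols = {}
    for imp in config.implants:
        flags = np.zeros(n, dtype=np.int8)
        for stage_label, freq in (("I", imp.carrier_freq_stageI),
                                  ("II", imp.carrier_freq_stageII)):
            idx = np.flatnonzero(stage == stage_label)
            if idx.size == 0:
                continue
            if config.carrier_mode == "binomial":
                flags[idx] = rng.random(idx.size) < freq
            else:
                quota = int(round(freq * idx.size))
                chosen = rng.choice(idx, size=quota, replace=False)
                flags[chosen] = 1
        cols[imp.name] = flags
    return pd.DataFrame(cols if cols else {}, index=range(n))


def _check_conflicts(config: CohortConfig, carriers: pd.DataFrame) -> None:
    imps = config.implants
    for i in range(len(imps)):
        for j in range(i + 1, len(imps)):
            a, b = imps[i], imps[j]
            if a.chromosome != b.chromosome or a.sign == b.sign:
                continue
            if a.start_bp <= b.end_bp and b.start_bp <= a.end_bp:
                both = (carriers[a.name] & carriers[b.name]).astype(bool)
                if both.any():
                    raise ValueError(
                        f"implants {a.name} and {b.name} overlap with opposite sign "
                        f"in sample(s) {list(carriers.index[both])[:3]}: ambiguous truth"
                    )


def simulate_cohort(config: CohortConfig) -> tuple[ProbeMap, RatioMatrix,
                                                   ClinicalTable, TruthRecord]:
    """Generate (probe map, log2-ratio matrix, clinical table, truth record).

    Per-probe value = sum of implanted mean_log2 over implants covering the
    probe in carrier samples, plus N(0, noise_sd). Survival times are
    exponential with hazard = baseline x prod(hazard multipliers over carried
    implants and satisfied interactions); times beyond the censoring window
    are censored there.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF]))
    probes = build_probe_map(config.probe_count, config.chromosomes)
    if config.chromosomes is not None:
        kept = tuple(i for i in config.implants if i.chromosome in config.chromosomes)
        if len(kept) < len(config.implants):
            dropped = [i.name for i in config.implants if i not in kept]
            logger.info("chromosome subset drops implants: %s", dropped)
            names = {i.name for i in kept}
            inter = tuple(x for x in config.interactions
                          if set(x.implants) <= names)
            config = config.with_(implants=kept, interactions=inter)
    n = config.n_samples
    sample_ids = [f"S{i+1:03d}" for i in range(n)]

    stage_collapsed = np.array(["I"] * config.n_stageI
                               + ["II"] * (n - config.n_stageI), dtype=object)
    n_II = n - config.n_stageI
    n_IIB = int(round(config.frac_stageIIB * n_II))
    stage_detail = np.array(
        ["I"] * config.n_stageI + ["IIA"] * (n_II - n_IIB) + ["IIB"] * n_IIB,
        dtype=object)

    carriers = _draw_carriers(config, stage_collapsed, rng)
    carriers.index = sample_ids
    _check_conflicts(config, carriers)

    implant_probes = {imp.name: _implant_probe_bounds(imp, probes)
                      for imp in config.implants}

    signal = np.zeros((n, len(probes)))
    for imp in config.implants:
        first, last = implant_probes[imp.name]
        mask = carriers[imp.name].to_numpy(dtype=bool)
        signal[np.ix_(mask, range(first, last + 1))] += imp.mean_log2
    noise = (rng.normal(0.0, config.noise_sd, size=signal.shape)
             if config.noise_sd > 0 else 0.0)
    values = signal + noise
    matrix = RatioMatrix(sample_ids=sample_ids, values=values, probes=probes)

    hazard = np.full(n, config.baseline_hazard)
    for imp in config.implants:
        hazard *= np.where(carriers[imp.name].to_numpy(dtype=bool),
                           imp.hazard_multiplier, 1.0)
    for inter in config.interactions:
        all_carried = carriers[list(inter.implants)].all(axis=1).to_numpy()
        hazard *= np.where(all_carried, inter.hazard_multiplier, 1.0)
    raw_times = rng.exponential(1.0 / hazard)
    event = (raw_times <= config.censoring_years).astype(int)
    times = np.minimum(raw_times, config.censoring_years)

    clinical_df = pd.DataFrame({
        "sample": sample_ids,
        "age_group": np.where(rng.random(n) < config.p_age_ge50, ">=50", "<50"),
        "stage": stage_detail,
        "er": np.where(rng.random(n) < config.p_er_positive, "positive", "negative"),
        "pr": np.where(rng.random(n) < config.p_pr_positive, "positive", "negative"),
        "her2": np.where(rng.random(n) < config.p_her2_positive, "positive", "negative"),
        "survival_years": np.round(times, 6),
        "event": event,
    })
    clinical = ClinicalTable(clinical_df)

    truth = TruthRecord(
        carriers=carriers,
        stage=pd.Series(stage_collapsed, index=sample_ids),
        survival_years=pd.Series(np.round(times, 6), index=sample_ids),
        event=pd.Series(event, index=sample_ids),
        hazard=pd.Series(hazard, index=sample_ids),
        implant_probes=implant_probes,
    )
    return probes, matrix, clinical, truth


def simulate_qpcr(truth: TruthRecord, implant: ImplantSpec, ct_noise_sd: float = 0.2,
                  dosage: float = 1.5, control_locus: str = "chr13q32.1",
                  n_replicates: int = 3, seed: int = 0,
                  base_ct_target: float = 30.0,
                  base_ct_control: float = 28.0) -> pd.DataFrame:
    """Ct table consistent with carrier dosage for a gain-type implant.

    Carriers' tumor-template target Ct drops by log2(dosage) cycles relative
    to non-carriers (default dosage 3/2, one extra copy over diploid);
    replicates are jittered by N(0, ct_noise_sd).
    """
    if implant.type not in ("gain", "amplification"):
        raise ValueError("qPCR simulation targets gain/amplification implants")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    if dosage <= 0:
        raise ValueError("dosage must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC7]))
    carrier = truth.carriers[implant.name]
    rows = []
    for sample, is_carrier in carrier.items():
        shift = np.log2(dosage) if is_carrier else 0.0
        means = {
            (implant.name, "tumor"): base_ct_target - shift,
            (control_locus, "tumor"): base_ct_control,
            (implant.name, "reference"): base_ct_target,
            (control_locus, "reference"): base_ct_control,
        }
        for (locus, template), mu in means.items():
            for rep in range(1, n_replicates + 1):
                ct = mu + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                rows.append({"sample": sample, "locus": locus, "template": template,
                             "replicate": rep, "ct": round(float(ct), 6)})
    return pd.DataFrame(rows)


def default_implants() -> tuple[ImplantSpec, ...]:
    """A compact implant panel with the structure the analysis expects.

    Implants are arm-scale, matching both the most common early
    breast-cancer alterations (1q gain, 8p loss) and the resolution of the
    binary rank-split procedure, whose power depends on an implant's width
    relative to its chromosome run. Two prognostic gains on 16p and 17q
    mirror the NUPR1/ERBB2 pair (their joint carriage carries the excess
    hazard), alongside a later-event 20q gain and a high-level 17q12-q21
    amplification nested in the 17q gain.
    """
    return (
        ImplantSpec("G-1q", "1", 142_000_000, 247_000_000, "gain",
                    carrier_freq_stageI=0.36, carrier_freq_stageII=0.54),
        ImplantSpec("L-8p", "8", 100_000, 43_000_000, "loss",
                    carrier_freq_stageI=0.36, carrier_freq_stageII=0.54),
        ImplantSpec("G-16p", "16", 100_000, 35_000_000, "gain",
                    carrier_freq_stageI=0.36, carrier_freq_stageII=0.41),
        ImplantSpec("G-17q", "17", 25_000_000, 79_000_000, "gain",
                    carrier_freq_stageI=0.36, carrier_freq_stageII=0.38),
        ImplantSpec("G-20q", "20", 30_000_000, 62_000_000, "gain",
                    carrier_freq_stageI=0.09, carrier_freq_stageII=0.46),
        ImplantSpec("AMP-17q12", "17", 30_000_000, 45_000_000, "amplification",
                    carrier_freq_stageI=0.18, carrier_freq_stageII=0.32),
    )


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default study conditions: 48 samples, planted markers, joint-gain hazard."""
    cfg = CohortConfig(
        implants=default_implants(),
        interactions=(InteractionSpec(("G-16p", "G-17q"), hazard_multiplier=7.31),),
        seed=seed,
    )
    return cfg.with_(**overrides) if overrides else cfg
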