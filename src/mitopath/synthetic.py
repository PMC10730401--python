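"""Synthetic input generators with recorded ground truth.

Every pipeline input can be emulated without external data: differential
expression tables with planted up/down-shifted gene sets, phase-structured
oxygen-consumption traces, pulsed calcium-indicator traces with a hard
uptake capacity, and linear-kinetic H2O2 traces.  All randomness flows from
one seeded generator per call; identical config and seed give byte-identical
serialized output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assays import InjectionSchedule, PlateTrace
from .enrichment import bh_fdr

__all__ = [
    "PlantedSet",
    "DESimConfig",
    "DESimTruth",
    "PulseModel",
    "TraceSimConfig",
    "TraceTruth",
    "CRCTruth",
    "generate_de_table",
    "generate_ocr_trace",
    "generate_crc_trace",
    "generate_h2o2_trace",
]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSet:
    """A gene set planted into a simulated contrast.

    Members may be given explicitly; otherwise ``size`` genes are sampled
    without replacement from the pool not yet claimed by another set.
    """

    name: str
    size: int = 0
    delta: float = 0.0
    direction: str = "up"
    members: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.members is None and self.size <= 0:
            raise ValueError("either explicit members or a positive size is required")


@dataclass(frozen=True)
class DESimConfig:
    n_genes: int
    null_sd: float = 0.5
    planted_sets: tuple[PlantedSet, ...] = ()
    se_per_gene: float = 0.25
    seed: int = 0
    gene_prefix: str = "gene"

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.null_sd < 0 or self.se_per_gene <= 0:
            raise ValueError("null_sd must be >= 0 and se_per_gene > 0")
        for ps in self.planted_sets:
            if ps.members is None and ps.size >= self.n_genes:
                raise ValueError(f"planted set {ps.name!r} larger than the universe")


@dataclass(frozen=True)
class DESimTruth:
    """Planted membership and direction per set, for recovery tests."""

    sets: dict[str, dict]

    def members(self, name: str) -> tuple[str, ...]:
        return tuple(self.sets[name]["members"])


def _gene_names(n: int, prefix: str) -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_de_table(cfg: DESimConfig) -> tuple[pd.DataFrame, DESimTruth]:
    """Simulate a (gene, log2fc, pvalue, padj) table with planted shifted sets.

    Null genes draw log2fc from Normal(0, null_sd); members of a planted set
    are shifted by +delta (up) or -delta (down).  The gene-level p-value is
    the two-sided normal tail of log2fc / se_per_gene and padj is BH over
    all genes.  Explicit member lists may overlap only if their directions
    agree.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes, cfg.gene_prefix)
    index = {g: i for i, g in enumerate(genes)}
    lfc = rng.normal(0.0, cfg.null_sd, size=cfg.n_genes)

    direction_of: dict[str, str] = {}
    claimed: set[int] = set()
    truth_sets: dict[str, dict] = {}
    for ps in cfg.planted_sets:
        if ps.members is not None:
            try:
                idx = np.array([index[g] for g in ps.members], dtype=int)
            except KeyError as err:
                raise ValueError(f"planted member {err} not in the simulated universe") from None
        else:
            pool = np.array(sorted(set(range(cfg.n_genes)) - claimed), dtype=int)
            if pool.size < ps.size:
                raise ValueError(f"not enough unclaimed genes for set {ps.name!r}")
            idx = rng.choice(pool, size=ps.size, replace=False)
        for i in idx:
            g = genes[i]
            prev = direction_of.get(g)
            if prev is not None and prev != ps.direction:
                raise ValueError(
                    f"gene {g!r} planted in overlapping sets with conflicting directions"
                )
            direction_of[g] = ps.direction
        claimed.update(int(i) for i in idx)
        shift = ps.delta if ps.direction == "up" else -ps.delta
        lfc[idx] += shift
        truth_sets[ps.name] = {
            "members": tuple(genes[i] for i in sorted(int(j) for j in idx)),
            "delta": ps.delta,
            "direction": ps.direction,
        }

    z = lfc / cfg.se_per_gene
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    padj = bh_fdr(pvals)
    table = pd.DataFrame(
        {"gene": genes, "log2fc": lfc, "pvalue": pvals, "padj": padj}
    )
    return table, DESimTruth(sets=truth_sets)


# ---------------------------------------------------------------------------
# plate traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseModel:
    """Calcium-pulse kinetics: jump by ``amplitude`` at each pulse, then decay
    toward baseline at ``uptake_rate`` per second while the cumulative uptake
    area (signal-units x seconds) stays below ``capacity``; once the capacity
    is exceeded decay stops and the signal accumulates."""

    amplitude: float = 10.0
    uptake_rate: float = 0.05
    capacity: float = math.inf
    n_pulses: int = 5
    pulse_interval: float = 180.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.uptake_rate < 0 or self.capacity < 0:
            raise ValueError("amplitude > 0, uptake_rate >= 0 and capacity >= 0 required")
        if self.n_pulses < 1 or self.pulse_interval <= 0:
            raise ValueError("n_pulses >= 1 and pulse_interval > 0 required")


@dataclass(frozen=True)
class TraceSimConfig:
    phase_means: tuple[tuple[str, float], ...] = ()
    cycles_per_phase: int = 6
    noise_sd: float = 0.0
    sample_interval: float = 30.0
    pulse_model: PulseModel | None = None
    seed: int = 0
    well: str = "A1"

    def __post_init__(self) -> None:
        if self.cycles_per_phase <= 0 or self.sample_interval <= 0:
            raise ValueError("cycles_per_phase and sample_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pulse_model is None and not self.phase_means:
            raise ValueError("phase_means must be non-empty")


@dataclass(frozen=True)
class TraceTruth:
    phase_means: dict[str, float]


@dataclass(frozen=True)
class CRCTruth:
    baseline: float
    amplitude: float
    uptake_rate: float
    capacity: float
    pulse_times: tuple[float, ...]


def generate_ocr_trace(
    cfg: TraceSimConfig, kind: str = "OCR_coupling"
) -> tuple[PlateTrace, InjectionSchedule, TraceTruth]:
    """Piecewise-constant phase means plus Gaussian noise, with an injection
    marked at the start of every phase after the first."""
    if not cfg.phase_means:
        raise ValueError("phase_means required for an OCR trace")
    rng = np.random.default_rng(cfg.seed)
    c, dt = cfg.cycles_per_phase, cfg.sample_interval
    labels = [lab for lab, _ in cfg.phase_means]
    if len(set(labels)) != len(labels):
        raise ValueError("phase labels must be unique")
    means = np.repeat([lvl for _, lvl in cfg.phase_means], c)
    times = dt * np.arange(means.size)
    signal = means + rng.normal(0.0, cfg.noise_sd, size=means.size)
    events = tuple((lab, float(times[i * c])) for i, lab in enumerate(labels))
    trace = PlateTrace(well=cfg.well, times=tuple(times.tolist()), signal=tuple(signal.tolist()), kind=kind)
    schedule = InjectionSchedule(events=events, kind=kind)
    return trace, schedule, TraceTruth(phase_means=dict(cfg.phase_means))


def generate_crc_trace(
    cfg: TraceSimConfig,
) -> tuple[PlateTrace, InjectionSchedule, CRCTruth]:
    """Pulsed calcium-indicator trace with exponential uptake and a hard capacity.

    The signal starts at a baseline (first phase mean if given, else 0),
    jumps by the pulse amplitude at each pulse and relaxes toward the
    baseline with rate ``uptake_rate``; relaxation stops once the cumulative
    above-baseline area taken up reaches ``capacity``.
    """
    pm = cfg.pulse_model
    if pm is None:
        raise ValueError("pulse_model required for a calcium trace")
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.sample_interval
    baseline = float(cfg.phase_means[0][1]) if cfg.phase_means else 0.0
    baseline_dur = cfg.cycles_per_phase * dt
    pulse_times = tuple(baseline_dur + i * pm.pulse_interval for i in range(pm.n_pulses))
    total_dur = baseline_dur + pm.n_pulses * pm.pulse_interval
    times = dt * np.arange(int(round(total_dur / dt)) + 1)

    signal = np.empty_like(times, dtype=float)
    level = baseline
    uptaken = 0.0
    next_pulse = 0
    k = pm.uptake_rate
    for i, t in enumerate(times):
        while next_pulse < len(pulse_times) and t >= pulse_times[next_pulse] - 1e-9:
            level += pm.amplitude
            next_pulse += 1
        signal[i] = level
        # relax toward baseline over the next step unless capacity is spent
        if k > 0 and uptaken < pm.capacity:
            decayed = baseline + (level - baseline) * math.exp(-k * dt)
            step_area = (level - baseline) * (1.0 - math.exp(-k * dt)) / k
            uptaken += step_area
            level = decayed
    signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.size)

    events = (("baseline", float(times[0])),) + tuple(
        (f"pulse{i + 1}", float(pt)) for i, pt in enumerate(pulse_times)
    )
    trace = PlateTrace(
        well=cfg.well, times=tuple(times.tolist()), signal=tuple(signal.tolist()), kind="CRC"
    )
    schedule = InjectionSchedule(events=events, kind="CRC")
    truth = CRCTruth(
        baseline=baseline,
        amplitude=pm.amplitude,
        uptake_rate=pm.uptake_rate,
        capacity=pm.capacity,
        pulse_times=pulse_times,
    )
    return trace, schedule, truth


def generate_h2o2_trace(
    slope: float,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    duration: float = 1200.0,
    interval: float = 30.0,
    seed: int = 0,
    well: str = "A1",
) -> PlateTrace:
    """Linear-kinetic fluorescence trace; *slope* is in signal units per minute."""
    if duration <= 0 or interval <= 0:
        raise ValueError("duration and interval must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    times = interval * np.arange(int(round(duration / interval)) + 1)
    signal = intercept + slope * times / 60.0 + rng.normal(0.0, noise_sd, size=times.size)
    return PlateTrace(
        well=well, times=tuple(times.tolist()), signal=tuple(signal.tolist()), kind="H2O2"
    )
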