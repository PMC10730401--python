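"""Derivations for plate-based mitochondrial functional assays.

Covers respirometry state extraction from injection-phased oxygen-consumption
traces, electron-flow complex activities, calcium retention capacity from
pulsed indicator traces, kinetic H2O2 slopes, luminescence standard-curve
inversion, and the small morphometric / two-group statistical helpers used
alongside them.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PlateTrace",
    "InjectionSchedule",
    "PhaseSummary",
    "RespStates",
    "ComplexActivities",
    "ASSAY_PHASE_LABELS",
    "segment_phases",
    "derive_resp_states",
    "derive_complex_activities",
    "crc_retention",
    "h2o2_slope",
    "atp_from_standard_curve",
    "er_aspect_ratio",
    "mann_whitney_exact",
    "effect_size",
    "mad_outlier_mask",
]

ASSAY_KINDS = ("OCR_coupling", "OCR_electron_flow", "CRC", "H2O2", "ATP_luminescence")

# phase grammar per assay kind (order of injections)
ASSAY_PHASE_LABELS: dict[str, tuple[str, ...]] = {
    "OCR_coupling": ("baseline", "ADP", "oligomycin", "FCCP", "antimycin"),
    "OCR_electron_flow": ("baseline", "rotenone", "succinate", "antimycinA", "ascTMPD"),
}


@dataclass(frozen=True)
class PlateTrace:
    """Time-stamped signal from one well."""

    well: str
    times: tuple[float, ...]  # seconds
    signal: tuple[float, ...]
    kind: str = "OCR_coupling"

    def __post_init__(self) -> None:
        if self.kind not in ASSAY_KINDS:
            raise ValueError(f"unknown assay kind {self.kind!r}")
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise ValueError("trace needs at least two samples")
        if len(self.times) != len(self.signal):
            raise ValueError("times and signal length mismatch")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.signal, dtype=float)


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered (label, time) events partitioning a trace into phases."""

    events: tuple[tuple[str, float], ...]
    kind: str = "OCR_coupling"

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("schedule needs at least one event")
        times = [t for _, t in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        grammar = ASSAY_PHASE_LABELS.get(self.kind)
        if grammar is not None:
            bad = [lab for lab, _ in self.events if lab not in grammar]
            if bad:
                raise ValueError(f"labels {bad} not valid for assay kind {self.kind!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.events)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.events)


@dataclass(frozen=True)
class PhaseSummary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class RespStates:
    """Respiratory states after residual (non-mitochondrial) subtraction."""

    state_ii: float
    state_iii: float
    state_iiiu: float
    state_ivo: float
    residual: float
    floored: tuple[str, ...] = ()

    @property
    def rcr(self) -> float:
        """Respiratory control ratio, state III / state IVo."""
        if self.state_ivo <= 0:
            return math.nan
        return self.state_iii / self.state_ivo


@dataclass(frozen=True)
class ComplexActivities:
    cx_i: float
    cx_ii: float
    cx_iii: float
    cx_iv: float
    negative: tuple[str, ...] = ()  # flagged, still reported


@dataclass(frozen=True)
class SlopeFit:
    slope_per_min: float
    stderr: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" | "normal"


@dataclass(frozen=True)
class EffectSize:
    difference: float
    sem: float


# ---------------------------------------------------------------------------
# phase segmentation and respirometry
# ---------------------------------------------------------------------------


def segment_phases(
    trace: PlateTrace, schedule: InjectionSchedule, discard_first: int = 1
) -> dict[str, PhaseSummary]:
    """Assign samples to the phase of the most recent injection and summarise.

    The first *discard_first* measurement cycles after each injection are
    dropped (mixing artifact); the opening event is treated as the
    pre-injection baseline when it starts at or before the first sample, so
    nothing is discarded there.
    """
    if discard_first < 0:
        raise ValueError("discard_first must be >= 0")
    t, y = trace.t, trace.y
    if schedule.times[0] > t[0]:
        raise ValueError("schedule must start at or before the first sample")
    if schedule.times[-1] > t[-1]:
        raise ValueError("event beyond the end of the trace")
    edges = list(schedule.times) + [math.inf]
    out: dict[str, PhaseSummary] = {}
    for i, (label, start) in enumerate(schedule.events):
        in_phase = (t >= start) & (t < edges[i + 1])
        idx = np.flatnonzero(in_phase)
        is_injection = not (i == 0 and start <= t[0])
        if is_injection and discard_first:
            idx = idx[discard_first:]
        if idx.size == 0:
            raise ValueError(f"phase {label!r} has no samples after discarding")
        vals = y[idx]
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        if label in out:
            raise ValueError(f"duplicate phase label {label!r}")
        out[label] = PhaseSummary(mean=float(np.mean(vals)), sd=sd, n=int(vals.size))
    return out


def _phase_means(summaries: Mapping[str, PhaseSummary | float]) -> dict[str, float]:
    return {
        k: (v.mean if isinstance(v, PhaseSummary) else float(v)) for k, v in summaries.items()
    }


def derive_resp_states(summaries: Mapping[str, PhaseSummary | float]) -> RespStates:
    """Respiratory states from coupling-assay phase means.

    The antimycin phase is the residual non-mitochondrial rate; every state
    is the phase mean minus this residual, floored at zero.  Mapping:
    baseline (substrate + rotenone) -> state II, ADP -> state III,
    oligomycin -> state IVo, FCCP -> state IIIu.
    """
    means = _phase_means(summaries)
    required = ASSAY_PHASE_LABELS["OCR_coupling"]
    missing = [lab for lab in required if lab not in means]
    if missing:
        raise ValueError(f"missing phases for respiratory states: {missing}")
    residual = means["antimycin"]
    mapping = {
        "state_ii": "baseline",
        "state_iii": "ADP",
        "state_ivo": "oligomycin",
        "state_iiiu": "FCCP",
    }
    values: dict[str, float] = {}
    floored: list[str] = []
    for state, phase in mapping.items():
        v = means[phase] - residual
        if v < 0:
            warnings.warn(
                f"{state}: residual exceeds phase mean ({means[phase]:.3g} < {residual:.3g}); floored at 0",
                stacklevel=2,
            )
            floored.append(state)
            v = 0.0
        values[state] = v
    return RespStates(residual=residual, floored=tuple(floored), **values)


def derive_complex_activities(summaries: Mapping[str, PhaseSummary | float]) -> ComplexActivities:
    """Electron-flow complex activities as phase differences.

    With phases P1 (substrate + uncoupler), P2 (+rotenone), P3 (+succinate),
    P4 (+antimycin A), P5 (+ascorbate/TMPD):
    CxI = P1 - P2, CxII = P3 - P2, CxIII = P3 - P4, CxIV = P5 - P4.
    Negative differences are reported but flagged.
    """
    means = _phase_means(summaries)
    required = ASSAY_PHASE_LABELS["OCR_electron_flow"]
    missing = [lab for lab in required if lab not in means]
    if missing:
        raise ValueError(f"missing phases for complex activities: {missing}")
    diffs = {
        "cx_i": means["baseline"] - means["rotenone"],
        "cx_ii": means["succinate"] - means["rotenone"],
        "cx_iii": means["succinate"] - means["antimycinA"],
        "cx_iv": means["ascTMPD"] - means["antimycinA"],
    }
    negative = tuple(k for k, v in diffs.items() if v < 0)
    if negative:
        warnings.warn(f"negative complex activities flagged: {negative}", stacklevel=2)
    return ComplexActivities(negative=negative, **diffs)


# ---------------------------------------------------------------------------
# calcium retention capacity
# ---------------------------------------------------------------------------


def crc_retention(
    trace: PlateTrace,
    pulse_times: Sequence[float],
    mode: str = "uptake",
    peak_window: float = 30.0,
) -> float:
    """Calcium retention capacity from a pulsed extramitochondrial Ca trace.

    ``uptake`` (default): per pulse, locate the post-pulse peak within
    *peak_window* seconds, then integrate (trapezoid) the deficit
    ``peak - signal(t)`` from the peak to the next pulse (or trace end),
    clipping negative contributions; the capacity is the sum over pulses.
    A flat post-pulse signal therefore scores zero.

    ``above_baseline``: literal area of the trace above the pre-pulse
    baseline within each inter-pulse window; for a pulse of amplitude A
    decaying completely at rate k this tends to the closed form A/k.
    """
    if mode not in ("uptake", "above_baseline"):
        raise ValueError(f"unknown mode {mode!r}")
    pulses = sorted(float(p) for p in pulse_times)
    if not pulses:
        raise ValueError("at least one pulse time required")
    t, y = trace.t, trace.y
    if pulses[-1] > t[-1]:
        raise ValueError("pulse after the end of the trace")
    edges = pulses + [float(t[-1])]

    baseline = math.nan
    if mode == "above_baseline":
        pre = y[t < pulses[0]]
        if pre.size == 0:
            raise ValueError("above_baseline mode needs samples before the first pulse")
        baseline = float(np.mean(pre))

    total = 0.0
    for i, (start, end) in enumerate(zip(edges[:-1], edges[1:])):
        last = i == len(edges) - 2
        # half-open window: the sample at the next pulse time has already jumped
        win = (t >= start) & ((t <= end) if last else (t < end))
        tw, yw = t[win], y[win]
        if tw.size < 2:
            continue
        if mode == "above_baseline":
            total += float(np.trapezoid(np.clip(yw - baseline, 0.0, None), tw))
            continue
        head = tw <= min(start + peak_window, end)
        peak_idx = int(np.argmax(yw[head]))
        peak = float(yw[peak_idx])
        seg_t, seg_y = tw[peak_idx:], yw[peak_idx:]
        if seg_t.size >= 2:
            total += float(np.trapezoid(np.clip(peak - seg_y, 0.0, None), seg_t))
    return total


# ---------------------------------------------------------------------------
# kinetic slopes and standard curves
# ---------------------------------------------------------------------------


def h2o2_slope(trace: PlateTrace, window: tuple[float, float] | None = None) -> SlopeFit:
    """Ordinary least-squares slope of a kinetic fluorescence trace, per minute."""
    t, y = trace.t, trace.y
    if window is not None:
        lo, hi = window
        keep = (t >= lo) & (t <= hi)
        t, y = t[keep], y[keep]
    if t.size < 2:
        raise ValueError("need at least two samples in the fitting window")
    fit = stats.linregress(t / 60.0, y)
    return SlopeFit(
        slope_per_min=float(fit.slope),
        stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def atp_from_standard_curve(
    standards: Sequence[tuple[float, float]],
    luminescence: float,
    max_extrapolation_log10: float = 0.5,
) -> float:
    """Invert a log-log luminescence standard curve for one sample.

    Fits log10(luminescence) against log10(concentration) by least squares
    and solves for the sample concentration.  Refuses to extrapolate more
    than *max_extrapolation_log10* decades beyond the standards' range.
    """
    if len(standards) < 2:
        raise ValueError("need at least two standards")
    conc = np.asarray([c for c, _ in standards], dtype=float)
    lum = np.asarray([l for _, l in standards], dtype=float)
    if np.any(conc <= 0) or np.any(lum <= 0) or luminescence <= 0:
        raise ValueError("concentrations and luminescence must be positive")
    fit = stats.linregress(np.log10(conc), np.log10(lum))
    if fit.slope == 0:
        raise ValueError("flat standard curve, cannot invert")
    log_c = (math.log10(luminescence) - fit.intercept) / fit.slope
    lo, hi = float(np.log10(conc).min()), float(np.log10(conc).max())
    if log_c < lo - max_extrapolation_log10 or log_c > hi + max_extrapolation_log10:
        raise ValueError(
            f"sample outside standard range: log10(conc)={log_c:.3g} vs [{lo:.3g}, {hi:.3g}]"
        )
    return float(10.0**log_c)


def er_aspect_ratio(major_axis: float, minor_axis: float) -> float:
    """Elongation measure: major axis divided by minor axis of a profile."""
    if minor_axis <= 0:
        raise ValueError("minor axis must be positive")
    if major_axis < minor_axis:
        raise ValueError("major axis must be >= minor axis")
    return major_axis / minor_axis


# ---------------------------------------------------------------------------
# two-group statistics
# ---------------------------------------------------------------------------


def _exact_u_distribution(ranks2: np.ndarray, n_a: int) -> np.ndarray:
    """Counts of doubled rank sums over all C(n, n_a) labelings (subset-sum DP).

    ``ranks2`` are midranks times two, hence integers even under ties.
    Returns an array ``counts`` where ``counts[s]`` is the number of subsets
    of size ``n_a`` with doubled rank sum ``s``.
    """
    total = int(ranks2.sum())
    table = np.zeros((n_a + 1, total + 1), dtype=np.int64)
    table[0, 0] = 1
    for r in ranks2:
        r = int(r)
        for size in range(n_a, 0, -1):
            if r:
                table[size, r:] += table[size - 1, :-r]
            else:
                table[size, :] += table[size - 1, :]
    return table[n_a]


def mann_whitney_exact(
    group_a: Sequence[float], group_b: Sequence[float], exact_limit: int = 25
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test, exact by enumeration for small samples.

    For ``n_a + n_b <= exact_limit`` the full permutation distribution of U
    over all labelings is computed (dynamic programming over midranks, so
    ties are handled exactly); otherwise a tie-corrected normal
    approximation with continuity correction is used.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    if n_a + n_b <= exact_limit:
        ranks2 = np.round(2 * ranks).astype(np.int64)
        counts = _exact_u_distribution(ranks2, n_a)
        total = counts.sum()
        # doubled U = doubled rank sum - n_a (n_a + 1)
        u2 = np.arange(counts.size) - n_a * (n_a + 1)
        u2_obs = int(round(2 * u_a))
        u2_mirror = 2 * n_a * n_b - u2_obs
        lo, hi = min(u2_obs, u2_mirror), max(u2_obs, u2_mirror)
        p = (counts[u2 <= lo].sum() + counts[u2 >= hi].sum()) / total
        return MannWhitneyResult(u=float(u_a), p=float(min(p, 1.0)), method="exact")

    n = n_a + n_b
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    mu = n_a * n_b / 2.0
    if sigma2 <= 0:
        return MannWhitneyResult(u=float(u_a), p=1.0, method="normal")
    z = (abs(u_a - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(u=float(u_a), p=float(p), method="normal")


def effect_size(group_a: Sequence[float], group_b: Sequence[float]) -> EffectSize:
    """Difference of group means (b minus a) with unpooled quadrature SEM."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    se_a = float(np.std(a, ddof=1) / math.sqrt(a.size)) if a.size > 1 else 0.0
    se_b = float(np.std(b, ddof=1) / math.sqrt(b.size)) if b.size > 1 else 0.0
    return EffectSize(
        difference=float(np.mean(b) - np.mean(a)),
        sem=math.hypot(se_a, se_b),
    )


def mad_outlier_mask(values: Sequence[float], threshold: float = 3.0) -> np.ndarray:
    """Optional robust outlier flag: ``|x - median| > threshold * MAD``.  Off by default everywhere."""
    x = np.asarray(list(values), dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x, dtype=bool)
    return np.abs(x - med) > threshold * mad
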