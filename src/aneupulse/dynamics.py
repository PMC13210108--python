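"""Phase-resolved signal analysis: size change, pulsation detection,
harmonic decomposition, and uncertainty-gated deformability.

The guiding principle is conservative: a dynamic finding is reported only
when it exceeds both a resolution floor and a noise-derived threshold, and
residual (non-periodic) variability is interpreted only when it clears the
minimum detectable change from repeatability analysis. Sub-threshold
signals are "not demonstrable above uncertainty", never "absent".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PhaseSeries",
    "SizeChangeVerdict",
    "GvpResult",
    "SwpResult",
    "SwpRegion",
    "QualificationRecord",
    "DecompositionResult",
    "BlandAltmanResult",
    "assess_size_change",
    "estimate_noise_sigma",
    "detect_gvp",
    "detect_swp",
    "qualify_signal",
    "fit_first_harmonic",
    "compute_mdc",
    "classify_deformability",
    "NotEvaluable",
]

# Gaussian-consistency constant for the MAD: MAD = 0.6745 * sigma.
MAD_TO_SIGMA = 0.6745


class NotEvaluable(Exception):
    """A signal excluded by reliability criteria; intentionally not scored."""


@dataclass(frozen=True)
class PhaseSeries:
    """One geometric parameter sampled at each cardiac phase.

    ``values[t]`` is the measurement at phase t (phases equally spaced over
    one R-R interval; 20 in a standard gated acquisition).
    """

    values: np.ndarray
    parameter_name: str = "V_sac"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 4:
            raise ValueError("need a 1-D series of at least 4 phases")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite values in phase series")
        object.__setattr__(self, "values", v)

    @property
    def phase_count(self) -> int:
        return len(self.values)

    @property
    def range(self) -> float:
        """Signal range ΔX = X_max - X_min."""
        return float(np.ptp(self.values))


@dataclass(frozen=True)
class SizeChangeVerdict:
    changed: bool
    direction: Literal["enlarged", "reduced", "none"]
    delta: float
    threshold: float
    mean_baseline: float
    mean_followup: float
    sd_baseline: float
    sd_followup: float


@dataclass(frozen=True)
class GvpResult:
    present: bool
    amplitude: float
    sigma_noise: float
    volume_floor: float


@dataclass(frozen=True)
class SwpRegion:
    vertices: np.ndarray
    area: float
    peak_amplitude: float


@dataclass(frozen=True)
class SwpResult:
    classification: Literal["focal", "heterogeneous", "none"]
    regions: tuple[SwpRegion, ...]
    pulsating_area_total: float
    pulsating_fraction: float
    thresholds: dict = field(default_factory=dict)


@dataclass(frozen=True)
class QualificationRecord:
    delta_x: float
    sd_noise: float
    mad: float
    snr: float
    qualified: bool


@dataclass(frozen=True)
class DecompositionResult:
    mean_level: float
    pulsation_amplitude: float
    harmonic_phase: float
    fitted: np.ndarray
    residuals: np.ndarray
    residual_mad: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    mdc: float
    sd_differences: float
    n_pairs: int


def assess_size_change(baseline: PhaseSeries, followup: PhaseSeries) -> SizeChangeVerdict:
    """Classify longitudinal size change from two phase-resolved volume series.

    The change is significant when |V_mean2 - V_mean1| exceeds twice the
    root-sum-square of the two phase-wise standard deviations (sample SD,
    n-1 denominator), i.e. the combined measurement variability of the
    two examinations.
    """
    if baseline.parameter_name != followup.parameter_name:
        raise ValueError(
            f"mismatched parameters: {baseline.parameter_name!r} vs {followup.parameter_name!r}"
        )
    m1, m2 = float(np.mean(baseline.values)), float(np.mean(followup.values))
    s1 = float(np.std(baseline.values, ddof=1))
    s2 = float(np.std(followup.values, ddof=1))
    return assess_size_change_from_summaries(m1, s1, m2, s2)


def assess_size_change_from_summaries(
    mean1: float, sd1: float, mean2: float, sd2: float
) -> SizeChangeVerdict:
    """Size-change criterion applied to printed mean +/- SD summaries."""
    delta = mean2 - mean1
    threshold = 2.0 * math.hypot(sd1, sd2)
    changed = abs(delta) > threshold
    direction = "none" if not changed else ("enlarged" if delta > 0 else "reduced")
    return SizeChangeVerdict(changed, direction, delta, threshold, mean1, mean2, sd1, sd2)


def estimate_noise_sigma(series: PhaseSeries, divisor: str = "sqrt2") -> float:
    """Robust per-phase noise SD from successive inter-phase differences.

    d_i = V_{i+1} - V_i; sigma = MAD(d) / (0.6745 * sqrt(2)). The MAD is
    taken about the median of d. First differences of independent
    equal-variance noise double the variance, hence the sqrt(2) in the
    denominator; ``divisor="literal"`` divides by 2 instead (a published
    variant of this estimator).
    """
    if series.phase_count < 5:
        raise ValueError("need at least 5 phases to difference robustly")
    d = np.diff(series.values)
    mad = float(np.median(np.abs(d - np.median(d))))
    if divisor == "sqrt2":
        return mad / (MAD_TO_SIGMA * math.sqrt(2.0))
    if divisor == "literal":
        return mad / (MAD_TO_SIGMA * 2.0)
    raise ValueError(f"unknown divisor variant {divisor!r}")


def detect_gvp(
    series: PhaseSeries,
    volume_floor: float = 3.0,
    sigma_multiple: float = 3.0,
    divisor: str = "sqrt2",
) -> GvpResult:
    """Detect global volumetric pulsation of the sac.

    The amplitude is the raw peak-to-peak excursion of the volume curve —
    no denoising or noise subtraction is applied. Pulsation is present only
    if the amplitude exceeds BOTH the resolution floor (default 3 mm^3) and
    ``sigma_multiple`` times the robust noise SD.
    """
    amplitude = series.range
    sigma = estimate_noise_sigma(series, divisor=divisor)
    present = amplitude > sigma_multiple * sigma and amplitude > volume_floor
    return GvpResult(bool(present), amplitude, sigma, volume_floor)


DEFAULT_SWP_THRESHOLDS = {
    "amp": 0.3,        # mm, per-vertex displacement amplitude
    "area": 5.0,       # mm^2, minimum region area
    "fraction": 0.05,  # of total sac surface area
    "hetero_fraction": 0.20,
}


def detect_swp(
    amplitude: np.ndarray,
    triangles: np.ndarray,
    vertex_areas: np.ndarray,
    sac_area: float,
    thresholds: dict | None = None,
) -> SwpResult:
    """Detect and classify spatial wall pulsation on the sac surface.

    Vertices whose displacement amplitude exceeds the amplitude threshold
    are grouped into edge-connected components; components whose
    (barycentric-lumped) area reaches the area floor are pulsating regions.
    The total pulsating area as a fraction of the sac surface decides the
    class: none (< 5%), focal (5-20%), heterogeneous (>= 20%).
    """
    thr = dict(DEFAULT_SWP_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    if sac_area <= 0:
        raise ValueError("sac_area must be positive")
    amplitude = np.asarray(amplitude, dtype=float)
    vertex_areas = np.asarray(vertex_areas, dtype=float)
    active = amplitude > thr["amp"]
    regions: list[SwpRegion] = []
    if active.any():
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components

        nv = len(amplitude)
        tri = np.asarray(triangles)
        edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        keep = active[edges[:, 0]] & active[edges[:, 1]]
        edges = edges[keep]
        adj = sp.coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(nv, nv)
        )
        n_comp, labels = connected_components(adj + adj.T, directed=False)
        for lbl in range(n_comp):
            members = np.flatnonzero((labels == lbl) & active)
            if len(members) == 0:
                continue
            area = float(vertex_areas[members].sum())
            if area >= thr["area"]:
                regions.append(
                    SwpRegion(members, area, float(amplitude[members].max()))
                )
    total = sum(r.area for r in regions)
    fraction = total / sac_area
    if not regions or fraction < thr["fraction"]:
        cls = "none"
    elif fraction < thr["hetero_fraction"]:
        cls = "focal"
    else:
        cls = "heterogeneous"
    return SwpResult(cls, tuple(regions), total, fraction, thr)


def qualify_signal(
    series: PhaseSeries, min_snr: float = 3.0, divisor: str = "sqrt2"
) -> QualificationRecord:
    """Screen a phase-resolved signal for dynamic validity.

    SNR = ΔX / SD_noise with the robust first-difference noise estimate.
    A noiseless but varying signal gets SNR = +inf and qualifies; a flat
    signal (ΔX = 0) never qualifies.
    """
    delta_x = series.range
    sd_noise = estimate_noise_sigma(series, divisor=divisor)
    d = np.diff(series.values)
    mad = float(np.median(np.abs(d - np.median(d))))
    if delta_x == 0:
        snr = 0.0
    elif sd_noise == 0:
        snr = math.inf
    else:
        snr = delta_x / sd_noise
    qualified = delta_x > 0 and snr >= min_snr
    return QualificationRecord(delta_x, sd_noise, mad, snr, qualified)


def fit_first_harmonic(series: PhaseSeries) -> DecompositionResult:
    """Least-squares first-harmonic fit X(t) = mu + a sin(wt) + b cos(wt).

    With equally spaced phases over one cycle (w = 2*pi/n) the design is
    orthogonal, so the amplitude sqrt(a^2 + b^2) equals the magnitude of
    the first Fourier coefficient. Residuals carry everything the single
    harmonic cannot represent; their MAD (about the residual median) is
    the conservative variability summary.
    """
    x = series.values
    n = series.phase_count
    t = np.arange(n)
    w = 2.0 * math.pi / n
    design = np.column_stack([np.ones(n), np.sin(w * t), np.cos(w * t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    mu, a, b = (float(c) for c in coef)
    fitted = design @ coef
    residuals = x - fitted
    amplitude = math.hypot(a, b)
    # a sin + b cos = amplitude * sin(wt + phase)
    phase = math.atan2(b, a)
    residual_mad = float(np.median(np.abs(residuals - np.median(residuals))))
    return DecompositionResult(mu, amplitude, phase, fitted, residuals, residual_mad)


def compute_mdc(pairs: Sequence[tuple[float, float]] | np.ndarray) -> BlandAltmanResult:
    """Bland-Altman repeatability: bias, limits of agreement, and MDC.

    MDC = 1.96 * SD(differences) — the smallest change in a single
    measurement distinguishable from repeat-measurement error at the 95%
    level (MDC95).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (m1, m2) pairs")
    diff = arr[:, 1] - arr[:, 0]
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    mdc = 1.96 * sd
    return BlandAltmanResult(bias, bias - mdc, bias + mdc, mdc, sd, arr.shape[0])


def classify_deformability(
    decomp: DecompositionResult,
    qualification: QualificationRecord,
    mdc: float,
    noise_floor: float = 0.0,
) -> bool:
    """Decide whether residual variability counts as wall deformability.

    True only when the residual MAD exceeds BOTH the MDC and any separate
    noise floor (their maximum). Signals that failed qualification are not
    scored at all: they raise :class:`NotEvaluable`, mirroring intentional
    exclusion by reliability criteria rather than a negative finding.
    """
    if not qualification.qualified:
        raise NotEvaluable(
            "signal failed dynamic qualification; deformability not evaluable"
        )
    return decomp.residual_mad > max(mdc, noise_floor)
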