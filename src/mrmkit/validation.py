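"""Method-validation statistics: linearity, LOD/LOQ, reproducibility, carry-over.

Linearity is an ordinary least-squares fit of measured versus nominal
concentration with r² the squared Pearson correlation.  LOD and LOQ come
from the empirical signal-to-noise approach: the concentrations at which the
interpolated S/N curve crosses 3 and 10 respectively, so under a
proportional (through-origin) S/N model LOQ/LOD = 10/3 exactly.

Reproducibility follows a (days x samples x replicate injections) block:

* intra-sample CV  — mean over (day, sample) cells of the CV across the
  replicate injections of that cell;
* inter-sample CV  — mean over days of the CV across the sample means
  within the day;
* inter-day CV     — CV across the day means.

CV is always 100 x SD/mean with the n-1 (sample) standard deviation.  The
default acceptance rule is CV < 25% at the lowest level and < 20% above it;
the stricter chromatographic-run-only FDA preset (20%/15%) is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .peaks import Peak

__all__ = [
    "CalibrationSeries",
    "CalibrationResult",
    "ReproducibilityDesign",
    "LevelCV",
    "CVReport",
    "SnrLimits",
    "CarryoverResult",
    "StabilityResult",
    "CV_THRESHOLDS",
    "fit_calibration",
    "lod_loq_from_snr",
    "cv_report",
    "carryover_check",
    "stability_check",
]

#: acceptance presets: (lowest level %, other levels %)
CV_THRESHOLDS = {"default": (25.0, 20.0), "fda": (20.0, 15.0)}


@dataclass
class CalibrationSeries:
    """Replicated measurements at increasing nominal concentrations."""

    protein: str
    levels: List[Tuple[float, Sequence[float]]]  # (nominal ng/ml, measured values)
    blank_response: float = 0.0

    def __post_init__(self):
        nominals = [lvl for lvl, _ in self.levels]
        if any(c <= 0 for c in nominals):
            raise ValueError("nominal concentrations must be strictly positive")
        if sorted(nominals) != nominals or len(set(nominals)) != len(nominals):
            raise ValueError("nominal concentrations must be strictly increasing")


@dataclass
class CalibrationResult:
    protein: str
    slope: float
    intercept: float
    r2: float
    lod: Optional[float] = None
    loq: Optional[float] = None


def fit_calibration(series: CalibrationSeries) -> CalibrationResult:
    """OLS of measured on nominal concentration; r² of the calibration line."""
    if len(series.levels) < 3:
        raise ValueError("calibration needs at least 3 distinct levels")
    x, y = [], []
    for nominal, measured in series.levels:
        for m in measured:
            x.append(nominal)
            y.append(m)
    x, y = np.asarray(x), np.asarray(y)
    if np.allclose(x, x[0]):
        raise ValueError("nominal concentrations have zero variance")
    fit = stats.linregress(x, y)
    return CalibrationResult(
        protein=series.protein,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )


@dataclass
class SnrLimits:
    """LOD/LOQ from the S/N-versus-concentration curve.

    ``lod``/``loq`` are None when the curve never reaches the threshold; in
    that case the corresponding ``*_censored_above`` carries the highest
    tested concentration and :meth:`describe` prints e.g. ``"> 100"``.
    """

    lod: Optional[float]
    loq: Optional[float]
    lod_censored_above: Optional[float] = None
    loq_censored_above: Optional[float] = None
    monotonic: bool = True

    def describe(self) -> str:
        def fmt(value, censored):
            return f"> {censored:g}" if value is None else f"{value:.3g}"

        return (
            f"LOD {fmt(self.lod, self.lod_censored_above)} ng/ml, "
            f"LOQ {fmt(self.loq, self.loq_censored_above)} ng/ml"
        )


def _crossing(concs: np.ndarray, snrs: np.ndarray, threshold: float) -> Optional[float]:
    """Concentration at which the piecewise-linear S/N curve reaches the
    threshold; linear extrapolation below the lowest point when the curve
    starts above it."""
    if snrs.max() < threshold:
        return None
    if snrs[0] >= threshold:
        # extrapolate through the first two points, clipped at 0
        if len(concs) >= 2 and snrs[1] != snrs[0]:
            slope = (snrs[1] - snrs[0]) / (concs[1] - concs[0])
            if slope > 0:
                return max(0.0, float(concs[0] - (snrs[0] - threshold) / slope))
        return float(concs[0])
    for i in range(len(concs) - 1):
        s0, s1 = snrs[i], snrs[i + 1]
        if s0 < threshold <= s1:
            frac = (threshold - s0) / (s1 - s0)
            return float(concs[i] + frac * (concs[i + 1] - concs[i]))
    return None


def lod_loq_from_snr(
    snr_by_conc: Sequence[Tuple[float, float]],
    lod_snr: float = 3.0,
    loq_snr: float = 10.0,
) -> SnrLimits:
    """LOD and LOQ as the concentrations where interpolated S/N crosses the
    detection (default 3) and quantification (default 10) thresholds."""
    if loq_snr <= lod_snr:
        raise ValueError("LOQ S/N threshold must exceed the LOD threshold")
    if len(snr_by_conc) < 2:
        raise ValueError("need at least 2 (concentration, S/N) points")
    pairs = sorted(snr_by_conc)
    concs = np.asarray([c for c, _ in pairs], dtype=float)
    snrs = np.asarray([s for _, s in pairs], dtype=float)
    monotonic = bool(np.all(np.diff(snrs) >= 0))
    lod = _crossing(concs, snrs, lod_snr)
    loq = _crossing(concs, snrs, loq_snr)
    return SnrLimits(
        lod=lod,
        loq=loq,
        lod_censored_above=None if lod is not None else float(concs[-1]),
        loq_censored_above=None if loq is not None else float(concs[-1]),
        monotonic=monotonic,
    )


@dataclass
class ReproducibilityDesign:
    """Measured concentrations per level as a (days, samples, replicates)
    array; the canonical protocol is 3 x 3 x 3."""

    protein: str
    levels: Dict[float, np.ndarray]

    def __post_init__(self):
        for conc, block in self.levels.items():
            block = np.asarray(block, dtype=float)
            if block.ndim != 3:
                raise ValueError(
                    f"level {conc}: block must be (days, samples, replicates)"
                )
            if np.isnan(block).any():
                raise ValueError(f"level {conc}: block has missing cells")
            self.levels[conc] = block


def _cv(values: np.ndarray) -> float:
    return 100.0 * float(np.std(values, ddof=1)) / float(np.mean(values))


@dataclass
class LevelCV:
    nominal_conc: float
    intra_sample_cv: float
    inter_sample_cv: float
    inter_day_cv: float
    threshold: float
    passed: bool


@dataclass
class CVReport:
    protein: str
    levels: List[LevelCV]

    @property
    def all_passed(self) -> bool:
        return all(lv.passed for lv in self.levels)


def cv_report(
    design: ReproducibilityDesign, thresholds: Tuple[float, float] = CV_THRESHOLDS["default"]
) -> CVReport:
    """Intra-sample, inter-sample and inter-day CVs with pass flags.

    ``thresholds = (lowest-level %, other-levels %)``.
    """
    low_thr, other_thr = thresholds
    concs = sorted(design.levels)
    out = []
    for conc in concs:
        block = design.levels[conc]
        if np.mean(block) <= 0:
            raise ValueError(f"level {conc}: non-positive mean response")
        days, samples, _ = block.shape
        intra = float(
            np.mean([_cv(block[d, s]) for d in range(days) for s in range(samples)])
        )
        sample_means = block.mean(axis=2)  # (days, samples)
        inter_sample = float(np.mean([_cv(sample_means[d]) for d in range(days)]))
        day_means = block.mean(axis=(1, 2))
        inter_day = _cv(day_means)
        threshold = low_thr if conc == concs[0] else other_thr
        passed = max(intra, inter_sample, inter_day) < threshold
        out.append(
            LevelCV(
                nominal_conc=conc,
                intra_sample_cv=intra,
                inter_sample_cv=inter_sample,
                inter_day_cv=inter_day,
                threshold=threshold,
                passed=passed,
            )
        )
    return CVReport(protein=design.protein, levels=out)


@dataclass
class StabilityResult:
    status: str  # 'pass' | 'fail'
    max_drift: float  # largest relative deviation from the first injection

    def __bool__(self) -> bool:
        return self.status == "pass"


def stability_check(
    control_responses: Sequence[float], max_relative_drift: float = 0.2
) -> StabilityResult:
    """Per-run control-sample drift check.

    The same spiked control is injected before each run; stability holds
    when every response stays within ``max_relative_drift`` of the first
    injection.  No numeric acceptance criterion is standard for this check,
    so the 20% default is a configurable repository choice.
    """
    responses = np.asarray(control_responses, dtype=float)
    if responses.size < 2:
        raise ValueError("need at least 2 control injections")
    if responses[0] <= 0:
        raise ValueError("first control response must be positive")
    drift = float(np.max(np.abs(responses / responses[0] - 1.0)))
    status = "pass" if drift <= max_relative_drift * (1 + 1e-12) else "fail"
    return StabilityResult(status=status, max_drift=drift)


@dataclass
class CarryoverResult:
    status: str  # 'pass' | 'fail' | 'indeterminate'
    blank_area: Optional[float]
    limit: float

    def __bool__(self) -> bool:
        return self.status == "pass"


def carryover_check(
    high_standard_peak: Peak,
    following_blank_peak: Optional[Peak],
    loq_area: float,
    fraction: float = 0.2,
) -> CarryoverResult:
    """A blank injected after the highest standard must show at most
    ``fraction`` of the LOQ-level area (boundary inclusive)."""
    if not high_standard_peak.found:
        raise ValueError("high standard peak was not found; carry-over undefined")
    limit = fraction * loq_area
    if following_blank_peak is None:
        return CarryoverResult("indeterminate", None, limit)
    blank_area = following_blank_peak.area if following_blank_peak.found else 0.0
    status = "pass" if blank_area <= limit * (1 + 1e-12) else "fail"
    return CarryoverResult(status, blank_area, limit)
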