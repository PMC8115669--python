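"""Chromatographic peak integration, QC checks and heavy/light quantification.

The peak model is deliberately simple and deterministic: within a retention
window around the expected RT, the baseline is the median intensity of the
flanking windows, the noise is the standard deviation there, the apex is the
maximum baseline-subtracted intensity, and the area is the trapezoidal
integral over the contiguous region around the apex that stays above
baseline + 1 noise SD.  A peak counts as found when its apex clears 3 noise
SDs (the detection criterion underlying LOD).

Relative quantification is classic isotope dilution: the ratio of the native
quantifier area to the co-eluting stable-isotope-labelled quantifier area,
multiplied by the spiked heavy-peptide concentration (default 50 ng/ml).
Because the heavy peptide is spiked after digestion while the native peptide
must be released by trypsin, a bovine serum albumin (BSA) digest control is
carried through every sample; its response, divided by a batch reference,
gives the digest-efficiency factor that normalizes all ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assay_design import TransitionDef

__all__ = [
    "Trace",
    "Peak",
    "SampleQuant",
    "CheckResult",
    "TraceWindowError",
    "integrate_peak",
    "snr",
    "coelution_check",
    "qualifier_ratio_check",
    "bsa_normalize",
    "quantify_sample",
    "quantify_batch",
    "BSA_CONTROL",
]

#: accession used for the digestion-efficiency control protein
BSA_CONTROL = "BSA"

_REL_EPS = 1e-12


class TraceWindowError(ValueError):
    """The expected RT (plus tolerance) does not fit inside the trace."""


@dataclass
class Trace:
    """A time-intensity chromatogram for one transition in one sample."""

    sample_id: str
    transition_id: str
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have the same length")
        if self.time.size < 20:
            raise ValueError("trace needs at least 20 points")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("trace time must be strictly increasing")
        if steps.max() / steps.min() >= 2:
            raise ValueError("trace sampling is too uneven (max/min step >= 2)")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass
class Peak:
    """An integrated chromatographic peak with its noise context."""

    apex_rt: float
    apex_height: float
    area: float
    baseline_level: float
    noise_sd: float
    snr: float
    found: bool


def integrate_peak(trace: Trace, expected_rt: float, rt_tolerance: float = 0.3) -> Peak:
    """Integrate the peak nearest ``expected_rt`` within ``+- rt_tolerance``.

    Baseline and noise come from one tolerance-width flanking window on each
    side of the search window; when both flanks fall outside the trace the
    noise is estimated from the lower quartile of the whole trace.  Raises
    :class:`TraceWindowError` when the expected RT lies outside the trace.
    """
    t, y = trace.time, trace.intensity
    if not (t[0] <= expected_rt <= t[-1]):
        raise TraceWindowError(
            f"expected RT {expected_rt} outside trace range [{t[0]}, {t[-1]}] "
            f"for {trace.transition_id!r}"
        )
    lo, hi = expected_rt - rt_tolerance, expected_rt + rt_tolerance
    window = (t >= lo) & (t <= hi)
    flank = ((t >= lo - rt_tolerance) & (t < lo)) | ((t > hi) & (t <= hi + rt_tolerance))
    flank_y = y[flank]
    if flank_y.size >= 2:
        baseline = float(np.median(flank_y))
        noise_sd = float(np.std(flank_y, ddof=1))
    else:
        # degenerate geometry: estimate from the quiet part of the whole trace
        q25 = np.quantile(y, 0.25)
        quiet = y[y <= q25]
        baseline = float(np.median(quiet)) if quiet.size else 0.0
        noise_sd = float(np.std(quiet, ddof=1)) if quiet.size >= 2 else 0.0
    sub = y - baseline
    win_idx = np.flatnonzero(window)
    if win_idx.size == 0:
        raise TraceWindowError("search window contains no points")
    apex_local = int(np.argmax(sub[win_idx]))
    apex_i = int(win_idx[apex_local])
    apex_height = float(sub[apex_i])
    apex_rt = float(t[apex_i])
    # peak region: contiguous points above baseline + 1 noise SD around the apex
    above = sub > noise_sd
    left = apex_i
    while left > 0 and above[left - 1]:
        left -= 1
    right = apex_i
    while right < len(t) - 1 and above[right + 1]:
        right += 1
    if right > left and apex_height > 0:
        area = float(np.trapezoid(sub[left : right + 1], t[left : right + 1]))
    else:
        area = 0.0
    found = apex_height > 0 and apex_height >= 3 * noise_sd
    value = apex_height / max(noise_sd, 1.0)
    return Peak(
        apex_rt=apex_rt,
        apex_height=apex_height,
        area=max(area, 0.0),
        baseline_level=baseline,
        noise_sd=noise_sd,
        snr=value,
        found=found,
    )


def snr(peak: Peak) -> float:
    """Signal-to-noise ratio: apex height over flanking-noise SD.

    The noise SD is floored at 1 count so that a noiseless trace yields a
    finite ratio.  Undefined for peaks that were not found.
    """
    if not peak.found:
        raise ValueError("S/N is undefined for a peak that was not found")
    return peak.apex_height / max(peak.noise_sd, 1.0)


@dataclass
class CheckResult:
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


def coelution_check(
    native_peak: Optional[Peak],
    labelled_peak: Optional[Peak],
    rt_delta_max: float = 0.1,
) -> CheckResult:
    """Native and labelled apexes must sit within ``rt_delta_max`` minutes."""
    if native_peak is None or not native_peak.found:
        return CheckResult(False, "native peak not found")
    if labelled_peak is None or not labelled_peak.found:
        return CheckResult(False, "labelled peak not found")
    delta = abs(native_peak.apex_rt - labelled_peak.apex_rt)
    if delta <= rt_delta_max * (1 + _REL_EPS):
        return CheckResult(True)
    return CheckResult(False, f"apex RT difference {delta:.3f} min > {rt_delta_max}")


def qualifier_ratio_check(
    quantifier_area: float,
    qualifier_area: float,
    reference_ratio: float,
    tolerance_fraction: float = 0.30,
) -> CheckResult:
    """Quantifier/qualifier area ratio must match the reference within the
    tolerance band (inclusive boundaries)."""
    if reference_ratio <= 0:
        raise ValueError("reference_ratio must be positive")
    if qualifier_area <= 0:
        return CheckResult(False, "qualifier area is zero")
    ratio = quantifier_area / qualifier_area
    lo = reference_ratio * (1 - tolerance_fraction) * (1 - _REL_EPS)
    hi = reference_ratio * (1 + tolerance_fraction) * (1 + _REL_EPS)
    if lo <= ratio <= hi:
        return CheckResult(True)
    return CheckResult(
        False, f"area ratio {ratio:.3f} outside {reference_ratio} +- "
        f"{tolerance_fraction * 100:.0f}%"
    )


def bsa_normalize(
    responses_by_protein: Mapping[str, float],
    bsa_response: float,
    bsa_reference_response: float,
    failure_fraction: float = 0.2,
) -> Tuple[Dict[str, float], float, bool]:
    """Divide responses by the BSA digest-efficiency factor.

    ``bsa_factor = bsa_response / bsa_reference_response``; a factor below
    ``failure_fraction`` (or a non-positive BSA response) marks a digest
    failure, in which case the responses are returned unchanged and the
    sample should be excluded from quantification.
    Returns (normalized responses, bsa_factor, digest_failure).
    """
    if bsa_reference_response <= 0:
        raise ValueError("bsa_reference_response must be positive")
    if bsa_response <= 0:
        return dict(responses_by_protein), 0.0, True
    factor = bsa_response / bsa_reference_response
    if factor < failure_fraction:
        return dict(responses_by_protein), factor, True
    return (
        {k: v / factor for k, v in responses_by_protein.items()},
        factor,
        False,
    )


@dataclass
class SampleQuant:
    """Per-protein relative concentration in one sample."""

    sample_id: str
    protein: str
    raw_ratio: float = float("nan")
    spike_conc: float = 50.0
    relative_conc: float = float("nan")
    bsa_factor: float = 1.0
    snr: float = float("nan")
    qc_flags: set = field(default_factory=set)


def _group_transitions(transitions: Sequence[TransitionDef]):
    """Group by protein into {role: {label: TransitionDef}} (first peptide
    carrying each role wins; qualifiers may live on a second peptide)."""
    groups: Dict[str, Dict[str, Dict[str, TransitionDef]]] = {}
    for tr in transitions:
        groups.setdefault(tr.protein, {}).setdefault(tr.role, {}).setdefault(
            tr.label, tr
        )
    return groups


def _integrate(traces, tr: Optional[TransitionDef], rt_tolerance) -> Optional[Peak]:
    if tr is None:
        return None
    trace = traces.get(tr.tid)
    if trace is None:
        return None
    try:
        return integrate_peak(trace, tr.rt_min, rt_tolerance)
    except TraceWindowError:
        return None


def quantify_sample(
    traces: Mapping[str, Trace],
    transitions: Sequence[TransitionDef],
    spike_conc: float = 50.0,
    bsa_reference_response: Optional[float] = None,
    rt_tolerance: float = 0.3,
    rt_delta_max: float = 0.1,
    qualifier_reference_ratios: Optional[Mapping[str, float]] = None,
    qualifier_tolerance: float = 0.30,
    digest_failure_fraction: float = 0.2,
    loq_by_protein: Optional[Mapping[str, float]] = None,
) -> List[SampleQuant]:
    """Quantify every protein of a sample from its transition traces.

    Per protein the native and labelled quantifier traces are integrated,
    co-elution and (when present) qualifier-ratio QC are applied, and
    ``relative_conc = native/labelled area ratio x spike_conc / bsa_factor``.
    QC failures are recorded as flags on the result, never silently dropped.
    The BSA control protein is quantified like the rest; its ratio against
    ``bsa_reference_response`` (default 1.0) gives the digest factor applied
    to all other proteins.
    """
    groups = _group_transitions(transitions)
    sample_id = next(iter(traces.values())).sample_id if traces else "?"
    results: Dict[str, SampleQuant] = {}
    ratios: Dict[str, float] = {}
    for protein, roles in groups.items():
        quant = roles.get("quantifier", {})
        sq = SampleQuant(sample_id=sample_id, protein=protein, spike_conc=spike_conc)
        native_tr, labelled_tr = quant.get("native"), quant.get("labelled")
        native = _integrate(traces, native_tr, rt_tolerance)
        labelled = _integrate(traces, labelled_tr, rt_tolerance)
        if native_tr is None or labelled_tr is None or (
            native_tr.tid not in traces or labelled_tr.tid not in traces
        ):
            sq.qc_flags.add("missing_trace")
        if native is None or labelled is None:
            sq.qc_flags.add("missing_trace")
            results[protein] = sq
            continue
        if not coelution_check(native, labelled, rt_delta_max):
            sq.qc_flags.add("coelution_fail")
        qual = roles.get("qualifier", {})
        qual_native = _integrate(traces, qual.get("native"), rt_tolerance)
        if qual_native is not None and qualifier_reference_ratios is not None:
            ref = qualifier_reference_ratios.get(protein)
            if ref is not None and not qualifier_ratio_check(
                native.area, qual_native.area, ref, qualifier_tolerance
            ):
                sq.qc_flags.add("qualifier_ratio_fail")
        if labelled.found and labelled.area > 0:
            sq.raw_ratio = native.area / labelled.area
            sq.snr = native.snr
            ratios[protein] = sq.raw_ratio
        else:
            sq.qc_flags.add("missing_trace")
        results[protein] = sq

    bsa_ratio = ratios.get(BSA_CONTROL)
    reference = bsa_reference_response if bsa_reference_response is not None else 1.0
    bsa_factor, digest_failure = 1.0, False
    if bsa_ratio is not None:
        analyte_ratios = {p: r for p, r in ratios.items() if p != BSA_CONTROL}
        normalized, bsa_factor, digest_failure = bsa_normalize(
            analyte_ratios, bsa_ratio, reference, digest_failure_fraction
        )
    for protein, sq in results.items():
        sq.bsa_factor = bsa_factor
        if digest_failure:
            sq.qc_flags.add("digest_failure")
        blocking = sq.qc_flags & {"missing_trace", "digest_failure"}
        if not np.isnan(sq.raw_ratio) and not blocking:
            divisor = bsa_factor if (bsa_ratio is not None and protein != BSA_CONTROL) else 1.0
            sq.relative_conc = sq.raw_ratio * spike_conc / divisor
            loq = (loq_by_protein or {}).get(protein)
            if loq is not None and sq.relative_conc < loq:
                sq.qc_flags.add("below_loq")
    return list(results.values())


def quantify_batch(
    traces_by_sample: Mapping[str, Mapping[str, Trace]],
    transitions: Sequence[TransitionDef],
    spike_conc: float = 50.0,
    bsa_reference_response: Optional[float] = None,
    **kwargs,
) -> pd.DataFrame:
    """Quantify a batch of samples with a shared BSA reference.

    When ``bsa_reference_response`` is not given it defaults to the batch
    median of the per-sample BSA quantifier ratios (the digest control is
    spiked identically in every sample, so its median response is the
    natural per-batch reference).  Returns a tidy DataFrame.
    """
    if bsa_reference_response is None:
        groups = _group_transitions(transitions)
        bsa = groups.get(BSA_CONTROL, {}).get("quantifier", {})
        ratios = []
        rt_tol = kwargs.get("rt_tolerance", 0.3)
        if "native" in bsa and "labelled" in bsa:
            for traces in traces_by_sample.values():
                native = _integrate(traces, bsa["native"], rt_tol)
                labelled = _integrate(traces, bsa["labelled"], rt_tol)
                if (
                    native is not None and labelled is not None
                    and labelled.found and labelled.area > 0
                ):
                    ratios.append(native.area / labelled.area)
        positive = [r for r in ratios if r > 0]
        bsa_reference_response = float(np.median(positive)) if positive else 1.0
    rows = []
    for sample_id, traces in traces_by_sample.items():
        for sq in quantify_sample(
            traces,
            transitions,
            spike_conc=spike_conc,
            bsa_reference_response=bsa_reference_response,
            **kwargs,
        ):
            rows.append(
                {
                    "sample_id": sample_id,
                    "protein": sq.protein,
                    "relative_conc_ng_ml": sq.relative_conc,
                    "raw_ratio": sq.raw_ratio,
                    "bsa_factor": sq.bsa_factor,
                    "snr": sq.snr,
                    "qc_flags": ";".join(sorted(sq.qc_flags)),
                }
            )
    return pd.DataFrame(rows)
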