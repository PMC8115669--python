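"""Synthetic MRM chromatograms and synthetic urine cohorts.

Chromatograms are Gaussian elution peaks on a noisy baseline: the peak area
is ``response_per_conc x concentration`` perturbed by a multiplicative CV,
the apex sits at the transition's expected RT plus a small shared jitter
(native and labelled partners of a peptide always co-elute), and additive
Gaussian point noise rides on a constant baseline.  Labelled-partner traces
are always generated at the spike-equivalent concentration (50 ng/ml), and a
digest-efficiency factor scales every *native* (digested) peak, including
the BSA control — which is exactly why BSA division-normalization removes it.

Cohorts are drawn from a latent-factor model on the log10 scale: every
urinary analyte loads negatively on a shared diuresis factor D (dilution),
LMW proteins additionally on tubular-reabsorption failure T, HSA on
glomerular leak G, and CC16/OPN on an airway signal S.  The shared -D
loading is the mechanism that makes division-by-creatinine overcorrect
analytes whose diuresis loading differs from creatinine's, reproducing the
negative residual correlation that motivates regression-based adjustment.
Latent factors are returned alongside the concentrations for
parameter-recovery tests but are never fed to the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .assay_design import TransitionDef
from .peaks import BSA_CONTROL, Trace

__all__ = [
    "ChromSimParams",
    "CohortParams",
    "ValidationSet",
    "simulate_chromatogram",
    "simulate_sample",
    "simulate_cohort",
    "cohort_population_correlation",
    "simulate_reproducibility_values",
    "simulate_validation_set",
]

SPIKE_CONC = 50.0  # ng/ml of each stable-isotope-labelled peptide


@dataclass(frozen=True)
class ChromSimParams:
    """Signal model for one simulated transition trace.

    Defaults describe a well-behaved triple-quadrupole acquisition: 5
    counts-min of area per ng/ml, 0.05 min (3 s) peak sigma, a 50-count
    baseline with 5 counts of RMS noise, 5% run-to-run response CV and
    0.01 min RT jitter at 100 points/min sampling.
    """

    response_per_conc: float = 5.0  # counts*min per ng/ml
    peak_sigma: float = 0.05  # min
    baseline_level: float = 50.0  # counts
    noise_sd: float = 5.0  # counts
    multiplicative_cv: float = 0.05
    rt_jitter_sd: float = 0.01  # min
    sampling_interval: float = 0.01  # min
    window_halfwidth: float = 1.0  # min of trace either side of expected RT
    qualifier_response_fraction: float = 0.5

    def __post_init__(self):
        for name in (
            "response_per_conc", "peak_sigma", "baseline_level", "noise_sd",
            "multiplicative_cv", "rt_jitter_sd", "sampling_interval",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.peak_sigma < 3 * self.sampling_interval:
            raise ValueError("peak_sigma must be >= 3 sampling intervals")


def _gaussian_trace(
    transition: TransitionDef,
    area: float,
    rt_shift: float,
    params: ChromSimParams,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> Trace:
    halfw = params.window_halfwidth
    n = int(round(2 * halfw / params.sampling_interval)) + 1
    t = transition.rt_min - halfw + params.sampling_interval * np.arange(n)
    y = np.full(n, params.baseline_level, dtype=float)
    if area > 0:
        apex_rt = transition.rt_min + rt_shift
        amp = area / (params.peak_sigma * np.sqrt(2 * np.pi))
        y += amp * np.exp(-0.5 * ((t - apex_rt) / params.peak_sigma) ** 2)
    if params.noise_sd > 0:
        y += rng.normal(0.0, params.noise_sd, size=n)
    np.maximum(y, 0.0, out=y)
    return Trace(sample_id=sample_id, transition_id=transition.tid, time=t, intensity=y)


def simulate_chromatogram(
    transition: TransitionDef,
    true_conc: float,
    params: ChromSimParams = ChromSimParams(),
    seed: int = 0,
    sample_id: str = "sim",
) -> Trace:
    """One trace: Gaussian peak with area ``response_per_conc x true_conc``
    (multiplicatively perturbed), RT jitter, baseline and point noise.
    Deterministic under a fixed seed; ``true_conc = 0`` yields baseline+noise
    only."""
    rng = np.random.default_rng(seed)
    rt_shift = rng.normal(0.0, params.rt_jitter_sd) if params.rt_jitter_sd > 0 else 0.0
    area = params.response_per_conc * true_conc
    if params.multiplicative_cv > 0 and area > 0:
        area *= 1.0 + params.multiplicative_cv * rng.normal()
    return _gaussian_trace(transition, max(area, 0.0), rt_shift, params, rng, sample_id)


def simulate_sample(
    transitions: Sequence[TransitionDef],
    conc_by_protein: Mapping[str, float],
    params: ChromSimParams = ChromSimParams(),
    seed: int = 0,
    sample_id: str = "sim",
    digest_efficiency: float = 1.0,
    spike_conc: float = SPIKE_CONC,
) -> Dict[str, Trace]:
    """Traces for every transition of one sample, keyed by transition id.

    Native peaks scale with the protein concentration times the digest
    efficiency (digestion releases the native peptide); labelled peaks are
    post-digest spikes at ``spike_conc`` and are unaffected.  The BSA control
    is treated as a digested protein at spike-equivalent concentration, so
    its native/labelled ratio reports the digest efficiency.  Qualifier
    transitions respond at ``params.qualifier_response_fraction`` of the
    quantifier response.  One shared RT jitter per peptide keeps heavy/light
    partners co-eluting.
    """
    rng = np.random.default_rng(seed)
    traces: Dict[str, Trace] = {}
    peptides = sorted({(tr.protein, tr.peptide) for tr in transitions})
    jitter = {
        key: (rng.normal(0.0, params.rt_jitter_sd) if params.rt_jitter_sd > 0 else 0.0)
        for key in peptides
    }
    for tr in sorted(transitions, key=lambda x: x.tid):
        if tr.protein == BSA_CONTROL:
            base_conc = spike_conc
        else:
            base_conc = float(conc_by_protein.get(tr.protein, 0.0))
        if tr.label == "native":
            conc = base_conc * digest_efficiency
        else:
            conc = spike_conc
        response = params.response_per_conc
        if tr.role == "qualifier":
            response *= params.qualifier_response_fraction
        area = response * conc
        if params.multiplicative_cv > 0 and area > 0:
            area *= 1.0 + params.multiplicative_cv * rng.normal()
        traces[tr.tid] = _gaussian_trace(
            tr, max(area, 0.0), jitter[(tr.protein, tr.peptide)], params, rng, sample_id
        )
    return traces


# ---------------------------------------------------------------------------
# cohort generator


@dataclass
class CohortParams:
    """Latent-factor generative model for a synthetic urine cohort."""

    n_samples: int = 72
    loadings: Dict[str, Dict[str, float]] = field(default_factory=dict)
    baselines: Dict[str, float] = field(default_factory=dict)
    residual_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not self.loadings:
            defaults = _load_cohort_defaults()
            self.loadings = defaults["loadings"]
            if not self.baselines:
                self.baselines = defaults["baselines"]
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


def _load_cohort_defaults() -> dict:
    text = resources.files("mrmkit.data").joinpath("cohort_defaults.yaml").read_text()
    raw = yaml.safe_load(text)
    loadings, baselines = {}, {}
    for analyte, spec in raw["analytes"].items():
        baselines[analyte] = float(spec["baseline"])
        loadings[analyte] = {k: float(spec[k]) for k in ("d", "t", "g", "s")}
    return {"loadings": loadings, "baselines": baselines}


def simulate_cohort(params: Optional[CohortParams] = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns (concentrations ng/ml, latent factors).

    ``log10 C = baseline + d*(-D) + t*T + g*G + s*S + noise`` with
    independent standard-normal D, T, G, S per sample.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    latents = pd.DataFrame(
        rng.normal(size=(n, 4)),
        columns=["D", "T", "G", "S"],
        index=[f"S{i + 1:03d}" for i in range(n)],
    )
    cols = {}
    for analyte, lam in params.loadings.items():
        log10c = (
            params.baselines[analyte]
            + lam["d"] * (-latents["D"])
            + lam["t"] * latents["T"]
            + lam["g"] * latents["G"]
            + lam["s"] * latents["S"]
            + rng.normal(0.0, params.residual_sd, size=n)
        )
        cols[analyte] = 10.0 ** log10c
    cohort = pd.DataFrame(cols, index=latents.index)
    cohort.index.name = "sample_id"
    return cohort, latents


def cohort_population_correlation(params: Optional[CohortParams] = None) -> pd.DataFrame:
    """Closed-form population correlation matrix of the log concentrations.

    cov(log A, log B) = sum over factors of lambda_A lambda_B (the -D sign
    cancels) plus residual variance on the diagonal.
    """
    params = params or CohortParams()
    analytes = list(params.loadings)
    k = len(analytes)
    cov = np.zeros((k, k))
    for i, a in enumerate(analytes):
        for j, b in enumerate(analytes):
            la, lb = params.loadings[a], params.loadings[b]
            cov[i, j] = sum(la[f] * lb[f] for f in "dtgs")
            if i == j:
                cov[i, j] += params.residual_sd**2
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    return pd.DataFrame(corr, index=analytes, columns=analytes)


# ---------------------------------------------------------------------------
# validation designs


def simulate_reproducibility_values(
    true_conc: float,
    cv: float,
    seed: int = 0,
    shape: Tuple[int, int, int] = (3, 3, 3),
    day_cv: float = 0.0,
    sample_cv: float = 0.0,
) -> np.ndarray:
    """Measured concentrations for a (days, samples, replicates) block with
    multiplicative replicate noise and optional day/sample effects."""
    rng = np.random.default_rng(seed)
    days, samples, reps = shape
    day_eff = 1.0 + day_cv * rng.normal(size=(days, 1, 1))
    sample_eff = 1.0 + sample_cv * rng.normal(size=(days, samples, 1))
    rep_noise = 1.0 + cv * rng.normal(size=(days, samples, reps))
    return np.maximum(true_conc * day_eff * sample_eff * rep_noise, 1e-9)


@dataclass
class ValidationSet:
    """Chromatogram bundle for a full method-validation run.

    ``traces`` maps sample id -> transition id -> Trace; the metadata frames
    label each sample's role (calibration level/replicate, reproducibility
    cell, carry-over kind).
    """

    traces: Dict[str, Dict[str, Trace]]
    calibration: pd.DataFrame
    reproducibility: pd.DataFrame
    carryover: pd.DataFrame


def simulate_validation_set(
    transitions: Sequence[TransitionDef],
    protein: str,
    calibration_levels: Sequence[float] = (4.0, 10.0, 25.0, 50.0, 100.0),
    n_replicates: int = 3,
    repro_concs: Sequence[float] = (4.0, 25.0, 100.0),
    repro_shape: Tuple[int, int, int] = (3, 3, 3),
    carryover_fraction: float = 0.0,
    params: ChromSimParams = ChromSimParams(),
    seed: int = 0,
) -> ValidationSet:
    """Traces for a calibration series, a (days x samples x replicates)
    reproducibility block and a high-standard/blank carry-over pair, all
    seeded deterministically for one target protein."""
    root = np.random.SeedSequence(seed)
    sub = iter(root.spawn(4))
    cal_seed, repro_seed, carry_seed, _ = (int(s.generate_state(1)[0] % 2**31) for s in sub)
    traces: Dict[str, Dict[str, Trace]] = {}
    cal_rows = []
    for li, level in enumerate(calibration_levels):
        for rep in range(n_replicates):
            sid = f"cal_L{li + 1}_r{rep + 1}"
            traces[sid] = simulate_sample(
                transitions, {protein: level}, params,
                seed=cal_seed + 97 * li + rep, sample_id=sid,
            )
            cal_rows.append(
                {"sample_id": sid, "protein": protein, "nominal_conc": level,
                 "replicate": rep + 1}
            )
    repro_rows = []
    days, samples, reps = repro_shape
    for li, level in enumerate(repro_concs):
        for d in range(days):
            for s in range(samples):
                for r in range(reps):
                    sid = f"rep_L{li + 1}_d{d + 1}_s{s + 1}_r{r + 1}"
                    traces[sid] = simulate_sample(
                        transitions, {protein: level}, params,
                        seed=repro_seed + 10007 * li + 101 * d + 11 * s + r,
                        sample_id=sid,
                    )
                    repro_rows.append(
                        {"sample_id": sid, "protein": protein,
                         "nominal_conc": level, "day": d + 1,
                         "sample": s + 1, "replicate": r + 1}
                    )
    high = max(calibration_levels)
    traces["carry_high"] = simulate_sample(
        transitions, {protein: high}, params, seed=carry_seed, sample_id="carry_high"
    )
    traces["carry_blank"] = simulate_sample(
        transitions, {protein: high * carryover_fraction}, params,
        seed=carry_seed + 1, sample_id="carry_blank", spike_conc=0.0,
    )
    carry_rows = [
        {"sample_id": "carry_high", "kind": "high", "nominal_conc": high},
        {"sample_id": "carry_blank", "kind": "blank",
         "nominal_conc": high * carryover_fraction},
    ]
    return ValidationSet(
        traces=traces,
        calibration=pd.DataFrame(cal_rows),
        reproducibility=pd.DataFrame(repro_rows),
        carryover=pd.DataFrame(carry_rows),
    )
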