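# Methods notes

This note records the models, defaults and design choices behind `mrmkit`,
and what the synthetic data do and do not establish.

## Mass and m/z arithmetic (`masscalc`)

Neutral peptide mass = Σ residue masses + water (monoisotopic 18.010565 Da,
proton 1.007276 Da); precursor m/z = (M + label shift + z·proton)/z; y- and
b-fragment m/z follow the standard series definitions, with the isotope
label contributing only when the labelled (C-terminal) residue lies inside
the fragment. The residue-mass table ships as a versioned plain-text
resource and can be overridden. Defaults:

* mass scheme **monoisotopic**;
* cysteine **carbamidomethylated** (+57.0215 Da) because the digestion
  protocol alkylates with iodoacetamide — toggleable;
* labels fixed at K +8.0142 Da (¹³C₆ ¹⁵N₂) and R +10.0083 Da (¹³C₆ ¹⁵N₄),
  the standard SIL chemistry for tryptic peptides;
* design-mode charge: smallest z ≥ 2 with precursor m/z in [300, 1250].

Vendor transition lists carry instrument-tuned m/z values that do not match
any single mass convention row-for-row (in the packaged reference list,
EAGAQLK's printed Q1 matches the average-mass value, GDSVVYGLR's the
monoisotopic one, and others neither within 0.2 m/z). Printed values are
therefore carried **verbatim and never recomputed silently**;
`masscalc.mz_deviation_report` makes |printed − computed| explicit with a
0.3 m/z warning threshold.

## Assay design (`assay_design`)

Trypsin cleaves C-terminal to K/R except before P. Candidate filters:
length 6–20; Kyte–Doolittle GRAVY in [−2.0, +2.5] (no specific metric or
bounds are standard for "too hydrophobic/hydrophilic"; GRAVY is the
community default and the window is deliberately permissive); ragged ends
excluded; M/N (and secondarily W/C) and non-uniqueness are *warnings*, not
exclusions — in practice a peptide shared with an irrelevant organism can
still quantify its parent correctly, and modification-prone residues only
degrade, not invalidate, a transition.

**Ragged ends.** A literal reading of "the residue next to the peptide is
K/R" would flag every fully tryptic peptide, whose preceding residue is K/R
by construction. We use the field-standard definition instead: a peptide is
ragged when it abuts a double-basic junction — the residue *after* its
C-terminus is K/R, or the residue before its N-terminal cleavage site
(position start−2) is K/R. Internal K/R only occur with missed cleavages
(default 0, fully tryptic).

Uniqueness is an exact tryptic-substring search against a local background
proteome FASTA — a reproducible, offline approximation of a BLAST
uniqueness check; it finds exact occurrences only, not near-homologues.

Design-mode expected RT is a linear map of GRAVY onto the 3–11 min gradient
window. This is a deterministic placeholder that orders peptides plausibly;
real retention times always come from the transition-list file.

## Peak model (`peaks`)

Within `expected_rt ± rt_tolerance` (default 0.3 min): baseline = median of
the two tolerance-width flanking windows; noise = SD of the flanking
intensities (SD rather than peak-to-peak for robustness); apex = maximum
baseline-subtracted intensity; area = trapezoidal integral over the
contiguous region around the apex above baseline + 1 noise SD; found ⇔
apex ≥ 3 noise SD. No Gaussian fitting — the trapezoid is deterministic and
adequate for well-resolved MRM peaks (< 2% error when σ ≥ 4 sampling
intervals). S/N floors the noise SD at 1 count so noiseless traces stay
finite. Ratios use areas, not heights. Co-elution requires heavy/light
apexes within 0.1 min; the qualifier/quantifier area ratio must sit within
±30% of its reference when a reference is configured.

The BSA reference response defaults to the **per-batch median** of BSA
heavy/light ratios (`quantify_batch`); whether the original protocol used a
batch mean or a fixed external value is not specified, and the median is
robust to the occasional failed digest. Per-sample quantification accepts
an explicit reference instead. A BSA factor < 0.2 suppresses quantification
with a `digest_failure` flag; below-LOQ values are flagged, not dropped.

## Validation statistics (`validation`)

* Linearity: OLS of measured on nominal; r² = squared Pearson r.
* LOD/LOQ: interpolation of the measured S/N–concentration curve at S/N 3
  and 10, with linear extrapolation through the two lowest points when the
  curve starts above a threshold, and "> max conc" censoring when it never
  reaches one. Interpolation was chosen over regressing S/N on
  concentration because it adds no model assumptions to an explicitly
  empirical criterion.
* Reproducibility mapping: **intra-sample** = mean CV across the 3
  injection replicates per (day, sample) cell; **inter-sample** = mean over
  days of the CV across sample means within a day; **inter-day** = CV
  across day means. This is one concrete reading of the ambiguous
  "between a sample prepared in threefold / threefold measurement of the
  same sample" phrasing; a variance-components decomposition would be a
  reasonable alternative and the block array is exposed for it. Note the
  plain CV of n = 3 values is biased low by the c₄ factor (~0.886), so a
  block simulated at CV 10% averages ≈ 8.9% — within the documented ±40%
  sampling band.
* Thresholds: 25% (lowest level) / 20% (others) by default; the stricter
  FDA chromatographic-run preset (20/15) is available.
* Carry-over: blank-after-high area ≤ 20% of the LOQ-level area, boundary
  inclusive.
* Stability: no numeric criterion is standard for per-run control-sample
  drift, so `stability_check` passes when every control injection stays
  within a configurable 20% of the first one; storage-stability *trending*
  beyond this is out of scope.

## Adjustment (`adjustment`)

Log base 10 by default (Pearson r is invariant to the base). Regression
adjustment returns the OLS residual **re-centred on the analyte mean** so
adjusted values stay on the analyte's log scale; re-centring does not
affect any correlation, and the residual construction is what guarantees
r(adjusted, adjuster) = 0 exactly. Missing and non-positive values are
masked and handled pairwise-complete, with counts reported. Significance
stars follow the tiers $ p<0.05, # p<0.01, * p<0.001 with **no
multiple-testing correction** — a documented limitation, matching common
practice for descriptive correlation tables. Samples are treated as
independent (repeated samples per child are not modelled).

## Synthetic data (`simulate`)

**Chromatograms.** Gaussian peaks (σ 0.05 min) on a 50-count baseline with
5-count RMS noise, 5 counts·min of area per ng/ml, 5% multiplicative
response CV and 0.01 min RT jitter shared between heavy/light partners,
sampled at 100 points/min over ±1 min. The response scale and noise are a
realistic, unremarkable triple-quadrupole regime chosen once; the stated
design constants (50 ng/ml spike; 4–100 ng/ml calibration with 3
replicates; 3×3×3 reproducibility block) come from the assay protocol.
The simulator does **not** model matrix interferences, ion suppression,
tailing or co-eluting isomers, so a green round-trip test establishes the
correctness of the integration/ratio arithmetic, not robustness to real
urine matrices.

**Cohorts.** log₁₀ concentration = baseline + λ_D(−D) + λ_T·T + λ_G·G +
λ_S·S + N(0, 0.15), with standard-normal latent diuresis D (shared, negative
— concentration ∝ 1/flow), tubular-reabsorption failure T (LMW proteins),
glomerular leak G (mainly HSA) and airway signal S (CC16/OPN only); defaults
in `data/cohort_defaults.yaml`, n = 72 samples matching a small field
cohort. The loading structure is qualitative, not physiologically
calibrated: it reproduces the *pattern* (β2M–RBP4 r ≈ 0.9; creatinine
division flips the residual correlation negative; regression-by-β2M is
orthogonal and recovers S best) but not any specific published correlation
value. Latent factors are returned for recovery tests and never fed to the
pipeline under test.

## Numerical conventions

Boundary comparisons (qualifier ratio band, carry-over limit) are inclusive
with a 1e-12 relative guard. All pass/fail decisions are pure functions of
inputs and configuration. Every writer emits a schema-version comment and
round-trips bit-identically (readers use round-trip float parsing). All
randomness flows through numpy `default_rng` seeds; batch designs derive
per-run seeds from a single `SeedSequence`.

## Known limitations

* Vendor raw files and mzML are not read; the long-format trace CSV is the
  interchange format.
* Collision-energy optimisation, instrument control and LC physics are
  carried as metadata only.
* Uniqueness screening is exact-match only (no homology search).
* Absolute quantification is out of scope: concentrations are relative to
  the heavy spike and the calibration materials.
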