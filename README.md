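# mrmkit

Tools for building and running a **multiplex MRM (multiple reaction
monitoring) assay of urinary protein biomarkers**: in silico assay design,
stable-isotope-dilution relative quantification from chromatograms, a full
method-validation suite, and the statistics needed to adjust urinary
concentrations for diuresis and renal protein handling.

The package targets the workflow used to monitor respiratory-health
biomarkers in children's urine — club cell protein (CC16), osteopontin
(OPN) and NF-κB — together with the renal-handling adjusters β2M, RBP4,
myoglobin and HSA, and a BSA digestion-efficiency control. It is a library:
everything is driven from Python (see `examples/`), with plain-text CSV/TSV
interchange formats throughout.

## The science in brief

**Quantification.** Each protein is represented by one or two proteotypic
tryptic peptides; each peptide by a quantifier and a qualifier transition
(Q1/Q3 m/z pair). A stable-isotope-labelled copy of every peptide
(C-terminal K +8.0142 Da or R +10.0083 Da) is spiked at 50 ng/ml, co-elutes
with the native peptide, and sits `shift/z` higher in Q1. The relative
concentration is

```
conc = (native quantifier area / labelled quantifier area) × 50 ng/ml / bsa_factor
```

where `bsa_factor` is the sample's BSA digest-control response over the
batch reference — trypsin digestion affects only the native peptides, so
the heavy/light ratio must be corrected for digest efficiency, and a factor
below 0.2 flags a failed digest.

**Validation.** Linearity is OLS of measured vs nominal concentration
(acceptance r² > 0.98). LOD and LOQ are the concentrations where the
interpolated signal-to-noise curve crosses S/N = 3 and S/N = 10 (so
LOQ/LOD = 10/3 under a proportional S/N model). Reproducibility uses a
3 days × 3 samples × 3 injections block with intra-sample, inter-sample and
inter-day CVs (100·SD/mean) accepted below 25% at the lowest level and 20%
elsewhere. Carry-over requires a post-high-standard blank under 20% of the
LOQ-level area.

**Adjustment.** Urinary concentrations confound the biology of interest
with diuresis, tubular reabsorption and glomerular leak. On log-transformed
data the package compares division adjustment, `log A − log X`, with
regression adjustment, `log A − β(log X − mean log X)` where β is the OLS
slope: the regression-adjusted series is *exactly* uncorrelated with the
adjuster (r = 0.00), while division over- or under-corrects whenever the
analyte's diuresis loading differs from the adjuster's — the mechanism that
flips CC16/creatinine ratios into negative correlation with creatinine.
A latent-factor cohort simulator (shared diuresis/tubular/glomerular/airway
factors on the log scale) makes the whole comparison testable end to end.

## Worked example

`python examples/04_adjust_cohort.py` simulates a 72-sample cohort and
compares the adjustment strategies:

```
division by creatinine: r(adjusted, log CREAT) = -0.35  (overcorrection)
regression by B2M (beta = 0.67): r(adjusted, log B2M) = -0.00  (orthogonal by construction)

correlation with the latent airway signal S: regression-B2M +0.83 vs creatinine-ratio +0.54
```

Dividing by creatinine leaves a *negative* residual correlation with
creatinine (the diuresis effect is overcorrected) and recovers the latent
airway signal poorly; regression adjustment by β2M removes the adjuster
correlation exactly and tracks the signal markedly better — the
quantitative case for regression-based adjustment of LMW urinary proteins.

The other examples show assay design from a FASTA sequence
(`01_design_assay.py`), single-sample heavy/light quantification with BSA
correction (`02_quantify_sample.py`), and the full validation battery
(`03_validate_method.py`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch: the monoisotopic
precursor m/z of the two reference peptides GDSVVYGLR (2+) and
LPPVLSHPIFDNR (3+) in native and R-labelled form (t1–t4), the Pearson
correlation between a regression-adjusted analyte and its adjuster on a
fresh synthetic cohort (t5), and the calibration r² of a 5-level synthetic
standard curve pushed through peak integration and heavy/light
quantification (t6). Results are written as JSON; all randomness derives
from `--seed`.

## Layout

```
src/mrmkit/        masscalc, assay_design, peaks, validation, adjustment,
                   simulate, io  (+ data/: residue masses, reference
                   transition list, cohort defaults)
examples/          four narrative scripts, one per capability
tests/             pytest suite incl. end-to-end acceptance checks
docs/methods.md    model assumptions, parameter choices, limitations
```
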