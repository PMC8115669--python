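"""Method validation on a simulated data set: linearity, LOD/LOQ, CVs,
carry-over.

Simulates a 5-level calibration series, a 3x3x3 reproducibility block and a
high-standard/blank pair, then runs the validation statistics: OLS
linearity (acceptance r^2 > 0.98), S/N-interpolated LOD (S/N = 3) and LOQ
(S/N = 10), intra-sample / inter-sample / inter-day CVs against the
25%/20% rule, and the carry-over check.
"""

import numpy as np

from mrmkit import io, peaks, simulate, validation

transitions = [t for t in io.load_reference_transitions() if t.protein == "OPN"]
tr = transitions[0]  # native quantifier

vs = simulate.simulate_validation_set(
    transitions, "OPN",
    calibration_levels=(4.0, 10.0, 25.0, 50.0, 100.0),
    n_replicates=3, repro_concs=(4.0, 25.0, 100.0), seed=5,
)

# --- linearity through the full quantification pipeline
cal_traces = {sid: vs.traces[sid] for sid in vs.calibration.sample_id}
quant = peaks.quantify_batch(cal_traces, transitions)
merged = quant[quant.protein == "OPN"].merge(vs.calibration, on="sample_id")
series = validation.CalibrationSeries(
    "OPN",
    [(c, list(g.relative_conc_ng_ml)) for c, g in merged.groupby("nominal_conc")],
)
cal = validation.fit_calibration(series)
print(f"linearity: slope {cal.slope:.3f}, intercept {cal.intercept:.2f}, "
      f"r^2 {cal.r2:.4f} (acceptance: > 0.98)")

# --- LOD/LOQ from the S/N of the native quantifier peak per level
snr_points = []
for conc, group in merged.groupby("nominal_conc"):
    snrs = quant.set_index("sample_id").loc[group.sample_id, "snr"]
    snr_points.append((conc, float(np.mean(snrs))))
limits = validation.lod_loq_from_snr(snr_points)
print(f"S/N by level: {[(c, round(s, 1)) for c, s in snr_points]}")
print(f"{limits.describe()}  (S/N thresholds 3 and 10)")

# --- reproducibility CVs from the quantified 3x3x3 blocks
rep_traces = {sid: vs.traces[sid] for sid in vs.reproducibility.sample_id}
rep_quant = peaks.quantify_batch(rep_traces, transitions).set_index("sample_id")
levels = {}
for conc, group in vs.reproducibility.groupby("nominal_conc"):
    block = np.empty((3, 3, 3))
    for row in group.itertuples():
        block[row.day - 1, row.sample - 1, row.replicate - 1] = rep_quant.loc[
            row.sample_id, "relative_conc_ng_ml"
        ]
    levels[conc] = block
report = validation.cv_report(validation.ReproducibilityDesign("OPN", levels))
print("\nreproducibility (CV %, rule: < 25% lowest level, < 20% others):")
for lv in report.levels:
    print(
        f"  {lv.nominal_conc:>6.1f} ng/ml  intra {lv.intra_sample_cv:5.1f}  "
        f"inter-sample {lv.inter_sample_cv:5.1f}  inter-day {lv.inter_day_cv:5.1f}"
        f"  -> {'pass' if lv.passed else 'FAIL'}"
    )

# --- carry-over: blank after the highest standard
high = peaks.integrate_peak(vs.traces["carry_high"][tr.tid], tr.rt_min, 0.3)
blank = peaks.integrate_peak(vs.traces["carry_blank"][tr.tid], tr.rt_min, 0.3)
loq_area = (limits.loq or 0.0) * 5.0  # response_per_conc x LOQ
carry = validation.carryover_check(high, blank, loq_area)
print(f"\ncarry-over: blank area {carry.blank_area:.2f} vs limit "
      f"{carry.limit:.2f} -> {carry.status}")
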