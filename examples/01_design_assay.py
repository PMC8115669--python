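"""Design MRM transitions for a target protein from its sequence.

Digests a small made-up target in silico, scores the tryptic peptides
against the proteotypic selection criteria (length 6-20, no ragged ends,
GRAVY window, modification-prone residues as warnings, uniqueness against a
background proteome), and emits native + stable-isotope-labelled Q1/Q3
transitions for the accepted candidates.
"""

from mrmkit.assay_design import (
    ProteinRecord,
    build_transition_list,
    digest,
    score_candidates,
)

target = ProteinRecord("DEMO1", "demo target", "MAAKGDSVVYGLRTTMNKAGSTNLDGRAAAK")
background = [
    target,
    ProteinRecord("BG1", "homolog sharing one peptide", "QQQKAGSTNLDGRQQQ"),
    ProteinRecord("BG2", "unrelated", "MWWHHGGPPLLVVK"),
]

peptides = digest(target, max_missed_cleavages=0)
scores = score_candidates(
    peptides, background, parent_sequences={target.accession: target.sequence}
)

print(f"{'peptide':<14} len  GRAVY  unique  warnings        accepted")
for s in scores:
    warn = ",".join(sorted(s.modifiable_residue_flags)) or "-"
    print(
        f"{s.peptide.sequence:<14} {len(s.peptide.sequence):>3}  "
        f"{s.gravy:>5.2f}  {str(s.unique):<6}  {warn:<14}  {s.accepted}"
    )

transitions, failures = build_transition_list(
    [s for s in scores if s.accepted], proteins=[target.accession]
)
print("\ntransitions (Q1/Q3 in m/z, native and labelled pairs):")
for t in transitions:
    print(
        f"  {t.peptide:<14} {t.label:<9} {t.role:<10} "
        f"Q1 {t.q1_mz:8.2f}  Q3 {t.q3_mz:8.2f}  ({t.fragment}, RT {t.rt_min} min)"
    )
if failures:
    print("design failures:", failures)

# The labelled Q1 sits mass_shift/charge above the native Q1 (here R-label:
# +10.0083/2 = +5.004), which is what lets the heavy spike quantify the
# native peptide from the same chromatogram.
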