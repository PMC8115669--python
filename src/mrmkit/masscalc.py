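"""Peptide and fragment mass / m/z arithmetic for MRM transitions.

Masses follow the standard residue-mass convention: a peptide's neutral mass
is the sum of its residue masses plus one water; a protonated precursor at
charge ``z`` has ``m/z = (M + z * m_p) / z``.  Stable-isotope labels
(SIL / AQUA peptides) add a fixed mass shift on the C-terminal K or R of a
fully tryptic peptide, so the heavy precursor sits ``shift / z`` above the
light one while co-eluting — the property isotope-dilution quantification
relies on.

Cysteine is treated as carbamidomethylated by default (the digestion
protocol alkylates with iodoacetamide); pass ``carbamidomethyl_cys=False``
to :func:`load_residue_table` for free cysteine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

__all__ = [
    "ResidueMassTable",
    "IsotopeLabel",
    "PeptideIon",
    "LABEL_K",
    "LABEL_R",
    "PROTON_MASS",
    "WATER_MONO",
    "WATER_AVG",
    "CARBAMIDOMETHYL_MASS",
    "load_residue_table",
    "label_for_residue",
    "peptide_mass",
    "precursor_mz",
    "fragment_mz",
    "label_shift_at_charge",
    "choose_charge",
    "mz_deviation_report",
]

PROTON_MASS = 1.007276
WATER_MONO = 18.010565
WATER_AVG = 18.01528
#: fixed carbamidomethyl modification on cysteine (iodoacetamide alkylation)
CARBAMIDOMETHYL_MASS = 57.02146
CARBAMIDOMETHYL_MASS_AVG = 57.0513


class UnknownResidueError(ValueError):
    """A sequence contains a character not present in the residue table."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue masses (Da) keyed by one-letter code, plus water and proton."""

    mono: dict
    average: dict
    water_mono: float = WATER_MONO
    water_average: float = WATER_AVG
    proton_mass: float = PROTON_MASS

    def residue_mass(self, residue: str, scheme: str = "monoisotopic") -> float:
        table = self.mono if scheme == "monoisotopic" else self.average
        try:
            return table[residue]
        except KeyError:
            raise UnknownResidueError(f"unknown residue {residue!r}") from None

    def water(self, scheme: str = "monoisotopic") -> float:
        return self.water_mono if scheme == "monoisotopic" else self.water_average


def load_residue_table(
    path: Optional[str] = None, carbamidomethyl_cys: bool = True
) -> ResidueMassTable:
    """Load the residue-mass table from the packaged resource or ``path``.

    The file is plain text: one residue per line, ``code  mono  average``,
    '#' comments allowed.  With ``carbamidomethyl_cys`` (default) the C mass
    carries the fixed +57.0215 Da alkylation.
    """
    if path is None:
        text = (
            resources.files("mrmkit.data").joinpath("residue_masses.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    mono, average = {}, {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, m, a = line.split()
        mono[code] = float(m)
        average[code] = float(a)
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(mono)
    if missing:
        raise ValueError(f"residue table incomplete, missing {sorted(missing)}")
    if carbamidomethyl_cys:
        mono["C"] += CARBAMIDOMETHYL_MASS
        average["C"] += CARBAMIDOMETHYL_MASS_AVG
    return ResidueMassTable(mono=mono, average=average)


_DEFAULT_TABLE: Optional[ResidueMassTable] = None


def default_table() -> ResidueMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_residue_table()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class IsotopeLabel:
    """A stable-isotope label on the C-terminal K or R of a tryptic peptide."""

    labelled_residue: str
    mass_shift: float

    def __post_init__(self):
        if self.labelled_residue not in ("K", "R"):
            raise ValueError("label residue must be K or R")
        if self.mass_shift <= 0:
            raise ValueError("label mass shift must be positive")


#: 13C6 15N2 lysine
LABEL_K = IsotopeLabel("K", 8.0142)
#: 13C6 15N4 arginine
LABEL_R = IsotopeLabel("R", 10.0083)


def label_for_residue(residue: str) -> IsotopeLabel:
    """Return the standard SIL label for a C-terminal K or R."""
    if residue == "K":
        return LABEL_K
    if residue == "R":
        return LABEL_R
    raise ValueError(f"no isotope label defined for residue {residue!r}")


@dataclass(frozen=True)
class PeptideIon:
    """A peptide sequence with charge, optional label and mass scheme."""

    sequence: str
    charge: int = 2
    label: Optional[IsotopeLabel] = None
    mass_scheme: str = "monoisotopic"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.mass_scheme not in ("monoisotopic", "average"):
            raise ValueError("mass_scheme must be 'monoisotopic' or 'average'")
        if self.label is not None and self.sequence[-1] != self.label.labelled_residue:
            raise ValueError(
                f"label residue {self.label.labelled_residue!r} is not the "
                f"C-terminal residue of {self.sequence!r}"
            )


def _validate_sequence(sequence: str, table: ResidueMassTable) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for i, ch in enumerate(sequence):
        if ch not in table.mono:
            raise UnknownResidueError(
                f"unknown residue {ch!r} at position {i + 1} in {sequence!r}"
            )


def peptide_mass(
    sequence: str,
    mass_scheme: str = "monoisotopic",
    table: Optional[ResidueMassTable] = None,
) -> float:
    """Neutral peptide mass in Da: sum of residue masses plus one water."""
    table = table or default_table()
    _validate_sequence(sequence, table)
    masses = table.mono if mass_scheme == "monoisotopic" else table.average
    return sum(masses[ch] for ch in sequence) + table.water(mass_scheme)


def precursor_mz(ion: PeptideIon, table: Optional[ResidueMassTable] = None) -> float:
    """Precursor m/z = (M + label shift + z * proton) / z."""
    table = table or default_table()
    mass = peptide_mass(ion.sequence, ion.mass_scheme, table)
    if ion.label is not None:
        mass += ion.label.mass_shift
    return (mass + ion.charge * table.proton_mass) / ion.charge


def fragment_mz(
    ion: PeptideIon,
    ion_series: str,
    index: int,
    fragment_charge: int = 1,
    table: Optional[ResidueMassTable] = None,
) -> float:
    """m/z of the b- or y-ion ``index`` of the peptide.

    ``y_k`` covers the last ``k`` residues (plus water), ``b_k`` the first
    ``k``; the isotope label contributes only when its residue lies inside
    the fragment (always for y-ions of a C-terminally labelled peptide,
    never for b-ions shorter than the full length).
    """
    table = table or default_table()
    if ion_series not in ("b", "y"):
        raise ValueError("ion_series must be 'b' or 'y'")
    n = len(ion.sequence)
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} out of range for length-{n} peptide")
    if fragment_charge < 1:
        raise ValueError("fragment charge must be >= 1")
    masses = table.mono if ion.mass_scheme == "monoisotopic" else table.average
    if ion_series == "y":
        residues = ion.sequence[n - index :]
        mass = sum(masses[ch] for ch in residues) + table.water(ion.mass_scheme)
        labelled = ion.label is not None  # C-terminal residue is in every y-ion
    else:
        residues = ion.sequence[:index]
        mass = sum(masses[ch] for ch in residues)
        labelled = False  # b_k with k <= n-1 never reaches the C-terminus
    if labelled:
        mass += ion.label.mass_shift
    return (mass + fragment_charge * table.proton_mass) / fragment_charge


def label_shift_at_charge(label: IsotopeLabel, charge: int) -> float:
    """m/z offset between heavy and light species at the given charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return label.mass_shift / charge


def choose_charge(
    sequence: str,
    mz_range: tuple = (300.0, 1250.0),
    max_charge: int = 4,
    table: Optional[ResidueMassTable] = None,
) -> int:
    """Smallest charge z >= 2 putting the precursor m/z inside the instrument
    range; falls back to 2 when no charge qualifies (tiny peptides)."""
    table = table or default_table()
    for z in range(2, max_charge + 1):
        mz = precursor_mz(PeptideIon(sequence, charge=z), table)
        if mz_range[0] <= mz <= mz_range[1]:
            return z
    return 2


def mz_deviation_report(transitions, warn_threshold: float = 0.3, table=None):
    """Compare printed precursor m/z values against recomputed monoisotopic
    ones.

    Vendor transition lists carry instrument-tuned m/z values that can sit a
    few tenths off any single mass convention, so printed values are carried
    verbatim and never recomputed silently; this report makes the deviation
    explicit.  Returns a pandas DataFrame with a ``warn`` column where
    ``|printed - computed| > warn_threshold``.
    """
    import pandas as pd

    table = table or default_table()
    rows = []
    for t in transitions:
        z = choose_charge(t.peptide, table=table)
        label = None
        if t.label == "labelled":
            label = label_for_residue(t.peptide[-1])
        computed = precursor_mz(PeptideIon(t.peptide, charge=z, label=label), table)
        dev = abs(t.q1_mz - computed)
        rows.append(
            {
                "protein": t.protein,
                "peptide": t.peptide,
                "label": t.label,
                "printed_q1": t.q1_mz,
                "computed_q1": round(computed, 4),
                "charge": z,
                "abs_deviation": round(dev, 4),
                "warn": dev > warn_threshold,
            }
        )
    return pd.DataFrame(rows)
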