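"""In silico tryptic digestion and proteotypic-peptide candidate selection.

The selection criteria follow standard MRM assay-design practice: candidate
peptides must be fully tryptic, 6-20 residues long, should avoid residues
prone to chemical modification (M, N oxidation/deamidation; W, C as
secondary warnings), ragged-end junctions (adjacent K/R), and
chromatographically extreme hydropathy (Kyte-Doolittle GRAVY outside
[-2.0, +2.5]).  Uniqueness is an exact substring search against a local
background proteome; a non-unique peptide is flagged but may still be
accepted, since in practice a shared sequence in an irrelevant organism
does not disturb the assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from . import masscalc
from .masscalc import PeptideIon, label_for_residue

__all__ = [
    "ProteinRecord",
    "DigestPeptide",
    "CandidateScore",
    "FilterConfig",
    "TransitionDef",
    "GRAVY",
    "gravy",
    "digest",
    "check_uniqueness",
    "score_candidates",
    "build_transition_list",
]

#: Kyte-Doolittle hydropathy index per residue
GRAVY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

TERMINUS = "-"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.accession}: empty sequence")


@dataclass(frozen=True)
class DigestPeptide:
    """One tryptic peptide with 1-based inclusive coordinates in its parent."""

    sequence: str
    accession: str
    start: int
    end: int
    missed_cleavages: int
    preceding_residue: str
    following_residue: str


@dataclass
class FilterConfig:
    min_length: int = 6
    max_length: int = 20
    gravy_min: float = -2.0
    gravy_max: float = 2.5
    max_missed_cleavages: int = 0


@dataclass
class CandidateScore:
    peptide: DigestPeptide
    length_ok: bool
    modifiable_residue_flags: frozenset
    ragged_end_flag: bool
    gravy: float
    gravy_ok: bool
    unique: Optional[bool]  # None when the background proteome was empty
    shared_in: Tuple[str, ...]
    accepted: bool

    @property
    def n_warnings(self) -> int:
        return len(self.modifiable_residue_flags) + (self.unique is False)


@dataclass(frozen=True)
class TransitionDef:
    """One Q1/Q3 transition: the assay's atomic measurement definition."""

    protein: str
    peptide: str
    label: str  # 'native' | 'labelled'
    q1_mz: float
    q3_mz: float
    fragment: str  # e.g. 'y5', or bare series letter when the index is unknown
    collision_energy_V: float
    cone_voltage_V: float
    rt_min: float
    role: str  # 'quantifier' | 'qualifier'

    def __post_init__(self):
        if self.label not in ("native", "labelled"):
            raise ValueError(f"label must be native/labelled, got {self.label!r}")
        if self.role not in ("quantifier", "qualifier"):
            raise ValueError(f"role must be quantifier/qualifier, got {self.role!r}")

    @property
    def tid(self) -> str:
        """Stable identifier used to key chromatogram traces."""
        return f"{self.protein}|{self.peptide}|{self.role}|{self.label}"


def cleavage_sites(sequence: str) -> List[int]:
    """0-based positions i such that trypsin cuts after sequence[i]
    (K or R not followed by P)."""
    return [
        i
        for i, ch in enumerate(sequence)
        if ch in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P")
    ]


def digest(protein, max_missed_cleavages: int = 0) -> List[DigestPeptide]:
    """Tryptic digest: cleave C-terminal to K/R except before P.

    Returns all peptides carrying 0..max_missed_cleavages missed internal
    sites, ordered by (start, end), with 1-based inclusive coordinates and
    flanking residues (``-`` at the protein termini).
    """
    if isinstance(protein, str):
        protein = ProteinRecord("?", "", protein)
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    seq = protein.sequence
    bounds = [0] + [i + 1 for i in cleavage_sites(seq)]
    if bounds[-1] != len(seq):
        bounds.append(len(seq))
    peptides = []
    nseg = len(bounds) - 1
    for i in range(nseg):
        for mc in range(max_missed_cleavages + 1):
            j = i + mc + 1
            if j > nseg:
                break
            start, end = bounds[i], bounds[j]
            peptides.append(
                DigestPeptide(
                    sequence=seq[start:end],
                    accession=protein.accession,
                    start=start + 1,
                    end=end,
                    missed_cleavages=mc,
                    preceding_residue=seq[start - 1] if start > 0 else TERMINUS,
                    following_residue=seq[end] if end < len(seq) else TERMINUS,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def check_uniqueness(
    sequence: str, background_proteome: Sequence[ProteinRecord],
    parent_accession: Optional[str] = None,
) -> Tuple[bool, List[str]]:
    """Exact substring search of the peptide across the background proteome.

    ``unique`` is true when the sequence occurs in at most one background
    entry (its parent).  Returns (unique, accessions sharing the sequence
    other than the parent).  A peptide absent from the background entirely is
    unique, with the caveat that its parent is not in the background.
    """
    hits = [rec.accession for rec in background_proteome if sequence in rec.sequence]
    shared = [acc for acc in hits if acc != parent_accession]
    if parent_accession is not None and parent_accession in hits:
        return len(shared) == 0, shared
    # parent not found: unique iff no more than one entry contains it
    return len(hits) <= 1, shared


def gravy(sequence: str) -> float:
    """Kyte-Doolittle grand average of hydropathy."""
    return sum(GRAVY[ch] for ch in sequence) / len(sequence)


def _ragged_end(pep: DigestPeptide, parent_sequence: Optional[str]) -> bool:
    # C-side: the residue after the peptide is itself K/R (K.K / R.K junction)
    if pep.following_residue in "KR":
        return True
    # N-side: the residue before the preceding cleavage site is K/R
    if parent_sequence is not None and pep.start >= 3:
        if parent_sequence[pep.start - 3] in "KR":
            return True
    return False


def score_candidates(
    peptides: Iterable[DigestPeptide],
    background_proteome: Sequence[ProteinRecord],
    config: Optional[FilterConfig] = None,
    parent_sequences: Optional[dict] = None,
) -> List[CandidateScore]:
    """Score digest peptides against the proteotypic selection criteria.

    Modifiable residues (M, N, W, C) and non-uniqueness are warnings, not
    exclusions; acceptance requires length in bounds, no ragged end and
    GRAVY inside the configured window.  The result is sorted accepted-first,
    then by fewest warnings, then by ascending start position.
    """
    config = config or FilterConfig()
    scores = []
    for pep in peptides:
        length_ok = config.min_length <= len(pep.sequence) <= config.max_length
        flags = frozenset(ch for ch in "MNWC" if ch in pep.sequence)
        parent_seq = (parent_sequences or {}).get(pep.accession)
        ragged = _ragged_end(pep, parent_seq)
        g = gravy(pep.sequence)
        gravy_ok = config.gravy_min <= g <= config.gravy_max
        if background_proteome:
            unique, shared = check_uniqueness(
                pep.sequence, background_proteome, pep.accession
            )
        else:
            unique, shared = None, []
        accepted = length_ok and not ragged and gravy_ok
        scores.append(
            CandidateScore(
                peptide=pep,
                length_ok=length_ok,
                modifiable_residue_flags=flags,
                ragged_end_flag=ragged,
                gravy=round(g, 4),
                gravy_ok=gravy_ok,
                unique=unique,
                shared_in=tuple(shared),
                accepted=accepted,
            )
        )
    scores.sort(key=lambda s: (not s.accepted, s.n_warnings, s.peptide.start))
    return scores


def _design_rt(g: float, config: FilterConfig, window=(3.0, 11.0)) -> float:
    """Placeholder expected RT: linear map of GRAVY onto the gradient window.

    Real retention times come from the transition-list file; this only gives
    design-stage transitions a plausible, deterministic elution order.
    """
    lo, hi = config.gravy_min, config.gravy_max
    frac = (min(max(g, lo), hi) - lo) / (hi - lo)
    return round(window[0] + frac * (window[1] - window[0]), 2)


def build_transition_list(
    candidates: Sequence[CandidateScore],
    proteins: Optional[Sequence[str]] = None,
    n_fragments: int = 2,
    collision_energy: float = 15.0,
    cone_voltage: float = 30.0,
    fragment_mz_range: Tuple[float, float] = (200.0, 1250.0),
    max_peptides_per_protein: int = 2,
    table=None,
) -> Tuple[List[TransitionDef], List[str]]:
    """Emit native + labelled transitions for accepted candidates.

    Per peptide: precursor at the smallest charge >= 2 inside the instrument
    range, and the top-``n_fragments`` y-ions chosen deterministically as the
    longest fragments whose singly charged m/z lies inside
    ``fragment_mz_range``.  The first fragment becomes the quantifier, the
    second the qualifier.  Proteins (from ``proteins``) with no usable
    candidate are returned in a design-failure list instead of aborting.
    """
    table = table or masscalc.default_table()
    config = FilterConfig()
    transitions: List[TransitionDef] = []
    covered = set()
    per_protein_count: dict = {}
    for score in candidates:
        if not score.accepted:
            continue
        pep = score.peptide
        if per_protein_count.get(pep.accession, 0) >= max_peptides_per_protein:
            continue
        seq = pep.sequence
        if seq[-1] not in "KR":
            continue  # protein C-terminal peptide: cannot carry a C-term label
        z = masscalc.choose_charge(seq, table=table)
        label = label_for_residue(seq[-1])
        native = PeptideIon(seq, charge=z)
        heavy = PeptideIon(seq, charge=z, label=label)
        q1_native = masscalc.precursor_mz(native, table)
        q1_heavy = masscalc.precursor_mz(heavy, table)
        rt = _design_rt(score.gravy, config)
        frags = []
        for k in range(len(seq) - 1, 0, -1):
            mz = masscalc.fragment_mz(native, "y", k, 1, table)
            if fragment_mz_range[0] <= mz <= fragment_mz_range[1]:
                frags.append((k, mz))
            if len(frags) == n_fragments:
                break
        if not frags:
            continue
        roles = ["quantifier", "qualifier"]
        for (k, mz_native), role in zip(frags, roles):
            mz_heavy = masscalc.fragment_mz(heavy, "y", k, 1, table)
            for lab, q1, q3 in (
                ("native", q1_native, mz_native),
                ("labelled", q1_heavy, mz_heavy),
            ):
                transitions.append(
                    TransitionDef(
                        protein=pep.accession,
                        peptide=seq,
                        label=lab,
                        q1_mz=round(q1, 4),
                        q3_mz=round(q3, 4),
                        fragment=f"y{k}",
                        collision_energy_V=collision_energy,
                        cone_voltage_V=cone_voltage,
                        rt_min=rt,
                        role=role,
                    )
                )
        covered.add(pep.accession)
        per_protein_count[pep.accession] = per_protein_count.get(pep.accession, 0) + 1
    wanted = list(proteins) if proteins is not None else sorted(
        {s.peptide.accession for s in candidates}
    )
    failures = [acc for acc in wanted if acc not in covered]
    return transitions, failures
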