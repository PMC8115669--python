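"""File formats, run configuration and the pipeline orchestrator.

All interchange formats are plain text: multi-record FASTA for protein
sequences, a transition-list CSV mirroring vendor MRM method tables, a
long-format chromatogram CSV (sample_id, transition_id, time_min,
intensity), a samples-by-analytes cohort CSV, and TSV reports.  Every
writer emits a ``# mrmkit-<kind> v1`` schema comment as its first line and
every reader skips comments, so outputs round-trip bit-identically.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import adjustment, assay_design, peaks, simulate, validation
from .assay_design import FilterConfig, ProteinRecord, TransitionDef
from .peaks import Trace

__all__ = [
    "FastaError",
    "TransitionListError",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_transitions",
    "write_transitions",
    "load_reference_transitions",
    "read_traces",
    "write_traces",
    "read_cohort",
    "write_cohort",
    "write_quant",
    "run_pipeline",
]

logger = logging.getLogger("mrmkit")

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

TRANSITION_COLUMNS = [
    "protein", "peptide", "label", "q1_mz", "q3_mz", "fragment",
    "collision_energy_V", "cone_voltage_V", "rt_min", "role",
]

_SCHEMA = {
    "transitions": "# mrmkit-transitions v1",
    "traces": "# mrmkit-traces v1",
    "cohort": "# mrmkit-cohort v1",
    "quant": "# mrmkit-quant v1",
}


class FastaError(ValueError):
    pass


class TransitionListError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> List[ProteinRecord]:
    """Read a multi-record FASTA into ProteinRecords.

    The accession is the first whitespace-delimited header token; sequences
    are uppercased, a trailing ``*`` stop is stripped with a warning, and
    non-amino-acid characters raise a :class:`FastaError` naming the record
    and position.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise FastaError(f"duplicate accession {accession!r}")
        seen.add(accession)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            logger.warning("stripping trailing stop '*' from %s", accession)
            seq = seq[:-1]
        if not seq:
            raise FastaError(f"record {accession!r} has an empty sequence")
        for i, ch in enumerate(seq):
            if ch not in VALID_RESIDUES:
                raise FastaError(
                    f"record {accession!r}: invalid residue {ch!r} at position {i + 1}"
                )
        records.append(
            ProteinRecord(accession=accession, name=rec.description, sequence=seq)
        )
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.name if rec.name.startswith(rec.accession) else rec.accession
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# transition lists


def write_transitions(transitions: Sequence[TransitionDef], path) -> None:
    """RFC-4180 CSV with the documented column schema and a version comment."""
    with open(path, "w", newline="") as fh:
        fh.write(_SCHEMA["transitions"] + "\n")
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(TRANSITION_COLUMNS)
        for t in transitions:
            writer.writerow(
                [
                    t.protein, t.peptide, t.label,
                    repr(t.q1_mz), repr(t.q3_mz), t.fragment,
                    repr(t.collision_energy_V), repr(t.cone_voltage_V),
                    repr(t.rt_min), t.role,
                ]
            )


def read_transitions(path) -> List[TransitionDef]:
    """Read and validate a transition-list CSV.

    Errors (with line numbers): unknown or missing columns, duplicate rows,
    and any native quantifier lacking its labelled partner — the heavy/light
    pairing is resolved by (protein, peptide, fragment, role).
    """
    with open(path, newline="") as fh:
        lines = [
            (i + 1, line) for i, line in enumerate(fh) if not line.startswith("#")
        ]
    if not lines:
        raise TransitionListError(f"{path}: empty transition list")
    reader = csv.reader([l for _, l in lines])
    header = next(reader)
    unknown = [c for c in header if c not in TRANSITION_COLUMNS]
    if unknown:
        raise TransitionListError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in TRANSITION_COLUMNS if c not in header]
    if missing:
        raise TransitionListError(f"{path}: missing column(s) {missing}")
    idx = {c: header.index(c) for c in TRANSITION_COLUMNS}
    transitions, keyed = [], {}
    for (lineno, _), row in zip(lines[1:], reader):
        if not row:
            continue
        try:
            t = TransitionDef(
                protein=row[idx["protein"]],
                peptide=row[idx["peptide"]],
                label=row[idx["label"]],
                q1_mz=float(row[idx["q1_mz"]]),
                q3_mz=float(row[idx["q3_mz"]]),
                fragment=row[idx["fragment"]],
                collision_energy_V=float(row[idx["collision_energy_V"]]),
                cone_voltage_V=float(row[idx["cone_voltage_V"]]),
                rt_min=float(row[idx["rt_min"]]),
                role=row[idx["role"]],
            )
        except ValueError as exc:
            raise TransitionListError(f"{path}:{lineno}: {exc}") from None
        key = (t.protein, t.peptide, t.fragment, t.role, t.label)
        if key in keyed:
            raise TransitionListError(
                f"{path}:{lineno}: duplicate row for {key} "
                f"(first at line {keyed[key]})"
            )
        keyed[key] = lineno
        transitions.append(t)
    pair_labels: Dict[tuple, set] = {}
    pair_line: Dict[tuple, int] = {}
    for t in transitions:
        key = (t.protein, t.peptide, t.fragment, t.role)
        pair_labels.setdefault(key, set()).add(t.label)
        pair_line[key] = keyed[(*key, t.label)]
    for key, labels in pair_labels.items():
        if key[3] == "quantifier" and "labelled" not in labels:
            raise TransitionListError(
                f"{path}:{pair_line[key]}: quantifier {key[:3]} has no "
                "labelled partner"
            )
    return transitions


def load_reference_transitions() -> List[TransitionDef]:
    """The transition list shipped with the package: nine proteotypic
    peptides covering the seven urinary target proteins (CC16, RBP4, β2M,
    OPN, HSA, MYO, NF-κB) plus the BSA digestion control, with the
    instrument-tuned Q1/Q3 values, collision energies and retention times of
    the published assay."""
    from importlib import resources

    with resources.as_file(
        resources.files("mrmkit.data").joinpath("reference_transitions.csv")
    ) as p:
        return read_transitions(p)


# ---------------------------------------------------------------------------
# chromatogram traces


def write_traces(traces_by_sample: Mapping[str, Mapping[str, Trace]], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_SCHEMA["traces"] + "\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "transition_id", "time_min", "intensity"])
        for sample_id in traces_by_sample:
            for tid, trace in traces_by_sample[sample_id].items():
                for t, y in zip(trace.time, trace.intensity):
                    writer.writerow([sample_id, tid, repr(float(t)), repr(float(y))])


def read_traces(path) -> Dict[str, Dict[str, Trace]]:
    """Long-format chromatogram CSV -> {sample_id: {transition_id: Trace}}.

    Monotone time within each (sample, transition) group is enforced by the
    Trace constructor.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = ["sample_id", "transition_id", "time_min", "intensity"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out: Dict[str, Dict[str, Trace]] = {}
    for (sample_id, tid), group in df.groupby(
        ["sample_id", "transition_id"], sort=False
    ):
        out.setdefault(str(sample_id), {})[str(tid)] = Trace(
            sample_id=str(sample_id),
            transition_id=str(tid),
            time=group["time_min"].to_numpy(),
            intensity=group["intensity"].to_numpy(),
        )
    return out


# ---------------------------------------------------------------------------
# cohort tables and reports


def write_cohort(cohort: pd.DataFrame, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_SCHEMA["cohort"] + "\n")
        cohort.to_csv(fh, float_format="%.10g", lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    """Cohort CSV (sample_id + one column per analyte) -> DataFrame."""
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: cohort table needs a sample_id column")
    return df.set_index("sample_id")


def write_quant(quant: pd.DataFrame, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_SCHEMA["quant"] + "\n")
        quant.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                     lineterminator="\n")


# ---------------------------------------------------------------------------
# run configuration and orchestration


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Aggregates the pipeline's paths and fixed constants.

    The quoted method constants are the defaults: 50 ng/ml heavy-peptide
    spike, S/N 3 and 10 for LOD and LOQ, CV acceptance 25%/20%, 0.3 min RT
    tolerance, log base 10.  All randomness flows from ``seed``.
    """

    fasta: Optional[str] = None
    background_fasta: Optional[str] = None
    transitions: Optional[str] = None
    traces: Optional[str] = None
    cohort: Optional[str] = None
    out_dir: str = "mrmkit_out"
    spike_conc: float = 50.0
    min_length: int = 6
    max_length: int = 20
    gravy_min: float = -2.0
    gravy_max: float = 2.5
    max_missed_cleavages: int = 0
    rt_tolerance: float = 0.3
    cv_threshold_lowest: float = 25.0
    cv_threshold_other: float = 20.0
    lod_snr: float = 3.0
    loq_snr: float = 10.0
    log_base: float = 10.0
    analytes: Tuple[str, ...] = ("CC16", "OPN")
    adjusters: Tuple[str, ...] = ("RBP4", "B2M", "CREAT", "HSA")
    seed: int = 0

    def __post_init__(self):
        positive = [
            "spike_conc", "rt_tolerance", "cv_threshold_lowest",
            "cv_threshold_other", "lod_snr", "loq_snr",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise PipelineConfigError(f"{name} must be positive")
        if self.loq_snr <= self.lod_snr:
            raise PipelineConfigError(
                "LOQ S/N threshold must exceed the LOD threshold"
            )
        if self.log_base <= 1:
            raise PipelineConfigError("log_base must exceed 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config key(s) {sorted(unknown)}")
        for key in ("analytes", "adjusters"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_length=self.min_length,
            max_length=self.max_length,
            gravy_min=self.gravy_min,
            gravy_max=self.gravy_max,
            max_missed_cleavages=self.max_missed_cleavages,
        )


def run_pipeline(config: RunConfig, stages: Sequence[str] = ("design", "quantify", "adjust")) -> Dict[str, str]:
    """Run the requested stages; returns {artifact name: written path}.

    Stage requirements are checked before any work: ``design`` needs
    ``fasta`` (+ optionally ``background_fasta``), ``quantify`` needs
    ``traces`` plus a transition list (from ``transitions`` or the design
    stage), ``adjust`` needs ``cohort``.  Partial per-protein failures are
    reported in the artifacts, never silently dropped.  Identical config and
    seed give byte-identical outputs.
    """
    known_stages = {"design", "quantify", "adjust"}
    bad = set(stages) - known_stages
    if bad:
        raise PipelineConfigError(f"unknown stage(s) {sorted(bad)}")
    if "design" in stages and config.fasta is None:
        raise PipelineConfigError("design stage requires 'fasta'")
    if "quantify" in stages and config.traces is None:
        raise PipelineConfigError("quantify stage requires 'traces'")
    if "quantify" in stages and config.transitions is None and "design" not in stages:
        raise PipelineConfigError(
            "quantify stage requires 'transitions' (or a design stage)"
        )
    if "adjust" in stages and config.cohort is None:
        raise PipelineConfigError("adjust stage requires 'cohort'")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, str] = {}
    transitions: Optional[List[TransitionDef]] = None
    if config.transitions is not None:
        transitions = read_transitions(config.transitions)

    if "design" in stages:
        targets = read_fasta(config.fasta)
        background = (
            read_fasta(config.background_fasta) if config.background_fasta else []
        )
        logger.info("design: %d targets, %d background entries, seed=%d",
                    len(targets), len(background), config.seed)
        fcfg = config.filter_config()
        scores = []
        parent_seqs = {rec.accession: rec.sequence for rec in targets}
        for rec in targets:
            scores.extend(
                assay_design.score_candidates(
                    assay_design.digest(rec, fcfg.max_missed_cleavages),
                    background,
                    fcfg,
                    parent_sequences=parent_seqs,
                )
            )
        designed, failures = assay_design.build_transition_list(
            scores, proteins=[rec.accession for rec in targets]
        )
        path = out_dir / "transitions.csv"
        write_transitions(designed, path)
        artifacts["transitions"] = str(path)
        fail_path = out_dir / "design_failures.txt"
        fail_path.write_text("".join(acc + "\n" for acc in failures))
        artifacts["design_failures"] = str(fail_path)
        if transitions is None:
            transitions = designed

    if "quantify" in stages:
        traces = read_traces(config.traces)
        logger.info("quantify: %d samples, %d transitions",
                    len(traces), len(transitions))
        quant = peaks.quantify_batch(
            traces, transitions,
            spike_conc=config.spike_conc, rt_tolerance=config.rt_tolerance,
        )
        path = out_dir / "quant.tsv"
        write_quant(quant, path)
        artifacts["quant"] = str(path)

    if "adjust" in stages:
        cohort = read_cohort(config.cohort)
        logger.info("adjust: %d samples x %d analytes", *cohort.shape)
        logged, masked = adjustment.log_transform(cohort, base=config.log_base)
        for method in ("division", "regression"):
            report = adjustment.residual_table(
                logged, analytes=config.analytes, adjusters=config.adjusters,
                method=method,
            )
            path = out_dir / f"correlations_{method}.tsv"
            with open(path, "w", newline="") as fh:
                fh.write(f"# mrmkit-correlations-{method} v1\n")
                for note in report.notes:
                    fh.write(f"# note: {note}\n")
                fh.write(f"# masked non-positive values: {int(masked.sum())}\n")
                report.formatted().to_csv(fh, sep="\t", lineterminator="\n")
            tidy_path = out_dir / f"correlations_{method}_tidy.tsv"
            with open(tidy_path, "w", newline="") as fh:
                fh.write(f"# mrmkit-correlations-{method}-tidy v1\n")
                report.to_tidy().to_csv(
                    fh, sep="\t", index=False, float_format="%.10g",
                    lineterminator="\n",
                )
            artifacts[f"correlations_{method}"] = str(path)
            artifacts[f"correlations_{method}_tidy"] = str(tidy_path)

    return artifacts
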