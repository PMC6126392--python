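"""Reading, validation and PSM-level filtering of peptide evidence tables.

The quantitative input is a MaxQuant-style ``evidence.txt``: one tab-delimited
row per peptide feature per run, carrying the summed XIC intensity of the heavy
(labeled) and light (unlabeled) channels. Column names follow the MaxQuant
1.5.x dialect by default but are configurable, since headers drift across
MaxQuant versions. A missing intensity is represented as ``None`` (absent),
never as 0 — "0" and empty cells in the file both mean "not observed".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import ExperimentDesign

logger = logging.getLogger("sidls")

__all__ = [
    "PeptideEvidence",
    "SignalPRecord",
    "ColumnDialect",
    "FilterTally",
    "load_evidence",
    "load_signalp",
    "load_run_map",
    "filter_psms",
    "abundance_peptides",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideEvidence:
    """One quantified peptide feature at one time point.

    ``heavy_intensity``/``light_intensity`` are summed XICs in arbitrary
    units; ``None`` means the channel was not observed. ``is_shared`` marks
    peptides assigned to more than one protein group (semicolon-separated
    accession list in the source table); such peptides are excluded from
    protein-level kinetics and abundance to avoid double-counting, but kept in
    peptide-level output.
    """

    peptide_sequence: str
    protein_accession: str
    heavy_intensity: float | None
    light_intensity: float | None
    missed_cleavages: int
    is_contaminant: bool
    is_reverse: bool
    time_point: float
    sample_id: str
    is_shared: bool = False

    def __post_init__(self) -> None:
        seq = self.peptide_sequence
        if not seq or not set(seq) <= _VALID_AA:
            raise ValueError(f"invalid peptide sequence: {seq!r}")
        for name in ("heavy_intensity", "light_intensity"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")


@dataclass(frozen=True)
class SignalPRecord:
    """Signal-peptide prediction for one protein: the SignalP d-score in [0,1]."""

    protein_accession: str
    d_score: float
    has_tm_domain: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_score <= 1.0:
            raise ValueError(f"d-score must lie in [0, 1], got {self.d_score}")


@dataclass(frozen=True)
class ColumnDialect:
    """Column-name mapping for the evidence table (MaxQuant 1.5.x defaults)."""

    sequence: str = "Sequence"
    proteins: str = "Proteins"
    heavy_intensity: str = "Intensity H"
    light_intensity: str = "Intensity L"
    missed_cleavages: str = "Missed cleavages"
    contaminant: str = "Potential contaminant"
    reverse: str = "Reverse"
    raw_file: str = "Raw file"

    def required(self) -> dict[str, str]:
        return asdict(self)


@dataclass
class FilterTally:
    """Per-stage PSM removal counts from :func:`filter_psms`.

    Stages apply in order; each PSM is counted exactly once, so
    ``n_contaminant + n_reverse + n_missed_cleavage + n_multi_label_site
    + n_identification_only + n_kinetic == n_input``.
    """

    n_input: int = 0
    n_contaminant: int = 0
    n_reverse: int = 0
    n_missed_cleavage: int = 0
    n_multi_label_site: int = 0
    n_identification_only: int = 0  # no labeling residue (e.g. Arg-terminated)
    n_kinetic: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def _parse_intensity(value) -> float | None:
    """Parse an intensity cell; empty, NaN and "0" all mean absent."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    v = float(s)
    if v < 0:
        raise ValueError(f"negative intensity {v!r} in evidence table")
    return None if v == 0 else v


def _parse_flag(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip() in {"+", "1", "True", "true", "yes"}


def load_evidence(
    path,
    design: ExperimentDesign,
    run_map: Mapping[str, tuple[str, float]],
    dialect: ColumnDialect = ColumnDialect(),
) -> list[PeptideEvidence]:
    """Read a MaxQuant-style evidence TSV into :class:`PeptideEvidence` records.

    ``run_map`` maps each raw-file label to ``(sample_id, time_point_hours)``;
    it is explicit rather than parsed out of file names. Rows whose run label
    is not in the map are skipped with a logged count; a row mapped to a time
    point outside the design raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = dialect.required()
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"evidence table is missing required column(s): {missing}")

    time_set = set(design.time_points)
    records: list[PeptideEvidence] = []
    n_unmapped = 0
    for _, row in df.iterrows():
        raw = str(row[cols["raw_file"]]).strip()
        if raw not in run_map:
            n_unmapped += 1
            continue
        sample_id, t = run_map[raw]
        t = float(t)
        if t not in time_set:
            raise ValueError(
                f"run {raw!r} maps to time point {t} h, not in the design {sorted(time_set)}"
            )
        proteins = str(row[cols["proteins"]]).strip()
        leading = proteins.split(";")[0].strip()
        records.append(
            PeptideEvidence(
                peptide_sequence=str(row[cols["sequence"]]).strip().upper(),
                protein_accession=leading,
                heavy_intensity=_parse_intensity(row[cols["heavy_intensity"]]),
                light_intensity=_parse_intensity(row[cols["light_intensity"]]),
                missed_cleavages=int(float(row[cols["missed_cleavages"]] or 0)),
                is_contaminant=_parse_flag(row[cols["contaminant"]]),
                is_reverse=_parse_flag(row[cols["reverse"]]),
                time_point=t,
                sample_id=str(sample_id),
                is_shared=";" in proteins,
            )
        )
    if n_unmapped:
        logger.warning("skipped %d evidence rows with unmapped run labels", n_unmapped)
    return records


def load_signalp(path) -> list[SignalPRecord]:
    """Read a SignalP summary table (accession, d-score[, TM flag]).

    Duplicate accessions keep the first occurrence with a warning; a d-score
    outside [0, 1] is fatal and names the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("SignalP table needs at least accession and d-score columns")
    acc_col, score_col = df.columns[0], df.columns[1]
    tm_col = df.columns[2] if df.shape[1] > 2 else None

    records: list[SignalPRecord] = []
    seen: set[str] = set()
    n_dup = 0
    for i, row in df.iterrows():
        acc = str(row[acc_col]).strip()
        if acc in seen:
            n_dup += 1
            continue
        seen.add(acc)
        score = float(row[score_col])
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"d-score {score} out of [0, 1] at row {i + 2} of {path}")
        tm = _parse_flag(row[tm_col]) if tm_col is not None and str(row[tm_col]).strip() else None
        records.append(SignalPRecord(acc, score, tm))
    if n_dup:
        logger.warning("SignalP table: kept first of %d duplicated accession rows", n_dup)
    return records


def load_run_map(path) -> dict[str, tuple[str, float]]:
    """Read a run map TSV with columns: raw-file label, sample_id, time (hours)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("run map needs columns: raw file, sample id, time (hours)")
    return {
        str(r.iloc[0]).strip(): (str(r.iloc[1]).strip(), float(r.iloc[2]))
        for _, r in df.iterrows()
    }


def _label_site_category(seq: str, residue: str) -> str:
    """Classify a sequence by labeling-site content: kinetic / id_only / multi."""
    n = seq.count(residue)
    if n == 0:
        return "id_only"
    if n == 1 and seq.endswith(residue):
        return "kinetic"
    return "multi"


def filter_psms(
    evidence: Sequence[PeptideEvidence], design: ExperimentDesign
) -> tuple[list[PeptideEvidence], FilterTally]:
    """Apply the PSM filtering cascade and return kinetics-grade PSMs + tally.

    Removal order: (1) contaminant-flagged, (2) reverse (decoy) hits,
    (3) mis-cleaved peptides (potentially >1 labeling site), (4) peptides that
    do not terminate in the labeling residue or carry more than one copy of
    it. Peptides free of the labeling residue (typically Arg-terminated) are
    identification-grade only: counted in the tally and available to abundance
    via :func:`abundance_peptides`, but never fitted. Idempotent.
    """
    residue = design.label_site_residue
    tally = FilterTally(n_input=len(evidence))
    kept: list[PeptideEvidence] = []
    for ev in evidence:
        if ev.is_contaminant:
            tally.n_contaminant += 1
        elif ev.is_reverse:
            tally.n_reverse += 1
        elif ev.missed_cleavages > 0:
            tally.n_missed_cleavage += 1
        else:
            cat = _label_site_category(ev.peptide_sequence, residue)
            if cat == "kinetic":
                tally.n_kinetic += 1
                kept.append(ev)
            elif cat == "id_only":
                tally.n_identification_only += 1
            else:
                tally.n_multi_label_site += 1
    return kept, tally


def abundance_peptides(
    evidence: Sequence[PeptideEvidence], design: ExperimentDesign
) -> list[PeptideEvidence]:
    """PSMs usable for abundance: past contaminant/reverse/mis-cleavage stages.

    Abundance needs no labeling site, so identification-grade (e.g.
    Arg-terminated) peptides contribute alongside kinetics-grade ones.
    """
    return [
        ev
        for ev in evidence
        if not (ev.is_contaminant or ev.is_reverse or ev.missed_cleavages > 0)
    ]
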