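"""Secretome abundance, the 18 h secreted amount P, and flux = k * P.

Abundance at a time point is the total (heavy + light) XIC of a peptide,
averaged over the protein's quantified peptides — total material needs no
label site, so identification-grade (Arg-terminated) peptides contribute
here even though they carry no kinetic information. P is the net amount
appearing in the medium between 6 h and 24 h; multiplied by the labeling
rate constant it gives a surrogate flux from the intracellular to the
extracellular pool. A negative P (shrinking pool) is meaningful and kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .design import ExperimentDesign
from .evidence import PeptideEvidence

__all__ = [
    "SignalPClass",
    "KineticClass",
    "Population",
    "ProteinRecord",
    "compute_abundance",
    "abundance_by_time",
    "compute_secreted_amount",
    "compute_flux",
    "classify_populations",
]


class SignalPClass(Enum):
    SECRETED = "SECRETED"
    NOT_SECRETED = "NOT_SECRETED"


class KineticClass(Enum):
    HIGH_K = "HIGH_K"
    LOW_K = "LOW_K"


class Population(Enum):
    COMMON = "COMMON"
    EXCLUSIVE_A = "EXCLUSIVE_A"
    EXCLUSIVE_B = "EXCLUSIVE_B"


@dataclass
class ProteinRecord:
    """Per-protein pipeline result for one sample (cell line)."""

    protein_accession: str
    sample_id: str
    k: float | None = None
    n_peptides: int = 0
    n_ria_points: int = 0
    rss: float | None = None
    converged: bool = False
    abundance_by_time: dict[float, float] = field(default_factory=dict)
    secreted_amount_P: float | None = None
    flux: float | None = None
    d_score: float | None = None
    signalp_class: SignalPClass | None = None
    kinetic_class: KineticClass | None = None
    population: Population | None = None
    artifact_flag: bool = False


def compute_abundance(rows: Sequence[PeptideEvidence]) -> float:
    """Protein abundance at one time point from its evidence rows.

    Per peptide the abundance is H + L (an absent channel contributes 0:
    abundance measures total material, unlike RIA which needs both
    channels); co-eluting features of the same peptide are summed; the
    protein value is the mean over peptides observed at that time point.
    """
    if not rows:
        raise ValueError("compute_abundance needs at least one evidence row")
    per_peptide: dict[str, float] = {}
    for ev in rows:
        h = ev.heavy_intensity or 0.0
        l = ev.light_intensity or 0.0
        per_peptide[ev.peptide_sequence] = per_peptide.get(ev.peptide_sequence, 0.0) + h + l
    return sum(per_peptide.values()) / len(per_peptide)


def abundance_by_time(
    rows: Iterable[PeptideEvidence],
) -> dict[tuple[str, str], dict[float, float]]:
    """(sample, protein) -> {time -> mean-peptide abundance} over all rows."""
    grouped: dict[tuple[str, str, float], list[PeptideEvidence]] = {}
    for ev in rows:
        grouped.setdefault((ev.sample_id, ev.protein_accession, ev.time_point), []).append(ev)
    out: dict[tuple[str, str], dict[float, float]] = {}
    for (sample, acc, t), evs in grouped.items():
        out.setdefault((sample, acc), {})[t] = compute_abundance(evs)
    return out


def compute_secreted_amount(
    abundance: Mapping[float, float], design: ExperimentDesign
) -> float | None:
    """Net secreted amount P over the late window: A(24 h) - A(6 h).

    ``None`` when either anchor abundance is missing; negative values
    (declining pool, e.g. a leaked protein being degraded or re-internalized)
    are propagated, not clipped.
    """
    start, end = design.secretion_window
    if start not in abundance or end not in abundance:
        return None
    return abundance[end] - abundance[start]


def compute_flux(k: float | None, P: float | None) -> float | None:
    """Flux (per hour, abundance units) = k * P; ``None`` if either absent."""
    if k is None or P is None:
        return None
    return k * P


def classify_populations(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Mark each protein COMMON to both samples or EXCLUSIVE to one.

    Sample identity A/B follows the sorted order of the sample ids present.
    Crossed with the signal-peptide class this yields up to six populations.
    With a single sample every protein is EXCLUSIVE_A. Records are modified
    in place and returned.
    """
    samples = sorted({r.sample_id for r in records})
    if len(samples) > 2:
        raise ValueError(f"population classification expects <= 2 samples, got {samples}")
    by_acc: dict[str, set[str]] = {}
    for r in records:
        by_acc.setdefault(r.protein_accession, set()).add(r.sample_id)
    for r in records:
        present = by_acc[r.protein_accession]
        if len(present) == 2:
            r.population = Population.COMMON
        elif r.sample_id == samples[0]:
            r.population = Population.EXCLUSIVE_A
        else:
            r.population = Population.EXCLUSIVE_B
    return list(records)
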