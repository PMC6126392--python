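"""Deterministic TSV/JSON serialization of pipeline outputs.

Numbers are written at fixed precision so repeated runs over the same inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

from .design import ExperimentDesign
from .evidence import FilterTally
from .metrics import ProteinRecord
from .trajectories import RIATrajectory

__all__ = ["write_protein_report", "write_trajectory_report", "write_tally"]


def _fmt(x, nd: int = 6) -> str:
    if x is None:
        return ""
    return f"{x:.{nd}g}"


def write_protein_report(
    records: Sequence[ProteinRecord], path, design: ExperimentDesign
) -> None:
    """Write the per-protein result table (one row per protein per sample).

    Columns: accession, sample, peptide/point counts, k and fit diagnostics,
    abundance at each design time point, P, flux, d-score and the three
    class labels, artifact flag. Rows are sorted (sample, accession).
    """
    times = design.time_points
    header = (
        ["accession", "sample_id", "n_peptides", "n_ria_points", "k", "rss", "converged"]
        + [f"abundance_{t:g}h" for t in times]
        + ["P", "flux", "d_score", "signalp_class", "kinetic_class", "population", "artifact_flag"]
    )
    lines = ["\t".join(header)]
    for r in sorted(records, key=lambda r: (r.sample_id, r.protein_accession)):
        row = [
            r.protein_accession,
            r.sample_id,
            str(r.n_peptides),
            str(r.n_ria_points),
            _fmt(r.k),
            _fmt(r.rss),
            str(r.converged),
        ]
        row += [_fmt(r.abundance_by_time.get(t)) for t in times]
        row += [
            _fmt(r.secreted_amount_P),
            _fmt(r.flux),
            _fmt(r.d_score),
            r.signalp_class.value if r.signalp_class else "",
            r.kinetic_class.value if r.kinetic_class else "",
            r.population.value if r.population else "",
            str(r.artifact_flag),
        ]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_trajectory_report(
    trajectories: Iterable[RIATrajectory], path, design: ExperimentDesign
) -> None:
    """Peptide-level RIA table: one RIA column per design time point."""
    times = design.time_points
    header = ["sample_id", "accession", "peptide"] + [f"ria_{t:g}h" for t in times] + ["filter_status"]
    lines = ["\t".join(header)]
    for traj in sorted(
        trajectories, key=lambda t: (t.sample_id, t.protein_accession, t.peptide_sequence)
    ):
        row = [traj.sample_id, traj.protein_accession, traj.peptide_sequence]
        row += [_fmt(traj.ria_at(t)) for t in times]
        row.append(traj.filter_status.value)
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_tally(tally: FilterTally, path) -> None:
    with open(path, "w") as fh:
        json.dump(tally.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
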