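"""Experiment design: the labeling time course and which points gate filtering.

A dynamic-SILAC secretome experiment exchanges the culture medium for
heavy-lysine medium at t = 0 and collects conditioned medium at a small set of
time points. The design records those times (hours), which late points must
carry a computable RIA for a peptide to be kinetically analyzable, which early
points participate in the impossible-profile check, and the labeled residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ExperimentDesign:
    """Time-course layout of a dynamic-labeling secretome experiment.

    Parameters
    ----------
    time_points
        Strictly increasing collection times in hours since medium exchange.
    required_late_points
        Time points (hours) at which a trajectory must have a computable RIA;
        the secretome accumulates with time, so late points anchor the fit.
    early_points
        Early time points used for the impossible-profile check: an early RIA
        exceeding a late RIA cannot arise from first-order label uptake.
    label_site_residue
        Single-letter code of the isotope-labeled amino acid (heavy lysine).
    """

    time_points: tuple[float, ...] = (0.5, 1.0, 2.0, 6.0, 24.0)
    required_late_points: tuple[float, ...] = (6.0, 24.0)
    early_points: tuple[float, ...] = (0.5, 1.0)
    label_site_residue: str = "K"

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must be strictly increasing")
        if not set(self.required_late_points) <= set(tp):
            raise ValueError("required_late_points must be a subset of time_points")
        if not set(self.early_points) <= set(tp):
            raise ValueError("early_points must be a subset of time_points")
        if len(self.label_site_residue) != 1:
            raise ValueError("label_site_residue must be a single residue code")
        object.__setattr__(self, "time_points", tp)
        object.__setattr__(
            self, "required_late_points", tuple(float(t) for t in self.required_late_points)
        )
        object.__setattr__(self, "early_points", tuple(float(t) for t in self.early_points))

    @property
    def secretion_window(self) -> tuple[float, float]:
        """(start, end) hours of the net-secretion window used for P.

        P is the medium abundance gained between the earliest and latest
        required late points (default 6 h -> 24 h, an 18 h window).
        """
        return (min(self.required_late_points), max(self.required_late_points))


DEFAULT_DESIGN = ExperimentDesign()
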