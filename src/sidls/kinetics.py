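"""First-order labeling kinetics: RIA_t = 1 - exp(-k t).

Medium is exchanged for heavy-lysine medium at t = 0, so every protein starts
fully unlabeled (RIA = 0) and newly synthesized protein is fully labeled
(RIA -> 1). A classically secreted protein has no large unlabeled
intracellular pool diluting the label, so its medium RIA rises quickly (large
k, per hour); a leaked intracellular protein equilibrates with a large
pre-existing pool and labels slowly (small k). The fit is a one-parameter
nonlinear least squares with the intercept fixed at 0 and the plateau fixed
at 1, at peptide, protein (pooled peptides) or class (pooled proteins) level.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .trajectories import FilterStatus, RIATrajectory

__all__ = [
    "FitLevel",
    "KineticFit",
    "model_ria",
    "fit_k",
    "fit_protein_k",
    "fit_class_k",
    "flag_artifact_profiles",
]

K_BOUNDS = (0.0, 10.0)  # per hour; 10/h saturates within the first time point


class FitLevel(Enum):
    PEPTIDE = "PEPTIDE"
    PROTEIN = "PROTEIN"
    CLASS = "CLASS"


@dataclass(frozen=True)
class KineticFit:
    """A fitted labeling rate constant with diagnostics.

    ``k`` is per hour, constrained non-negative; ``rss`` is the residual sum
    of squares of the RIA fit; non-converged fits carry ``k=None`` and are
    excluded from any downstream pooling.
    """

    k: float | None
    n_points: int
    rss: float | None
    converged: bool
    level: FitLevel

    def __post_init__(self) -> None:
        if self.converged and (self.k is None or self.k < 0):
            raise ValueError("a converged fit must carry k >= 0")
        if not self.converged and self.k is not None:
            raise ValueError("a non-converged fit carries no k")


def model_ria(k: float, t) -> np.ndarray | float:
    """Labeling curve 1 - exp(-k t); vectorized over t."""
    t = np.asarray(t, dtype=float)
    if k < 0 or np.any(t < 0):
        raise ValueError("model_ria requires k >= 0 and t >= 0")
    out = -np.expm1(-k * t)
    return float(out) if out.ndim == 0 else out


def _initial_k(t: np.ndarray, ria: np.ndarray) -> float:
    """Closed-form start: invert the model at the latest observed point."""
    i = int(np.argmax(t))
    r = min(float(ria[i]), 0.99)
    k0 = -np.log1p(-r) / float(t[i])
    return float(np.clip(k0, 1e-6, K_BOUNDS[1] - 1e-6))


def fit_k(points: Sequence[tuple[float, float]], level: FitLevel = FitLevel.PEPTIDE) -> KineticFit:
    """Least-squares estimate of k for RIA_t = 1 - exp(-k t).

    Intercept fixed at 0, plateau fixed at 1, k bounded to [0, 10]/h;
    ordinary (unweighted) least squares on the RIA scale. Requires >= 3
    points with t > 0 and RIA in [0, 1]. All-zero RIA gives k = 0 exactly.
    Non-convergence is reported via ``converged=False``, never silently
    defaulted.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("fit_k requires at least three (t, RIA) points")
    t, ria = pts[:, 0], pts[:, 1]
    if np.any(t <= 0):
        raise ValueError("all time points must be positive")
    if np.any((ria < 0) | (ria > 1)):
        raise ValueError("RIA values must lie in [0, 1]")

    if np.all(ria == 0):
        return KineticFit(k=0.0, n_points=len(t), rss=0.0, converged=True, level=level)

    res = least_squares(
        lambda p: -np.expm1(-p[0] * t) - ria,
        x0=[_initial_k(t, ria)],
        bounds=([K_BOUNDS[0]], [K_BOUNDS[1]]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        return KineticFit(k=None, n_points=len(t), rss=None, converged=False, level=level)
    return KineticFit(
        k=float(res.x[0]),
        n_points=len(t),
        rss=float(2.0 * res.cost),
        converged=True,
        level=level,
    )


def pooled_points(trajectories: Iterable[RIATrajectory]) -> list[tuple[float, float]]:
    """All (t, RIA) observations from PASS trajectories, pooled."""
    pts: list[tuple[float, float]] = []
    for traj in trajectories:
        if traj.filter_status is not FilterStatus.PASS:
            continue
        for p in traj.points:
            if p.ria is not None:
                pts.append((p.time_point, p.ria))
    return pts


def fit_protein_k(trajectories: Sequence[RIATrajectory]) -> KineticFit | None:
    """Pool all PASS peptide trajectories of one protein into a single fit.

    Grouping peptides of the same protein increases the point count per fit;
    returns ``None`` (caller logs/excludes) when no PASS trajectory exists or
    fewer than three points remain.
    """
    pts = pooled_points(trajectories)
    if len(pts) < 3:
        return None
    return fit_k(pts, level=FitLevel.PROTEIN)


def fit_class_k(
    points_by_protein: dict[str, Sequence[tuple[float, float]]],
    members: Iterable[str],
) -> KineticFit | None:
    """Combined fit over all RIA points of every member protein.

    ``points_by_protein`` maps accession -> pooled PASS (t, RIA) points; the
    class fit pools across member accessions. This "combined fit" k for the
    signal-peptide-positive class doubles as the default kinetic cutoff.
    Empty class -> ``None``.
    """
    pts: list[tuple[float, float]] = []
    for acc in members:
        pts.extend(points_by_protein.get(acc, ()))
    if len(pts) < 3:
        return None
    return fit_k(pts, level=FitLevel.CLASS)


def flag_artifact_profiles(
    traj: RIATrajectory,
    fit: KineticFit | None = None,
    plateau_fraction: float = 0.9,
    floor: float = 0.5,
) -> bool:
    """Detect requant-style channel mis-assignment artifacts.

    True when (a) the earliest observed RIA is already at >= plateau_fraction
    of the latest RIA and at least ``floor`` — an instant rise to plateau
    with no subsequent increase, which genuine label uptake cannot produce at
    30 min — or (b) every point of the trajectory was quantified from a
    single channel only (no co-observed light and heavy features). Flagged
    trajectories stay in the outputs but are excluded from class fits.
    """
    pts = [p for p in traj.points if p.ria is not None]
    if not pts:
        return False
    if all(p.single_channel for p in pts):
        return True
    first, last = pts[0].ria, pts[-1].ria
    return first >= floor and first >= plateau_fraction * last
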