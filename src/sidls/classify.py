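"""Crossing labeling kinetics with signal-peptide predictions.

A SignalP d-score > 0.5 operationally defines a classically secreted protein
(signal-peptide-bearing, ER/Golgi-routed). The kinetic counterpart splits
proteins into fast-labeling ("high k") and slow-labeling ("low k") groups at
a cutoff chosen by one of three strategies: the combined-fit k of the
signal-peptide-positive class (default), a fixed empirical value (0.1/h), or
the association threshold (0.02/h) used in the Fisher exact test of the
kinetics-vs-SignalP agreement. All comparisons are strict: ties fall to the
negative class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import fisher_exact

from .kinetics import KineticFit
from .metrics import KineticClass, ProteinRecord, SignalPClass

logger = logging.getLogger("sidls")

__all__ = [
    "classify_by_signalp",
    "kinetic_cutoff",
    "classify_by_k",
    "association_test",
    "AssociationResult",
    "cohens_kappa",
]

SIGNALP_THRESHOLD = 0.5
SIGNALP_THRESHOLD_NO_TM = 0.45  # SignalP's own eukaryote threshold without a TM domain
FIXED_CUTOFF = 0.1  # per hour, empirical
ASSOCIATION_THRESHOLD = 0.02  # per hour, used in the Fisher exact association


def classify_by_signalp(
    d_score: float | None, threshold: float = SIGNALP_THRESHOLD
) -> SignalPClass:
    """SECRETED iff d_score > threshold (strict); no score -> NOT_SECRETED."""
    if d_score is None:
        return SignalPClass.NOT_SECRETED
    return SignalPClass.SECRETED if d_score > threshold else SignalPClass.NOT_SECRETED


def kinetic_cutoff(
    secreted_class_fit: KineticFit | None,
    strategy: str = "combined_fit",
    fixed_value: float = FIXED_CUTOFF,
) -> float:
    """Choose the k cutoff separating high-k from low-k proteins.

    Strategies: ``combined_fit`` (the class-level combined-fit k of the
    d-score > 0.5 proteins; data-driven, cell-type specific), ``fixed``
    (``fixed_value``, default 0.1/h), ``association`` (0.02/h). An empty or
    unfitted secreted class falls back to ``fixed`` with a warning.
    """
    if strategy == "fixed":
        return fixed_value
    if strategy == "association":
        return ASSOCIATION_THRESHOLD
    if strategy != "combined_fit":
        raise ValueError(f"unknown cutoff strategy: {strategy!r}")
    if secreted_class_fit is None or not secreted_class_fit.converged:
        logger.warning(
            "no combined fit for the secreted class; falling back to fixed cutoff %.3g/h",
            fixed_value,
        )
        return fixed_value
    return secreted_class_fit.k


def classify_by_k(k: float | None, cutoff: float) -> KineticClass | None:
    """HIGH_K iff k > cutoff (strict); unfitted proteins stay unclassified."""
    if k is None:
        return None
    return KineticClass.HIGH_K if k > cutoff else KineticClass.LOW_K


@dataclass(frozen=True)
class AssociationResult:
    """Fisher exact test of SignalP-positive vs fast-labeling membership.

    ``table`` is [[a, b], [c, d]]: rows = d-score > 0.5 yes/no, columns =
    k > threshold yes/no. ``odds_ratio`` is ``None`` when a margin is zero.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float | None
    p_value: float
    k_threshold: float


def association_test(
    records: Sequence[ProteinRecord],
    k_threshold: float = ASSOCIATION_THRESHOLD,
    signalp_threshold: float = SIGNALP_THRESHOLD,
) -> AssociationResult:
    """Two-sided Fisher exact test that fast labeling tracks signal peptides.

    Builds the 2x2 table of (d-score > 0.5) x (k > 0.02/h) over records with
    a fitted k and no artifact flag. A zero margin makes the odds ratio
    undefined (returned as ``None``) and p = 1.
    """
    usable = [r for r in records if r.k is not None and not r.artifact_flag]
    if not usable:
        raise ValueError("association_test needs at least one fitted record")
    a = b = c = d = 0
    for r in usable:
        sp = r.d_score is not None and r.d_score > signalp_threshold
        hk = r.k > k_threshold
        if sp and hk:
            a += 1
        elif sp:
            b += 1
        elif hk:
            c += 1
        else:
            d += 1
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return AssociationResult(table, None, 1.0, k_threshold)
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return AssociationResult(table, float(odds) if math.isfinite(odds) else None, float(p), k_threshold)


def cohens_kappa(records: Sequence[ProteinRecord]) -> float:
    """Chance-corrected agreement between kinetic and signal-peptide classes."""
    usable = [
        r
        for r in records
        if r.kinetic_class is not None and r.signalp_class is not None and not r.artifact_flag
    ]
    n = len(usable)
    if n == 0:
        raise ValueError("no classified records")
    agree = sum(
        1
        for r in usable
        if (r.kinetic_class is KineticClass.HIGH_K) == (r.signalp_class is SignalPClass.SECRETED)
    )
    p_o = agree / n
    p_hk = sum(1 for r in usable if r.kinetic_class is KineticClass.HIGH_K) / n
    p_sp = sum(1 for r in usable if r.signalp_class is SignalPClass.SECRETED) / n
    p_e = p_hk * p_sp + (1 - p_hk) * (1 - p_sp)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)
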