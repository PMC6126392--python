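"""Synthetic dynamic-SILAC secretome generator.

Emits evidence tables in the same MaxQuant dialect the reader consumes, with
the kinetic structure the method assumes (the generative inverse of the
labeling model): classically secreted proteins label fast (no diluting
intracellular pool) with rising medium abundance; leaked intracellular
proteins label slowly — pool dilution by a large pre-existing unlabeled
reservoir collapses, over a 24 h window, to a small effective first-order
rate — with static-to-declining abundance; regulated-pathway proteins keep a
constant stored pool. A configurable fraction of proteins is emitted as
single-channel "instant plateau" profiles mimicking requant-style channel
mis-assignment artifacts. All randomness flows from one seeded generator in
a fixed draw order, so a seed pins the output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .kinetics import model_ria

__all__ = ["SimulationConfig", "simulate_secretome", "default_run_map", "make_toy_fixture"]

# residues available for synthetic peptide bodies: everything except the
# labeling residue K and the alternative cleavage residue R
_BODY_AA = np.array(list("ACDEFGHILMNPQSTVWY"))

EVIDENCE_COLUMNS = [
    "Sequence",
    "Proteins",
    "Intensity H",
    "Intensity L",
    "Missed cleavages",
    "Potential contaminant",
    "Reverse",
    "Raw file",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic secretome.

    Rate constants are per hour; a 2-tuple is a log-uniform range, a float a
    fixed value. ``ria_noise_sd`` is additive Gaussian noise on the RIA scale
    (applied before the intensity split, clipped to [0, 1]);
    ``intensity_cv`` is the CV of the multiplicative lognormal intensity
    noise shared by both channels of a feature (so intensity noise cancels
    out of the RIA, as it does for a co-measured isotope pair).
    ``dropout_rate`` drops each channel independently. ``common_fraction``
    only matters with two sample ids: the probability a protein is present
    in both secretomes.
    """

    n_secreted: int = 50
    n_leaked: int = 50
    n_regulated: int = 5
    peptides_per_protein: int = 3
    time_points: tuple[float, ...] = (0.5, 1.0, 2.0, 6.0, 24.0)
    k_secreted: float | tuple[float, float] = (0.05, 0.5)
    k_leaked: float | tuple[float, float] = (0.001, 0.01)
    k_regulated: float | tuple[float, float] = (0.05, 0.5)
    ria_noise_sd: float = 0.03
    intensity_cv: float = 0.2
    dropout_rate: float = 0.1
    artifact_fraction: float = 0.02
    seed: int = 0
    sample_ids: tuple[str, ...] = ("CAM",)
    common_fraction: float = 0.6
    # per-protein baseline abundance: log-uniform over realistic XIC scales
    abundance_range: tuple[float, float] = (1e5, 1e8)

    def __post_init__(self) -> None:
        if self.n_secreted < 0 or self.n_leaked < 0 or self.n_regulated < 0:
            raise ValueError("class counts must be non-negative")
        if self.n_secreted + self.n_leaked + self.n_regulated == 0:
            raise ValueError("at least one protein must be simulated")
        if min(self.ria_noise_sd, self.intensity_cv, self.artifact_fraction) < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 1 <= len(self.sample_ids) <= 2:
            raise ValueError("one or two sample_ids supported")

    @property
    def design(self) -> ExperimentDesign:
        return ExperimentDesign(time_points=self.time_points)


def _draw_k(rng: np.random.Generator, spec: float | tuple[float, float]) -> float:
    if isinstance(spec, tuple):
        lo, hi = spec
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(spec)


def _abundance(cls: str, a0: float, t: float) -> float:
    """Class abundance model: secreted grows linearly to 3x by 24 h; leaked
    declines 20% over 24 h; regulated holds a constant store."""
    if cls == "secreted":
        return a0 * (1.0 + 2.0 * t / 24.0)
    if cls == "leaked":
        return a0 * (1.0 - 0.2 * t / 24.0)
    return a0


def _peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 14))
    return "".join(rng.choice(_BODY_AA, size=length)) + "K"


def default_run_map(
    sample_ids=("CAM",), time_points=(0.5, 1.0, 2.0, 6.0, 24.0)
) -> dict[str, tuple[str, float]]:
    """Run map matching the raw-file labels the simulator emits."""
    return {f"{s}_t{t:g}h": (s, float(t)) for s in sample_ids for t in time_points}


def simulate_secretome(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (evidence, signalp, truth) tables for a synthetic secretome.

    Per protein: draw its class-specific true k and SignalP d-score
    (Beta(8,2) for secreted, Beta(2,8) otherwise — prediction and kinetics
    are imperfectly concordant, as for real proteins), a baseline abundance,
    and peptide sequences; per peptide and time point emit heavy/light
    intensities H = RIA*A*eps, L = (1-RIA)*A*eps after RIA-scale noise and
    channel dropout. Artifact proteins emit heavy-only flat profiles. The
    truth table carries class, true k, d-score, per-time abundance, the true
    net secreted amount P and true flux for every protein/sample.
    """
    rng = np.random.default_rng(config.seed)
    times = tuple(float(t) for t in config.time_points)
    two_samples = len(config.sample_ids) == 2

    ev_rows: list[dict] = []
    sp_rows: list[dict] = []
    truth_rows: list[dict] = []

    classes = (
        [("secreted", config.k_secreted)] * config.n_secreted
        + [("leaked", config.k_leaked)] * config.n_leaked
        + [("regulated", config.k_regulated)] * config.n_regulated
    )
    for idx, (cls, k_spec) in enumerate(classes):
        acc = f"SYN{idx:04d}_{cls.upper()[:3]}"
        true_k = _draw_k(rng, k_spec)
        a, b = (8.0, 2.0) if cls == "secreted" else (2.0, 8.0)
        d_score = float(rng.beta(a, b))
        a0 = float(np.exp(rng.uniform(*np.log(config.abundance_range))))
        is_artifact = bool(rng.random() < config.artifact_fraction)
        if two_samples:
            u = rng.random()
            if u < config.common_fraction:
                present = config.sample_ids
            else:
                present = (config.sample_ids[0] if rng.random() < 0.5 else config.sample_ids[1],)
        else:
            present = config.sample_ids
        peptides = [_peptide(rng) for _ in range(config.peptides_per_protein)]
        sp_rows.append({"accession": acc, "d_score": d_score})

        for sample in present:
            abund = {t: _abundance(cls, a0, t) for t in times}
            true_p = abund.get(24.0, np.nan) - abund.get(6.0, np.nan)
            truth_rows.append(
                {
                    "accession": acc,
                    "sample_id": sample,
                    "true_class": cls,
                    "true_k": true_k,
                    "d_score": d_score,
                    "artifact": is_artifact,
                    **{f"abundance_{t:g}h": abund[t] for t in times},
                    "true_P": true_p,
                    "true_flux": true_k * true_p,
                }
            )
            sigma = float(np.sqrt(np.log1p(config.intensity_cv**2)))
            for pep in peptides:
                for t in times:
                    eps = float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
                    if is_artifact:
                        h: float | None = abund[t] * eps
                        l: float | None = None
                    else:
                        ria = float(
                            np.clip(model_ria(true_k, t) + rng.normal(0.0, config.ria_noise_sd), 0.0, 1.0)
                        )
                        h = ria * abund[t] * eps
                        l = (1.0 - ria) * abund[t] * eps
                        if rng.random() < config.dropout_rate:
                            h = None
                        if rng.random() < config.dropout_rate:
                            l = None
                    ev_rows.append(
                        {
                            "Sequence": pep,
                            "Proteins": acc,
                            "Intensity H": h,
                            "Intensity L": l,
                            "Missed cleavages": 0,
                            "Potential contaminant": "",
                            "Reverse": "",
                            "Raw file": f"{sample}_t{t:g}h",
                        }
                    )

    evidence = pd.DataFrame(ev_rows, columns=EVIDENCE_COLUMNS)
    signalp = pd.DataFrame(sp_rows, columns=["accession", "d_score"])
    truth = pd.DataFrame(truth_rows)
    return evidence, signalp, truth


def make_toy_fixture() -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Deterministic miniature evidence table exercising every filter branch.

    Ten proteins: a contaminant, a decoy, a mis-cleaved PSM, a two-lysine
    peptide, an Arg-terminated identification-only peptide, a two-point
    trajectory, a trajectory missing the 6 h anchor, an impossible
    early-high profile, a heavy-only artifact, and two clean proteins (one
    fast-labeling secreted at k = 0.2/h with rising abundance, one
    slow-labeling leaked at k = 0.005/h with declining abundance). The
    returned dict holds the hand-enumerated expected outcome at every stage.
    """
    run = lambda t: f"CAM_t{t:g}h"
    rows: list[dict] = []

    def add(seq, prot, h, l, t, mc=0, cont="", rev=""):
        rows.append(
            {
                "Sequence": seq,
                "Proteins": prot,
                "Intensity H": h,
                "Intensity L": l,
                "Missed cleavages": mc,
                "Potential contaminant": cont,
                "Reverse": rev,
                "Raw file": run(t),
            }
        )

    add("ACDEFGHK", "P_CONT", 100.0, 900.0, 6.0, cont="+")
    add("ACDEFGHK", "P_REV", 100.0, 900.0, 6.0, rev="+")
    add("ACDKEFGHK", "P_MISS", 100.0, 900.0, 6.0, mc=1)
    add("ACKDEFGK", "P_TWOK", 100.0, 900.0, 6.0)
    add("ACDEFGHR", "P_ARG", 100.0, 900.0, 6.0)
    add("ACDEFGHR", "P_ARG", 300.0, 700.0, 24.0)
    # two points only -> TOO_FEW_POINTS
    add("ADEFGHIK", "P_FEW", 600.0, 400.0, 6.0)
    add("ADEFGHIK", "P_FEW", 900.0, 100.0, 24.0)
    # four points but no 6 h anchor -> MISSING_LATE_POINTS
    for t, r in [(0.5, 0.05), (1.0, 0.10), (2.0, 0.18), (24.0, 0.95)]:
        add("AEFGHILK", "P_NOLATE", r * 1000.0, (1 - r) * 1000.0, t)
    # early RIA above late RIA -> IMPOSSIBLE_PROFILE
    for t, r in [(0.5, 0.8), (6.0, 0.4), (24.0, 0.5)]:
        add("AFGHILMK", "P_IMP", r * 1000.0, (1 - r) * 1000.0, t)
    # heavy-only artifact: no computable RIA unless requant imputes L = 0
    for t in (0.5, 6.0, 24.0):
        add("AGHILMNK", "P_ART", 1000.0, None, t)
    # clean secreted protein, two peptides, k = 0.2/h, abundance 1000 -> 3000
    for pep in ("SQNPVQPIGPQTPK", "ACDEGHILMNPK"):
        for t in (0.5, 1.0, 2.0, 6.0, 24.0):
            ria = model_ria(0.2, t)
            a = 1000.0 * (1.0 + 2.0 * t / 24.0)
            add(pep, "P_SEC", ria * a, (1 - ria) * a, t)
    # clean leaked protein, k = 0.005/h, abundance 2000 declining 20%/24 h
    for t in (0.5, 1.0, 2.0, 6.0, 24.0):
        ria = model_ria(0.005, t)
        a = 2000.0 * (1.0 - 0.2 * t / 24.0)
        add("ADEGHILMNPQK", "P_LEAK", ria * a, (1 - ria) * a, t)

    evidence = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    signalp = pd.DataFrame(
        [
            ("P_SEC", 0.92),
            ("P_LEAK", 0.08),
            ("P_IMP", 0.30),
            ("P_ART", 0.20),
            ("P_NOLATE", 0.60),
            ("P_FEW", 0.40),
            ("P_ARG", 0.70),
        ],
        columns=["accession", "d_score"],
    )
    expected = {
        "tally": {
            "n_input": 33,
            "n_contaminant": 1,
            "n_reverse": 1,
            "n_missed_cleavage": 1,
            "n_multi_label_site": 1,
            "n_identification_only": 2,
            "n_kinetic": 27,
        },
        "n_trajectories": 7,
        "status_counts": {
            "PASS": 3,
            "TOO_FEW_POINTS": 2,  # P_FEW; P_ART has no computable RIA at all
            "MISSING_LATE_POINTS": 1,
            "IMPOSSIBLE_PROFILE": 1,
        },
        "kinetic_proteins": ["P_LEAK", "P_SEC"],
        "protein_k": {"P_SEC": 0.2, "P_LEAK": 0.005},
        "abundance_P": {"P_SEC": 1500.0, "P_LEAK": -300.0},
    }
    return evidence, signalp, expected
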