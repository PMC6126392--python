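"""The SecretomeKinetics model: evidence in, classified secretome out.

``SecretomeKinetics`` holds the inputs (peptide evidence, SignalP scores,
experiment design, pipeline options); ``fit()`` runs the full analysis —
PSM filtering, RIA trajectory assembly and filtering, per-protein and
per-class first-order fits, abundance/P/flux, artifact flagging,
SignalP x kinetics classification and the Fisher association test — and
returns a ``SecretomeResults`` carrying estimates, diagnostics and a
``summary()`` table, statsmodels-style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import classify as _classify
from .classify import AssociationResult
from .design import DEFAULT_DESIGN, ExperimentDesign
from .evidence import (
    ColumnDialect,
    PeptideEvidence,
    SignalPRecord,
    abundance_peptides,
    filter_psms,
    load_evidence,
    load_signalp,
)
from .kinetics import KineticFit, fit_class_k, fit_protein_k, flag_artifact_profiles, pooled_points
from .metrics import (
    ProteinRecord,
    SignalPClass,
    abundance_by_time,
    classify_populations,
    compute_flux,
    compute_secreted_amount,
)
from .report import write_protein_report, write_tally, write_trajectory_report
from .trajectories import (
    FilterStatus,
    RIATrajectory,
    apply_trajectory_filters,
    build_trajectories,
    ria_density_by_class,
)

logger = logging.getLogger("sidls")

__all__ = ["PipelineConfig", "SecretomeKinetics", "SecretomeResults"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline options (defaults follow the method as published)."""

    requant: bool = False  # impute an absent channel as 0 when computing RIA
    cutoff_strategy: str = "combined_fit"  # or "fixed" / "association"
    fixed_cutoff: float = _classify.FIXED_CUTOFF
    signalp_threshold: float = _classify.SIGNALP_THRESHOLD
    association_k_threshold: float = _classify.ASSOCIATION_THRESHOLD
    impossible_profile_epsilon: float = 0.0
    artifact_plateau_fraction: float = 0.9
    artifact_floor: float = 0.5


class SecretomeKinetics:
    """Dynamic-SILAC secretome labeling-kinetics model.

    Parameters
    ----------
    evidence
        Filtered-input peptide evidence (``PeptideEvidence`` records).
    signalp
        Per-protein SignalP d-scores; proteins without a score classify as
        NOT_SECRETED.
    design
        The labeling time course; defaults to 0.5/1/2/6/24 h with 6 h and
        24 h as required late anchors.
    config
        Pipeline options (requant handling, cutoff strategy, thresholds).
    """

    def __init__(
        self,
        evidence: Sequence[PeptideEvidence],
        signalp: Sequence[SignalPRecord] = (),
        design: ExperimentDesign = DEFAULT_DESIGN,
        config: PipelineConfig = PipelineConfig(),
    ) -> None:
        self.evidence = list(evidence)
        self.signalp = list(signalp)
        self.design = design
        self.config = config

    @classmethod
    def from_files(
        cls,
        evidence_path,
        signalp_path=None,
        run_map: Mapping[str, tuple[str, float]] | None = None,
        design: ExperimentDesign = DEFAULT_DESIGN,
        config: PipelineConfig = PipelineConfig(),
        dialect: ColumnDialect = ColumnDialect(),
    ) -> "SecretomeKinetics":
        if run_map is None:
            raise ValueError("a run map (raw-file label -> sample, time) is required")
        evidence = load_evidence(evidence_path, design, run_map, dialect)
        signalp = load_signalp(signalp_path) if signalp_path is not None else []
        return cls(evidence, signalp, design, config)

    @classmethod
    def from_frames(
        cls,
        evidence: pd.DataFrame,
        signalp: pd.DataFrame | None = None,
        run_map: Mapping[str, tuple[str, float]] | None = None,
        design: ExperimentDesign = DEFAULT_DESIGN,
        config: PipelineConfig = PipelineConfig(),
        dialect: ColumnDialect = ColumnDialect(),
    ) -> "SecretomeKinetics":
        """Build from in-memory DataFrames in the evidence-table dialect
        (e.g. straight from :func:`sidls.simulate.simulate_secretome`)."""
        import io as _io

        buf = _io.StringIO()
        evidence.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        if run_map is None:
            from .simulate import default_run_map

            samples = sorted({str(r).rsplit("_t", 1)[0] for r in evidence[dialect.raw_file]})
            run_map = default_run_map(tuple(samples), design.time_points)
        ev = load_evidence(buf, design, run_map, dialect)
        sp: list[SignalPRecord] = []
        if signalp is not None:
            sp = [
                SignalPRecord(str(r.iloc[0]), float(r.iloc[1]))
                for _, r in signalp.iterrows()
            ]
        return cls(ev, sp, design, config)

    def fit(self) -> "SecretomeResults":
        cfg, design = self.config, self.design
        kept, tally = filter_psms(self.evidence, design)
        trajectories = [
            apply_trajectory_filters(t, design, cfg.impossible_profile_epsilon)
            for t in build_trajectories(kept, requant=cfg.requant)
        ]

        d_scores = {r.protein_accession: r.d_score for r in self.signalp}
        abundances = abundance_by_time(
            [ev for ev in abundance_peptides(self.evidence, design) if not ev.is_shared]
        )

        # group PASS trajectories by (sample, protein); shared peptides are
        # excluded from protein-level fits to avoid double-counting evidence
        by_protein: dict[tuple[str, str], list[RIATrajectory]] = {}
        for traj in trajectories:
            if traj.is_shared:
                continue
            by_protein.setdefault((traj.sample_id, traj.protein_accession), []).append(traj)

        records: list[ProteinRecord] = []
        points_by_protein: dict[str, dict[str, list]] = {}
        artifact_by_key: dict[tuple[str, str], bool] = {}
        for (sample, acc), trajs in sorted(by_protein.items()):
            passing = [t for t in trajs if t.filter_status is FilterStatus.PASS]
            if not passing:
                continue
            fit = fit_protein_k(passing)
            if fit is None:
                logger.info("protein %s/%s: no fittable points", sample, acc)
                continue
            flags = [
                flag_artifact_profiles(t, fit, cfg.artifact_plateau_fraction, cfg.artifact_floor)
                for t in passing
            ]
            artifact = all(flags)
            artifact_by_key[(sample, acc)] = artifact
            rec = ProteinRecord(
                protein_accession=acc,
                sample_id=sample,
                k=fit.k if fit.converged else None,
                n_peptides=len(passing),
                n_ria_points=fit.n_points,
                rss=fit.rss,
                converged=fit.converged,
                abundance_by_time=abundances.get((sample, acc), {}),
                d_score=d_scores.get(acc),
                artifact_flag=artifact,
            )
            rec.signalp_class = _classify.classify_by_signalp(rec.d_score, cfg.signalp_threshold)
            rec.secreted_amount_P = compute_secreted_amount(rec.abundance_by_time, design)
            rec.flux = compute_flux(rec.k, rec.secreted_amount_P)
            records.append(rec)
            points_by_protein.setdefault(sample, {})[acc] = pooled_points(passing)

        # class-level combined fits per sample (artifact proteins excluded)
        class_fits: dict[tuple[str, str], KineticFit | None] = {}
        cutoffs: dict[str, float] = {}
        associations: dict[str, AssociationResult] = {}
        for sample in sorted({r.sample_id for r in records}):
            sample_recs = [r for r in records if r.sample_id == sample and not r.artifact_flag]
            pts = points_by_protein.get(sample, {})
            sec = [r.protein_accession for r in sample_recs if r.signalp_class is SignalPClass.SECRETED]
            non = [r.protein_accession for r in sample_recs if r.signalp_class is not SignalPClass.SECRETED]
            class_fits[(sample, "SECRETED")] = fit_class_k(pts, sec)
            class_fits[(sample, "NOT_SECRETED")] = fit_class_k(pts, non)
            cutoff = _classify.kinetic_cutoff(
                class_fits[(sample, "SECRETED")], cfg.cutoff_strategy, cfg.fixed_cutoff
            )
            cutoffs[sample] = cutoff
            for r in sample_recs:
                r.kinetic_class = _classify.classify_by_k(r.k, cutoff)
            fitted = [r for r in sample_recs if r.k is not None]
            if fitted:
                associations[sample] = _classify.association_test(
                    fitted, cfg.association_k_threshold, cfg.signalp_threshold
                )

        if len({r.sample_id for r in records}) >= 1:
            classify_populations(records)

        return SecretomeResults(
            model=self,
            records=records,
            trajectories=trajectories,
            tally=tally,
            class_fits=class_fits,
            cutoffs=cutoffs,
            associations=associations,
        )


@dataclass
class SecretomeResults:
    """Fitted secretome: per-protein estimates, class fits and diagnostics."""

    model: SecretomeKinetics
    records: list[ProteinRecord]
    trajectories: list[RIATrajectory]
    tally: object
    class_fits: dict[tuple[str, str], KineticFit | None]
    cutoffs: dict[str, float]
    associations: dict[str, AssociationResult]

    @property
    def design(self) -> ExperimentDesign:
        return self.model.design

    @property
    def proteins(self) -> pd.DataFrame:
        """Per-protein results as a DataFrame (one row per protein/sample)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "accession": r.protein_accession,
                    "sample_id": r.sample_id,
                    "k": r.k,
                    "n_peptides": r.n_peptides,
                    "n_ria_points": r.n_ria_points,
                    "rss": r.rss,
                    "P": r.secreted_amount_P,
                    "flux": r.flux,
                    "d_score": r.d_score,
                    "signalp_class": r.signalp_class.value if r.signalp_class else None,
                    "kinetic_class": r.kinetic_class.value if r.kinetic_class else None,
                    "population": r.population.value if r.population else None,
                    "artifact_flag": r.artifact_flag,
                }
            )
        return pd.DataFrame(rows)

    def ria_density(self, time_point: float, sample_id: str | None = None):
        """Fig.-style kernel densities of RIA at one time, split by SignalP."""
        trajs = self.trajectories
        if sample_id is not None:
            trajs = [t for t in trajs if t.sample_id == sample_id]
        return ria_density_by_class(
            trajs, self.model.signalp, time_point, self.model.config.signalp_threshold
        )

    def summary(self) -> str:
        """Text summary: filter tally, class fits, cutoffs, association."""
        lines = ["Secretome labeling kinetics", "=" * 60]
        t = self.tally
        lines.append(
            f"PSMs: {t.n_input} in; removed {t.n_contaminant} contaminant, "
            f"{t.n_reverse} reverse, {t.n_missed_cleavage} mis-cleaved, "
            f"{t.n_multi_label_site} multi-site; {t.n_identification_only} id-only; "
            f"{t.n_kinetic} kinetic-grade"
        )
        n_pass = sum(1 for x in self.trajectories if x.filter_status is FilterStatus.PASS)
        lines.append(f"Trajectories: {len(self.trajectories)} built, {n_pass} PASS")
        lines.append(f"Proteins fitted: {len(self.records)} "
                     f"({sum(1 for r in self.records if r.artifact_flag)} artifact-flagged)")
        for (sample, cls), fit in sorted(self.class_fits.items()):
            if fit is not None and fit.converged:
                lines.append(f"  combined fit [{sample} / {cls}]: k = {fit.k:.4g} /h "
                             f"(n = {fit.n_points})")
        for sample, cutoff in sorted(self.cutoffs.items()):
            strat = self.model.config.cutoff_strategy
            lines.append(f"  kinetic cutoff [{sample}]: {cutoff:.4g} /h ({strat})")
        for sample, assoc in sorted(self.associations.items()):
            orr = f"{assoc.odds_ratio:.3g}" if assoc.odds_ratio is not None else "undefined"
            lines.append(
                f"  SignalP>0.5 vs k>{assoc.k_threshold:g}/h [{sample}]: "
                f"table {assoc.table}, OR = {orr}, Fisher p = {assoc.p_value:.3g}"
            )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the protein report, trajectory table and tally JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_protein_report(self.records, out / "proteins.tsv", self.design)
        write_trajectory_report(self.trajectories, out / "trajectories.tsv", self.design)
        write_tally(self.tally, out / "filter_tally.json")
        (out / "summary.txt").write_text(self.summary() + "\n")

    def plot_flux_vs_k(self, sample_id: str | None = None, ax=None):
        """Scatter of flux against k, colored by SignalP class."""
        import matplotlib.pyplot as plt

        df = self.proteins
        if sample_id is not None:
            df = df[df.sample_id == sample_id]
        df = df.dropna(subset=["k", "flux"])
        if ax is None:
            _, ax = plt.subplots()
        for cls, color in [("SECRETED", "tab:red"), ("NOT_SECRETED", "tab:blue")]:
            sub = df[df.signalp_class == cls]
            ax.scatter(sub["k"], sub["flux"], s=12, c=color, label=cls, alpha=0.7)
        ax.set_xscale("log")
        ax.set_xlabel("k (/h)")
        ax.set_ylabel("flux = k · P (/h)")
        ax.legend()
        return ax

    def plot_ria_density(self, time_point: float, sample_id: str | None = None, ax=None):
        """Kernel density of RIA at one time point, split by SignalP class."""
        import matplotlib.pyplot as plt

        curves = self.ria_density(time_point, sample_id)
        if ax is None:
            _, ax = plt.subplots()
        for cls, color in [("secreted", "tab:red"), ("not_secreted", "tab:blue")]:
            grid, dens = curves[cls]
            if grid.size:
                ax.plot(grid, dens, color=color, label=cls)
        ax.set_xlabel(f"RIA at {time_point:g} h")
        ax.set_ylabel("density")
        ax.legend()
        return ax
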