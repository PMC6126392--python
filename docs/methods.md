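# Methods

## The labeling model

At medium exchange (t = 0) the cells switch to heavy-lysine medium, so every
protein already in the conditioned medium is unlabeled (RIA = 0) and newly
synthesized protein is fully labeled (RIA → 1). For a peptide observed in the
medium the relative isotope abundance RIA_t = H/(H+L) is modeled as a
one-parameter first-order rise to plateau,

    RIA_t = 1 − exp(−k·t),

with the intercept fixed at 0 and the plateau fixed at 1. The single
parameter k (per hour) absorbs everything between synthesis and appearance in
the medium: for a classically secreted protein it approaches the synthesis/
transit rate (no diluting pool); for a leaked intracellular protein the
dilution of new label into a large pre-existing pool collapses, over a 24 h
window, to a small effective k. Amino-acid recycling means the true attainable
plateau is slightly below 1; we keep the plateau fixed at 1 anyway (a free
plateau is unidentifiable with five time points and would trade off directly
against k), accepting a small downward bias on k for very fast proteins.

Assumptions: precursor (tRNA) pool equilibrates fast relative to the first
time point; H and L intensities of a feature are measured on the same scale so
their ratio cancels ionization efficiency; no re-uptake or extracellular
degradation term (those manifest as negative P instead).

## Fitting

`fit_k` minimizes the unweighted squared RIA residuals with
`scipy.optimize.least_squares`, k bounded to [0, 10]/h, tolerances 1e−14. The
start value inverts the model at the latest point, k₀ = −ln(1 − min(RIA_last,
0.99))/t_last, which is basin-adjacent for this monotone one-parameter
problem. An all-zero trajectory short-circuits to k = 0 exactly. Fits need ≥ 3
points; non-convergence is reported, never defaulted. Protein-level fits pool
all (t, RIA) points of the protein's PASS trajectories; class-level "combined
fits" pool across proteins (artifact-flagged proteins excluded). Pooling means
each PSM, not each peptide, carries equal weight — duplicating a trajectory
does not move the optimum, which the tests assert.

## Filtering cascade

PSM level, in order: contaminant flag, decoy flag, missed cleavage (> 1
potential labeling site), then sequence check — kinetics uses only peptides
with exactly one C-terminal labeling lysine. Lysine-free (Arg-terminated)
peptides are retained for identification/abundance only. Trajectory level, in
order: ≥ 3 computable RIA points; computable RIA at both required late points
(6 h and 24 h — the secretome accumulates, so late anchors are mandatory); no
early point (0.5/1 h) with RIA strictly greater than any late point
(first-order uptake cannot produce that; an `epsilon` option relaxes the
strictness for noisy data, default 0). First failure wins, so every
trajectory carries exactly one status.

Artifact detection: requant-style channel mis-assignment shows up as an
instant plateau. A trajectory is flagged when its earliest RIA is ≥ 0.9 of
its latest and ≥ 0.5 (both configurable operationalizations of "instant rise
to plateau"), or when every point was quantified from a single channel. A
protein is flagged when all of its PASS trajectories are flagged; flagged
proteins stay in the report but are excluded from class fits and
classification.

Missing intensities are absent, never 0, and absence is asymmetric by design:
an absent channel invalidates RIA (both channels are needed for a ratio) but
contributes 0 to abundance (H+L measures total material). The `requant`
switch imputes an absent channel as 0 for RIA, emulating MaxQuant's requant
mode; default off.

## Abundance, P, flux

Per peptide and time point, abundance is H+L (co-eluting features summed);
per protein it is the mean over peptides observed at that time point, with no
cross-run normalization (raw summed XICs). P = A(24 h) − A(6 h) is the net
amount secreted over the late 18 h window; negative values (shrinking pool)
are propagated. flux = k·P. Peptides shared between protein groups are
excluded from both protein-level fits and abundance to avoid double-counting;
they remain in the peptide-level output.

## Classification

SignalP: SECRETED iff d-score > 0.5, strict (0.45 is exposed for the
no-TM-domain convention but 0.5 is the single default). Kinetic: HIGH_K iff
k > cutoff, strict, with three cutoff strategies — `combined_fit` (default:
the class-level combined-fit k of the SignalP-positive proteins, data-driven
and cell-type specific), `fixed` (default 0.1/h), and `association` (0.02/h).
The three thresholds serve different roles and are deliberately not merged:
the combined fit describes the secreted class's aggregate kinetics, 0.1/h is
an empirical classification cutoff, and 0.02/h is the split used in the
Fisher exact association test. Note the combined-fit cutoff sits near the
middle of a broad secreted-k distribution, so when the question is agreement
with an external truth (simulation truth classes, or Cohen's kappa against
SignalP) the `association` threshold is the appropriate instrument, and that
is what the recovery tests use. The association test itself is two-sided
(`scipy.stats.fisher_exact`); a zero margin returns p = 1 with the odds ratio
reported as absent.

## The synthetic secretome

The generator emulates the pool-dilution logic of the experiment: secreted
proteins draw k from log-uniform [0.05, 0.5]/h with medium abundance growing
linearly to 3× baseline by 24 h; leaked proteins draw k from log-uniform
[0.001, 0.01]/h with abundance declining 20% over 24 h (the single-exponential
slow-k form stands in for explicit two-compartment pool dilution, which is
indistinguishable from it on a 5-point, 24 h window); regulated-pathway
proteins keep a constant stored pool with a secreted-like k (their labeling
delay is biologically ambiguous, so the rate is a parameter, not an
assertion). Defaults: 50/50/5 proteins, 3 peptides each, time points
0.5/1/2/6/24 h. Per-protein baselines are log-uniform over [1e5, 1e8]
(realistic XIC scales). d-scores come from Beta(8,2) for secreted and
Beta(2,8) otherwise, so prediction and kinetics are imperfectly concordant,
as in real data (~2% of proteins land on the wrong side of 0.5).

Noise: additive Gaussian on the RIA scale (sd 0.03, clipped to [0, 1]),
applied before the intensity split H = RIA·A·ε, L = (1−RIA)·A·ε with a shared
multiplicative lognormal ε (CV 0.2) — shared, because the two channels of one
feature are co-measured, so intensity noise cancels from the ratio and RIA
reconstructs exactly from the emitted intensities. Each channel then drops
out independently with probability 0.1. 2% of proteins are emitted as
heavy-only instant-plateau artifact profiles. All draws come from one seeded
`numpy` generator in a fixed documented order: identical seeds give
byte-identical tables.

What the simulator does not emulate: between-peptide ionization-efficiency
differences (every peptide reports the protein-level abundance), retention-
time/match-between-runs structure in missingness (dropout is i.i.d.),
co-elution interference, and saturation effects. Consequences worth knowing:
passing recovery tests shows the estimator chain is correct under the stated
noise model, not that real evidence tables are this clean; and because the
leaked class's 20% abundance decline is shallow relative to intensity noise
plus dropout, the sign of the estimated P is recovered essentially always for
the secreted class but only ~70–75% of the time for the leaked class — the
kinetic classifier, not the sign of P, is the reliable discriminator at these
noise levels, which mirrors why abundance alone is not enough in the first
place.

## Problem sizes and numerical choices

The recovery experiments use the default 105-protein simulation
(~1,600 evidence rows), which fits on one CPU in seconds and gives ~70
fitted proteins after stringent filtering — enough for stable medians and a
decisive Fisher test. The grid-search oracle uses a 1e−4 step over [0, 2.5]/h;
the Fisher enumeration oracle uses exact integer binomial coefficients. Report
files serialize numbers at 6 significant digits so repeated runs are
byte-identical. Degenerate inputs: empty evidence yields an empty report with
a zeroed tally; a class with < 2 RIA values yields an empty density curve with
a warning; an all-identical RIA set gets a fixed narrow-bandwidth bump since
Silverman's rule collapses. Proteins lacking any PASS trajectory are excluded
from the protein report (they have no kinetic estimate to report); abundance-
only proteins can be recovered from the evidence directly if needed.

## Known limitations

Single-pool first-order kinetics only (no precursor-enrichment or
two-compartment models, no confidence intervals on k — point estimates match
the scope of the method); no cross-run normalization or retention-time
alignment; protein inference is "leading accession" with shared peptides
excluded from protein-level aggregation; the plateau-at-1 convention biases k
slightly low when label recycling is substantial.
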