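# sidls — dynamic-SILAC secretome labeling kinetics

Global secretome profiling of cultured cells has a chronic interpretation
problem: alongside genuinely secreted proteins (signal-peptide-bearing,
ER/Golgi-routed), conditioned medium always contains intracellular proteins
released by damage, apoptosis or plain leakage, and a single-time-point
experiment cannot tell the two apart. `sidls` implements a kinetic solution:
pulse the cells with heavy lysine at medium exchange and follow, per peptide,
the relative isotope abundance

```
RIA_t = H / (H + L)
```

over a short time course (0.5, 1, 2, 6, 24 h). A classically secreted protein
has no large unlabeled intracellular pool diluting the label, so its medium
RIA rises quickly toward 1; a leaked intracellular protein equilibrates with a
big pre-existing pool and barely labels. Fitting the one-parameter first-order
rise

```
RIA_t = 1 − exp(−k·t)        (intercept 0, plateau 1, k ≥ 0 per hour)
```

at peptide, protein (pooled peptides) and class (pooled proteins) level turns
the secretome into rate constants. Combined with the net amount secreted over
the late window, `P = A(24 h) − A(6 h)` (A is the mean per-peptide H+L XIC),
and the flux surrogate `flux = k·P`, the package classifies each protein as
fast-labeling/"high k" (physiologically secreted) or slow-labeling/"low k"
(leakage), and cross-validates the split against SignalP d-scores (> 0.5 =
classical signal peptide) with a Fisher exact test.

The package consumes MaxQuant-style `evidence.txt` tables, applies the
published filtering cascade (contaminants, decoys, mis-cleaved peptides,
peptides without exactly one C-terminal labeling lysine, trajectories with
< 3 points or missing 6/24 h anchors or impossible early-high profiles,
requant-style single-channel artifacts) and ships a fully parameterized
synthetic-secretome generator so the whole pipeline is testable without any
external download.

## Worked example

```python
from sidls import SecretomeKinetics, SimulationConfig, simulate_secretome

# synthetic secretome: 50 secreted, 50 leaked, 5 regulated-pathway proteins
evidence, signalp, truth = simulate_secretome(SimulationConfig(seed=1))
results = SecretomeKinetics.from_frames(evidence, signalp).fit()
print(results.summary())
```

prints

```
Secretome labeling kinetics
============================================================
PSMs: 1575 in; removed 0 contaminant, 0 reverse, 0 mis-cleaved, 0 multi-site; 0 id-only; 1575 kinetic-grade
Trajectories: 315 built, 131 PASS
Proteins fitted: 72 (0 artifact-flagged)
  combined fit [CAM / NOT_SECRETED]: k = 0.01442 /h (n = 187)
  combined fit [CAM / SECRETED]: k = 0.105 /h (n = 352)
  kinetic cutoff [CAM]: 0.105 /h (combined_fit)
  SignalP>0.5 vs k>0.02/h [CAM]: table ((43, 0), (5, 24)), OR = undefined, Fisher p = 1.49e-14
```

Reading this: of 315 peptide trajectories, 131 survive the stringent filters;
72 proteins get a pooled first-order fit. The combined-fit rate constant of
the SignalP-positive class (0.105/h) is ~7-fold that of the SignalP-negative
class (0.014/h), and the 2×2 association between having a signal peptide and
labeling faster than 0.02/h is overwhelming (Fisher p ≈ 1.5e-14; the odds
ratio is undefined here because no SignalP-positive protein labels slowly).
`results.proteins` is a DataFrame with per-protein `k`, `P`, `flux`, d-score
and class labels; `results.save(outdir)` writes the deterministic TSV/JSON
reports, and `results.plot_flux_vs_k()` / `results.plot_ria_density(6.0)`
reproduce the standard diagnostic views.

The same pipeline runs from the shell:

```bash
sidls simulate --out sim/ --seed 1
sidls run --evidence sim/evidence.txt --signalp sim/signalp.tsv \
          --run-map sim/run_map.tsv --out results/
```

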