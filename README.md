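# plimse

EEG functional-connectivity and signal-complexity analysis for two-group
(patient vs. control) resting-state studies, with a synthetic cohort
generator for method validation.

`plimse` implements the full analysis chain used to contrast a
healthy-control-like (HC) group against an Alzheimer's-disease-like (AD)
group on 16-channel, 200-Hz resting EEG:

1. **Connectivity — phase lag index (PLI).** Each recording is band-passed
   into the canonical bands (delta 2–4, theta 4–8, alpha 8–13, beta 13–30,
   gamma 30–60 Hz), instantaneous phases φ(t) are taken from the analytic
   signal, and for every electrode pair (a, b)

   PLI_ab = | (1/T) Σᵢ sign(Δφ_ab(tᵢ)) |,

   with Δφ wrapped into (−π, π] and sign(0) = 0. Consistently lagged pairs
   score near 1; random or zero-lag (volume-conducted) relationships score
   near 0. PLI is computed on ten 5-s epochs and averaged. The node degree
   ND_a = (1/(K−1)) Σ_b PLI_ab summarises each electrode's coupling.

2. **Complexity — multiscale entropy (MSE).** Sample entropy
   SampEn = −ln(A/B) — where B counts length-m template pairs within a
   Chebyshev tolerance r and A the same for length m+1 (m = 2,
   r = 0.2 × SD) — is evaluated on coarse-grained copies of the broadband
   signal at scales 1–20. The mean SampEn over scales 1–5 is the
   small-scale complexity feature.

3. **Group statistics.** Electrode-pair, node-degree and SampEn t-maps with
   pooled Benjamini–Hochberg FDR at q < 0.05 and q < 0.01 (600, 80 and 320
   tests respectively); mixed repeated-measures ANOVA (group × electrode,
   and group × electrode × scale) with Greenhouse–Geisser-corrected degrees
   of freedom; per-group Pearson correlation grids between SampEn and ND
   (16 electrodes × 5 bands × 20 scales = 1,600 tests, FDR-pooled).

4. **Classification.** PCA keeping the smallest number of components that
   explain ≥ 90 % of variance, then a linear SVM under stratified 5-fold
   cross-validation; performance is pooled held-out accuracy and the area
   under the ROC curve.

Because comparable clinical recordings are rarely shareable, the
`synthetic` module generates labeled cohorts with independently tunable
per-band phase coupling (a shared band-limited oscillator mixed at strength
κ with per-channel phase lags) and temporal complexity (broadband 1/f^β
noise). The default configuration injects the qualitative disease contrast
— reduced alpha/beta/gamma coupling and a smoother fast component in the
AD-like group — so the whole pipeline can be validated by parameter
recovery.

## Worked example

```
cat > demo.yaml <<'YAML'
cohort:
  n_hc: 6
  n_ad: 6
  master_seed: 11
YAML
plimse run --config demo.yaml --out demo_out
```

This simulates twelve 60-s recordings, trims 1,000 samples from each end
(leaving 50 s), runs every stage, and prints a JSON report (about a minute
on one core). Key lines from the run above:

```
"nd":        {"n_tests": 80,  "n_significant_q0.05": 48, ...}
"sampen":    {"n_tests": 320, "n_significant_q0.05": 65, ...}
"pli_pairs": {"n_tests": 600, "n_significant_q0.05": 124, ...}
"nd_alpha":  {"accuracy_pct": 100.0, "auc": 1.0, "n_components": 2, ...}
"sampen_1_5":{"accuracy_pct": 100.0, "auc": 1.0, "n_components": 1, ...}
```

The 48 significant node-degree cells are exactly the 16 electrodes in each
of the alpha, beta and gamma bands — the three bands in which the AD-like
group's coupling was reduced — and none fall in delta or theta, where the
groups share the same coupling. The alpha-band ANOVA reports a group main
effect of F = 1026.2 (Greenhouse–Geisser p = 2.1 × 10⁻¹¹), and the SampEn
ANOVA a group × scale interaction of F = 203.7 (ε = 0.246,
p = 4.8 × 10⁻³⁰): with only six subjects per group, the injected contrasts
dominate. `demo_out/` also contains tidy CSVs of every grid
(`grid_nd.csv`, `grid_sampen.csv`, `grid_pli_pairs.csv`, `grid_corr_*.csv`),
per-band ANOVA tables, per-subject features (`node_degree.csv`, `mse.csv`),
ROC curves, and `run_report.json` with the config hash and seed; rerunning
with the same config reproduces all of them byte for byte.

Individual stages are available as `plimse simulate | preprocess |
connectivity | complexity | classify`, and everything is importable from
the library (`plimse.pli`, `plimse.sample_entropy`,
`plimse.rm_anova_mixed`, `plimse.svm_cv`, ...).

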