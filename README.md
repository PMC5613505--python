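# emoeeg

Entropy analysis of emotion-evoked EEG for staging schizophrenia
severity.

Clinician-rated severity scales (the PANSS — positive, negative and
general-psychopathology subscales; totals near 75 mark *moderate*, near
95 *marked* illness) are slow and subjective.  A candidate objective
marker is the *complexity* of emotion-evoked EEG: patients view blocks
of affective pictures (HVLA / LVLA / LVHA — valence × arousal
categories) while midline EEG (Fz, Cz, Pz, earlobe references A1/A2,
256 Hz) is recorded; the irregularity of band-limited signal fragments,
summarised by entropy statistics, is then used to discriminate severity
groups and to track PANSS totals.

`emoeeg` implements that analysis as a tested, reusable pipeline:

* **entropy estimators** — approximate entropy
  ApEn(m, r, N) = Φ^m(r) − Φ^{m+1}(r); permutation entropy
  PE = −Σ p(π) ln p(π) over ordinal patterns; and amplitude-aware PE,
  which weights each window by (A/m)Σ|xₖ| + ((1−A)/(m−1))Σ|Δxₖ|
  (`emoeeg.entropy_core`, numba-accelerated, oracle-verified to 1e−10);
* **preprocessing** — A1/A2/linked-ears re-referencing, zero-phase
  order-6 Butterworth decomposition into θ(4–8), α(8–12), β1(12–15),
  β2(15–18), β3(18–30) Hz, and segmentation of the 225-s, nine-block
  stimulus timeline into 15-s emotion fragments (`emoeeg.preprocess`);
* **features** — the subject × (electrode, method, emotion, band,
  section) entropy table with CSV round-trip (`emoeeg.features`);
* **classification** — per condition cell, z-score → PCA retaining 95%
  variance → quadratic-kernel SVM, 27-fold stratified cross-validation,
  leakage-free by construction (`emoeeg.classify`);
* **statistics** — Pearson/regression of features against PANSS totals,
  pooled-variance group t tests, and `t_from_summary`, which reproduces
  published t values from printed (mean, SD, n) summaries alone
  (`emoeeg.stats`);
* **synthetic cohorts** — a generator that plants the published group
  structure (10 controls + 17 moderate + 17 marked, PANSS
  70.06 ± 4.25 vs 95.88 ± 10.53, a marked > moderate β1/β2 complexity
  effect, feature–PANSS correlation ≈ 0.55) into band-limited
  noise/sinusoid mixtures, so every stage is testable without patient
  recordings (`emoeeg.synthetic_data`);
* **I/O and workflow** — CSV/EDF readers, run configs, the end-to-end
  `run_pipeline`, and the `emoeeg` CLI with `simulate`, `features`,
  `classify`, `stats`, `t-from-summary` and `run` subcommands
  (`emoeeg.cli_io`).

The numbered scripts under `analysis/` retrace the study on the default
synthetic cohort: generator calibration, cohort simulation, feature
extraction, the identification-rate grid, and the severity statistics.
Their small output tables land in `results/`.

## Worked example

Published group summaries are data: the moderate-vs-marked t statistic
for any cell of the published β-band table can be recomputed from its
printed means and SDs alone.

```pycon
>>> from emoeeg import t_from_summary
>>> res = t_from_summary(0.537, 0.066, 17, 0.607, 0.014, 17)   # β2, LVHA, section 3
>>> print(f"t = {res.value:.3f}, df = {res.df}, p = {res.p:.2g} {res.stars}")
t = -4.278, df = 32, p = 0.00016 ***
```

The published value for that cell is −4.276; the 0.002 gap is
print-rounding.  The moderate group's mean β2 ApEn (0.537) sits ~4.3
pooled standard errors below the marked group's (0.607): markedly ill
patients show *more* irregular β-band activity, and the difference is
far beyond chance at n = 17 + 17.

End to end on synthetic data:

```pycon
>>> from emoeeg import CohortSpec, generate_cohort, correlation_grid, ttest_grid, svm_cv, ClassifierConfig
>>> from emoeeg.cli_io import cohort_feature_table
>>> cohort = generate_cohort(CohortSpec(n_normal=0, electrodes=("Fz", "A1", "A2"), seed=1))
>>> table = cohort_feature_table(cohort, methods=("ApEn",))
>>> ttest_grid(table, cohort.metadata).groupby("band")["t"].mean().round(2)
band
beta1   -4.18
beta2   -3.81
beta3   -1.74
Name: t, dtype: float64
>>> correlation_grid(table, cohort.metadata).loc[["beta1", "beta2"], "r"].mean().round(3)
np.float64(0.563)
>>> labels = cohort.labels()
>>> svm_cv(table.select_cell("Fz", "ApEn", "HVLA").to_numpy(),
...        [labels[s] for s in table.subjects], ClassifierConfig(seed=1)).accuracy
82.3529411764706
```

The planted β-band effect comes back with the right sign and size
(group t ≈ −4 in β1/β2, none in θ/α), the pooled entropy–PANSS
correlation lands near the 0.55 target, and the Fz/ApEn/HVLA cell
classifies the two patient groups at ~82% cross-validated accuracy on
this cohort (averaged over 20 cohort seeds: group t ≈ −4.5, r ≈ 0.57,
accuracy ≈ 77%) — the same qualitative picture as the published grid.

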