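# Methods

## The analysis being modelled

Subjects view blocks of emotionally evocative pictures — three
categories, HVLA (high valence / low arousal), LVLA (low valence / low
arousal) and LVHA (low valence / high arousal) — while midline EEG (Fz,
Cz, Pz against earlobe references A1/A2) is recorded at 256 Hz.  Each
stimulation unit shows five pictures for 3 s (15 s) and is followed by
10 s of rest; every category appears three times, so a session lasts
225 s and contributes nine stimulation fragments.  The scientific
question is whether the *complexity* of those fragments, summarised by
entropy statistics per frequency band, (a) discriminates moderately from
markedly ill schizophrenia patients and (b) tracks symptom severity as
measured by the PANSS total score (Positive and Negative Syndrome
Scale; positive + negative + general-psychopathology subscales; totals
near 75 ≈ moderate, near 95 ≈ marked illness).

The pipeline is: re-reference → five-band decomposition → fragment
segmentation → entropy features → (A) PCA + SVM group classification
and (B) correlation/regression of features against PANSS totals plus
group t tests.

## Entropy estimators

All three estimators return natural-log entropies (nats).

**Approximate entropy (ApEn).**  ApEn(m, r, N) = Φ^m(r) − Φ^{m+1}(r),
where Φ^p(r) is the mean natural log of C_i^p(r), the fraction of
length-p templates within Chebyshev distance r of template i.  The
denominator is the template count N − p + 1 at each level and the
self-match is counted, so every C_i^p > 0 and the statistic is defined
for any finite series.  Defaults m = 2 and r = 0.2 × SD of the analysed
fragment — the field-standard convention, exposed in `ApEnConfig`; the
SD-relative tolerance makes ApEn scale-invariant.  Two boundary facts
are worth knowing and are asserted in the tests: a constant series has
ApEn exactly 0, but "perfectly regular" finite series generally do not —
a monotone ramp or a 2-periodic series carries an O(1/N) residue because
the level-(m+1) template set is one shorter than the level-m set.

The production kernel sorts templates by first coordinate so candidate
matches lie in a contiguous window, and counts level-m and level-(m+1)
matches in one pass (a match at m+1 requires one at m).  It is compiled
with numba and agrees with a naive transcription of the definition to
1e−10 across 100 random series; a 3840-sample fragment takes ~5–10 ms.

**Permutation entropy (PE).**  Shannon entropy of the distribution of
ordinal patterns of m consecutive samples (delay 1 by default);
p(π) = f(π)/(N − m + 1).  Default order m = 3.  Ties are ranked by order
of occurrence (stable argsort), the standard Bandt–Pompe convention.

**Amplitude-aware permutation entropy (AAPE).**  Each window contributes
to its ordinal pattern the weight (A/m) Σ|x| + ((1−A)/(m−1)) Σ|Δx|,
A = 0.5 by default; pattern probabilities are weight shares, summing to
one.  When every window has equal weight AAPE reduces exactly to PE.
An optional `normalize` flag divides PE/AAPE by ln(m!) (it is off by
default; both raw and normalized scales are available because the
choice does not change ordinal information, only the scale).

## Preprocessing

Bands: θ 4–8, α 8–12, β1 12–15, β2 15–18, β3 18–30 Hz.  Each band is
isolated by an order-6 Butterworth band-pass (three pole pairs,
second-order sections) applied forward–backward.  Zero-phase filtering
was chosen so that fragment boundaries are not phase-delayed; the cost
is a doubled effective roll-off, which only helps the band-separation
contract (center-frequency gain ≥ 0.95, DC leakage < 1e−6, ≥ 40 dB at
4× the upper band edge — the measured margins are far larger).
Re-referencing subtracts A1, A2, or their average (default) from every
scalp channel.  Fragments are half-open sample ranges
[onset, onset + duration), 0-based; rest periods are discarded.  No
artifact rejection is applied (the modelled protocol relied on shielded
acquisition); `segment` accepts a user-supplied boolean mask that
blanks samples to NaN so downstream code fails loudly rather than
silently absorbing artifacts.

## Classification protocol

One condition cell = the subjects × 15 matrix of (5 bands × 3 sections)
entropies for a fixed electrode, entropy method and emotion.  Per
cross-validation fold: z-score using training-fold statistics → PCA
keeping the smallest component count reaching 95% cumulative explained
variance → SVM with a quadratic kernel (γ·x·y + 1)², C = 1, with
sklearn's automatic kernel scale γ = 1/(n_features · Var).  The
automatic scale is the same convention MATLAB's quadratic-SVM preset
uses; with γ fixed at 1 the kernel magnitudes on 15 z-scored features
are ~16² and the SVM visibly underfits (56% vs 77% cross-validated
accuracy on a planted-effect cohort), so the auto-scaled kernel is the
package's reading of "quadratic kernel".

Folds: 27 by default, matching the modelled protocol (leave-one-out for
its 27-subject comparisons; folds of 1–2 subjects for the 34-patient
comparison).  Because standard stratified splitters refuse fold counts
above the smaller class size, folds are built by shuffling within class,
interleaving classes by fractional position and splitting the merged
order evenly; `folds="loo"` is available and identical to folds = n.
Everything is deterministic given (data, seed, config).  Preprocessing
is never fit on held-out rows; the test suite includes an intentional
leakage variant (fit scaler, PCA and SVM on all rows, then score those
rows) and demonstrates the inflation it buys on pure noise.

## Statistics

Pearson r with the exact t-transform p (df = n − 2); simple least-squares
regression (slope p identical to the Pearson p); two-sample t tests with
pooled variance by default.  Pooled rather than Welch because
recomputing the published group t values from their printed means/SDs
with the pooled formula reproduces them within print-rounding error
(max deviation 0.09, fully explained by ±0.0005 input rounding; the
well-conditioned showcase cells agree to < 0.005); Welch is a flag.
`t_from_summary` computes the same pooled t from (mean, SD, n) alone and
is algebraically identical to the raw-data route — the property the test
suite checks to 1e−10 — which is what makes published summary tables
re-analysable without recordings.  Grids report unadjusted p values with
the conventional stars (* .05, ** .01, *** .001), matching the modelled
presentation; Benjamini–Hochberg adjusted columns are an opt-in extra.

Degenerate inputs: zero pooled variance returns t = 0, p = 1 when means
agree and signals ±inf, p = 0 otherwise; constant inputs make Pearson r
undefined and raise.

## Synthetic cohorts

No recordings from the modelled study are available, so the generator
manufactures cohorts carrying exactly the structure the analysis is
meant to detect, with published numbers used wherever they exist:
group sizes 10/17/17, PANSS totals N(70.06, 4.25²) and N(95.88, 10.53²),
subscores partitioning the total ≈ 1:1:2 (summing exactly), and a
β-band severity effect oriented marked > moderate with a pooled
feature–PANSS correlation near 0.55.

Each scalp channel is a sum over the five bands of unit-variance band
processes scaled by a relative band power (θ 1.0, α 0.8, β1 0.35,
β2 0.30, β3 0.25 — a generic 1/f-ish EEG profile; overall RMS 10 µV).
A band process mixes band-filtered white noise (fraction c) with a
sinusoid at the band's geometric center (fraction 1 − c, random phase).
This "MIX-style" construction was chosen because fragment ApEn/PE are
monotone in c — approximately linear in ln c below c ≈ 0.3 and
saturating above ≈ 0.5 (see `analysis/01_calibrate_generator.py`) —
without pretending to model cortical physiology.

Complexity defaults (calibrated once against the published group
summaries, then frozen): base c = 0.18 in β1/β2, raised by
beta_effect = 0.47 for the marked group; per-subject log-normal spread
of 0.6 driven by a single severity latent z, identical in every group.
The identical spread is what makes the beta_effect = 0 null an exact
exchangeability statement, and the saturating response converts it into
the published variance pattern automatically: moderate subjects sit on
the steep part (entropy SD ≈ 0.05–0.07), marked subjects on the shelf
(SD ≈ 0.01).  Non-effect bands get independent 0.10 log jitter; θ/α
bases (0.5, 0.3) put them mid-curve, and the β3 base (0.8) sits on the
shelf to damp spillover of the β2 group effect across the shared 18-Hz
filter edge.  A residual β3 group difference (mean t ≈ −1.5) remains —
adjacent-band leakage through overlapping filter skirts is physically
inherent to the band definitions — and is a known limitation; θ and α
stay clean (|mean t| < 0.4).

PANSS totals couple to the severity latent through a within-group
correlation ρ = 0.25 (`panss_coupling`).  A closed-form solve of ρ from
the target pooled correlation is not attempted: the entropy response is
nonlinear and saturating, so ρ was calibrated by simulation under the
default conditions to land the pooled entropy–PANSS correlation at the
0.55 target (the between-group separation alone contributes ≈ 0.49);
the parameter-recovery suite verifies the result within ±0.15.

Determinism: per-subject integer seeds come from
`numpy.random.SeedSequence(master).generate_state(n)`, a stable
documented splitting rule; identical specs give bit-identical cohorts.

### What the generator does and does not emulate

It emulates the protocol's dimensions, the published group summary
structure, the direction and rough size of the β-band effect, and the
feature–severity coupling.  It does not emulate real EEG physiology:
no 1/f broadband background, no ocular/muscle artifacts, no
non-stationarity within a session, no per-emotion signal differences
(emotion categories are generated identically by default — an optional
per-emotion gain exists purely for stress-testing the classifier grid),
and no electrode covariance structure (channels are independent given
the subject's complexity).  Passing tests therefore show the *pipeline*
is correct and calibrated, not that real patients are classifiable at
any particular accuracy.

## Numerical choices and problem sizes

Simulation studies in the tests and acceptance script use
patients-only, Fz-only cohorts (the statistics and the showcase
classification cell all live at Fz), 23 null cohorts for correlation
calibration (1035 grid cells), 50 null cohorts for classification
calibration, and 20 cohorts for planted-effect recovery — sizes chosen
to keep a full run in the tens of minutes on one CPU while leaving the
Monte-Carlo error well inside the asserted bands.  Null-calibration
bands are cluster-robust (t-based, with the SE estimated from
per-cohort replicates) because cells within a cohort share band
processes and CV predictions share training folds; per-cohort null CV
accuracy has SD ≈ 15%, nearly twice the naive binomial value, so a
binomial band would be anti-conservative.

Ties in ordinal patterns: earlier index = lower rank (stable sort).
PCA component count: smallest k with cumulative explained variance ≥
the target fraction, tolerating 1e−12 float round-off at fraction 1.0.
Fold assignment, SVM and PCA are all seeded/deterministic; reported
accuracies are reproducible bit for bit.

## Known limitations

* EDF recordings are read (via mne) but not written; synthetic
  recordings round-trip through CSV.
* The β3 spillover effect described above.
* ApEn's finite-sample boundary residues mean "perfectly regular ⇒
  exactly zero" holds only for constant inputs; tests assert the exact
  closed-form residues instead.
* 27-fold CV on 34 subjects mixes fold sizes 1 and 2; accuracies are
  then multiples of 1/34, not 1/27 (they are k/27 exactly when n = 27).
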