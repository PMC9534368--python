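# Methods

## Scoring model

All per-participant scores are defined on the piecewise-linear interpolant
of the recorded samples, which makes them independent of the (possibly
irregular) sampling grid of the rating device:

* **Heat pain threshold.** The CoVAS cursor rests at exactly 0 until the
  participant first moves it, so pain onset is the first upward crossing of
  a minimal level (0.1/100, roughly the cursor resolution); the threshold is
  the ramp temperature at that instant, averaged over the pretest trials in
  which any pain was reported. On a 0.3 °C/s ramp sampled at 1 Hz the choice
  of the minimal level moves the result by well under 0.05 °C.
* **T50.** Temperature at the first upward CoVAS crossing of 50/100,
  averaged over trials that reach 50; trials that never reach 50 are
  excluded, and a session without any such trial has no T50 (it is excluded
  with a logged reason unless a T50 is supplied directly in the metadata).
* **Tonic means.** Time-weighted (trapezoidal) averages over the full 120 s.
  For uniform grids this equals the sample mean; for irregular grids it is
  the natural estimator of the mean of the underlying rating trajectory.
* **TSP.** The signed endpoint difference `covas(120) − covas(60)` of the
  interpolant. The sign is retained (inhibitory drifts are negative);
  changes of at least 20/100 in either direction are classified as
  significant increase/decrease, cutoffs inclusive.
* **CS mean.** Arithmetic mean of the 0–10 ratings; early withdrawal is
  imputed as 10/10 (withdrawal is, by protocol, the behavioural expression
  of intolerable pain).
* **CPM efficiency.** `100 × (mean_TS2 − mean_TS1) / mean_TS1`. The −30/−10
  class cutoffs are assigned to the more-inhibitory class, fixing a
  convention the verbal definition leaves open. The value is kept unclipped
  internally; the −100..+100 clip is applied only at presentation time.
  A session with zero mean TS1 pain has undefined CPM and is excluded with
  a logged reason.

## Clustering

The four indicators (TSP1, CS mean, TSP2, CPM%) are z-scored with the
population SD (divisor n), after which the total inertia is exactly 4n.
Ward's minimum-variance hierarchy is built on Euclidean distances
(scipy linkage); scipy's Ward heights h are converted to within-inertia
gains h²/2, which sum to the total inertia — the identity the tests check.

The partition is chosen by the highest relative loss of inertia,
Δ(k) = (W(k−1) − W(k)) / W(k−1), with ties broken toward the smaller k.
The default search range is **k ∈ [3, 6]**. This follows the convention of
hierarchical-clustering-with-consolidation software, whose partition search
conventionally starts at three clusters, and it matters here: for strongly
overlapping groups the first split (k = 2) carries a relative loss
comparable to the true partition's, so including k = 2 in the scan makes
the selection an essentially random choice between 2 and 3 (measured on the
default synthetic mixture: k = 3 is chosen in ~60% of seeds with a [2, 6]
range and in ~98% with [3, 6]). `select_partition` accepts any range for
users who want the wider scan.

The chosen cut is consolidated by Lloyd k-means initialized at the
hierarchical centroids — a single deterministic initialization (the seed
only affects degenerate tie-breaking), run to centroid convergence (tol
1e-8, max 100 iterations). Consolidation is a descent method: the
within-cluster inertia of the result never exceeds that of the initial
partition. Cluster ids are renumbered 1..k by decreasing size. Controls are
never clustered; they are compared with the clusters post hoc.

## Inferential statistics

* **χ².** Pearson statistic without continuity correction at any table
  size; zero marginals are rejected naming the offending row/column.
* **Gender-adjusted ANOVA.** "One-way ANOVA controlling for gender" is
  realized as the additive linear model `value ~ group + gender` with a
  Type II sum of squares for the group factor (no interaction term). With
  unbalanced groups this is the standard way to test a factor in the
  presence of a covariate factor. The effect size is
  ω² = (SS_group − df_group · MS_error) / (SS_total + MS_error), labelled
  negligible/small/medium/large at 0.01/0.06/0.14; ω² can be ≤ 0 under the
  null, which is labelled negligible.
* **Scheffé.** Pairwise statistics use gender-adjusted means (model
  predictions averaged over the cohort's gender distribution — for the
  additive model, differences equal coefficient differences) and the
  full-model MS_error: S = Δ²/(MS_error (1/n_a + 1/n_b)),
  p = 1 − F_cdf(S/(k−1); k−1, df_error). Using adjusted means keeps the
  post hoc consistent with the adjusted omnibus test; this is a modelling
  choice, as the procedure is also sometimes run on raw means.
* **Fisher LSD.** Unadjusted pairwise t tests with the pooled one-way
  MS_error; by construction never more conservative than Scheffé, which the
  tests verify on random fixtures.
* **Spearman CI.** rho on average ranks; the 95% CI applies the Fisher z
  transform with the Fieller–Hartley–Pearson standard error
  sqrt(1.06/(n−3)). Monte Carlo checks at n = 600 put the realized coverage
  of the 95% interval near 94–95%.

## Synthetic cohort generator

The generator defines the study conditions the pipeline is validated under.
It draws, per participant, the four latent indicator targets from one of
three patient phenotypes (mixture weights 0.446/0.306/0.248) or the control
distribution, with means and SDs set to the per-group values the analysis
is designed around (e.g. phenotype 1: TSP1 N(−10.62, 20.17), CS
N(8.16, 1.47), TSP2 N(−6.11, 16.42), CPM N(−41.06, 34.19)); CS is truncated
to [0, 10] and TSP/CPM to [−100, 100]. Demographics: 81% female patients /
48% female controls, age ≈ N(15.2, 2.1²) clipped to the 8–21.4 study range,
per-phenotype T50 means 42.7–44.4 °C (SD ≈ 2–2.5), heat-pain threshold
T50 − N(4.45, 1.5²) °C.

Sessions are then built by **inverse construction** so that the scoring
module recovers the targets:

* TS1 is a plateau at 50/100 (the T50 calibration level) with a linear
  drift to 50 + TSP1 over the last 60 s, giving mean 50 + TSP1/4;
* TS2 must satisfy mean_TS2 = mean_TS1 (1 + CPM/100) with endpoint change
  TSP2. The plateau-plus-drift shape is used when it fits in [0, 100];
  otherwise a 3-knot, late-drift or dip-shaped piecewise-linear profile
  with the same mean and endpoint change is substituted (all knots on the
  sampling grid, so the sampled trace still scores back exactly). This
  matters scientifically: without the generalized shapes, strongly
  inhibited sessions with falling TS2 would have to be redrawn, truncating
  the CPM distribution by several points. A (CPM, TSP2) pair that no
  in-range profile can represent (≈1% of draws) is redrawn and logged;
  a CPM draw at the −100 floor pins TS2 at zero, which physically forces
  TSP2 = 0.
* Cold-pressor ratings are eight 0.5-step NRS values whose mean matches the
  CS target to within 1/32 NRS units (noise-free) or a noisy rising profile
  around it. **Withdrawal** is coupled to latent pain: a participant
  withdraws when the untruncated CS draw exceeds the phenotype's
  (1 − withdrawal_prob) quantile, with per-phenotype withdrawal
  probabilities set to the probability that latent cold pain exceeds the
  scale maximum (10.5%, 0.02%, 9.1% for the three phenotypes, 6.3% for
  controls; ≈7% of patients overall). This keeps imputation (CS = 10)
  consistent with the truncated target and avoids inflating the
  low-cold-pain phenotype's CS spread, which an independent withdrawal coin
  flip would do. The latent-truth table records effective targets (CS = 10
  for withdrawers).
* Pretest ramps place the CoVAS 50-crossing at the participant's T50.

Per-sample Gaussian CoVAS noise (default SD 2/100, scaled to 0.2 for NRS)
is added after profile construction and clipped to the scale; pretest noise
is applied only after pain onset, since an untouched cursor reads exactly 0.
The default cohort is 639 patients + 60 controls with exactly
round(31/639 · n_patients) patient sessions made incomplete by deleting one
phase at random, exercising the exclusion path (608 retained).

The generator does **not** model: within-phenotype correlations among the
four indicators (unknown; assumed independent), rating drift/hysteresis or
serial correlation within a trace, site or tester effects, and any
psychosocial covariates. Passing recovery tests therefore show that the
pipeline recovers the intended structure under independent, unimodal
indicator noise — not that real cohorts are this well behaved.

## Validation conditions and known limitations

* Scoring round-trip: noise-free synthetic sessions score back to their
  targets within 0.5 on every indicator (worst observed ≈ 0.03, dominated
  by the 0.5-step NRS quantization).
* Latent recovery: at the default mixture (n = 608 scored patients) the
  pipeline chooses k = 3 in ~98% of seeds and reaches an adjusted Rand
  index ≥ 0.5 against the latent phenotypes in ~85% (median ARI ≈ 0.53).
  The phenotypes overlap heavily on every indicator except CS, so ARI ≈ 0.5
  is the realistic ceiling region, and a 10-seed panel will occasionally
  dip below 9/10 — this reflects the overlap of the generating mixture, not
  a pipeline defect.
* The explained-inertia fraction of the consolidated 3-cluster partition on
  synthetic cohorts (~0.37–0.39) is a property of the independent-indicator
  mixture; real data with correlated indicators can explain less.
* Report tables round half-up at 2 decimals; machine-readable outputs keep
  full precision. CSV floats are written/parsed round-trip exactly.
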