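# Methods

## Study design the package targets

A longitudinal three-group design: a control group (e.g. wild-type mice), a
disease group, and a treated disease group, each with `n_subjects_per_group`
subjects sampled at ordered timepoints (defaults: 6 subjects, months 8/9/10,
treatment starting at the first timepoint so that the later two are
post-treatment). Three measured layers share the sample set: taxon counts
(16S-style), metabolite feature intensities (LC-MS-style), and continuous
pathological/neurochemical indicators.

## Synthetic-data generator

The generator produces the *processed* data layer only (no reads, no peaks).
Its generative model:

1. Per-taxon baseline log-abundance `b_j ~ N(0, taxon_base_logmean_sd)`.
2. A planted set of responsive taxa (default 5 of 100, alternating
   disease-up/disease-down). In the disease group a responsive taxon's
   expected abundance is multiplied by `disease_effect^(t_index+1)` in its
   planted direction (monotone age-dependence). The treated group receives
   the full effect at the pre-treatment baseline and the effect scaled by
   `1 - reversal_fraction` at the post-treatment timepoints.
3. Expected abundances are closed to proportions per sample; counts are drawn
   **multinomially** at a per-sample library size drawn log-normally
   (mean 50 000, log-sd 0.3). Multinomial-after-closure is deliberate: it
   reproduces compositionality, the artifact the renormalized permutation
   null in the network stage exists to combat. Within a group × timepoint
   cell the latent expectation is constant, so all within-cell variation in
   the taxon layer is sampling (multinomial + library-size) noise.
4. Each planted mediating metabolite's log-intensity is
   `link_strength × (source taxon's latent log-abundance) + N(0, metabolite_noise_sd)`;
   unplanted metabolites are independent log-normals.
5. Each linked indicator is a signed sum of its mediators' latent values plus
   `N(0, indicator_noise_sd)`, exponentiated so all tables are nonnegative;
   unplanted indicators are independent log-normals.

Defaults (100 taxa / 300 metabolites / 11 indicators, 5 + 5 planted,
`disease_effect` 2.5, `reversal_fraction` 0.8, n = 6/group) are sized to the
three-group rodent design the pipeline addresses and to minutes-scale
runtimes. Library-size mean 50 000 is a typical per-sample 16S depth; log-sd
0.3 gives the mild depth variation real runs show. `link_strength` 1.0 makes
the mediator track its source taxon one-to-one on the log scale, with
metabolite noise (0.3) clearly smaller than the planted log-effects
(0.9–2.7), i.e. a *strong-mediator* scenario.

What the generator does **not** emulate: batch effects, zero-inflation beyond
multinomial sampling, taxon–taxon ecological interactions, nonlinear
metabolite–taxon links, subject-level random effects (samples within a
subject are conditionally independent given group × timepoint). Passing tests
therefore show the pipeline recovers planted structure under clean
compositional sampling, not that it is robust to those real-data features.

All randomness derives from one seed through named substreams (CRC-32 of the
stage/layer name mixed into a `SeedSequence`), so any stage can be re-run in
isolation and reproduce bit-identically.

### Compositional false positives in the screening stage

With a 2.5-fold effect compounding over three timepoints, the planted taxa
come to hold a large share of the composition, so every *unplanted* taxon's
relative abundance also shifts — systematically, in the same direction at all
timepoints, and cleanly separated at n = 6 vs 6. These taxa are genuinely
differential *in relative terms*; trend-consistency cannot and should not
remove them (typically ~20–50 of 95 unplanted taxa are trend-consistent per
seed), and a p-value cut would not either (the separation is complete). This
is the expected behaviour of relative-abundance screens on compositional
data, not a defect; the reversal filter, qPCR-style validation and the
tripartite bridge ranking are the stages that re-isolate the planted signal
(planted recovery is perfect across seeds while false top-10 bridges average
≈ 0).

## Screening

* **PLS-DA**: NIPALS PLS1 on autoscaled predictors (mean 0, sd 1 with
  ddof = 1; constant columns get unit scale and zero weight) against a
  ±1-coded, centred class vector; X deflated per component; inner-loop
  tolerance 1e-10, cap 500 iterations (PLS1 converges in one pass; the loop
  covers the general contract). Per-component explained response sum of
  squares `SSY_a = c_a² t_aᵀt_a` feeds the standard VIP formula. Two
  components by default, configurable. If the class vector is exactly
  orthogonal to every predictor (e.g. duplicated groups) the screen degrades
  to VIP = 0 everywhere instead of failing.
* **Rank-sum test**: exact null when both groups ≤ 10 and there are no
  cross-group ties, else the tie-corrected normal approximation with
  continuity correction (scipy). At n = 6 vs 6 the attainable two-sided level
  just below 0.05 is ≈ 0.041, inside the calibration band used in tests.
* **BH**: step-up `q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1, input order
  preserved; applied within one screen (one timepoint, one omic layer), never
  across layers.
* **Direction** is the sign of the disease-minus-control median difference;
  exact ties give direction 0 and can never be trend-consistent.
* **Trend consistency** requires selection at every timepoint with one
  nonzero direction; a feature missing from a timepoint's screen counts as
  not selected (recorded, not an error).
* **Reversal** requires strict shrinkage of |median(treated) −
  median(control)| below |median(disease) − median(control)| at *every*
  post-treatment timepoint; per-timepoint shrinkage ratios are reported.
* **qPCR**: standard curves by OLS of Ct on log10 copies (≥ 3 distinct
  dilutions); efficiency `10^(-1/slope) - 1`; positive-slope fits are valid
  objects flagged as invalid assays. In the end-to-end pipeline, where no
  plate data exist, per-sample relative abundances at the final timepoint
  stand in for absolute copy numbers when calling responsiveness
  (disease-vs-treated rank-sum p < 0.05 *and* treated median strictly closer
  to control).

## Ensemble co-occurrence network

Four association measures over taxon pairs (profiles are per-sample-closed
relative abundances; for the dissimilarities each feature's cross-sample
profile is additionally closed to sum 1): Pearson, Spearman, Bray–Curtis, and
symmetrized KL with pseudocount 1e-6 added post-normalization (KL only — the
other measures handle zeros natively). Candidate edges are the 1000 top and
1000 bottom scorers per measure (ties broken by lexicographic pair index);
for correlations top = co-presence, for dissimilarities bottom = co-presence.

Significance per candidate edge:

* **Permutation null** (1000 iterations): one feature of the pair is shuffled
  across samples; with renormalization on (default for taxon–taxon), samples
  are re-closed to proportions after each shuffle so the null preserves the
  closure constraint — this is what absorbs spurious negative correlations on
  compositional data. Two-sided
  `p = (1 + #{|null − c| ≥ |obs − c|}) / (iterations + 1)`, where the centre
  c is 0 for correlations and the null mean for the dissimilarities (a
  dissimilarity has no natural zero; this choice makes "two-sided" meaningful
  for them). With renormalization off, rows are scored exactly as given,
  which keeps the Spearman null invariant under order-preserving transforms.
* **Bootstrap** (1000 resamples of samples with replacement): 2.5/97.5
  percentile interval of the score; edges whose interval covers the null
  centre are flagged unstable, never silently removed.

Consolidation: BH within each measure across its candidates; an edge enters
the final network iff q < 0.05 in ≥ 2 measures with one consistent sign
(sign conflicts are dropped and logged); reported p is Fisher's combination
(−2Σln p ~ χ²(2k)) over the supporting measures, with a second BH across the
final edges. The ≥ 2-measure sign-consistent merge with Fisher combination is
a transparent, testable ensemble rule chosen where the exact historical merge
of ensemble co-occurrence tools is not documented; support counts and
per-measure q values are all retained in the edge record, so other merges can
be applied downstream.

Permutation and bootstrap index matrices are drawn once per run and shared
across edges, which makes the stage fully vectorizable (chunks of edges ×
iterations × samples) and byte-reproducible given the seed.

## Tripartite network and bridge ranking

Cross-layer pairs (taxon–metabolite, taxon–indicator, metabolite–indicator;
taxon–taxon only if explicitly enabled) are tested with Pearson *and*
Spearman; analytic two-sided p from `t = r√((n−2)/(1−r²))`; BH jointly across
all cross-layer tests per method; an edge is retained only when both methods
pass q < 0.05 with agreeing sign. Edge weight is the Spearman rho; the edge
record carries the more conservative of the two p/q values. In the pipeline
the taxon layer is the validated responsive taxa (trend-consistent as
fallback) and the metabolite layer the reversed metabolites, mirroring a
workflow that networks only its screened candidates.

A **bridge metabolite** has ≥ 1 significant taxon edge *and* ≥ 1 significant
indicator edge; bridges are ranked by total degree, then summed |rho|, then
id — deterministic without exception.

## Pipeline, manifest, determinism

Stage order is fixed (the procedure is linear; no DAG engine). Every stage
writes TSV/JSON/GraphML outputs; `manifest.json` records the config snapshot
(minus the output directory, so identical runs in different places compare
equal), package version, seed and per-output SHA-256 checksums. Wall-clock
timings go to `timings.json`, kept out of the manifest precisely so the
manifest is byte-reproducible. When the study is simulated, `recovery.json`
reports precision/recall of the planted taxa and mediators at each recovery
stage.

## Numerical choices and degenerate inputs

* Shannon in nats; Simpson reported as Gini–Simpson (both conventions exist;
  these are the dominant ones in the ecology stack used here). Evenness is 0
  for single-taxon samples. All-zero count vectors are errors.
* Chao1 uses the bias-corrected form so it is defined when F2 = 0.
* No rarefaction anywhere; depth normalization is closure to proportions.
* PCoA retains negative eigenvalues in the report (no Lingoes/Cailliez
  correction); axes and proportion explained use positive eigenvalues only;
  eigenvalues below `max(|λ₁|,1)·1e-12` count as zero.
* Constant profiles are NaN under correlation measures; the pair is skipped
  and never becomes a candidate edge.
* NaN permutation draws (a shuffle producing a constant profile) count as
  non-exceeding, which is conservative.
* Exact float ties in medians give direction 0.
* The alpha-diversity, UniFrac and PCoA sample sizes in the test suite and
  the 10-seed recovery checks use the generator defaults; the network null
  calibration uses 20 samples and the rank-sum calibration n = 6 vs 6.

## Known limitations

* Differential screening on relative abundances inherits compositional
  coupling (see above); interpret taxon screens as relative, not absolute,
  statements — the package's qPCR module is the absolute-scale counterweight.
* The exact rank-sum null is discrete at n = 6 (attainable levels ~0.041,
  not 0.05); calibration statements are about the attainable level.
* Bootstrap intervals at n = 18 samples are coarse; they flag instability
  rather than provide coverage guarantees.
* PLS-DA is fixed to two-class comparisons; multi-class designs are screened
  pairwise.
* The tripartite stage assumes indicators are measured on (or joinable to)
  the same samples as the omics layers.
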