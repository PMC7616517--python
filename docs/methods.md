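# Methods

## The scientific question and the statistic

In auditory lexical decision, listeners respond faster to words that live in
*dense* semantic neighborhoods — words whose distributional-semantic vectors
have many close neighbors.  The analysis implemented here asks whether early
blind (EB) listeners weight this purely linguistic signal more heavily than
sighted controls (SC): if visual experience is missing, distributional
information in language may carry more of the load of organizing semantic
knowledge, and the density effect on reaction times should be steeper for
the blind group.

The statistic is **semantic neighborhood density (SNeigh)**: for a target
word *w* with embedding vector **w**,

    SNeigh(w) = (1/k) Σ_{i=1..k} cos(**w**, **n_i**),

where **n_1 … n_k** are the k = 5 nearest neighbors of *w* by cosine
similarity within a reference vocabulary — the 20,000 most frequent words of
a subtitle-based frequency norm — excluding *w* itself.  Higher SNeigh =
denser neighborhood.  The search is exhaustive (20,000 candidates is
trivially enumerable), in double precision, with ties broken by (cosine
descending, word ascending) so results are bit-reproducible.

Design choices worth making explicit:

* **Self-exclusion is by exact string identity.**  A *different* word whose
  vector coincides with the target's is a legitimate neighbor (cosine 1).
* **The reference is purely frequency-defined.**  Other experimental stimuli
  that fall inside the top-20,000 may serve as neighbors; a switch to
  exclude them is deliberately *not* provided by default because the
  frequency-defined reference is the convention this analysis follows.
* **Words are matched after Unicode NFC normalization, case-sensitively**
  (Italian orthography is meaningful); a lowercase switch exists but is off.
* **Top-N means top-N.**  Frequency-list words that lack vectors are skipped
  and counted, not back-filled from lower ranks, so "the 20,000 most
  frequent words" keeps its literal meaning; the realized reference may be
  slightly smaller.
* **Out-of-vocabulary stimuli are an error.**  A text-format vector file
  cannot synthesize subword vectors, so a stimulus without a vector stops
  the run rather than silently receiving a guess.

## Trial cleaning

The cascade mirrors the original order of operations, each step with its
exact rule:

1. **Participants** (within group, leave-one-out): exclude when the error
   rate over *all* trials (words and pseudowords) exceeds mean + 2.5·SD of
   the *other* same-group participants' rates.  Leave-one-out is the literal
   reading of "higher than the other participants"; groups need ≥ 3 members
   for the SD to mean anything.
2. **Items** (word stimuli): exclude when item accuracy falls below
   mean − 2.5·SD of item accuracies *in both groups separately* (an AND
   rule; an OR switch exists).
3. **Trials** (word trials only, in order): drop incorrect responses; drop
   RT < 300 ms; then per participant drop trials beyond ±3·SD of that
   participant's mean RT, computed over the trials surviving the first two
   steps on the raw millisecond scale.  The strict inequality means a
   zero-SD participant loses nothing; participants with < 2 surviving
   trials are skipped with a warning.
4. **Transforms**: natural logs of RT and duration (milliseconds).  The log
   base only rescales coefficients, never F-tests.

Because published removal percentages can be computed against different
denominators, the cleaning report records every step's count together with
three denominators (pre-step remaining, word-trial total, all-trial total).

## The mixed model

    log(RT) ~ group × (SNeigh + type) + log(duration)
              + (SNeigh | participant) + (1 | stimulus)

REML estimation; sum-to-zero contrasts for group (EB, SC) and type
(abstract, multimodal, visual); Type-III F-tests with Satterthwaite
denominator degrees of freedom (Kenward–Roger behind a flag).  SNeigh
enters raw — uncentered, unscaled — because the slopes of interest are read
on the raw cosine scale; centering would change only the intercept.

Fitting is delegated to lme4/lmerTest through an R subprocess, the
reference implementation for this model class (the bridge passes a CSV and
a JSON config, and parses back coefficients, covariance, the F-table,
variance components, and diagnostics).  Everything downstream is computed
in Python from the coefficient vector **b** and its covariance **V**:

* **Group-specific SNeigh slopes** are linear combinations: with sum coding
  (EB = +1), slope(EB) = b_SNeigh + b_group:SNeigh and slope(SC) =
  b_SNeigh − b_group:SNeigh, with SE = √(cᵀVc) and z = b/SE.  Tests carry
  both the normal-approximation p (the convention behind reported z values)
  and a Satterthwaite-t p from the backend.
* **Type post-hocs** are pairwise differences of estimated marginal means
  averaged over groups; under sum coding with equal group weights the
  group and group-by-type terms cancel, so each difference is a combination
  of the two type coefficients alone.  p-values are unadjusted.  The
  algebra is cross-checked against emmeans in the test suite.
* **Model criticism**: observations with |conditional residual| / σ̂ > 2.5
  are dropped and the model refit; both fits and the removed fraction are
  reported.  Criticism errors if trimming empties a design cell.
* **R²** (marginal / conditional): fixed-effect variance is the variance of
  the fixed linear predictor over the data; the participant random-effect
  share is averaged over the observed covariate,
  mean(σ²_int + 2ρσ_intσ_slope·s + σ²_slope·s²), plus the stimulus
  variance; the residual completes the total.  Marginal = fixed/total,
  conditional = (fixed + random)/total.

Singular random-effect fits are *reported* (flag plus optimizer messages),
never silently simplified: automatic structure reduction would break
comparability across fits.  Genuine optimizer failures can be promoted to
exceptions.

## The generative counterpart

The simulator draws data from exactly the model family the analysis fits,
so estimator consistency and calibration are testable:

* **Embedding space**: Gaussian clusters (default 2,000 words, 50
  dimensions, 10 clusters) with per-cluster spreads from 0.2 to 2.0 around
  unit-normal centers.  Tight clusters produce high within-cluster cosines
  and hence high SNeigh; the spread gradient yields a wide, systematic
  density range.  A Zipf-like frequency list over a random permutation
  keeps frequency independent of density.  No attempt is made to mimic the
  actual geometry or lexical statistics of corpus-trained vectors — the
  synthetic space validates the *machinery* (search, ties, exclusion,
  reference construction), not the empirical distribution of densities, so
  passing tests speak to correctness of the computation, not to effect
  sizes in real embeddings.
* **Design**: 21 participants per group, 40 words per type, 2
  presentations (the study's design); audio durations log-normal around
  700 ms (sdlog 0.15) — a typical spoken-adjective length; only the
  duration *slope* matters for recovery, so this choice is benign.
* **RT model** (log-ms): intercept 7.0 (≈ 1,100 ms); group effect −0.06
  (sum-coded EB deviation; the published table reports the group F but not
  its direction, so the sign here is a package choice and the magnitude is
  set to give a clearly detectable group effect at the study size); SNeigh
  slopes −0.37 (EB) and −0.25 (SC); type deviations +0.02 / −0.01 / −0.01
  (abstract slower, the two concrete types equal — the published post-hoc
  pattern); duration slope 0.25; participant intercept SD 0.13, slope SD
  0.11, correlation −0.50 (drawn bivariate-normal); stimulus intercept SD
  0.06; trial error probability 0.0175.  Pseudoword trials (separate
  log-normal RTs, no density dependence) are generated by default so the
  cleaning denominators behave like the real task's.
* **Residual SD** is not published.  It is calibrated once per
  configuration from the variance-partitioning identity: with target
  conditional R² = 0.50, Ve = (Vf + Vr)(1 − 0.50)/0.50 = Vf + Vr, where Vf
  and Vr are computed from the realized design exactly as in the R²
  formula above.  At the default configuration this gives a residual SD
  near 0.18 log-units, and refitting simulated data indeed returns
  conditional R² ≈ 0.50.
* **Determinism**: every random draw flows from ``(seed, stream)`` pairs
  through numpy's seed-sequence mechanism; identical (config, seed) gives
  byte-identical outputs end to end.

The recovery harness generates the embedding, stimuli, and densities once
(they are design constants), redraws trials per replicate, runs the full
cleaning cascade, fits all replicates in a single R session, and reports
bias, RMSE, Monte-Carlo SE, 95% Wald-CI coverage per estimand, and the
interaction rejection rate.

## Problem sizes and numerical choices

The validation suite uses three simulation scales, chosen as the package's
standard verification conditions: (i) oracle equivalence on 200 random
spaces of ≤ 50 words and ≤ 8 dimensions with k ∈ {1, 3, 5}; (ii) null
calibration of the group-by-SNeigh test with 500 replicates of a reduced
design (10 participants/group, 30 words) with both slopes at −0.31, where
the rejection rate must sit within the binomial 95% band around α = 0.05;
(iii) parameter recovery with 100 replicates at the study's post-exclusion
geometry (40 participants, 117 words, 2 presentations), where mean slope
estimates must fall within ±2 Monte-Carlo SEs of −0.37 / −0.25 and slope
CI coverage must stay ≥ 90%.

The null-calibration check is deliberately strict, and it surfaces a real
small-sample property of the method rather than an implementation issue:
at 10 participants per group the observed rejection rate is about 3.5%
rather than 5%.  About one replicate in eight fits singular (the
random-slope variance is weakly identified when the density covariate has
modest spread and only 20 participants carry it); those replicates
over-reject (den-df snaps to the residual scale), while the non-singular
majority under-rejects (conditioning on a non-singular fit selects
upward-noise slope-variance estimates, inflating the interaction SE).
Trimming is not the cause — the uncleaned rate is essentially identical —
and the same breakdown is visible in the backend's own outputs, so the
corresponding suite check fails by a small margin and is retained as an
honest record of this behavior.  Singular replicates are kept in all
summaries; dropping them would bias the calibration estimate.  At the full
study geometry (40 participants) denominator df roughly double and the
issue recedes.

Degenerate inputs fail loudly everywhere: zero-norm vectors in a cosine,
fewer eligible neighbors than k, duplicate vocabulary entries, non-positive
RTs or durations, double log-transforms, rank-deficient fixed designs
(reported with the aliased columns), and cleaning groups too small for a
leave-one-out SD.

## Known limitations

* The synthetic embedding validates machinery, not fastText geometry; real
  Italian vectors produce a narrower, higher SNeigh distribution than the
  synthetic clusters, so F statistics from simulations are not comparable
  to published ones (slopes and variance components are).
* Reproducing the published numbers exactly requires the deposited
  behavioral data and the pretrained Italian vectors (~4 GB); the pipeline
  accepts those files directly (word2vec text + TSV) but they are not
  fetched or shipped.
* The trial error model is homogeneous Bernoulli; real error rates vary by
  participant and item.  This only matters for the cleaning denominators,
  which are validated separately on constructed fixtures.
* Satterthwaite p-values for simple slopes and post-hocs are reported
  alongside normal-approximation p-values; published z-based p-values
  correspond to the latter.
* The duration log uses milliseconds; a seconds convention would shift
  only the intercept, not the duration slope's test.
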