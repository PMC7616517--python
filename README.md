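# semdense

Semantic neighborhood density and auditory lexical decision: a tested,
reproducible pipeline for asking whether early blind (EB) listeners are
more sensitive than sighted controls (SC) to the distributional-semantic
density of words.

## The problem and the model

Words that live in dense semantic neighborhoods — whose embedding vectors
have many close neighbors — are recognized faster in lexical decision.  If
visual experience is missing, language's distributional statistics may
carry more of the load of organizing semantic knowledge, so the density
effect should be *steeper* for early blind listeners.  The pipeline
implements the full analysis:

1. **SNeigh** — for each stimulus word *w*,
   `SNeigh(w) = mean of cos(w, n_i), i = 1..k`, over its k = 5 nearest
   neighbors (cosine similarity, word itself excluded) within a reference
   vocabulary of the 20,000 most frequent words.  Computed exhaustively and
   deterministically from word2vec-text vectors plus a frequency table.
2. **Cleaning** — leave-one-out participant exclusion (error rate >
   mean + 2.5 SD of the other same-group participants), item exclusion
   (accuracy < mean − 2.5 SD in both groups), then per-trial filters:
   incorrect responses, RT < 300 ms, ±3 SD per-participant trimming;
   natural-log transforms.
3. **Model** — the crossed-random-effects linear mixed model

       log(RT) ~ Group × (SNeigh + Type) + log(duration)
                 + (SNeigh | participant) + (1 | stimulus)

   fit by REML (lme4/lmerTest via a bundled R bridge) with Type-III
   Satterthwaite F-tests, per-group SNeigh slopes, pairwise Type contrasts,
   2.5-SD model criticism, and marginal/conditional R².
4. **Simulation** — a generative twin of the model (clustered synthetic
   embedding space + the mixed model's variance components) for parameter
   recovery, null calibration, and end-to-end testing without downloads.

## Worked example

Simulate a study at the default design (21 participants per group, 40
words per type, published effect sizes and variance components), clean it,
and fit the model:

```python
from semdense import GenerativeConfig, simulate_study, clean_pipeline, fit_lmm
from semdense.lmm import simple_slopes, r2_nakagawa

study = simulate_study(GenerativeConfig(seed=7))
cleaned, report = clean_pipeline(study.trials)
data = cleaned.merge(study.density[["word", "sneigh"]],
                     left_on="stimulus", right_on="word").drop(columns=["word"])
fit = fit_lmm(data)
print(fit.anova.round(3)[["f_value", "num_df", "den_df", "p_value"]])
print(simple_slopes(fit).round(3)[["b", "se", "z"]])
print("R2 (marginal, conditional):", [round(x, 3) for x in r2_nakagawa(fit)])
```

Output (seed 7):

```
              f_value  num_df    den_df  p_value
term
group           7.226     1.0    40.026    0.010
sneigh         91.836     1.0   111.041    0.000
type            1.946     2.0   114.946    0.148
log_duration   87.559     1.0   114.979    0.000
group:sneigh    4.282     1.0    40.044    0.045
group:type      1.121     2.0  9646.324    0.326

           b     se      z
group
EB    -0.345  0.038 -9.078
SC    -0.256  0.038 -6.744
R2 (marginal, conditional): [0.202, 0.503]
```

Reading it: the group-by-density interaction is significant (F(1, 40) =
4.28) with the EB slope (−0.345) steeper than the SC slope (−0.256) —
the fitted slopes recover the generative values −0.37 / −0.25 within
sampling error, the Satterthwaite denominator df for between-participant
terms sits near the participant count, and the conditional R² lands on the
0.50 the residual noise was calibrated to.

The same stages are available from the shell:

```bash
semdense simulate --config sim.yaml --out-dir runs/demo
semdense sneigh --vectors v.vec --freq freq.tsv --stimuli stim.tsv \
    --k 5 --n-top 20000 --out density.tsv
semdense clean --trials trials.tsv --out clean.tsv --report report.json
semdense fit --trials clean.tsv --density density.tsv --out fit.json --criticism
semdense run-all pipeline.yaml
```

`run-all` writes `density.tsv`, `clean_trials.tsv`, `cleaning_report.json`,
`fit.json`, and a `manifest.json` with input hashes, per-stage row counts,
seeds, and timestamps.  Real data drop in through the `inputs:` block of
the config (word2vec-text vectors, frequency TSV, stimulus and trial
tables).

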