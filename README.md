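# sigrecover

Quantify how far treatments return gene-signature expression toward a
healthy baseline in a multi-group RNA-seq study.

The package grew out of a question from pain neuromodulation: chronic
neuropathic pain (e.g. the spared-nerve-injury model in rats) shifts the
expression of microglial-activation gene programs in the spinal cord, and
spinal cord stimulation programs differ in how completely they reverse that
shift. Answering it requires a pipeline rather than a single statistic:
normalize a count matrix across five animal groups, cross-reference
literature-derived gene signatures against the measured genes, and score,
gene by gene and signature by signature, how much of the disease-induced
displacement each treatment undoes. `sigrecover` implements that pipeline
for any study with the same shape — a naive (healthy) group, an untreated
disease reference group, and one or more treatment arms — and ships a
seeded synthetic-study generator so every stage can be validated against
planted ground truth.

## The model

Counts are TMM-normalized, genes below 0.5 counts-per-million in at least 4
samples are removed, factors are recomputed, and log2 CPM values (prior
count 2) are averaged per group; X_g denotes the back-transformed
(geometric-mean) CPM of a gene in group g. For each gene:

- percent change under disease: `%C = (X_pain − X_naive) / X_naive × 100`
- recovery factor of a treatment: `R_f = (X_pain − X_SCS) / (X_pain − X_naive)`
  (1 = full return to baseline, 0 = no movement, < 0 = moved away,
  > 1 = overshot)
- residual after treatment: `%C_SCS = (X_SCS − X_naive) / X_naive × 100`

Per signature, the pipeline reports `%C_p` (share of genes with
|%C| ≥ 10%) with its up/down split, `%R_SCS` (share of changed genes whose
R_f satisfies the recovery rule — both `R_f ≤ 1` and `0 ≤ R_f ≤ 1` are
always reported), `%D_n` (share of changed genes with |%C_SCS| ≤ 15%), and
the Pearson correlation (with two-sided t-test p-value) between each
treatment's and the naive group's log2 fold-change profiles, both taken
against the untreated reference.

## Worked example

```python
from sigrecover import (SimConfig, simulate_study, preprocess_study,
                        summarize_transcriptome, Thresholds)

cfg = SimConfig(seed=1)              # 4000 genes; groups n = 7/10/9/10/11
study, truth = simulate_study(cfg)   # counts + planted ground truth
prep = preprocess_study(study)       # TMM -> filter -> logCPM -> group means

genes = truth.signature_symbols["post_injury"]
summ = summarize_transcriptome(prep.group_expression, genes,
                               Thresholds(), name="post_injury",
                               fc=prep.fold_changes)
print(f"%C_p = {summ.pct_changed:.1f} (up {summ.up_share:.0f}%)")
for arm, ts in summ.treatments.items():
    print(f"{arm}: R = {ts.r:.2f} ({ts.strength}), "
          f"%R_SCS = {ts.pct_recovered_unit_interval:.0f}%, "
          f"%D_n = {ts.pct_near_naive:.0f}%")
```

Output:

```
%C_p = 36.2 (up 60%)
dtmp: R = 0.96 (very strong), %R_SCS = 87%, %D_n = 54%
hrp: R = 0.70 (strong), %R_SCS = 71%, %D_n = 25%
lrp: R = 0.15 (very weak), %R_SCS = 50%, %D_n = 18%
```

The generator planted a 33% disease-changed fraction with a 61% up split in
this signature and treatment recovery levels 0.8/0.5/0.2; the estimates
recover them: `%C_p` lands a few points above the planted fraction (the
fixed 10% change threshold also admits some sampling noise), and every
recovery statistic orders the arms by their planted effectiveness, with the
weak arm's profile correlation dropping to "very weak".

The same analysis runs from the shell:

```bash
sig-recover simulate --seed 1 --out sim/
sig-recover run --config config.yaml --seed 1 --out results/
```

writing `recovery_summary.tsv` (one row per signature), `gene_metrics.tsv`,
`overlap_report.tsv` ("size (overlapped)" per signature and source),
normalization tables, and blue-up/red-down fold-change heat maps.

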