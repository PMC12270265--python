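# grsim

Simulate SNP genotype arrays directly from summary statistics — per-SNP
allele frequencies (plus genotype-class fractions for SNPs out of
Hardy-Weinberg equilibrium) and pairwise dosage correlations — and compute
linear-plus-interaction genetic risk scores (GRS) from the result.

The simulator first draws each SNP column to match its target marginal
exactly in distributional form (two Bernoulli haplotype draws per sample,
or exact genotype-class counts for non-HWE SNPs). Correlated SNPs are then
grouped as connected components of the |r| >= threshold correlation graph,
and within each group the optimizer repeatedly exchanges two samples'
values of a single column, keeping an exchange only when it strictly lowers

    loss = (1/l) * sum over the group's l correlated pairs of (r_hat - r_target)^2

Within-column exchanges never change a column's genotype counts, so
frequencies are conserved exactly while correlations are steered toward
their targets. A group converges when its loss reaches the tolerance
(default 0.03, correlation threshold 0.1, iteration limit 10000).

## Layout

- `grsim.sumstats` — summary-statistics types, computation (including the
  chi-square HWE flag), TSV I/O, and an optional VCF reader.
- `grsim.simulator` — initialization, correlation-graph grouping, the group
  loss, and the swap optimizer.
- `grsim.grs` — GRS model (effect alleles, weights, ranked two-SNP
  interaction table with `eq0|eq1|eq2|ge1|ge2` predicates), scoring, model
  and score TSV I/O.
- `grsim.evaluation` — bootstrap distribution summaries, ROC/AUC
  (Mann-Whitney semantics, ties 1/2), two-component PCA comparison.
- `grsim.fixtures` — Gaussian-copula ground-truth genotype generator so the
  whole pipeline is testable with no external data.
- `grsim.cli` — the `grsim` command.

## CLI

```sh
# make a synthetic ground-truth bundle (truth array + summary stats + model)
grsim fixtures make-default --out-dir bundle --n-samples 2000 --seed 7

# summary statistics from any genotype matrix TSV
grsim stats --genotypes bundle/truth_genotypes.tsv --out-freq freq.tsv --out-corr corr.tsv

# simulate a genotype array from summary statistics
grsim simulate --freq bundle/freq.tsv --corr bundle/corr.tsv \
    --out-genotypes sim.tsv --out-report report.json --n-samples 2000 --seed 13

# score it (the freq TSV names the allele each dosage column counts)
grsim score --genotypes sim.tsv --model-linear bundle/model_linear.tsv \
    --model-interactions bundle/model_interactions.tsv \
    --freq bundle/freq.tsv --out scores_sim.tsv

# compare two score sets (summaries + ROC/AUC) or two arrays (PCA)
grsim evaluate --scores scores_sim.tsv scores_truth.tsv --out eval.json
grsim evaluate --genotypes sim.tsv bundle/truth_genotypes.tsv --out pca.tsv
```

Exit codes: 0 success, 2 input validation error, 1 internal error. All
randomness is controlled by `--seed`; identical inputs and seed give
byte-identical genotype output.

File formats are plain TSV: a genotype matrix (`sample_id` + one column per
SNP, dosages in {0,1,2}), a frequencies table (`snp_id`, `effect_allele`,
`other_allele`, `freq`, `hwe_deviates`, `frac0..frac2`), a correlations
table (`snp_a`, `snp_b`, `rho`), and GRS model tables (linear weights and a
ranked interaction table). The simulation report is JSON with per-group
convergence status, final loss, and swap counters.

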