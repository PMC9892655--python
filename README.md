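# dtusage

Differential transcript usage (DTU) analysis for bulk and single-cell
RNA-seq, built on per-transcript quasi-binomial GLMs with empirical-Bayes
dispersion moderation and empirical-null p-value calibration.

Genes express several transcript isoforms, and biology often shifts the
*mix* of isoforms without changing total gene output. Standard
differential gene expression misses this entirely. `dtusage` tests, for
every transcript, whether its within-gene usage — its share of the gene's
expression — differs between conditions. It is aimed at analysts working
from a transcript-level (or exon-level, or equivalence-class-level)
quantification matrix, a transcript-to-gene map and a sample/cell
annotation table.

## Model

For transcript *t* of gene *g* in sample *i*, with `Y_gti` the expression
estimate, `Y_g.i` the gene total and `U_gti = Y_gti / Y_g.i` the usage:

    E[U_gti | X_i, Y_g.i] = pi_gti          logit(pi_gti) = X_i' beta_gt
    Var[U_gti | X_i, Y_g.i] = pi_gti (1 - pi_gti) / Y_g.i * phi_gt

a quasi-binomial GLM: logit-linear mean, binomial variance with the gene
total as trial count, and a transcript-specific overdispersion `phi_gt`.
Coefficients are log-odds (ratios) of transcript choice. Per-transcript
Pearson dispersions are shrunk toward a common prior `(d0, s0^2)`
estimated across transcripts; contrasts are tested with moderated
t-statistics on `df + d0` degrees of freedom. Because the theoretical
null can fail in large-scale single-cell settings, p-values are
recalibrated against an empirical null `N(mu*, sigma*)` fitted by maximum
likelihood to the central z-scores, then adjusted with
Benjamini-Hochberg. See `docs/methods.md` for the full account.

The package also ships the two standard DTU pre-filters (edgeR-style CPM
and DRIMSeq-style three-step), scaledTPM conversion, a synthetic
two-group benchmark generator with swap-based DTU ground truth, and
FDR-TPR evaluation utilities.

## Worked example

Simulate a benchmark with known ground truth, run the full pipeline and
evaluate the calls:

```python
import dtusage as d

out = d.run_benchmark(d.SyntheticParams(n_genes=3000, seed=1), alpha=0.05)
r, c = out["results"], out["confusion"]
print("retained transcripts:", out["n_filtered"])
print("mu*=%.3f sigma*=%.3f d0=%.2f s0^2=%.3f"
      % (r.attrs["mu_star"], r.attrs["sigma_star"], r.attrs["d0"], r.attrs["s0_sq"]))
print("TP=%d FP=%d TN=%d FN=%d  TPR=%.3f FDP=%.3f"
      % (c.TP, c.FP, c.TN, c.FN, c.tpr, c.fdp))
```

prints

```
retained transcripts: 10252
mu*=-0.006 sigma*=1.082 d0=7.32 s0^2=2.084
TP=747 FP=26 TN=9293 FN=186  TPR=0.801 FDP=0.034
```

Reading this: 10,252 transcripts survive the lenient CPM filter; the
fitted empirical null is slightly wider than N(0,1) (`sigma* = 1.08`), so
the recalibration damps mildly inflated raw statistics; dispersions are
shrunk toward `s0^2 = 2.08` with about 7 prior degrees of freedom (the
data are overdispersed relative to binomial sampling, as simulated). At
the 5% BH level the pipeline recovers 80% of the truly perturbed
transcripts with an observed false discovery proportion of 3.4% — below
the nominal level. The head of the result table ranks the strongest
usage switches, e.g.:

```
transcript_id   gene_id  estimate          t        p_emp      fdr_emp
gene01734_tx1 gene01734 -4.048278 -33.568577 4.794174e-29 1.871602e-25
gene02782_tx2 gene02782  6.014833  33.382601 6.678665e-29 1.871602e-25
```

where `estimate` is the log-odds ratio of usage between the groups.

The same pipeline runs from the shell on files:

```sh
dtusage simulate --genes 3000 --n-per-group 20 --seed 1 --out-prefix sim/bench
dtusage fit-test --values sim/bench_counts.tsv --tx2gene sim/bench_tx2gene.tsv \
    --samples sim/bench_samples.tsv --out results.tsv
dtusage evaluate --results results.tsv --truth sim/bench_truth.tsv \
    --alpha 0.05 --out curve.tsv
```

For real data, point `--values` at a TSV/CSV matrix (first column =
transcript id) or a MatrixMarket `.mtx` file with `.mtx.rows`/`.mtx.cols`
sidecar name files.

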