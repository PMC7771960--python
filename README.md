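# combisig

When two signals (say, retinoic acid and TGF-β) both upregulate a gene,
does the combined response add the two individual effects, multiply their
fold-changes, or something else? `combisig` implements a statistical
pipeline for answering that question genome-wide from replicate-level
RNA-seq (TPM) and ATAC-seq (fragment count) measurements of cells treated
with each signal alone and in combination, across doses. It is written
for computational biologists analyzing paired two-signal perturbation
experiments, and ships a ground-truth synthetic-data generator so every
stage can be validated end to end without external data.

## The statistics at its core

For a feature with baseline `x0` and individual effects `ΔA = xA − x0`,
`ΔB = xB − x0`, the additive prediction for the combined treatment is
`x0 + ΔA + ΔB` and the multiplicative prediction is
`x0 · (xA/x0) · (xB/x0)`; the two differ by the interaction scale
`ΔA·ΔB/x0`. The **combined response factor**

```
c = (xAB − x0 − ΔA − ΔB) · x0 / (ΔA·ΔB)
```

places the observed combined mean `xAB` linearly on that spectrum:
`c = 0` is perfect addition, `c = 1` perfect multiplication, `c < 0`
sub-additive, `c > 1` super-multiplicative. For accessibility peaks,
where addition is the default, the deviation statistic is
`d = xAB / (x0 + ΔA + ΔB) − 1`.

Replicate noise is modeled as a folded Gaussian per feature and condition
with a coefficient of variation shared across the doses of a signal
(per-dose `CV = (1 + 1/(4n))·s/x̄`, averaged over doses), and combined
responses are classified by where the two predictions fall relative to
the 80% confidence interval of the combined treatment's estimated
distribution. Monte-Carlo nulls resimulate every feature under perfectly
additive or multiplicative integration to ask whether the observed
c-value histogram needs both peaks. Differential ATAC peaks are called
with an empirical-FDR grid (50×50 fold-change × count thresholds) whose
false-positive counts come from extra control samples, followed by
250-bp merging and a second fixed-threshold pass. Downstream analyses
link peaks to genes within 100 kb of the TSS, label signal-exclusive
peaks (≥90% of the summed effect from one signal), and score motif
densities, enrichment, co-occurrence shuffles, and motif-conditional d
values.

## Worked example

The canonical hand calculation: a gene at 100 mRNA copies rises to 200
under signal A and to 300 under signal B. If both signals together give
400 copies the effects added; 600 copies means the fold-changes
multiplied:

```pycon
>>> from combisig import compute_c
>>> compute_c(100, 100, 200, 400)   # x0, dA, dB, observed combined
0.0
>>> compute_c(100, 100, 200, 600)
1.0
```

A full synthetic run (200 genes, 600 peaks, three replicates, three
doses, known ground truth):

```pycon
>>> from combisig import SynthConfig, PipelineConfig, generate_dataset, run_pipeline
>>> ds, gene_truth, peak_truth = generate_dataset(SynthConfig(n_genes=200, n_peaks=600, seed=0, genome_length=20_000_000))
>>> tables = run_pipeline(ds, PipelineConfig(n_sims_gene=100, poisson_n_reps=200, n_bootstrap_genes=2000), "out", seed=0)
>>> gc = tables["gene_classification"]
>>> (gc[gc["dose"] == "medium"]["category"].value_counts(normalize=True) * 100).round(1)
category
ambiguous               51.5
additive                21.0
super_multiplicative    10.0
sub_additive             9.5
multiplicative           6.5
between_add_mult         1.5
>>> tables["fdr_summary"]
 round  pooled_fdr  fp_estimate  n_calls
     1    0.000000          0.0      259
     2    0.073086          3.5      431
>>> dm = tables["d_values"]
>>> round(float(dm[dm["dose"] == "medium"]["d"].median()), 4)
0.0287
```

The classification fractions reflect the generator's 50/50
additive/multiplicative ground-truth mixture seen through three-replicate
noise (ambiguous collects the genes whose interaction scale is too small
to tell the models apart); the round-1 pooled FDR estimate of 0 over 259
calls is flagged in the log as saturated (the two extra-control
comparisons resolve FP rates only down to ~1.7% here); and the median d
near 0 reflects the generator's additive-by-default peak universe.

The same stages are available from a shell:

```
combisig simulate --seed 0 --n-genes 200 --n-peaks 600 --out data/
combisig all --data data/ --seed 0 --out results_dir/
```

Subcommands `noise`, `classify`, `nulls`, `callpeaks`, and `integrate`
run individual stages; `--config` accepts a YAML file overriding any
`PipelineConfig` default.

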