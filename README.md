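# chiprx

Spike-in normalized differential ChIP-seq analysis for broad histone
marks, with enhancer–gene expression integration and downstream
enrichment statistics — plus a synthetic-data generator that plants
recoverable ground-truth effects so every stage of the pipeline can be
validated end to end.

## The problem

When a chromatin writer is knocked out, the mark it deposits (here
H3K4me1, the enhancer mark laid down by the methyltransferase Kmt2d) can
drop **globally**. Standard per-library normalization (CPM) silently
renormalizes such a shift away: if every region loses half its signal,
every region still receives the same share of the sequenced reads.  The
remedy is an exogenous **spike-in** (ChIP-Rx): a fixed fraction of
chromatin from a second species is added to every immunoprecipitation, so
the exogenous read count provides a cross-sample yardstick,

```
scale(s) = n_spike(reference) / n_spike(s),        signal_scaled = signal_raw × scale(s)
```

with the reference chosen as the sample with the fewest spike reads (all
scales ≤ 1).

On the spike-scaled signal the pipeline then:

1. calls **islands** for the broad mark — fixed `w`-bp windows, a window
   is *eligible* when its tag count `c` satisfies the Poisson tail bound
   `P(X ≥ c; λ_bg) ≤ p0`, eligible windows within `g` bp of each other
   merge into islands scored by `Σ −ln Poisson(c_i; λ_bg)`;
2. classifies islands as promoter (within ±2 kb of a TSS) or distal
   enhancer, and links each enhancer to its nearest TSS within 100 kb;
3. applies the **dual fold-change filter**: a gene is called only if both
   its enhancer's spike-scaled WT/KO signal and its expression fold
   change (CPM) are ≥ 1.6-fold, and reports how many of the passing
   genes' enhancers carry binding of the enzyme itself
   (`n_pass`, `n_pass_bound`, `bound_fraction`);
4. provides GSEA (weighted-KS running sum, permutation NES with BH FDR)
   and a single-cell cluster DE filter (expressed in ≥ 30 % of cells,
   fold change ≥ 1.2, Student's t-test at 5 % FDR).

## Worked example

```python
import chiprx as cx

# a synthetic two-genotype study: 1000 genes, one distal enhancer each,
# 100 genes planted with a 2.5-fold KO reduction in both enhancer
# H3K4me1 and expression, 60 % of enhancers bound by the enzyme
genome, truth = cx.default_scenario(seed=1)
wt  = cx.simulate_chip_sample(genome, truth, "WT", "H3K4me1", depth=200_000, seed=11)
ko  = cx.simulate_chip_sample(genome, truth, "KO", "H3K4me1", depth=200_000, seed=12)
kmt = cx.simulate_chip_sample(genome, truth, "WT", "Kmt2d",   depth=100_000, seed=13)
rna = cx.simulate_rna_counts(genome, truth, seed=14)

out = cx.integrate_study(genome, wt, ko, rna, kmt2d_tags=kmt)
print(out.result.summary())
```

prints

```
{'n_pass': 97, 'n_pass_bound': 58, 'bound_fraction': 0.5979381443298969}
```

meaning 97 genes pass the dual 1.6-fold filter (of 100 planted — the
pipeline recovers them with ~0.97 sensitivity and 1.0 precision here),
and 59.8 % of their enhancers overlap a binding island of the enzyme
(60 % were planted as bound).  On real data the same three summary
numbers drop out of the same call.

The same steps are available from the shell:

```bash
chiprx simulate --out-dir study --seed 1
chiprx normalize --sample WT=study/H3K4me1_WT.bed --sample KO=study/H3K4me1_KO.bed --out scale.tsv
chiprx islands --chip study/H3K4me1_WT.bed --chrom-sizes study/chrom_sizes.tsv \
       --count-bed WT=study/H3K4me1_WT.bed --count-bed KO=study/H3K4me1_KO.bed --out-prefix isl
chiprx integrate --islands-tsv isl.tsv --genes study/genes.tsv --rna study/rna_counts.tsv \
       --scale scale.tsv --out-records records.tsv --out-summary summary.json
```

All subcommands accept a flat `key=value` config file (`--config`);
command-line flags override it, and reruns with the same config and seed
are byte-identical.

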