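# admixpanel

Design and evaluate small SNP panels for two tasks in admixed (cattle-like)
populations:

1. **Breed-proportion estimation** — select ancestry-informative markers by
   absolute allele-frequency differences between ancestral populations
   (split-fraction or weighted hypothetical-pool criteria), prune them by a
   stepwise physical-distance schedule (3.5 Mb for the first 100 SNPs, 3 Mb
   up to 300, 1.25 Mb after), and estimate each individual's ancestry vector
   with a supervised maximum-likelihood (EM) estimator against fixed
   reference allele frequencies. Accuracy is the squared Pearson correlation
   of panel-based total-dairy estimates against full-marker estimates.
2. **Parentage assignment** — select high-MAF markers (optionally pruned at
   1 Mb), count opposing homozygotes between candidate pairs, assign
   parent–offspring pairs below a strict 1%-of-panel threshold, and score
   panels with the separation value (sv) and the powers of assignment (Pa)
   and exclusion (Pe) under two search scenarios (all-pairs vs known
   parents × progeny).

Everything runs end-to-end on a built-in synthetic-data generator
(Balding–Nichols ancestral divergence calibrated to realistic pairwise
F_ST ranges, admixed crossbreds with known ancestry, parent–offspring
families with configurable genotyping error), so no external genotype data
is needed.

## Layout

| module | contents |
| --- | --- |
| `admixpanel.io` | `GenotypeMatrix` container, PLINK text and native TSV dialects, call-rate filtering, merge on common SNPs |
| `admixpanel.simulate` | variant maps, Balding–Nichols ancestral frequencies, HWE/admixed genotype sampling, families, genotyping errors |
| `admixpanel.freqs` | population allele frequencies, MAF, \|pA_i − pA_j\|, weighted hypothetical pools |
| `admixpanel.panels` | ranking, stepwise physical-distance pruning, split/weighted/MAF panel selection (nested panels) |
| `admixpanel.ancestry` | supervised admixture EM, total dairy proportion, r² accuracy |
| `admixpanel.parentage` | opposing homozygotes, candidate pairs, reconstruction, sv/Pa/Pe |
| `admixpanel.pipeline` | experiment sweeps reproducing the figure structure on synthetic data |
| `admixpanel.cli` | `admixpanel` command-line tool |

## CLI

```bash
admixpanel simulate --out data/                      # synthetic dataset + truth
admixpanel freqs --data data/references --out ref_freqs.tsv
admixpanel select-panel --freqs ref_freqs.tsv --mode weighted --w 0.7 \
    --sizes 100,200,300 --variants data/references.variants.tsv --out panel.tsv
admixpanel estimate --data data/crossbreds --refs ref_freqs.tsv \
    --dairy EUT --panel panel.tsv --out estimates.tsv
admixpanel parentage --data data/parentage --scenario 2 \
    --pedigree data/parentage.pedigree.tsv --out counts.tsv
admixpanel evaluate --kind breed --out results/    # full sweep from a YAML config
```

All commands accept YAML configs; every source of randomness is seeded, and
reruns are byte-identical.

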