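# asekit

Allele-specific expression (ASE) analysis for F1 reciprocal crosses.

In an F1 hybrid of two inbred mouse strains — C57BL/6J ("B") and DBA/2J
("D") — every variant site is heterozygous and the two alleles share one
cellular environment. RNA-seq reads that cover a B/D SNP can therefore be
assigned to their parental chromosome, and unequal allelic read counts are
direct evidence of *cis*-acting regulation (a cis-eQTL), without the
population mapping and phasing that local-eQTL studies need. Because the
maternal strain differs between the reciprocal crosses (BxD vs DxB,
maternal strain named first), the same counts also separate strain effects
from parent-of-origin (imprinting) effects.

`asekit` is for people analysing such designs: it counts alleles from
alignments against an N-masked reference, aggregates SNP counts over genes,
tests allelic imbalance with a replicate-aware negative-binomial (NB) exact
test, screens for the artifacts peculiar to ASE data, and relates the calls
to DNase I open-chromatin polymorphism and to external local-eQTL tables.
A synthetic-data module generates full toy studies (reference, gene models,
variants, truth tables, counts, pre-placed alignments) so every stage is
testable without any downloads.

## The statistical model

Each sequenced pool contributes two *pseudo-samples* — its B-allele and
D-allele count vectors — treated as independent replicate libraries of two
conditions. For gene *i* in pseudo-sample *j*:

    K_ij ~ NB(mean = s_j * q_i,c(j),  variance = mean + alpha_i * mean^2)

* `s_j` — median-of-ratios size factor; it absorbs both sequencing depth
  and the global reference-mapping bias (B-allele columns systematically
  gain a factor ~1.1–1.2 even after N-masking).
* `q_i,c` — condition mean; the contrast is either strain (B vs D →
  cis-eQTL) or parent of origin (maternal vs paternal, derived from allele
  × cross direction → imprinting), optionally sex-restricted.
* `alpha_i` — per-gene dispersion, estimated by method of moments across
  replicates and shrunk toward a fitted trend `alpha(mu) = a0 + a1/mu`;
  the working value is `max(empirical, fitted)` (conservative).

The p-value is the NB conditional exact test: given the two condition sums
K_A, K_B, it sums the probabilities of all splits `a + b = K_A + K_B` no
more likely than the observed one. Benjamini–Hochberg FDR control at 0.05
yields the significant set and a direction (B-up / D-up, or maternal /
paternal). A per-SNP Fisher exact test (each SNP against the rest of its
library, intersected across samples) is included as the classical baseline;
on matched synthetic data the NB test finds substantially more true
positives at the same realized FDR.

## Worked example

```python
from asekit import synth, asetest

cfg = synth.SimulationConfig(seed=42, n_genes=500)     # 4 F1 pools, bias 1.2
ann = synth.gen_annotation(cfg)
truth = synth.gen_truth(cfg)
table = synth.gen_counts(ann, truth, cfg)

table, removed = asetest.filter_exclusive(table)       # drop single-allele SNPs
model = asetest.ASEModel.from_count_table(table, level="gene", mode="strain")
print(model.fit().summary())
```

```
Allelic imbalance results
================================================================
contrast:            strain (D vs B, log2fc = log2 D/B)
aggregation level:   gene
units tested:        490
pseudo-samples:      8
FDR threshold:       0.05
significant units:   37  (D-up: 18, B-up: 19)
dispersion curve:    alpha(mu) = 0.05141 + 1.553/mu
size factors:        BxD_F.B=1.116, BxD_F.D=0.924, DxB_F.B=1.098, ...
================================================================
top units by FDR:
           base_mean  log2fc     pval     padj direction
gene00035        493    -1.5  2.1e-09 5.36e-07         B
gene00413        330   -1.54 2.19e-09 5.36e-07         B
...
```

Reading this: 34 exclusive-expression SNPs (the genotyping-error signature)
were removed up front; of 490 testable genes, 37 show significant allelic
imbalance at FDR 0.05, split evenly between B-up and D-up as expected from
the balanced simulation; the B-column size factors sit ~1.2× above the
D-columns, showing the normalization absorbing the injected mapping bias;
and the fitted dispersion trend recovers the simulated `alpha = 0.05`.
Refitting the same counts with `mode="parent"` tests imprinting instead
(9 significant genes here — the simulated imprinted fraction).

The same pipeline runs from the shell:

```bash
asekit simulate --seed 42 --outdir study --reads
asekit count --sam study/reads.sam --vcf study/variants.vcf --out counts.tsv
asekit test --counts study/counts.tsv --mode strain --out ase.tsv
asekit qc --counts study/counts.tsv --bed12 study/genes.bed --outdir qc/
```

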