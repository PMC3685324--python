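# mhcev

Macroevolutionary analysis toolkit for codon alignments of MHC class I
exon 3 (or any in-frame immune-gene exon): allele filtering and per-species
diversity statistics, peptide-binding-region (PBR) partitioned dN/dS by
pathway counting, neighbor-joining phylogenetics with bootstrap support, a
parsimony-based species-clustering permutation test, codon-position GC
analysis with Welch tests, and maximum-likelihood Brownian-motion clade-model
comparison of continuous traits (e.g. GC3) with a stem-branch sensitivity
analysis. A synthetic-data generator makes every stage testable without any
external downloads.

## Inputs

* **Alignment** — gapped FASTA, all records equal length, length divisible
  by 3 (codon-aware alignment in reading frame).
* **Metadata** — 4-column TSV with header `id  species  family  clade`;
  `clade` is one of `songbird`, `nonpasserine`, `outgroup`.
* **Partition file** (optional) — one exon codon number per line; by default
  the a-priori avian class-I PBR set {5,7,8,9,23,25,38,60,61,62,65,66,68,73}
  with frame offset 4 (the alignment starts at exon codon 5).

## CLI

```bash
mhcev simulate  --outdir sim --seed 1                 # synthetic dataset
mhcev all       --alignment sim/alignment.fasta \
                --metadata  sim/metadata.tsv \
                --outdir out --boot 100 --nrand 1000 --seed 1
```

`mhcev all` writes, per stage: `retained.fasta` + `discarded.json` (allele
filtering), `table1_diversity.tsv` (Na, S, pi, k, per-species PBR/non-PBR
omega), `table2_dnds.tsv` (pooled partitioned dN/dS per clade with bootstrap
SEs), `nj_tree.nwk` (TN93+Gamma NJ tree with bootstrap support),
`permtest_<clade>.json` (species-clustering permutation tests),
`gc_profiles.tsv` + `gc_tests.json` (GC by codon position, Welch tests),
`table3_bm_<trait>.tsv` (Brownian-motion clade models at each stem-scaling
factor) and `manifest.json` (seed, config, per-stage runtimes).

Single stages: `mhcev diversity | dnds | tree | permtest | gc | bmfit`
(see `mhcev <cmd> --help`).

## Package layout

| module | contents |
| --- | --- |
| `mhcev.seqio` | alignment/metadata I/O, functional vs pseudogene classification, min-3-difference allele filtering |
| `mhcev.diversity` | polymorphic sites S, mean pairwise differences k, diversity pi |
| `mhcev.selection` | NG86-style site/pathway counting with ts/tv weight R, Jukes–Cantor correction, partitioned dN/dS with codon bootstrap |
| `mhcev.phylo` | K2P / TN93(+Gamma) distances, neighbor joining, bootstrap support, ultrametricization, stem scaling, random topologies |
| `mhcev.parsimony_test` | Fitch length, permutation test against random topologies |
| `mhcev.basecomp` | GC by codon position, Welch's unequal-variance t-test |
| `mhcev.bm_clades` | ML Brownian-motion clade models (shared/clade means x shared/clade rates), AIC comparison, stem sensitivity |
| `mhcev.synthetic_data` | two-clade tree / codon alignment / Brownian trait simulators |
| `mhcev.pipeline`, `mhcev.cli` | end-to-end orchestration and the `mhcev` command |
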