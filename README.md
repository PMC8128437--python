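# krascope

Analysis pipeline for studying how carcinogen mutation signatures and
oncogene expression interact to select *Kras* driver mutations in mouse lung
tumors. The package implements four connected analyses:

1. **Hotspot amplicon calling** — assigns barcoded tumor cDNA/gDNA amplicon
   reads to single-nucleotide missense variants at the RAS hotspot codons
   G12, G13 and Q61 by exact comparison against the enumerated variant set,
   resolves which *Kras* allele (native vs codon-optimised "ex3op" exon 3)
   and which mouse strain (129 vs B6, via the SNP at CDS nt 96) each read
   came from, and computes per-tumor mutant:wildtype mRNA read-count ratios.
2. **Maximum-depth sequencing (MDS)** — ultra-rare mutation frequencies from
   libraries in which every template molecule carries a 14-nt random barcode.
   Reads are grouped into barcode families; a family is trusted only if it
   has ≥ 2 reads of which ≥ 90% are identical, and its modal sequence becomes
   the molecule's consensus. The mutation frequency (MF) of a substitution is
   mutant families ÷ total accepted families, with a detection floor of
   1/N<sub>families</sub> (10⁻⁵ at a recovery of 10⁵ families) added before
   log₁₀ transform for heatmap matrices, and class summaries for the
   urethane signature (C**A**N>C**T/G**N: CA>CT in exon 2 produces Q61L,
   GG>GA in exon 1 produces G12D/G13D).
3. **qPCR quantification** — ΔCt relative levels (2^ΔCt), recombined-allele
   fractions, allele copy number vs 2-copy normal tissue, and −ΔΔCt relative
   expression.
4. **Cohort statistics** — tumor volume ½·L·W², per-mouse burden and
   multiplicity, ≥ 100 mm³ size binning, and the standard comparisons
   (Mann-Whitney, Fisher exact, Kruskal-Wallis + Dunn, ANOVA + Holm-Šidák,
   Spearman).

A synthetic-data module generates every input the pipeline consumes — paired
FASTQ amplicon libraries with controlled mutant fractions, barcoded MDS
libraries with known per-site mutation frequencies, Ct tables and tumor
cohorts — so each stage is testable against ground truth without external
downloads. The published 8-nt exon-3 allele discriminator and nt-96 SNP bases
are not public; the bundled `synthetic_locus()` is a clearly-labelled
synthetic stand-in carrying the real coordinate landmarks (GGT/GGC/CAA at
codons 12/13/61, so Q61L is C**A₁₈₂**A>C**T**A in a 5′-C context). Real loci
are supplied as FASTA + a key/value config (`krascope.refmodel.load_reference`).

## Worked example

Simulate a tumor whose ex3op allele carries Q61L in 60% of transcripts, then
call it back:

```sh
krascope simulate-amplicon --pairs 2000 --seed 3 --out-prefix demo
krascope call-hotspots demo.R1.fastq demo.R2.fastq \
    --index-tsv demo.indexes.tsv --out calls.tsv
```

Key rows of `calls.tsv`:

```
sample_id  variant  allele  strain  count  fraction  hotspot_site  ratio    bin
S1         Q61L     ex3op   129     1166   0.5910    Q61           1.5156   high
S1         WT       ex3op   129     770    0.3903    Q61           1.5156   high
```

The caller recovers the Q61L driver on the ex3op allele at a fraction of
0.591 (the seeded binomial draw of the 0.6 truth), and the mutant:wildtype
read-count ratio 1166/769.4… ≈ 1.516 falls in the "high" bin (> 1.5), the
allelic-imbalance regime in which weaker G12/13 drivers reach Q61-sized
tumors. Sequencing errors surface as sub-percent variant categories and are
removed by the published filters (samples under 30 reads excluded, variant
categories under 8% dropped).

The MDS caller runs the same way from a single-end FASTQ:

```sh
krascope simulate-mds --families 2000 --seed 3 --out mds.fastq
krascope call-mds mds.fastq --index-tsv mds.indexes.tsv --out-prefix mds
```

which writes per-substitution frequency tables (position, ref, alt, 5′/3′
context, mutant-family count, total families, frequency) and a
log₁₀(MF + 10⁻⁵) signature matrix for A>T transversions.

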