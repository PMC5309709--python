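# strseq

Analysis toolkit for probe-indexed targeted sequencing of short tandem
repeats (STRs/microsatellites). Paired-end reads are indexed to their target
locus by the Read 2 primer-probe alignment position (a `ZP` SAM tag), repeat
counts are measured on Read 1 between exact 15-base flanking sequences,
diploid genotypes are called with stutter-aware allelic-distance thresholds,
and SNPs called from probe-masked Read 2s are phased with the repeat counts
into STR-SNP haplotypes. Cohort analyses cover capillary-electrophoresis
concordance (with per-locus median offset correction), trio Mendelian
validation, and minor-contributor detection/quantification in DNA mixtures.
A read simulator generates synthetic panels, individuals, trios, mixtures
and truth-placed alignment records, so the entire pipeline runs and is
tested without external data or an aligner.

## Layout

| module | role |
|---|---|
| `strseq.reference_model` | panel metadata bundle (loci, probes, flank/exclusion BEDs, gRNA cut sites): load, validate, write |
| `strseq.simulate` | synthetic panels, diploid individuals, trios, mixtures, stutter + fragmentation read simulation |
| `strseq.indexing` | ZP probe tagging of read pairs; CRISPR on-/off-target fragment-end classification |
| `strseq.genotype` | flank-anchored repeat counting, allele histograms, threshold genotype calls, stutter fraction, bp dosage, threshold calibration |
| `strseq.snp_phase` | probe masking, pileup SNP calling + filter cascade, read-backed STR-SNP haplotyping |
| `strseq.cohort` | CE concordance, trio concordance, informative haplotypes, mixture quantification |
| `strseq.design` | candidate STR selection, microsatellite criteria, probe-uniqueness screen, gRNA candidate enumeration |
| `strseq.config` / `strseq.cli` | run configuration, provenance manifest, end-to-end driver, `strseq` CLI |

## CLI

```sh
# synthetic dataset (panel dir, genome.fa, reads.sam, truth tables)
strseq simulate --out demo --n-loci 20 --coverage 50 --seed 1

# pipeline stages
strseq index    --panel demo/panel --in demo/reads.sam --out demo/tagged.sam --tolerance 2
strseq genotype --panel demo/panel --in demo/tagged.sam --out demo/calls.tsv --min-reads 5
strseq haplotype --panel demo/panel --ref demo/genome.fa --in demo/tagged.sam \
                 --out demo/haps.tsv --vcf demo/snps.vcf

# cohort analyses
strseq trio --panel P --ref G --child c.sam --father f.sam --mother m.sam --out trio.tsv
strseq mixture --panel P --ref G --in mix.sam --minor minor.sam --major major.sam \
               --minor-fraction 0.1 --out mix.tsv
strseq ce-compare --panel P --ce ce.tsv --calls s1=calls1.tsv --calls s2=calls2.tsv --out ce.tsv

# end-to-end (simulate -> index -> genotype -> haplotype) with a manifest
strseq run --seed 1 --out runout
```

All positions are 0-based half-open internally (BED convention); SAM I/O
converts at the boundary. Defaults follow the published parameters: probe
tolerance 2 b, cut-site tolerance 4 b, 15-base flanks, 40-base probe mask,
secondary-allele thresholds {−1: 0.35, +1: 0.15, <−1: 0.45, >+1: 0.02},
SNP filters (pvar 0.05, mapq ≥ 25, baseq ≥ 15, coverage ≥ 3, mapping-qsum
≥ 90, allele-qsum ≥ 60, 6-bp thinning, avg alt qual > 8), parent
heterozygosity fraction 0.15, trio minimum coverage 10.

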