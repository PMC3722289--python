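# hlacall

One-step HLA typing from targeted MHC capture sequencing data.

The human MHC region on chromosome 6p is the most polymorphic stretch of the
genome, and clinical decisions (unrelated-donor transplantation, GVHD risk)
hinge on knowing a sample's HLA allele pair per gene at high resolution.
`hlacall` calls allele pairs for every gene of an IMGT/HLA-style allele
database directly from short-read data, in four steps:

1. **Read preparation** — per gene, harvest read pairs with either end
   mapped inside the gene's interval, plus fully unmapped pairs of high
   base quality (rescue pool).
2. **Error correction** — align each read to every allele of its gene;
   keep reads with at most two discordances (a mismatched base, or an
   insertion/deletion run of any length, each count one event) to their
   closest reference, snap them to that reference, and record every
   discordance in a variant ledger.
3. **Haplotype assembly** — per exon, chain corrected reads wherever they
   overlap perfectly by ≥ 10 bp; drop assemblies that occur in no database
   allele (chimeras); score survivors with

   &nbsp;&nbsp;`R = 1 / (1 + D)`, `D = [Σᵢ (Xᵢ − X̄)² / X̄] / (L − 1)` (depth evenness),
   &nbsp;&nbsp;`S = C · R · ln(1 + N)` (coverage C, reads N).

4. **Typing** — each compatible database allele gets
   `TScore = Σₑ Nₑ·Sₑ` over its supported exons; the zygosity ratio
   (unique supporting reads of the runner-up ÷ supporting reads of the
   best type) below 0.1 calls a homozygote, otherwise both top types are
   reported; confidence is `AScore = (S₂ − S₁)/S₀`.  Well-supported ledger
   discordances absent from every known allele are flagged as novel
   SNPs/indels.

A diploid read simulator (2×91 bp pairs, insert 500 ± 10 bp, configurable
depth and error rate) and a synthetic allele-panel generator make the whole
pipeline testable without real capture data.

## Worked example

```bash
hlacall make-db --genes 2 --alleles 4 --exons 4 --seed 7 --out-prefix panel
# wrote 8 alleles (2 genes) to panel.fasta
hlacall simulate --db panel --depth 80 --seed 5 --sample-id s1 --out-prefix sim
# wrote 1936 reads for 2 genes
hlacall type --db panel --fastq1 sim_1.fq --fastq2 sim_2.fq --sample-id s1 --out report.tsv
```

which writes the typing report:

```
sample	gene	allele1	allele2	zygosity	ratio	tscore1	tscore2	ascore
s1	G1	G1*02:02	G1*02:01	heterozygote	0.7398	730.706	646.450	0.4221
s1	G2	G2*02:01	G2*02:02	heterozygote	0.7615	1185.902	935.536	0.4839
```

Each gene gets one or two alleles: the `ratio` column is the runner-up's
unique-read support relative to the best type (≥ 0.1 ⇒ heterozygote), the
`tscore` columns the read-support-weighted assembly scores of the two called
alleles, and `ascore` the normalised score separation from the closest
competing type (larger = more confident).  Checking against the simulation
truth:

```bash
hlacall evaluate --report report.tsv --truth sim.truth.tsv --resolution 0
# {"accuracy": 1.0, "n_alleles": 4}
```

Both genes' allele pairs match the simulated truth exactly.  The same
`hlacall type` command accepts `--bam` plus a gene-region table for
coordinate-sorted alignments of real capture data.

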