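# mhcmate

Analysis toolkit for replicated-amplicon MHC class II B exon-2
genotyping studies: allele-calling QC filters, population-genetic
diversity and selection statistics, and Monte Carlo mate-choice
randomization tests — plus a synthetic-data generator so the entire
pipeline is testable end-to-end without any external downloads.

## Modules

| module | purpose |
| --- | --- |
| `mhcmate.synth` | synthetic allele pools, skewed-frequency genotypes (two unresolvable duplicated loci), breeding pairs under random/assortative/disassortative regimes, replicated amplicon read tables with substitution/indel errors and single-breakpoint chimeras |
| `mhcmate.qc` | filter cascade: quality/length cleaning, error-variant consolidation, chimera removal, run combination, final genotype calling (frequency, replication, depth, ORF and max-allele rules) |
| `mhcmate.popgen` | haplotype count, segregating sites, Eta, π, Watterson's θ, K, and overall/sliding-window Tajima's D |
| `mhcmate.selection` | modified Nei–Gojobori dN/dS with Jukes–Cantor correction and a codon-bootstrap Z-test of positive selection on PBR vs non-PBR codons |
| `mhcmate.matechoice` | pair metrics (heterozygosity difference, band sharing `2·Fab/(Fa+Fb)`, additive/maximum amino-acid dissimilarity in whole-fragment and PBR contexts), the 10,000-iteration re-pairing null, Bonferroni control and sample-size sensitivity curves |
| `mhcmate.io` / `mhcmate.cli` | plain-text readers/writers (FASTA, TSV, YAML mask) and the umbrella CLI |

## CLI

```bash
# generate a synthetic study (FASTA + genotype/pair/read tables + mask)
mhcmate simulate --out data/sim --seed 1

# call genotypes from the replicated read-variant table
mhcmate qc --reads data/sim/reads.tsv --fasta data/sim/alleles.fasta --out out/qc

# diversity statistics and windowed Tajima's D
mhcmate popgen --fasta data/sim/alleles.fasta --window 25 --step 5 --out out/popgen

# dN/dS Z-test on PBR vs non-PBR codons
mhcmate selection --fasta data/sim/alleles.fasta --mask data/sim/mask.yaml --out out/sel

# the six mate-choice randomization tests
mhcmate matechoice --pairs data/sim/pairs.tsv --genotypes data/sim/genotypes.tsv \
    --fasta data/sim/alleles.fasta --mask data/sim/mask.yaml \
    --iters 10000 --seed 1 --out out/mc

# everything at once, with a provenance manifest
mhcmate pipeline --fasta data/sim/alleles.fasta --genotypes data/sim/genotypes.tsv \
    --pairs data/sim/pairs.tsv --reads data/sim/reads.tsv --out out/all --seed 1
```

## File conventions

Tables are tab-separated with a header row and optional `# key=value`
provenance comments; allele sets are semicolon-joined; all coordinates
are 0-based half-open. The PBR codon mask is a small YAML file
(`frame_offset`, `total_codons`, `pbr_codons`); the packaged default
(`src/mhcmate/data/pbr_mask.yaml`) maps the classical human DRB
peptide-contact residues onto a 298-nt fragment and is explicitly an
editable interpretation.

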