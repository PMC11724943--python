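# minibarc

A toolkit for developing and applying mitochondrial **mini-barcodes**
(100–250 bp markers for degraded-DNA species identification) across a
panel of closely related species:

1. **scan** — per-gene nucleotide diversity (π) and a sliding-window
   profile (default 20 bp window, 1 bp step) over gene alignments to
   rank hypervariable genes and locate perfectly conserved windows.
2. **design** — enumerate primer candidates on zero-diversity anchor
   stretches, score GC%, melting temperature (nearest-neighbor or
   Wallace), hairpin/self-dimer/cross-dimer complementarity, pair them
   under insert-length (100–250 bp) and compatibility constraints, and
   rank pairs by variable sites in the inter-primer region.
3. **ispcr** — mismatch-tolerant in-silico PCR (ungapped Hamming model
   with an exact 3'-anchor requirement) to extract amplicons from
   unaligned templates.
4. **classify** — turn amplicon reads from a mixed sample into a species
   composition table: primer trimming, dereplication, a lite greedy
   denoiser, best-hit global-identity assignment against a reference
   amplicon panel, and a <1 % abundance filter.
5. **simulate** — fully specified synthetic fixtures: species panels
   with planted conserved anchors and hypervariable cores, plus
   error-bearing read mixtures with known weights.

## Test

```bash
python -m pytest -q tests/
```

The accession-dependent acceptance tests additionally require the five
reference mitogenome GenBank records (NC_023776, NC_023925, NC_023928,
NC_023926, NC_013569) in `data/accessions/`. They are not bundled (the
build environment had no NCBI network access) and those tests **fail
with an explanatory message** until you populate the directory:

```bash
python scripts/fetch_accessions.py        # needs internet
```

## CLI

```bash
# diversity scan over one or more gene alignments
minibarc scan --alignment 16S.aln.fasta --alignment ATP6.aln.fasta \
    --out-genes genes.tsv --out-windows windows.tsv

# primer design on a gene alignment
minibarc design --alignment 16S.aln.fasta --gene 16S --out pairs.tsv

# in-silico PCR against FASTA or GenBank templates
minibarc ispcr --templates panel.fasta \
    --fwd AGAAGACCCTATAAAGC --rev TTAAGTCAACATCGAGG \
    --out-fasta amplicons.fasta --out-bed amplicons.bed --out-tsv amplicons.tsv

# read classification into a composition table
minibarc classify --reads reads.fastq --panel refs.fasta \
    --fwd AGAAGACCCTATAAAGC --rev TTAAGTCAACATCGAGG --out composition.tsv

# synthetic fixture generation
minibarc simulate --seed 1 --out fixture/
```

All tabular output is TSV with a header row and `.` for missing values;
coordinates in reports are 1-based inclusive (internally everything is
0-based half-open). Exit codes: 0 success, 1 data error, 2 usage error.

## Package layout

| module | purpose |
| --- | --- |
| `minibarc.seqio` | FASTA / aligned FASTA / GenBank / FASTQ I/O, sequence and alignment containers, gene-name alias table |
| `minibarc.diversity` | per-column & gene-wide π, sliding windows, gene ranking |
| `minibarc.primer_design` | conserved-window detection, candidate enumeration, thermodynamic screening, pairing, ranking |
| `minibarc.insilico_pcr` | primer matching and amplicon extraction |
| `minibarc.classify` | trimming, dereplication, denoising, assignment, composition |
| `minibarc.synthetic` | seeded fixture generator with truth records |
| `minibarc.align` / `minibarc.workflow` | MAFFT wrapper and panel convenience workflows |
| `minibarc.cli` | `minibarc` command-line entry point |
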