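# Reference mitogenome records

This directory should hold the five reference leech mitochondrial
genomes as GenBank flat files:

- `NC_023776.gb` — *Hirudo nipponia* (reference species)
- `NC_023925.gb` — *Poecilobdella manillensis*
- `NC_023928.gb` — *Whitmania acranulata*
- `NC_023926.gb` — *Whitmania laevis*
- `NC_013569.gb` — *Whitmania pigra*

They are not bundled with the repository because the build environment
had no network route to NCBI. Populate them with:

```bash
python scripts/fetch_accessions.py
```

The accession-dependent acceptance tests and `scripts/acceptance.py`
targets t4/t5/t6/t8/t10 consume these files.
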