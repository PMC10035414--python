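# famscan

A toolkit for genome-wide transcription-factor family surveys of the
bHLH type, exercised entirely on synthetic fixtures with known ground
truth. It covers the full analysis chain:

- **`synthetic_data`** — fixture generator: proteins with planted
  79-residue domains, gene models on pseudo-chromosomes (GFF3),
  promoters with planted cis-elements, a 4-treatment expression matrix
  with planted cluster/fold-change structure, GO and replicated Ct
  tables, plus truth labels for every stage. The versioned `cp159`
  preset plants the headline composition of a published survey
  (174 putative → 159 validated members on 21 pseudo-chromosomes,
  93/43/23 binding census, 12.6% intronless, 155 expressed genes,
  12 salt-stress candidates).
- **`family_identification`** — position-specific scoring model built
  from a seed alignment, local affine-gap domain scanning,
  completeness/redundancy filtering, chromosomal-order naming, and
  molecular weight / isoelectric point computation.
- **`domain_conservation`** — model-frame alignment, per-column
  consensus ratios (>50% / >75% calls), region labels
  (basic/helix1/loop/helix2), and DNA-binding classification
  (G-box / E-box / non-E-box) from basic-region residues 9/13/16/17.
- **`phylogeny`** — p-distances with pairwise deletion, neighbor
  joining (exact on additive matrices), seeded bootstrap support, and
  subfamily assignment against labeled references.
- **`structure_and_cis`** — GFF3 gene models, exon/intron statistics,
  and IUPAC cis-element scanning on both strands from a versioned
  catalog (`src/famscan/data/cis_catalog.tsv`).
- **`expression_screen`** — abundance filter (>1 in ≥1 treatment),
  log2(x+1) normalization, average-linkage clustering of z-scored
  profiles, fold-change DEG screening, and candidate selection as the
  union with GO salt-annotated genes.
- **`qpcr_stats`** — 2^−ΔΔCT relative expression, one-way ANOVA, and
  Duncan's multiple range test with a compact letter display.
- **`pipeline`/`cli`** — end-to-end orchestration with a JSON report.

## CLI

```bash
# generate a fixture bundle with truth labels
famscan simulate --preset cp159 --seed 1 --outdir fixture/

# individual stages
famscan identify --proteins fixture/proteins.faa --gff fixture/genes.gff3 \
    --seed-alignment fixture/seed_domains.fasta --prefix CpbHLH --outdir out/
famscan cis --promoters fixture/promoters.fa --outdir out/
famscan qpcr --qpcr fixture/qpcr.tsv --reference 18sRNA --calibrator CK --outdir out/

# everything from one YAML config (see PipelineConfig for keys)
famscan all --config config.yaml
```

`famscan all` writes per-stage TSV/FASTA/Newick artifacts plus a
`report.json` with summary counts, a file manifest and a config hash.

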