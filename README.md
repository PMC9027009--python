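# sexmark

Sex-linked marker discovery from GBS/RAD genotype catalogs.

Given a genotype catalog (tag/SNP genotype table or VCF) and a sample→sex
map, `sexmark`:

1. **screens** every SNP site and tag with three per-sex criteria —
   allele-frequency differentiation (one allele at frequency ≥ 0.95 in the
   homogametic sex with a between-sex difference ≥ 0.4), heterozygosity
   contrast (homozygous in every homogametic-sex individual, heterozygous in
   at least half of the heterogametic sex), and sex-limited tag occurrence
   (absent from one sex, present in all of the other);
2. **classifies** the heterogametic system (XY vs ZW) from the pattern
   tallies of the deduplicated tag union;
3. **confirms** putative markers against parsed BLAST tabular hits (top-hit
   E ≤ 1e-20; optional second-hit margin rule of ≥ 5 orders of magnitude);
4. **proposes validation primers** — SD primers on conserved footprints
   flanking a target SNP, and allele-specific PA primers whose 3′-terminal
   base is anchored on the male-specific allele;
5. **calls genotypic sex** per individual from a marker panel and flags
   discordance with phenotypic sex (putative sex reversal).

A seeded simulator generates genotype catalogs with known truth (sex-linked
SNPs, sex-limited tags, autosomal Hardy–Weinberg background, genotyping
error, missing data, planted sex reversals) so the whole pipeline is
testable offline.

## CLI

All subcommands share `--out`; detection/sexing consume `--genotypes`,
`--sex-map` and optionally `--presence` (or `--vcf`).

```sh
# simulate a catalog with truth tables
sexmark simulate --config sim.yaml --seed 7 --out sim

# run the three detectors and classify the system
sexmark detect --genotypes sim.genotypes.tsv --sex-map sim.sexmap.tsv \
    --presence sim.presence.tsv --out markers.tsv

# confirm markers against BLAST outfmt-6 hits (add --gene for the margin rule)
sexmark confirm --markers markers.tsv --hits blast.tsv --out confirmed.tsv --bed confirmed.bed

# genotypic sexing from a marker panel
sexmark sex --genotypes sim.genotypes.tsv --sex-map sim.sexmap.tsv \
    --presence sim.presence.tsv --panel panel.tsv --out calls.tsv

# primer proposals from tag FASTA + SNP table
sexmark primers --tags tags.fasta --snps sites.tsv --type PA --out primers.tsv
```

Thresholds and simulator parameters are YAML-overridable (`detection:`,
`classify:`, `confirmation:`, `simulation:` sections); defaults match the
study's printed criteria.

### File dialects

- genotype table: TSV `tag_id  site  ref  alt  <sample>...` with tokens
  `0/0 0/1 1/1 ./.` (site is a 0-based offset within the tag);
- sex map: `sample  M|F|U`;
- presence matrix: `tag_id  <sample>...` with `1/0/NA`;
- panel: `tag_id  site  marker_type(SD|PA)  system(XY|ZW)` (site 1-based, or
  `tag` for PA);
- BLAST hits: 12-column `-outfmt 6`.

Coordinates are 0-based half-open internally, 1-based in report columns.

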