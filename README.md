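# msytools

Toolkit for analysing the male-specific region of the Y chromosome (MSY)
from short-read data:

- **`msytools.coverage`** — classify assembly windows into single-copy Y
  (scY), multi-copy Y (mcY) and non-Y (nonMSY) classes with a Poisson
  likelihood-ratio model contrasting male and female mapping coverage;
  calibrate per-sample diploid coverage from pseudoautosomal windows and
  female mismapping background from trusted scY windows (or a two-pass
  bootstrap); filter contigs by Y-specific content and length.
- **`msytools.variants`** — staged quality filter for haploid Y variant
  calls (scY intersection; phased / multi-allelic / reference-error
  exclusion; depth ≥ 3 & GQ ≥ 9 in at least one individual; ≤ 10%
  het-or-missing calls), plus nearest-neighbour imputation of residual
  missing genotypes by phylogenetic clustering.
- **`msytools.phylogeny`** — haplotype collapsing, outgroup polarization,
  four-gamete (infinite-sites) checking, perfect-phylogeny construction
  with per-branch mutation lists, an exhaustive Fitch maximum-parsimony
  oracle (≤ 8 taxa), site-resampling bootstrap support, exact
  flank-identity coordinate liftover, and STR allele-length arithmetic.
- **`msytools.rates`** — chi-square branch-equality tests with simulated
  p-values (Poisson or total-conditioned resampling) and an exact binomial
  oracle; pedigree generation-interval estimation; de novo mutation-rate
  estimation and per-year conversion; closed-form Poisson-clock TMRCA
  dating with envelope confidence intervals.
- **`msytools.simulate`** — synthetic coverage tables, infinite-sites
  haplotype matrices on known genealogies, and patriline pedigrees, all
  deterministic in their seed.
- **`msytools.io` / `msytools.cli`** — TSV/BED/VCF/FASTA/newick readers and
  writers and the `msy` command-line interface.

## CLI

```sh
# synthetic fixtures
msy simulate coverage --seed 1 --out simcov/
msy simulate tree     --seed 1 --out simtree/
msy simulate pedigree --n-tips 500 --seed 1 --out simped/

# pipeline stages
msy classify --windows simcov/coverage.tsv --profiles simcov/profiles.tsv \
    --out classes.bed --summary contigs.tsv
msy filter-variants --vcf calls.vcf --scy scY.bed --out kept.vcf \
    --report report.tsv --outgroup donkey
msy tree --matrix simtree/matrix.tsv --outgroup outgroup \
    --out tree.nwk --branches branches.tsv
msy branch-test --counts 5,26 --sims 10000 --seed 1
msy date --mutations 10 --length 5830000 --rate-per-gen 1.69e-8 --interval 8:12
msy liftover --variants flanks.tsv --target assembly.fa --out lift.tsv
```

Coverage tables are TSV (`contig  start  end  <sample...>`, BED-style
0-based half-open windows); profiles are TSV (`sample_id  sex  c  b`, `b`
empty for males); haplotype matrices are TSV with cells `0`/`1`/`.`;
trees are newick with `name:mutation_count` branch labels.

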