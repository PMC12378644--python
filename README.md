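# spikequant

Internal-standard ("spike-in") quantitative metagenomics: convert shotgun
read counts into **absolute, per-liter abundances** by calibrating against
known quantities of spiked genomic standards, using single-copy marker
genes (*recA* for bacteria, *radA* for archaea, *psbO* for phototrophs).

The package implements:

- **`spikequant.synthetic`** — a deterministic spiked-metagenome
  generator: multi-sample transects of communities with known truth,
  three genomic standards dosed at ~1% of DNA mass, and merged shotgun
  reads drawn by a mass-weighted multinomial model (plus a counts-only
  fast path with the identical distribution).
- **`spikequant.matcher`** — a k-mer-seeded, ungapped, deterministic
  read classifier (a desk-scale stand-in for BLAST-style search) with
  per-class percent-identity and alignment-length-fraction filters and
  best-hit-only semantics.
- **`spikequant.quantify`** — the recovery-ratio calculus: per-standard
  genome copies recovered `S_r = S_s / S_p`, recovery ratio
  `R = S_r / S_a`, combined per-sample recovery (geometric / arithmetic /
  pooled), gene molecules `G_a = G_s / R`, haploid genome equivalents per
  liter, ploidy-adjusted cell counts, and per-sample detection limits
  `1 / (R × volume)`.
- **`spikequant.crossdomain`** — two eukaryotic-phytoplankton
  estimators from *psbO* counts: the *direct* recovery-ratio route and
  the *anchored* route (cyanobacterial *recA* absolute abundance scaled
  by the eukaryote/cyanobacteria *psbO* read ratio), in which any common
  *psbO* annotation undercount cancels.
- **`spikequant.validation`** — comparison statistics: paired slope
  (through-origin / OLS / SMA) and Pearson correlation, fold-range,
  filament-to-cell conversion, relative-abundance derivation, and
  Bray–Curtis dissimilarity with classical PCoA variance explained.
- **`spikequant.experiments`** — replicated end-to-end simulation
  experiments (parameter recovery, undercount-bias cancellation,
  detection-limit scaling with depth).

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (equation
oracles, brute-force matcher equivalence, end-to-end parameter recovery
on 20 × 100 000-read samples, undercount-bias cancellation, detection
limit scaling, determinism); the full suite takes a few minutes, most of
it in the end-to-end classification run.

## CLI

```bash
# generate a synthetic spiked transect (reads, references, truth tables)
spikequant simulate --config config.yaml --out-dir out/ --seed 7

# classify reads into a count table
spikequant match --reads out/reads_sample001.fasta \
    --references out/references.fasta --out counts.tsv

# recovery ratios + absolute abundances
spikequant quantify --counts counts.tsv --samples out/samples.tsv \
    --standards out/standards.tsv --method geometric --out-dir quant/

# eukaryotic phytoplankton estimators (direct + anchored)
spikequant crossdomain --counts counts.tsv --abundance quant/abundance.tsv \
    --samples out/samples.tsv --standards out/standards.tsv \
    --domains domains.tsv --estimator both --out euk.tsv

# comparison statistics / ordination
spikequant validate compare --pairs pairs.tsv --slope-model all --out stats.tsv
spikequant validate ordinate --matrix matrix.tsv --mode relative --out-dir ord/

# everything at once
spikequant end-to-end --config config.yaml --out-dir run/ --seed 7
```

A YAML config (see `spikequant.synthetic.default_config()` for all keys)
describes the taxon roster, abundance range, standard dosing fraction,
read depth and per-marker annotation sensitivities. Every run writes a
JSON manifest (config, seed, versions, input checksums); outputs are
TSV/FASTA/BED, written atomically, and re-readable by `spikequant.io`.

## File formats

- **TSV** — tab-separated, UTF-8, optional `#key=value` metadata lines
  before the header; missing values are empty strings.
- **FASTA** — reads (headers carry the simulator's latent-source tags,
  used only by tests) and references (headers carry
  `class=<ref_class> group=<taxon or standard>` attributes).
- **BED** — marker/gene loci, 0-based half-open.
- **YAML** — simulation/threshold configs; **JSON** — run manifests.
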