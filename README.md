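# its2meta

An ITS2 amplicon metabarcoding toolkit for soil-algae community profiling:
paired-end read processing, greedy centroid OTU clustering at 97% identity,
normalized-bit-score (NB) consensus taxonomy with genotype/species identity
calling, site-overlap classification, and community diversity statistics —
exercised end-to-end on synthetic data with known ground truth.

## What it does

- **`its2meta.synthetic`** — generates a hierarchical reference database
  (class → order → genus → species → genotype) with controlled pairwise
  divergence bands, site communities with a controlled shared-genotype
  fraction between two site groups, and primer-tagged paired-end reads with
  substitution errors, two-parent chimeras and an off-target minority.
  Every read has a ground-truth row, enabling parameter-recovery tests.
- **`its2meta.reads`** — primer screening and re-orientation into amplicon
  pools, ungapped overlap merging with quality-weighted base resolution
  (including read-through "outie" layouts), maxEE quality filtering
  (keep iff length > 200 and expected errors < 1), dereplication, and
  de novo two-parent single-crossover chimera flagging.
- **`its2meta.clustering`** — motif-proxy ITS2 core extraction, exhaustive
  greedy abundance-sorted centroid clustering (the maxaccepts/maxrejects=0
  regime), a 0.005%-of-initial-reads abundance floor, and clone-library
  co-clustering that flags mixed OTUs.
- **`its2meta.taxonomy`** — local alignment with blastn-style scoring and
  Karlin–Altschul bit scores, NB = bit score / reference length (ceiling
  ≈ 1.81 for a perfect full-length match), consensus assignment by
  bit-score sums over the top 10 hits with non-target suppression over all
  50 recorded hits, identity classes (genotype: NB = 1.81; species:
  1.75 ≤ NB < 1.81), and groupA/groupB overlap classification.
- **`its2meta.stats`** — per-class OTU composition, Observed/Shannon/
  InvSimpson alpha diversity, rarefaction curves, Kruskal–Wallis tests,
  per-genus NB box statistics, and top-N abundance matrices.
- **`its2meta.pipeline` / `its2meta.cli`** — orchestration of all stages
  from one YAML config with per-stage read-conservation logging, derived
  per-stage seeds and a hashed output manifest.

## Test

```bash
python -m pytest -q tests/
```

The suite includes randomized oracle-equivalence tests (brute-force
re-derivations of merging, local alignment, greedy clustering, consensus
assignment and Kruskal–Wallis) and a full-scale zero-error recovery run
(4 classes x 3 genera x 2 species x 2 genotypes, 50k reads/site, 7+1 sites).

## CLI

```bash
# generate a synthetic dataset (reference FASTA, paired FASTQ, truth TSV)
its2meta simulate --config config.yaml --seed 1 --out simdir/

# run the full pipeline from one config
its2meta run --config config.yaml --seed 1 --out rundir/

# recompute the headline summary from a finished run directory
its2meta stats --out rundir/
```

Example config:

```yaml
seed: 1
simulate:
  divergence:
    genotype: [0.032, 0.042]
    species: [0.06, 0.11]
    genus: [0.18, 0.28]
  shared_fraction: 0.35
  reads_per_site: 50000
  error_rate: 0.001
  chimera_rate: 0.01
  offtarget_fraction: 0.01
identity_threshold: 0.97
floor_fraction: 0.00005
```

Instead of the `simulate` block, real inputs can be given via
`fastq_fwd`/`fastq_rev` (plus `sample_groups`) and a precomputed
15-column BLAST tabular `hit_table` with an optional `lineage_table`.

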