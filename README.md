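# mutacc

Mutation-accumulation contrasts between sexual and clonal (apomictic)
plant lineages from resequencing variants.

Sexually reproducing lineages purge deleterious mutations that
non-recombining clonal lineages retain (Muller's Ratchet,
Hill–Robertson interference). `mutacc` implements an end-to-end,
testable analysis of this contrast for cohorts of sympatric
sexual/apomict genotype pairs:

* **`mutacc.simulate`** — a seeded synthetic-cohort generator (reference,
  annotation BED, multi-sample VCF, phased apomict haplotype blocks,
  truth JSON) with highly selfing sexual lineages, hybrid apomicts
  carrying a conspecific and a diverged sister-species haplotype, clonal
  genealogies within hybridization-origin groups, and a configurable
  relaxation factor ρ for constrained-site mutation retention in
  apomicts. Every planted event is truth-logged, so all downstream
  stages are verifiable without real data.
* **`mutacc.variants`** — VCF/BED/FASTA readers, site/genotype-quality
  filters, a callable-fraction window filter, cohort-polymorphism
  restriction, and ancestral/derived allele polarization against an
  outgroup reference.
* **`mutacc.diversity`** — observed heterozygosity H0 and derived-allele
  proportion D per sample and annotation category ({0fold, 4fold, CNS,
  CCS, other}), the constrained/neutral ratio d_constrained/d_neutral,
  Fisher exact pair tests, one-sided Z-tests of log-odds-ratio
  differences, SNP-windowed H0/d_ij profiles, derived-allele-frequency
  binned ratios, and a minimum-spanning distance network.
* **`mutacc.trees`** — five-taxon alignments (two phased apomict
  haplotypes, two randomly split sexual pseudo-haplotypes, outgroup),
  GTR+Γ likelihoods by the pruning algorithm over compressed site
  patterns, exhaustive ML evaluation of all 15 rooted-by-outgroup
  topologies, RELL or full-refit bootstrap supports, and
  support/divergence tree filters.
* **`mutacc.topology`** — classification of trees into the six topology
  classes (H1/H2 hybrid, P1 pure, C4/B1/B2 ambiguous), conspecific-tip
  identification, parsimony assignment of derived mutations to branches
  by category, terminal-branch Fisher contrasts (C1–C4 plus combined),
  and the exact binomial test against the conservative 2× terminal-branch
  null.
* **`mutacc.pipeline` / `mutacc.cli`** — configuration, orchestration,
  per-stage TSV/JSON reports and a deterministic summary.

## CLI

```sh
# simulate a cohort
mutacc simulate --config config.yaml --out out_dir --seed 1

# filter a VCF against the standard thresholds (15 / 40 / 20 kb / 30%)
mutacc filter --vcf cohort.vcf --bed annotation.bed \
    --fasta reference.fa --samples samples.tsv --out filtered

# full chain: simulate/read -> filter -> diversity -> trees -> contrasts
mutacc run-all --config config.yaml --seed 1
```

A config is a YAML file of `mutacc.pipeline.PipelineConfig` fields, e.g.

```yaml
out_dir: run1
sim:
  genome_length: 100000
  n_pops: 8
  mu: 0.001
  hybrid_divergence: 0.02
  selfing_F: 0.75
  relax_factor_rho: 3.0
seed: 1
```

Every run writes a `config_snapshot.yaml` and a `summary.json`; identical
config + seed reproduce byte-identical summaries. Exit status 3 marks an
empty-result condition (e.g. no sites survive filtering), distinct from
errors.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: an exhaustive
internal-state likelihood oracle for GTR+Γ, topology-class enumeration,
exact-test oracles (rational hypergeometric enumeration; the one-sided
normal-tail convention), planted-effect recovery (ρ=3) and null
calibration (ρ=1) over 100 simulated cohorts each, hybrid-origin and
conspecific-tip recovery, a hand-enumerated filter fixture, and seeded
determinism. The full suite runs on one CPU in roughly 10–15 minutes;
the heavy simulation tests are sized accordingly.

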