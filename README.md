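# coremix

Relative abundance estimation for microbial communities from shotgun
metagenomic reads, using **concatenated core-genome references** and a
**finite mixture / latent Dirichlet model** inferred by collapsed Gibbs
sampling. It is aimed at microbiome researchers who have (or simulate)
short single-ended reads and want species-level relative abundances that
handle multi-mapping reads properly instead of discarding them.

## The model

A metagenome over M reference species G = {g₁…g_M} is modelled as a
mixture Σᵢ θᵢ gᵢ with weights θ ~ Dir(α), Σθᵢ = 1. Each of the N reads
carries a hidden origin index zᵢ ~ Mult(θ) and its sequence is drawn from
the origin's read-composition distribution φ. With no prior on Φ, it is
estimated from an all-hits alignment:

    φ_{k,m} ≈ (# reads of sequence r_k hitting g_m with high quality)
            / (# reads hitting g_m with high quality)

where "high quality" means edit-distance rate ≤ 0.1 of the aligned length
(NM tag). Integrating θ out by Dirichlet–multinomial conjugacy leaves the
collapsed full conditional

    p(zᵢ = t | z₋ᵢ, R) ∝ φ_{rᵢ, g_t} · (n_{t,¬i} + α_t),

sampled in a systematic scan. Posterior mean counts n̄ give
θ̂_k = (n̄_k + α_k)/Σ(n̄ + α), and since θᵢ ∝ aᵢ·lᵢ (longer references
attract more reads), relative abundances follow by length normalisation:

    aᵢ = (θᵢ / lᵢ) / Σ_s (θ_s / l_s).

The package also contains a community simulator (preset abundances,
fixed-length reads with i.i.d. substitution errors, shared-gene ambiguity)
and a built-in all-hits ungapped matcher whose seeded k-mer index is
provably equivalent to an exhaustive scan, so the whole pipeline runs and
validates end-to-end with no external mapper. Any SAM-producing mapper
(e.g. `bwa mem -a`) can be used instead.

## Worked example

```python
import coremix as cm

fx = cm.make_fixture(n_species=4, genes_per_species=10, gene_length=500,
                     shared_fraction=0.3, n_reads=2000, seed=5)
hits = cm.filter_high_quality(cm.simulate_alignment(fx.reads, fx.refset, 0.1), 0.1)
table = cm.build_read_table(fx.reads)
phi = cm.estimate_phi(table, hits, fx.refset)
summary = cm.run_gibbs(table, phi, alpha=1.0,
                       config=cm.GibbsConfig(burn_in_sweeps=500, kept_samples=500, seed=1),
                       lengths=fx.refset.lengths)
```

Running `python examples/03_estimate_abundance.py` (the same computation)
prints:

```
species          estimate   truth
species_00         0.3444  0.3657
species_01         0.2749  0.2743
species_02         0.2079  0.2057
species_03         0.1728  0.1543
unassigned fraction: 0.0000
RRMSE: 6.70%
```

The estimate column is â, the posterior relative abundance of each
species; truth is the preset community profile the reads were simulated
from; RRMSE = 100·√(mean(((â−a)/a)²)) summarises the relative deviation —
here ~7% from only 2,000 reads with 30% of the reference bases shared
between species. The `examples/` directory has one short script per
capability (reference building, simulation, estimation, the exact
enumeration cross-check, and sample distance matrices).

## Command line

A thin CLI wraps the library:

```sh
coremix simulate -o data --n-reads 50000 --write-sam
coremix run --reference data/reference.fasta --reads data/reads.fasta \
            --seed 1 -o abundance.tsv
coremix evaluate --estimated abundance.tsv --truth data/abundance_truth.tsv
```

Subcommands: `build-ref`, `simulate`, `profile`, `estimate`, `run`,
`evaluate`, `distances`; all flags can come from a flat `key = value`
config file (`--config`), with explicit flags taking precedence.

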