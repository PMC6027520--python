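# Methods

## Model and inference

The estimator treats a metagenomic read set as draws from a finite
mixture of M reference species. Reference i is a single sequence g_i of
length l_i obtained by concatenating that species' core genes — the genes
shared by all strains of the clade — so that strain-level variation in
the accessory genome does not fragment the mapping signal. The mixture
weight θ_i is the probability that a random read originates from g_i;
because a species' read output scales with both its cell abundance a_i
and its reference length, θ_i ∝ a_i·l_i, and the two parameterisations
are inter-convertible (`abundance_to_theta` / `theta_to_abundance`).

Each read occurrence i has a hidden origin z_i ~ Mult(θ) with θ ~ Dir(α).
The read-composition distributions Φ (probability of each distinct read
sequence given each reference) carry no prior; they are plugged in from
alignment results as the hit-count ratio
φ_{k,m} = #(occurrences of sequence r_k hitting g_m) / #(occurrences
hitting g_m), counting each (occurrence, reference) pair once no matter
how many alignment lines connect them. "Hitting" means an alignment whose
edit-distance rate (NM / aligned length) is at most `max_error_rate`
(default 0.10). This ratio is an approximation, used unweighted; no
alignment-score weighting is applied.

Collapsing θ by Dirichlet–multinomial conjugacy gives the full
conditional p(z_i = t | z_¬i) ∝ φ_{r_i,t}·(n_{t,¬i} + α_t). The sampler
initialises every z_i uniformly over its read's candidate references
(those with φ > 0) and performs systematic sweeps in occurrence order:
decrement, sample, increment. After `burn_in_sweeps` sweeps the count
vector is recorded every `thinning` sweeps until `kept_samples` samples
exist; θ̂ is the conjugate posterior mean applied to the averaged counts
and â its length-normalised transform. Identical read sequences share a
φ row but keep individual z_i. Reads with no qualifying hit are excluded
from inference and reported as an unassigned fraction — the model has no
outlier component. Species with zero assigned reads retain prior-driven
θ̂ mass; `PosteriorSummary.detected_only()` optionally zeroes and
renormalises them for reporting.

### Exact oracle

`exact_posterior_oracle` enumerates all M^N assignments (guarded at
M^N ≤ 10⁶), weighting each by Π_i φ_{r_i,z_i} · Δ(n(z)+α)/Δ(α) with
Δ(α) = ΠΓ(α_k)/Γ(Σα_k), computed in log space via `gammaln`. It is an
independent route to the posterior used to validate the sampler; the test
suite additionally checks the oracle itself against a literal
`itertools.product` enumeration with explicit Γ arithmetic.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α | 1 (symmetric) | Dirichlet pseudo-counts per species; 1 is a flat prior and adds one phantom read per species. Configurable per species. |
| max_error_rate | 0.10 | hit-quality threshold, as edit distance per aligned base; also the matcher's mismatch budget. |
| burn_in_sweeps | 1000 | discarded sweeps before collection. |
| kept_samples | 1000 | count vectors averaged for n̄. |
| thinning | 1 | sweeps between recorded samples. |
| convergence_tolerance | off | optional early stop when the running-mean θ̂ moves less than this between 100-sample checkpoints (min. 200 samples kept). |
| seed | — | one seed drives initialisation and all sweeps; recorded in the output header, and fixed seeds give byte-identical reports. |

The Gibbs inner loop and the matcher's mismatch verification are
numba-compiled; a sweep visits every assigned occurrence once, so the
default schedule costs 2,000 × N candidate-weighted draws.

## The simulator and what it does (not) emulate

`make_fixture` builds communities whose references are concatenations of
fixed-length pseudo-genes; a fraction `shared_fraction` of each species'
genes is drawn without replacement from a common pool (pool size 1.5×
the per-species share), so the same gene recurs in several species —
the core-gene sharing between related clades that makes reads ambiguous.
Reads are fixed-length (default 100 bp), single-ended, forward-strand
(a flag enables reverse-complement sampling at probability ½), with
uniform start positions and i.i.d. substitutions at 1% by default; an
optional per-position rate profile hooks in position-dependent error.
The default ten-species profile (0.25, 0.18, 0.14, 0.11, 0.09, 0.07,
0.06, 0.05, 0.03, 0.02) spans a 12.5-fold dominant-to-rare range —
chosen as a realistic skewed community with no species so rare that its
relative error is pure shot noise.

Not emulated: indels, quality-score-correlated errors, GC bias, real
phylogenetic sequence divergence (shared genes are identical, private
genes are unrelated random sequence), paired ends, and contaminant or
"unknown species" reads. Passing recovery tests therefore shows the
inference machinery is correct under the stated generative model, not
that real-data accuracy will match; with real data, accuracy additionally
depends on reference completeness and mapper behaviour.

The built-in matcher performs ungapped all-hits matching with a mismatch
budget t = ⌊max_error_rate·L⌋ per read of length L. It takes t+1 disjoint
seeds per read (length min(⌊L/(t+1)⌋, 13)); by pigeonhole any placement
with ≤ t mismatches matches at least one seed exactly, so the k-mer index
finds exactly the placements an exhaustive scan would (asserted against a
brute-force scan in the tests). It is a validation tool, not a general
aligner: no indels, no clipping, and identical shared genes are hit
exactly, which is the intended ambiguity mechanism.

## Numerical and design choices

- In the collapsed conditional the prior term uses α_t of the *candidate*
  species, consistent with the normalising sum Σ_j (n_{j,¬i} + α_j).
- Sweep order is a fixed systematic scan (occurrence index order) for
  reproducibility; random-scan Gibbs would mix similarly but not be
  replayable from a seed alone.
- With a single-candidate read the draw is skipped entirely (it cannot
  move), which also makes the all-unambiguous case exactly deterministic:
  θ̂ equals (n+α)/(N+Σα) bit-for-bit.
- φ columns are normalised only over references that received hits;
  hitless references keep all-zero columns and never enter candidate
  sets.
- Genes are concatenated without spacers by default; reads spanning gene
  junctions are an accepted, tiny artifact. A `spacer_n` option inserts
  N-runs for users who want junction alignments suppressed; l_i counts
  all bases including N and spacers since it normalises read attraction.
- Abundance reports are written with fixed `%.10g` formatting so equal
  runs are byte-identical.
- The accuracy metric is the relative root-mean-square error in percent,
  100·√(mean(((â−a)/a)²)); per-replicate RRMSEs are averaged (not pooled
  before the square root) when summarising over seeds.
- Sample distances are 1 − Spearman ρ between abundance profiles;
  constant profiles are rejected (undefined ranks). Dendrogram drawing is
  left to downstream tools (e.g. `scipy.cluster.hierarchy` with average
  linkage on the emitted matrix).

## Problem sizes used in validation

The recovery benchmark uses ten 50 kb references (50 genes × 1 kb, 20%
shared), 50,000 reads of 100 bp at 1% substitution error, and the default
1000/1000 sweep schedule — small enough to run in seconds yet deep enough
that the rarest species (2%) receives ~1,000 reads. The depth-trend check
(1,000 / 10,000 / 50,000 reads, five seeds each) uses a 300/300 schedule,
sufficient for a trend statistic on seed-averaged RRMSE. Sampler
correctness is checked against exhaustive enumeration on instances with
M ∈ {2,3} and N ≤ 8, where 50,000 kept samples pin the posterior mean
counts to within 0.05.

## Known limitations

- Eq.-10-style φ estimation weights every qualifying hit equally; a
  highly abundant reference inflates its φ denominator, which leaves a
  small systematic transfer of mass from abundant to rare species on
  heavily shared references (visible as the ~8–10% RRMSE floor at high
  depth in the benchmark).
- The unassigned fraction is reported but not modelled; communities with
  many reads from species absent in the reference set will redistribute
  those reads' mass only if they spuriously pass the hit filter.
- The exact oracle is exponential in N and deliberately capped.
- The matcher is ungapped; indel-bearing reads must come from an external
  mapper via SAM.
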