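# Methods

## Attribution model

Every palm sample is treated as a *sink* whose reads are a mixture over
*sources*: each individual stool, tongue and forehead sample in the
cohort, plus one latent "unknown" environment. The model is the collapsed
mixture formulation used by SourceTracker-style trackers. Source taxon
profiles are held fixed at their observed counts, smoothed by a
pseudocount α₁ per taxon; the unknown environment has no observed counts
and builds its profile as a Pólya urn over the sink reads currently
assigned to it, smoothed by α₂; a symmetric Dirichlet pseudocount β acts
as the prior over source membership. A Gibbs sweep resamples every read's
label from

P(z_i = v | rest) ∝ φ_v(x_i) · (n_v^(−i) + β),

with φ as defined in the README. Assumptions worth stating:

- **Sources are fixed.** Sink reads never flow back into known source
  profiles, so estimates for different sinks are independent and source
  depth does not grow with sink size.
- **Taxa are exchangeable.** No phylogenetic relatedness: a read either
  matches a source's taxon counts or it does not.
- **Relative abundances only.** The model says nothing about bacterial
  load; all outputs are proportions of reads.

### Sampler schedule and defaults

| parameter | default | meaning |
|---|---|---|
| α₁ | 0.001 | known-source taxon pseudocount (weak smoothing of observed profiles) |
| α₂ | 0.1 | unknown-source taxon pseudocount (stronger, since the urn starts empty) |
| β | 10 | source-membership pseudocount |
| restarts | 10 | independent chains from random initialisation |
| burnin | 100 | sweeps discarded per chain |
| draws_per_restart | 1 | recorded draws after burn-in |
| delay | 1 | sweeps between recorded draws |
| sink depth | 1000 | rarefaction depth of each sink before fitting |

These are the conventional defaults of the tracking tools this design
follows. The SD of each proportion is taken across all recorded draws
pooled over restarts (10 draws by default) — this is the uncertainty the
noise *t* test consumes. Chains initialise uniformly at random over
sources + unknown; categorical sampling uses cumulative-sum inversion on
one uniform variate. Per-sink seeds are derived by CRC-32 hashing of the
sink ID mixed with the master seed, so results do not depend on palm
order and any subset of palms reproduces exactly. The inner loop is
compiled with numba; the enumeration oracle (`exact_posterior`) is
independent pure-Python/NumPy code that sums the collapsed joint (rising
factorials for membership and urn, fixed φ for known sources) over all
(V+1)^n label vectors, refused above 10 reads.

Sources are used at full depth by default (only sinks are rarefied);
`fit_all(rarefy_sources=True)` subsamples them too, for users who want
symmetric depths.

### A degenerate regime worth knowing about

When a sink contains very few *distinct* taxa, the unknown environment
competes with even a perfectly matching source: the urn pays its
"first-occurrence" cost only once per distinct taxon, and assignment
entropy then favours splitting reads between the matching source and the
unknown (a single-taxon sink splits roughly 3:1). This is a property of
the model, not a sampler failure — the enumeration posterior shows the
same split. With realistically rich sinks (hundreds of reads over tens of
taxa) the unknown is correctly suppressed and a matching source receives
>0.95. Tests of source separation therefore use multi-taxon sinks.

## Depth filter, rarefaction, age classes

Samples under 1,000 reads are dropped before any analysis. Rarefaction is
a seeded multivariate-hypergeometric subsample (without replacement) of
the read multiset. Age classes are infant (<2), child (2–<18), adult
(≥18); the published groupings leave ages exactly 2 and 18 uncovered by
their strict inequalities, and this implementation resolves both upward.

## Spike-in validation

To spike a palm of S reads so the planted reads form a fraction r of the
final sample, R = round(S/(1−r) − S) reads are drawn without replacement
from the owner's stool (or tongue) sample, added to the palm, and the
combined sample is rarefied to 1,000 reads before fitting. Rounding is
half-to-even; the achieved ratio is within one read of r. Recovery is
reported as the attributed proportion divided by r: `recovery_any` sums
over all sources of the spiked site, `recovery_specific` takes the spiked
sample alone. Normalising by r is a design choice — the palms are chosen
to have minimal pre-existing fecal/oral signal (smallest stool+tongue
attribution in a baseline fit), so no background subtraction is applied;
values can slightly exceed 1 when background exists.

High spike levels need source libraries much deeper than the starting
palm (r = 0.9 requires 9S source reads). Cohorts whose samples share one
depth therefore thin the palm first (`run_spike_grid(palm_depth=...)`);
the validation runs use a 150-read starting palm against 1,500-read
sources, leaving the post-spike sample at full rarefaction depth.

## Cohort statistics

**Noise test.** A site-summed attribution is "above noise" if a one-sided
one-sample *t* test of mean/(SD/√n_draws) against zero is significant at
α = 0.05. Site-level SDs are computed from draw-level site sums (kept on
each estimate), preserving covariance between same-site sources; when
estimates are re-loaded from TSV the SDs fall back to a
sum-of-variances approximation. A zero SD with positive mean counts as
signal; zero mean never does.

**Permutation null.** Each palm's attributed (non-unknown) read count —
reconstructed as mean proportions × rarefaction depth, since per-read
labels are not persisted — is reassigned uniformly over all source
*samples* (not read-mass-weighted; "equal chance to be assigned to any
sample" is taken literally), 25 permutations by default, with the SE
taken across permutations.

**Enrichment test.** One 2×3 table per palm (stratum): observed
self/family/unrelated counts over the rounded permutation-mean null
counts. The summed score statistic (O − E)ᵀV⁻¹(O − E) uses the
multinomial covariance normalisation (n³ denominator) rather than the
multiple-hypergeometric n²(n−1); the two differ by a factor (n−1)/n that
is negligible at read-count scale, and the multinomial form makes the
single-stratum case reduce *exactly* to the Pearson 2×3 chi-square,
which is the closed form the tests verify against. Unknown mass is
excluded from relation grouping; both raw and renormalised relation
shares are available per palm. All p-values are reported raw, in one
table, so any multiple-testing correction can be applied afterwards.

**Group comparisons.** Two-sided Mann-Whitney U (exact for small tie-free
samples, normal approximation with tie correction otherwise), applied
pairwise to every grouping level for every site and relation column.
"Individuals with signal" counts a person once if any of their palms is
above noise.

## Synthetic cohorts

The generator emulates the features the analysis relies on, with a
Dirichlet-multinomial hierarchy: three site base profiles over partially
overlapping taxon pools (`site_pool_overlap`, default 0.2); per family
and site a family profile drawn around the base; per member a profile
drawn around the `family_coefficient`-blend (default 0.3) of family and
base, with Dirichlet concentration `interpersonal_concentration`
(default 50; 5 in the "high distinctness" preset used for spike-in
validation). Each member emits one stool, tongue and forehead sample
(multinomial, depth 1500) and two palms drawn from a role-dependent truth
mixture — infants tongue-self-heavy, adults forehead-self-heavy with
small own/family stool components — plus an environmental profile over
taxa disjoint from every source pool (`unknown_profile_weight`, default
0.2). The default cohort is 8 families × 3 members (adult couple plus a
child), 300 taxa. Truth presets: `role_default` (above), `self_heavy`
(power checks of the enrichment test), `population` (each site's mass
spread evenly over *all* samples of that site, so self/family mass sits
exactly at chance — the calibration condition for the null), and
`clean_palm_hosts` marks hosts whose palms are pure forehead +
environment, giving the spike-in experiment its clean palms.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: within-person variability over time and within
a body site (real sample-specific recovery will be lower, making
synthetic spike-ins an upper bound, as for the real ones); uneven
sequencing depths and library-size artefacts; taxonomic structure and
cross-site generalists beyond the shared pool; contamination and OTU
inflation. Real-cohort numbers also depend on the exact tracker defaults
of the original runs, which is why only property-level behaviour (site
recovery, specificity degrading with interpersonal similarity,
calibration of the null) is asserted, not published percentages.

## Problem sizes and tolerances in the shipped checks

Oracle agreement uses 20 random instances of ≤3 sources, ≤4 taxa, ≤6
reads at 50 restarts × 200 draws (total-variation bound 0.05). Truth
recovery runs the default 8×3 cohort (48 palms, 72 sources) with the
default sampler; site-grouped MAE bound 0.10 and unknown within ±0.10.
Spike-in validation uses 5 clean palms × levels {0.3, 0.6, 0.9} × 2
replicates of own-stool spikes. Null/CMH checks run 3-family cohorts at
500-read sinks with a reduced schedule (3 restarts, 50 burn-in), 20
generator seeds for calibration. These sizes keep the full suite and the
acceptance script each under a minute of compute while leaving every
threshold comfortably non-trivial.

## Known limitations

- Attribution among highly similar individuals is intrinsically
  ambiguous; only site-level sums are reliable then (this is the point of
  the spike-in conservation check).
- The permutation null is uniform over samples; cohorts with very uneven
  samples-per-person would motivate a person-weighted variant.
- The unknown-vs-matching-source split in taxon-poor sinks (above).
- BIOM support covers the standard JSON and HDF5 count layouts (IDs +
  CSR matrix); exotic metadata embedded in BIOM files is ignored rather
  than parsed.
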