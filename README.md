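# handtracer

Bayesian source tracking of fecal, oral and skin bacteria on human palms in
family cohorts.

Hands pick up microbes from everything they touch — one's own mouth and
skin, family members, shared surfaces. Given 16S OTU count tables from a
family study (palm, forehead, stool and tongue samples per person),
`handtracer` estimates, for every palm, what fraction of its bacterial
community came from **each individual sample** in the cohort, plus an
"unknown" environment for reads no sampled source explains. Because each
source is one person's sample, attributions can be folded into body-site
sums (forehead / stool / tongue / unknown) and relation sums (self /
family / unrelated), which is the level at which questions like *"is the
fecal signal on this child's palm from her mother?"* are answered.

The package is aimed at microbiome researchers who want a tested,
reproducible implementation of this per-sample source-attribution design:
the attribution engine, a spike-in simulator to validate it, the
permutation-null / enrichment statistics, and a synthetic family-cohort
generator so the whole pipeline runs and is testable without any data
download.

## The model

Each sink (palm) read *i* with taxon *x<sub>i</sub>* carries a latent label
*z<sub>i</sub>* naming its source environment: one of the *V* known source
samples, or the unknown environment *U*. Collapsed Gibbs sampling updates
each label from

P(z_i = v | rest) ∝ φ_v(x_i) · (n_v^(−i) + β)

where *n<sub>v</sub>^(−i)* counts sink reads currently assigned to *v*
(excluding *i*), β is a symmetric membership pseudocount, and

- known source *v*: φ_v(t) = (m_tv + α₁) / (Σ_t m_tv + τα₁), with
  *m<sub>tv</sub>* the fixed taxon counts of source sample *v* and τ the
  number of taxa;
- unknown: φ_U(t) = (q_t^(−i) + α₂) / (Σ_t q_t^(−i) + τα₂), a Pólya urn
  over the sink reads currently assigned to *U*.

Independent restarts each contribute recorded draws; the mean and SD of
the assignment fractions over draws are the mixing proportions and their
uncertainty. An exact enumeration posterior (tiny instances only) serves
as an independent oracle in the tests.

Downstream statistics: a one-sample *t* test on mean/SD decides whether a
palm's fecal or oral signal exceeds sampler noise; a permutation null
reassigns each palm's reads uniformly over all source samples; a
Cochran-Mantel-Haenszel-style stratified test (one stratum per palm,
categories self/family/unrelated, observed vs null counts) tests
enrichment; Mann-Whitney U compares groups (age class, gender, parent
status, hand side, dog ownership).

## Worked example

```bash
python examples/02_track_sources.py
```

```
palm fam00.h0.palm.left: posterior over 36 sources + unknown
  fam00.h0.forehead             0.274
  Unknown                       0.256
  fam00.h2.stool                0.045
  ...
by body site:    {'forehead': 0.432, 'stool': 0.197, 'tongue': 0.116, 'unknown': 0.256}
by relation:     {'self': 0.347, 'family': 0.111, 'unrelated': 0.287}
true mixture:    {'fam00.h0.forehead': 0.48, 'fam00.h0.tongue': 0.12,
                  'fam00.h2.stool': 0.12, 'fam00.h0.stool': 0.08, 'unknown': 0.2}
```

The palm was simulated as 48% own forehead, 12% own tongue, 12% a family
member's stool, 8% own stool and 20% environment. The fitted site sums
(43% forehead, 20% stool, 12% tongue, 26% unknown) recover that mixture;
attribution that lands on the right site but the wrong (similar)
individual shows up as "unrelated" relation mass, exactly the behaviour
the spike-in analysis quantifies:

```bash
python examples/03_spike_in_validation.py
```

```
   r  recovery_any  recovery_specific
 0.3         0.960              0.545
 0.6         0.960              0.757
 0.9         0.991              0.913
```

At spike level r, `recovery_any` is the fraction of the planted stool
signal tracked to *any* stool sample and `recovery_specific` the fraction
tracked to the owner's *own* stool sample (both normalised by r).

The other examples cover cohort simulation (`01`) and the cohort-level
statistics — permutation null, CMH enrichment, age/gender/parent
contrasts (`04`).

## Command line

The same stages are exposed as a thin CLI:

```bash
handtracer simulate --out cohort/ --seed 1
handtracer validate-inputs --table cohort/table.tsv --metadata cohort/mapping.tsv
handtracer track    --table cohort/table.tsv --metadata cohort/mapping.tsv --out run/ --seed 42
handtracer spike    --table cohort/table.tsv --metadata cohort/mapping.tsv --site stool --out run/ --seed 42
handtracer summarize --proportions run/ --metadata cohort/mapping.tsv --out run/ --seed 42
```

OTU tables are read as classic TSV or BIOM (JSON / HDF5); metadata as a
QIIME-style mapping file with a configurable column-name dictionary.

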