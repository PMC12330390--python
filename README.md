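# sodalake

Biogeography of soda-lake microbial communities, as a tested, reusable
pipeline. Soda lakes are hypersaline, high-pH (9–12) carbonate lakes
scattered across Africa, Asia and North America in isolated inland
basins, which makes them a natural laboratory for asking how dispersal
limitation structures microbial communities at the global scale. The
package implements the full analysis stack for that question:

* **Community profiling** — species abundances from metagenomic
  read-recruitment summaries, normalized as TPM (per species *i* in a
  sample, rate\_i = mapped bases / reference length, TPM\_i = rate\_i / Σ
  rate × 10⁶); classification of species into **core** (detected in every
  region), **endemic** (exactly one region) and **intermediate**
  occupancy classes, with a gene-family (KO) analogue after discarding
  singleton KOs; and the **range-size index** `1 − sd(f₁ … f_K)`, where
  *f* are a species' abundance fractions across K regions (for K = 4 it
  runs from 0.5, fully restricted, to 1.0, evenly spread).
* **Biogeography statistics** — Bray-Curtis / Euclidean dissimilarity
  matrices, the distance-decay relationship (OLS of log₁₀ similarity on
  log₁₀ great-circle distance), one-way PERMANOVA with the standard
  pseudo-F permutation scheme, Mann-Whitney group contrasts with
  Benjamini-Hochberg adjustment, and the range-size-vs-genome-size
  regression.
* **Genome divergence** — within- versus between-region contrasts of
  pairwise average nucleotide identity (ANI) at the species tier (all
  genome pairs) and the strain tier (ANI ≥ 95 %), and region-pair
  summaries ordered by centroid distance.
* **Cross-continent transition rates** — a from-scratch Bayesian
  MultiState (Mk) engine on a rooted species phylogeny: a K-state
  continuous-time Markov chain with rate matrix Q (optionally with rates
  tied q_ij = q_ji, or fixed to zero), Felsenstein pruning for
  ambiguity-coded tips, Metropolis-Hastings MCMC under uniform /
  exponential / gamma priors and their hyper-prior versions,
  stepping-stone estimation of the log marginal likelihood for
  log-Bayes-factor model comparison (|log BF| ≥ 10 read as very strong
  evidence), and Gelman-Rubin congruence checks across repeated runs.
* **Synthetic data** — generators for every input above with known
  ground truth (occupancy classes, decay scales, ANI region effects,
  Mk-evolved tip states under a known rate matrix), so the whole stack
  is testable without any sequence data.

See `docs/methods.md` for the models, parameter conventions and
numerical choices.

## Worked example

```python
import numpy as np
from sodalake import synthetic_data as sd, mk_transition as mk
from sodalake.community_profiling import (abundance_table, classify_occupancy,
                                          occupancy_summary)
from sodalake.biogeography_stats import ddr_fit, distance_pairs

# a 4-region, 51-sample survey with 400 species and known occupancy design
out = sd.generate_abundance_inputs(sd.SimConfig(n_species=400, seed=1))
table = abundance_table(out.mapping_summaries, out.sample_metadata)
print(occupancy_summary(classify_occupancy(table)).head(3).to_string(index=False))
fit = ddr_fit(distance_pairs(table))
print(f"DDR slope={fit.slope:.3f} adjR2={fit.r2_adjusted:.3f} n={fit.n_pairs}")
```

```
             group  count  fraction
class:intermediate    197  0.492500
     class:endemic    138  0.345000
        class:core     65  0.162500
DDR slope=-0.665 adjR2=0.570 n=1272
```

The class fractions recover the generator's design (34.5 % endemic,
16.3 % core), and community similarity decays with distance (negative
log-log slope) because the generator places species' occurrences around
home-region centroids with an exponential distance decay.

Transition-rate recovery on a simulated 300-tip phylogeny, where the
true Asia↔North-America rate (0.5) is ten-fold higher than any rate
involving Africa (0.05):

```python
names = ("Africa", "Asia", "NorthAmerica")
true = {(1, 2): .5, (2, 1): .5, (0, 1): .05, (1, 0): .05, (0, 2): .05, (2, 0): .05}
tree = mk.scale_tree(sd.generate_tree(300, seed=1), 0.1)   # mean branch 0.1
tips = sd.simulate_tip_states(tree, sd.MkSimConfig(n_tips=300, true_rates=true,
                                                   state_names=names, seed=2))
model = mk.RateModel(n_states=3, state_names=names).tie_symmetric()
trace = mk.mcmc_sample(tree, tips, model, mk.PriorSpec("exponential"),
                       mk.McmcConfig(iterations=6000, burn_in=1000, thinning=5, seed=1))
print(trace.summary(model).to_string(index=False))
```

```
              parameter   median  ci_2.5%  ci_97.5%
        q(Africa->Asia) 0.059682 0.020780  0.143951
q(Africa->NorthAmerica) 0.030054 0.002465  0.096189
  q(Asia->NorthAmerica) 0.598823 0.036591  3.545123
```

The posterior medians recover the order-of-magnitude gap between the
Asia–North-America rate and the Africa rates, and every 95 % credible
interval covers its true value.

## Command line

```bash
sodalake run --config config.yaml --seed 1 --outdir results/
```

Subcommands `generate`, `profile`, `biogeo`, `ani`, `transition` run one
stage each; `run` executes every enabled stage in dependency order and
writes a `run_manifest.json` listing each output file with the stage,
parameters and seed that produced it. All tables are TSV with
`#`-prefixed metadata headers; trees are newick with branch lengths.
Reruns with the same config and seed are byte-identical.

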