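# Methods

This note documents the models and procedures implemented in `crisprcost`,
the defaults they ship with, and what the synthetic-data generators do and do
not emulate.

## The eco-evolutionary serial-transfer model

### Core model

Three bacterial genotypes and lytic phage share a well-mixed batch culture:
sensitive cells `S`, CRISPR-immune cells `C`, and surface (receptor-loss)
mutants `M`, with free phage `V` (all per mL). Within a day:

```
dS/dt = r S (1 - N/K) - a S V
dC/dt = r C (1 - N/K) - a C V (tau_tox + p q_self)
dM/dt = r (1 - c_sm) M (1 - N/K)
dV/dt = b a S V - a (S + C) V - d V,          N = S + C + M
```

Assumptions: logistic growth with a shared carrying capacity; mass-action
adsorption; infections of `S` always lyse (burst `b`); infections of `C` are
cleared, but with probability `tau_tox + p*q_self` the cell dies anyway —
`tau_tox` is the induced cost of phage gene expression before clearance, and
`p*q_self` the probability of acquiring a lethal self-targeting spacer;
surface mutants are never adsorbed and instead pay the constitutive cost
`c_sm`; every adsorption (by `S` or `C`) removes a phage particle. Optional
mutational influx terms (`mu_sm`: S→M per division; `mu_bim`: S→C per
infection) default to 0 — the competition scenarios start from standing
variation at frequencies 0.45/0.45/0.10 (S/C/M).

Each transfer multiplies all densities by the dilution factor (1:100) and
adds 10^7 PFU of ancestral phage to the 6 mL culture; 30 daily transfers of
24 h, inoculated with 10^6 cells and 10^7 PFU. Integration uses LSODA with
`rtol=1e-8`, `atol=1e-10` (the system is stiff during phage blooms);
densities are clipped at zero between days. The integrator reproduces the
closed-form logistic solution in the phage-free limit to < 1e-6 relative
error (tested).

### Baseline parameters

| parameter | value | meaning |
|---|---|---|
| `r` | 1.0 /h | maximal growth rate |
| `K` | 1e9 CFU/mL | carrying capacity |
| `a` | 1e-9 mL/h | adsorption rate |
| `b` | 50 | burst size |
| `d` | 0.1 /h | free-phage decay |
| `c_sm` | 0.001 | constitutive cost of receptor loss |
| `tau_tox` | 0.05 | induced toxicity per infection of `C` |
| `p` | 0.01 | acquisition probability per surviving infection |
| `q_self` | 0.0 | self-targeting fraction of acquisitions |

These are order-of-magnitude values for a *Pseudomonas*–phage batch system,
calibrated so that the model's qualitative contrasts (below) hold
simultaneously. Two choices deserve comment. `c_sm` is nearly zero because
the experiments take place in shaken liquid, where losing the pilus carries
almost no growth penalty; with a large `c_sm` the surface mutant can never
retain an advantage once phage pressure subsides, contradicting the observed
end state. `tau_tox` is small per-infection because the day-1 phage bloom
exposes every cell to many adsorptions; larger values annihilate the immune
class within one transfer instead of eroding it over weeks.

### Scenario contrasts

`run_scenarios` runs the escape-free core model from standing variation and
classifies the fate of `C` relative to `M` by comparing the final to the
initial C:M frequency ratio (relative tolerance 1e-3; `C` below one cell per
culture is "extinct"):

* induced cost present (`tau_tox > 0`, `q_self = 0`) → **decline**;
* no induced cost, acquisition-deficient (`tau_tox = 0`, `p = 0`) →
  **no_decline**;
* no induced cost, frequent lethal self-targeting (`tau_tox = 0`,
  `p = 0.25`, `q_self = 0.8`) → **decline**.

The self-targeting scenario's event probability (0.2 per infection) was set
so the decline is clear while `C` remains extant; the induced-cost contrast
shows that toxicity alone suffices to recreate the decline even without any
self-targeting.

### Escape-phage extension

A fifth compartment `W` (escape phage) can be enabled
(`escape_mu > 0`): escape mutants arise at rate `escape_mu` per burst
particle during replication on `S`, replicate on `S` at full efficiency, and
infect `C` lytically with reduced efficiency `escape_infectivity`
(residual targeting by the host's remaining spacers). Defaults when enabled:
`escape_mu = 1e-5`, `escape_infectivity = 0.015`.

The extension exists because the 30-day trajectory — immunity sweeping
early, surface mutants overtaking late — is unattainable in the core model:
the 1:100 dilution quenches any phage bloom, so virtually all phage exposure
falls on day 1, and one can show that in any persistent phage–host balance
the immune class necessarily gains on the surface mutant (its per-infection
cost is a fraction `tau_tox` of what sensitive cells pay, while the mutant's
cost is constitutive). Escape phage decouple the two phases: the ancestral
bloom removes sensitives on day 1 while immunity peaks, then the delayed
escape bloom (its delay set by `escape_infectivity`, which must clear the
daily dilution yet stay slow enough to mature after the peak) erodes the
immune class days 2–6, after which phage collapse and ranks freeze.
`evolution_experiment_params()` returns this parameterisation; the scenario
contrasts always run escape-free.

With it, the baseline trajectory shows: CRISPR frequency peaking at 0.64 on
day 1–2, surface mutants overtaking by day 4 and finishing at 0.63 vs 0.37,
phage titres high for the first week and collapsing afterwards — the shape
the package's acceptance tests assert.

## Spacer amplicon pipeline

* **Size selection**: merged reads kept at 30–140 bp (CRISPR1) or 70–500 bp
  (CRISPR2), inclusive.
* **Extraction**: repeat occurrences located by Hamming scan (≤ 2
  substitutions by default, non-overlapping, left to right); inter-repeat
  segments are spacers; segments flanked by a single repeat are flagged
  partial and excluded from clustering.
* **Clustering**: dereplicated variants are agglomerated single-linkage at
  edit distance `d = 1` (substitutions + indels, computed with edlib); the
  result equals the connected components of the ≤d-edit graph, which a
  brute-force DP oracle verifies in the tests. Centroid = most abundant
  member (ties: lexicographically smallest); clusters below 2 total reads
  are discarded.
* **Abundance**: every sequence is assigned to the best centroid at ≥ 99%
  identity over the full global alignment (ties to the more abundant
  centroid); the remainder is tallied as unassigned.
* **Classification**: exact match of the spacer and its reverse complement,
  phage genome first, then host. The PAM is read adjacent to the protospacer
  on the protospacer strand — side (3' default) and motif (GG default, the
  type I-F consensus) are configuration, since conventions vary. Multiple
  hits resolve to the one nearest the priming site (position 27847).
  Coordinates are 0-based, forward strand, with strand recorded separately.

## Estimators

* **Diversity**: observed variants, bias-corrected Chao1
  (`S_obs + F1(F1-1)/(2(F2+1))`), Shannon (base e by default), Simpson
  (`1 - sum p^2`) and Simpson evenness (`(1/sum p^2)/S_obs`).
* **Rarefaction**: subsampling without replacement (multivariate
  hypergeometric), 33 repetitions by default, averaged per sample and depth;
  depths beyond the sample total return the plug-in value flagged
  `saturated`. At full depth the mean equals the plug-in metric exactly.
* **Self-targeting**: canonical-PAM self-targeters are lethal and thus
  unobservable; the estimator multiplies the observable non-canonical
  self-targeting read fraction by the canonical:non-canonical ratio `rho`
  estimated from phage-targeting spacers. `rho` uses distinct spacer types
  by default (read counts are distorted by post-acquisition selection; a
  `rho_from="reads"` switch exists). Whether the denominator should be all
  cells or infected cells is unknowable from frequency data alone; the
  estimator reports a fraction of sequenced arrays, i.e. of cells.
* **Selection coefficient**: `s = [logit(x_end) - logit(x_0)] / days` from
  colony counts; zero counts raise unless an explicit +0.5 pseudocount is
  requested (logged in the API by being explicit). Relative fitness is
  reported as `1 + s` because colony fractions carry no absolute growth
  information.
* Uncertainty is reported via seeded percentile bootstrap (1000 resamples);
  no p-values.

## Expression module

Phage gene time-courses are min-max normalised per gene
(`(v - min)/(max - min)`; constant genes map to zero and are flagged), then
averaged across the five infected wild-type replicates — normalise-then-
average, in that order; the reverse order is available and differs whenever
replicates disagree on scale (asserted on a counterexample in the tests).
Profiles are clustered by complete-linkage agglomeration on Euclidean
distance (single/average available); genes are sorted by id first, making
the result input-order invariant; the merge tree is exported as Newick.
Counts enter profiles raw: min-max rescaling within each gene absorbs
library size. Per-sample phage read fractions are phage counts over total
counts, and group contrasts are ratios of group means with bootstrap CIs.
Differential-expression testing is deliberately absent.

## Synthetic-data generators

* **Spacer datasets**: each acquisition event targets the host with
  probability `frac_self` (default 1.02e-4) else the phage; PAM is canonical
  with probability `rho/(1+rho)` (`rho = 2` by default — the true
  acquisition ratio is not published, so it is a free parameter);
  phage protospacer positions follow a discretised Laplace kernel centred on
  the priming site (spread 2 kb, truncated to the 36.4 kb genome) — a peaked
  symmetric kernel being the minimal model of primed acquisition; canonical
  self-targeters' expected abundances are multiplied by a survival factor
  (default 0.05) before multinomial read sampling at fixed depth. The
  defaults make the canonical-PAM self-targeting cell fraction
  `frac_self * rho/(1+rho) = 6.8e-5`, i.e. 0.0068% of cells, matching the
  condition the estimator is meant to recover.
* **Competition counts**: binomial colony draws around a logit-linear
  frequency trajectory — exactly the model the selection-coefficient
  estimator inverts.
* **Expression counts**: negative binomial with shared dispersion (0.05), a
  standard RNA-seq count model; host genes constant across groups, phage
  genes follow early/middle/late shapes peaking at 35/60/120 min, phage
  means divided by 5 in infected immune hosts and zero in uninfected
  controls; phage reads are ~5% of the infected wild-type library at peak.
  Note the group contrast of phage *fractions* recovers slightly less than
  the attenuation factor (4.86 vs 5 at the defaults) because attenuating
  phage counts inflates the host share of a fixed library — a composition
  effect intrinsic to fraction-based measures, kept within the 10% recovery
  tolerance by the ~5% phage share.
* **Clone phenotypes**: multinomial draws of 24 clones per sample from
  genotype frequencies.

What the generators do **not** emulate: raw reads, quality scores, chimeras,
PCR artefacts, sequencing error in spacers (spacer sequences are distinct
random 32-mers, so clustering on synthetic data exercises the machinery but
not near-duplicate resolution), overdispersion structure across genes, or
correlations between replicates. Passing tests therefore demonstrate the
correctness of the algorithms under their stated models, not robustness to
every artefact of real libraries.

## Problem sizes

The shipped demo and tests use deliberately modest sizes chosen to keep the
full synthetic study reproducible on a laptop: ~2 500 acquisition events
across five sampled days for the clustering stage, 10^4 events × 10^6 reads
per dataset (50–100 seeds) for estimator recovery, 10^5 colonies for
competition recovery, 30 phage genes × 50 noise seeds for programme
recovery, and 30-day trajectories for all dynamics runs.

## Known limitations

* The within-day model compresses infection kinetics (no latent period), so
  phage blooms complete faster than in reality; multi-day successions are
  carried by the escape extension rather than by intra-day realism.
* One escape class with fixed infectivity stands in for the full
  arms-race of escape mutations against multi-spacer hosts.
* The PAM side/motif conventions of the classification are assumptions
  exposed as configuration, not inferences.
* The cluster-size filter counts total reads, not unique sequences; the
  alternative reading is a one-line change via `min_size`.
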