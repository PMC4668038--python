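# Methods

## Model

Each species *i* is assigned a probability `p_i` of going extinct over a
~100-year horizon, determined solely by its IUCN Red List category:

| category | LC | NT | VU | EN | CR |
|----------|------|------|-----|-------|-------|
| `p_ext`  | 0.001| 0.01 | 0.1 | 0.786 | 0.999 |

Tip fates are treated as independent.  A branch *b* of a tree survives iff
at least one tip descending from it survives, so its persistence
probability is `1 − Π_{i ∈ tips(b)} p_i`; for a branch whose two descendant
tips are CR and EN this is `1 − 0.786 × 0.999 = 0.215`.  Expected (future)
diversity is the persistence-weighted branch-length sum
`E[D] = Σ_b l_b (1 − Π p_i)`.  The same statistic serves phylogenetic
diversity (on a dated phylogeny) and trait diversity (on a neighbour-joining
dendrogram of Gower trait distances); the code path is shared and the trait
tree's storage anchor is immaterial because only edges are summed.  Any
root edge is excluded from all sums.

The independence assumption is the model's main simplification: correlated
extinctions (shared drivers within clades or regions) would lower interior-
branch persistence below the product form used here.

Per-species scores follow the EDGE framework: fair-proportion evolutionary
distinctiveness `ED(s) = Σ_{b ∈ path(s)} l_b / n_tips(b)` (which conserves
total branch length when summed over species), the global-endangerment
ordinal GE (LC=0 … CR=4), and `EDGE = ln(1+ED) + GE·w` with `w = ln 2` by
default and configurable for weight sweeps (0.05–2).  ThreatED is ED
computed on the persistence-weighted tree.

## Data Deficient species

DD species have no ordinal position.  They stay in the tree for ED
computation (pruning them would change other species' scores) but are
excluded from every candidate pool and from the shift pool.  Where a
`p_ext` is unavoidable (expected diversity of a tree containing DD tips)
they default to LC's 0.001, configurable via `dd_pext` — the choice matters
little because DD tips are rare in the synthetic defaults (0 by default)
and never selected or shifted.

## Trait distances

Gower dissimilarity with pairwise deletion: a pair's distance is the mean,
over traits observed in *both* species, of `|x_i − x_j| / range` for
continuous traits (range taken over all observed values of that trait) and
a 0/1 mismatch for categorical traits.  Pairs sharing no observed trait
receive the mean distance over all computable pairs (policy configurable to
an error).  A continuous trait with zero observed range contributes 0 with
a warning.  Distances therefore lie in [0, 1], symmetric, zero diagonal.

Trait selection (`select_orthogonal_traits`) uses backward greedy
elimination on an association matrix: |Pearson r| for continuous pairs on
pairwise-complete cases, Cramér's V when a categorical trait is involved
(continuous partners quartile-binned).  Greedy elimination is a heuristic;
on the small randomly structured instances in the test suite it coincides
with the exhaustive optimum.

Neighbour joining is classical Saitou–Nei (via scikit-bio), with negative
estimated branch lengths clamped to zero on import — standard NJ practice
that keeps all diversity sums non-negative.  On an additive matrix the
generating tree is recovered exactly (path-length matrix to 1e-9).

## Protection schemes

`RANDOM` uniform over threatened species (NT/VU/EN/CR — the conservative
null); `THREAT` fills from CR downwards with uniform random resolution of
the boundary category; `ED`, `EDGE`, `THREAT_ED` take the top *n* by score
with exact ties resolved uniformly at random; `MAX` greedily adds the
threatened species whose protection most increases expected diversity,
recomputing marginal gains each step (deterministic first-id tie-break).
Expected diversity is submodular in the protected set, so greedy achieves
at least `1 − 1/e` of the optimum; on the test fixtures it is at or near
the exact optimum.  "Protection" resets a species' category to LC
(`p_ext = 0.001`); a strict `protect_pext = 0` switch exists.  ED and EDGE
rank over all scored species by default (as published EDGE lists do), with
a `threatened`-only restriction available.

The cost index counts, per protected species, the categories it must
traverse to reach LC (CR=4 … LC=0, configurable ladder).

## Future simulation

`ShiftModel(n_shifted=1500, delta_mean=−1, delta_sd=1)`: per replicate,
`n_shifted` species are sampled uniformly without replacement from the
non-DD, non-protected pool; each moves `round(N(−1,1))` categories
(half-away-from-zero rounding; negative = toward CR; clamped at LC/CR).
Under these defaults the fraction of sampled species that worsen is
`Φ(0.5) ≈ 0.6915`.  Protected species are excluded from the shift pool —
protection is taken as durable over the horizon.

Replicates use common random numbers: one species permutation and one delta
stream per replicate, shared across schemes (each scheme skips its own
protected species), which sharply reduces the variance of between-scheme
gain differences.  Gains are measured against the NONE scenario of the same
replicate.  Replicate seeds are `base_seed + index`, so the whole
experiment is byte-identical given (config, seed).  Scheme means are
compared with a one-way ANOVA plus paired one-sided t-tests for ordering
claims, and each scheme's mean gain is reported as a fraction of MAX's.

When the trait tree is the evaluation substrate, prioritization ranks still
come from the phylogeny (`run_experiment(scores=...)`) — only the
re-weighted tree changes — while MAX-TD runs greedy on the trait tree
itself.

## Synthetic data

The generator emulates a mammal-like study system: a pure-birth (Yule)
ultrametric tree rescaled to a crown age of 170 (the "million years" scale
of a mammal phylogeny); iid category assignment with frequencies LC .7256,
NT .08, VU .09, EN .065, CR .0394, calibrated so the threatened fraction is
0.2744 ≈ 1350/4920 (the within-threatened split is a free parameter chosen
to taper like a Red List: LC ≫ NT ≈ VU > EN > CR); 7 continuous traits
evolving by Brownian motion along the tree and 3 categorical traits by a
Markov switch (rate 0.01 per unit time, ≈1.7 expected switches per
root-to-tip path), so trait distance correlates with phylogenetic distance
— the regime in which high-ED species tend to be trait-distinct; and 25%
missing cells, MCAR.  An iid-trait mode (`phylo_traits=False`) and a
phylogenetically clumped threat mode (threat concentrated in random clades
at the same margins) exist to probe those structural assumptions.

What the generator does *not* emulate: non-random (phylogenetically or
environmentally biased) missingness, correlated trait blocks beyond shared
phylogeny, category-dependent extinction correlations, taxonomy mismatch
between data sources, or the particular imbalanced shape of a real
supertree.  Passing tests on synthetic data therefore demonstrate the
machinery and the qualitative scheme ordering under the stated generative
assumptions, not quantitative predictions for any real clade.

## Problem sizes and numerics

The replicated comparison in the test suite runs at the full community size
(4920 species, 100 protected, 1500 shifted, 200 replicates); the trait
arm builds its dendrogram on a seeded 1000-species subsample with the shift
count scaled proportionally (305), keeping NJ and Gower costs modest while
preserving per-species shift pressure.  Smaller sizes (150–300 species)
back the unit tests.

Persistence products are evaluated in log space through a sparse
edge-by-tip incidence matrix (`PersistenceEngine`), so a whole-tree
evaluation is one sparse mat-vec; `p = 0` maps to `−inf` and back to a
persistence of exactly 1.  Greedy MAX maintains per-edge log-sums plus
zero-counts so a marginal gain costs O(path length).  Expected-diversity
values agree with naive per-edge tip-set enumeration to 1e-12 relative.
Newick branch lengths are written to 10 significant digits; tree equality
is asserted at 1e-9 relative.  Ordering assertions across schemes are
statistical (paired t across replicates) because at small scale EDGE and
MAX means can overlap within replicate noise.

## Known limitations

- Greedy MAX optimises *static* expected diversity; under simulated shifts
  it is near- but not provably optimal per replicate.
- The no-shared-trait Gower fallback assigns a single global mean distance,
  which slightly shrinks the trait tree for very incomplete species.
- ANOVA is reported on possibly heteroscedastic gains; the paired tests,
  not the omnibus F, carry the ordering claims.
- `n_reps` defaults to 1000 in the CLI; the suite uses 200 for the
  full-scale comparison and 20–100 elsewhere.
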