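# edgegain

Expected phylogenetic and trait diversity under extinction risk, and the
conservation gain of EDGE-style prioritization schemes.

## The problem

Conservation budgets cannot cover every threatened species, so which ones
should be protected first if the goal is to preserve as much of the tree of
life — and of trait diversity — as possible?  `edgegain` implements the
expected-diversity framework for answering that question on a clade like the
mammals: a dated phylogeny, an IUCN Red List threat table, and a
mixed-type trait matrix go in; replicated comparisons of prioritization
schemes under simulated future threat change come out.

The core quantities, in standard notation:

- **Phylogenetic diversity** `PD = Σ_b l_b`, the sum of branch lengths.
- **Expected (future) PD**: each species *i* carries a 100-year extinction
  probability `p_i` from its IUCN category (LC 0.001, NT 0.01, VU 0.1,
  EN 0.786, CR 0.999).  A branch persists iff any descendant tip survives,
  so `E[PD] = Σ_b l_b (1 − Π_{i∈tips(b)} p_i)`.  For example, an interior
  branch above a Critically Endangered and an Endangered tip persists with
  probability `1 − 0.786 × 0.999 = 0.215`.
- **Trait diversity (TD)**: the same statistic on a dendrogram built from
  traits — Gower distances (pairwise deletion of missing values) fed to
  neighbour joining.
- **ED** (evolutionary distinctiveness): fair-proportion apportionment,
  `ED(s) = Σ_{b∈path(s)} l_b / n_tips(b)`; ED sums over species to total PD.
- **EDGE score**: `ln(1 + ED) + GE·ln 2` with GE the ordinal category
  (LC=0 … CR=4).

Protection schemes compared: `RANDOM` (random threatened species, the null),
`THREAT` (most threatened first), `ED`, `EDGE`, `THREAT_ED` (ED on the
persistence-weighted tree), and `MAX` (greedy set maximising expected
diversity).  Protected species are treated as secured (category reset to
LC); a further 1500 species then shift categories by `round(N(−1, 1))`
steps (negative = worsening), and the conservation gain of a scheme is its
expected diversity minus the no-protection scenario under the same
simulated future.

Because the original mammal supertree, Red List snapshot and trait
compilation are not redistributable, the package includes a first-class
synthetic-data generator that emulates their statistical shape (4920
species, ~1350 threatened, 10 traits ~75% complete).

## Worked example

```sh
edgegain synth --n 300 --seed 1 --out fixtures/
edgegain experiment --tree fixtures/tree.nwk --threat fixtures/threat.tsv \
    --n 25 --n-shifted 90 --n-reps 200 --seed 1 \
    --out-gains gains.tsv --out-summary summary.json
```

prints

```
ANOVA F=1085.51 p=0
  MAX        mean gain 909.013
  EDGE       mean gain 869.714
  THREAT     mean gain 736.118
  RANDOM     mean gain 394.584
  ED         mean gain 391.333
```

Reading this: protecting 25 of the ~78 threatened species in a 300-species
community and simulating 90 category shifts per future, the greedy
expected-diversity set (`MAX`) saves the most future diversity (909 units of
branch length over doing nothing), EDGE ranking comes close (96% of MAX),
threat-only ranking captures 81%, while random choice among threatened
species and pure ED ranking save well under half.  The ANOVA confirms the
scheme means differ far beyond replicate noise.  The same machinery applied
at full scale (4920 species, 100 protected, 1500 shifts) reproduces the
qualitative pattern MAX ≥ EDGE ≥ max(ED, THREAT) ≥ RANDOM > 0 for
phylogenetic diversity, and EDGE ≈ THREAT > RANDOM for trait diversity; see
`tests/test_acceptance.py`.

The library API mirrors the CLI:

```python
import edgegain as eg

bundle = eg.generate(eg.SyntheticConfig(n_species=300, seed=1))
eg.expected_diversity(bundle.tree, bundle.threat)   # baseline future PD
scores = eg.species_scores(bundle.tree, bundle.threat)  # ED/GE/EDGE/ThreatED
results = eg.run_experiment(bundle.tree, bundle.threat,
                            ["RANDOM", "EDGE", "MAX"], n_protected=25,
                            model=eg.ShiftModel(n_shifted=90),
                            n_reps=200, base_seed=1)
eg.compare_schemes(results)
```

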