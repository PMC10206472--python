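# eggshell-traits

Comparative analysis of eggshell surface properties — surface roughness
(S_a, nm), wettability (contact angle, degrees) and calcium carbonate
content (% of dry mass) — across avian brood parasites, their hosts and
non-parasitic relatives.

Obligate brood parasites lay their eggs in other species' nests, so
their eggshells face unusual selection pressures (microbial exposure,
rapid laying, host rejection). Two hypotheses compete: parasitic eggs
carry *specialized* surface structures, or they *match* their hosts'
eggs because both experience the same nest environment. Species are not
independent data points — close relatives have similar eggs — so both
questions need the phylogeny in the model. This package provides, for
researchers in avian ecology and phylogenetic comparative methods:

* trait derivation from raw measurements: S_a from profilometric height
  maps with second-order (quadratic) plane correction, settle-time
  contact angles with wettability classification, and CaCO₃ content
  from crucible ashing masses;
* a **phylogenetic mixed model** (PMM): for eggs grouped by species,
  `y = Xβ + Zu + ε` with `u ~ N(0, σ²_p A)` and `ε ~ N(0, σ²_e I)`,
  where `A` is the Brownian-motion covariance of the tree standardized
  to unit maximal diagonal. Fitted by deterministic profiled REML/ML.
  Phylogenetic heritability `H² = σ²_p/(σ²_p+σ²_e)` measures signal
  (0 = none, 1 = Brownian motion); predictors are tested by χ²
  likelihood-ratio tests of nested ML fits;
* a **host-match test**: per-egg |Δtrait| of parasite–host pairs vs
  parasite–random pairs (with the mean-of-hosts rule for generalist
  parasites whose eggs lack host records), compared by a two-sample t
  and a seeded label-shuffling permutation test;
* a **synthetic-data generator** (Yule trees, Brownian species effects
  at chosen H², parasitism shifts, tunable host convergence, synthetic
  height maps) so the whole pipeline is testable against known truth;
* a CLI orchestrating everything into JSON/markdown/CSV reports.

## Worked example

```python
import eggshell as es

# a synthetic study at the default scale: 45 species, 14 brood
# parasites, 2-10 eggs per species, strong phylogenetic signal
ds = es.simulate_dataset(es.SimulationConfig(rng_seed=1))
print(f"true H2 = {ds.truth['true_h2']:.3f}")

report = es.run_analysis(
    es.AnalysisConfig(traits=["Sa"], n_permutations=2000, rng_seed=1),
    tree=ds.tree, table=ds.table, hostmap=ds.hostmap,
)
pmm = report["pmm"]["Sa"]
hm = report["hostmatch"]["Sa"]
print(f"estimated H2 = {pmm['H2']:.3f}")
print(f"parasitic-status LRT: chi2 = {pmm['lrt']['chi2']:.3f}, "
      f"p = {pmm['lrt']['p_value']:.3f}")
print(f"host-match contrast = {hm['estimate']:.1f} nm, "
      f"permutation p = {hm['p_permutation']:.4f}")
```

prints

```
true H2 = 0.950
estimated H2 = 0.945
parasitic-status LRT: chi2 = 1.533, p = 0.216
host-match contrast = -44.0 nm, permutation p = 0.3958
```

The simulated trait had no parasitism effect and no host convergence,
and the analysis agrees: the phylogenetic signal is recovered (H² ≈
0.95), the status effect is non-significant, and parasite eggs are no
closer to their hosts' than chance expects. Rerunning with
`SimulationConfig(convergence_w=0.8, rng_seed=1)` drives the host-match
permutation p down (host pairs become systematically closer than random
pairs).

The same analysis runs from the shell:

```sh
eggshell simulate --seed 1 --out data/
eggshell analyze --tree data/tree.nwk --eggs data/eggs.csv \
    --hosts data/hosts.csv --trait Sa --seed 1 --out results/
eggshell report results/report.json
```

To analyze real data, supply a Newick tree, an egg-level CSV
(`egg_id,species,parasitic,host_species,sa_nm,ca_deg,caco3_pct,...`)
and a two-column parasite→host CSV in the same commands.

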