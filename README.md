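# mimodiv

Eco-evolutionary analysis of dry-season deciduousness in *Mimosa*
(Fabaceae) — and of binary drought-strategy traits on time-calibrated
phylogenies generally. Dropping all leaves in the dry season is a
drought-avoidance strategy; whether it shaped the radiation of a clade,
whether it changes how climatic niches evolve, and which environmental
axes predict it today are three different questions, and this package
implements the matching three analyses plus the data preparation and the
synthetic generators that make everything testable offline:

1. **Time-sliced state-dependent diversification** — likelihoods for
   speciation/extinction models in which rates may depend on leaf habit
   (deciduous vs evergreen) or on a hidden rate class, with an epoch
   switch at a chosen age (e.g. 7 or 15 Ma) and symmetric/asymmetric,
   constant/time-variable habit transitions; ML fitting with multi-start
   and AIC/Akaike-weight comparison across the 18-model family.
2. **Multi-regime niche evolution** — the nine-model BM/OU family (BM1,
   BMV, OU1, OUA, OUV, OUM, OUVA, OUMV, OUMVA) for a continuous
   environmental variable evolving under habit regimes painted by
   stochastic character mapping, ranked by AICc and Akaike weights.
3. **Bayesian phylogenetic multilevel model** — Bernoulli regression of
   habit on 2-SD-scaled environmental predictors with phylogenetic and
   iid species-level random intercepts, sampled by a Polya-Gamma Gibbs
   sampler, with marginal/conditional Bayesian R², posterior predictive
   checks and prior power-scaling sensitivity.

Supporting stages: occurrence cleaning (native-range filtering, convex
hulls, random points for species with <5 records, 1.5-km spatial
thinning), environmental extraction and VIF screening, and seeded
generators for every data type (trees from a composite-state Gillespie
birth-death process, OU traits on regime paintings, logistic habit data,
clustered occurrences on gradient layers).

## Worked example

```python
from mimodiv import sse
from mimodiv.simulate import SimConfig, simulate_sse_dataset

# a ~200-tip tree whose speciation is habit-independent before 7 Ma and
# habit-dependent after, with frequent early evergreen->deciduous switches
cfg = SimConfig(seed=14, n_tips=220)
tree, traits, truth = simulate_sse_dataset(cfg)   # 203 tips realized

specs = [
    sse.SSEModelSpec(7.0, em, lm, "asymmetric", "variable")
    for em in ("dependent", "independent")
    for lm in ("dependent", "independent")
] + [
    sse.SSEModelSpec(None, m, m, "asymmetric", "constant")
    for m in ("dependent", "independent")
]
fits = [sse.fit_sse(tree, traits, s, n_starts=2, seed=i) for i, s in enumerate(specs)]
print(sse.compare_sse_models(fits)[["model", "logL", "k", "AIC", "AICw"]])
```

```
                                    model        logL   k          AIC      AICw
0  indEarly_depLate_asymmetric_variable@7 -580.922260  12  1185.844520  0.903253
1  depEarly_depLate_asymmetric_variable@7 -583.562932  12  1191.125865  0.064414
2  indEarly_indLate_asymmetric_variable@7 -584.846158  12  1193.692315  0.017852
3         unsliced_independent_asymmetric -591.631217   6  1195.262434  0.008142
4           unsliced_dependent_asymmetric -592.231148   6  1196.462295  0.004469
5  depEarly_indLate_asymmetric_variable@7 -587.102401  12  1198.204802  0.001870
```

The epoch-sliced model with habit-independent early and habit-dependent
late speciation — the structure the data were generated under — takes 90%
of the Akaike weight. Its fitted rates recover the generating asymmetries:
evergreen-to-deciduous transitions high early and indistinguishable from
zero late (0.47 vs 0.00 per Myr against a roughly constant reverse rate),
and late speciation higher in evergreen than deciduous lineages (0.27 vs
0.13 per Myr). `sse.rate_summary(fits[0])` tabulates these per-epoch rates
directly.

The other stages follow the same pattern: `mimodiv.niche.fit_all_niche_models`
+ `compare_niche_models` for the nine-model table per environmental
variable, and `mimodiv.glmm.sample_posterior` + `bayes_r2` /
`posterior_predictive_check` / `power_scale_sensitivity` for the
multilevel model. A single `mimodiv` console command exposes the stages
(`simulate`, `env-prep`, `sse-fit`, `niche-fit`, `glmm-fit`) and `mimodiv
run` drives the whole pipeline from a YAML config, writing a manifest
with seeds and checksums for reproducibility.

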