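# phenobma

Bayesian model averaging for phenotype definition, with sib-pair linkage on
the averaged traits.

Genetic studies of complex disorders often lack a biomarker and must define
the phenotype from a symptom checklist. Different clustering models applied
to the same checklist produce different phenotypes, and that choice
propagates into every downstream genetic analysis. `phenobma` fits two
Bayesian clustering models to binary symptom data — latent class analysis
(LCA, one class per individual) and grade of membership (GoM, partial
memberships g_i on the simplex) — by Gibbs sampling, weights them by their
Laplace–Gibbs-approximated marginal likelihoods,

    w_s ∝ p(Y | M_s) p(M_s),      φ_i = Σ_s w_s φ_is ,

reconciles the clusters of the two models (merging near-identical
symptom-prevalence profiles, keeping unmatched clusters distinct, excluding
low-prevalence "unaffected" clusters), and uses the model-averaged
per-individual phenotype probabilities φ_i as quantitative traits in a
single-point Haseman–Elston genome scan (squared sib-pair trait differences
regressed on IBD sharing π̂; LOD = t²/(2 ln 10) for a negative slope).

It is aimed at statistical geneticists and psychiatric-genetics
methodologists who want phenotype calls that carry model uncertainty
instead of committing to a single clustering. Because the motivating
dataset (a simulated "Kofendred Personality Disorder" family study) is
restricted, the package ships a synthetic-data module that emulates its
structure: 12 symptoms with three overlapping affected sub-types plus an
unaffected class, nuclear families, fully informative microsatellites
7.5 cM apart, and a liability locus co-segregating with a chosen marker.

## Worked example

```bash
phenobma run-all --seed 1 --out-dir out --n-iter 1500 --burn-in 700
```

simulates 200 KPD-like families (800 offspring), fits LCA and GoM with
K = 3, averages them and scans every marker. The log ends with:

```
INFO phenobma: K1: max LOD 11.18 at M06 (causal M06)
INFO phenobma: K2: max LOD 1.23 at M06 (causal M06)
```

`K1` is the merged high-prevalence trait (the P3-like sub-type, averaged
across both models with the evidence weights found in `out/weights.json`);
its genome scan peaks with LOD 11.18 exactly at the simulated causal
marker M06. `K2` is the weaker P1-like trait. The directory also contains
the simulated symptoms and pedigree (`symptoms.csv`, `pedigree.ped/.map`),
per-model membership probabilities (`phi_lca.csv`, `phi_gom.csv`), the
cluster correspondence and averaged traits (`correspondence.json`,
`traits.csv`) and one LOD table per trait (`lod_K1.tsv`, ...).

The same pipeline is available as library calls (`simulate_pedigrees`,
`fit_lca`, `fit_gom`, `evidence_for_fit`, `model_weights`,
`match_clusters`, `average_phenotypes`, `genome_scan`), and the individual
CLI stages (`simulate`, `fit-lca`, `fit-gom`, `average`, `linkage`) accept
the intermediate files.

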