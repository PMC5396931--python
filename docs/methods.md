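# Methods

## Problem and approach

Complex-disease phenotypes without biomarkers are usually defined from
clinical symptom checklists, and different statistical clusterings of the
same checklist data can yield materially different phenotypes — and hence
different downstream genetic results. This package treats the choice of
clustering model as a source of uncertainty to be averaged over rather than
selected away. Two Bayesian clustering models are fit to an n × J binary
symptom matrix Y:

**Latent class analysis (LCA).** A finite mixture of Bernoulli products:

    p(Y_i | p, λ) = Σ_k p_k Π_j λ_kj^{y_ij} (1 − λ_kj)^{1−y_ij}

with non-informative priors p ~ Dirichlet(1, …, 1) and λ_kj ~ Beta(1, 1).
Augmenting with one-hot class indicators z_ik gives conjugate full
conditionals (multinomial for z with membership probabilities δ_ik,
Dirichlet for p, Beta for λ), sampled by plain Gibbs. The per-individual
phenotype estimate φ_i1(k) is the post-burn-in average of δ_ik
(Rao-Blackwellised — lower variance than averaging the one-hot z draws).

**Grade of membership (GoM).** Each individual carries a membership vector
g_i on the K-simplex and symptom j is present with probability
Σ_k g_ik γ_kj; priors g_i ~ Dirichlet(1, …, 1), γ_kj ~ Beta(1, 1).
Conjugacy is restored by per-symptom latent class labels ω_ij ∈ {1..K}
(multinomial with probabilities κ_ijk ∝ g_ik γ_kj^{y_ij}(1−γ_kj)^{1−y_ij}),
giving Dirichlet updates for g and Beta updates for γ. φ_i2(k) is the
post-burn-in mean of g_ik. Only the g and γ draws are retained; ω is
discarded every sweep, so memory scales with the number of retained draws.

**Model averaging.** Model weights follow from Bayes' theorem,
w_s ∝ p(Y|M_s) p(M_s) with equal model priors by default, and the averaged
phenotype is φ_i = Σ_s w_s φ_is. The marginal likelihood p(Y|M_s) is
approximated by the Laplace–Gibbs formula

    log p(Y|M) ≈ (d/2) log 2π + ½ log|H*| + log p(Y|θ*, M) + log p(θ*|M)

with θ* the posterior mean of the retained Gibbs draws and H* the posterior
covariance estimated from the same draws.

**Linkage.** The averaged φ is used directly as a quantitative trait in a
single-point Haseman–Elston sib-pair scan: at each marker, squared sib-pair
trait differences are regressed on the IBD-sharing proportion π̂; linkage
predicts a negative slope, summarised as LOD = t²/(2 ln 10) for the
one-sided t-test (0 if the slope is non-negative).

## Evidence: dimension and covariance structure

The Laplace formula needs a parameter dimension d and a covariance H*:

- LCA: d = (K−1) + K·J. Blocks: one (K−1)-dim block for p (last simplex
  coordinate dropped to keep the covariance full-rank) and one J-dim block
  per class for the λ row.
- GoM: d = K·J + n·(K−1). The membership scores g_i carry priors and are
  sampled, so they count as parameters; each individual contributes one
  (K−1)-dim block, plus one J-dim block per class for γ.

H* is taken block-diagonal over these blocks (log|H*| = Σ block log-dets):
the full covariance of n·(K−1)+K·J parameters estimated from ~10⁴ draws
would be singular, and the block structure is the weakest factorisation
that keeps every log-determinant finite. Eigenvalues are floored at 1e-10
before the log, with a warning when the floor binds. θ* is the simple
posterior mean. The prior density at θ* is Γ(K) per simplex (symmetric
Dirichlet(1,…,1) normalising constant) and 1 for each Beta(1,1) term.

Because d(GoM) grows with n, the Laplace evidence penalises GoM heavily on
data of realistic size; weights on crisp data are near-degenerate in favour
of LCA. The weight *ordering* (not its absolute size) is the tested
property: the GoM weight rises by many orders of magnitude when the data
are genuinely mixed-membership.

BIC = −2ℓ̂ + d log n uses the maximum log-likelihood over post-burn-in
draws and the same d. The BIC scan over K = 2..6 reports the argmin only;
no monotonicity of the curve is assumed.

## Label switching and initialisation

Mixture posteriors are invariant under label permutation. Every retained
draw is aligned by permuting its clusters to minimise the total L1 distance
between its profile rows and a running mean profile; the minimisation is an
assignment problem solved exactly (Hungarian algorithm), and the same
permutation is applied to mixing proportions and membership columns. Draws
pooled across chains pass through the same alignment, which also reconciles
chains that converged in different label orders.

LCA chains start from a per-chain randomly seeded k-means partition of the
rows (profiles shrunk into [0.1, 0.9]). Purely random dispersed starts were
tried first and fail structurally: a plain Gibbs sampler cannot split a
merged cluster once its profile sharpens, and random starts essentially
never land in the dominant mode's basin on separable data. GoM keeps
dispersed random starts; its n·J symptom-level labels move one at a time,
which mixes across modes without assistance.

A related, genuine property of the model (not a sampler artifact): when two
classes differ in a single symptom, the flat-prior partition posterior can
favour merging them — exact conjugate enumeration shows the merged
configuration beats the separated one for KPD-like P2/P3 at n = 300. Class
pairs differing in ≥ 2–3 symptoms are recovered cleanly.

## Cluster reconciliation and trait construction

Clusters from the two models need not correspond. Reconciliation uses the
posterior-mean symptom-prevalence profiles:

1. Clusters whose mean prevalence is below `unaffected_threshold`
   (default 0.20) are flagged unaffected and excluded from trait building.
2. Remaining cross-model pairs are greedily matched by ascending mean
   absolute profile difference; pairs at distance ≤ `merge_threshold`
   (default 0.10) merge.
3. Merged traits: φ_i = Σ_s w_s φ_is with weights renormalised over the
   contributing models. Unmatched clusters stay distinct and pass their
   model's φ column through unchanged — a cluster found by only one model
   should not be diluted by a model that never found it.

The numeric thresholds are this package's own calibration of a judgment
that is qualitative in practice (profiles "nearly identical" merge); both
are exposed as parameters. Traits are named K1, K2, … by decreasing mean
profile prevalence. Threshold classification (φ ≥ 0.5 ⇒ affected, ties
affected; 0.7 supported as a stricter variant) feeds sensitivity/
specificity evaluation against simulation truth.

## Synthetic data

The KPD-like generator emulates the structure of the study population,
which is not redistributable:

- 12 symptoms a–l; affected classes P1 = {b,e,f,h}, P2 = {c,d,e,f,g,h},
  P3 = {b,c,d,e,f,g,h} plus an unaffected class; default class proportions
  (184, 193, 178, 853)/1408. Background symptoms (a, i, j, k, l) carry no
  class signal.
- Penetrances default to 0.9 (class symptom) and 0.05 (background): the
  published source does not state the generating penetrances, so these are
  structural choices giving separable but overlapping clusters.
- A crisp generator (classes drawn from the proportions; the LCA law) and a
  mixed-membership generator (g_i ~ symmetric Dirichlet(c); the GoM law).
- Pedigrees: nuclear families; founders carry four distinct marker alleles
  per family, so markers are fully informative and single-point IBD is
  exact by parental-origin tracing — this isolates the linkage stage from
  IBD-inference noise. Markers are 7.5 cM apart by default; gametes follow
  Haldane (no-interference) recombination.
- Liability: a single biallelic locus co-segregating with one marker
  (risk-allele frequency 0.5) shifts a standard-normal liability by
  `qtl_effect` per risk allele. Offspring below threshold 2.0 are
  unaffected; affected classes occupy successive liability bands of width
  1.0 in order of severity (symptom-set size), so the most symptomatic
  subtype has the highest genetic loading. This single-locus graded model
  is an emulation, not a reproduction, of the original four-locus epistatic
  architecture (whose parameters are not public). The pedigree `trait`
  field stores the continuous liability.

What the generator does not emulate: ascertainment schemes, SNP panels,
linkage disequilibrium between markers, epistasis, genotyping error or
missing data. Passing tests therefore demonstrate correctness of the
machinery under a clean additive single-locus world, not performance on the
original data or on real clinical samples.

## Study conditions used by the tests and the acceptance script

Chain lengths are scaled for desk-scale runs: library defaults are
n_iter = 20,000 / burn-in 10,000 / thin 2 / 3 chains; the test suite and
acceptance script use 1,200–1,500 iterations with 400–700 burn-in and 1–2
chains, which the deviance traces show is amply post-convergence at these
problem sizes (n ≤ 800, J = 12, K ≤ 6). Exact-posterior checks run one
chain of 50,000–60,000 retained sweeps on 4×2 (LCA, 16 assignments
enumerated) and 3×2 (GoM, 64 label configurations enumerated) instances.
The end-to-end pipeline simulates 200 families × 4 offspring, 12 markers at
7.5 cM, causal locus at marker 6, qtl_effect 2.5.

Haseman–Elston power at the spec's 200-pair design saturates near 0.9
regardless of effect size (quarter of families have QTL-homozygous parents
and contribute pure-noise pairs), reaching ~0.69 when the locus explains
89% of trait variance and ~0.89 at 97%; the "strong QTL" power condition
therefore uses qtl_effect = 8 (97% VE). Null calibration uses 200
zero-effect scans; P(LOD > 3) per scan is ~1.3e-4 under the t reference,
so zero to two exceedances are expected.

## Numerical choices

- Probabilities are clamped to [1e-12, 1 − 1e-12] inside likelihoods;
  Beta(1,1) posteriors have no mass exactly on the boundary but floating
  point can land there.
- Model weights are computed with the max-log-ml shift, stable for
  arbitrarily large |log p(Y|M)| gaps.
- Categorical draws use inverse-CDF sampling on row-wise cumulative sums
  with the last entry pinned to 1.
- In the HE regression, a zero residual standard error yields t = −∞ (LOD
  ∞) for a negative slope and LOD 0 otherwise; an all-constant trait gives
  slope 0 and LOD 0. All sib pairs within a sibship enter unweighted — the
  non-independence of pairs within large sibships is a known approximation.
- Missing symptom data are rejected at parse time; the model has no
  missing-data mechanism.

## Known limitations

- Single-point linkage only; no multipoint IBD, no variance-components
  models, no interaction/epistasis tests.
- The Laplace–Gibbs evidence for GoM depends on a covariance structure the
  method itself does not pin down; the block-diagonal choice here is a
  documented decision and other factorisations would shift the absolute
  weights (the orderings tested are robust to this).
- Binary symptoms only; two models; extension of the averaging data model
  to more than two models is structurally supported but unvalidated.
- With uninformative or partially informative real markers the IBD step
  abstains rather than estimating; real-data use would need a proper
  multipoint IBD engine upstream.
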