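# Methods

## The simulated system

`traitrank` simulates an F2 population descended from a cross between two
fully contrasting homozygous parents, genotyped at 1,000 evenly spaced
codominant biallelic markers on 10 linkage groups of 100 cM (1 cM between
adjacent markers), and phenotyped for 11 quantitative traits with a known
genetic architecture. The point of the simulation is that the truth is
known: which auxiliary traits genuinely carry information about the
principal trait is fixed by construction, so statistical and
machine-learning importance measures can be scored against it.

### Meiosis model

Gametes are generated per linkage group as a two-state Markov walk along
the ordered markers: the allele at the first marker is a fair coin, and
each subsequent allele switches parental phase with the recombination
fraction of the adjacent 1 cM interval. Distances are converted to
recombination fractions with Haldane's map function,
r = (1 − e^(−2d/100))/2, which makes the per-interval Markov walk exact
under no crossover interference; Kosambi's function is available as an
option but changes only the interval probabilities, not the model.
Linkage groups assort independently. An F2 genotype is the sum of two
independent F1 gametes, coded AA/Aa/aa = 1/0/−1. At 1 cM the Haldane
fraction is 0.00990, and each marker segregates 1:2:1 in expectation.

### Trait model

Each trait is controlled by 40 loci drawn from a fixed candidate grid:
the markers at within-group positions 10, 20, ..., 80 on every group.
The 11 traits differ in which groups contribute loci and in their target
heritability. PT1, the principal trait (h² = 0.5), takes all 8
candidates on groups 1–5. PT2 mirrors that layout on groups 6–10, so it
shares no loci (and no linkage) with PT1 — it is the designed null
trait. PT3–PT5 take 4 candidates on every group at h² = 0.3/0.5/0.8;
PT6–PT8 and PT9–PT11 repeat that heritability ladder with progressively
less overlap with PT1's groups. Where a trait takes 4 of the 8
candidates, *which* 4 is the scenario: scenario 1 = positions
{10,20,30,40}, 2 = {50,60,70,80}, 3 = {10,20,70,80}, 4 = {30,40,50,60}.

The genotypic value of an individual is

    G = μ + Σⱼ pⱼ·cⱼ + Σⱼ₌₁..₃₉ pⱼ·cⱼ·cⱼ₊₁

with cⱼ the contribution of the coded genotype at the j-th control locus
in genome order — +a for AA, d·a for Aa (degree of dominance d = 0.5 by
default), −a for aa — and locus weights pⱼ ~ Uniform(0,1). The second
sum is adjacent-locus epistasis over the trait's genome-ordered locus
list (39 pairs, including pairs that span group boundaries), weighted by
the left member of each pair. One weight is drawn per candidate locus
per replicate and shared by every trait that locus controls, so traits
with shared loci have well-defined genetic correlations and differ only
through "the environment" (their noise scale); a flag switches to
independent per-trait weights. μ defaults to 100 and a to 1.

Environmental noise is scaled to the target heritability through
σ²ₑ = (1 − h²)·σ²_g/h², where σ²_g is the *empirical* variance of G in
the realized population (including its epistatic component). Using the
realized rather than theoretical genotypic variance means each
replicate's realized heritability Var(G)/Var(Y) is centred on the target
regardless of sampling fluctuations in the genotypes; across 200 default
replicates the means recover 0.30/0.50/0.80 within ±0.02. Phenotypes,
genotypic values and errors are all stored, so heritability and genetic
correlations can be computed exactly ("oracle mode") instead of
estimated.

## The benchmarked prediction methods

All methods predict PT1 from PT2–PT11 on a random 80/20
train/validation split (there are no classes to stratify over for a
continuous response), with optional 10-fold cross-validation R²
alongside the training and validation R² = 1 − SSE/SST.

* **Stepwise multiple regression** — bidirectional selection with
  p-to-enter = p-to-remove = 0.05 on OLS t-tests; per-predictor |t| is
  the regression importance measure, 0 for never-selected traits. Note
  that forward entry picks the minimum of 10 p-values, so under a global
  null *some* predictor enters with probability ≈ 1 − 0.95¹⁰ ≈ 0.40.
* **MLP** — one hidden layer (default 30 tanh units), linear output,
  inputs and response range-scaled to [−1, 1] on the training set,
  trained by L2-regularized LBFGS in warm-start bursts until the
  training MSE reaches 1e−3 or 5,000 iterations are spent. The default
  weight decay is deliberately strong (α = 1): with 400 training points
  a 30-unit network driven to MSE = 1e−3 memorizes the noise (validation
  R² ≈ −3 at α = 1e−3), whereas strong decay plays the role the
  Bayesian-regularization training algorithm plays in the original
  protocol. α is a config knob.
* **RBF network** — Gaussian units at k-means centers on the normalized
  inputs, shared radius, output weights by (ridge-stabilised, 1e−8)
  least squares; a grid of 10–30 centers (step 2) × radius 5–15
  (step 0.5) — 231 cells — is scanned and the cell with the best
  validation R² kept.
* **Tree learners** — a single regression tree; bagged trees (bootstrap,
  all predictors per split); a random forest (bootstrap, 1/3 of the
  predictors per split, the regression-forest convention); and gradient
  boosting (squared error, depth-3 trees, shrinkage 0.1). The reference
  configuration grows 5,000 trees; the replicated test studies use 500,
  which changes ensemble variance negligibly at 10 predictors.

## Importance measures

* **Garson/Goh partitioning** (MLP): per hidden unit, each input's
  absolute input→hidden weight share, weighted by the absolute
  hidden→output weight, summed and normalized to percentages (sum = 100;
  bias terms excluded; hidden units with no input connections skipped).
* **Permutation ΔR² (pVR)**: validation R² minus the mean R² after
  shuffling one predictor column, averaged over `n_perm` (default 10)
  permutations. Note pVR is not bounded by R²_obs: permuting the sole
  predictor of a perfect fit gives R²_perm ≈ −1, hence pVR ≈ 2.
* **Zero-input destructuring** (normalized-input models): validation R²
  after holding one predictor at 0 on the [−1, 1] scale, i.e. the middle
  of its training range — this makes "constant" comparable across traits.
  Reported as the resulting R², so *smaller* means more important.
* **Permutation ΔMSE (IV) and %IMSE** (tree learners): mean rise in
  validation MSE under permutation, absolute and as a percentage of the
  baseline MSE.

Permutations shuffle a single validation column and never refit the
model. A pure-noise predictor appended to a dataset has expected pVR and
IV of 0 (checked to 2 Monte-Carlo SE over 100 replicates).

## Genetics summaries

Selection intensity is i = φ(z)/p for a selected fraction p (i = 0.9659
at p = 0.40). Indirect selection response in trait y when selecting on
x is GS = i·h_x·r_g·s_y, with s_y the phenotypic SD of y and the
percentage gain taken relative to the trait mean μ_y (the only
scale-bearing constant available). The genetic correlation r_g is
computed two ways: from the stored genotypic values (exact, primary) and
as the field-data estimator r_p/(h_x·h_y) clipped to [−1, 1]; on traits
constructed with identical loci and weights the two agree within
sampling error. Traits are grouped structurally
(PT1 | PT2 | PT3–5 | PT6–8 | PT9–11) and the correlation matrix is also
exported as an adjacency list for network summaries.

## What the simulation does and does not emulate

It emulates segregation, linkage, pleiotropy through shared loci,
directional dominance, adjacent-pair epistasis, and heritability-scaled
independent noise. It does not include genotype-by-environment
interaction, maternal effects, missing or mistyped genotypes,
multi-allelic markers, crossover interference, or selection during
population development. Conclusions from passing tests therefore speak
to how importance measures behave when the generative assumptions hold
exactly, not to their robustness on real field data.

## Numerical and design choices

* Marker coordinates are 1-based (marker k of a group sits at k cM),
  matching the 1-based global marker ids.
* Child RNG streams are seeded by the (master seed, scenario, replicate)
  tuple, so any replicate can be regenerated in isolation and replicate
  streams are independent.
* Cross-validated R² is recomputed by refitting each method k times, so
  it sits behind the `compute_cv` config flag (off by default; turning
  it on multiplies study runtime roughly k-fold). Training and
  validation R² are always reported.
* The RBF radius grid is applied on the [−1, 1] normalized scale as
  given; large radii saturate the units and the ridge term keeps the
  solve well-posed.
* `r_squared` requires a non-constant observed vector and equals
  1 − MSE/Var(y) (population variance) to machine precision.
* Degenerate inputs fail loudly: monomorphic populations (zero genotypic
  variance), h² = 0, constant columns under range scaling, zero baseline
  MSE for %IMSE.

## Known limitations and an honest negative result

With independent noise at h² = 0.5, the out-of-sample R² for predicting
PT1 from the *noisy* auxiliary phenotypes has a ceiling well below the
training-set figures flexible learners produce. In this generative
model, errors-in-variables attenuates the epistatic interactions, and
the conditional mean of PT1 given the auxiliary phenotypes is very
nearly linear: at 16,000 training individuals OLS reaches validation
R² ≈ 0.24 while a tuned gradient booster and a random forest reach
≈ 0.21–0.23. Consequently the nonlinear learners do *not* beat stepwise
regression out of sample at n = 500, even though they dominate on
training R². The package reports training, validation and
cross-validated R² side by side so the two orderings are visible.

A second, subtler finding concerns the designed null trait. PT5 is
recovered as the most important trait by every measure, method and
scenario, and its average rank always beats PT2's. But PT2 does *not*
reliably average among the very worst ranks: once PT3–PT5 are in the
model, the remaining auxiliary traits are conditionally almost
redundant, so seven traits compete for the bottom slots with importance
scores fluctuating around zero — weak-signal traits can even show
slightly negative permutation ΔMSE (their overfit component hurts on
held-out data), placing them below the null trait. A single realization
can show PT2 at the very bottom; replication shows that to be a draw
from a near-tie, not a stable property. Top-rank recovery is robust;
bottom-rank identification among conditionally redundant predictors is
not.

## Problem sizes used by the test suite

The replicated analyses in the test suite use 200 simulation-only
replicates for the heritability/correlation recovery checks and 50 full
pipeline replicates per scenario (500-tree ensembles) for the ranking
checks; these sizes give Monte-Carlo standard errors comfortably inside
the asserted tolerances.
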