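# Methods

This note documents the statistical model, the estimation procedure, the
simulator, and the numerical choices behind `pedsem`.

## Model

`pedsem` fits linear structural equation models with latent variables to
general pedigree data.  For one family (pedigree) k with n_k members and
t observed traits per member, the stacked trait vector **y**_k (one
length-t block per individual) is modeled as multivariate normal with

    E[y_ki]   = nu + Lambda (I - B)^-1 (alpha + Gamma_eta x_ki) + Gamma_y x_ki
    var(y_k)  = sum_c  R_{c,k}  (x)  V_c(theta),         (x) = Kronecker product

where per variance component c

    V_c(theta) = Lambda (I - B)^-1 Psi_c (I - B)^-T Lambda' + Theta_c.

The measurement model (`Lambda`), structural model (`B`), covariate
effects (`Gamma_eta`, `Gamma_y`; SNP genotypes enter as fixed additive
regressors 0/1/2), intercepts (`nu`; latent intercepts `alpha` are held
at zero) and the per-component residual covariances (`Psi_c` latent,
`Theta_c` observed) are all populated from a lavaan-like model
description (operators `=~`, `~`, `=`, component groups `<p,e,...>`).

The relationship matrices R_c separate the familial-correlation model
from the structural model:

| component | label | R_c | interpretation |
|---|---|---|---|
| polygenic | `p` | 2*Phi_k (numerator relationship matrix) | additive background genetics |
| environment | `e` | I | individual residual environment |
| household | `c` | block of ones per household | shared environment |
| linkage | `a(marker)` | realized IBD proportions, diag 1 | locus-specific genetic variance |

Using 2*Phi (diagonal 1 for non-inbred individuals) rather than the bare
kinship matrix Phi (diagonal 1/2) means a polygenic variance parameter
equals the additive genetic variance of a single individual; the
alternative convention simply doubles every `p`-component parameter.
This scaling is applied uniformly in the simulator and the estimator, so
round-trip recovery is convention-free.

Kinship is computed by the standard recursion in topological order
(phi_ii = (1 + phi(f,m))/2, phi_ij = (phi(f_i,j) + phi(m_i,j))/2), which
handles inbreeding and marriage loops without special cases.

## Two-stage estimation

**Stage 1 (saturated model).**  Each observed variable is fitted by ML to
a univariate variance-component model (mean = intercept + one slope per
model covariate; covariance = sum_c sigma_c R_c), then each variable pair
is fitted by ML for its per-component cross-covariances with the
univariate parameters held fixed (a profile two-step).  Variances are
*not* constrained to be nonnegative; only positive definiteness of each
assembled covariance matrix is enforced during optimization.
Unconstrained variances keep the estimator asymptotically normal (no
boundary), at the price of occasionally negative point estimates under
low heritability — which is expected behavior, not an error.

The stacked stage-1 estimates s (intercepts, slopes, variances,
covariances, in a fixed documented order) receive the M-estimation
sandwich covariance Gamma_hat = A^-1 B A^-T / N, with B the empirical
second moment of the per-pedigree scores and A the Jacobian of the mean
stacked score in all stage-1 coordinates.  Because the bivariate
estimating equations depend on the univariate estimates, A is block
*lower-triangular*; differentiating the analytic scores numerically
(central differences, step 1e-5 scaled) produces those cross blocks
automatically, which is what makes the two-step standard errors honest.

When the model has exactly two components, one of which is the identity
(`e`), every likelihood reduces — after rotating each pedigree by the
eigenvectors of its other relationship matrix — to independent scalar
(univariate) or 2x2 (bivariate) normal terms.  This fast path is exact,
not an approximation; models with three or more components use a general
batched dense-matrix path.

**Stage 2 (minimum distance).**  theta_hat minimizes
Q(theta) = (s - sigma(theta))' W (s - sigma(theta)), where sigma(theta)
is the model-implied moment vector.  The default weight is
W = diag(Gamma_hat)^-1 (numerically robust when the moment vector is
long); `weight="full"` uses the pseudo-inverse of Gamma_hat, which makes
Q asymptotically chi-square on its degrees of freedom.  Parameter
covariance is the usual minimum-distance sandwich
(D'WD)^-1 D'W Gamma_hat W D (D'WD)^-1 with D = d sigma / d theta
evaluated at theta_hat by central finite differences.  Wald z and
two-sided normal p-values are reported per free parameter; variance
components are tested the same way (valid because they are unconstrained).

Starting values come from a small evolutionary search (population 20, 10
generations, tournament selection of size 3, blend crossover alpha=0.5,
Gaussian mutation sd = 0.1 x scale at rate 0.2, elitist), seeded around a
heuristic center (coefficients 1, intercepts at their stage-1 values,
variance components an equal split of the stage-1 totals).  The top
candidates *and always the heuristic center* are polished by
Levenberg-Marquardt on the weighted residuals with an analytic Jacobian;
the best polished minimum wins.  Polishing the center guards against the
rare deceptive basin in which the population converges onto a ridge
(e.g. two latent variances trading off against each other).

**Ascertainment.**  Families recruited through an affected index case
(proband) are handled by single ascertainment: every stage-1 likelihood
term is replaced by log f(y_pedigree) - log f(y_proband), where the
proband contribution uses the proband's values of the variables in the
current fit (its one trait in a univariate fit, the pair in a bivariate
fit).  Pedigrees without a proband, or whose proband has no observed
values for the fit, contribute unconditionally.  Conditioning on the
per-fit variables is an approximation to conditioning on the proband's
full trait vector — exact per-fit conditioning is the only option
available to a two-stage estimator, and the ascertainment study below
shows it restores nominal coverage in practice.

## Tests of fit

Q at the optimum is asymptotically a weighted sum of 1-df chi-squares
with weights the eigenvalues of U*Gamma_hat,
U = W - W D (D'WD)^-1 D'W.  Four p-values are reported: unadjusted
(Q ~ chi2(df), exact only under full weighting), mean adjusted (first
moment matched), mean-and-variance adjusted (fractional
df* = (sum w)^2 / sum w^2), and the theoretically corrected test: the
Monte-Carlo tail probability of the exact mixture (default 1e5 draws,
add-one smoothing so p > 0), from which a chi-square statistic on model
df is back-calculated.  Negative estimated weights (sampling noise in
Gamma_hat) are floored at zero with a warning.  CFI compares the
theoretical statistic's noncentrality against an independence baseline
(all covariance moments implied zero; means and per-variable variances
free), computed with the same correction.  Under diagonal weighting only
the theoretical p-value is uniform under a correct model; the unadjusted
test is badly miscalibrated — the replicate studies in the test suite
demonstrate both.

## Simulator

The simulator generates data from exactly the model family the estimator
fits, plus the genetic machinery around it:

* **Founder haplotypes** come from a phased panel.  A synthetic panel
  generator (first-order Markov chain over binary alleles) provides
  controllable marker count, MAF range (MAFs sorted along the chromosome
  so adjacent targets stay feasible), and adjacent-marker r^2; a real
  phased panel can be supplied in the same text format.
* **Gene dropping** assigns each founder two panel haplotypes (uniform
  with replacement) and transmits Haldane-model recombinants (1 cM/Mb
  default) through each meiosis, tracking founder-haplotype descent
  labels; realized IBD matrices are computed from the labels
  (pi = shared alleles / 2, diagonal 1).
* **Traits** are drawn per component as matrix-normal deviates with row
  covariance R_c and column covariance Psi_c / Theta_c, then pushed
  through the structural equations — the same Kronecker covariance the
  estimator assumes.
* **Ascertainment** flags a member affected when the mean of its trait
  values exceeds the upper-prevalence quantile of the trait-mean
  distribution in a 1e5-individual reference population simulated at the
  true parameters (empirical rather than analytic, because the trait
  mean is a genotype mixture).  Affected members become proband
  candidates with the ascertainment probability; the first candidate is
  the proband; probandless pedigrees are discarded and simulation
  continues until the requested number of analyzed pedigrees is reached.

Everything is a pure function of (configuration, seed).  What the
simulator does *not* emulate: non-normal trait distributions, missing
data patterns, genotyping error, sex linkage, and population
stratification — so passing recovery/coverage studies certify the
estimator under correct specification and Gaussian traits, not
robustness to those violations (the sandwich standard errors are,
however, derived without normality).

Pedigree presets: `nuclear75` (75 nuclear families, 477 individuals,
sibships of 4–11: 69 four-child sibships plus one each of 6..11) and
`extended5` (five 10-member three-generation structures, including a
half-sib family and a first-cousin-mating loop).

## Evaluation studies and problem sizes

The test suite runs scaled replicate studies chosen to finish on a single
CPU while retaining statistical power: type-I error of the SNP Wald test
(1000 replicates at 75 nuclear pedigrees, 200 at 500); parameter
recovery and 95% CI coverage for all four example models (200 replicates
at 300 pedigrees, 100 at 75 for the bias-vs-N comparison; 200 replicates
of the association model on extended pedigrees); fit-test calibration
(300 replicates, 75 extended pedigrees, KS uniformity at alpha = 0.01);
and the ascertainment study (prevalence 5%, ascertainment probability
0.05, 150 analyzed pedigrees, 200 replicates, analyzed with and without
correction).  Monte-Carlo tolerances are 3 standard errors (binomial or
replicate-based) throughout.  `scripts/acceptance.py` re-runs the same
studies at somewhat smaller replicate counts and writes the headline
numbers as JSON.

## Numerical choices

* Stage-1 optimization: BFGS with analytic gradients; non-PD covariances
  return a large sentinel value; up to 3 perturbed restarts.  The PD
  region in the eigen fast path is characterized exactly (all rotated
  variances positive).
* Stage-2 LM: xtol = ftol = 1e-8, gtol = 1e-8; saturated models reach
  Q ~ 1e-12 and report df = 0 with all fit indices NA.
* Identification: df >= 0 plus a numeric rank check of the moment
  Jacobian at 5 random draws (singular values below 1e-8 x largest count
  as zero).
* Gamma_hat is symmetrized and eigenvalue-floored (1e-10 x largest) so
  diagonal weights and the full pseudo-inverse are well defined.
* Missing trait values are handled by per-fit row deletion; covariates
  must be observed for a row to enter a fit.  Models with missing data
  or 3+ components take the dense path; results agree with the eigen
  path where both apply.
* Tie-breaks: the first proband in member order is used (multiple
  probands produce a validation warning); the first loading of each
  latent anchors its scale unless the user fixes another coefficient or
  a variance.

## Known limitations

* Observed endogenous variables can receive latent and covariate effects,
  but observed-on-observed regressions must be routed through a latent.
* The conditional ascertainment correction assumes single ascertainment
  (sampling probability near zero); with high ascertainment probabilities
  (>~0.2) coverage degrades slowly, consistent with the method's theory.
* The theoretically corrected p-value is Monte-Carlo (seeded,
  reproducible); two different seeds agree only within MC error.
* Bivariate stage-1 fits are profile two-step, not joint; the sandwich
  accounts for this, but a full joint refit is not implemented.
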