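# Methods

## The model

`igevar` studies how competition between social partners generates
*inherited variability* — heritable differences among families in the
environmental variance of a trait — and which standard mixed models
recover the genetic effects involved. The motivating system is paired
growth in fish (e.g. juveniles reared two per tank), where a heavier
partner depresses the focal fish's growth.

Individuals grow in fixed pairs over `n_steps` discrete increments.
For focal individual *i* with partner *j*,

    P[t,i] − P[t−1,i] = μ_GR + A_GR,i + Ep,i + Et,t,i + b_ij (P[t−1,j] − P[t−1,i])

where `P[t,i]` is body weight (g), `μ_GR` the mean growth rate,
`A_GR,i` a breeding value for growth, `Ep,i` a permanent and `Et,t,i` a
temporary environmental effect. The interaction coefficient

    b_ij = b̄ + A_D,i + E_D,i + A_I,j + E_I,j

is fixed for life per ordered pair and in general asymmetric.  `b̄ < 0`
is competition (weight differences amplify within a pair), `b̄ > 0`
cooperation (they damp).  `A_D` is genetic *resistance to competition*
(a direct effect on one's own sensitivity), `A_I` a genetic
*cooperative effect* on the partner.  Because b varies genetically,
families differ heritably in how variable their offspring turn out —
inherited variability arises from social interaction rather than from a
canalization gene acting within an individual.

## Synthetic populations

The generator reproduces the study design exactly and is first-class,
tested code:

* Base population: `n_sires` (100) and `n_sires × n_dams_per_sire`
  (10,000) unrelated parents with trivariate-normal breeding values
  (A_GR, A_D, A_I); SDs from the scenario, correlation matrix identity
  by default (±0.5 runs supported).
* Offspring: each dam mated once, 10 (trait purpose) or 100
  (variability purpose) offspring per dam; breeding value = midparent +
  Mendelian deviation with **half** the additive (co)variance for all
  three traits.  Environmental effects Ep, E_D, E_I drawn once per
  offspring; Et redrawn independently at every time step.
* Pairing: a uniform random perfect matching over the whole cohort
  (full sibs may be paired); the partner map is a fixed-point-free
  involution.
* Growth: synchronous updates (both members' step-t increments use
  step t−1 weights), 10 steps from a 10 g start.  Weights are not
  clamped; a diagnostic counts negative values (never triggered at the
  default parameters).

Default parameters: μ_GR = 10 g, start 10 g, σ_A,GR = 1 g (3 or 0.3 in
the σ_AGR scenarios), b̄ ∈ {−0.05, 0, +0.05},
σ_AD = σ_AI = σ_ED = σ_EI = 0.015 (so that the total SD of b is 0.03,
i.e. 60 % of |b̄|; 0.045/0.005 in the sensitivity scenarios).  With
heritability h² = 0.5 and repeatability 0.7 at b = 0, the phenotypic
variance of the growth increment σ²_P = σ²_A/h² splits into
σ²_Ep = 0.2 σ²_P and σ²_Et = 0.3 σ²_P (0.4 and 0.6 g² at defaults).
Treating Et as per-step is what makes repeatability (0.7) exceed
heritability (0.5); a single lifetime draw would be indistinguishable
from Ep.

The 21 canonical scenarios cross b̄ with 3× larger/smaller σ_AD, σ_AI
and σ_AGR; the catalogue ships as `igevar/data/scenarios.csv`.

Useful closed forms at b ≡ 0 (used as test oracles): final weight =
start + n(μ + A_GR + Ep) + ΣEt, so Var(final) = n²(σ²_A + σ²_Ep) +
n σ²_Et = 146 g² at defaults, the additive variance of final weight is
n²σ²_A = 100 g², and the sire–dam variance component is a quarter of
that, 25 g².

## Statistical models

All four analysis models are intercept-plus-one-random-effect mixed
models fit by REML.

*Variability (sire) models.* The response for sire–dam family *f* is
the natural log of the unbiased sample variance of final weight of the
family's offspring (direct) or of those offspring's partners
(indirect); each sire has `n_dams_per_sire` records.  A one-way sire
model is fit to each response.  On this balanced design REML coincides
with the ANOVA closed form σ̂²_s = (MSB − MSW)/n (truncated at zero),
which serves as the documented cross-check.

*Trait (sire–dam) models.* The response is individual final weight;
the incidence row of a record carries a 1 for the sire and the dam of
the offspring itself (direct) or of its partner (indirect).  Sires and
dams share one variance component, as parents are unrelated no
relationship matrix is needed.

*REML engine.* Both model families share one engine: with
λ = σ²_e/σ²_u and M(λ) = Z′Z + λI, the Woodbury identity reduces the
restricted likelihood to sparse solves against M; μ and σ²_e are
profiled analytically and λ is found by bounded 1-D search on log λ
(`scipy.optimize.minimize_scalar`, xatol 1e-10 on the log scale, λ ∈
[1e-8, 1e10]).  Log-determinants come from a sparse LU factorization
(M is SPD, so the diagonal of U gives log|M|).  If the boundary fit
σ²_u = 0 (ordinary least squares) attains a lower criterion than the
interior optimum, the estimate is truncated at zero with zero BLUPs.
BLUPs solve û = M⁻¹Z′(y − μ̂).  A dense-matrix evaluation of the same
criterion, written independently in the tests, is the oracle for the
sparse path; `statsmodels` MixedLM cross-checks the one-way model.

*Evaluation.* Per replicate, Pearson correlations are computed between
predicted effects and simulated breeding values: sire models against
the sires' own (A_GR, A_D, A_I); sire–dam models against the pooled
parental values.  Correlations are scale-invariant, so the fact that
sire/parent effects estimate *half* breeding values does not affect
them.  Reports aggregate by the arithmetic mean of per-replicate
correlations (with SEs); the pooled-data correlation across replicates
is emitted alongside for transparency.  A constant vector (e.g. a
degenerate scenario with no genetic variance in b) yields a missing
correlation, not a number.

## Reproducibility and problem sizes

One master seed per run; `numpy.random.SeedSequence` spawns
deterministic sub-streams per replicate and, within a replicate, per
stage (base population, offspring, pairing, growth noise), so every
stage is independently reproducible and identical config + seed gives
byte-identical outputs.

The full design (100 × 100 × 100 = 10⁶ offspring per variability
replicate, 10⁵ per trait replicate) simulates in about a second per
replicate vectorized; the acceptance script runs 10 replicates per
scenario.  The `reduced` preset (100 × 20 × 50 and 100 × 20 × 10) is
used by the analysis drivers: with fewer dams per sire and fewer
offspring per family the log-variance records are noisier, so
correlations are attenuated by roughly 0.05–0.15 relative to the full
design — the preset demonstrates structure, not headline magnitudes.
The `tiny` preset exists for smoke tests only.

## Design choices and known limitations

* Mendelian sampling variance is half the additive variance for all
  three traits (standard quantitative-genetic theory), with Mendelian
  covariances scaled by the same genetic correlation matrix.
* Dams are allocated to sires in contiguous blocks; as dams are i.i.d.
  and unrelated this is distributionally identical to random
  allocation.
* Environmental covariances among (Ep, Et, E_D, E_I) are zero; only
  genetic correlations are configurable.
* The same individuals appear both in direct records (as family
  members) and in indirect records of other families (as partners).
  This double use is inherent to pair-structured data and is why the
  two variability models are fit separately (two-step analysis) rather
  than jointly.
* Groups larger than two, multi-generation selection on b, and
  time-series (random-regression) estimation of b are out of scope.
* The generator emulates an idealized design: no mortality or missing
  records, exactly balanced families, normal effects, and a constant
  b per ordered pair.  Passing tests therefore demonstrate the
  statistical behaviour of the estimators under the model, not
  robustness to the messiness of real husbandry data.
* The simulation reproduces the reference correlation structure of the
  direct variability model and both trait models closely; for the
  indirect variability model in weak-signal settings (cooperation, or
  small σ_AI) it yields somewhat stronger correlations than the
  reference values, with the same qualitative ordering.  The numbers
  reported by the acceptance script are always the computed ones.
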