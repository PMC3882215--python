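# Methods

This note records the mathematical conventions, numerical choices and
design decisions behind `bdiv`, and what the validation studies do and do
not demonstrate.

## Process and probability functions

The clade is a Markovian birth–death process with per-lineage speciation
rate λ(t) and extinction rate μ(t), started with two lineages at the MRCA
(time 0) and stopped at the present (time T).  Time runs forward from the
MRCA everywhere in the core; `treeio` converts user-facing node ages
(time before present) into this convention.

All core quantities derive from three ingredients:

* `r(s,t) = ∫ₛᵗ (μ − λ) dx` — the negative net-diversification integral;
* `A(s,T) = ∫ₛᵀ μ(x) e^{r(s,x)} dx` — the extinction-weighted integral;
* the sampling fraction ρ applied as a Bernoulli mark on tips at the
  present.

Writing `D(s) = ρ(1 + A(s,T)) + (1 − ρ)e^{r(s,T)}`, the probability that
a lineage alive at s has at least one *sampled* descendant is
`P_s = ρ/D`, and the number of sampled descendants given survival is
geometric with parameter `q = e^{r(s,T)}/D`.  The ρ-modified functions
follow from solving the backward (Riccati) equation with boundary value
1 − ρ at the present; at ρ = 1 they reduce to the classical formulas, and
for constant rates they reproduce the published sampled `p₀/p₁`
functions, which the test suite asserts to 1e-10.

The identity `dq(t)/dt = λ(t) ρ e^{r(t,T)} / D(t)²` gives the i.i.d.
divergence-time density and CDF in closed form up to `A`:

    f(t) = λ(t) ρ e^{r(t,T)} / D(t)² / (1 − q(0)),
    F(t) = (q(t) − q(0)) / (1 − q(0)).

## Likelihood conventions

All likelihoods are densities of the **ordered** divergence times (and of
the tip/species count where that count is informative), conditioned on
the MRCA age and on both root lineages reaching the sample:

* complete / uniform(ρ):  `(m−1)·(m−2)!·q(0)² ∏ᵢ λ(tᵢ) ρ e^{r(tᵢ,T)}/D(tᵢ)²`
* diversified given n:    `(n−2)!/(n−m)! ∏ᵢ f(tᵢ) · (1 − F(t*))^{n−m}`
* diversified (MRCA only): the above times `(n−1) q(0)² (1−q(0))^{n−2}`,
  the survival-conditioned geometric law of the total species count.

The cut point t* is the youngest observed divergence time (the MRCA
itself when m = 2), and `1 − F(t*)` is always accumulated through
`log1p(−q(t*)) − log1p(−q(0))`, which survives F → 1 when thousands of
species are missing.  The combinatorial prefactors are chosen so the
three schemes coincide *exactly* at ρ = 1 and so uniform-vs-diversified
AICc comparisons are over densities of the same observable.  The
topology probability is omitted: it is a constant shared by every
candidate model and scheme for a fixed tree.  Unconditioned variants
(`condition_on_survival=False`) are provided because survival
conditioning itself can inflate extinction estimates in near-critical
clades; they simply multiply by P_s(0,T)².

When only ρ is known, the species count is n = round(m/ρ), with a
warning when m/ρ is not integral.

## The six rate families

Every family is of the form λ(t) = a + b·e^{−δt} with constant μ, which
pins down closed forms for all rate integrals.  M5 is parameterized as
λ(t) = λ·e^{−δt} + μ with its *own* decay rate δ — the minimal reading of
"speciation converging to the extinction rate", and the one that keeps
the nesting M1 ⊂ M3 ⊂ M5/M6 intact.  The optimizer boxes (rates in
[0, 10³], decays in [10⁻¹⁰, 10³]) are numerical guards, not biological
statements.

`A(s,T)` is elementary for M1–M4 (μ = 0, or constant rates).  For M5/M6
the integrand mixes `e^{ct}` with `e^{k·e^{−δt}}`, whose antiderivative
is an incomplete gamma of negative order at positive argument — outside
the real-domain special functions available here — so `A` is evaluated by
composite 12-point Gauss–Legendre quadrature on a union grid of the
requested points with a 256-interval refinement, validated against
adaptive quadrature to 1e-8 in the tests.  All survival-type quantities
are computed in log space; likelihood products over hundreds of events
are accumulated as sums of logs.

## Simulation

Reconstructed trees are simulated through exchangeability rather than by
event-by-event forward simulation: conditioned on the MRCA age and
survival of both root lineages, each root lineage's sampled descendant
count is geometric(q), and the non-root divergence times are i.i.d. draws
from F via a 2049-point monotone grid inverse followed by three Newton
refinements (residual |F(t) − u| ≲ 1e-12).  Topology, which carries no
rate information in this model class, is attached on demand by splitting
a uniformly chosen extant lineage at each successive event — the uniform
ranked-shape law.  A forward Gillespie simulation and the truncated
Kolmogorov master equations serve as independent oracles in the tests.

Taxa-conditioned simulation draws the MRCA age from
p(T | n) ∝ (n−1)q(T)²(1−q(T))^{n−2}, i.e. the age law induced by the
process with a flat prior over the age, normalized numerically on an
adaptive grid that expands until the density has decayed by e^{−34.5}
from its peak.  This convention is a package choice (the age law under
taxa conditioning is not otherwise determined); it is exposed through
`draw_age_given_taxa`.

Uniform sampling is simulated literally — binomial tip thinning followed
by pruning and re-rooting at the sampled MRCA.  The test suite verifies
that this mechanical route reproduces the analytic ρ-modified density
and tip-count law, which is the strongest internal check of the
uniform-sampling mathematics.  Where the bootstrap needs nulls
*conditioned on the sampled MRCA age* (matching the likelihood's
conditioning), the sampled tree is instead drawn directly in its
ρ-modified i.i.d. representation.  Simulation without survival
conditioning is rejected: a reconstructed tree rooted at the MRCA only
exists when both root lineages survive.

## Inference

Rates are optimized on the log scale with Nelder–Mead (derivative-free;
the surface can be ridge-like in λ − μ), convergence tolerance 1e-8 on
the log-likelihood, restarted from one moment-based start (ln m / T) plus
log-uniform draws on [10⁻³, 10]; a fit is flagged unconverged when the
two best restarts disagree by more than 1e-4 log units.  An optional
λ(t) ≥ μ constraint supports the analysis style used for near-critical
clades.  AICc and BIC use sample size m − 1 by default (m − 2 i.i.d.
speciation times plus one geometric count observation); the convention is
an explicit argument.  Ties in model selection resolve to the earliest
candidate in the list.

## Adequacy testing

The parametric bootstrap simulates under the fitted parameters *with the
fitted sampling scheme applied before statistics are computed*: γ and the
sampled tip count from age-conditioned replicates, the tree age from
taxa-conditioned replicates.  Empirical p-values are two-sided
equal-tail, `p = 2·min(r, 1−r)` with r the fraction of null draws at or
below the observation, clamped to [2/(n_sims+1), 1]; the one-sided
lower tails are reported alongside because published analyses do not
always state sidedness.

## Validation studies and their scope

`bdiv.experiments` (driven by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs desk-scale versions of the full simulation
designs; problem sizes were fixed once as a compromise between Monte
Carlo resolution and a single-CPU run of a few minutes: 10⁴ draws for
distributional KS tests, 200 replicates per recovery regime, 100
replicates for selection rates, 500×500 for adequacy calibration.  The
generating regimes (in `bdiv.fixtures`) hold the expected clade size at
≈200 species (≈20 for the small-tree study): Yule with λT = ln 100;
constant-rate birth–death with λ = 1, μ = 0.5; and a decreasing-rate
birth–death λ(t) = 0.5e^{−0.1t} + 0.1 with its age solved numerically.

Findings worth recording:

* Medians at E[N] ≈ 200 recover all parameters of all three regimes to
  within ~10%, and median absolute errors shrink with tree size.
* Small-tree bias directions are size- and statistic-dependent.  In the
  20–50-tip band the birth–death fits show a right-skewed joint
  distribution of (λ̂, μ̂): the *mean* speciation estimate is pulled above
  truth by ridge excursions while the *typical* (median) extinction
  estimate sits well below truth with a point mass at zero — the
  "speciation over, extinction under" pattern, each direction expressed
  by the statistic that robustly shows it.  Below ~10 tips the survival
  conditioning dominates and both rates are overestimated on average;
  the bias study therefore evaluates the 20–50-tip band and this
  boundary behaviour is stated here rather than hidden.
* The decreasing-rate family recovers all three medians within ~10% at
  E[N] ≈ 200, but on small trees (E[N] ≈ 20) the typical decay-rate and
  extinction estimates are roughly double the truth — the small-tree
  "rapid radiation" artifact.  Mean biases for this family are dominated
  by rare optimizer excursions to the box bound and are not a stable
  summary; medians are reported instead.
* Sampling-scheme identification from AICc is reliable at sparse
  sampling (86–96% at ρ = 0.2 across seeds) and degrades only near
  complete sampling, as it must, since the schemes coincide at ρ = 1.

What passing these studies does **not** show: the generator emulates the
model exactly, so the studies validate internal consistency and
estimator behaviour *under the model* — homogeneous rates across
lineages, no rate shifts, strict diversified sampling.  Real chronograms
violate several of these (that is precisely what the adequacy test is
for), and empirical trees also carry dating error, which is not modelled
here.

## Known limitations

* Diversified sampling is the strict all-oldest-splits idealization; the
  softened variant in which recent splits retain a small sampling
  probability is not implemented.
* No rate shifts, diversity-dependence, or lineage-specific rates.
* Confidence intervals are limited to restart-spread diagnostics; no
  Bayesian machinery.
* For extreme parameter excursions during optimization the quadrature
  guard maps overflow to −∞ log-likelihood, which is correct for model
  ranking but means the reported surface is truncated far from the
  optimum.
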