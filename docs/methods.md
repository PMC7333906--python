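# Methods

`largeclade` studies a selection effect in divergence-time estimation: when a
clade is chosen for analysis *because* it is unusually species-rich (or
species-poor) for its age and diversification rate, a Bayesian molecular-clock
analysis with a birth–death/Yule tree prior systematically overestimates (or
underestimates) its age.  The package simulates the generating process,
re-infers ages under a correctly specified model, and quantifies the bias; it
also provides the analytic clade-size theory, lineage-through-time (LTT)
diagnostics, and a fossil-appearance-order Monte Carlo that frame the problem.

## Models

### Birth–death trajectories (`treesim.simulate_bd_trajectory`)

Exact event-driven (Gillespie) simulation of the species count: with n
lineages the waiting time to the next event is Exponential(n(λ+μ)), the event
is a speciation with probability λ/(λ+μ), and zero is absorbing.  An optional
count cap stops supercritical survivors (who would otherwise grow without
bound); the ultimate extinction probability from one founder, (μ/λ), is the
reference check.  Rates are per lineage per Myr.

### Age- and size-conditioned Yule trees (`treesim.simulate_yule_conditioned`)

The study's generating process: a pure-birth (Yule) clade of age T with rate
λ conditioned on exactly N extant tips.  We use the standard conditioned-
process results: the non-root branching ages x (Myr before present) are
i.i.d. with density λe^(−λx)/(1−e^(−λT)) on (0, T), sampled by inverting the
truncated-exponential CDF; for a crown clade (two founders, root fixed at T)
the tip count of one root child is uniform on {1, …, N−1}; topology follows
by splitting a uniformly chosen extant lineage at each branching, oldest
first.  The contract for correctness is behavioural, not algebraic: the test
suite compares the simulator against a rejection sampler that runs the plain
forward Yule process and keeps only realizations with the right tip count
(two-sample KS at α = 0.01), and checks the root split and the unconditioned
size distribution the same way.

### Clade-size distributions (`cladesize`)

A single-founder Yule clade of age T has geometric size with
p = e^(−λT) (mean 1/p); a crown clade is the sum of its two root lineages'
clades, hence negative binomial with two successes (mean 2/p).  Both forms
are exposed (`n_founders` 1 or 2) because both are in common use for total
groups versus crown groups.  Relative-size window probabilities use inclusive
integer bounds ⌈lo·mean⌉ … ⌊hi·mean⌋; upper tails use the closed-form
survival function S(n) = q^(n−2)(q+(n−1)p) for two founders (q = 1−p),
verified against brute-force pmf summation to 1e−10.  The reference
parameterization, mean 200 with two founders, yields the summary quoted
throughout: 65% of crown clades lie within [0.5×, 2×] of the mean, ~9% are
at least 2× too large, ~2% at least 3×, ~26% below 0.5×, ~6% below 0.2×.

The naive origin estimator ln(N)/λ (single-founder convention) is the time a
steadily growing Yule clade "should" need to reach N species; a clade α times
its expected size is mis-dated by ln(α)/λ.

### Sequence simulation (`seqsim`)

Jukes–Cantor at the event level: per branch of duration t and per site the
substitution count is Poisson(r·t) with r the strict clock rate (total rate
away from the current base; each of the three alternatives at r/3), events
applied sequentially, root states uniform.  The matching transition-
probability closed form P(same) = 1/4 + 3/4·e^(−4rt/3) lives only in the
likelihood code, so simulator and likelihood are independent routes onto the
same model and are cross-checked through the pairwise-divergence saturation
curve.  No rate heterogeneity, no indels.  Default study settings: 1000
sites at r = 0.03 substitutions/site/Myr.  Note that at this rate the
tip-to-tip paths crossing a 100-Myr root carry ~6 expected substitutions per
site — essentially saturated — which is precisely why deep node ages lean on
the tree prior.

### Bayesian strict-clock dating (`clockinfer`)

A compact Metropolis–Hastings sampler over the internal node ages and the
Yule birth rate of a *fixed* topology, with the clock rate fixed to its true
value:

* Likelihood: Felsenstein pruning under JC, site-vectorized; the MCMC uses a
  compiled kernel with per-node current/proposal partial buffers so a
  node-age move refreshes only the moved node's ancestor path, with per-site
  conditional rescaling against underflow.
* Tree prior: the Yule density over the node ages of the fixed labelled
  topology, (n−2)·log λ − λ·L, with L the total branch length including both
  root branches.  Conditional on the root age this makes the non-root ages
  i.i.d. truncated exponentials — exactly the law of the conditioned
  simulator, and the prior-only MCMC is tested against it (the strongest
  guard against a wrong prior form).  The exponent equals the familiar
  λ·(Σ internal node heights + root height) form used by mainstream Yule
  tree priors.
* Birth-rate prior: flat on (0, 10) per Myr.  An unbounded flat prior is
  improper; 10/Myr is several hundred times the posterior scale of every
  problem here, and the recovery results are insensitive to the bound.
* Moves: (i) uniform slide of a non-root node within (oldest child, parent)
  — symmetric; (ii) ±12 Myr random-walk slide of the root age; (iii) rescale
  of all internal ages with log-uniform step (Hastings factor s^m, m = n−1);
  (iv) multiplicative random walk on the birth rate (Hastings factor s).
  Default mixture 0.80/0.17/0.01/0.02, fixed scales, no adaptation
  (reproducibility).  Acceptance rates sit in the 0.2–0.6 band on the
  200-tip problems.
* Diagnostics: shortest-interval HPD on sorted samples; ESS by Geyer's
  initial-positive-sequence rule on paired autocorrelations (zero-variance
  chains are defined to have ESS = n).  A chain with any ESS below the
  threshold (default 200) is flagged and warned about, never discarded.

Fixing the topology to the generating tree is a deliberate divergence from
samplers that integrate over topologies: the bias of interest operates
through node ages under the tree prior, and with ~1000 informative sites the
topology is essentially resolved anyway.  It makes the engine desk-scale; it
also means topological uncertainty's contribution to full-scale HPDs is not
reproduced.

One consequence of the reference regime deserves emphasis.  The generating
process pins the crown age at exactly T, but the inference model treats the
root as free under the conditioned-on-n prior, and with saturated deep
branches the root posterior is right-skewed above the oldest root-child age.
The posterior *mean* height of even correctly-sized (1×) clades therefore
sits several percent above T in this regime — a small intrinsic overshoot on
top of which the clade-size selection effect operates in both directions.
The acceptance script's 1× output quantifies it for the settings used.

### Fossil appearance order (`fossilorder`)

k clades with strictly ordered true origins each wait an independent
Exponential(mean w) time before first appearing; a replicate is a success if
the appearance dates are strictly in origin order (ties, a measure-zero
event, count as failure).  The exponential is parameterized by its *mean*
waiting time in Myr.  Default origins are the five nested Ediacaran–Cambrian
first appearances (571, 566, 556, 546, 535 Ma) used as stand-ins for the true
origins; they are configurable, and the two-clade case has the closed form
1 − e^(−g/w)/2 used as the oracle.

### LTT diagnostics (`lttstats`)

The LTT curve counts lineages after each branching.  The lineage-production
rate assigns each inter-branching interval (k lineages, duration dt) the
value 1/(k·dt) — the inverse of the branch length laid down — at the interval
midpoint.  Individual points have a heavy upper tail (dt is exponential), so
the smoothed track computes events per unit branch length within a centred
age window (the local maximum-likelihood rate, equivalently a harmonic-style
average of the raw points; window truncated at the data range; whether such
smoothing should be centred or trailing is a free choice and centred was
adopted).  Naive origin
extrapolation fits log(count) against age over a window defaulting to the
middle 60% of the age span — wide enough for a stable slope, while avoiding
both the root-adjacent bulge and the near-present flattening — and solves for
one lineage.

## The experiments (`experiments`)

`run_bias_experiment` wires the pipeline per condition and replicate:
conditioned tree → alignment → MCMC → posterior summaries, with every seed
spawned deterministically from a master seed (`numpy.random.SeedSequence`),
so identical configs give identical summaries.  The canonical grid holds
N = 200 tips and T = 100 Myr fixed and varies the birth rate so that 200
species is α ∈ {0.1, 0.2, 0.5, 1, 2, 3, 5, 10} times the expectation
2e^(λT): λ = 0.0691, 0.0621, 0.0530, 0.0461, 0.0391, 0.0351, 0.0300, 0.0230
(4 d.p.).  `naive_expected_height` returns T + ln(α)/d, the pure
size-extrapolation answer.  Rescaling simulation Myr to absolute Ma is
presentation only (the process is scale-free): ×545/100 maps the true origin
to 545 Ma.

`run_sensitivity_experiment` simulates one clade and re-dates it at several
alignment lengths; with more sites the likelihood increasingly overrules the
tree prior and the inferred height of an oversized clade relaxes toward the
truth — slowly, because the deep branches are saturated.

## Problem sizes and tolerances

Chains default to 5×10⁵ steps thinned to 2000 samples with 10% burn-in,
which yields root-height ESS comfortably above 200 on the 200-tip problems;
a production-scale 2×10⁷-step run is a config change (`MCMCConfig(n_steps=...)`),
not a code change.  The acceptance script uses 10 replicates per dating
condition; the test suite uses 3–8 replicates at 2.5×10⁵ steps.  Between-tree
variability dominates between-chain variability (posterior-mean root heights
vary with sd ≈ 9 Myr across 1× trees, against a within-chain standard error
below 1 Myr), so replicate counts, not chain lengths, set the precision of
the reported means.

## What the generator does and does not emulate

The synthetic data are exactly the model the sampler assumes: ultrametric
trees, a strict clock at a known rate, JC substitution, no rate variation,
no missing data, and the true topology given to the sampler.  Passing tests
therefore demonstrate the *selection* bias in its pure form — a correctly
specified analysis mis-dating clades chosen for their size — and say nothing
about the additional (typically inflating) effects of relaxed clocks,
calibration densities, topology uncertainty, or model misspecification on
real data.

## Known limitations

* Only Yule (no-extinction) generation is supported for the conditioned
  trees; with extinction the conditioned branching-age law changes.
* The clock rate is never estimated; in real analyses rate–time confounding
  widens everything.
* ESS is computed per scalar parameter (root height, birth rate); no
  multivariate diagnostics.
* The sampler's node-age moves are single-node slides plus whole-tree
  scales; for trees far larger than ~10³ tips a mixing-oriented operator set
  would be needed.
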