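# Methods

`dfdm` detects data faults in multivariate physiological sensor streams in
three stages: a density-based outlier gate over whole reading vectors, a
fuzzy regression that predicts a plausible range for each suspected
reading, and a position-based judgment that separates sensor faults from
genuine patient-state changes. This note records the model, the defaults,
and the design choices made where the design was genuinely open.

## Stage 1 — mean-k-distance LOF (D-LOF)

Each reading vector X_j = (X_j1 … X_jn) is a point in n-dimensional space.
The classical local outlier factor compares a point's local reachability
density with that of its k-distance neighbours. This package uses a
modified neighbourhood: the **mk-distance** of a point is the *mean*
distance to its k nearest neighbours, and the working neighbourhood N_mk
contains only the points within that mean. Since the mean never exceeds
the k-th neighbour distance, N_mk ⊆ N_k and the score reacts more sharply
to isolated points. Reachability distance, lrd and LOF then follow the
standard construction with mk-distance in place of k-distance:

    reach(s, o) = max(mk-distance(o), d(s, o))
    lrd(s)      = 1 / mean_{o ∈ N_mk(s)} reach(s, o)
    LOF(s)      = mean_{o ∈ N_mk(s)} lrd(o) / lrd(s)

A vector is outlying when LOF > 2.0 (an empirical cutoff; LOF of inliers
fluctuates around 1). `variant="original"` switches every occurrence of
mk-distance back to k-distance, giving the classical LOF for comparisons.

**Distance and standardization.** Physiological attributes have
incommensurable units, so distances are Euclidean after per-attribute
standardization (subtract mean, divide by standard deviation of the
knowledge base). The standardization parameters are frozen when the base
is fitted and reused for every insertion; 2-D point-set benchmarks run
unstandardized.

**Ties and duplicates.** The k-distance is tie-inclusive: every point at
exactly the k-distance radius belongs to N_k, so neighbourhoods may exceed
k. Coincident duplicates would give a zero mean reachability; the mean is
floored at 1e-12, so duplicate piles get a very large lrd and LOF ≈ 1
among themselves rather than a division error.

**Incremental insertion.** Inserting a point p refreshes caches only for
three tiers of influenced points: F1 (points whose k-distance ball
contains p, plus p itself — neighbourhoods, mk-distance, lrd and LOF all
change), F2 (points outside F1 whose mk-neighbourhood contains a member of
F1 — lrd and LOF change), and F3 (points outside F1 ∪ F2 whose
mk-neighbourhood contains a member of F2 — only LOF changes). The
neighbourhood update distinguishes the three insertion situations (p on
the k-distance circle; strictly inside with ties holding the radius;
strictly inside with exactly k−1 interior points, which evicts the
boundary neighbours and shrinks the radius); all three are realized
exactly by re-deriving N_k from the old neighbourhood plus p, because no
point outside the old N_k can enter. This truncation is *exact*, not an
approximation: a point whose mk-neighbourhood contains no influenced
member keeps identical lrd (any point with an F1 member in its
mk-neighbourhood is in F2 by definition) and identical LOF, and the test
suite asserts a zero residual outside the tiers after every insertion.
A configurable size cap with oldest-first retirement and full batch
refresh is provided for long streams.

**Neighbour search** is exact (scikit-learn `NearestNeighbors` with a
tie-resolution buffer and full-scan fallback); approximate search is out of
scope because the acceptance tests require exact neighbour sets.

## Stage 2 — trapezoidal fuzzy linear regression

A trapezoidal fuzzy number (a, b, l, r) has membership 1 on the core
[a, b], linear shoulders of widths l and r, support [a−l, b+r], and crisp
expectation E = (2a + 2b − l + r)/4. The regression model

    Y~_j = A~_0 + A~_1 x_j1 + … + A~_n x_jn

has trapezoidal coefficients; the predicted core bounds are linear in x
and the predicted spreads are linear in |x|.

**Fuzzification of the outputs.** Training data are u within-period
instants observed over m historical periods ("sample groups", the stream
being cyclical). Per instant the core bounds are the minimum and maximum
of the m group values; the spreads are left to the optimizer. The most
recent group supplies the crisp regressors and the crisp targets Y_jm of
the error statistic

    R = Σ_j ((E[Y~_jm] − Y_jm) / Y_jm)²,

a relative error, which is why attributes whose observed values can be
zero must be shifted or rescaled first (the code raises a configuration
error). Whether Y_jm should be a held-out observation or a crisp
prediction is ambiguous in the formulation; it is interpreted here as the
observed value of the most recent group.

**Constraints and penalty.** The core must match the fuzzified envelope
(equality residuals h) and the prediction must contain the observation
with membership at least the fitting degree λ_j (inequalities g). The
constrained program is folded into the exact penalty R + Σ|h| +
Σ|min(0, g)|, which equals R exactly at feasible points. λ_j defaults to a
linear ramp from 0.5 (oldest instant) to 0.9 (most recent), encoding that
readings closer to the prediction instant matter more; it is fully
configurable and independent of the judgment-stage λ.

**Spread parsimony.** The statistic R depends on the spreads only through
r − l, so inflating both spreads symmetrically is objective-neutral — the
formulation as written does not identify the spread scale, and an
unconstrained search drifts to supports wide enough to swallow any fault.
Following the possibilistic-regression convention (minimal fuzziness
subject to containment), the *search* objective adds a small parsimony
term, 1e-3 × mean predicted spread relative to the output scale; reported
penalty values exclude it, so the feasible-point identity above is
preserved. Spread-coefficient bounds are additionally scaled so the total
support width stays on the data scale.

**Optimizer.** A seeded real-coded genetic algorithm, fully vectorized
over the population: tournament selection (size 3), blend crossover with
mild extrapolation (rate 0.9), Gaussian mutation (rate 0.1) with step size
annealed from 0.1 to 1e-4 of the bound width, one elite, population 100,
300 generations. The initial population is seeded with informed
individuals (least-squares fits of the min/max envelopes), and the winner
is polished by a bounded Powell pass followed by a Nelder–Mead pass on the
same non-smooth objective (a memetic step; the landscape has L1 ridges
where direction-set search stalls). Fits are deterministic for a fixed
seed. Core bounds are centred on the crisp OLS solution ± 3 residual
standard deviations (scaled by regressor spread); a ≤ b is enforced by
bounds plus swap-repair, and spreads are floored at 1e-6 to honour strict
positivity. An exhaustive grid search (5 levels per parameter, polished)
is shipped as an independent reference solver for n = 1 instances.

**Baselines.** `model="triangle"` collapses the core (b = a), giving the
triangular-fuzzy-number regression; `fit_slr` is ordinary least squares.
All three report the same relative-error statistic. Note that both fuzzy
models tune E through r − l, so their achieved R coincide to optimizer
precision; the trapezoid's real advantage is feasibility (a single-peak
core cannot match the min/max envelope equalities), visible in the penalty
value.

## Stage 3 — 15-case fault judgment

The λ-level cuts of the prediction, a_λ = a − (1−λ)l and b_λ = b + (1−λ)r
(with 0.5 < λ < 1, default 0.8), together with the support bounds, divide
the reading axis into five regions. Interleaving the normal interval
(low, high) with these four breakpoints yields exactly 15 cases — each
endpoint falls into one of five regions with low ≤ high — and across all
15 the verdict reduces to:

* reading in the λ-core → **good**;
* reading on a shoulder → **undecided**;
* reading below the support → **fault**, unless it is above `high`
  (then undecided);
* reading above the support → **fault**, unless it is below `low`
  (then undecided).

The full case table follows from these four rules; it is mirror-symmetric
(reflecting trapezoid, interval and reading about any point maps each case
onto its mirror case, which a reflection property test verifies), and it
implies the two global guarantees: a reading the model endorses at level λ
is good, and a reading beyond max(b+r, high) or below min(a−l, low) is
faulty. A subtlety worth stating: when the whole prediction sits beyond
the normal interval, a reading *inside* the normal interval is judged
faulty — the model and the interval cannot both be right about that
reading, and the model was fitted on the reliable sensors.
Boundary equalities are
resolved fault-aversely: each breakpoint belongs to the neighbouring
region with the less severe verdict, and interval bounds are inclusive.

Undecided verdicts encode out-of-sync physiology (the predictors may lag
the suspected attribute). A sensor whose undecided state persists for
`persistence` consecutive rounds (default 3; a good round resets the
streak) is promoted to faulty.

## Pipeline

The first `warmup` instants (default m·period + u) form the initial
knowledge base and are all considered normal. Per streamed instant: the
vector is inserted into the base; if not outlying, every sensor is good
and the vector stays. An outlying vector is rolled back out of the base
(the base keeps only vectors deemed normal) and its readings are split by
the per-attribute normal intervals — defaults HR (50, 130) bpm,
RR (10, 30) /min, BT (36, 38.5) °C, SpO2 (89, 100.5) %, GLU (3.9, 7.8)
mmol/L, systolic BP (90, 140) mmHg. If every reading falls on one side,
the excursion is coherent and is attributed to a patient-state change (no
sensor blamed). Otherwise the larger set is the reliable regressor set —
ties favour the physiologically normal side, normal readings being the
more trustworthy regressors — and each member of the smaller set is
regressed (independently, on the full reliable set) and judged. Sample
groups are the same within-period instants of the m most recent periods.
The alarm filter suppresses an alarm instant only when every
interval-violating reading at that instant belongs to a sensor classified
faulty.

## Synthetic data

The simulator emulates a monitored adult: HR cycles around 85 ± 20 bpm
inside 40–140; RR = 20 + 0.2·(HR − 85) plus noise; BT stable at 37 ± 0.2
°C; SpO2 in 90–100 with rare dips below 90 (probability 5e-3 per instant,
configurable); glucose and systolic pressure cycle gently around 5.5
mmol/L and 115 mmHg. A body-temperature excursion of +1 °C raises HR by
the coupling gain (default 12, range 10–15 bpm/°C). Illness episodes
shift the attributes with per-attribute onset lags (HR immediately, RR one
instant later, BT after five) and ramped profiles, so no instant shows a
synchronized anomaly. Hard physical ranges are clipped and logged.

Fault injection is a design choice (the failure taxonomy is not specified
upstream): stuck-at, offset, spike and drift, with magnitudes in units of
the attribute's stream standard deviation; the benchmark default is
6-sigma spikes at a 5% cell rate. Ground-truth labels are the exact
cell-wise difference mask between clean and faulted matrices.

The planted-outlier generator draws Gaussian clusters (σ = 1) on a widely
spaced grid of centres and places each outlier uniformly in an annular
shell 10–25 cluster radii (radius = maximum inlier distance to its centre)
around a centre, with planted points kept mutually separated by ≥ 27
cluster radii. The separation is deliberate: density-ratio detectors
score a point against its neighbours, so a clump of mutually close
planted points is an *outlying cluster*, which LOF-family methods are not
designed to find; the benchmark therefore plants isolated gross outliers,
matching the near-perfect published detection rates. The number of
centres grows with the outlier count so the shells can host all planted
points in isolation.

**What the simulator does not model:** real sensor noise spectra,
measurement quantization, missing samples, inter-patient variability,
circadian asymmetry, or correlated multi-sensor failures. Passing
benchmarks certify the mechanism on this generator's statistical
structure, not clinical performance.

## Benchmark problem sizes

Benchmarks run at reduced sizes chosen so the full suite completes on one
CPU in minutes, keeping the detector settings and outlier geometry of the
published experiments: the incremental planted-outlier run uses 2×10^4
points (15 outliers, k = 10, 83%/17% batch/stream split); the k = 20 run
uses 2×10^4 points with 40 outliers over 20 seeds; the k = 40 run uses
5×10^4 points with 115 outliers over 10 seeds; the end-to-end benchmark
uses six attributes, 520-instant streams (period 50, u = 8, m = 4, warmup
208), ~5% spike faults and one illness episode per stream, over 20 seeds.
In-pipeline regression fits use the GA without the polish stage
(population 40, 60 generations); standalone fits default to the full
memetic configuration.

## Known limitations

* Stuck-at or small-offset faults that stay inside both the knowledge
  base's density support and the normal interval are undetectable by
  construction (the gate never fires, or the partition attributes the
  vector to a patient-state change); the end-to-end fault recall is
  therefore dominated by whether a fault exits its normal interval.
* Illness onsets can raise brief false alarms before the lagging
  attributes catch up; the undecided state and its persistence rule bound
  but do not eliminate this.
* The regression assumes the reliable set actually predicts the suspected
  attribute within a period-stationary cycle; abrupt regime changes
  violate this.
* Deletion or update of knowledge-base points is out of scope (insertion
  only), as are approximate neighbour search and learned per-patient
  intervals.
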