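# Methods

## Model

`jumpcount` quantifies the sampling uncertainty of equilibrium constants and
free energy differences estimated from molecular-simulation trajectories, using
nothing but the numbers of observed transitions between two states and the
temperature.

For a reversible two-state process A ⇌ B with Markovian kinetics, the
first-passage times out of each state are exponential with rates k₁ (A→B) and
k₋₁ (B→A). The maximum-likelihood rate estimates are counts over total dwell
time, k̂₁ = n_A/Σtₐ and k̂₋₁ = n_B/Σt_B, and the equilibrium constant is
estimated as

    K̂ = k̂₁ / k̂₋₁ = (n_A · Σt_B) / (n_B · Σtₐ),      ΔĜ = −kT ln K̂.

Because Σtₐ ~ Gamma(n_A, k₁) and Σt_B ~ Gamma(n_B, k₋₁) are independent, the
pivot K̂/K follows an F-distribution with degrees of freedom d₁ = 2n_B and
d₂ = 2n_A. This gives an **exact**, equal-tailed confidence interval for any
number of transitions:

    K  ∈ [ K̂ / qF_{d₁,d₂}(1−α/2),  K̂ / qF_{d₁,d₂}(α/2) ]
    ΔG ∈ [ ΔĜ + kT ln qF_{d₁,d₂}(α/2),  ΔĜ + kT ln qF_{d₁,d₂}(1−α/2) ]

The interval width depends only on (n_A, n_B, T, α). At 300 K and 95%:
±2.18 kcal/mol for n_A = n_B = 1, ±1.35 for 2, and ±0.89 — already below the
common 1 kcal/mol accuracy threshold — for 4 transitions each way.

Since ln K̂ − ln K is a difference of two independent log-gamma variates, its
variance is a trigamma sum, giving the standard error

    SE(ΔĜ) = kT · sqrt( ψ⁽¹⁾(n_A) + ψ⁽¹⁾(n_B) ).

For chained states (A ⇌ B ⇌ C) per-step standard errors combine as a root sum
of squares; this is exact only for normal estimates and therefore an
approximation that improves with the transition counts.

### Assumptions

* Clearly distinguishable states separated by a barrier; labels supplied by
  the user (state assignment from collective variables is out of scope).
* Markovian inter-state kinetics — exponential passage times. The
  `exponentiality_test` (Kolmogorov–Smirnov against the fitted exponential)
  probes this, but its power is low: with few transitions it neither rejects
  nor confirms Markovianity, and because the rate is fitted from the same
  sample the plain p-value is conservative (a parametric-bootstrap p-value is
  available).
* The trajectory is sampled finely enough that no transition is missed between
  frames.

## Conventions and parameters

* **Sign/log convention.** K = [B]/[A] = k₁/k₋₁ and ΔG(A→B) = −kT ln K, natural
  logarithm everywhere. Only this convention reproduces the 2.18 and
  1.35 kcal/mol reference widths.
* **Boltzmann constant.** 0.0019872041 kcal·mol⁻¹·K⁻¹ and
  0.0083144626 kJ·mol⁻¹·K⁻¹; default unit kcal/mol, default T = 300 K,
  default level 0.95; the unit "kT" makes energies dimensionless.
* **Tails.** Equal-tailed intervals (α/2 per side).
* **Counts.** The closed-form designs are n_A = n_B (trajectory returns to the
  start state) and n_A = n_B + 1 (start state A, asymmetric interval). The same
  formulas are evaluated for any positive pair, but results with
  |n_A − n_B| > 1 are flagged `design: extrapolated` in the metadata.
* **Zero counts.** No interval exists without at least one transition each
  way; a structured `InsufficientTransitions` record (not NaN) is returned.

## Trajectory counting

Only *accomplished* transitions count. For a state pair (a, b) all other
labels are transparent: an accomplished a→b transition is the first entry into
b after the most recent entry into a, and its passage time includes time spent
in intermediate states (so A→B→A→B→C is one accomplished A→C transition).
On the sampled grid a state change between frames i and i+1 is placed at the
time stamp of frame i+1; at the resolution required by the no-missed-transition
assumption, sub-frame placement is immaterial, but the convention is fixed.
Time before the first entry into {a, b} and after the last accomplished
transition is credited to neither state. `balance_counts` relabels so that the
start state is A and reports whether the equal or the asymmetric (n_A = n_B + 1)
convention applies.

## Censored ensembles

For the independent-simulation design (n runs from A until they reach B, and
vice versa), runs stopped at t_max without a transition are right-censored.
Discarding them biases the rate upward — with nine of ten runs censored the
naive estimate can be off by an order of magnitude. The right-censored
exponential MLE keeps their elapsed time in the denominator:

    k̂₁ = n_A / ( Σᵢ t_{A,i} + Σⱼ t_max,j ).

Per-run censoring times may differ; the general likelihood simply sums them.
With no observed transition only an upper bound on the rate exists, and the
error message reports it. K̂ and ΔĜ use the censored totals automatically.

## Binding

For PL ⇌ P + L, K_d = c_L · Σt_P / Σt_PL with c_L the free-ligand
concentration in the box (helper: c_L = 1/(N_A·V_box) for a single ligand).
K_d inherits the F-distribution interval through the dwell-time ratio; the
interval is exact for the alternating design with equal bound/unbound counts.
The binding free energy is reported as kT ln K_d in the units of c_L, with no
standard-state correction applied — if c_L is in mol/L the value is relative
to a 1 M reference.

## Monte Carlo validation

Two experiments verify the closed forms end to end:

* **Type-I-error grid** (`type1_error_grid`): for each n_A = n_B in 1..20 and
  K in {1, 10, 100, 1000} (k₋₁ = 1, k₁ = K), 10,000 replicate sets of
  exponential passage times are generated and the fraction of replicates whose
  95% CI excludes the true K is recorded. For an exact interval every cell
  sits at 5% up to binomial noise (SD ≈ 0.22 pp at 10,000 replicates); the
  acceptance check allows the handful of ~3-SD excursions expected among 80
  simultaneous cells. The asymmetric n_A = n_B + 1 design is validated the
  same way. The default K grid {1, 10, 100, 1000} spans the 1–1000 range
  log-uniformly and is configurable.
* **SE agreement** (`se_agreement_study`): the trigamma formula against the
  standard deviation of 10,000 simulated ΔĜ values; relative deviation is
  below 5% for all tested (n_A, n_B), shrinking toward zero as replicates grow.

For speed the replicate dwell-time *sums* are drawn directly from the Gamma
distribution (the exact law of a sum of exponentials); the per-time generator
`sample_passage_times` draws individual exponentials and is itself tested for
gamma-sum agreement, so the shortcut changes nothing statistically.

The synthetic trajectory generator (`simulate_markov_trajectory`) samples a
continuous-time Markov chain on a uniform grid using the exact per-frame
transition matrix expm(Q·dt) and warns when dt·max_rate > 0.1, where
inter-frame transitions would be missed. Synthetic data are ideal-Markovian by
construction: passing validation shows the statistics are exact under the
model's assumptions, not that any particular molecular system satisfies them
(non-Markovian coarse-grained states, hidden intermediates and discretisation
error in real trajectories are outside what these tests can show).

## Numerical choices

* F quantiles via `scipy.stats.f.ppf`; tests cross-check against an
  independent brute-force oracle (numerical integration of the density plus
  bisection) to 1e-8 relative tolerance.
* Trigamma via `scipy.special.polygamma(1, ·)`; the n = 1 case has the closed
  form kT·π/√3 used as a test anchor.
* RNG: `numpy.random.default_rng` (PCG64); every stochastic study takes an
  explicit seed and records it in its result.
* All validation studies are reproducible from (config, seed); study sizes
  default to 10,000 replicates per cell.

## Known limitations

* Re-analyses of the glycerol conformer equilibria and of the D.E. Shaw
  fast-folding miniprotein trajectories require those external datasets and
  are not reproduced here; the trajectory module supports such analyses when a
  user supplies labelled state series.
* No treatment of time-dependent bias potentials (e.g. metadynamics); static
  bias such as single-replica umbrella sampling is compatible in principle.
* No autocorrelation/block-averaging error estimators and no Bayesian or
  bootstrap intervals — the F-interval replaces, not complements, them here.
* State discretisation and Markov-state-model construction are out of scope.
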