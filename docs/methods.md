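# Methods

## The task and the generative model

The package models a two-display orientation change-detection task. Each
trial shows four oriented items twice. Between displays, with probability
`p = 0.5`, exactly one item (uniformly chosen) changes orientation by an
amount drawn uniformly from the orientation circle. Item reliability (a
stimulus property such as ellipse elongation) is binary: the number of
high-reliability items `N_H` is uniform on {0..4} and their positions are
uniform given `N_H`. The observer reports "change" or "no change".

Physical orientations live on `[-90, 90)` degrees. Internally every
orientation is doubled onto `[-pi, pi)` radians so that standard circular
machinery applies; files always store physical degrees.

### Encoding

The measurement `x` of an orientation `theta` is Von Mises,
`x ~ VM(theta, kappa)`. Precision is defined as the Fisher information of
the measurement,

    J(kappa) = kappa * I1(kappa) / I0(kappa),

a strictly increasing bijection with `J(0) = 0` and `J(kappa) < kappa`
(`I0`, `I1`: modified Bessel functions of the first kind). Under **equal
precision (EP)** an item's `J` is fixed by its reliability (`J_low`,
`J_high`). Under **variable precision (VP)** the precision itself is a
random variable, `J ~ Gamma(mean = Jbar_reliability, scale = tau)`,
independent across items, displays and trials; the marginal measurement
distribution is then a gamma mixture of Von Mises densities (a circular
analog of Student's t). Draws with `J -> 0` are legal and give a uniform
measurement; the gamma is never truncated.

The inverse map `kappa(J)` has no closed form; scalars are solved by
bracketed root finding in `(J, J+2)` (the bracket is valid because
`kappa - 1 < J(kappa) < kappa`), arrays by a cached monotone log-log
interpolation polished with Newton steps. The round-trip contract is
relative error below 1e-9 over `J` in `[1e-3, 500]` and is tested.

### Decision stage

Writing `x_i, y_i` for the two measurements of item `i` and
`kx_i, ky_i` for the concentrations the observer *assumes*, the local
evidence for a change at location `i` is the likelihood ratio

    d_i = I0(kx_i) I0(ky_i) / I0(kc_i),
    kc_i = sqrt(kx_i^2 + ky_i^2 + 2 kx_i ky_i cos(x_i - y_i)),

obtained by marginalizing the location's generative model over the unknown
orientation (and, in the change branch, the uniform change magnitude). This
closed form was verified against brute-force 2-D trapezoid marginalization
(relative error < 1e-13 over random configurations up to `kappa ~ 100`); the
test suite re-checks it to 1e-4 over 100 random configurations.

The **optimal rule** reports change when
`p/(1-p) * mean_i(d_i) > 1`; the **Max rule** reports change when
`max_i d_i > k` for a constant criterion `k`. Ties go to "no change"
(a measure-zero event kept deterministic for testability). The criterion is
applied on the ratio scale of `d_i`; its search range `[-2.2, 51.8]` is kept
verbatim (values `k <= 0` always report change), and fits that pin `k` at a
range boundary raise a warning rather than silently extending the range.

Four assumptions about precision define what `kx, ky` are: **V** the actual
realized values (requires VP encoding to differ from E); **E** the
reliability-determined value; **A** the mean realized precision of each
display (a "gist" of precision, averaged over the display's four items,
separately per display — precision means `J`, so `J` values are averaged and
then mapped to `kappa`); **S** one fixed `J_assumed` for everything.
Crossing encoding (E/V), assumption (V/E/A/S; V=E under EP) and rule (O/M)
gives the 14-model taxonomy. Under the S assumption with the Max rule,
thresholding `max_i d_i` is equivalent to thresholding the maximum absolute
circular difference `max_i |x_i - y_i|`, so `J_assumed` is not identifiable
and is dropped as a free parameter (VSM has 4 parameters, ESM 3); the
implementation fixes a reference `J_assumed = 8` - the scale of typical
encoding precisions here - which maps the verbatim criterion range onto
non-degenerate operating points. Two decision-noise control variants of EEO
add zero-mean Gaussian noise of s.d. sigma either to each `log d_i`
("local") or once to the log of the integrated quantity ("global").

## Monte-Carlo likelihoods

A model's report probability depends on a trial only through its type: the
change magnitude binned to the nearest multiple of 3 degrees (bins
0, 3, ..., 90), `N_H`, and the changed item's reliability - a
`31 * 5 * 2 = 310`-cell space. No-change trials are assigned the
(bin 0, `N_H`, low) cell, which is predicted by simulating genuine
no-change trials; 61 cells (e.g. a high-reliability change with `N_H = 0`)
are unreachable by the design, carry NaN predictions, and are never touched
by the likelihood. Per type the engine simulates `n_samples` percepts
(default 1000), applies the decision rule, and estimates the report
probability with the add-half estimator `(count + 1/2)/(n + 1)` - removing
the leading-order bias of plugging a raw frequency into a log-likelihood -
clipped to `[eps, 1-eps]`, `eps = 1/(2 n_samples)`, so log-likelihoods stay
finite. The dataset log-likelihood is the sum of `log p` / `log(1-p)` over
trials via per-cell counts.

Three engine design points matter for accuracy and speed:

* **Exchangeability.** Items are exchangeable given reliability labels, so
  each (`N_H`, changed-reliability) stratum is simulated once with a
  canonical location assignment, and the measurement-noise draws are shared
  across the 31 magnitude bins (the magnitude only offsets the changed
  item's measurement difference). This is distribution-identical to
  redrawing the nuisance configuration per sample and cuts the draw count
  by ~20x.
* **Common random numbers.** Each stratum draws one set of base
  standard-normal quantiles keyed by (seed, stratum); every parameter point
  pushes the same base draws through gamma and Von Mises quantile tables.
  The Monte-Carlo likelihood surface is therefore a smooth deterministic
  function of the parameters for a given seed, which keeps grid arg-maxes
  stable. Measurement-noise quantiles are drawn before the VP precision
  quantiles so EP and VP candidates share identical measurement noise.
* **Lookup tables.** The engine evaluates `log I0`, `kappa(J)` and the
  gamma/Von Mises quantile transforms by dense-table interpolation
  (relative error ~1e-7, far below Monte-Carlo resolution; base quantiles
  clamped at +-6, a 1e-9 tail). The public API functions always use exact
  scipy paths; tables are engine-internal.

Grid fitting (`fit_mle`) evaluates the likelihood exhaustively on a linear
grid with common random numbers and returns the first arg-max. Axis
resolution follows per-axis cost: VP means, `tau` and `J_assumed` require
fresh simulation or decision-variable passes per point and get
`points_per_dim` points (default 15); the decision thresholds (`p_change`,
`k`, noise sigmas) are swept over precomputed statistics at negligible cost,
and the EP precisions are deterministic percept transforms, so these axes
default to the nested 4x ladder (`4 * points_per_dim - 3`). The finer
criterion ladder matters: behaviorally distinct (liberal) criteria occupy a
narrow slice of `[-2.2, 51.8]`, and a coarse ladder leaves the whole
informative region inside one cell.

## Bayesian model comparison

Model evidence uses a uniform prior over each parameter's range (`J`-type
parameters `[1, 100]`; `p_change` `[0.3, 0.7]`; `k` `[-2.2, 51.8]`; `tau`
`[1, 30]` - the `tau` range is a package default, echoed in all run
metadata, because no authoritative value is available). The marginal
likelihood is a Riemann sum over the grid; with the grid spanning the full
range this reduces to the grid mean of the likelihood, computed stably as
`logsumexp(log L) - log(n_points)`. A naive (unstabilized) reference path
exists for testing; the two agree to 1e-10 whenever the naive sum does not
underflow. Results are reported in natural-log units as differences against
a named reference model.

`recovery_harness` simulates a dataset from every model at representative
parameters and lets all models compete on every dataset. Prediction tables
over a candidate's grid do not depend on the data, so they are built once
per candidate and reused across all 14 datasets.

## Representative observers (the synthetic study conditions)

`representative_params` fixes one parameter point per model, used for all
recovery checks and examples. The choices, made once:

* Every value lies on the model's own default fitting lattice, so the
  generating model can represent itself in recovery checks.
* EP precisions `J_low = 4.54`, `J_high = 11.61`: with
  `J_high ~ 11.6` the largest local log decision variables reach ~20, the
  top of the range seen in fits of the behavioral data, and simulated hit
  and false-alarm rates land in the observed bands (hits ~0.5-0.8 rising
  with `N_H`, false alarms ~0.1-0.25).
* VP means `Jbar_low = 15.14`, `Jbar_high = 29.29` (the lowest
  non-degenerate points of the coarser VP lattice) with `tau = 13.43`,
  giving gamma shape ~1.1 for low-reliability items - the
  strong-variability regime the VP hypothesis describes.
* `p_change = 0.5` (the true design prior), `J_assumed = 15.14`
  (a mid-range single assumed precision).
* Max-rule criteria: for each model, the lattice criterion whose mean
  false-alarm rate is closest to 0.15, the center of the behaviorally
  observed band. A very conservative criterion drives false alarms toward
  zero, where the Max rule is behaviorally indistinguishable from optimal
  integration and recovery is uninformative.
* Decision-noise sigmas 0.34 (local) and 0.30 (global), the scale reported
  for the fitted noise controls.

## What the recovery checks show (and their limits)

At the scale used in the validation harness (2,000 trials per dataset,
`n_samples = 500`, reduced grids), parameter recovery for EEO and VVO is
exact to within one grid step, and most generating models win their own
data outright (8-11 of 14 across harness seeds; structurally distinct pairs
separate by tens to hundreds of log points). The confusions are instructive
rather than accidental: they occur between optimal/Max "twin" pairs and
within-family assumption pairs whose expected evidence difference at 2,000
trials is about 1-3 natural-log units - smaller than dataset-to-dataset and
Monte-Carlo fluctuation, so which twin wins is close to a coin flip (some
misses flip back to the generating model when the Monte-Carlo resolution is
raised). Distinguishing those pairs reliably needs more trials, finer
grids, or larger Monte-Carlo budgets than the scaled-down harness uses.

## What the synthetic generator does and does not emulate

The generator reproduces the task's statistical design exactly (reliability
counts, uniform orientations and change magnitudes, 50% change rate) and
produces responses from exactly specified observers. It does not emulate
lapses, response bias drift, learning or fatigue, finite display geometry,
or inter-subject heterogeneity. Passing recovery checks therefore show that
the fitting and comparison machinery is correct and that the models are
(mostly) mutually identifiable under ideal conditions - not that real
observers satisfy any model's assumptions.

## Numerical conventions

* All circular arithmetic in internal doubled space; conversion only at I/O
  boundaries. Trial tables round-trip bit-identically through CSV.
* `classify_trial` bins `|delta|` to the nearest multiple of 3 degrees
  (half-ties round up); the 8-bin psychometric summaries are a
  presentation-level view over equal-width bins on `(0, 90]`.
* Summary cells with no trials are NaN, never zero; the unconditioned hit
  rate equals the count-weighted mixture of the conditioned rates exactly.
* Response simulation draws a counter-based stream per trial keyed by
  (seed, trial id): no hidden state between trials, and permuting a trial
  table permutes the responses identically.
* Every stochastic entry point takes an explicit seed or Generator; run
  metadata records seeds, grids, sample counts and the `tau` range.
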