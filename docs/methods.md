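# Methods

This note records the statistical model behind `erp-select`, the conventions
chosen where the construction leaves genuine freedom, and what the bundled
simulations do and do not demonstrate.

## Model and estimation

For a single variable measured on `N0` control and `N1` experimental
subjects, the upward rule with threshold `c` classifies a subject as
experimental when its value exceeds `c`; its weighted combined error rate is
`er_up(c) = w0(1 − F0(c)) + w1 F1(c)` with misclassification costs
`w0 + w1 = 1`. The downward rule reverses the comparison, and pointwise
`er_up(c) + er_down(c) = 1`. The empirical error rate replaces the CDFs by
group counts; it is a step function of `c` changing only at distinct data
values, so the exact minimiser is found by evaluating:

* the midpoints between consecutive **distinct** sorted values (duplicates
  collapse — the step function cannot change inside a tie group), and
* two **sentinel thresholds** at `min − g` and `max + g`, `g` being the
  median gap between consecutive distinct values (1.0 when all values
  coincide). These represent the degenerate classify-everyone-one-way rules
  and guarantee the bound `er* ≤ min(w0, w1)`; a constant variable therefore
  yields `er* = min(w0, w1)` rather than an error.

Tie-breaks: when several candidate thresholds achieve the minimum, the
smallest is returned (deterministic and reproducible). In direction-free
mode (`mode="min"`) the up- and down-minima are compared as computed floats
with no tolerance, and an exact tie resolves to `down`. Both curves are
computed directly in the lattice form `w0·j/N0 + w1·k/N1` (never as
`1 − er_up`), so equal lattice values are bit-identical across directions —
this matters for tie detection and for the up/down distributional symmetry.

Because the minimised statistic depends on the data only through the labels
of the ranked observations, any strictly increasing transform of the data
leaves `er*` and the chosen direction unchanged (the threshold moves to the
corresponding midpoint of the transformed scale, separating the same
subjects). That rank-invariance is the operational content of the method's
non-parametricity and is enforced by property tests.

## Null distribution and p-values

Under `H0: F0 = F1` (continuous) the probability integral transform reduces
the statistic's null law to the uniform case, so it depends only on
`(N0, N1, w0, w1, mode)`. The package simulates it directly: draw `N`
iid Uniform(0,1) variates, label the first `N0` as controls, minimise, and
repeat `M` times (default `M = 100,000`, default seed 20160114; draws are
memoised per key and can be persisted as CSV). The support is the finite
lattice `{w0·j/N0 + w1·k/N1}`.

Two tail-counting conventions coexist deliberately:

* **Inference p-value** (`NullDistribution.p_value`, used by the selection
  pipeline): `p = (1 + #{draws ≤ obs}) / (M + 1)`. Inclusive counting plus
  the add-one correction makes this a *valid* p-value on the discrete
  lattice — it can never be 0 and its simulated type-I error stays at or
  below the nominal level, which is what the FWER guarantee needs.
* **Raw tail fraction** (`NullDistribution.tail_fraction`, used by the power
  comparison): `#{draws < obs} / M`, the plain Monte-Carlo estimate of the
  strictly-below tail. It can reach 0 (e.g. at complete group separation)
  and slightly understates the inclusive tail on a lattice with large atoms.

The difference is `O(1/M)` for continuous statistics but not negligible on
the lattice: head-to-head p-value comparisons between statistics (below)
behave correctly only with the raw fraction, whereas inference needs the
valid version. A 1e-12 tolerance absorbs floating error when comparing
observed rates to lattice values.

The **critical error rate** at level α is the largest lattice value whose
(valid) p-value is at most α, or `None` when no value qualifies (possible
for tiny groups: with one subject per group even perfect separation has
p = 1/2). For `N0 = 21, N1 = 12` and `M = 10^6` this gives 0.2857 (equal
weights) and 0.2302 (weights 1/3–2/3) at α = 0.05, and 0.1786 at α = 0.001 —
the "surprisingly high error rates are still significant" phenomenon.
Strict counting would report the next lattice step up (0.2976 / 0.2460);
both readings are within one lattice step of each other.

## Selection across variables

All variables of a dataset share one simulated null (same group sizes and
weights), so p-values are a monotone function of the error rates and the
ranked table inherits its order. FWER control is Holm's step-down with a
tie rule: variables with exactly equal error rates (equal as lattice floats,
not merely equal Monte-Carlo p-values) form a group that succeeds or fails
as a whole, held to the group's most conservative critical level. For
exactly tied p-values literal Holm cannot split a group anyway (its
thresholds grow along the step-down), so the rule is a safeguard that
becomes active only when tie-groups are defined on a coarser key than the
p-value — it keeps decisions invariant to column order and robust to
Monte-Carlo granularity. Other step-down corrections can be slotted in
behind the same `(p_values, alpha, tie_keys) → flags` interface; only Holm
ships.

Missing values are rejected by default. The optional complete-case mode
(`missing="drop"`) drops subjects per variable and re-simulates the null for
that variable's reduced `(N0, N1)` — necessary because the null law depends
on the group sizes; tie-groups then require equal error rate *and* equal
effective sizes.

## Classification of new subjects

Each selected variable votes through its own rule, with the boundary
convention "control if value ≤ threshold" under the upward rule (the exact
mirror for downward). The final label is the unweighted majority; an even
split resolves toward the costlier misclassification (experimental when
`w1 ≥ w0`). An optional scheme weights votes by `−log10 p` instead
(off by default). When true labels are supplied the report counts, per
subject, how many individual variables misvoted it; a subject is flagged as
a potential outlier when that count is at least `max(2, median + 3·MAD)`
**and** strictly above the median count. The second condition is our
refinement: without it a uniformly misvoted cohort (all counts equal) would
flag everyone, though an outlier is by definition relative to its cohort.
The cutoff is a conventional robust rule, exposed as configuration rather
than claimed optimal.

## Power study

The generator draws controls as `exp(Z)`, `Z ~ N(0,1)`, and experimental
subjects as `exp(Z + μ)` — an upward log-scale shift; downward alternatives
follow by the label-swap duality and are not separately simulated. Default
design: `N0 = 21, N1 = 12`, μ from 0 to 4 in steps of 0.2 (bracketing both
interesting crossovers with one-step resolution), 2,000 repetitions per grid
point (standard error of a proportion ≤ 0.011; the acceptance script uses
10,000), and one-million-draw null distributions. The null size matters
here: the comparisons happen deep in the left tail (median p-values around
10⁻⁴ at moderate shifts), where a 10⁵-draw null quantises the error-rate
p-values too coarsely and visibly shifts the proportion-better curves.

Per repetition three p-values are computed: `er*_up` and `er*_min` against
their nulls (raw tail fraction, see above) and the one-sided two-sample
Mann–Whitney test in the upward direction. The Mann–Whitney p-value uses
the normal approximation with continuity correction by default — the
convention of the mainstream statistical packages at these sample sizes,
and the regime in which the error-rate and rank-sum statistics are compared
on equal footing in the deep tail; `mw_method="exact"` is available (the
exact tail is noticeably heavier than the normal approximation out there,
which systematically flatters the rank-sum test in the head-to-head
proportion and pushes the apparent crossover about two grid steps higher).

Summaries per grid point: the mean p-value per statistic (expected power)
and the proportion of repetitions in which a competitor's p-value falls
below `er*_up`'s. The **crossover shift** is where the Mann–Whitney
proportion-better curve last crosses 50% downward. Two estimators are
provided: linear interpolation between the bracketing grid points (default —
the analogue of reading the crossing off a plotted curve, and stable when
the curve touches 0.5 exactly at a grid point) and the first grid point of
the sustained below-50% region. At the default design these land near
μ ≈ 1.6 for equal weights and μ ≈ 1.9–2.0 for weights (1/3, 2/3): knowing
the shift direction (`er*_up` vs `er*_min`) buys power at every shift, the
rank-sum test leads at small shifts, and the error-rate statistic catches up
from moderate shifts on — exactly the regime where a usable classification
threshold exists.

What the generator does *not* emulate: correlated variables (real spectra
are strongly correlated; FWER control is still valid but power statements
are per-variable), values below a detection limit, heteroscedastic or
non-log-normal noise, and batch structure. Passing tests therefore certify
the inferential machinery and the stated simulation claims, not performance
on any particular real dataset.

## Numerical and scale choices

* Error rates are accumulated in the form `w0·j/N0 + w1·k/N1` in double
  precision; for the bundled weight presets equal lattice rationals compare
  equal exactly often enough that tie detection is reliable; remaining
  1-ulp discrepancies are absorbed by the 1e-12 comparison tolerance.
* The batched minimiser used for simulation assumes continuous (tie-free)
  rows, which holds almost surely for the variates it serves; the
  per-variable path handles tied data via distinct-value collapsing.
* Test-suite problem sizes: nulls of 10³–10⁵ draws, a 100,000-draw null for
  the critical-value checks, power runs of 400–2,000 repetitions, FWER
  calibration with 55 variables × 500 null datasets. The acceptance script
  uses 10⁶-draw nulls and 10,000-repetition power runs. The full suite runs
  in well under a minute; the script in about one minute.
* Exhaustive enumeration of label arrangements (feasible up to 8+8) serves
  as the exact oracle for the simulated null in tests; a dense 10,000-point
  threshold grid serves as the oracle for the minimiser.

## Known limitations

Interactions between variables are out of scope (votes are per-variable);
no probability calibration is attempted for the majority vote; the
asymptotic approximation of the null CDF is not implemented (simulation is
cheap at these sizes); leave-one-out error-rate statistics are not
implemented.
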