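# Methods

## The process

The model is a discrete-step, two-layer Moran process. A closed layer
holds `K` master stem cells, one per clone label, each supplying a new
competitive cell at rate `epsilon`; an open layer holds exactly `N`
competitive stem cells that are lost to differentiation and replaced
by symmetric division (rate `lam` per cell) or by master-cell supply.
Each elementary step draws a loss clone with probability `n_k/N` and,
independently on the same pre-removal state, a compensation clone with
probability `(lam*n_k + epsilon)/(lam*N + epsilon*K)`; drawing the
same clone twice leaves the state unchanged. That independent-draw
scheme is the only one consistent with the single-clone kernel
`r_up(n) = q(n)(1 - n/N)`, `r_down(n) = (1 - q(n)) n/N` with
`q(n) = (epsilon + lam*n)/(epsilon*K + lam*N)`, which every analytic
module is built on. `N` is conserved exactly at every step and the
test suite asserts it on every recorded snapshot.

Competition is strictly neutral: no clone carries a fitness advantage,
no spatial structure, no transit-amplifying compartment, no
cell-intrinsic state. Time is the step count calibrated by the mean
replacement interval, `t = m/(lam*N + epsilon*K)`, so parameter sets
with different absolute rates share a clock. Only the ratio
`epsilon/lam` affects the embedded chain; `lam = 1` is the reference
scale throughout.

## Parameters

| parameter | meaning | default used in examples/tests |
|---|---|---|
| `K` | master stem cells = clone labels | 10 (burst regime), 50 (estimation), 420 (hematopoiesis scale) |
| `N` | competitive stem cells | 100 / 500 / 1000 matching the above |
| `epsilon` | supply rate per master cell (per unit calibrated time) | 0.01–0.1 for bursty dynamics |
| `lam` | symmetric-division rate per competitive cell | 1 (reference scale) |

`epsilon = 0` recovers pure neutral competition (NC), `lam = 0` the
purely hierarchical model. Validation is eager: parameters are checked
at construction and downstream code assumes validity.

## Exact single-clone analytics

- **Master equation.** The tridiagonal update is applied exactly
  (O(mN) dense iteration), not by eigendecomposition; for N of order
  10^3 this is both trivial in cost and numerically transparent. Mass
  is conserved by construction; a final renormalization only absorbs
  float round-off.
- **Stationary law.** Detailed balance gives
  `P_n ∝ prod_{k<=n} r_up(k-1)/r_down(k)`. The unnormalized products
  span hundreds of orders of magnitude at N = 1000, so they are
  accumulated as log-sums and normalized with log-sum-exp.
  `epsilon = 0` is rejected rather than returning a point mass at 0:
  the formal answer misrepresents the true absorbing mixture between
  extinction and fixation. `K = 1` returns the point mass at `N`,
  which is genuinely absorbing there.
- **Bursts.** A burst of height `H` is an excursion from size 0 up to
  exactly `H` and back. Its generation probability per step spent at 0
  is `r_up(0) * P_fwd(1;H) * P_bwd(H;H+1)` with the gambler's-ruin
  closed forms; sums of ratio-products are accumulated in log space
  because `r_down/r_up` products explode for small `epsilon`. Expected
  durations use the product transform `X = P_split * T_cond`, which
  turns the ill-posed conditional-time recurrence (the absorbing
  boundary at 0 leaves `T(0)` undefined) into tridiagonal systems with
  zero boundaries, solved by banded elimination rather than one-way
  recursion (near-zero pivots make the recurrences unstable). All
  burst quantities are cross-checked in the tests against an
  independent dense fundamental-matrix/Doob-transform oracle (1e-8
  relative) and against Monte-Carlo censuses.

## Duration conventions (important)

Two conventions for a burst's duration coexist and the package exposes
both, because they genuinely measure different things:

- **Waiting-inclusive** (`include_waiting=True`, and the `duration`
  attribute of detected bursts): from the last entry into size 0 to
  the return to 0. Its expectation carries the geometric waiting term
  `1/r_up(0) = (lam*N + epsilon*K)/epsilon`, which diverges as
  `epsilon → 0`.
- **Excursion** (`excursion_duration`, the default of
  `mean_burst_duration`): from the clone's appearance (first up-step)
  to its return. This is the interval an experiment can observe — a
  clone at size 0 is simply absent — and the census-weighted mean
  under this convention increases monotonically with `epsilon` in the
  small-K burst regime, which is what makes duration-based estimation
  of `epsilon` possible. With the waiting term included the weighted
  mean is dominated by the divergent wait at small `epsilon` and is
  not monotone.

At large `K` even the excursion mean is non-monotone in `epsilon`
(total supply `epsilon*K` suppresses above-average excursions), so the
duration-based estimator probes the map on the requested bracket and
refuses non-invertible brackets instead of returning an arbitrary
root.

## Pulse labeling as an exact marginal

Labeling one random cell out of the `K + N` master and competitive
cells and tracking its descendants does not require simulating the
full clone vector: cells within a clone are exchangeable, so the count
of labeled competitive cells is itself a birth–death chain whose
supply term is `epsilon` if the label sits in a master cell and 0 if
it marks a competitive sub-lineage. The ensemble simulator runs this
scalar chain (a labeled master is drawn with probability
`K/(K+N)`, starting at 0 labeled cells; otherwise the labeled clone
starts at 1). Because the reduction is exact and independent of the
background configuration, no burn-in option is needed — the label's
law is the same whatever the unlabeled clones are doing. A direct
multi-clone bookkeeping oracle in the tests confirms the equivalence.
The labeled count covers competitive cells only; the labeled master
itself is not counted, since only open-layer cells compete and
differentiate.

## Scaling-law statistic

The scaling law states that the surviving labeled-clone distribution,
rescaled by its mean (`x = n/⟨n⟩`, density `⟨n⟩ P_n`), is
time-independent. Comparing two such lattice distributions with a raw
step-CDF Kolmogorov–Smirnov distance is misleading: the supports have
spacings `1/⟨n⟩` that differ between timepoints, and the sup-distance
is then dominated by grid misalignment (half-atom offsets of order
`1/⟨n⟩`), not by shape. The collapse statistic therefore smears each
atom uniformly over its lattice cell and takes the sup-distance
between the resulting piecewise-linear CDFs. Identical inputs give
exactly 0; two geometrics with means 10 and 40 — the discrete
exponential family is the scaling fixed point — give ≈ 0.03, which is
the honest discretization floor at those means.

Conditioning on survival is the default for scaling comparisons (the
unconditioned law accumulates mass at 0 and the convention in the
field is to report persisting clones).

Observation windows matter. The law holds in the drift regime
`1 ≪ ⟨n⟩ ≪ N`; with `N = 100` that window is steps ≈ 10^3–4×10^3
(means ≈ 10–35). Between two late timepoints inside the window the NC
and low-supply hNC ensembles collapse (exact lattice computations give
KS ≈ 0.02–0.03; 10^5-replicate ensembles measure ≈ 0.02–0.03), while
the purely hierarchical model — whose distribution relaxes to a
binomial of fixed mean — *also* trivially collapses once saturated.
Its violation lives in the growth phase, so the hierarchical contrast
statistic spans the full labeling window (steps 250–2000), where it
measures ≈ 0.44, four times the residual drift of the neutral models
over the same window. As supply approaches the division rate
(`epsilon → lam`) the master-origin sub-population equilibrates within
the window and the hNC collapse degrades continuously toward the
hierarchical behaviour; the bursty `epsilon ≪ lam` regime is where the
collapse is clean.

## Diversity and estimation

The Shannon index of clone fractions uses natural logs (nats) with the
`0 ln 0 = 0` convention. Exchangeability of clones gives the exact
stationary expectation `E[H] = -K E[p ln p]` under the closed-form
marginal; this is both a fast large-`K` inversion route
(`invert_expected_shannon`) and the oracle against which the simulated
diversity curve is validated.

The simulation-based estimator (`estimate_epsilon_from_shannon`) burns
in for 100 calibrated time units, then averages the index over
snapshots thinned by twice the clone-turnover interval
`(lam*N + epsilon*K)/epsilon`; the standard error comes from ten batch
means (a guard against residual autocorrelation), the fitted curve is
made monotone by isotonic regression, and the observed index is
inverted by linear interpolation, with the uncertainty band obtained
by inverting `H ± 1.96 SE`. An observed index above the simulated
range but below `ln K` returns the top of the grid with a saturation
warning (hierarchical-like evenness); anything else out of range is an
extrapolation error.

Duration-based estimation requires event-clock series; inputs sampled
at coarser intervals (e.g. monthly tracking tables) are refused, and a
separate descriptive excursion detector (`detect_excursions`,
threshold-crossing runs) is provided for such tables, clearly
separated from the analytic-grade detector.

## Synthetic tracking tables

`generate_fixture` emulates a clonal-tracking study: the multi-clone
process sampled once per "month" of `steps_per_month` steps (1000 by
default, the calibration used for the decade-long hematopoiesis
comparison), written as a wide clone × month CSV, with optional
multinomial subsampling to mimic blood-draw noise. It reproduces the
features the analyses rely on — repeated rises and falls of most
clones, late-month size histograms within total variation 0.05 of the
closed-form stationary law, single-timepoint Shannon indices
fluctuating around the exact expectation — but not features of real
data outside the model: no measurement error beyond multinomial
sampling, no clone birth/death of labels, no non-stationarity from
transplantation dynamics, no unequal master-cell outputs. Passing
tests on these tables therefore validates the machinery, not the
biological fidelity of any particular dataset.

## Numerical choices and problem sizes

- All log-space sums use `logsumexp`/`logaddexp.accumulate`; pairwise
  summation comes with numpy.
- Tridiagonal systems: `scipy.linalg.solve_banded`; a blocking state
  (`r_up + r_down = 0` in the interior) raises a domain error naming
  the state.
- Monotone fit for the diversity curve: `scipy.optimize.isotonic_regression`.
- RNG: numba kernels seed their own generator; replicate `r` of an
  ensemble uses `seed + r`. Identical arguments reproduce identical
  output bit-for-bit.
- Occupation-histogram checks run 2×10^7 steps because the histogram
  decorrelates on the burst timescale (10^3–10^4 steps); shorter runs
  leave total-variation residuals of 0.02–0.06 regardless of accuracy.
- Census-based duration recovery uses 8×10^7 steps: burst durations
  are heavy-tailed and the locally flat duration map (log-slope ≈ 0.2)
  amplifies the census mean's error about five-fold into the estimate.
- Uniform initial condition `n_k = N/K` uses largest-remainder
  rounding when `K` does not divide `N`.

## Known limitations

- The discrete-step chain is the model; there is no continuous-time
  (Gillespie) variant, and no spectral/relaxation-time analysis.
- Burst analytics require `epsilon > 0`; the NC limit has no bursts
  from size 0 (the generation probability is 0 by convention, with a
  warning).
- The scaling-collapse statistic compares lattice estimates of a
  continuous scaling function; at surviving means below ≈ 5 the
  discretization floor exceeds the collapse signal and comparisons
  there are not meaningful.
- Diversity-based estimation assumes stationarity of the clone
  fractions and a known `N` (above the observed clone count only the
  supply rate matters); duration-based estimation additionally needs
  event-level sampling, which most tracking studies do not have.
- At large `K` the burst-duration map is non-monotone in `epsilon`
  and only the diversity route is usable there.
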