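# Methods

## The problem

Large single-cell datasets (e.g. *E. coli* lineages imaged in mother-machine
microfluidic devices) are routinely summarised with binned trends and ordinary
least-squares fits, and the resulting slopes are read as biology — most
prominently, a slope of one on the ln(Ld/Lb) vs ⟨λ⟩Td plot as evidence of
exponential growth. Because both plotted variables carry intrinsic biological
noise, these constructs can mislead: attenuation, conditional-expectation
curvature and inspection bias all produce "non-exponential-looking" trends
from perfectly exponential cells, and vice versa. The package implements the
generative models needed to predict what each statistical construct *should*
show, the closed-form small-noise predictions, and the analysis constructs
themselves, so the analysis can be validated against the model before it is
trusted on data.

## Generative models

All lineage models share: perfectly symmetric division (the next birth length
is exactly half the division length; one daughter kept deterministically), a
per-cycle rate drawn fresh each generation from a Gaussian (no
mother–daughter inheritance), and a division strategy on the normalized birth
length l_b = Lb/⟨Lb⟩,

    f(l_b) = 2 l_b^(1−α),   0 ≤ α ≤ 2,

interpolating timer (α = 0) → adder (α = 1/2) → sizer (α = 1). Division
timing carries Gaussian noise, either **time-additive** (SD σn, entering the
generation time as ζ/⟨λ⟩) or **size-additive** (SD σbd in units of ⟨Lb⟩,
entering the division length). To first order the two are equivalent under
σn = σbd/2; the simulators implement both, and the parameter objects expose
the mapping. Generation times always come from the exact growth relations —
Td = ln(Ld/Lb)/λ (exponential), Td = (Ld−Lb)/λ′ (linear) — never from the
first-order expansions used on the theory side.

Growth laws within a cycle:

* **exponential** — λ constant per cycle, λ ~ N(⟨λ⟩, (CVλ⟨λ⟩)²);
* **linear** — constant elongation speed, the division strategy is the
  linearization g(l_b) = 2 + 2(1−α)(l_b−1);
* **super-exponential** — λ(t) = λ0 for t < t_c and λ0 + k(t−t_c)² after the
  crossover (the integral of dλ/dt = 2k(t−t_c)), with t_c a fixed fraction
  (default 1/2) of the cycle's generation time and k defaulting to 2/⟨Td⟩³
  (k carries units of time⁻³, which fixes the otherwise ambiguous
  "2 Td 3" convention; it is configurable). The deterministic division time
  solves λ0 T + k(1−t_c/Td)³T³/3 = ln(f(l_b)/l_b) (a monotone cubic,
  bracketed and solved with Brent's method), then time-additive noise is
  added. With k = 0 the simulator reduces bit-for-bit to the exponential one.

Two cell-cycle-structure models, both exponential:

* **adder-per-origin** — replication initiation fires when the length crosses
  L_i + O·Δii (length added per origin since the previous initiation, O the
  post-doubling origin count); each initiation schedules its division a C+D
  period later; origins double at initiation and halve at division.
  Implemented event-driven: initiation-crossing times are solved in closed
  form under exponential growth and snapped *up* to the 0.01-min grid;
  when an initiation and a division fall on the same grid step, the division
  is applied first. The mean and CV of Δii (0.41 µm, 0.17) and of C+D
  (160 min, 0.16) are the package's defaults for slow-growth conditions,
  chosen to give realistic cell sizes (⟨Lb⟩ ≈ 1.4 µm) with one overlapping
  replication round; they are fully configurable.
* **constriction** — Ln = Lb + Δbn and Ld = Ln + Δnd with Gaussian
  increments (defaults 1.18 µm CV 0.23 and 0.53 µm CV 0.26, slow-growth
  values); records carry Tn = ln(Ln/Lb)/λ.

A branching-population simulator (both daughters kept, breadth-first) backs
the growth-rate vs inverse-generation-time analyses, where the sampled
ensemble is a population rather than a single lineage.

Degenerate draws (Td ≤ 0, Ld ≤ Lb, negative increments) are rejected and
resampled with a logged count; a rejection rate above 1% aborts, since the
small-noise regime these models describe makes such draws negligible.
Lineages start at the mean birth length with a 50-generation burn-in
discarded (the stationary birth-size law is reached well within 50 steps at
σ ≈ 0.15). Per-cycle draws are consumed in a fixed order (rate, then
division noise, then event noises), so a seed pins the lineage down exactly.

**Default study conditions.** ⟨Td⟩ = 212 min (alanine-like slow growth),
⟨Lb⟩ = 1.73 µm (equal to the mean added length at the adder fixed point),
CVλ = 0.15, σn = 0.15 (σbd = 0.15 for the linear model's size-additive
noise), lineages of 2500 generations, trajectories sampled every 4 min
(the imaging frame rate being emulated), beyond-division window 12 min.
The super-exponential runs use ⟨Td⟩ = 242 min for the initial rate, as in
the reference simulations of that law.

## Closed-form predictions

To first order in the noise every plotted per-cycle observable is a linear
combination of three independent zero-mean Gaussian components: the
stationary log birth-size fluctuation x (variance σn²/(α(2−α)), the pole at
α = 0 reflecting the timer's lack of homeostasis), the rate fluctuation ξ
(variance CVλ²) and the timing noise ζ. The theory module expresses each
axis of the four supported plots in these components and derives slope,
intercept and Pearson correlation from the implied second moments
(m = ρσy/σx, c = ⟨y⟩ − m⟨x⟩). One code path therefore yields, among others:

* ln(Ld/Lb) vs ⟨λ⟩Td (exponential truth): slope
  1/(1 + (1−α/2) ln²2 · CVλ²/σn²) — attenuated below one whenever rate
  noise is appreciable, i.e. a slope ≠ 1 does **not** falsify exponential
  growth;
* ⟨λ⟩Td vs ln(Ld/Lb) (exponential truth): slope exactly 1, intercept 0,
  for every α and every noise magnitude;
* ⟨λ⟩Td vs ln(Ld/Lb) when growth is truly **linear**: slope (3/2)ln 2 ≈
  1.0397, intercept ln 2(1 − (3/2)ln 2) ≈ −0.0275 — indistinguishable from
  exponential growth by this plot;
* ⟨λlin⟩Td vs l_d−l_b when growth is truly **exponential**: slope
  3α/((4α+1)ln 2), = 1/(2 ln 2) ≈ 0.7213 at the adder, intercept ≈ 0.279.

Axis normalizations are ⟨λ⟩ = ln 2/⟨Td⟩ and ⟨λlin⟩ = ⟨λ⟩/ln 2.

The binned trend of the natural plot is the conditional expectation
E[ln(Ld/Lb) | ⟨λ⟩Td = s] = (1+A)s − (A/ln 2)s², with
A = 1/(1 + (2/(2−α))σn²/(CVλ² ln²2)); at the adder with CVλ = σn = 0.15
this is 1.26 s − 0.38 s² (two decimals). With the axes interchanged the
conditional expectation is exactly the identity. Both follow from the same
Gaussian conditioning and are verified in the tests against a brute-force
quadrature oracle (Gaussian grids truncated at ±6 SD, 201 nodes per
dimension).

### Validity of the first-order theory

The closed forms neglect terms of relative order σ² (σ ∈ {σn, σbd, CVλ}).
The simulators, by design, use the exact relations, so simulation and theory
differ by genuinely second-order amounts: at σ = 0.15 the OLS coefficients
of the natural plots shift by 0.01–0.07 (e.g. the exponential-truth
linear-natural slope is ≈ 0.667 in exact simulation vs 0.7213 at first
order), and the deviation scales cleanly as σ² (verified in the tests at
noise scales 1, 1/2, 1/4). The validation pipeline therefore scores
simulation against theory with a tolerance of
`validity_coeff × (CVλ² + σ²)` (default coefficient 3) **plus** 3
Monte-Carlo standard errors estimated across replicate seeds (default 10).
Agreement at Monte-Carlo precision is *not* attainable at the study noise
with 2500-generation lineages, and the suite documents this with an
intentionally strict companion check; the meaningful statements — theory is
the exact small-noise limit, and theory matches simulation within the
documented band at σ = 0.15 — both hold.

The same caveat applies to the population-level identity
⟨λ⟩ = ln 2 ⟨1/Td⟩: 1/Td is convex in the noise and its Gaussian tails are
heavy, so at σn = 0.17, CVλ = 0.2 the ratio is biased by 10–15%. The
identity is validated in the small-noise regime (σ = CV = 0.05, holds to
<1%); at data-like noise the robust signatures are qualitative and match
what is seen in single-cell data: the binned 1/Td-vs-λ trend lies near the
y = x/ln 2 line over the central λ range, while the interchanged regression
is strongly attenuated (slope/ln 2 ≈ 0.03).

## Analysis constructs

* **OLS** (`ols_fit`) is always run on raw points, never on binned data.
* **Binning** (`bin_xy`): equal-width, half-open [lo, hi) bins (last bin
  closed) over the observed x-range; bins with ≤ `min_count` points
  (default 15, strict) are masked for display while raw counts are always
  retained.
* **Rates** (`rate_series`): forward differences,
  growth rate = (L(t+Δt)−L(t))/(Δt·L(t)), elongation speed without the
  1/L factor, each attached to the left endpoint (age t/Td). At Δt = 4 min
  this estimator carries an O(λΔt/2) ≈ 0.7% upward discretization bias
  relative to λ; flatness checks account for it.
* **Growth rate vs age** (`growth_rate_vs_age`): per trajectory, the rate
  series is linearly interpolated onto 200 equally spaced times, binned
  into 50 age bins, and averaged per bin; the reported trend is the
  unweighted across-trajectory mean per bin, with sd/√N error bars
  (N = contributing trajectories). Equal per-trajectory weight is the
  point: pooling samples would over-represent long-lived (slow) cells —
  inspection bias. The trend is insensitive to the interpolation count
  (100–500).
* **Beyond-division extension**: ages near 1 need L(Td+Δt), approximated
  by the summed size of the two equal daughters, whose common rate is one
  fresh draw from the cycle-rate distribution. For linear growth the fresh
  draw is assigned to the summed object's elongation speed (each daughter
  at half of it); this is the only convention consistent with the observed
  constant speed-vs-age trend across division — independent per-daughter
  speeds from the mother distribution would double the summed speed at
  division. Without the extension, late age bins are reachable only by
  cells whose Td aligns favourably with the sampling grid, which biases
  the last bins low; validation checks therefore use extended trajectories
  and consider bins covered by at least half the trajectories.
* **Time from an event** (`growth_rate_vs_time_from_event`): rates pooled
  across cells and binned by t − T_event (birth or constriction), with the
  mean generation time of contributing cells reported per bin as the
  inspection-bias diagnostic: bins where it rises are dominated by
  long-lived cells and their depressed rate trend is an artefact, which
  disappears when the axis is restricted to t ≤ min(Td).
* **Elongation speed vs size** (`elongation_speed_vs_size`): each
  trajectory is binned into 10 equal-width size bins and its per-bin mean
  speed/size pooled; the final trend bins the pooled averages, and OLS on
  the pooled averages provides the slope (≈ ⟨λ⟩ for exponential growth)
  or intercept (≈ mean speed for linear growth) readout. The construct is
  model-dependent: adder-per-origin lineages, though perfectly
  exponential, produce a significantly curved trend (tested via the
  z-score of a quadratic coefficient).

## What the synthetic data does and does not emulate

The generators reproduce the noise structure and sampling of mother-machine
experiments: per-cycle Gaussian rate and division-timing noise, symmetric
division, fixed-interval sampling, beyond-division tracking of summed
daughters. They deliberately omit measurement error, asymmetric division
and division-ratio noise, mother–daughter rate inheritance, and
volume/surface geometry effects. Passing validation on this synthetic data
shows the statistical constructs behave as derived *under the model*; on
real data the same constructs additionally face measurement noise (which
attenuates OLS slopes) and possible sub-population structure. The
experimental regression values reported for real lineage data (e.g. slope
0.3, intercept 0.4 for slow-growth *E. coli* on the natural plot) require
the deposited dataset and are not reproduced here; the I/O layer reads such
tables (including foreign column layouts via a remap) so the full analysis
battery can be applied to them.

## Numerical and design choices

* Error bars are standard errors (sd/√N); where a source describes error
  bars only as "sd scaled by 1/N" the standard-error reading is used and
  flagged in CLI output metadata.
* Ties at bin edges go right; the last bin is closed.
* The age of a forward-difference rate is its left endpoint's t/Td.
* Super-exponential division times: Brent root-finding on a bracketed
  monotone cubic, tolerance 1e−12 min.
* Rejection-resampling retries are capped (10³) and rates above 1% abort.
* The validation battery (`reproduce_all`) runs at the default study sizes
  (2500 generations, 1000 trajectories, 4000–5000-cell populations) in
  about one second; `scale` shrinks the sample sizes for smoke runs and
  widens stochastic tolerances as 1/√scale.
* Seeds: every simulator takes one `numpy.random.Generator` seeded from
  `ModelParams.seed`; replicate seeds are derived as `seed + 1000·k`.

## Known limitations

* All closed forms are strictly first-order; no second-order extension is
  attempted (the validity band above is the honest statement of accuracy).
* The adder-per-origin simulator assumes exponential growth and symmetric
  partitioning of origins; Δii/C+D defaults are plausible slow-growth
  values, not fitted constants.
* `read_trajectories_csv` infers Td from the last in-cycle sample when no
  per-cycle table is supplied — exact for simulated grids, a lower bound
  for real data.
* The constriction model draws increments independently; correlated
  Δbn/Δnd or timer-like C+D variants are not implemented.
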