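# growthmodes

Generative models and validated statistics for single-cell growth data.

Mother-machine experiments yield, per cell cycle, a birth length Lb, a
division length Ld, a generation time Td, and a length-vs-time trajectory
sampled every few minutes. The mode of growth within the cycle —
exponential (λ = (1/L)dL/dt constant), linear (dL/dt constant), or faster
than exponential — is routinely inferred from binned trends and ordinary
least-squares fits on plots such as ln(Ld/Lb) vs ⟨λ⟩Td. Because both axes
carry intrinsic biological noise, these constructs can badly mislead: for
the widely used class of division-control models
f(l_b) = 2·l_b^(1−α) (timer α=0, adder α=1/2, sizer α=1) with per-cycle
rate noise CVλ and division-timing noise σn, the best-fit slope of the
natural plot is

    m = 1 / (1 + (1 − α/2) ln²2 · CVλ²/σn²),

below one even for perfectly exponential cells, while the interchanged plot
⟨λ⟩Td vs ln(Ld/Lb) has slope exactly 1 regardless of noise — and keeps
slope (3/2)ln 2 ≈ 1.04 even when growth is truly linear. The binned trend
of the natural plot is the quadratic conditional expectation
E[y|x] = (1+A)x − (A/ln2)x², A = 1/(1 + (2/(2−α))σn²/(CVλ²ln²2)).

`growthmodes` packages:

* **simulate** — stochastic lineage/population simulators for exponential,
  linear and super-exponential growth under α-control, the
  adder-per-origin replication-coupled model, a constriction model, and
  fixed-interval trajectory sampling with beyond-division extension;
* **theory** — the closed-form small-noise slopes, intercepts,
  correlations, stationary variances and binned-trend curves for all of
  the plots above;
* **analyze** — the data-side constructs exactly as used on experiments:
  OLS on raw points, minimum-count binning, forward-difference rates,
  equal-contribution growth-rate-vs-age trends, time-from-event binning
  with an inspection-bias diagnostic, and two-stage
  elongation-speed-vs-size binning;
* **pipeline / CLI** — reproducible simulate → analyze → theory validation
  experiments (`growthmodes simulate|theory|analyze|validate|reproduce-all`).

Intended users: anyone analysing single-cell growth data who wants to know
what a binned trend or regression slope would look like *if* a given
generative model were true, before reading biology into it.

## Worked example

```python
import growthmodes as gm
from growthmodes import ModelParams
from growthmodes.pipeline import plot_xy

params = ModelParams()          # exponential adder, <Td>=212 min, CV=sigma=0.15
theory = gm.predicted_regression("logratio_vs_lamTd", params)
print(f"theory:    slope={theory.slope:.4f} intercept={theory.intercept:.4f} "
      f"rho={theory.correlation:.4f}")

lineage = gm.simulate_lineage(params, 2500)
x, y = plot_xy(lineage, params, "logratio_vs_lamTd")
fit = gm.ols_fit(x, y)
print(f"simulated: slope={fit.slope:.4f} intercept={fit.intercept:.4f} "
      f"rho={fit.correlation:.4f}")

c1, c2 = gm.binned_trend_coefficients(params)
print(f"binned-trend curve: E[y|x] = {c1:.2f} x {c2:+.2f} x^2")
```

prints

```
theory:    slope=0.7351 intercept=0.1836 rho=0.8574
simulated: slope=0.6735 intercept=0.2131 rho=0.8296
binned-trend curve: E[y|x] = 1.26 x -0.38 x^2
```

Reading: although every simulated cell grows exactly exponentially, the
best-fit slope of ln(Ld/Lb) vs ⟨λ⟩Td is far from 1 (first-order theory
0.735; the exact simulation sits a further ~0.06 below it, a second-order
noise effect), and the binned trend is the curved 1.26x − 0.38x² — so
neither is evidence against exponential growth. The discriminating
statistic is the growth-rate-vs-age trend
(`gm.growth_rate_vs_age(trajectories)`): flat for exponential growth,
∝ 1/(1+age) for linear growth, rising past the crossover for
super-exponential growth.

The full validation battery — regression and binned-trend comparisons for
both growth modes, rate-vs-age discrimination, inspection-bias
demonstrations, speed-vs-size model dependence, and the population
λ vs 1/Td axis asymmetry — runs with:

```sh
growthmodes reproduce-all --seed 0
```

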