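# Methods

## Amplification-curve model and analysis

A qPCR amplification curve has four phases: ground (signal below noise),
exponential (constant per-cycle efficiency E, so log fluorescence is linear
in cycle), transition (efficiency decays as reagents deplete) and plateau.
All quantities are derived from the exponential phase of the
baseline-corrected curve.

### Baseline estimation

The observed fluorescence is `F_c = baseline + N_c` (plus noise). Instead of
extrapolating a trend through the noisy ground-phase cycles, the baseline is
chosen so that the exponential phase is maximally log-linear: a candidate
baseline starts *too high* (99% of the minimum fluorescence over the
candidate exponential region) and is lowered step-wise; at each candidate
the exponential-phase cycles are split into lower and upper halves (by
cycle; the middle cycle goes to the lower half) and the slopes of
`log10(F - b)` vs cycle are compared. A too-high baseline depresses the
early cycles (lower half steeper); a too-low baseline inflates them (upper
half steeper). When the upper half first becomes steeper the candidate is
raised one step, the step is halved, and the search iterates until the
slopes differ by less than `slope_diff_tol = 1e-4` (at E = 1.8 this
corresponds to an efficiency difference of ln 10 × 1.8 × 1e-4 ≈ 4e-4).
The initial step is 25% of the starting candidate; the iteration cap is 100.
Non-convergence, or convergence with a non-positive half slope, is a
baseline error. The exponential region is re-detected for every candidate,
so ground-phase cycles never enter the fit. On noiseless synthetic curves
the result agrees with a dense grid search maximizing the log-linear R² to
well within 0.5% of the true baseline.

### Exponential phase and its centre

The phase end is the second-derivative maximum (SDM): the arg-max of the
central second difference of the 3-point-smoothed fluorescence (invariant to
the baseline shift; ties go to the earlier cycle). The phase start is the
first cycle of the maximal strictly-increasing, strictly-positive run ending
at the SDM. A reaction classified "no plateau" (still rising steeply at the
last cycle) uses the last cycle as the phase end. The phase *centre* is the
point (mean cycle, geometric-mean fluorescence), which lies exactly on the
ordinary-least-squares line through the phase on the log scale.

### Window of linearity (W-o-L) and per-assay efficiency

Individual efficiencies are `10^slope` of `log10 F` vs cycle over at least
`min_window_cycles = 3` consecutive cycles. Per assay, a fluorescence band
of fixed width on the log10 axis is stepped downward in 1/10-band
increments from the highest usable phase fluorescence; at each position
every reaction whose phase has ≥ 3 cycles inside the band contributes an
efficiency, and the band minimizing the CV (sd/mean) of those efficiencies
is the W-o-L. Two numerical choices matter here and are deliberate:

- **Band width = log10(16)** (four doublings). A narrower band can span
  fewer than three cycles when E approaches 2, starving the fit.
- **SDM margin = log10(4)**: candidate cycles stay at least a factor 4 in
  fluorescence below the reaction's SDM. At the SDM the reaction is already
  deep in the transition phase; because the efficiency decay is (to first
  order) a function of the fluorescence level alone, it biases all
  reactions in a band equally and is invisible to the CV criterion, so the
  band must be kept out of that region outright.
- **Tie-breaks**: CV ties (within 1e-12) are resolved toward the band whose
  worst per-reaction R² is best, then toward the higher band. On noiseless
  replicate assays every band position ties at CV ≈ 0 and the R² rule is
  what settles the window inside the truly log-linear region.

### Efficiency outliers

Two exclusion strategies operate on the per-assay efficiency list:
`fixed_band` drops efficiencies outside median ± 0.05; `grubbs` (default)
computes the adjusted Fisher–Pearson sample skewness, tests the extreme
value on the skewed side with a one-sided Grubbs test at α = 0.05 (critical
value from the t-distribution formula; two-sided on the larger deviation
when |skewness| < 1e-3), excludes on rejection and repeats. Spreads with
sd < 1e-3 efficiency units are treated as degenerate and left alone — at
that scale an "outlier" is numerically significant but scientifically
meaningless (noiseless replicates would otherwise be thinned arbitrarily).
Because exclusion changes the distribution, the W-o-L placement (on
included reactions) and outlier detection alternate until the inclusion
mask is stable, with a cap of 10 rounds; an oscillating mask keeps the
largest inclusion set and logs a warning. Excluded reactions are reported,
keep their individual efficiency, and still receive Cq/N0 from the assay
mean efficiency.

### Threshold, Cq and N0

One threshold `Nq` serves the whole run: the geometric mean of the bounds of
the intersection of all valid reactions' exponential-phase fluorescence
ranges. If the intersection is empty, `Nq` falls back to the geometric mean
of the phase centres and every reaction whose phase excludes it is flagged.
`Cq` is called on the ideal curve `N(c) = centre_fluor · E_tar^(c −
centre_cycle)`, i.e. `Cq = centre_cycle + log(Nq/centre_fluor)/log(E_tar)`
(fractional cycles), which cancels residual per-reaction baseline noise.
The reported quantity is `N0 = Nq / E_tar^Cq`, in threshold-fluorescence
units; `N0 = Nq/E^Cq` holds to machine precision for every reported
reaction by construction.

### Detection heuristics and classification

A reaction is *not amplified* when its total rise above the first-six-cycle
median is below 7× the standard deviation of the first-six-cycle
differences (plus a tiny absolute floor); it has *no plateau* when the mean
slope of the last 5 cycles exceeds 1/4 of the maximum per-cycle slope. Both
factors are configuration fields. Sample-type-aware classification:
amplification in a negative control and a silent positive control are
errors (`control_error`); a silent unknown, a missing plateau and a
deviating efficiency are warnings. Errors severe enough to distrust the
automatic quantity (baseline error, amplified negative control) suppress
the reported N0 but leave Cq and the individual efficiency available for a
manual `N0 = Nq / E^Cq`.

## Melting-curve analysis

### Smoothing

A simplified supersmoother: local-linear fits over a ladder of spans
(0.005, 0.05, 0.2 and 0.5 of the series length), the span with the smallest
mean leave-one-out residual selected globally, with a mild preference for
larger spans among near-ties (within 15%) to stabilize the derivative. On
noiseless curves the smallest span wins and the data pass through
essentially unchanged (< 1e-3 of the range), so peak positions are never
displaced by smoothing.

### Normalization

The dissociation-independent, temperature-dependent fluorescence loss is
removed before differentiation. *Bilinear*: straight trend lines through
the lowest and highest 10% of the temperature range; the normalized value
is the height above the lower trend as a proportion of the trend
separation (degenerate trends raise an error). *Exponential*: an
exponential background whose slopes match the observed start/end anchor
slopes is divided out (skipped as a no-op when the anchor slopes do not
describe a decaying exponential). *Combined* (default): exponential, then
bilinear. The result is ≈1 before and ≈0 after the transitions, and
re-normalizing a background-free curve is an identity to < 1e-6.

### Peaks, expected Tm, fractions and correction

Derivatives are central differences on the temperature grid (one-sided at
the ends). Before candidate detection the −dF/dT series is conditioned
with the same smoother — differencing amplifies residual noise, which would
otherwise fragment a real peak; on noiseless input this is a no-op.
Candidates are local maxima of −dF/dT; each candidate's inflection points
are the nearest flanking extrema of the second derivative (falling back to
the −dF/dT valley on a side without one, e.g. shoulder peaks). The peak Tm
is refined sub-grid by a parabola through the apex. Delta height = apex
−dF/dT minus the mean at the inflection points; width = inflection-point
separation. Retained peaks need delta height ≥ 0.05 of the summed candidate
delta heights and width ≤ 5 °C (both configurable; the width rule excludes
wide bumps). A peak within 1.0 °C of the target's expected Tm is the
intended product (closest wins if several qualify); no such peak raises a
warning, more than one retained peak raises a note.

Each peak's fluorescence is the drop of the normalized curve between its
inflection points, with overlapping neighbours split at the −dF/dT valley
between apexes; fractions are shares of the summed drops and always sum
to 1. With a saturating DNA-binding dye the correct-peak fraction corrects
the amplification results: `corrected_N0 = fraction × N0` and
`corrected_Cq = Cq − log(fraction)/log(E_tar)`, preserving
`corrected_N0 = Nq / E_tar^corrected_Cq`. With a non-saturating dye the
correction is reported as not applicable; `apply_correction=False` disables
it entirely.

## Synthetic data

The amplification simulator is the logistic-limited recurrence
`N_1 = n0`, `N_{c+1} = N_c (1 + (E−1)(1 − N_c/plateau))`, observed as
`(baseline + N_c)(1 + ε_c)` with seeded multiplicative Gaussian noise —
the minimal model with all four phases; it is a test fixture, not a claim
about PCR chemistry. Because `N_1 = n0`, the quantity the analysis
extrapolates to cycle 0 is `n0/E`; truth records carry both, and recovery
comparisons use the cycle-0 value. The exact Cq at any threshold is solved
on the noiseless recurrence by log-linear interpolation. Melting curves
are sums of logistic dissociation transitions over a linear background,
with per-product amplitude shares as truth. Default study conditions:
baseline 50, plateau 5000 (baseline = 1% of the end-of-run signal, typical
of an optimized dye assay), 45 cycles, efficiencies 1.7–2.0, starting
quantities spanning six decades; melting on a 0.1 °C grid over 65–95 °C
with transition steepness 0.8 °C. Multiplicative (signal-proportional)
noise was chosen over additive to exercise the baseline estimator
realistically.

What the simulator does **not** emulate: cycle-correlated drift, pipetting
or evaporation trends, probe chemistry, temperature-calibration error,
inter-well optical crosstalk, or melt products with asymmetric/multi-domain
transitions. Passing the recovery suite therefore shows the algorithms are
correct and numerically stable under controlled conditions, not that their
accuracy carries over to every instrument quirk.

## Known limitations

- The CV criterion cannot see efficiency bias that is common to all
  reactions at a given fluorescence level; the SDM margin controls this
  structurally, and a residual downward bias of ≲1% in E remains at 1%
  multiplicative noise.
- Under noise, small "reproducible bumps" can pass the relative height
  cut-off and appear as extra peaks; the cut-offs are configurable, and the
  expected-Tm match keeps the product peak identification stable.
- The common threshold is not recomputed after melt-based corrections.
- RDML support is a practical subset (no XSD validation, single dialect on
  write); the melt correction factor is stored as a `corrF` child of the
  reaction data element, a documented convention for schema versions
  without a dedicated field.
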