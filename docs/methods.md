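# Methods

`nanorelease` quantifies nanomaterial (TiO2) release from photocatalytic
air-purifier surfaces and predicts the resulting indoor exposure. This
note records the models, the conventions and the genuinely open design
choices, and what the synthetic-data experiments do and do not show.

## The well-mixed compartment model

A room or chamber is a single fully mixed air volume whose concentration
C(t) (number 1/cm3 or mass ng/m3; the model is unit-generic) obeys

    V dC/dt = G + P·Q·C_out − (Q + λ·V + Σ_j η_j Q_j) · C

with V the volume (m3), Q the ventilation flow (m3/h), P ∈ [0,1] the
penetration of supply-air particles, λ the first-order surface-deposition
rate (1/h), C_out the supply concentration, G a constant source
(quantity/h) and η_j Q_j the clean-air-delivery flow of any filtering
device. Ventilation and deposition are strictly losses: the implementation
uses the physically consistent sign −(Q + λV)·C throughout (an algebraic
variant in which ventilation adds chamber particles has no physical
reading and is not supported; for the sealed-chamber application both loss
terms are ≈ 0, so nothing downstream depends on this choice).

With constant coefficients the solution is the exponential relaxation

    C(t) = C_ss + (C0 − C_ss)·e^(−k t),   k = (Q + λV + Σ η_j Q_j)/V,
    C_ss = (G + P·Q·C_out)/(kV),

which is the primary solution path. An adaptive Dormand–Prince
integrator (`solve_profile_numeric`, rtol 1e-12, absolute tolerance scaled
to the solution magnitude) exists as an independent oracle and for
time-varying supply concentration; the test suite checks closed form vs
integrator to better than 1e-9 relative on 100 randomized parameter sets.
When k = 0 (sealed volume) there is no steady state: `steady_state`
raises, and the profile reduces to linear accumulation C(t) = C0 + G·t/V
(`closed_chamber_profile`), for which V·(C − C0) = G·t holds exactly.

## Chamber emission-rate estimation

In a sealed chamber (Q ≈ 0, λ ≈ 0) the balance gives G = V·dC/dt, so the
source rate follows from the slope of the concentration series:

1. **Masking.** Intervals known to be perturbed (brief external sampling
   draws that pull laboratory air into the chamber) are removed; the gap
   locations are kept as segment boundaries.
2. **Block averaging.** Non-overlapping blocks (default 15 min,
   configurable) anchored at the first timestamp; each output point is the
   mean of its block's samples, timestamped at their mean time. The mean
   time equals the geometric block centre for symmetric sampling and makes
   the block means of a linear ramp fall exactly on the ramp, so a
   noiseless constant-source series is recovered exactly. Blocks that
   straddle a masked gap are dropped.
3. **Differencing.** Finite differences between consecutive blocks within
   a segment only — a derivative never spans a gap (the choice of gap
   handling is ours; the alternative of differencing across gaps would let
   excluded transients leak into the statistics).
4. **Statistics and bound.** Mean, sample (n−1) standard deviation and
   count of the differences; then point = mean·V and
   upper = (mean + k_σ·sd)·V with k_σ = 1 by default ("one standard
   deviation upper range"), floored at zero because an emission rate is
   non-negative — a negative upper range simply indicates net loss. The
   estimator choice (n−1 sd) is ours; at n ≈ 280 windows the n vs n−1
   distinction is far below the reported precision.

Because consecutive differences telescope, the mean derivative equals
(C_last − C_first)/span: an endpoint-driven slope estimate whose noise
shrinks with the full series span, while the sd term captures
window-to-window fluctuation for the conservative upper range.

## Release quantification from censored filter gravimetry

Emitted particles collected on a quartz filter are assayed for titanium;
the assay's limit of quantification (LOQ, 1 ng for the campaigns shipped
as examples) censors low masses. A censored sample propagates the LOQ as
the largest mass consistent with the assay, so every derived quantity is
an upper bound, flagged as such end to end. The chain per sample:

    Ti conc  = mass (or LOQ) / sampled volume               [ng/m3]
    TiO2 conc = Ti conc × M(TiO2)/M(Ti)                     [ng/m3]
    rate     = TiO2 conc × mean flow                        [ng/h]
    release factor = TiO2 conc / photoactive area           [ng/(m2·m3)]

Conventions that matter:

- **Atomic masses** fixed at Ti = 47.867, O = 15.999 g/mol (IUPAC), giving
  a TiO2/Ti mass ratio of 79.865/47.867 ≈ 1.6685.
- **Mean flow** is the empirical sampled volume / duration, not the pump's
  nominal setting; the two differ by ~30% in the shipped campaigns and
  only the empirical flow keeps the chain internally consistent
  (rf × area × flow = rate holds exactly on the raw chain).
- **Honeycomb area** defaults to 90 cm2 per unit, the low end of the
  90–100 cm2 manufacturing range, three units per device (0.027 m2);
  configurable.
- **Printed-report rounding** (the `table1` mode) reproduces
  fixed-precision report cells: Ti concentration at 1 significant figure;
  TiO2 concentration at 1 significant figure (converted from the printed
  Ti value); emission rate at 2 significant figures computed from the
  *unrounded* concentration; release factor at 3 significant figures
  computed from the *printed* TiO2 concentration. No single rounding point
  reproduces all published-style cells simultaneously — this mixed chain is
  the one that matches the open-circuit campaign exactly and the
  sealed-circuit concentration and release factor; the sealed-circuit rate
  then prints 2.3×10⁻² rather than a 2.2×10⁻² obtained by rounding before
  multiplying. Rounding is half-away-from-zero; raw full-precision values
  are always carried alongside and used for every onward computation.

Censoring is monotone by construction (a larger LOQ never lowers a bound)
and the flag is sticky: any quantity derived from a censored input is an
upper bound.

## Exposure scenarios and risk characterisation

A purifier's source strength is G = release_factor × photoactive area ×
volume flow, which is what makes the release factor transferable across
devices and operating points. The reference "reasonable worst case" is a
20 m3 room at 0.5 1/h (typical European-dwelling ventilation) with two
devices recirculating 10 m3/h each over three 90 cm2 honeycombs, zero
particle filtration (measured TiO2 filtration is negligible), clean
outdoor air and λ = 0 (no deposition claim is made for the room; both are
configurable). The source-rate convention applies the release factor to
the **combined** area and **combined** flow (0.054 m2 × 20 m3/h), i.e. the
two devices are represented as one purifier bank; summing each device's
own area × own flow would instead give half the source. The combined
convention is the more conservative of the two and is the one used here
for worst-case screening. With the measured release-factor upper bound of
0.185 ng/(m2·m3): G = 0.1998 ng/h, steady state G/(0.5 × 20 m3) =
0.01998 ≈ 0.020 ng/m3, 95% of which is reached after ln(20)/k ≈ 6.0 h —
hence "steady state within a 10 h run".

Risk characterisation divides the predicted steady state by a proposed
occupational exposure limit; proposed limits for nanosized TiO2 span
0.8–5000 µg/m3 as 8 h time-weighted averages, and a 24 h general-population
variant divides the limit by 3. The reference scenario yields ratios of
2.5×10⁻⁵ (strictest limit, 8 h) to 4×10⁻⁹ — orders of magnitude below 1
even with every censored quantity read as its upper bound.

## Synthetic data: what it emulates and what it does not

`gen_chamber_series` produces C0 + (G/V)·t plus independent Gaussian noise
(the resulting concentration floored at 0) plus Poisson-arriving,
exponentially decaying spikes emulating infiltration transients from
external sampling draws; spike windows are returned as exclusion-interval
ground truth. Defaults emulate the chamber study: 220 L, 4400 1/s source,
three days at 1 Hz, 8 1/cm3 background, 0.5 1/cm3 noise, three spikes per
day of ~5 1/cm3 decaying at 30 1/h. `gen_filter_sample` computes the
deterministic collected mass rf × area × flow × duration, optionally
perturbs the assayed Ti mass with multiplicative lognormal noise (a
standard model for positive gravimetric/ICP-MS errors; the number-series
noise is additive Gaussian because counting noise at these concentrations
is near-symmetric), and censors iff mass < LOQ — the boundary mass
exactly at the LOQ is reported as measured. Notably, a filter campaign
generated at the measured release-factor bound of 0.185 ng/(m2·m3)
collects only ≈ 0.91 ng Ti over 96 h, below the 1 ng LOQ: the measured
bound is itself unmeasurable at this LOQ, consistent with every campaign
sample censoring.

`recovery_experiment` reruns the full pipeline on seeded replicates. At
10% white noise (sd relative to the final concentration) over 288
15-minute windows, the median relative bias of the point estimate is
well under 2% and the one-sigma upper range covers the true rate in
≈ 100% of 200 replicates. One subtlety: at that noise level a near-zero
baseline would make the non-negativity floor clip the early samples,
biasing the recovered slope by about −4% — the noise would no longer be
white. The recovery experiments therefore offset the baseline by the
accumulated rise so the floor never binds; at the chamber's own noise
level (0.5 1/cm3 on a ≥ 8 1/cm3 signal) the floor never binds anyway.

The generators do not emulate instrument physics (optical sizing channels,
condensation-counter coincidence), drifting backgrounds, autocorrelated
noise, or losses inside the chamber; passing recovery tests demonstrates
estimator correctness under the stated noise model, not robustness to
those effects.

## Numerical and interface choices

- Internal units: ng, m3, m2, h (series timestamps in s); number
  concentrations 1/cm3. Unit conversion is by exact scalar factors
  (round-trip identity to < 1e-12 relative).
- Seeding: one `numpy.random.default_rng(seed)` per generator call;
  replicate seeds are spawned from a `SeedSequence` and kept below 2^31.
- Degenerate inputs fail loudly: empty series after masking, windows
  shorter than twice the median sampling interval, sealed volumes queried
  for a steady state, negative masses/concentrations, all-censored report
  requests on empty sample lists.
- Scenario configs are YAML validated by pydantic models; CSV dialects are
  documented in `nanorelease.io`; all JSON reports embed their resolved
  configuration. Timestamps parse as elapsed seconds or ISO-8601.

## Problem sizes

The analysis drivers and the test suite use the study-scale problems
directly: three-day 1 Hz chamber series (259 200 samples), 288 15-minute
windows, 200-replicate recovery experiments; the headline report
quantities are desk-scale closed-form computations. The full suite runs in
a few seconds on one CPU.

## Known limitations

- Single-zone, size-integrated, constant-coefficient model: no near-field/
  far-field split, no coagulation or size-dependent deposition, no
  time-varying sources beyond step on/off.
- Deterministic exposure prediction (no Monte-Carlo uncertainty bands);
  censored inputs propagate as hard upper bounds, not distributions.
- The derivative estimator assumes losses in the chamber are negligible;
  it does not deconvolve ventilation/deposition from the slope.
- Printed-report mode reproduces a fixed rounding convention; any other
  reporting precision should start from the raw chain.
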