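# Methods

## Kinetic model of the ComX time course

Extracellular ComX activity $a(t)$ (Miller units, MU) and the activity
$EA(t)$ of a putative ComX-specific protease (CSP) obey

    da/dt  = b·X(t) + d·dX/dt − e·EA(t)
    dEA/dt = f·a(t) − g·EA(t)

driven by the cell dry weight $X(t)$ (g/L).  The production side combines a
standing-biomass term (every cell secretes pheromone at rate $b$) with a
growth-coupled term ($d$·dX/dt: newly formed biomass releases a burst of
pheromone); degradation is first order in protease activity, and the
protease is induced by ComX ($f$) and decays ($g$).  Autoinduction and
cell-associated degradation are deliberately absent: incubation experiments
show autodegradation and intracellular loss of the pheromone to be minor
(a few percent over 8–24 h), while extracellular protease-mediated loss
dominates.

Given $X(t)$ the system is linear in $(a, EA)$ with matrix
$[[0, −e], [f, −g]]$; the defaults give complex eigenvalues
$−0.164 ± 0.377i$ 1/h, i.e. damped oscillation with period ≈ 16.7 h and
decay time ≈ 6 h — the model's built-in tendency to overshoot and ring,
consistent with the oscillation tendency observed late in such
cultivations.  For constant biomass the fixed point is
$a_{ss} = bXg/(ef)$ and $EA_{ss} = bX/e$ (≈ 197 MU and ≈ 69 activity
units at X = 5.4 g/L with midpoint parameters).

### Parameters

| name | units | default (midpoint) | bounds | role |
|------|-------|--------------------|--------|------|
| a0 | MU | 26.5 | 21–32, free | initial ComX activity |
| b | MU·L/(g·h) | 18.835 | 17.72–19.95, free | biomass-proportional production |
| d | MU·L/g | 476 | 436–516, free | growth-coupled production |
| e | MU/(EA·h) | 1.47 | 1.36–1.58, free | protease-mediated degradation |
| f | EA/(MU·h) | 0.115 | fixed | protease induction |
| g | 1/h | 0.328 | fixed | protease decay |

The range entry for d ("0.436–0.516·10³") is read as 436–516 MU·L/g; the
alternative reading (d ≈ 0.5) would make the growth-coupled term
numerically negligible and the parameter unidentifiable, which would
contradict its presence in the model.  The initial protease level is not
specified anywhere; the default is $EA(0) = 0$ (no ComX-induced protease
at inoculation), overridable via `ea0`.

### Numerics

`simulate` uses the stiff-capable adaptive LSODA integrator at relative
tolerance 1e-8 (absolute 1e-10).  Trajectories are clipped at zero on
output with a warning whenever the raw solution dips below −1e-9 — with
steep biomass curves the post-peak downswing of the damped oscillation can
genuinely cross zero; the raw solver state is never clipped
mid-integration.  The test suite checks the solver against an independent
fixed-step forward-Euler oracle (dt = 1e-3 h, 1e-3 relative sup-norm over
48 h) and against the closed-form steady state (0.1 % at t = 200 h).

The ±8 % sensitivity envelope applies the full factorial
{0.92, 1, 1.08} to the four free parameters (3⁴ = 81 simulations) rather
than one-at-a-time variation, so the band genuinely bounds every
combination of admissible mis-specifications; fixed parameters are not
varied.

## Parameter estimation

Bounded nonlinear least squares (scipy's trust-region reflective method)
over (a0, b, d, e) with f, g held fixed; plain unweighted residuals.  A
seeded multistart — the bounds midpoint plus four Latin-hypercube points —
guards against local minima; the lowest final SSE wins, ties broken by
start index, so fits are deterministic given `random_state`.  Parameters
within 1e-4 of their bound span are flagged `at_bounds`.  Replicated
observations at the same sampling time are supported by simulating once on
the unique time grid.

Identifiability note: the admissible ranges are narrow (±6–8 % around the
midpoints), so the constrained fit can never stray far even when the data
are weakly informative; the recovery study in the test suite (20 seeded
cultivations, σ = 5 MU, 25 samples) shows median absolute relative errors
well below 15 % for b, d and e, and noiseless data are recovered to 1e-3.

## Curve fits

Observables are smoothed with the two classic families used in
process-data analysis: the 4-parameter logistic
$y_0 + a/(1+e^{-(t-t_0)/\tau})$ and the 3-parameter exponential
$y_0 + a e^{kt}$, both with closed-form derivatives (no numerical
differencing anywhere downstream).  Initialisation is a fixed rule of the
data — baseline = min, amplitude = range, $t_0$ = earliest half-range
crossing (ties broken by earliest time), $\tau$ = span/10 — plus two
deterministic alternates (negative amplitude, negated $\tau$) so
decreasing data fit equally well; the best final SSE wins and is never
allowed to exceed the flat-fit SSE.  Which variable receives which family
is the caller's choice, exposed as configuration.

## Assay calculus

* Miller units: $1000\,(OD_{420} − 1.75\,OD_{550})/(t\,v\,OD_{600})$ with
  t in minutes and v in mL (the units are adopted from the classic Miller
  protocol; the hours-long bioassay pre-incubation is *not* t).  Values
  may be negative at blank level and are not clipped.
* Blank screening: one pass removes blanks with |z| ≥ 2.0 computed from
  the full set's mean and sample SD (n−1 throughout); the statistics are
  then recomputed.  Shapiro–Wilk normality of the full set is reported and
  warned about below p = 0.05, never enforced.
* LOD = mean + 3·SD, LOQ = mean + 10·SD, hence LOQ − LOD = 7·SD exactly.
* Endopeptidase activity: (ΔA₄₅₀ sample − blank)·dilution/(h·mL).
* Degradation rate: negated OLS slope of activity vs time (positive =
  loss); an endpoint difference-quotient mode is available since the
  choice between the two is not fixed by convention.

## Process metrics

Yields and productivities are evaluated at sampled time points only — the
reference point is the earliest sample at which ≥ 90 % of the maximum is
reached, with no interpolation.  Y_X/S uses the X ≥ 90 % point, Y_P/S the
P ≥ 90 % point, Y_P/X and q_overall both (Δm_P over [t₀, t_P90], biomass
averaged between t₀ and t_X90, Δt = t_P90 − t₀; the pairing of reference
points in the overall productivity admits more than one reading and this
one is recorded as the package's choice).  Surfactin is converted mg→g
before any yield.  The correlation curve uses the instantaneous limit
q(t) = P′(t)/X(t) of the interval formula, computed from fitted-curve
derivatives and truncated at the ComX maximum.

## Mass arithmetic

Monoisotopic residue masses are hard-coded at 5-decimal precision; a
peptide's mass is the residue sum plus one water (18.010565 Da) plus
modification deltas; farnesylation is net +C15H24 = +204.18780 Da on the
tryptophan indole; m/z of [M+zH]ᶻ⁺ is (M + z·1.007276)/z.  The computed
farnesylated +2 ion (681.87443) differs from the commonly quoted
instrument target (681.87470) by ~0.3 mDa (≈ 0.4 ppm), within the
tolerance of any targeted acquisition window.

## Synthetic-data generator

`synthgen` emulates a 48-h batch bioreactor reference process at 40 g/L
glucose, sampled every 2 h in biological duplicate: logistic biomass from
0.031 to 5.4 g/L at rate 0.52 1/h; glucose tied to biomass through a
constant yield of 0.15 g/g (no maintenance term — a documented
simplification); surfactin as an independent sigmoid reaching 1346.6 mg/L
(half-maximum at 20 h, scale 4 h — the productivity/pheromone correlation
is an empirical, not mechanistic, relation, so the generator does not
couple them); total endopeptidase activity proportional to biomass
(15 ΔA/(h·mL) per g/L, matching an ~81 ΔA/(h·mL) maximum at peak
biomass); ComX as the kinetic model's output on the true biomass curve
plus additive Gaussian noise (σ = 5 MU), with multiplicative 5 % CV noise
on the concentration-like observables.  Every generator is a pure function
of (config, seed).

What the generator does *not* reproduce: with the steep 0.52 1/h logistic
and midpoint parameters the growth-coupled term d·dX/dt spikes near
334 MU/h, so the simulated ComX transient peaks around 1000 MU before
relaxing to the ~197 MU plateau — several-fold above the 150–250 MU peaks
of real cultivations, whose biomass rises far more gradually (maximum
reached after ~30 h, with lag and substrate transitions).  The transient's
*shape* (peak after the growth-rate maximum, decline toward a plateau
below the peak, damped ringing) is faithful; its amplitude is not.
Passing tests therefore demonstrate correctness of the kinetics,
estimation and arithmetic under realistic noise, not a quantitative match
of the synthetic peak height to measured ones.  Real-data features also
absent: lag phases, diauxic shifts, pH/dissolved-oxygen effects, foam
losses, and the late-cultivation surfactin decline seen in shake flasks.

## Problem sizes

The recovery study uses 20 replicates of 25 samples each; the Euler oracle
integrates 48 000 fixed steps; the sensitivity envelope runs 81
simulations on a 97-point grid.  These sizes were chosen so the entire
suite (including the recovery study) completes in about two minutes while
keeping every statistical margin comfortable.

## Known limitations

* The kinetic model has no mechanism for sustained oscillation and no
  Rap-phosphatase feedback; the CSP is putative and its activity scale is
  nominal (azocasein units capture it only partly).
* The estimation reports at-bound flags but no posterior or profile
  uncertainties.
* Replicate statistics in the metrics module are plain per-time means; no
  error propagation.
* The OD↔CDW factor direction (CDW = OD/3.2) is a recorded convention,
  chosen because it maps the observed biomass plateau (5.4 g/L) to a
  plausible OD ≈ 17 and an inoculation OD of 0.1 to ≈ 0.03 g/L; the
  factor lives in `ConversionConfig` so it can be flipped.
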