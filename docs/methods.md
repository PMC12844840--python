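# Methods

## The composition calculus

The package models a measured total first-order rate constant or
clearance as a composition of *rate-defining processes*: steps that,
were each the only slow one, could individually determine the total
and be measured doing so.  Two rules generate everything else:

* **Parallel** (independent simultaneous routes): totals add.
* **In series** (each step feeds the next): mean times add, so
  reciprocals of totals add.

The rules hold identically for rate constants (1/h) and clearances
(L/h); a `ProcessNetwork` is a finite tree of parallel/series groups
over leaves of one kind, and mixing kinds is rejected at construction.
Empty groups are errors, not identities — a total of 0 or ∞ is never
rate-defining.  A forward/backward transporter pair
(`NetDifferenceProcess`) reduces to a rate-defining stage only when
forward − backward > 0; by default a non-positive net stage is a hard
error, with an explicit opt-in (`drop_non_rate_defining=True`) that
omits the stage from a series chain with a warning, reflecting that
processes which are not rate-defining simply do not appear in the
total.

Units are canonical internally: hours, liters, L/h.  Constructors and
file formats accept explicitly tagged mL/min (1 L/h = 16.667 mL/min)
because renal physiology is conventionally quoted that way.

## Why the series rule is exact for linear chains

For a catenary chain of first-order stages (stage total λᵢ = through
rate + parallel losses), the amount of the terminal species is a
Bateman-type signed sum of exponentials, and its moment ratio
AUMC/AUC equals Σ 1/λᵢ exactly.  The `linear` module proves this
numerically rather than assuming it: `species_moments` solves
`M·AUC = −A(0)` and `M·AUMC = −AUC` with the rate matrix M
(`M[j,i] = k(i→j)`, diagonal = −total outflow), which requires no
eigendecomposition and no distinct-rate assumption; `analytic_curves`
eigendecomposes M into a closed-form term list when eigenvalues are
pairwise separated by more than 1e-10 of the spectral radius, and
refuses (pointing to dense `expm` sampling via `sample_amounts`) when
they are not.  Terminal sinks are kept out of M — which keeps it
invertible — and tracked as absorbing states in the sampling matrix,
so total mass is conserved to machine precision and checkable.

### Reversible side compartments

Adding a reversible, non-eliminating side compartment (C1 ⇄ C6)
leaves every AUC unchanged (integrate the mass balance: the side
compartment's net lifetime flux is zero) but *does* change the moment
MRT of downstream species — mass parked in C6 still accumulates
residence time.  The stage-sum MRT, by contrast, is blind to the side
exchange because those rate constants are not rate-defining.  The two
notions answer different questions, and `kirchhoff_vs_oracle`
deliberately reports both numbers and their difference without
encoding a judgement.  No test asserts either one as "the" MRT for
such networks.

## Organ models

**Renal.**  `1/CL_R = 1/Q_R + 1/(f_uB·GFR + CL_sec − CL_reab)`:
delivery by blood flow in series with the parallel sum of filtration
and net tubular transport.  The inversion
`net = 1/(1/CL_R − 1/Q_R) − f_uB·GFR` recovers the net transport
implied by an observed clearance; a flow-free traditional mode
(`CL_R − f_uB·GFR`) is kept for comparison.  An observed CL_R ≥ Q_R is
an infeasible observation, and a non-positive leaving stage (net
reabsorption exceeding filtration) is reported, never clamped.

**Hepatic.**  Up to three series stages: Q_H, f_uB·(CL_int,influx −
CL_int,efflux), f_uB·CL_int (intrinsic metabolic + biliary).  With
transport out of scope this is algebraically the classical well-stirred
model expression `Q·f_uB·CL_int/(Q + f_uB·CL_int)` — here obtained
with no intra-organ mixing assumption, which is the point of the
calculus.  In the Q_H → ∞ regime the transport-limited form
`f_uB·CL_int·net/(CL_int + net)` applies.

**ECC.**  The Extended Clearance Concept keeps influx and efflux as
separate parameters:
`CL = Q·CL_inf·f_uB·CL_int/(CL_inf·f_uB·CL_int + Q·CL_int + Q·CL_eff)`,
simplifying as Q → ∞ to `CL_inf·f_uB·CL_int/(CL_int + CL_eff)`.
Influx ≤ efflux is *permitted* on this path (the two directions are
independent parameters there), while the series path rejects a
non-positive net — `compare_ecc_vs_kirchhoff` exists precisely to
tabulate this structural difference, reporting per-framework failures
inside the result instead of raising.

**Perfusion back-calculation.**  From a single-pass steady state,
CL_H = Q_H·(C_in,u − C_out,u)/C_in,u, and each mechanistic convention
divides by its own average unbound concentration: outlet (WSM) or
logarithmic mean (PTM).  Since outlet ≤ log-mean, CL_int,WSM ≥
CL_int,PTM at any nonzero extraction.  The reference concentration
C_blood is not fixed by the steady-state relation itself, so
`PerfusionSteadyState` carries its convention (`inlet_total` for all
fixtures generated here) as data.

**Rate-limit classification.**  A series stage is labelled
rate-limiting when its reciprocal contributes ≥ `dominance_fraction`
(default 0.9) of 1/CL_H, else "mixed".  The 0.9 default quantifies an
otherwise qualitative "much greater than"; it is a reporting threshold
with no effect on any computed clearance.

## NCA and the oral chain

Polyexponential curves `Σ cᵢ·e^(−λᵢt)` carry their moments in closed
form (AUC = Σc/λ, AUMC = Σc/λ²).  Concentrations are mg/L, numerically
identical to µg/mL.  The iv parameter set is standard: CL = dose/AUC,
CL_R = (U∞/dose)·CL, CL_H = CL − CL_R, MRT = AUMC/AUC, Vss = CL·MRT,
V_initial = dose/C(0).

Two bioavailability estimates are computed and *neither is clamped*:
F_urine from dose-corrected urinary recovery (assumption-free) and
F_plasma from dose-corrected AUC (assumes route-independent
clearance).  The oral systemic clearance uses the urinary measure,
`CL(oral) = F_urine·dose_oral/AUC_oral`, and the absorption-site
clearance follows from series inversion,
`CL_abs = 1/(1/CL(oral) − 1/CL(iv))`.  When absorption-site clearance
is small the oral-route clearance collapses toward it, AUC inflates,
and F_plasma can exceed 1 while F_urine cannot — the central
diagnostic the package is built to expose.  A measured CL(oral) ≥
CL(iv) leaves no room for the absorption stage and raises.  The
absorption rate constant is never inferred from the printed summaries
(it is not identifiable from them); when the caller supplies it,
V_absorption_site = CL_abs/k_abs is reported.

A negative MAT is a warning, not an error: with noisy fitted inputs it
is a recognisable artifact the analyst should see, not a crash.
Flip-flop labelling uses a 3× ratio between k_absorption and k_elim
("absorption_limited" / "elimination_limited" / "comparable"); the
composed rate `k_el·k_abs/(k_el + k_abs)` is exact and label-free.

## Fitting and synthetic data

`generate_series` samples a known curve on a grid — default 0.25, 0.5,
1, 1.5, 2, 3, 4, 6, 8, 10, 12, 16, 20, 24 h, spanning both phases of a
typical biexponential — with optional proportional (`1 + cv·N(0,1)`)
or additive Gaussian noise, seeded through `numpy.random.default_rng`
with no global state; negative values are clipped to zero and counted.
Proportional noise with cv = 0.05 emulates a typical PK assay's
multiplicative error.  What it does not emulate: below-limit-of-
quantification censoring, correlated residuals, between-subject
variability, or irregular sampling — so passing recovery tests show
estimator correctness under clean error assumptions, not field
robustness.

Fitting is classical two-step: method-of-residuals stripping (terminal
log-linear fit on the late tail, subtract, repeat; for oral curves the
terminal phase comes from the late post-peak decline and the
absorption exponent from the pre-peak residual rise, with a negative
coefficient) followed by `scipy.optimize.least_squares`.  Residuals
are log-scale for iv curves (multiplicative error) and linear with
1/ŷ weighting for oral curves, which pass through zero at t = 0 and
make log residuals undefined there.  Exponents (and iv coefficients)
are log-parameterised to stay positive; fits are deterministic given
(series, start); non-convergence is flagged, never silent.  Term
count is caller-specified; `compare_term_counts` offers an AIC-style
comparison but is never applied automatically.

### Identifiability of the fast phase

With the default 14-point grid only four samples fall below 2 h, so
the fast exponent of the 1.39/0.173 biexponential template is weakly
determined: the Cramér–Rao bound at cv = 0.05 gives a ~20% relative
standard deviation (~13% expected median absolute error) for any
unbiased estimator, and the least-squares fit performs near that
limit.  The terminal exponent, covered by ten samples, recovers to a
few percent.  Integral quantities (AUC, CL) are far more robust than
the fast exponent itself.  This is a property of the sampling design,
not of the optimizer — tests assert recovery relative to this
information limit.

## Numerical choices

* Algebraic identities are tested at 1e-9 relative; closed-form vs
  matrix-solve cross-checks at 1e-9; golden values against published
  summaries at the precision those summaries carry.  Published derived
  values are themselves chained through 3-significant-figure
  intermediates (e.g. a clearance printed as dose/AUC with AUC
  pre-rounded to 103 where full precision gives 103.28), so derived
  golden comparisons use a 1% band while exact-arithmetic quantities
  are asserted tight.
* Eigendecomposition requires pairwise eigenvalue separation
  > 1e-10 × spectral radius; `catenary_coefficients` rejects exactly
  coincident stage totals.
* Curve terms are canonicalised to strictly decreasing exponents;
  terms whose exponents coincide to ~1e-12 relative are merged.
* All randomness flows through a single explicit seed per call.

## Known limitations

Linear (first-order) kinetics only: no saturable processes, no
time-varying rates.  No dispersion-model closed form and no
unbound-tissue-partition (Kp_uu) estimation.  Single-dose analyses
only (no steady-state superposition), cumulative U∞ only (no urine
time course), and no population-level (mixed-effects) fitting.
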