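# Methods

## The problem

When individual pharmacokinetic parameters are the quantity of
interest — for dose individualization, covariate analysis on empirical
Bayes estimates (EBEs), or model diagnostics — the sampling schedule
should be chosen to maximize the precision of the *individual*
(posterior-mode) estimates, not of the population parameters.
Inter-occasion variability (IOV) complicates this: deviations that
change from one dose interval to the next both dilute the information
any single occasion carries about the individual's own deviation and
open the question of how the design criterion should account for them.

`iovdesign` implements maximum-a-posteriori (MAP) optimal design for
nonlinear mixed-effects (NLME) models with three random-effect levels:

    y_i = f(chi_i, g(theta, eta_i, kappa_1..kappa_m)) + h(..., eps_i)

with `eta_i ~ N(0, Omega)` (inter-individual variability, IIV),
`kappa_j,i ~ N(0, Pi)` per occasion (IOV; an occasion is one dose
interval, half-open `[start, start + tau)`, samples at a dose time are
post-dose), and residual error `eps ~ N(0, Sigma)`.

## The MAP information matrix and the four IOV treatments

The population model is transformed to an individual model: the random
effects become individual parameters `theta_eta` sampled from `Omega`.
The design criterion is built from the FO individual Fisher
information.  For Gaussian observations with mean `f(p)` and residual
variance `V(p)`,

    FIM_kl = J_k' V^-1 J_l + 1/2 tr(V^-1 dV/dp_k V^-1 dV/dp_l),

where `J` are prediction sensitivities (central finite differences,
relative step 1e-5 with absolute floor 1e-6; the floor balances
truncation against double-precision roundoff of the solvers).  The
half-trace block carries the information on parameters entering the
residual variance — without it the colistin error-magnitude effect
`eta_ER` would be undesignable, contradicting the evaluation results;
it can be disabled by configuration.

The MAP FIM is the Monte-Carlo expectation over prior draws plus the
prior precision, and optimization maximizes the Ds objective

    OFV = E_prior[ log |FIM_i + Prior| - log |(FIM_i + Prior)_unint| ],

the expectation taken per draw inside the log (the averaged-then-logged
alternative differs by a Jensen gap; the per-draw form is used for
optimization throughout).  Draws are reused across all evaluations of
one run so the search surface is deterministic.

Four treatments of IOV:

- **Omit** — IOV ignored; parameters `eta`, prior `Omega^-1`.
- **Inflate** — as Omit on an IOV-inflated IIV matrix `Omega*`
  (mimicking a model whose design could not separate IIV from IOV);
  residual error is not inflated.
- **MAPocc** — occasion deviations become per-occasion individual
  parameters with prior `diag(Omega^-1, Pi^-1, ..., Pi^-1)`, marked
  *uninteresting* in the Ds ratio.
- **POPocc** — IOV stays a random effect: its FO-linearized variance
  contribution `sum_j S_j Pi S_j'` (with `S_j = df/dkappa_j` at
  `kappa = 0`) is added to `V`, `Pi` held fixed.  Fixing `Pi` is
  represented by omitting its rows rather than carrying an explicit
  zero-precision block — algebraically identical in the Ds ratio and
  numerically cleaner.  When the variance-derivative block is formed,
  the occasion term is held at its linearization and only the residual
  variance is differentiated; its parameter dependence is a
  FOCE-order effect and FO is the linearization used throughout.

On any model *linear* in `(eta, kappa)` with additive error the MAPocc
Ds value equals the POPocc log-determinant over `eta` exactly (Schur
complement of the `kappa` block); this identity is asserted to 1e-10 in
the tests and is the strongest internal consistency check of the two
constructions.

## Design search

Candidate schedules live on a 0.05-unit time grid (continuous times are
kept internally; the grid is only the sweep resolution); every time
point samples all output channels, matching assays of CMS and colistin
from the same draw.  Search = uniform random search (300 iterations)
followed by cyclic line search (each time swept over the full feasible
grid, up to 3 cycles), ties broken toward the earlier time.  Samples in
constraint windows (infusion blackouts) contribute zero information by
default; a hard-constraint mode excludes them from the search instead.
Duplicate times are allowed and treated as independent observations.
A stochastic-gradient stage is deliberately absent: random search plus
exhaustive coordinate sweeps already recovers the described layouts,
and the per-draw cached evaluator makes the sweeps cheap.

The evaluator pre-computes per prior draw and grid time the quantities
the FO FIM is assembled from (`J`, residual variance and its parameter
gradient, and for POPocc the occasion sensitivities), so one objective
evaluation is a gather plus batched log-determinants.  It is tested to
agree with the reference per-design FIM path to machine precision.

## Predicted iSE and shrinkage

Per draw, `iSE = sqrt(diag((FIM_i + Prior)^-1))` — the Cramér–Rao
bound on the posterior SD; medians and IQRs are reported over draws.
Shrinkage of the EBE distribution is predicted on the variance scale
either from the averaged FIM (`diag(FIM_MAP^-1 Prior)`) or from the
expected posterior covariance (inverting per draw before averaging),
and reported on the SD scale as `1 - sqrt(1 - SH_var)`; the
expected-covariance SD-scale form is the headline predictor.  For
MAPocc the `eta` sub-block of the full inverse is used against
`Omega^-1` — marginal, not conditional-on-`kappa`, uncertainty; the
source is silent on the sub-block convention and the marginal form is
the one comparable to evaluated EBE shrinkage.

## Evaluation by simulation and MAP re-estimation

Designs are scored by simulating individuals from the *full* model
(whatever method produced the design), then minimizing

    -2 log post = sum_s [(y_s - f_s)^2 / v_s + ln v_s]
                  + eta' Omega^-1 eta + sum_j kappa_j' Pi^-1 kappa_j

over `(eta, kappa_1..kappa_m)` by L-BFGS from multiple starts (prior
mode plus prior draws — the multi-start analog of NONMEM's MCETA).
With parameter-free residual variance the problem is exactly a
penalized least squares and a Gauss–Newton solver is used instead.
Empirical iSE is the `eta` sub-block of the inverse numerical Hessian
of the half-objective at the mode (Laplace approximation).  Metrics:
per-parameter R² of the EBEs against the simulated deviations (sample
mean of the simulated deviations in the denominator; negative values
possible) and SD-scale shrinkage `1 - SD(EBE)/omega` in percent.

The colistin posterior (12 parameters from as few as 6 observations)
is multimodal: 2 starts visibly overdisperse the `eta_CL` EBEs while 6
starts match 12; 6 starts are used for colistin runs and 2 for the
unimodal 1-compartment fixture.  Monte-Carlo sizes in the acceptance
script (2000 individuals for 1-compartment runs, 400 for colistin
sparse designs, 300–1200 for rich-sampling runs) put the MC standard
error of a reported R² near 0.01–0.02.

## Fixtures and transcription choices

Fixtures ship as TOML documents (`[theta]`, `[omega]`, `[pi]`,
`[sigma]`-like error sections, `[dosing]`, `[channels]`,
`[constraints]`).  Variances are authoritative; CV% columns equal
`sqrt(variance)` throughout.

**Colistin/CMS** (hours, litres, µmol, µM): three-state linear system —
central and peripheral CMS plus formed colistin — solved exactly per
constant-rate segment via the closed-form eigenstructure (2×2 CMS
block plus a triangular colistin row), with a matrix-exponential
fallback for degenerate rates; verified against adaptive ODE
integration to 1e-8.  413 µmol loading infusion (30 min) then
206.5 µmol q12h; three occasions over 36 h; sampling blacked out during
and 15 min after each infusion.  Both channels are log concentrations;
the CMS residual SD carries `e^{eta_ER}`.  Two transcription points
deserve note: the intercompartmental clearance is 206 L/h (fast,
near-complete distribution within minutes — the reading under which
`eta_Q` is as poorly identifiable as the evaluation results show and
the Omit design collapses onto first-feasible-time + duplicated
end-of-study samples), and the fraction-metabolized occasion effect
`kappa_FM` has variance 0.35 (the printed value; the only reading under
which the MAPocc/POPocc 3-sample designs concentrate in the first
occasion).  `kappa_FM` cancels out of the colistin elimination rate and
acts purely through the observation volume.  The additive error terms
divide by the concentration (transform-both-sides) rather than by the
log concentration as printed — the printed form is singular at 1 µM,
in the middle of the colistin concentration range; the as-printed
variant remains selectable.

**1-compartment IV bolus** (dimensionless units): `CL = 9`, `V = 40`,
IIV and IOV (variance 0.0625 each) on both parameters entering one
shared exponent, q6 dosing, four occasions over 24; additive error
variance 1, optionally plus proportional variance 0.04.  A 1-unit dose
against an additive error SD of 1 gives concentrations three orders of
magnitude below the noise and cannot produce the reported recovery;
the dose scale is therefore exposed as configuration, and a dose of
500 units (concentrations ≈ 5–17, i.e. noise of 6–20 %) is the scale
consistent with the printed error magnitudes — it reproduces the
additive-error recovery and shrinkage results across methods.  No
single scale also reproduces the combined-error *Omit* values (R² 0.09
/ SH 73 % for `eta_V`); the package's fits recover `eta_V` around
0.45 under that design at every plausible scale, and this residual
discrepancy is documented rather than tuned away.

**Inflated variants**: the 1-compartment `Omega*` is the diagonal sum
`omega*^2 = omega^2 + pi^2`; the colistin `Omega*` is transcribed
re-estimated values (0.20, 3.26, 1.8), with the shared-`eta` scaling
factor moved to `sqrt(0.70/0.20) ≈ 1.871` so the printed inflated
colistin-CL IIV of 0.70 is honored.

## What the generator emulates — and what it does not

Simulated data follow the fitted model exactly: Gaussian random
effects, independent residuals (including for duplicate samples taken
at the same instant — an acknowledged idealization), no covariates, no
model misspecification, identical design for every individual.
Passing tests therefore demonstrate the estimator and design machinery,
not robustness to the correlated errors, nonlinear kinetics or
time-varying variances of real data.

## Numerical choices and degenerate inputs

- Log-determinants via `slogdet` with explicit positive-definiteness
  checks; failures raise, naming the draw — never silently clipped.
- FIMs are symmetrized; PSD is enforced to 1e-8 in tests.
- Negative rounding artifacts inside the shrinkage square root are
  clamped at zero with a warning when within 1e-10, raised otherwise.
- Singular `Omega`/`Pi` raise with a condition-number report.
- Zero-clearance models route through the augmented-state
  matrix-exponential fallback (mass-balance tests run there).
- MAP fits that fail every start are flagged, excluded and counted;
  more than 5 % failures marks a report unreliable.

## Known limitations

- FO linearization only (no FOCE), matching the evaluated methods.
- The POPocc variance-derivative simplification above.
- Design search optimizes sampling *times* only (all channels drawn
  per time); per-channel schedules would need a small extension.
- Runtimes are machine-dependent; only the MAPocc-cheaper-than-POPocc
  ordering is asserted.
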