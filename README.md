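# iovdesign

Optimal sampling-schedule design for **individual** parameter
estimation in population PK models with inter-occasion variability
(IOV) — for pharmacometricians planning studies whose goal is precise
empirical Bayes estimates (EBEs): therapeutic drug monitoring,
feedback dose individualization, or covariate analysis on EBEs.

## The problem and the criterion

In a nonlinear mixed-effects model

```
y_i = f(χ_i, g(θ, η_i, κ_1,i … κ_m,i)) + h(·, ε_i),
η_i ~ N(0, Ω),   κ_j,i ~ N(0, Π),   ε ~ N(0, Σ)
```

the individual deviations η are estimated as posterior modes (MAP).
The design χ is chosen to maximize a Ds-optimality objective built on
the MAP Fisher information — the expectation over the prior of the
individual FO information plus the prior precision:

```
FIM_MAP = E_Ω[FIM_i] + Ω⁻¹,
OFV     = E[ log |FIM_i + Prior| − log |(FIM_i + Prior)_uninteresting| ]
```

Occasion-level deviations κ (one vector per dose interval) can enter
this criterion four ways: ignored (**Omit**), folded into an inflated
IIV matrix Ω* (**Inflate**), as per-occasion nuisance parameters with
Π⁻¹ prior blocks (**MAPocc**), or as an occasion random effect whose
FO-linearized variance Σⱼ SⱼΠSⱼ' inflates the model variance
(**POPocc**).  The package optimizes schedules under all four, predicts
per-individual standard errors `iSE = sqrt(diag((FIM_i + Prior)⁻¹))`
and η-shrinkage `SH = 1 − sqrt(1 − diag(E[(FIM_i+Prior)⁻¹] Ω⁻¹))`,
and evaluates any design by stochastic simulation from the full model
followed by MAP re-estimation (R², empirical shrinkage, empirical iSE).

Two models ship as fixtures: a three-compartment colistin/prodrug
(CMS) model with log-scale concentrations on two channels, a combined
residual error carrying its own IIV, and IOV on three parameters; and
a one-compartment IV-bolus test model with IIV and IOV on clearance
and volume.  See `docs/methods.md` for the model equations, parameter
tables and every numerical choice.

## Worked example

```python
import iovdesign as iv

fx = iv.onecomp_fixture(dose_scale=500.0)          # 1-COMP fixture
cfg = iv.SearchConfig(n_samples=5, seed=1)

for method in ("omit", "mapocc"):
    design = iv.optimize_design(fx, method, cfg).design
    report = iv.evaluate_design(fx, design, 1000, seed=11, n_starts=2)
    print(method, sorted(design.times.tolist()))
    print(report.table[["R2", "SH_pct"]].round(2))
```

prints (times in hours; q6 dosing, four occasions):

```
omit [0.0, 0.0, 18.0, 20.85, 20.85]
      R2  SH_pct
CL  0.57   27.01
V   0.58   25.31
mapocc [0.0, 6.0, 9.9, 12.85, 22.35]
     R2  SH_pct
CL  0.7   20.35
V   0.7   18.14
```

Ignoring IOV (Omit) clusters duplicate samples at the concentration
peak of the first dose interval and at the end of the last one; the
IOV-aware MAPocc criterion spreads single samples across all four
occasions so individual and occasion deviations can be separated.
That shows up directly in recovery: R² of the re-estimated η rises
from ≈0.55 to ≈0.7 and shrinkage drops by ~7 percentage points.

The same workflows run from the shell via a TOML config:

```
iovdesign full --config study.toml --seed 1 --out results/
```

which writes per-method design, iSE, shrinkage and evaluation CSVs
plus a cross-method comparison table and a JSON metadata file
sufficient to re-run the bundle bit-identically.

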