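"""Design evaluation by stochastic simulation and MAP re-estimation.

Individuals are simulated from the *full* population model (IIV, IOV
and residual error, regardless of which method produced the design)
and their deviations re-estimated as posterior modes:

    -2 log post = sum_s [ (y_s - f_s)^2 / v_s + ln v_s ]
                  + eta' Omega^-1 eta + sum_j kappa_j' Pi^-1 kappa_j

minimized over ``(eta, kappa_1..kappa_m)`` from multiple starts.  The
recovered empirical Bayes estimates are scored per eta parameter by the
coefficient of determination against the simulated deviations, the
empirical SD-scale shrinkage ``1 - SD(eta_EBE)/omega`` in percent, and
(optionally) the curvature-based individual SE at the mode — the
Laplace-approximation posterior SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .nlme_model import Design, IndividualRealization, ModelFixture

__all__ = [
    "SimulatedDataset",
    "MAPFit",
    "EvaluationReport",
    "simulate_population",
    "map_estimate",
    "r_squared",
    "empirical_shrinkage",
    "evaluate_design",
]


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated individual: observations plus the true deviations."""

    times: np.ndarray
    channels: np.ndarray
    y: np.ndarray
    eta: np.ndarray
    kappas: np.ndarray
    seed: int


@dataclass(frozen=True)
class MAPFit:
    eta: np.ndarray
    kappas: np.ndarray
    objective: float  # -2 log posterior at the mode (up to a constant)
    converged: bool
    start_index: int
    ise: np.ndarray | None = None  # curvature-based posterior SD of eta
    hessian: np.ndarray | None = None


@dataclass(frozen=True)
class EvaluationReport:
    """Per-eta-parameter recovery metrics from one SSE run."""

    table: pd.DataFrame  # index: eta names; R2, SH_pct, iSE_median, iSE_IQR
    n_individuals: int
    n_failed: int
    seed: int
    unreliable: bool  # more than 5% failed fits

    def __getitem__(self, key):
        return self.table[key]


def simulate_population(
    fixture: ModelFixture,
    design: Design,
    n: int,
    seed: int,
    *,
    eps_scale: float = 1.0,
) -> list[SimulatedDataset]:
    """Simulate ``n`` individuals at ``design`` from the full model.

    ``eta ~ N(0, Omega)``, ``kappa_j ~ N(0, Pi)`` independently per
    occasion, residuals independent per sample (duplicate times get
    independent draws).  ``eps_scale=0`` is a diagnostic switch that
    returns noise-free observations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u, m, v = fixture.n_eta, fixture.n_occasions, fixture.n_kappa
    L_om = np.linalg.cholesky(fixture.omega)
    etas = rng.standard_normal((n, u)) @ L_om.T
    if v:
        L_pi = np.linalg.cholesky(fixture.pi)
        kappas = np.einsum("nmv,wv->nmw", rng.standard_normal((n, m, v)), L_pi)
    else:
        kappas = np.zeros((n, m, 0))
    eps = rng.standard_normal((n, design.n_obs))
    out = []
    for i in range(n):
        pred = fixture.predict(design.times, design.channels, etas[i], kappas[i])
        sd = fixture.error_sd(design.times, design.channels, pred, etas[i])
        y = pred + eps_scale * sd * eps[i]
        out.append(
            SimulatedDataset(
                times=design.times,
                channels=design.channels,
                y=y,
                eta=etas[i],
                kappas=kappas[i],
                seed=seed,
            )
        )
    return out


def _neg2_log_posterior(fixture, dataset, omega_inv, pi_inv):
    u, m, v = fixture.n_eta, fixture.n_occasions, fixture.n_kappa
    times, chans, y = dataset.times, dataset.channels, dataset.y

    def obj(p):
        eta = p[:u]
        kap = p[u:].reshape(m, v) if v else np.zeros((m, 0))
        try:
            with np.errstate(over="raise", invalid="raise"):
                f = fixture.predict(times, chans, eta, kap)
                var = fixture.error_sd(times, chans, f, eta) ** 2
        except (FloatingPointError, ValueError, OverflowError, RuntimeError):
            return 1e12
        if np.any(var <= 0) or not np.all(np.isfinite(f)):
            return 1e12
        val = float(np.sum((y - f) ** 2 / var + np.log(var)))
        val += float(eta @ omega_inv @ eta)
        if v:
            val += float(np.einsum("ja,ab,jb->", kap, pi_inv, kap))
        return val

    return obj


def _batched_fun_grad(fixture, dataset, omega_inv, pi_inv, fallback_obj):
    """Objective and forward-difference gradient from one batched solve.

    Evaluates the model at the base point and one forward perturbation
    per parameter in a single vectorized call; an order of magnitude
    faster than scalar finite differences for the ODE-based fixtures.
    """
    u, m, v = fixture.n_eta, fixture.n_occasions, fixture.n_kappa
    times, chans, y = dataset.times, dataset.channels, dataset.y
    dim = u + m * v

    def fun_grad(p):
        h = 1e-6 * (1.0 + np.abs(p))
        pmat = np.tile(p, (dim + 1, 1))
        pmat[1:] += np.diag(h)
        etas = pmat[:, :u]
        kaps = pmat[:, u:].reshape(dim + 1, m, v) if v else np.zeros((dim + 1, m, 0))
        try:
            with np.errstate(over="raise", invalid="raise"):
                f = fixture.predict_batch(times, chans, etas, kaps)
                var = fixture.error_sd_batch(times, chans, f, etas) ** 2
        except (FloatingPointError, ValueError, OverflowError, RuntimeError):
            return fallback_obj(p), np.zeros(dim)
        vals = np.sum((y[None, :] - f) ** 2 / var + np.log(var), axis=1)
        vals += np.einsum("bi,ij,bj->b", etas, omega_inv, etas)
        if v:
            vals += np.einsum("bja,ac,bjc->b", kaps, pi_inv, kaps)
        if not np.all(np.isfinite(vals)):
            return fallback_obj(p), np.zeros(dim)
        return float(vals[0]), (vals[1:] - vals[0]) / h

    return fun_grad


def _block_prior_precision(omega_inv, pi_inv, m, v):
    dim = omega_inv.shape[0] + m * v
    prec = np.zeros((dim, dim))
    u = omega_inv.shape[0]
    prec[:u, :u] = omega_inv
    for j in range(m):
        s = u + j * v
        prec[s : s + v, s : s + v] = pi_inv
    return prec


def _numerical_hessian(fun, p, h: float = 1e-4) -> np.ndarray:
    n = p.size
    H = np.empty((n, n))
    steps = h * (1.0 + np.abs(p))
    f0 = fun(p)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        H[i, i] = (fun(p + ei) - 2 * f0 + fun(p - ei)) / steps[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                fun(p + ei + ej) - fun(p + ei - ej) - fun(p - ei + ej) + fun(p - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


def map_estimate(
    fixture: ModelFixture,
    dataset: SimulatedDataset,
    n_starts: int = 10,
    seed: int = 0,
    *,
    compute_ise: bool = True,
    ftol: float = 1e-10,
) -> MAPFit:
    """Posterior mode of ``(eta, kappa_1..kappa_m)`` for one individual.

    The first start is the prior mode (all zeros); the remaining
    ``n_starts - 1`` are drawn from the priors (the multi-start analog
    of NONMEM's MCETA initial-estimate testing).  With no observations
    the prior mode is returned directly.  The empirical iSE is the
    square root of the eta diagonal of the inverse Hessian of the
    half-objective at the mode.
    """
    u, m, v = fixture.n_eta, fixture.n_occasions, fixture.n_kappa
    omega_inv = np.linalg.inv(fixture.omega)
    pi_inv = np.linalg.inv(fixture.pi) if v else None
    obj = _neg2_log_posterior(fixture, dataset, omega_inv, pi_inv)
    dim = u + m * v
    if dataset.y.size == 0:
        return MAPFit(np.zeros(u), np.zeros((m, v)), 0.0, True, 0, np.sqrt(np.diag(fixture.omega)))

    rng = np.random.default_rng(seed)
    starts = [np.zeros(dim)]
    for _ in range(max(0, n_starts - 1)):
        eta0 = rng.standard_normal(u) @ np.linalg.cholesky(fixture.omega).T
        if v:
            kap0 = np.einsum(
                "mv,wv->mw", rng.standard_normal((m, v)), np.linalg.cholesky(fixture.pi)
            ).ravel()
            starts.append(np.concatenate([eta0, kap0]))
        else:
            starts.append(eta0)

    # with parameter-free residual variance the objective is exactly a
    # penalized least squares: use a Gauss-Newton solver
    ls_residual = None
    if fixture.constant_error_variance:
        base = fixture.predict(dataset.times, dataset.channels, np.zeros(u), np.zeros((m, v)))
        sd0 = fixture.error_sd(dataset.times, dataset.channels, base, np.zeros(u))
        prec_chol = np.linalg.cholesky(
            _block_prior_precision(omega_inv, pi_inv, m, v)
        ).T

        def ls_residual(p):
            eta = p[:u]
            kap = p[u:].reshape(m, v) if v else np.zeros((m, 0))
            try:
                f = fixture.predict(dataset.times, dataset.channels, eta, kap)
            except (ValueError, FloatingPointError, RuntimeError):
                return np.full(dataset.y.size + p.size, 1e6)
            return np.concatenate([(dataset.y - f) / sd0, prec_chol @ p])

    best = None
    best_val = np.inf
    best_start = -1
    any_converged = False
    fun_grad = None
    if ls_residual is None and hasattr(fixture, "predict_batch"):
        fun_grad = _batched_fun_grad(fixture, dataset, omega_inv, pi_inv, obj)

    for s_idx, p0 in enumerate(starts):
        if ls_residual is not None:
            res = least_squares(ls_residual, p0, method="lm", xtol=1e-10, ftol=1e-10)
            fun = obj(res.x)
        elif fun_grad is not None:
            res = minimize(
                fun_grad, p0, jac=True, method="L-BFGS-B",
                options={"maxiter": 400, "ftol": ftol},
            )
            fun = obj(res.x)
        else:
            res = minimize(
                obj, p0, method="L-BFGS-B", options={"maxiter": 400, "ftol": ftol}
            )
            fun = res.fun
        if res.success or getattr(res, "status", 0) > 0:
            any_converged = True
        if fun < best_val:
            best_val, best, best_start = fun, res.x, s_idx

    eta = best[:u]
    kap = best[u:].reshape(m, v) if v else np.zeros((m, 0))
    ise = hess = None
    if compute_ise:
        hess = 0.5 * _numerical_hessian(obj, best)
        try:
            cov = np.linalg.inv(hess)
            d = np.diag(cov)[:u]
            ise = np.sqrt(np.maximum(d, 0.0)) if np.all(d > -1e-8) else None
        except np.linalg.LinAlgError:
            ise = None
    return MAPFit(eta, kap, best_val, any_converged, best_start, ise, hess)


def r_squared(true_eta: np.ndarray, ebe: np.ndarray) -> np.ndarray:
    """Per-parameter coefficient of determination of the EBEs.

    ``1 - sum (ebe - eta)^2 / sum (mean(eta) - eta)^2`` with the sample
    mean of the *simulated* deviations in the denominator.  Negative
    values signal re-estimation worse than predicting the mean.
    """
    true_eta = np.atleast_2d(np.asarray(true_eta, float))
    ebe = np.atleast_2d(np.asarray(ebe, float))
    if true_eta.shape != ebe.shape:
        raise ValueError("tables must have identical shape")
    if true_eta.shape[0] < 2:
        raise ValueError("need at least two individuals")
    num = np.sum((ebe - true_eta) ** 2, axis=0)
    den = np.sum((true_eta.mean(axis=0) - true_eta) ** 2, axis=0)
    if np.any(den == 0):
        raise ZeroDivisionError("zero variance in simulated deviations")
    return 1.0 - num / den


def empirical_shrinkage(ebe: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """SD-scale shrinkage ``(1 - SD(ebe)/omega) * 100`` per parameter."""
    ebe = np.atleast_2d(np.asarray(ebe, float))
    prior_sd = np.sqrt(np.diag(np.atleast_2d(omega)))
    return (1.0 - ebe.std(axis=0, ddof=1) / prior_sd) * 100.0


def evaluate_design(
    fixture: ModelFixture,
    design: Design,
    n_individuals: int,
    seed: int,
    n_starts: int = 10,
    *,
    compute_ise: bool = False,
    eps_scale: float = 1.0,
) -> EvaluationReport:
    """Full SSE pipeline: simulate, MAP-fit, score.

    Simulation and fitting always use the given (full) fixture; pass
    the fixture with IOV even when the design came from an
    IOV-ignoring method.  Reports per-eta R^2, shrinkage %, iSE
    summaries and the failed-fit count; more than 5 % failures flag the
    report as unreliable.
    """
    if n_individuals < 2:
        raise ValueError("need at least two individuals")
    datasets = simulate_population(
        fixture, design, n_individuals, seed, eps_scale=eps_scale
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF17]))
    u = fixture.n_eta
    ebe = np.empty((n_individuals, u))
    ises = []
    ok = np.ones(n_individuals, bool)
    for i, ds in enumerate(datasets):
        try:
            fit = map_estimate(
                fixture,
                ds,
                n_starts=n_starts,
                seed=int(rng.integers(2**31)),
                compute_ise=compute_ise,
            )
        except Exception:
            ok[i] = False
            continue
        if not fit.converged:
            ok[i] = False
            continue
        ebe[i] = fit.eta
        if compute_ise and fit.ise is not None:
            ises.append(fit.ise)
    n_failed = int(np.sum(~ok))
    true_eta = np.array([d.eta for d in datasets])[ok]
    ebe_ok = ebe[ok]
    r2 = r_squared(true_eta, ebe_ok)
    sh = empirical_shrinkage(ebe_ok, fixture.omega)
    if ises:
        arr = np.array(ises)
        ise_med = np.median(arr, axis=0)
        ise_iqr = np.percentile(arr, 75, axis=0) - np.percentile(arr, 25, axis=0)
    else:
        ise_med = np.full(u, np.nan)
        ise_iqr = np.full(u, np.nan)
    table = pd.DataFrame(
        {"R2": r2, "SH_pct": sh, "iSE_median": ise_med, "iSE_IQR": ise_iqr},
        index=list(fixture.eta_names),
    )
    return EvaluationReport(
        table=table,
        n_individuals=n_individuals,
        n_failed=n_failed,
        seed=seed,
        unreliable=n_failed > 0.05 * n_individuals,
    )
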