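"""MAP Fisher information matrices under four IOV-handling methods.

The individual FIM is the FO (first-order) information of the
*individual* model obtained by transferring the population random
effects to individual parameters ``theta_eta ~ N(0, Omega)`` (and, for
``mapocc``, per-occasion parameters ``theta_kappa_j ~ N(0, Pi)``).  For
a Gaussian observation model with mean ``f(p)`` and diagonal residual
variance ``v(p)``,

    FIM_kl = J_k' V^-1 J_l  +  1/2 tr(V^-1 dV/dp_k V^-1 dV/dp_l)

where ``J`` holds the prediction sensitivities.  The half-trace block is
what carries information on parameters that enter only the residual
variance (the colistin ``eta_ER``); it can be switched off.

Method tags
-----------
``omit``
    IOV ignored; parameters are ``eta``, prior ``Omega^-1``.
``inflate``
    As ``omit`` but on the IOV-inflated fixture (``Omega*``).
``mapocc``
    Occasion deviations are additional individual parameters with
    block prior ``diag(Omega^-1, Pi^-1, ..., Pi^-1)``; the ``kappa``
    entries are *uninteresting* in the Ds criterion.
``popocc``
    IOV enters as an occasion random effect: its FO-linearized variance
    contribution (sensitivities at ``kappa = 0`` times ``Pi``) is added
    to the model variance with ``Pi`` held fixed.  Fixing ``Pi`` is
    represented by omitting the ``kappa`` rows from the FIM, which is
    algebraically identical to the zero-precision prior block.

The MAP FIM is the Monte-Carlo expectation of the individual FIM over
the prior plus the prior precision; design optimization uses the Ds
objective, the expected log determinant ratio of the interesting block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import block_diag

from .nlme_model import Design, IndividualRealization, ModelFixture, build_inflated

__all__ = [
    "METHODS",
    "PriorSpec",
    "MCSet",
    "FIMResult",
    "assemble_prior",
    "draw_mcset",
    "individual_fim",
    "popocc_variance",
    "fim_map_expectation",
    "ds_ofv",
    "method_fixture",
]

METHODS = ("omit", "inflate", "mapocc", "popocc")

#: finite-difference steps: relative with an absolute floor chosen to
#: balance truncation against roundoff of the double-precision solvers
FD_REL_STEP = 1e-5
FD_ABS_FLOOR = 1e-6


class SingularVarianceError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Block prior precision with the interesting/uninteresting partition."""

    precision: np.ndarray
    labels: tuple[str, ...]
    interesting: np.ndarray
    uninteresting: np.ndarray
    method: str

    @property
    def dim(self) -> int:
        return self.precision.shape[0]


@dataclass(frozen=True)
class MCSet:
    """Reusable Monte-Carlo draws from the prior.

    The same set is used for every objective evaluation within one
    optimization run to remove Monte-Carlo jitter from the search.
    ``kappas`` is zero except for the ``mapocc`` method.
    """

    eta: np.ndarray  # (n, u)
    kappas: np.ndarray  # (n, m, v)
    seed: int
    method: str

    @property
    def n(self) -> int:
        return self.eta.shape[0]

    def realization(self, i: int) -> IndividualRealization:
        return IndividualRealization(self.eta[i], self.kappas[i])


@dataclass(frozen=True)
class FIMResult:
    matrix: np.ndarray
    labels: tuple[str, ...]
    method: str

    def to_frame(self):
        """Labelled DataFrame view (for CSV export)."""
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def method_fixture(fixture: ModelFixture, method: str) -> ModelFixture:
    """The fixture a method actually operates on (inflate -> ``Omega*``)."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {METHODS}")
    return build_inflated(fixture) if method == "inflate" and fixture.pi is not None else fixture


def _param_labels(fixture: ModelFixture, method: str) -> tuple[str, ...]:
    labels = list(fixture.eta_names)
    if method == "mapocc":
        for j in range(1, fixture.n_occasions + 1):
            labels += [f"{k}[{j}]" for k in fixture.kappa_names]
    return tuple(labels)


def assemble_prior(fixture: ModelFixture, method: str, m: int | None = None) -> PriorSpec:
    """Prior precision and Ds partition for one method.

    ``omit``/``inflate``: ``Omega^-1`` (``Omega*^-1``), all interesting.
    ``mapocc``: ``diag(Omega^-1, Pi^-1 x m)``, kappa entries uninteresting.
    ``popocc``: ``Omega^-1`` over eta only (``Pi`` fixed, its zero-prior
    rows omitted from the parameter vector).
    """
    fixture = method_fixture(fixture, method)
    m = fixture.n_occasions if m is None else m

    def _inv(mat, label):
        cond = np.linalg.cond(mat)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"{label} is singular (condition number {cond:.3g})"
            )
        return np.linalg.inv(mat)

    omega = fixture.omega_star if method == "inflate" and fixture.omega_star is not None else fixture.omega
    u = omega.shape[0]
    labels = _param_labels(fixture, method)
    if method == "mapocc":
        if fixture.pi is None:
            raise ValueError("mapocc requires a fixture with IOV")
        blocks = [_inv(omega, "Omega")] + [_inv(fixture.pi, "Pi")] * m
        precision = block_diag(*blocks)
        interesting = np.arange(u)
        uninteresting = np.arange(u, precision.shape[0])
    else:
        precision = _inv(omega, "Omega")
        interesting = np.arange(u)
        uninteresting = np.arange(0)
    return PriorSpec(precision, labels, interesting, uninteresting, method)


def draw_mcset(fixture: ModelFixture, method: str, n: int, seed: int) -> MCSet:
    """Draw ``n`` parameter sets from the method's sampling scheme.

    ``eta ~ N(0, Omega)`` (``Omega*`` for inflate); ``kappa_j ~ N(0, Pi)``
    per occasion for ``mapocc``, zero otherwise (``kappa = 0`` is the
    linearization point for ``popocc``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fixture = method_fixture(fixture, method)
    omega = fixture.omega_star if method == "inflate" and fixture.omega_star is not None else fixture.omega
    rng = np.random.default_rng(seed)
    u = omega.shape[0]
    m, v = fixture.n_occasions, fixture.n_kappa
    eta = rng.standard_normal((n, u)) @ np.linalg.cholesky(omega).T
    kappas = np.zeros((n, m, max(v, 0)))
    if method == "mapocc" and v:
        kappas = np.einsum(
            "nmv,wv->nmw", rng.standard_normal((n, m, v)), np.linalg.cholesky(fixture.pi)
        )
    return MCSet(eta=eta, kappas=kappas, seed=seed, method=method)


# ---------------------------------------------------------------------------
# individual FIM
# ---------------------------------------------------------------------------


def _pack(fixture: ModelFixture, realization: IndividualRealization, method: str):
    if method == "mapocc":
        return np.concatenate([realization.eta, realization.kappas.ravel()])
    return np.asarray(realization.eta, float).copy()


def _unpack(fixture: ModelFixture, p: np.ndarray, method: str) -> IndividualRealization:
    u = fixture.n_eta
    if method == "mapocc":
        kap = p[u:].reshape(fixture.n_occasions, fixture.n_kappa)
    else:
        kap = np.zeros((fixture.n_occasions, fixture.n_kappa))
    return IndividualRealization(p[:u], kap)


def _pred_var(fixture, design, p, method, mask):
    r = _unpack(fixture, p, method)
    f = fixture.predict(design.times, design.channels, r.eta, r.kappas)
    sd = fixture.error_sd(design.times, design.channels, f, r.eta)
    return f[mask], sd[mask] ** 2


def _fd_step(p0k: float) -> float:
    return max(FD_REL_STEP * abs(p0k), FD_ABS_FLOOR)


def batch_pred_var(fixture, times, chans, pmat, method):
    """Predictions and residual variances for a batch of parameter vectors.

    Uses the fixture's vectorized solver when it has one; otherwise
    falls back to one scalar solve per row.
    """
    u, m = fixture.n_eta, fixture.n_occasions
    v = fixture.n_kappa
    B = pmat.shape[0]
    etas = pmat[:, :u]
    if method == "mapocc":
        kaps = pmat[:, u:].reshape(B, m, v)
    else:
        kaps = np.zeros((B, m, v))
    if hasattr(fixture, "predict_batch"):
        f = fixture.predict_batch(times, chans, etas, kaps)
        var = fixture.error_sd_batch(times, chans, f, etas) ** 2
        return f, var
    f = np.empty((B, len(times)))
    var = np.empty_like(f)
    for i in range(B):
        f[i] = fixture.predict(times, chans, etas[i], kaps[i])
        var[i] = fixture.error_sd(times, chans, f[i], etas[i]) ** 2
    return f, var


def _fd_points(p0):
    """Perturbation matrix [p0; p0 +/- h_k e_k] and the step sizes."""
    P = p0.size
    h = np.array([_fd_step(p0[k]) for k in range(P)])
    pmat = np.tile(p0, (2 * P + 1, 1))
    pmat[1 : P + 1] += np.diag(h)
    pmat[P + 1 :] -= np.diag(h)
    return pmat, h


def _sensitivities(fixture, design, p0, method, mask):
    """Central-difference Jacobians of predictions and residual variances."""
    P = p0.size
    pmat, h = _fd_points(p0)
    f, var = batch_pred_var(fixture, design.times, design.channels, pmat, method)
    f, var = f[:, mask], var[:, mask]
    J = ((f[1 : P + 1] - f[P + 1 :]) / (2 * h[:, None])).T
    Dv = ((var[1 : P + 1] - var[P + 1 :]) / (2 * h[:, None])).T
    return f[0], var[0], J, Dv


def popocc_variance(
    fixture: ModelFixture,
    design: Design,
    realization: IndividualRealization,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """FO occasion-variance contribution to the model variance.

    ``sum_j S_j Pi S_j'`` with ``S_j = df/dkappa_j`` evaluated at
    ``kappa = 0``.  Sensitivities carry forward across occasion
    boundaries, so off-block entries are generally nonzero.
    """
    if fixture.pi is None or fixture.n_kappa == 0:
        n = int(np.sum(mask)) if mask is not None else design.n_obs
        return np.zeros((n, n))
    mask = np.ones(design.n_obs, bool) if mask is None else mask
    S = kappa_sensitivities(fixture, design, realization, mask)
    return np.einsum("jna,ab,jmb->nm", S, fixture.pi, S)


def kappa_sensitivities(fixture, design, realization, mask) -> np.ndarray:
    """``S[j, n, a] = df_n / dkappa_{j,a}`` at the realization's eta, kappa=0."""
    m, v = fixture.n_occasions, fixture.n_kappa
    eta = realization.eta
    h = _fd_step(0.0)
    B = m * v
    kaps = np.zeros((2 * B, m, v))
    for j in range(m):
        for a in range(v):
            kaps[j * v + a, j, a] = h
            kaps[B + j * v + a, j, a] = -h
    if hasattr(fixture, "predict_batch"):
        f = fixture.predict_batch(
            design.times, design.channels, np.tile(eta, (2 * B, 1)), kaps
        )[:, mask]
    else:
        f = np.stack(
            [
                fixture.predict(design.times, design.channels, eta, kaps[i])[mask]
                for i in range(2 * B)
            ]
        )
    S = (f[:B] - f[B:]) / (2 * h)
    return S.reshape(m, v, -1).transpose(0, 2, 1)


def individual_fim(
    fixture: ModelFixture,
    design: Design,
    realization: IndividualRealization,
    method: str,
    *,
    variance_block: bool = True,
) -> FIMResult:
    """FO individual Fisher information for one prior draw.

    Samples inside forbidden windows contribute nothing (their rows are
    dropped, equivalent to zero information).  For ``popocc`` the
    occasion-variance term is added to ``V`` at the ``kappa = 0``
    linearization and held fixed when the variance-derivative block is
    formed (only the residual variance is differentiated).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {METHODS}")
    fixture = method_fixture(fixture, method)
    labels = _param_labels(fixture, method)
    p0 = _pack(fixture, realization, method)
    if p0.size != len(labels):
        raise ValueError(
            f"realization dimension {p0.size} does not match method "
            f"parameters {len(labels)}"
        )
    mask = design.active_mask()
    P = len(labels)
    if not np.any(mask):
        return FIMResult(np.zeros((P, P)), labels, method)

    f0, v0, J, Dv = _sensitivities(fixture, design, p0, method, mask)
    if method == "popocc":
        V = np.diag(v0) + popocc_variance(fixture, design, realization, mask)
        try:
            W = np.linalg.inv(V)
        except np.linalg.LinAlgError as exc:
            raise SingularVarianceError("model variance not invertible") from exc
    else:
        if np.any(v0 <= 0):
            raise SingularVarianceError("non-positive residual variance")
        W = np.diag(1.0 / v0)
    fim = J.T @ W @ J
    if variance_block:
        # 1/2 tr(V^-1 dV_k V^-1 dV_l) with diagonal dV reduces to a
        # quadratic form in the Hadamard square of V^-1
        fim = fim + 0.5 * Dv.T @ (W * W) @ Dv
    fim = 0.5 * (fim + fim.T)
    return FIMResult(fim, labels, method)


# ---------------------------------------------------------------------------
# expectation and Ds objective
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FimMapExpectation:
    fim_map: np.ndarray  # mean individual FIM plus prior precision
    per_draw: tuple[FIMResult, ...]
    prior: PriorSpec


def fim_map_expectation(
    fixture: ModelFixture,
    design: Design,
    method: str,
    mcset: MCSet,
    *,
    variance_block: bool = True,
) -> FimMapExpectation:
    """Monte-Carlo expectation of the individual FIM plus the prior.

    Returns both the averaged matrix and every per-draw FIM (the latter
    feed the expected-covariance shrinkage and iSE predictors).
    """
    if mcset.n == 0:
        raise ValueError("empty Monte-Carlo set")
    if mcset.method != method:
        raise ValueError(f"MCSet was drawn for {mcset.method!r}, not {method!r}")
    prior = assemble_prior(fixture, method)
    fims = tuple(
        individual_fim(
            fixture, design, mcset.realization(i), method, variance_block=variance_block
        )
        for i in range(mcset.n)
    )
    mean = np.mean([f.matrix for f in fims], axis=0)
    return FimMapExpectation(mean + prior.precision, fims, prior)


def _logdet_pd(mat: np.ndarray, context: str) -> float:
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0:
        raise np.linalg.LinAlgError(f"{context}: matrix not positive definite")
    return logdet


def ds_ofv(per_draw, prior: PriorSpec) -> float:
    """Ds objective: expected log-det ratio of the interesting block.

    ``E[ log |FIM_i + Prior| - log |(FIM_i + Prior)_uninteresting| ]``;
    with no uninteresting parameters the denominator log-det is zero and
    the criterion reduces to D-optimality on the posterior information.
    """
    fims = [f.matrix if isinstance(f, FIMResult) else np.asarray(f) for f in per_draw]
    if not fims:
        raise ValueError("ds_ofv needs at least one draw")
    uidx = prior.uninteresting
    total = 0.0
    for i, fim in enumerate(fims):
        M = fim + prior.precision
        val = _logdet_pd(M, f"draw {i}")
        if uidx.size:
            val -= _logdet_pd(M[np.ix_(uidx, uidx)], f"draw {i} (uninteresting block)")
        total += val
    return total / len(fims)
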