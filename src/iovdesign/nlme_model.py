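"""Nonlinear mixed-effects PK models with three random-effect levels.

A model here is a population PK model with fixed effects ``theta``, an
inter-individual random-effect vector ``eta ~ N(0, Omega)``, one
inter-occasion random-effect vector per dose interval
``kappa_j ~ N(0, Pi)`` and residual error.  An *occasion* is one dose
interval; occasion membership of a time point follows the half-open
convention ``[start, start + tau)`` so that a sample taken exactly at a
dose time is post-dose.

Two fixtures are bundled as TOML documents:

``colistin``
    Three-state model for the prodrug CMS (central + peripheral
    compartment) and formed colistin, with log-transformed
    concentrations on two output channels and a combined residual error
    carrying its own inter-individual variability (``eta_ER``).

``onecomp``
    One-compartment IV-bolus model with IIV and IOV on both clearance
    and volume and an additive or combined residual error.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "DoseEvent",
    "DosingRegimen",
    "Channel",
    "Design",
    "IndividualRealization",
    "ModelFixture",
    "OneCompFixture",
    "ColistinFixture",
    "LinearToyFixture",
    "solve_onecomp",
    "solve_colistin",
    "model_predict",
    "error_sd",
    "occasion_of",
    "build_inflated",
    "design_from_times",
    "load_fixture",
    "colistin_fixture",
    "onecomp_fixture",
]


class InvalidParameterError(ValueError):
    """A structural parameter violated positivity or shape constraints."""


# ---------------------------------------------------------------------------
# dosing / occasions / designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseEvent:
    """One administration: ``duration == 0`` means an IV bolus."""

    time: float
    amount: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.amount < 0 or self.duration < 0 or self.time < 0:
            raise InvalidParameterError("dose time/amount/duration must be >= 0")


@dataclass(frozen=True)
class DosingRegimen:
    """Dose events plus the occasion structure of the trial.

    Parameters
    ----------
    events : sequence of DoseEvent
    tau : float
        Interdose interval (h); one occasion spans one interval.
    n_occasions : int
    horizon : float
        Design horizon (h); must satisfy ``n_occasions * tau >= horizon``.
    """

    events: tuple[DoseEvent, ...]
    tau: float
    n_occasions: int
    horizon: float

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.n_occasions < 1:
            raise InvalidParameterError("tau must be > 0 and n_occasions >= 1")
        if self.n_occasions * self.tau < self.horizon - 1e-12:
            raise InvalidParameterError("occasions do not cover the design horizon")

    def occasion_of(self, time: float) -> int:
        return occasion_of(time, self)

    def occasion_index(self, times: np.ndarray) -> np.ndarray:
        """Vectorized 1-based occasion index with half-open intervals."""
        t = np.asarray(times, dtype=float)
        if np.any(t < -1e-12) or np.any(t > self.horizon + 1e-12):
            raise ValueError("time outside [0, horizon]")
        idx = np.floor(t / self.tau).astype(int) + 1
        return np.minimum(idx, self.n_occasions)


def occasion_of(time: float, regimen: DosingRegimen) -> int:
    """1-based occasion index of ``time`` (half-open ``[start, start+tau)``).

    ``time == horizon`` maps to the last occasion.
    """
    if time < -1e-12 or time > regimen.horizon + 1e-12:
        raise ValueError(f"time {time} outside [0, {regimen.horizon}]")
    return min(int(math.floor(time / regimen.tau)) + 1, regimen.n_occasions)


@dataclass(frozen=True)
class Channel:
    name: str
    log_scale: bool = False


@dataclass(frozen=True)
class Design:
    """An ordered sampling schedule of ``(time, channel)`` pairs.

    ``forbidden_windows`` are half-open intervals ``[lo, hi)`` in which
    samples carry no information (the FIM module zeroes their rows);
    predictions are still defined there.  Duplicate ``(time, channel)``
    pairs are allowed and treated as independent observations.
    """

    times: np.ndarray
    channels: np.ndarray
    forbidden_windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        c = np.atleast_1d(np.asarray(self.channels, dtype=int))
        if t.shape != c.shape:
            raise ValueError("times and channels must have equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "channels", c)

    @property
    def n_obs(self) -> int:
        return self.times.size

    def active_mask(self) -> np.ndarray:
        """Boolean mask of samples outside every forbidden window."""
        mask = np.ones(self.n_obs, dtype=bool)
        for lo, hi in self.forbidden_windows:
            mask &= ~((self.times >= lo) & (self.times < hi))
        return mask

    def occasions(self, regimen: DosingRegimen) -> np.ndarray:
        return regimen.occasion_index(self.times)

    def sorted(self) -> "Design":
        order = np.lexsort((self.channels, self.times))
        return Design(self.times[order], self.channels[order], self.forbidden_windows)


@dataclass(frozen=True)
class IndividualRealization:
    """One individual's random-effect realization.

    ``kappas`` has shape ``(m, v)`` — one IOV vector per occasion — and
    may be a zero array of shape ``(m, 0)`` for models without IOV.
    """

    eta: np.ndarray
    kappas: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "eta", np.atleast_1d(np.asarray(self.eta, float)))
        k = np.asarray(self.kappas, dtype=float)
        if k.ndim != 2:
            raise ValueError("kappas must be a (n_occasions, n_kappa) array")
        object.__setattr__(self, "kappas", k)


def design_from_times(
    fixture: "ModelFixture",
    times: Sequence[float],
    channels: Sequence[int] | None = None,
) -> Design:
    """Build a design sampling every fixture channel at each time.

    This matches the study setting in which all output channels are
    assayed from the same draw (e.g. CMS and colistin concentrations
    measured at each time point).  Pass ``channels`` to override.
    """
    t = np.asarray(times, dtype=float)
    if channels is None:
        nc = len(fixture.channels)
        tt = np.repeat(t, nc)
        cc = np.tile(np.arange(nc), t.size)
    else:
        tt = t
        cc = np.asarray(channels, dtype=int)
    return Design(tt, cc, tuple(fixture.forbidden_windows))


# ---------------------------------------------------------------------------
# structural solvers
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _segment_structure(regimen: DosingRegimen):
    """Static per-regimen segmentation: breakpoints, occasion and doses.

    Segments are the half-open intervals between consecutive breakpoints
    (occasion boundaries, dose/infusion edges); within a segment all
    rates and inputs are constant.
    """
    bounds = {regimen.tau * j for j in range(regimen.n_occasions + 1)}
    for e in regimen.events:
        bounds.add(e.time)
        if e.duration > 0:
            bounds.add(e.time + e.duration)
    bounds.add(regimen.horizon)
    bp = np.array(sorted(b for b in bounds if b <= regimen.horizon + 1e-12))
    occ = np.minimum(
        np.floor(bp / regimen.tau).astype(int), regimen.n_occasions - 1
    )
    bolus = np.zeros(bp.size)
    rate_in = np.zeros(bp.size)
    for e in regimen.events:
        i = int(np.searchsorted(bp, e.time))
        if e.duration == 0:
            bolus[i] += e.amount
        else:
            sel = (bp >= e.time - 1e-12) & (bp < e.time + e.duration - 1e-12)
            rate_in[sel] += e.amount / e.duration
    return bp, occ, bolus, rate_in


def solve_onecomp(
    regimen: DosingRegimen,
    cl_per_occ: np.ndarray,
    v_per_occ: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Concentrations of a one-compartment IV-bolus model.

    Elimination rate ``k_j = CL_j / V_j`` is piecewise constant per
    occasion; the amount is continuous across occasion boundaries while
    the concentration ``A / V_j`` may jump when the realized volume
    switches.  Doses superpose linearly.

    Parameters are the *realized* per-occasion clearances and volumes
    (``theta * exp(eta + kappa_j)``), both strictly positive.
    """
    cl = np.asarray(cl_per_occ, dtype=float)
    v = np.asarray(v_per_occ, dtype=float)
    if np.any(cl <= 0) or np.any(v <= 0):
        raise InvalidParameterError("CL and V must be strictly positive")
    if any(e.duration != 0 for e in regimen.events):
        raise InvalidParameterError("onecomp model supports bolus doses only")
    t = np.asarray(times, dtype=float)
    if np.any(t < -1e-12) or np.any(t > regimen.horizon + 1e-12):
        raise ValueError("time outside [0, horizon]")
    k = cl / v

    bp, occ, bolus, _ = _segment_structure(regimen)
    n_seg = bp.size
    # amount at the start of each segment (just after any bolus there)
    width = np.diff(bp, append=bp[-1])
    decay = np.exp(-k[occ] * width)
    a_start = np.empty(n_seg)
    amount = 0.0
    for i in range(n_seg):
        amount += bolus[i]
        a_start[i] = amount
        amount *= decay[i]

    seg = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, n_seg - 1)
    a_t = a_start[seg] * np.exp(-k[occ[seg]] * (t - bp[seg]))
    occ_t = np.minimum((t // regimen.tau).astype(int), regimen.n_occasions - 1)
    return a_t / v[occ_t]


def _propagate_linear(A, b, x0, dts):
    """States ``x(dt)`` of ``x' = A x + b`` and the state at ``max(dt)``.

    Uses the eigendecomposition of ``A`` (fast, vectorized over ``dts``)
    with a matrix-exponential fallback on an augmented state when ``A``
    is singular or badly conditioned (e.g. all clearances zero).
    """
    dts = np.asarray(dts, dtype=float)
    n = A.shape[0]
    use_eig = True
    try:
        lam, P = np.linalg.eig(A)
        if np.linalg.cond(P) > 1e8 or np.min(np.abs(lam)) < 1e-12 * max(
            1.0, np.max(np.abs(lam))
        ):
            use_eig = False
    except np.linalg.LinAlgError:  # pragma: no cover - eig on 3x3 rarely fails
        use_eig = False

    if use_eig:
        xp = np.linalg.solve(A, -b)
        coef = np.linalg.solve(P, x0 - xp)
        states = xp[None, :] + np.real(
            (np.exp(np.outer(dts, lam)) * coef[None, :]) @ P.T
        )
        return states
    # augmented constant-input formulation; exact for singular A
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = b
    x_aug = np.concatenate([x0, [1.0]])
    states = np.empty((dts.size, n))
    for i, dt in enumerate(dts):
        states[i] = (expm(M * dt) @ x_aug)[:n]
    return states


def solve_colistin(
    regimen: DosingRegimen,
    rates_per_occ: dict,
    times: np.ndarray,
) -> np.ndarray:
    """Amounts ``(A_CMS1, A_CMS2, A_Col)`` of the CMS/colistin system.

    ``rates_per_occ`` maps the first-order rate constants, each an array
    of length ``n_occasions``:

    - ``k10``: CMS1 elimination (all of it forms colistin),
    - ``k12``/``k21``: distribution to/from the peripheral compartment,
    - ``kcol``: colistin elimination.

    The system is linear with piecewise-constant rates (they change only
    at occasion boundaries) and constant infusion input into CMS1, so it
    is solved exactly segment by segment.  Amounts are continuous across
    occasion boundaries.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < -1e-12) or np.any(t > regimen.horizon + 1e-12):
        raise ValueError("time outside [0, horizon]")
    k10 = np.asarray(rates_per_occ["k10"], float)
    k12 = np.asarray(rates_per_occ["k12"], float)
    k21 = np.asarray(rates_per_occ["k21"], float)
    kcol = np.asarray(rates_per_occ["kcol"], float)
    if np.any(k10 < 0) or np.any(k12 < 0) or np.any(k21 < 0) or np.any(kcol < 0):
        raise InvalidParameterError("rate constants must be non-negative")

    bp, seg_occ, bolus, rate_in = _segment_structure(regimen)
    n_seg = bp.size

    # closed-form eigenstructure per occasion: the CMS block is 2x2 and
    # the colistin row is triangular, so eigenvalues/vectors are analytic
    decomp_cache: dict[int, tuple | None] = {}

    def decomp(occ: int):
        if occ not in decomp_cache:
            a = -(k12[occ] + k10[occ])
            b = k21[occ]
            c = k12[occ]
            e = kcol[occ]
            tr = a - b
            disc = (a + b) ** 2 + 4.0 * b * c
            scale = max(abs(a), b, c, e, 1e-300)
            res = None
            if disc > 1e-18 * scale**2 and b > 1e-12 * scale and e > 1e-12 * scale:
                sq = math.sqrt(disc)
                lam1 = 0.5 * (tr + sq)
                lam2 = 0.5 * (tr - sq)
                if (
                    abs(lam1 - lam2) > 1e-9 * scale
                    and abs(lam1 + e) > 1e-9 * scale
                    and abs(lam2 + e) > 1e-9 * scale
                    and k10[occ] > 1e-12 * scale
                ):
                    w1 = k10[occ] * b / (lam1 + e)
                    w2 = k10[occ] * b / (lam2 + e)
                    res = (a, b, e, lam1, lam2, w1, w2, k10[occ], c)
            decomp_cache[occ] = res
        return decomp_cache[occ]

    out = np.empty((t.size, 3))
    x = np.zeros(3)
    seg = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, n_seg - 1)
    for i in range(n_seg):
        x = x.copy()
        x[0] += bolus[i]
        dc = decomp(seg_occ[i])
        need = np.flatnonzero(seg == i)
        dts = t[need] - bp[i]
        last = i + 1 == n_seg
        if not last:
            dts = np.append(dts, bp[i + 1] - bp[i])
        if dts.size == 0:
            continue
        r_in = rate_in[i]
        if dc is not None:
            a, b, e, lam1, lam2, w1, w2, k10o, c = dc
            if r_in:
                xp1 = r_in / k10o
                xp2 = r_in * c / (k10o * b)
                xp3 = r_in / e
            else:
                xp1 = xp2 = xp3 = 0.0
            y1, y2, y3 = x[0] - xp1, x[1] - xp2, x[2] - xp3
            c1 = (y2 - (lam2 - a) * y1 / b) / (lam1 - lam2)
            c2 = y1 / b - c1
            c3 = y3 - c1 * w1 - c2 * w2
            E1 = np.exp(lam1 * dts)
            E2 = np.exp(lam2 * dts)
            E3 = np.exp(-e * dts)
            states = np.empty((dts.size, 3))
            states[:, 0] = xp1 + b * (c1 * E1 + c2 * E2)
            states[:, 1] = xp2 + c1 * (lam1 - a) * E1 + c2 * (lam2 - a) * E2
            states[:, 2] = xp3 + c1 * w1 * E1 + c2 * w2 * E2 + c3 * E3
        else:
            A = np.array(
                [
                    [-(k12[seg_occ[i]] + k10[seg_occ[i]]), k21[seg_occ[i]], 0.0],
                    [k12[seg_occ[i]], -k21[seg_occ[i]], 0.0],
                    [k10[seg_occ[i]], 0.0, -kcol[seg_occ[i]]],
                ]
            )
            states = _propagate_linear(A, np.array([r_in, 0.0, 0.0]), x, dts)
        if last:
            out[need] = states
        else:
            out[need] = states[:-1]
            x = states[-1]
    total_dose = float(np.sum(bolus) + np.sum(rate_in * np.diff(bp, append=bp[-1])))
    if np.any(out < -1e-6 * max(1.0, total_dose)):
        raise RuntimeError("solver consistency: negative compartment amount")
    return out


def _solve_colistin_batch(regimen, rates_b: dict, times: np.ndarray) -> np.ndarray:
    """Batched variant of :func:`solve_colistin`.

    ``rates_b`` entries have shape ``(B, n_occasions)``; returns amounts
    of shape ``(B, n_times, 3)``.  Parameter sets whose eigenstructure
    is degenerate are routed through the scalar solver.
    """
    t = np.asarray(times, dtype=float)
    k10 = np.asarray(rates_b["k10"], float)
    k12 = np.asarray(rates_b["k12"], float)
    k21 = np.asarray(rates_b["k21"], float)
    kcol = np.asarray(rates_b["kcol"], float)
    B = k10.shape[0]

    # per-(row, occasion) analytic eigenstructure
    a = -(k12 + k10)
    b = k21
    c = k12
    e = kcol
    disc = (a + b) ** 2 + 4.0 * b * c
    sq = np.sqrt(np.maximum(disc, 0.0))
    lam1 = 0.5 * (a - b + sq)
    lam2 = 0.5 * (a - b - sq)
    scale = np.maximum.reduce([np.abs(a), b, c, e]) + 1e-300
    good = (
        (disc > 1e-18 * scale**2)
        & (b > 1e-12 * scale)
        & (e > 1e-12 * scale)
        & (k10 > 1e-12 * scale)
        & (np.abs(lam1 - lam2) > 1e-9 * scale)
        & (np.abs(lam1 + e) > 1e-9 * scale)
        & (np.abs(lam2 + e) > 1e-9 * scale)
    )
    good_rows = np.all(good, axis=1)
    out = np.empty((B, t.size, 3))
    if not np.all(good_rows):
        for ib in np.flatnonzero(~good_rows):
            out[ib] = solve_colistin(
                regimen,
                {k: rb[ib] for k, rb in (("k10", k10), ("k12", k12), ("k21", k21), ("kcol", kcol))},
                t,
            )
        keep = np.flatnonzero(good_rows)
        if keep.size == 0:
            return out
    else:
        keep = np.arange(B)
    w1 = k10 * b / (lam1 + e)
    w2 = k10 * b / (lam2 + e)

    bp, seg_occ, bolus, rate_in = _segment_structure(regimen)
    n_seg = bp.size
    seg = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, n_seg - 1)
    x = np.zeros((keep.size, 3))
    res = np.empty((keep.size, t.size, 3))
    for i in range(n_seg):
        x = x.copy()
        x[:, 0] += bolus[i]
        occ = seg_occ[i]
        ai, bi, ei = a[keep, occ], b[keep, occ], e[keep, occ]
        l1, l2 = lam1[keep, occ], lam2[keep, occ]
        w1i, w2i = w1[keep, occ], w2[keep, occ]
        k10i, ci = k10[keep, occ], c[keep, occ]
        r_in = rate_in[i]
        if r_in:
            xp1 = r_in / k10i
            xp2 = r_in * ci / (k10i * bi)
            xp3 = r_in / ei
        else:
            xp1 = xp2 = xp3 = np.zeros(keep.size)
        y1 = x[:, 0] - xp1
        y2 = x[:, 1] - xp2
        y3 = x[:, 2] - xp3
        c1 = (y2 - (l2 - ai) * y1 / bi) / (l1 - l2)
        c2 = y1 / bi - c1
        c3 = y3 - c1 * w1i - c2 * w2i
        need = np.flatnonzero(seg == i)
        dts = t[need] - bp[i]
        last = i + 1 == n_seg
        if not last:
            dts = np.append(dts, bp[i + 1] - bp[i])
        if dts.size == 0:
            continue
        E1 = np.exp(np.outer(l1, dts))
        E2 = np.exp(np.outer(l2, dts))
        E3 = np.exp(np.outer(-ei, dts))
        s0 = xp1[:, None] + bi[:, None] * (c1[:, None] * E1 + c2[:, None] * E2)
        s1 = (
            xp2[:, None]
            + c1[:, None] * (l1 - ai)[:, None] * E1
            + c2[:, None] * (l2 - ai)[:, None] * E2
        )
        s2 = (
            xp3[:, None]
            + c1[:, None] * w1i[:, None] * E1
            + c2[:, None] * w2i[:, None] * E2
            + c3[:, None] * E3
        )
        if last:
            res[:, need, 0], res[:, need, 1], res[:, need, 2] = s0, s1, s2
        else:
            res[:, need, 0], res[:, need, 1], res[:, need, 2] = (
                s0[:, :-1],
                s1[:, :-1],
                s2[:, :-1],
            )
            x = np.stack([s0[:, -1], s1[:, -1], s2[:, -1]], axis=1)
    out[keep] = res
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFixture:
    """A complete NLME model: structure, random effects, dosing, channels.

    Subclasses implement :meth:`predict` (structural prediction on the
    observation scale of each channel) and :meth:`error_sd` (per-sample
    residual SD).  ``omega_star`` is the IOV-inflated IIV matrix used by
    the *Inflate* design method.
    """

    name: str
    theta: dict
    eta_names: tuple[str, ...]
    kappa_names: tuple[str, ...]
    omega: np.ndarray
    pi: np.ndarray | None
    omega_star: np.ndarray | None
    regimen: DosingRegimen
    channels: tuple[Channel, ...]
    forbidden_windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "omega", np.atleast_2d(np.asarray(self.omega, float)))
        if self.pi is not None:
            object.__setattr__(self, "pi", np.atleast_2d(np.asarray(self.pi, float)))
        if self.omega_star is not None:
            object.__setattr__(
                self, "omega_star", np.atleast_2d(np.asarray(self.omega_star, float))
            )
        for mat, label in ((self.omega, "omega"), (self.pi, "pi")):
            if mat is None:
                continue
            if not np.allclose(mat, mat.T):
                raise InvalidParameterError(f"{label} must be symmetric")
            if np.min(np.linalg.eigvalsh(mat)) < -1e-10:
                raise InvalidParameterError(f"{label} must be positive semidefinite")
        if self.omega.shape[0] != len(self.eta_names):
            raise InvalidParameterError("omega dimension != number of eta names")
        if self.pi is not None and self.pi.shape[0] != len(self.kappa_names):
            raise InvalidParameterError("pi dimension != number of kappa names")

    # -- dimensions ---------------------------------------------------
    @property
    def n_eta(self) -> int:
        return len(self.eta_names)

    @property
    def n_kappa(self) -> int:
        return len(self.kappa_names) if self.pi is not None else 0

    @property
    def n_occasions(self) -> int:
        return self.regimen.n_occasions

    def zero_realization(self) -> IndividualRealization:
        return IndividualRealization(
            np.zeros(self.n_eta), np.zeros((self.n_occasions, self.n_kappa))
        )

    @property
    def constant_error_variance(self) -> bool:
        """True when the residual variance depends on no parameter.

        Lets MAP estimation use an exact penalized-least-squares path.
        """
        return False

    # -- model surface ------------------------------------------------
    def predict(self, times, channels, eta, kappas) -> np.ndarray:
        raise NotImplementedError

    def error_sd(self, times, channels, pred, eta) -> np.ndarray:
        raise NotImplementedError

    def inflated(self) -> "ModelFixture":
        return build_inflated(self)

    def _check_realization(self, eta, kappas) -> tuple[np.ndarray, np.ndarray]:
        eta = np.atleast_1d(np.asarray(eta, float))
        kappas = np.asarray(kappas, float)
        if eta.size != self.n_eta:
            raise ValueError(f"eta must have length {self.n_eta}")
        if kappas.shape != (self.n_occasions, self.n_kappa):
            raise ValueError(
                f"kappas must have shape {(self.n_occasions, self.n_kappa)}"
            )
        return eta, kappas


def model_predict(
    fixture: ModelFixture, design: Design, realization: IndividualRealization
) -> np.ndarray:
    """Per-sample structural predictions on each channel's observation scale.

    Samples inside forbidden windows are still predicted; zeroing their
    information is the FIM module's concern.
    """
    return fixture.predict(
        design.times, design.channels, realization.eta, realization.kappas
    )


def error_sd(
    fixture: ModelFixture,
    design: Design,
    prediction: np.ndarray,
    realization: IndividualRealization,
) -> np.ndarray:
    """Per-sample residual SD for predictions computed on ``design``."""
    return fixture.error_sd(design.times, design.channels, prediction, realization.eta)


# -- one-compartment fixture ------------------------------------------------


@dataclass(frozen=True)
class OneCompFixture(ModelFixture):
    """1-compartment IV-bolus model, additive or combined residual error.

    IIV and IOV act multiplicatively on the same parameters:
    ``CL_j = theta_CL * exp(eta_CL + kappa_CL_j)`` and likewise for V, so
    the realized parameter differs per occasion.
    """

    sigma2_add: float = 1.0
    sigma2_prop: float = 0.0

    @property
    def constant_error_variance(self) -> bool:
        return self.sigma2_prop == 0.0

    def _realized(self, eta, kappas):
        m = self.n_occasions
        cl = np.full(m, self.theta["CL"], dtype=float)
        v = np.full(m, self.theta["V"], dtype=float)
        exps = {"CL": np.zeros(m), "V": np.zeros(m)}
        for i, nm in enumerate(self.eta_names):
            exps[nm] = exps[nm] + eta[i]
        for i, nm in enumerate(self.kappa_names[: kappas.shape[1]]):
            exps[nm] = exps[nm] + kappas[:, i]
        return cl * np.exp(exps["CL"]), v * np.exp(exps["V"])

    def predict(self, times, channels, eta, kappas):
        eta, kappas = self._check_realization(eta, kappas)
        cl, v = self._realized(eta, kappas)
        return solve_onecomp(self.regimen, cl, v, times)

    def error_sd(self, times, channels, pred, eta):
        var = self.sigma2_add + self.sigma2_prop * np.asarray(pred, float) ** 2
        return np.sqrt(var)

    # batched variants (leading axis = parameter set) for fast MAP fits
    def predict_batch(self, times, channels, etas, kappas_b):
        B = etas.shape[0]
        m = self.n_occasions
        exps_cl = np.zeros((B, m))
        exps_v = np.zeros((B, m))
        for i, nm in enumerate(self.eta_names):
            tgt = exps_cl if nm == "CL" else exps_v
            tgt += etas[:, i, None]
        for i, nm in enumerate(self.kappa_names[: kappas_b.shape[2]]):
            tgt = exps_cl if nm == "CL" else exps_v
            tgt += kappas_b[:, :, i]
        cl = self.theta["CL"] * np.exp(exps_cl)
        v = self.theta["V"] * np.exp(exps_v)
        k = cl / v
        t = np.asarray(times, float)
        reg = self.regimen
        bp, occ, bolus, _ = _segment_structure(reg)
        n_seg = bp.size
        width = np.diff(bp, append=bp[-1])
        decay = np.exp(-k[:, occ] * width)
        a_start = np.empty((B, n_seg))
        amount = np.zeros(B)
        for i in range(n_seg):
            amount = amount + bolus[i]
            a_start[:, i] = amount
            amount = amount * decay[:, i]
        seg = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, n_seg - 1)
        a_t = a_start[:, seg] * np.exp(-k[:, occ[seg]] * (t - bp[seg]))
        occ_t = np.minimum((t // reg.tau).astype(int), reg.n_occasions - 1)
        return a_t / v[:, occ_t]

    def error_sd_batch(self, times, channels, pred_b, etas):
        return np.sqrt(self.sigma2_add + self.sigma2_prop * pred_b**2)


# -- colistin fixture -------------------------------------------------------


@dataclass(frozen=True)
class ColistinFixture(ModelFixture):
    """CMS/colistin population PK model.

    Random-effect structure: ``eta = (eta_CL, eta_Q, eta_ER)`` with
    ``eta_CL`` shared between CMS and colistin clearance (scaled by
    ``theta_sc`` for colistin) and ``eta_ER`` scaling the CMS residual
    SD; ``kappa = (kappa_CL_CMS, kappa_V_CMS2, kappa_FM)`` per occasion.
    Output channels are log concentrations of CMS (central) and colistin.
    """

    error: dict = field(default_factory=dict)

    def _rates(self, eta, kappas):
        th = self.theta
        m = self.n_occasions
        e_cl, e_q = eta[0], eta[1]
        if kappas.shape[1]:
            k_cl, k_v2, k_fm = kappas[:, 0], kappas[:, 1], kappas[:, 2]
        else:  # inflated variant: no IOV
            k_cl = k_v2 = k_fm = np.zeros(m)
        cl_cms = th["CL_CMS"] * np.exp(e_cl + k_cl)
        q = th["Q"] * math.exp(e_q)
        v2 = th["V_CMS2"] * np.exp(k_v2)
        # kappa_FM cancels between the clearance and volume terms of the
        # colistin elimination rate; written out as in the model equations.
        cl_col = th["CL_col"] * np.exp(e_cl * th["sc"] + k_fm)
        v_col = th["V_col"] * np.exp(k_fm)
        return {
            "k10": cl_cms / th["V_CMS1"],
            "k12": np.full(m, q / th["V_CMS1"]),
            "k21": q / v2,
            "kcol": cl_col / v_col,
        }

    def amounts(self, times, eta, kappas) -> np.ndarray:
        eta, kappas = self._check_realization(eta, kappas)
        return solve_colistin(self.regimen, self._rates(eta, kappas), times)

    def predict(self, times, channels, eta, kappas):
        eta, kappas = self._check_realization(eta, kappas)
        times = np.asarray(times, float)
        channels = np.asarray(channels, int)
        amt = self.amounts(times, eta, kappas)
        occ = self.regimen.occasion_index(times) - 1
        k_fm = kappas[occ, 2] if kappas.shape[1] else np.zeros(times.size)
        conc = np.where(
            channels == 0,
            amt[:, 0] / self.theta["V_CMS1"],
            amt[:, 2] / (self.theta["V_col"] * np.exp(k_fm)),
        )
        bad = conc <= 0
        if np.any(bad):
            raise ValueError(
                f"non-positive concentration under log channel at sample(s) "
                f"{np.flatnonzero(bad).tolist()}"
            )
        return np.log(conc)

    def error_sd(self, times, channels, pred, eta):
        pred = np.asarray(pred, float)
        channels = np.asarray(channels, int)
        er = self.error
        if er.get("denominator", "conc") == "conc":
            denom = np.exp(pred)  # transform-both-sides: additive SD / C
        else:
            denom = pred  # as-printed: additive SD / ln(C)
            if np.any(np.abs(denom) < 1e-12):
                bad = np.flatnonzero(np.abs(denom) < 1e-12).tolist()
                raise ZeroDivisionError(
                    f"singular log-concentration error denominator at sample(s) {bad}"
                )
        with np.errstate(divide="ignore"):
            var = np.where(
                channels == 0,
                er["CMS_prop"] ** 2 + er["CMS_add"] ** 2 / denom**2,
                er["col_prop"] ** 2 + er["col_add"] ** 2 / denom**2,
            )
        sd = np.sqrt(var)
        return np.where(channels == 0, sd * math.exp(eta[2]), sd)

    # batched variants (leading axis = parameter set) for fast MAP fits
    def predict_batch(self, times, channels, etas, kappas_b):
        B = etas.shape[0]
        times = np.asarray(times, float)
        channels = np.asarray(channels, int)
        m = self.n_occasions
        th = self.theta
        if kappas_b.shape[2]:
            k_cl, k_v2, k_fm = kappas_b[:, :, 0], kappas_b[:, :, 1], kappas_b[:, :, 2]
        else:
            k_cl = k_v2 = k_fm = np.zeros((B, m))
        cl_cms = th["CL_CMS"] * np.exp(etas[:, 0, None] + k_cl)
        q = th["Q"] * np.exp(etas[:, 1])
        rates = {
            "k10": cl_cms / th["V_CMS1"],
            "k12": np.repeat(q[:, None] / th["V_CMS1"], m, axis=1),
            "k21": q[:, None] / (th["V_CMS2"] * np.exp(k_v2)),
            "kcol": np.repeat(
                (th["CL_col"] * np.exp(etas[:, 0] * th["sc"]) / th["V_col"])[:, None],
                m,
                axis=1,
            ),
        }
        amt = _solve_colistin_batch(self.regimen, rates, times)
        occ = self.regimen.occasion_index(times) - 1
        conc = np.where(
            channels[None, :] == 0,
            amt[:, :, 0] / th["V_CMS1"],
            amt[:, :, 2] / (th["V_col"] * np.exp(k_fm[:, occ])),
        )
        if np.any(conc <= 0):
            raise ValueError("non-positive concentration under log channel")
        return np.log(conc)

    def error_sd_batch(self, times, channels, pred_b, etas):
        channels = np.asarray(channels, int)
        er = self.error
        if er.get("denominator", "conc") == "conc":
            denom = np.exp(pred_b)
        else:
            denom = pred_b
        with np.errstate(divide="ignore"):
            var = np.where(
                channels[None, :] == 0,
                er["CMS_prop"] ** 2 + er["CMS_add"] ** 2 / denom**2,
                er["col_prop"] ** 2 + er["col_add"] ** 2 / denom**2,
            )
        sd = np.sqrt(var)
        return np.where(
            channels[None, :] == 0, sd * np.exp(etas[:, 2, None]), sd
        )


# -- linear toy fixture -----------------------------------------------------


def _ones_basis(u):
    def basis(t):
        t = np.atleast_1d(np.asarray(t, float))
        return np.ones((t.size, u))

    return basis


@dataclass(frozen=True)
class LinearToyFixture(ModelFixture):
    """Linear-Gaussian toy model for closed-form cross-checks.

    ``y(t) = intercept + eta_basis(t) @ eta + kappa_basis(t) @ kappa_occ(t)``
    with constant residual SD ``sigma`` (optionally scaled by
    ``exp(eta[error_eta_index])`` to emulate a variance parameter).
    Linear in all random effects, so FO linearization and the Laplace
    posterior are exact — the analytic normal posterior is the oracle.
    """

    sigma: float = 1.0
    intercept: float = 0.0
    eta_basis: Callable = None
    kappa_basis: Callable = None
    error_eta_index: int | None = None

    @property
    def constant_error_variance(self) -> bool:
        return self.error_eta_index is None

    def predict(self, times, channels, eta, kappas):
        eta, kappas = self._check_realization(eta, kappas)
        times = np.atleast_1d(np.asarray(times, float))
        eb = self.eta_basis or _ones_basis(self.n_eta)
        y = self.intercept + eb(times) @ eta
        if self.n_kappa:
            kb = self.kappa_basis or _ones_basis(self.n_kappa)
            occ = self.regimen.occasion_index(times) - 1
            y = y + np.einsum("tv,tv->t", kb(times), kappas[occ])
        return y

    def error_sd(self, times, channels, pred, eta):
        sd = np.full(np.atleast_1d(np.asarray(pred, float)).shape, self.sigma)
        if self.error_eta_index is not None:
            sd = sd * math.exp(eta[self.error_eta_index])
        return sd


def linear_toy(
    omega,
    pi=None,
    sigma: float = 1.0,
    m: int = 2,
    tau: float = 1.0,
    eta_basis=None,
    kappa_basis=None,
    error_eta_index=None,
    intercept: float = 0.0,
) -> LinearToyFixture:
    """Convenience constructor for :class:`LinearToyFixture`."""
    omega = np.atleast_2d(np.asarray(omega, float))
    u = omega.shape[0]
    v = 0 if pi is None else np.atleast_2d(np.asarray(pi, float)).shape[0]
    regimen = DosingRegimen((), tau=tau, n_occasions=m, horizon=m * tau)
    return LinearToyFixture(
        name="linear-toy",
        theta={},
        eta_names=tuple(f"eta{i}" for i in range(u)),
        kappa_names=tuple(f"kappa{i}" for i in range(v)),
        omega=omega,
        pi=None if pi is None else np.atleast_2d(np.asarray(pi, float)),
        omega_star=None,
        regimen=regimen,
        channels=(Channel("DV", False),),
        sigma=sigma,
        intercept=intercept,
        eta_basis=eta_basis,
        kappa_basis=kappa_basis,
        error_eta_index=error_eta_index,
    )


# ---------------------------------------------------------------------------
# inflation and fixture loading
# ---------------------------------------------------------------------------


def build_inflated(fixture: ModelFixture) -> ModelFixture:
    """Return the fixture with IIV replaced by the IOV-inflated ``Omega*``.

    The inflated matrix is taken verbatim from the fixture (for the
    colistin model these are re-estimated values; for the 1-compartment
    model the diagonal sum ``omega*^2 = omega^2 + pi^2``); ``Pi`` is
    removed and the residual error is left unchanged.  For the colistin
    fixture the IIV scaling factor ``theta_sc`` is replaced by its
    inflated counterpart so the colistin-clearance IIV matches the
    re-estimated value.
    """
    if fixture.pi is None:
        raise ValueError("fixture has no IOV to inflate")
    if fixture.omega_star is None:
        raise KeyError("fixture has no inflated covariance (omega_star) configured")
    kwargs = dict(
        name=fixture.name + "-inflated",
        omega=fixture.omega_star,
        omega_star=fixture.omega_star,
        pi=None,
        kappa_names=(),
    )
    if isinstance(fixture, ColistinFixture) and "sc_star" in fixture.theta:
        theta = dict(fixture.theta)
        theta["sc"] = theta["sc_star"]
        kwargs["theta"] = theta
    inflated = replace(fixture, **kwargs)
    # inflated model still needs per-occasion kappa arrays of width 0
    return inflated


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("iovdesign") / "fixtures" / f"{name}.toml"))


def load_fixture(
    source: str | Path,
    *,
    error: str | None = None,
    dose_scale: float = 1.0,
    error_denominator: str | None = None,
    iiv: Sequence[str] | None = None,
    iov: Sequence[str] | None = None,
) -> ModelFixture:
    """Load a model fixture from a bundled name or a TOML document path.

    Parameters
    ----------
    source : str or Path
        ``"colistin"``, ``"onecomp"`` or a path to a fixture document.
    error : str, optional
        For the one-compartment model: ``"additive"`` (default) or
        ``"combined"``.
    dose_scale : float
        Multiplies every dose amount.  The one-compartment table prints
        a 1-unit dose against an additive error SD of 1; the scale that
        is consistent with those error magnitudes (concentrations of
        order tens of units) is 1000 — see the methods note.  Any
        rescaling is recorded on the returned fixture's ``theta``.
    error_denominator : str, optional
        Colistin additive-error denominator convention: ``"conc"``
        (transform-both-sides, default) or ``"logconc"`` (as printed,
        singular at 1 µM).
    iiv, iov : sequence of str, optional
        Restrict the one-compartment random effects to a subset of
        parameter names (used for reduced toy variants).
    """
    path = Path(source) if Path(str(source)).suffix == ".toml" else _fixture_path(str(source))
    if not path.exists():
        raise FileNotFoundError(f"no fixture document at {path}")
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)

    kind = doc["model"]
    dosing = doc["dosing"]
    events = tuple(
        DoseEvent(d["time"], d["amount"] * dose_scale, d.get("duration", 0.0))
        for d in dosing["doses"]
    )
    regimen = DosingRegimen(
        events, dosing["tau"], dosing["n_occasions"], dosing["horizon"]
    )
    channels = tuple(
        Channel(n, bool(ls))
        for n, ls in zip(doc["channels"]["names"], doc["channels"]["log_scale"])
    )
    forbidden = tuple(tuple(w) for w in doc.get("constraints", {}).get("forbidden", []))
    theta = dict(doc["theta"])
    if dose_scale != 1.0:
        theta["dose_scale"] = dose_scale

    if kind == "onecomp":
        names = list(doc["omega"]["names"])
        om = dict(zip(names, doc["omega"]["variances"]))
        om_star = dict(zip(names, doc["omega_star"]["variances"]))
        pi = dict(zip(doc["pi"]["names"], doc["pi"]["variances"]))
        eta_names = tuple(iiv) if iiv is not None else tuple(names)
        kappa_names = tuple(iov) if iov is not None else tuple(doc["pi"]["names"])
        err = error or "additive"
        if err not in ("additive", "combined"):
            raise ValueError("error must be 'additive' or 'combined'")
        return OneCompFixture(
            name="onecomp" + ("" if err == "additive" else "-combined"),
            theta=theta,
            eta_names=eta_names,
            kappa_names=kappa_names,
            omega=np.diag([om[n] for n in eta_names]),
            pi=np.diag([pi[n] for n in kappa_names]) if kappa_names else None,
            omega_star=np.diag([om_star[n] for n in eta_names]),
            regimen=regimen,
            channels=channels,
            forbidden_windows=forbidden,
            sigma2_add=doc["error"]["add_var"],
            sigma2_prop=doc["error"]["prop_var"] if err == "combined" else 0.0,
        )
    if kind == "colistin":
        err_cfg = dict(doc["error"])
        if error_denominator is not None:
            if error_denominator not in ("conc", "logconc"):
                raise ValueError("error_denominator must be 'conc' or 'logconc'")
            err_cfg["denominator"] = error_denominator
        theta["sc_star"] = doc["omega_star"]["sc"]
        return ColistinFixture(
            name="colistin",
            theta=theta,
            eta_names=tuple(doc["omega"]["names"]),
            kappa_names=tuple(doc["pi"]["names"]),
            omega=np.diag(doc["omega"]["variances"]),
            pi=np.diag(doc["pi"]["variances"]),
            omega_star=np.diag(doc["omega_star"]["variances"]),
            regimen=regimen,
            channels=channels,
            forbidden_windows=forbidden,
            error=err_cfg,
        )
    raise ValueError(f"unknown model kind {kind!r}")


def colistin_fixture(**kwargs) -> ColistinFixture:
    """The CMS/colistin fixture (413 µmol load then 206.5 µmol q12h)."""
    return load_fixture("colistin", **kwargs)


def onecomp_fixture(**kwargs) -> OneCompFixture:
    """The 1-compartment IV-bolus fixture (1-unit dose q6, 4 occasions)."""
    return load_fixture("onecomp", **kwargs)
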