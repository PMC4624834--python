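"""Ds-optimal sampling-schedule search.

Candidate designs live on a discrete time grid; every grid time samples
all of the model's output channels (both CMS and colistin are assayed
from one draw).  The search is a random-search seeding stage followed
by a cyclic line-search polish: each sampling time in turn is swept
over the feasible grid holding the others fixed, until a full cycle
brings no improvement.  Ties in the objective are broken toward the
earlier time.  One fixed Monte-Carlo set of prior draws is reused for
every objective evaluation of a run so the search surface is
deterministic.

The evaluator pre-computes, per prior draw and grid time, the
prediction/variance sensitivities that the FO individual FIM is built
from, so evaluating a candidate design is a cheap gather-and-logdet.
It reproduces :func:`iovdesign.fim_map.individual_fim` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fim_map
from .fim_map import MCSet, PriorSpec, assemble_prior, draw_mcset, method_fixture
from .nlme_model import Design, ModelFixture, design_from_times

__all__ = [
    "SearchConfig",
    "OptimizationResult",
    "DesignEvaluator",
    "random_search",
    "line_search",
    "optimize_design",
]


@dataclass(frozen=True)
class SearchConfig:
    """Search-space and budget settings for one optimization run."""

    n_samples: int
    t_min: float | None = None
    t_max: float | None = None
    grid_step: float = 0.05
    rs_iterations: int = 300
    ls_cycles: int = 3
    n_draws: int = 100
    seed: int = 0
    hard_constraints: bool = False
    variance_block: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")


@dataclass(frozen=True)
class OptimizationResult:
    design: Design
    ofv: float
    trace: tuple[float, ...]  # best-so-far OFV at each accepted step
    n_evaluations: int
    seed: int
    method: str


class DesignEvaluator:
    """Cached Ds-objective evaluator on a fixed time grid.

    Parameters mirror :func:`optimize_design`; ``fixture`` must already
    be the method's working fixture (i.e. inflated for ``inflate``).
    """

    def __init__(
        self,
        fixture: ModelFixture,
        method: str,
        mcset: MCSet,
        grid: np.ndarray,
        *,
        variance_block: bool = True,
        forbidden_windows=None,
    ) -> None:
        self.fixture = fixture
        self.method = method
        self.mcset = mcset
        self.grid = np.asarray(grid, float)
        self.variance_block = variance_block
        self.prior: PriorSpec = assemble_prior(fixture, method)
        windows = (
            fixture.forbidden_windows if forbidden_windows is None else forbidden_windows
        )
        self.windows = tuple(tuple(w) for w in windows)
        feas = np.ones(self.grid.size, bool)
        for lo, hi in self.windows:
            feas &= ~((self.grid >= lo) & (self.grid < hi))
        self.feasible = feas
        if not np.any(feas):
            raise ValueError("no feasible sampling time on the grid")
        self._cache_index = np.full(self.grid.size, -1)
        self._cache_index[feas] = np.arange(int(feas.sum()))
        self.n_evaluations = 0
        self._build_caches()

    # -- cache construction -------------------------------------------
    def _build_caches(self) -> None:
        fx, method = self.fixture, self.method
        tg = self.grid[self.feasible]
        C = len(fx.channels)
        times = np.repeat(tg, C)
        chans = np.tile(np.arange(C), tg.size)
        n, G = self.mcset.n, tg.size
        P = self.prior.dim
        J = np.empty((n, G * C, P))
        v = np.empty((n, G * C))
        Dv = np.empty((n, G * C, P))
        pi_dim = fx.n_kappa
        S = (
            np.empty((n, fx.n_occasions, G * C, pi_dim))
            if method == "popocc" and pi_dim
            else None
        )

        design_grid = Design(times, chans)
        for i in range(n):
            p0 = fim_map._pack(fx, self.mcset.realization(i), method)
            pmat, h = fim_map._fd_points(p0)
            f, var = fim_map.batch_pred_var(fx, times, chans, pmat, method)
            v[i] = var[0]
            J[i] = ((f[1 : P + 1] - f[P + 1 :]) / (2 * h[:, None])).T
            Dv[i] = ((var[1 : P + 1] - var[P + 1 :]) / (2 * h[:, None])).T
            if S is not None:
                S[i] = fim_map.kappa_sensitivities(
                    fx, design_grid, self.mcset.realization(i),
                    np.ones(times.size, bool),
                )
        # reshape to (n, G, C, ...) for time-indexed gathering
        self._J = J.reshape(n, G, C, P)
        self._v = v.reshape(n, G, C)
        self._Dv = Dv.reshape(n, G, C, P)
        self._S = None if S is None else S.reshape(n, fx.n_occasions, G, C, pi_dim)

    # -- objective -----------------------------------------------------
    def fims(self, idx: np.ndarray) -> np.ndarray:
        """Per-draw individual FIMs of the design at grid indices ``idx``."""
        idx = np.atleast_1d(np.asarray(idx, int))
        cidx = self._cache_index[idx]
        cidx = cidx[cidx >= 0]  # forbidden-window samples: zero information
        n, P = self.mcset.n, self.prior.dim
        if cidx.size == 0:
            return np.zeros((n, P, P))
        C = len(self.fixture.channels)
        Jr = self._J[:, cidx].reshape(n, cidx.size * C, P)
        vr = self._v[:, cidx].reshape(n, cidx.size * C)
        Dvr = self._Dv[:, cidx].reshape(n, cidx.size * C, P)
        if self._S is not None:
            Sr = self._S[:, :, cidx].reshape(
                n, self.fixture.n_occasions, cidx.size * C, -1
            )
            V = np.einsum("nmoa,ab,nmpb->nop", Sr, self.fixture.pi, Sr)
            V[:, np.arange(vr.shape[1]), np.arange(vr.shape[1])] += vr
            W = np.linalg.inv(V)
            out = np.einsum("nip,nij,njq->npq", Jr, W, Jr)
            if self.variance_block:
                out += 0.5 * np.einsum("nip,nij,njq->npq", Dvr, W * W, Dvr)
        else:
            wi = 1.0 / vr
            out = np.einsum("nop,no,noq->npq", Jr, wi, Jr)
            if self.variance_block:
                out += 0.5 * np.einsum("nop,no,noq->npq", Dvr, wi**2, Dvr)
        return 0.5 * (out + np.swapaxes(out, 1, 2))

    def ofv(self, idx: np.ndarray) -> float:
        """Ds objective of the design given by grid indices ``idx``."""
        self.n_evaluations += 1
        M = self.fims(idx) + self.prior.precision[None]
        sign, logdet = np.linalg.slogdet(M)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("FIM + prior not positive definite")
        vals = logdet
        u = self.prior.uninteresting
        if u.size:
            sub = M[:, u[:, None], u[None, :]]
            s2, ld2 = np.linalg.slogdet(sub)
            if np.any(s2 <= 0):
                raise np.linalg.LinAlgError("uninteresting block not positive definite")
            vals = vals - ld2
        return float(np.mean(vals))

    def design_for(self, idx: np.ndarray) -> Design:
        times = np.sort(self.grid[np.asarray(idx, int)])
        return design_from_times(self.fixture, times)

    @property
    def candidate_indices(self) -> np.ndarray:
        """Grid indices the search may place samples on."""
        return np.flatnonzero(self.feasible)


def random_search(
    evaluator: DesignEvaluator,
    config: SearchConfig,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Uniform random candidate designs; returns the best seen.

    In zero-information mode any grid time may be proposed (samples in
    forbidden windows simply contribute nothing); with hard constraints
    only feasible times are drawn.
    """
    pool = (
        evaluator.candidate_indices
        if config.hard_constraints
        else np.arange(evaluator.grid.size)
    )
    if start is None:
        start = rng.choice(pool, size=config.n_samples, replace=True)
    best_idx = np.asarray(start, int)
    best = evaluator.ofv(best_idx)
    trace = [best]
    for _ in range(config.rs_iterations):
        cand = rng.choice(pool, size=config.n_samples, replace=True)
        val = evaluator.ofv(cand)
        if val > best + 1e-12:
            best, best_idx = val, cand
            trace.append(best)
    return best_idx, best, trace


def line_search(
    evaluator: DesignEvaluator,
    start: np.ndarray,
    config: SearchConfig,
) -> tuple[np.ndarray, float, list[float]]:
    """Cyclic coordinate sweep over the feasible grid; deterministic.

    Each sampling time in turn is replaced by the grid time maximizing
    the objective (earliest time on ties), holding the others fixed;
    cycles repeat until no coordinate moves or the cycle budget is
    spent.
    """
    idx = np.asarray(start, int).copy()
    cand = evaluator.candidate_indices
    best = evaluator.ofv(idx)
    trace = [best]
    for _ in range(config.ls_cycles):
        moved = False
        for c in range(idx.size):
            vals = np.empty(cand.size)
            trial = idx.copy()
            for g, gi in enumerate(cand):
                trial[c] = gi
                vals[g] = evaluator.ofv(trial)
            g_best = int(np.argmax(vals))  # first occurrence = earliest time
            if cand[g_best] != idx[c] and vals[g_best] >= best - 1e-12:
                if vals[g_best] > best + 1e-12 or evaluator.grid[cand[g_best]] < evaluator.grid[idx[c]]:
                    idx[c] = cand[g_best]
                    if vals[g_best] > best + 1e-12:
                        best = vals[g_best]
                        trace.append(best)
                        moved = True
        if not moved:
            break
    return idx, best, trace


def optimize_design(
    fixture: ModelFixture,
    method: str,
    config: SearchConfig,
    mcset: MCSet | None = None,
) -> OptimizationResult:
    """Random-search seeding followed by line-search polish.

    The Monte-Carlo prior draws are fixed for the whole run; rerunning
    with the same seed and configuration reproduces the result exactly.
    """
    fx = method_fixture(fixture, method)
    if mcset is None:
        mcset = draw_mcset(fixture, method, config.n_draws, config.seed)
    t_min = 0.0 if config.t_min is None else config.t_min
    t_max = fx.regimen.horizon if config.t_max is None else config.t_max
    if not (0.0 <= t_min < t_max <= fx.regimen.horizon + 1e-9):
        raise ValueError("time bounds must lie within the design horizon")
    grid = np.round(np.arange(t_min, t_max + config.grid_step / 2, config.grid_step), 10)
    evaluator = DesignEvaluator(
        fx, method, mcset, grid, variance_block=config.variance_block
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EA2C4]))
    idx, best, trace_rs = random_search(evaluator, config, rng)
    idx, best, trace_ls = line_search(evaluator, idx, config)
    design = evaluator.design_for(idx)
    return OptimizationResult(
        design=design,
        ofv=best,
        trace=tuple(trace_rs + trace_ls[1:]),
        n_evaluations=evaluator.n_evaluations,
        seed=config.seed,
        method=method,
    )
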