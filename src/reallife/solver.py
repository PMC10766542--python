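"""Subspace Barzilai-Borwein non-negative least squares (SBB-NNLS).

Minimizes ``O(w) = 1/2 ||b - Mw||^2`` over ``w >= 0``, optionally with an L1
(``+ lambda ||w||_1``) or L2 penalty, by projected-gradient iterations

    w(i+1) = [w(i) - alpha(i) * grad(w(i))]+

whose step size alternates between two spectral ratios: odd iterations use
``<g~, g~> / <Mg~, Mg~>`` and even iterations ``<Mg~, Mg~> / <M^T M g~,
M^T M g~>``, where ``g~`` is the gradient projected into the feasible
directions at the current iterate. Convergence is declared when the objective
changes by less than ``delta`` times its initial value over a window of
iterations.

The L2 penalty as printed in the field's literature is ``lambda * ||w||_2``
while the accompanying gradient is ``+ lambda * w``; those two are not a
consistent pair. ``objective`` reproduces the printed penalty by default; the
solver's internal trace uses ``lambda/2 * ||w||_2^2`` so that the traced
objective and the gradient agree (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Connectome
from .encode import SparseModel

__all__ = [
    "SolverConfig",
    "SolverTrace",
    "objective",
    "gradient",
    "project_gradient",
    "sbb_step_size",
    "solve",
    "converged",
    "calibrate_lambda",
    "prune",
]

_REGS = ("none", "l1", "l2")


@dataclass
class SolverConfig:
    regularization: str = "none"  # one of none | l1 | l2
    lam: float = 0.0
    max_iters: int = 500
    delta: float = 0.001  # convergence tolerance, fraction of O(t0)
    window: int = 10  # iterations between convergence checks
    init: np.ndarray | None = None  # initial weights, default zeros

    def __post_init__(self) -> None:
        reg = self.regularization.lower()
        if reg not in _REGS:
            raise ValueError(f"regularization must be one of {_REGS}")
        self.regularization = reg
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class SolverTrace:
    objectives: np.ndarray  # (n_iters + 1,), objectives[0] = O(t0)
    alphas: np.ndarray  # (n_iters,)
    converged_at: int | None = None
    reason: str = "max_iters"  # converged | stationary | max_iters

    @property
    def n_iters(self) -> int:
        return self.alphas.shape[0]


def _check_weights(w: np.ndarray, n_fibers: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n_fibers,):
        raise ValueError("weight vector length must equal the fiber count")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return w


def _penalty(w: np.ndarray, cfg: SolverConfig, consistent_l2: bool) -> float:
    if cfg.regularization == "l1":
        return cfg.lam * float(np.sum(w))
    if cfg.regularization == "l2":
        nrm = float(np.linalg.norm(w))
        return 0.5 * cfg.lam * nrm * nrm if consistent_l2 else cfg.lam * nrm
    return 0.0


def objective(
    model: SparseModel,
    w: np.ndarray,
    cfg: SolverConfig | None = None,
    consistent_l2: bool = False,
) -> float:
    """Regularized least-squares objective 1/2 ||b - Mw||^2 + penalty."""
    cfg = cfg or SolverConfig()
    w = _check_weights(w, model.n_fibers)
    r = model.b - model.matvec(w)
    return 0.5 * float(r @ r) + _penalty(w, cfg, consistent_l2)


def gradient(model: SparseModel, w: np.ndarray, cfg: SolverConfig | None = None) -> np.ndarray:
    """Gradient M^T(Mw - b), plus lambda*1 (L1) or lambda*w (L2)."""
    cfg = cfg or SolverConfig()
    w = _check_weights(w, model.n_fibers)
    g = model.rmatvec(model.matvec(w) - model.b)
    if cfg.regularization == "l1":
        g = g + cfg.lam
    elif cfg.regularization == "l2":
        g = g + cfg.lam * w
    return g


def project_gradient(w: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Zero the components that would push an at-bound weight negative."""
    w = np.asarray(w, dtype=float)
    g = np.asarray(g, dtype=float)
    if w.shape != g.shape:
        raise ValueError("w and g must have the same length")
    out = g.copy()
    out[(w == 0) & (g > 0)] = 0.0
    return out


def sbb_step_size(model: SparseModel, g_tilde: np.ndarray, iteration: int) -> float:
    """Spectral step: iteration 1 (odd) uses <g,g>/<Mg,Mg>, even the next ratio."""
    g_tilde = np.asarray(g_tilde, dtype=float)
    Mg = model.matvec(g_tilde)
    if iteration % 2 == 1:
        num, den = float(g_tilde @ g_tilde), float(Mg @ Mg)
    else:
        MtMg = model.rmatvec(Mg)
        num, den = float(Mg @ Mg), float(MtMg @ MtMg)
    if num == 0.0 or den <= np.finfo(float).eps * num:
        raise DegenerateStep("degenerate step: projected gradient is (near) null")
    return num / den


class DegenerateStep(RuntimeError):
    """Raised when the spectral denominators vanish (stationary point)."""


def converged(trace, delta: float = 0.001, window: int = 10) -> bool:
    """True when |O(t) - O(t - window)| < delta * O(t0)."""
    objs = trace.objectives if isinstance(trace, SolverTrace) else np.asarray(trace, float)
    if objs.shape[0] < window + 1:
        raise ValueError("not enough history: need at least window+1 objective values")
    return bool(abs(objs[-1] - objs[-1 - window]) < delta * objs[0])


def solve(model: SparseModel, cfg: SolverConfig | None = None):
    """Run SBB-NNLS on a sparse model; returns (weights, trace)."""
    cfg = cfg or SolverConfig()
    if cfg.init is None:
        w = np.zeros(model.n_fibers)
    else:
        w = _check_weights(cfg.init, model.n_fibers).copy()

    objs = [objective(model, w, cfg, consistent_l2=True)]
    alphas: list = []
    converged_at = None
    reason = "max_iters"
    for it in range(1, cfg.max_iters + 1):
        g = gradient(model, w, cfg)
        g_tilde = project_gradient(w, g)
        try:
            alpha = sbb_step_size(model, g_tilde, it)
        except DegenerateStep:
            reason = "stationary"
            break
        w = np.maximum(w - alpha * g, 0.0)
        obj = objective(model, w, cfg, consistent_l2=True)
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        objs.append(obj)
        alphas.append(alpha)
        if it >= cfg.window and it % cfg.window == 0:
            if abs(objs[it] - objs[it - cfg.window]) < cfg.delta * objs[0]:
                converged_at = it
                reason = "converged"
                break
    trace = SolverTrace(np.asarray(objs), np.asarray(alphas), converged_at, reason)
    return w, trace


def calibrate_lambda(
    model_ref: SparseModel,
    model_big: SparseModel,
    grid: np.ndarray,
    cfg: SolverConfig | None = None,
):
    """Pick the L1 penalty matching the reference solution's summed weights.

    Solves ``model_ref`` unregularized to obtain the target ||w||_1, then
    solves ``model_big`` with an L1 penalty at every grid value and returns the
    grid lambda minimizing |(||w(lambda)||_1) - target| (ties -> smaller
    lambda), together with the per-lambda L1 norms.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("lambda grid must be strictly ascending")
    base = cfg or SolverConfig()
    w_ref, _ = solve(model_ref, SolverConfig(
        regularization="none", max_iters=base.max_iters,
        delta=base.delta, window=base.window,
    ))
    target = float(np.sum(w_ref))
    norms = np.empty(grid.size)
    for i, lam in enumerate(grid):
        w, _ = solve(model_big, SolverConfig(
            regularization="l1", lam=float(lam), max_iters=base.max_iters,
            delta=base.delta, window=base.window,
        ))
        norms[i] = float(np.sum(w))
    best = int(np.argmin(np.abs(norms - target)))  # argmin takes first = smaller lam
    return float(grid[best]), norms


@dataclass
class PruneResult:
    connectome: Connectome
    retained: np.ndarray  # indices of retained streamlines


def prune(c: Connectome, w: np.ndarray, threshold: float = 0.0) -> PruneResult:
    """Keep streamlines whose weight strictly exceeds the threshold."""
    w = np.asarray(w, dtype=float)
    if w.shape != (len(c),):
        raise ValueError("weight vector length must match the connectome")
    retained = np.flatnonzero(w > threshold)
    streamlines = [c.streamlines[i] for i in retained]
    labels = None if c.labels is None else c.labels[retained]
    return PruneResult(Connectome(streamlines, labels), retained)
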