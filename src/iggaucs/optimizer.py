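"""Iterative gradient maximization of the penalized GAUCS surrogate.

The fitting algorithm alternates two steps, EM style:

* ascend the differentiable surrogate E(w, theta) in w by one (or more)
  Polak-Ribiere conjugate-gradient steps with a backtracking (Armijo) line
  search, the variational parameters theta held fixed;
* tighten the bound by the closed-form update theta_l <- w_l, which makes
  the surrogate touch the exact penalized objective E_p at the current
  point.

Each cycle therefore cannot decrease E_p (majorize-minimize guarantee);
iteration stops when ||w^{t+1} - w^t|| falls below a tolerance. Because
the quadratic bound's curvature eta_l = p|theta_l|^{p-2}/2 diverges as a
group norm approaches zero, a group whose norm falls below a small floor
is frozen at exactly zero and dropped from the working set: under the
local quadratic approximation such a group can never re-enter, and
removing it keeps the line search well scaled. The same engine maximizes
any smooth data term minus the bounded group penalty, which is how the
group-lasso Cox comparator reuses it at p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

from .data import SurvivalDataset
from .gaucs import ComparablePairSet, comparable_pairs, pair_differences
from .groups import GroupStructure
from .penalty import EPS_THETA, PenaltySpec, VariationalState

__all__ = [
    "OptimizerConfig",
    "FitResult",
    "PairwiseLogitLoss",
    "fit_iggaucs",
    "conjugate_direction",
    "surrogate_gradient",
    "maximize_penalized",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Convergence and line-search control for the MM optimizer.

    Attributes
    ----------
    eps : float
        Stop when the full-coefficient step norm ||w^{t+1} - w^t|| drops
        below this.
    max_iter : int
        Outer iteration cap.
    seed : int
        Seed for the random initialization (ignored with a warm start).
    prune_tol : float
        Group-norm threshold below which a group is reported zero in the
        returned fit (coefficients hard-zeroed).
    freeze_tol : float
        Group-norm threshold at which a group is frozen at zero during
        iteration; must satisfy EPS_THETA <= freeze_tol <= prune_tol.
    armijo_c1, backtrack, max_backtracks : float, float, int
        Armijo sufficient-ascent constant, step shrink factor and trial cap
        of the backtracking line search.
    inner_steps : int
        Conjugate-gradient steps per theta update (1 interleaves them).
    pr_clamp : bool
        Clamp the Polak-Ribiere coefficient at zero (automatic restart);
        the raw formula is available by switching this off.
    init_scale : float
        Standard deviation of the Normal(0, init_scale^2) random start.
    """

    eps: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    prune_tol: float = 1e-4
    freeze_tol: float = 1e-6
    armijo_c1: float = 1e-4
    backtrack: float = 0.5
    max_backtracks: int = 50
    inner_steps: int = 1
    pr_clamp: bool = True
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.max_iter < 1:
            raise ValueError("eps must be positive and max_iter >= 1")
        if not (EPS_THETA <= self.freeze_tol <= self.prune_tol):
            raise ValueError("require EPS_THETA <= freeze_tol <= prune_tol")


@dataclass
class FitResult:
    """Outcome of a penalized fit.

    ``w_hat`` is the full-length coefficient vector with pruned groups
    hard-zeroed; ``objective_trace`` holds the exact penalized objective
    E_p after every outer iteration and is non-decreasing up to
    line-search tolerance.
    """

    w_hat: np.ndarray
    group_norms: np.ndarray
    selected_groups: list[int]
    objective_trace: list[float]
    n_iter: int
    converged: bool
    structure: GroupStructure = field(repr=False, default=None)

    @property
    def selected_names(self) -> list[str]:
        return [self.structure.names[l] for l in self.selected_groups]


class PairwiseLogitLoss:
    """Average pairwise log-sigmoid data term over comparable pairs.

    Caches the pair-difference matrix D (N x m) and a restriction of it to
    the active feature columns; exposes the projected linear form z = D w
    so line-search trials cost O(N) after one matrix-vector product.
    """

    def __init__(self, D: np.ndarray):
        self.D = np.ascontiguousarray(D, dtype=float)
        self.N = D.shape[0]
        self._cols: np.ndarray | None = None
        self._Da = self.D
        self._curv: np.ndarray | None = None

    @classmethod
    def from_dataset(cls, ds: SurvivalDataset, pairs: ComparablePairSet | None = None):
        return cls(pair_differences(ds, pairs))

    @property
    def m(self) -> int:
        return self.D.shape[1]

    def set_active(self, cols: np.ndarray) -> None:
        self._cols = cols
        self._Da = np.ascontiguousarray(self.D[:, cols])
        self._curv = None

    def project(self, wa: np.ndarray) -> np.ndarray:
        return self._Da @ wa

    def curvature_diag(self) -> np.ndarray:
        """Upper bound on the negative Hessian diagonal: (1/4N) sum_p D_pi^2."""
        if self._curv is None:
            self._curv = (self._Da**2).sum(axis=0) / (4.0 * self.N)
        return self._curv

    def value_from(self, z: np.ndarray) -> float:
        return float(np.mean(log_expit(z)))

    def grad_from(self, z: np.ndarray) -> np.ndarray:
        return self._Da.T @ expit(-z) / self.N


def conjugate_direction(
    g: np.ndarray,
    g_prev: np.ndarray | None,
    d_prev: np.ndarray | None,
    clamp: bool = True,
) -> np.ndarray:
    """Polak-Ribiere ascent direction d = g + u * d_prev.

    u = (g - g_prev)'g / (g_prev'g_prev), clamped at zero by default
    (PR+ restart). The first iteration, or a vanishing previous gradient,
    returns the gradient itself.
    """
    if g_prev is None or d_prev is None:
        return g.copy()
    denom = float(g_prev @ g_prev)
    if denom <= 1e-300:
        return g.copy()
    u = float((g - g_prev) @ g) / denom
    if clamp:
        u = max(u, 0.0)
    return g + u * d_prev


def surrogate_gradient(
    ds: SurvivalDataset,
    w: np.ndarray,
    structure: GroupStructure,
    vs: VariationalState,
    spec: PenaltySpec,
    pairs: ComparablePairSet | None = None,
) -> np.ndarray:
    """Gradient of the surrogate E(w, theta) in w, full length m.

    Data part (1/N) sum sigma(-w'dx) dx over comparable pairs, minus the
    bounded-penalty pull 2 lam d_l eta_l w_l on each group.
    """
    w = np.asarray(w, dtype=float)
    D = pair_differences(ds, pairs)
    g = D.T @ expit(-(D @ w)) / D.shape[0]
    for l, ix in enumerate(structure.indices):
        g[ix] -= 2.0 * spec.lam * structure.d[l] * vs.eta[l] * w[ix]
    return g


class _ActiveSet:
    """Bookkeeping of unfrozen groups and their columns in the work vector."""

    def __init__(self, structure: GroupStructure, active: list[int]):
        self.structure = structure
        self.groups = list(active)
        self.cols = (
            np.concatenate([structure.indices[l] for l in self.groups])
            if self.groups
            else np.array([], dtype=int)
        )
        slices, off = [], 0
        for l in self.groups:
            size = len(structure.indices[l])
            slices.append(slice(off, off + size))
            off += size
        self.slices = slices

    def norms(self, wa: np.ndarray) -> np.ndarray:
        return np.array([np.linalg.norm(wa[s]) for s in self.slices])


def maximize_penalized(
    loss,
    structure: GroupStructure,
    spec: PenaltySpec,
    cfg: OptimizerConfig,
    w0: np.ndarray | None = None,
) -> FitResult:
    """MM conjugate-gradient ascent of loss(w) - lam * sum d_l ||w_l||^p.

    ``loss`` is any object with the ``set_active / project / value_from /
    grad_from`` interface (see :class:`PairwiseLogitLoss`). A warm start
    ``w0`` replaces the random initialization; its already-zero groups are
    frozen immediately, so warm starts along an increasing-lambda path
    preserve the monotone shrinkage of the working set.
    """
    m = loss.m
    if structure.n_features > m:
        raise ValueError("group structure references more features than available")
    rng = np.random.default_rng(cfg.seed)
    lam, p, d_all = spec.lam, spec.p, structure.d

    w_full = np.zeros(m)
    if w0 is None:
        w_full[:] = 0.0
        for ix in structure.indices:
            block = rng.normal(0.0, cfg.init_scale, size=len(ix))
            while np.linalg.norm(block) <= EPS_THETA:
                block = rng.normal(0.0, cfg.init_scale, size=len(ix))
            w_full[ix] = block
    else:
        w0 = np.asarray(w0, dtype=float)
        if len(w0) != m:
            raise ValueError("warm start length mismatch")
        if not np.all(np.isfinite(w0)):
            raise ValueError("warm start contains non-finite values")
        w_full[:] = w0

    active = [
        l
        for l, ix in enumerate(structure.indices)
        if np.linalg.norm(w_full[ix]) >= cfg.freeze_tol
    ]
    for l, ix in enumerate(structure.indices):
        if l not in active:
            w_full[ix] = 0.0

    def exact_objective(z, aset, wa) -> float:
        pen = float(
            np.sum(d_all[aset.groups] * aset.norms(wa) ** p)
        ) if aset.groups else 0.0
        return loss.value_from(z) - lam * pen

    aset = _ActiveSet(structure, active)
    loss.set_active(aset.cols)
    wa = w_full[aset.cols]
    z = loss.project(wa)
    trace = [exact_objective(z, aset, wa)]
    if not np.isfinite(trace[0]):
        raise FloatingPointError("objective not finite at initialization")

    if not aset.groups:
        return FitResult(
            w_hat=np.zeros(m),
            group_norms=np.zeros(structure.r),
            selected_groups=[],
            objective_trace=trace,
            n_iter=0,
            converged=True,
            structure=structure,
        )

    def make_q(aset, theta_norms):
        # per-coordinate quadratic penalty weight 2 lam d_l eta_l
        vs = VariationalState(theta_norms=theta_norms, p=p)
        q = np.empty(len(aset.cols))
        for i, s in enumerate(aset.slices):
            q[s] = 2.0 * lam * d_all[aset.groups[i]] * vs.eta[i]
        return q

    q = make_q(aset, aset.norms(wa))
    g_prev = y_prev = d_prev = None
    n_iter = 0
    converged = False

    for n_iter in range(1, cfg.max_iter + 1):
        w_old_full = w_full.copy()
        # --- CG ascent step(s) on the surrogate, theta fixed ---
        for _ in range(cfg.inner_steps):
            g = loss.grad_from(z) - q * wa
            # precondition by the surrogate's diagonal curvature: the bound
            # gives collapsing groups enormous quadratic weight q, and an
            # unscaled gradient step would be throttled by them
            y = g / (loss.curvature_diag() + q + 1e-300)
            if g_prev is None or d_prev is None or float(g_prev @ y_prev) <= 1e-300:
                dvec = y
            else:
                u = float((g - g_prev) @ y) / float(g_prev @ y_prev)
                if cfg.pr_clamp:
                    u = max(u, 0.0)
                dvec = y + u * d_prev
            slope = float(g @ dvec)
            if slope <= 0.0:
                dvec = y
                slope = float(g @ y)
            if slope <= 1e-300:
                break
            zd = loss.project(dvec)
            qd2 = float(q @ dvec**2)
            qwd = float(q @ (wa * dvec))
            f0 = loss.value_from(z) - 0.5 * float(q @ wa**2)
            alpha = 1.0
            accepted = False
            for _bt in range(cfg.max_backtracks):
                z_try = z + alpha * zd
                f_try = (
                    loss.value_from(z_try)
                    - 0.5 * float(q @ wa**2)
                    - alpha * qwd
                    - 0.5 * alpha**2 * qd2
                )
                if np.isfinite(f_try) and f_try >= f0 + cfg.armijo_c1 * alpha * slope:
                    accepted = True
                    break
                alpha *= cfg.backtrack
            if not accepted:
                g_prev = y_prev = d_prev = None
                break
            wa = wa + alpha * dvec
            z = z_try
            g_prev, y_prev, d_prev = g, y, dvec

        # --- theta update (bound tightened at the new w) and freezing ---
        norms = aset.norms(wa)
        frozen = [aset.groups[i] for i in range(len(aset.groups)) if norms[i] < cfg.freeze_tol]
        if frozen:
            keep = [l for l in aset.groups if l not in frozen]
            w_full[aset.cols] = wa
            for l in frozen:
                w_full[structure.indices[l]] = 0.0
            aset = _ActiveSet(structure, keep)
            loss.set_active(aset.cols)
            wa = w_full[aset.cols]
            z = loss.project(wa)
            g_prev = y_prev = d_prev = None
            if not keep:
                trace.append(exact_objective(z, aset, wa))
                converged = True
                break
            norms = aset.norms(wa)
        q = make_q(aset, norms)

        w_full[aset.cols] = wa
        obj = exact_objective(z, aset, wa)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"objective became non-finite at iteration {n_iter} (lam={lam:g})"
            )
        trace.append(obj)
        if float(np.linalg.norm(w_full - w_old_full)) < cfg.eps:
            converged = True
            break

    group_norms = structure.group_norms(w_full)
    selected = [l for l in range(structure.r) if group_norms[l] > cfg.prune_tol]
    w_hat = w_full.copy()
    for l in range(structure.r):
        if l not in selected:
            w_hat[structure.indices[l]] = 0.0
    return FitResult(
        w_hat=w_hat,
        group_norms=structure.group_norms(w_hat),
        selected_groups=selected,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        structure=structure,
    )


def fit_iggaucs(
    ds: SurvivalDataset,
    structure: GroupStructure,
    spec: PenaltySpec,
    cfg: OptimizerConfig | None = None,
    pairs: ComparablePairSet | None = None,
    w0: np.ndarray | None = None,
    loss: PairwiseLogitLoss | None = None,
) -> FitResult:
    """Fit the group-L_p penalized GAUCS model to a survival dataset.

    Maximizes (1/N) sum log sigma(w'(x_j - x_k)) - lam sum_l d_l ||w_l||^p
    over comparable pairs. Pass a prebuilt ``loss`` to reuse the pair
    matrix across several lambda values (cross-validation paths).
    """
    cfg = cfg or OptimizerConfig()
    if loss is None:
        if pairs is None:
            pairs = comparable_pairs(ds)
        loss = PairwiseLogitLoss.from_dataset(ds, pairs)
    return maximize_penalized(loss, structure, spec, cfg, w0=w0)
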