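"""Group L_p penalty and its local quadratic variational bound.

The weighted group L_p norm is sum_l d_l ||w_l||^p with 0 < p <= 1, an L_p
norm over per-group L2 norms: it shrinks whole groups to zero, and for
p < 1 is nonconvex but less biased than the group lasso (p = 1). Because
||w_l||^p is concave in ||w_l||^2 it admits a quadratic upper bound

    ||w_l||^p <= (1/2) { p |theta_l|^{p-2} ||w_l||^2 + (2-p) |theta_l|^p },

tight at ||w_l|| = |theta_l|, with precision eta_l = p |theta_l|^{p-2} / 2.
Subtracting the bounded penalty from the pairwise log-likelihood gives the
differentiable surrogate E(w, theta) that the EM-style optimizer ascends:
maximizing over theta with w fixed returns theta_l = w_l (bound tight), and
ascending the surrogate in w then cannot decrease the exact penalized
objective E_p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalDataset
from .gaucs import ComparablePairSet, log_pair_likelihood
from .groups import GroupStructure

__all__ = [
    "PenaltySpec",
    "VariationalState",
    "group_lp",
    "quad_bound",
    "penalized_objective",
    "surrogate_objective",
]

#: Floor on |theta_l| when forming eta_l = p|theta_l|^{p-2}/2: with p < 2 the
#: bound's curvature blows up as a group norm approaches zero.
EPS_THETA = 1e-8


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty exponent p in (0, 1] and strength lam >= 0."""

    p: float
    lam: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


@dataclass
class VariationalState:
    """Variational parameters theta (per-group norms) and precisions eta.

    Only the group norms |theta_l| enter the bound, so the state stores
    them directly. ``eta = p |theta|^{p-2} / 2`` with |theta| floored at
    ``EPS_THETA``.
    """

    theta_norms: np.ndarray
    p: float
    eta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        th = np.maximum(np.asarray(self.theta_norms, dtype=float), EPS_THETA)
        self.theta_norms = th
        self.eta = 0.5 * self.p * th ** (self.p - 2.0)

    @classmethod
    def from_w(cls, w: np.ndarray, structure: GroupStructure, p: float) -> "VariationalState":
        """The optimal theta given w: theta_l = w_l (bound made tight)."""
        return cls(theta_norms=structure.group_norms(w), p=p)


def group_lp(w: np.ndarray, structure: GroupStructure, spec: PenaltySpec) -> float:
    """Weighted group L_p norm sum_l d_l ||w_l||^p.

    Reduces to the L2 norm for a single group, and to the ordinary L_p
    norm for singleton groups (d_l = 1). Zero iff w = 0.
    """
    norms = structure.group_norms(w)
    return float(np.sum(structure.d * norms ** spec.p))


def quad_bound(wl_norm: float, theta_l_norm: float, p: float) -> float:
    """Quadratic majorant of ||w_l||^p at variational point |theta_l|.

    Returns (1/2){p |theta|^(p-2) |w|^2 + (2-p) |theta|^p}; always
    >= |w|^p, with equality at |w| = |theta|.
    """
    if theta_l_norm < EPS_THETA:
        raise ValueError(f"theta norm below floor {EPS_THETA:g}")
    return 0.5 * (
        p * theta_l_norm ** (p - 2.0) * wl_norm**2
        + (2.0 - p) * theta_l_norm**p
    )


def bound_penalty(
    w: np.ndarray, structure: GroupStructure, vs: VariationalState, spec: PenaltySpec
) -> float:
    """The bounded penalty lam * sum_l d_l quad_bound(||w_l||, |theta_l|)."""
    norms = structure.group_norms(w)
    vals = (
        vs.eta * norms**2
        + 0.5 * (2.0 - spec.p) * vs.theta_norms**spec.p
    )
    return float(spec.lam * np.sum(structure.d * vals))


def penalized_objective(
    ds: SurvivalDataset,
    w: np.ndarray,
    structure: GroupStructure,
    spec: PenaltySpec,
    pairs: ComparablePairSet | None = None,
) -> float:
    """Exact penalized objective E_p = pairwise log-likelihood - lam * group_lp."""
    return log_pair_likelihood(ds, w, pairs) - spec.lam * group_lp(w, structure, spec)


def surrogate_objective(
    ds: SurvivalDataset,
    w: np.ndarray,
    structure: GroupStructure,
    vs: VariationalState,
    spec: PenaltySpec,
    pairs: ComparablePairSet | None = None,
) -> float:
    """Variational surrogate E(w, theta): log-likelihood - bounded penalty.

    Lower-bounds E_p for any theta and equals it (to rounding) at
    theta = w.
    """
    return log_pair_likelihood(ds, w, pairs) - bound_penalty(w, structure, vs, spec)
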