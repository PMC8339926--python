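"""One-parameter continuation and bifurcation location by bisection.

Three locators are provided, each a bisection on a qualitative indicator that
flips across the bifurcation:

* Andronov–Hopf — sign of the maximal eigenvalue real part of a tracked fixed
  point (a complex pair crossing the imaginary axis);
* saddle-node — the number of fixed points (pairs are created/annihilated, so
  the count changes by an even number; simultaneous events are inferred from
  ``|change| / 2``);
* homoclinic — existence of a stable limit cycle (operationally, the boundary
  of cycle existence; the period diverging toward the critical value
  distinguishes the saddle collision from a fold of cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import root

from .core import candidate_jacobian, candidate_residual, jacobian, vector_field
from .params import GRUParams
from .phase import FixedPoint, _make_fixed_point, find_fixed_points

__all__ = [
    "ParameterFamily",
    "BifurcationResult",
    "track_fixed_point",
    "locate_hopf",
    "locate_saddle_node",
    "locate_homoclinic",
]


@dataclass
class ParameterFamily:
    """A curve in parameter space: scalar value -> GRUParams."""

    generator: Callable[[float], GRUParams]
    name: str = "parameter"

    def __call__(self, value: float) -> GRUParams:
        return self.generator(value)


@dataclass
class BifurcationResult:
    kind: str  # hopf | saddle_node | homoclinic
    critical_value: float
    bracket_width_final: float
    evidence: dict = field(default_factory=dict)


def _newton_root(params: GRUParams, h0: np.ndarray, tol: float = 1e-12):
    try:
        sol = root(lambda h: candidate_residual(params, h), h0,
                   jac=lambda h: candidate_jacobian(params, h), tol=tol)
    except ValueError:  # iterate escaped to non-finite territory
        return None
    if not sol.success or np.linalg.norm(candidate_residual(params, sol.x)) > 1e-9:
        return None
    return sol.x


def track_fixed_point(
    family: ParameterFamily,
    h_seed,
    values: Sequence[float],
    *,
    marginal_tol: float = 1e-6,
) -> list:
    """Warm-started Newton continuation of one fixed point along a value grid.

    Returns ``(value, FixedPoint)`` pairs; stops with a labelled break when the
    branch loses convergence (a fold).  Raises if the very first value fails.
    """
    h = np.asarray(h_seed, dtype=float)
    branch = []
    for i, v in enumerate(values):
        params = family(v)
        x = _newton_root(params, h)
        if x is None or np.linalg.norm(x - h) > 0.5:
            if i == 0:
                raise ValueError(f"seed failed to converge at {family.name}={v}")
            branch.append((float(v), None))  # labelled break: branch lost (fold)
            break
        h = x
        branch.append((float(v), _make_fixed_point(params, h, marginal_tol)))
    return branch


def locate_hopf(
    family: ParameterFamily,
    bracket: Sequence[float],
    tol: float = 1e-8,
    *,
    h_seed=None,
    max_steps: int = 60,
) -> BifurcationResult:
    """Bisect on the sign of the tracked point's maximal eigenvalue real part."""
    lo, hi = float(bracket[0]), float(bracket[1])
    d = family(lo).d
    h = np.zeros(d) if h_seed is None else np.asarray(h_seed, dtype=float)

    def max_re(value, h_start):
        params = family(value)
        x = _newton_root(params, h_start)
        if x is None:
            raise RuntimeError(f"fixed point lost at {family.name}={value}")
        eig = np.linalg.eigvals(jacobian(params, x))
        return float(np.max(eig.real)), eig, x

    re_lo, eig_lo, h_lo = max_re(lo, h)
    re_hi, eig_hi, h_hi = max_re(hi, h)
    if np.sign(re_lo) == np.sign(re_hi):
        raise ValueError(
            "no eigenvalue real-part sign change over the bracket: "
            f"Re at {lo}={re_lo:.3g} (eigs {eig_lo}), at {hi}={re_hi:.3g} (eigs {eig_hi})")
    h_mid = h_lo
    steps = 0
    while hi - lo > tol and steps < max_steps:
        mid = 0.5 * (lo + hi)
        re_mid, eig_mid, h_mid = max_re(mid, h_mid)
        if np.sign(re_mid) == np.sign(re_lo):
            lo = mid
        else:
            hi = mid
        steps += 1
    crit = 0.5 * (lo + hi)
    _, eig_c, _ = max_re(crit, h_mid)
    return BifurcationResult(
        kind="hopf", critical_value=crit, bracket_width_final=hi - lo,
        evidence={"eigenvalues_at_crossing": eig_c.tolist(),
                  "complex_pair": bool(np.any(np.abs(eig_c.imag) > 1e-12))})


def locate_saddle_node(
    family: ParameterFamily,
    bracket: Sequence[float],
    tol: float = 1e-8,
    *,
    box: Sequence[float] = (-1.2, 1.2),
    grid_n: int = 30,
    max_steps: int = 60,
) -> BifurcationResult:
    """Bisect on the fixed-point count; report simultaneous pair events."""
    lo, hi = float(bracket[0]), float(bracket[1])

    def points(value):
        return find_fixed_points(family(value), box=box, grid_n=grid_n)

    n_lo, n_hi = len(points(lo)), len(points(hi))
    if n_lo == n_hi:
        raise ValueError(f"fixed-point count is {n_lo} at both bracket endpoints")
    steps = 0
    while hi - lo > tol and steps < max_steps:
        mid = 0.5 * (lo + hi)
        if len(points(mid)) == n_lo:
            lo = mid
        else:
            hi = mid
        steps += 1
    crit = 0.5 * (lo + hi)
    pair_events = abs(n_hi - n_lo) / 2
    # generic fold: the new pair is born away from the persisting roots; a
    # pitchfork births it on top of one (symmetric, non-generic)
    delta = max(10 * (hi - lo), 1e-5) * (1 if n_hi > n_lo else -1)
    many = points(crit + delta)
    few = points(crit - delta)
    few_locs = np.stack([fp.location for fp in few])
    born_dist = []
    for fp in many:
        dmin = float(np.min(np.linalg.norm(few_locs - fp.location, axis=1)))
        born_dist.append(dmin)
    born_dist.sort(reverse=True)
    n_new = abs(n_hi - n_lo)
    non_generic = bool(n_new and max(born_dist[:n_new], default=0.0) < 0.05)
    return BifurcationResult(
        kind="saddle_node", critical_value=crit,
        bracket_width_final=hi - lo,
        evidence={"count_low_side": n_lo, "count_high_side": n_hi,
                  "pair_events": pair_events, "non_generic": non_generic})


def locate_homoclinic(
    family: ParameterFamily,
    bracket: Sequence[float],
    tol: float = 1e-6,
    *,
    detect_kwargs: Optional[dict] = None,
    max_steps: int = 60,
    record_periods: bool = True,
) -> BifurcationResult:
    """Bisect on limit-cycle existence; the period grows toward the collision."""
    from .oscillations import detect_limit_cycle

    lo, hi = float(bracket[0]), float(bracket[1])
    kw = detect_kwargs or {}
    periods: list[tuple[float, float]] = []

    def has_cycle(value):
        cycle = detect_limit_cycle(family(value), **kw)
        if cycle is not None and record_periods:
            periods.append((float(value), cycle.period))
        return cycle is not None

    c_lo, c_hi = has_cycle(lo), has_cycle(hi)
    if c_lo == c_hi:
        raise ValueError(
            f"limit-cycle existence is {c_lo} at both bracket endpoints")
    steps = 0
    while hi - lo > tol and steps < max_steps:
        mid = 0.5 * (lo + hi)
        if has_cycle(mid) == c_lo:
            lo = mid
        else:
            hi = mid
        steps += 1
    periods.sort()
    return BifurcationResult(
        kind="homoclinic", critical_value=0.5 * (lo + hi),
        bracket_width_final=hi - lo,
        evidence={"cycle_at_low": c_lo, "cycle_at_high": c_hi,
                  "period_samples": periods})
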