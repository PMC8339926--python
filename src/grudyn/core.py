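"""Continuous-time GRU vector field, discrete map, Jacobians, integration.

The autonomous continuous-time GRU is

    z(h) = sigma(U_z h + b_z)          (update gate, pointwise in (0,1))
    r(h) = sigma(U_r h + b_r)          (reset gate)
    dh/dt = (1 - z) * (tanh(U_h (r*h) + b_h) - h)

where ``*`` is elementwise multiplication.  The familiar discrete-time GRU is
the forward-Euler step of this field with unit step size:

    h' = (1 - z) * tanh(W_h x + U_h (r*h) + b_h) + z * h

Because ``1 - z`` is strictly positive it only rescales flow speed pointwise;
fixed points and their topology are those of the *gate-factored* field
``(tanh(U_h (r*h) + b_h) - h)`` (times the constant 1/2 when the update gate
is unparameterized).  All trajectories are asymptotically trapped in
``[-1, 1]^d``.

All evaluation functions broadcast over a leading batch axis: ``h`` may be a
``(d,)`` vector or an ``(N, d)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .params import GRUParams

__all__ = [
    "gates",
    "vector_field",
    "candidate_residual",
    "jacobian",
    "candidate_jacobian",
    "discrete_step",
    "integrate",
    "Trajectory",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Integration failed (step-size collapse); carries the last valid state."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = np.asarray(last_state)


def _check_state(params: GRUParams, h) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.d:
        raise ValueError(f"state has dimension {h.shape[-1]}, expected {params.d}")
    if not np.all(np.isfinite(h)):
        raise ValueError("state contains non-finite entries")
    return h


def gates(params: GRUParams, h) -> tuple[np.ndarray, np.ndarray]:
    """Update and reset gate activations ``(z, r)`` at state ``h``.

    Both are elementwise logistic sigmoids of affine functions of ``h`` and so
    lie strictly in ``(0, 1)``.
    """
    h = _check_state(params, h)
    z = expit(h @ params.U_z.T + params.b_z)
    r = expit(h @ params.U_r.T + params.b_r)
    return z, r


def vector_field(params: GRUParams, h, factored: bool = False) -> np.ndarray:
    """Right-hand side ``dh/dt`` of the autonomous continuous-time GRU.

    With ``factored=True`` the leading ``(1 - z)`` factor is replaced by the
    constant 1/2 — a topology-preserving time reparameterization, exact when
    the update gate is unparameterized (``U_z = 0``, ``b_z = 0``).
    """
    h = _check_state(params, h)
    z, r = gates(params, h)
    g = np.tanh((r * h) @ params.U_h.T + params.b_h) - h
    if factored:
        return 0.5 * g
    return (1.0 - z) * g


def candidate_residual(params: GRUParams, h) -> np.ndarray:
    """``tanh(U_h (r*h) + b_h) - h``: zero exactly at the fixed points.

    Since ``1 - z > 0`` everywhere, the roots of this residual are the fixed
    points of the full field; Newton iterations on it are better conditioned
    than on the gate-scaled field.
    """
    h = _check_state(params, h)
    r = expit(h @ params.U_r.T + params.b_r)
    return np.tanh((r * h) @ params.U_h.T + params.b_h) - h


def _phi_and_da(params: GRUParams, h, r):
    """tanh output and its argument's state derivative ``da[i,j] = d a_i / d h_j."""
    a = (r * h) @ params.U_h.T + params.b_h
    phi = np.tanh(a)
    # d(r_k h_k)/dh_j = r_j delta_kj + h_k r_k (1-r_k) U_r[k,j]
    da = params.U_h * r[..., None, :] + np.einsum(
        "ik,...k,kj->...ij", params.U_h, h * r * (1.0 - r), params.U_r)
    return phi, da


def candidate_jacobian(params: GRUParams, h) -> np.ndarray:
    """Jacobian of :func:`candidate_residual` (used by the Newton solvers)."""
    h = _check_state(params, h)
    r = expit(h @ params.U_r.T + params.b_r)
    phi, da = _phi_and_da(params, h, r)
    eye = np.eye(params.d)
    return (1.0 - phi**2)[..., None] * da - eye


def jacobian(params: GRUParams, h, factored: bool = False) -> np.ndarray:
    """Exact Jacobian of :func:`vector_field` at ``h``.

    Includes the chain-rule terms through both gates.  At a fixed point the
    update-gate term vanishes identically because it multiplies the candidate
    residual, which is zero there.
    """
    h = _check_state(params, h)
    z, r = gates(params, h)
    phi, da = _phi_and_da(params, h, r)
    g = phi - h
    eye = np.eye(params.d)
    inner = (1.0 - phi**2)[..., None] * da - eye
    if factored:
        return 0.5 * inner
    dz = (z * (1.0 - z))[..., None] * params.U_z
    return -dz * g[..., None] + (1.0 - z)[..., None] * inner


def discrete_step(params: GRUParams, h, x=None) -> np.ndarray:
    """One step of the discrete-time GRU map.

    With zero (or absent) input this equals ``h + vector_field(params, h)``
    exactly — the unit-step forward-Euler identity.
    """
    h = _check_state(params, h)
    if x is not None:
        x = np.asarray(x, dtype=float)
        if not params.has_input:
            if np.any(x != 0):
                raise ValueError("params has no input matrices but a nonzero input was given")
            x = None
    if x is None:
        z, r = gates(params, h)
        g = np.tanh((r * h) @ params.U_h.T + params.b_h)
    else:
        if x.shape[-1] != params.p:
            raise ValueError(f"input has dimension {x.shape[-1]}, expected {params.p}")
        z = expit(x @ params.W_z.T + h @ params.U_z.T + params.b_z)
        r = expit(x @ params.W_r.T + h @ params.U_r.T + params.b_r)
        g = np.tanh(x @ params.W_h.T + (r * h) @ params.U_h.T + params.b_h)
    return (1.0 - z) * g + z * h


@dataclass
class Trajectory:
    """A solution curve: strictly increasing ``times`` and aligned ``states``."""

    times: np.ndarray
    states: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times and states must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states contain non-finite entries")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_csv(self, path) -> None:
        import pandas as pd

        d = self.states.shape[1]
        df = pd.DataFrame(self.states, columns=[f"h{i + 1}" for i in range(d)])
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


def integrate(
    params: GRUParams,
    h0,
    duration: float,
    *,
    method: str = "rk45",
    rtol: float = 1e-9,
    atol: float = 1e-12,
    max_step: float = np.inf,
    t_eval: Optional[np.ndarray] = None,
    events=None,
    factored: bool = False,
    dense_output: bool = False,
):
    """Integrate the autonomous GRU field from ``h0`` for ``duration`` time units.

    ``method='rk45'`` uses an adaptive order-5(4) Runge–Kutta pair;
    ``method='euler'`` takes unit forward-Euler steps and therefore reproduces
    the discrete GRU orbit exactly.  Returns a :class:`Trajectory`; with
    ``dense_output=True`` returns ``(trajectory, scipy_solution)`` so callers
    can interpolate (e.g., for section crossings).
    """
    h0 = _check_state(params, np.asarray(h0, dtype=float).reshape(-1))
    if duration <= 0:
        raise ValueError("duration must be positive")

    if method == "euler":
        n = int(np.ceil(duration))
        states = np.empty((n + 1, params.d))
        states[0] = h0
        for k in range(n):
            states[k + 1] = discrete_step(params, states[k])
        traj = Trajectory(np.arange(n + 1, dtype=float), states,
                          {"solver": "euler", "dt": 1.0})
        return (traj, None) if dense_output else traj
    if method != "rk45":
        raise ValueError(f"unknown method {method!r}")

    def rhs(t, h):
        return vector_field(params, h, factored=factored)

    sol = solve_ivp(rhs, (0.0, duration), h0, method="RK45", rtol=rtol, atol=atol,
                    max_step=max_step, t_eval=t_eval, events=events,
                    dense_output=dense_output)
    if not sol.success and sol.status != 1:  # status 1 = terminal event, fine
        raise IntegrationError(f"integration failed: {sol.message}",
                               sol.t[-1] if sol.t.size else 0.0,
                               sol.y[:, -1] if sol.t.size else h0)
    traj = Trajectory(sol.t, sol.y.T,
                      {"solver": "rk45", "rtol": rtol, "atol": atol})
    return (traj, sol) if dense_output else traj
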