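"""Limit-cycle detection, period measurement, attractor classification, sweeps.

A planar limit cycle is detected by integrating past a transient and
recording crossings of a Poincaré half-line anchored at a fixed point inside
the candidate orbit.  A cycle is declared when successive returns agree to a
tight tolerance while the loop amplitude stays above a floor (separating
genuine periodic orbits from slow spirals into a sink).  The period is the
mean spacing of the final return times; frequency is its reciprocal with
model time read in seconds.

A cycle enclosing an unstable fixed point is *self-exciting*; one enclosing
none is a *hidden attractor* (conjectured not to exist for the planar GRU).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .core import Trajectory, integrate, vector_field
from .params import GRUParams
from .phase import FixedPoint, find_fixed_points

__all__ = [
    "LimitCycle",
    "detect_limit_cycle",
    "orbital_period",
    "classify_attractor",
    "frequency_sweep",
    "SweepResult",
]


@dataclass
class LimitCycle:
    """A detected periodic orbit: one sampled loop, its period and frequency."""

    loop: Trajectory
    period: float
    frequency: float
    amplitude: float
    encloses: list = field(default_factory=list)
    return_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    return_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")


def _fp_probes(fps: Sequence[FixedPoint], offset: float) -> list:
    """Default probes: small offsets from each non-sink fixed point."""
    probes = []
    for fp in fps:
        if fp.stability != "sink":
            probes.append((fp.location + np.array([offset, 0.0]), fp.location))
    return probes


def _section_returns(params, start, anchor, t_detect, rtol, atol):
    """Integrate and collect returns to a Poincaré half-line through ``anchor``.

    Crossings of the horizontal line ``y = anchor_y`` in the direction of
    increasing y are recorded; a loop around the anchor crosses upward on one
    consistent side of it (which side depends on the sense of rotation), so
    the majority side is kept — one return per period.
    """
    ax, ay = anchor

    def crossing(t, h):
        return h[1] - ay

    crossing.direction = 1.0

    def at_rest(t, h):
        return float(np.linalg.norm(vector_field(params, h))) - 1e-10

    at_rest.terminal = True
    at_rest.direction = -1.0

    traj, sol = integrate(params, start, t_detect, rtol=rtol, atol=atol,
                          events=[crossing, at_rest], dense_output=True)
    if sol is None or len(sol.t_events[0]) == 0:
        return np.empty(0), np.empty((0, 2)), traj
    t_ev = sol.t_events[0]
    y_ev = sol.y_events[0]
    side = y_ev[:, 0] > ax
    if side.sum() < (~side).sum():
        side = ~side
    return t_ev[side], y_ev[side], traj


def _converge_returns(params, state, anchor, t_detect, rtol, atol, *,
                      return_tol, t_max):
    """Collect section returns until successive ones agree within tolerance.

    Close to a Hopf bifurcation the cycle attracts only weakly (the Floquet
    exponent vanishes at the bifurcation), so the return sequence converges
    geometrically but slowly.  Integration is extended in blocks up to
    ``t_max``; once the returns contract geometrically, Aitken extrapolation
    of the sequence jumps onto the cycle and the extrapolated point is
    verified by direct recurrence.  Returns ``(times, points)`` or
    ``(None, None)``.
    """
    all_t: list[float] = []
    all_p: list[np.ndarray] = []
    t_offset = 0.0
    while t_offset < t_max:
        t_ret, p_ret, traj = _section_returns(params, state, anchor,
                                              t_detect, rtol, atol)
        all_t.extend((t_ret + t_offset).tolist())
        all_p.extend(list(p_ret))
        t_offset += traj.times[-1]
        state = traj.final_state
        if np.linalg.norm(vector_field(params, state)) < 1e-9:
            return None, None  # settled onto a fixed point
        if len(all_t) >= 3 and np.linalg.norm(all_p[-1] - all_p[-2]) < return_tol:
            return np.asarray(all_t), np.asarray(all_p)
        if len(all_t) >= 4:
            d1 = all_p[-2] - all_p[-3]
            d2 = all_p[-1] - all_p[-2]
            n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
            if n1 > 0 and n2 < 0.95 * n1 and float(d1 @ d2) > 0:
                ratio = n2 / n1
                p_star = all_p[-1] + d2 * ratio / (1.0 - ratio)
                period_est = all_t[-1] - all_t[-2]
                t_v, p_v, _ = _section_returns(
                    params, p_star, anchor, 3.5 * period_est, rtol, atol)
                if len(t_v) >= 3 and np.linalg.norm(p_v[-1] - p_v[-2]) < return_tol:
                    return t_v + t_offset, p_v
    return None, None


def detect_limit_cycle(
    params: GRUParams,
    probes: Optional[Iterable] = None,
    t_transient: float = 250.0,
    t_detect: float = 250.0,
    *,
    fps: Optional[Sequence[FixedPoint]] = None,
    probe_offset: float = 0.01,
    return_tol: float = 1e-5,
    amplitude_floor: float = 1e-3,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    generic_probes: bool = True,
    loop_samples: int = 400,
    t_max: float = 3000.0,
) -> Optional[LimitCycle]:
    """Search for a stable limit cycle of a planar GRU.

    Probes default to small offsets from every non-sink fixed point (a stable
    cycle born of a Hopf bifurcation surrounds the destabilized point).  When
    the portrait contains only sinks and ``generic_probes`` is set, a few
    generic starts are tried with the section anchored at the trajectory
    centroid, so a hidden attractor would still be found.  Returns ``None``
    when no orbit passes the recurrence test.
    """
    if params.d != 2:
        raise ValueError("limit-cycle detection is implemented for d = 2 only")
    if fps is None:
        fps = find_fixed_points(params)
    probe_list: list
    if probes is not None:
        probe_list = [(np.asarray(p, dtype=float), None) for p in probes]
    else:
        probe_list = _fp_probes(fps, probe_offset)
        if not probe_list and generic_probes:
            probe_list = [(np.array(p), None) for p in
                          ((0.9, 0.9), (-0.9, 0.9), (0.9, -0.9), (-0.9, -0.9))]

    for start, anchor in probe_list:
        # discard the transient; stop early if the orbit settles onto a fixed point
        def at_rest(t, h):
            return float(np.linalg.norm(vector_field(params, h))) - 1e-10

        at_rest.terminal = True
        at_rest.direction = -1.0
        tr = integrate(params, start, t_transient, rtol=rtol, atol=atol,
                       events=[at_rest])
        state = tr.final_state
        if np.linalg.norm(vector_field(params, state)) < 1e-9:
            continue  # settled onto a fixed point
        if anchor is None:
            tail = tr.states[len(tr.states) // 2:]
            anchor = tail.mean(axis=0)
        t_ret, p_ret = _converge_returns(
            params, state, anchor, t_detect, rtol, atol,
            return_tol=return_tol, t_max=t_max)
        if t_ret is None or len(t_ret) < 3:
            continue
        if np.linalg.norm(p_ret[-1] - p_ret[-2]) > return_tol:
            continue
        diffs = np.diff(t_ret)
        k = min(5, len(diffs))
        period = float(np.mean(diffs[-k:]))
        # sample one closed loop from the last return point; one Newton
        # correction of the period along the flow tightens the closure
        loop = integrate(params, p_ret[-1], period, rtol=rtol, atol=atol,
                         t_eval=np.linspace(0.0, period, loop_samples))
        f_end = vector_field(params, loop.states[-1])
        gap = loop.states[0] - loop.states[-1]
        denom = float(f_end @ f_end)
        if denom > 0:
            period = period + float(gap @ f_end) / denom
            loop = integrate(params, p_ret[-1], period, rtol=rtol, atol=atol,
                             t_eval=np.linspace(0.0, period, loop_samples))
        pts = loop.states
        amplitude = float(np.max(
            np.linalg.norm(pts[:, None, :] - pts[None, ::7, :], axis=-1)))
        if amplitude < amplitude_floor:
            continue
        if np.linalg.norm(pts[-1] - pts[0]) > 1e-4 * max(1.0, amplitude):
            continue  # loop failed to close
        path = MplPath(pts)
        enclosed = [fp for fp in fps if path.contains_point(fp.location)]
        return LimitCycle(loop=loop, period=period, frequency=1.0 / period,
                          amplitude=amplitude, encloses=enclosed,
                          return_times=t_ret, return_points=p_ret)
    return None


def orbital_period(cycle: LimitCycle) -> tuple[float, float]:
    """Period (mean of the last >= 5 section-return spacings) and frequency."""
    if len(cycle.return_times) < 2:
        raise ValueError("need at least two section returns to measure a period")
    diffs = np.diff(cycle.return_times)
    k = min(5, len(diffs))
    period = float(np.mean(diffs[-k:]))
    return period, 1.0 / period


def classify_attractor(cycle: LimitCycle, fps: Sequence[FixedPoint]) -> str:
    """``'self-exciting'`` if the loop encloses an unstable point, else ``'hidden'``."""
    pts = cycle.loop.states
    from shapely.geometry import LineString

    if not LineString(pts).is_simple:
        raise ValueError("degenerate (self-intersecting) loop polygon")
    path = MplPath(pts)
    for fp in fps:
        if path.contains_point(fp.location) and fp.max_real_part > 0:
            return "self-exciting"
    return "hidden"


@dataclass
class SweepResult:
    """Frequency map over a rotation-family parameter grid."""

    alphas: np.ndarray
    betas: np.ndarray
    s: float
    frequency: np.ndarray  # (len(alphas), len(betas)), NaN where no cycle
    failures: list = field(default_factory=list)

    @property
    def mean_frequency(self) -> float:
        vals = self.frequency[np.isfinite(self.frequency)]
        return float(np.mean(vals)) if vals.size else float("nan")

    @property
    def var_frequency(self) -> float:
        vals = self.frequency[np.isfinite(self.frequency)]
        return float(np.var(vals)) if vals.size else float("nan")

    @property
    def n_cycles(self) -> int:
        return int(np.isfinite(self.frequency).sum())

    def to_dataframe(self):
        import pandas as pd

        A, B = np.meshgrid(self.alphas, self.betas, indexing="ij")
        freq = self.frequency.ravel()
        return pd.DataFrame({
            "alpha": A.ravel(), "beta": B.ravel(),
            "frequency": [f if np.isfinite(f) else None for f in freq]})


def frequency_sweep(
    alphas: np.ndarray,
    betas: np.ndarray,
    s: float = 0.0,
    *,
    detect_kwargs: Optional[dict] = None,
) -> SweepResult:
    """Oscillation frequency over the rotation family's ``(alpha, beta)`` grid.

    Each cell builds the rotation-family GRU, runs limit-cycle detection, and
    records the frequency in Hz or NaN where no cycle exists.  Detection
    probes are seeded at the non-sink fixed points (every cycle in this family
    surrounds the destabilized origin); individual cell failures are recorded
    and never abort the sweep.
    """
    from .params import rotation_family

    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    kw = dict(generic_probes=False)
    kw.update(detect_kwargs or {})
    freq = np.full((len(alphas), len(betas)), np.nan)
    failures = []
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            try:
                cycle = detect_limit_cycle(rotation_family(a, b, s), **kw)
            except Exception as exc:  # cell failure: log and continue
                failures.append(((float(a), float(b)), repr(exc)))
                continue
            if cycle is not None:
                freq[i, j] = cycle.frequency
    return SweepResult(alphas=alphas, betas=betas, s=s, frequency=freq,
                       failures=failures)
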