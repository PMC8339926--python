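"""Planar target systems and trajectory datasets for the forecasting task.

Three prescribed systems:

* FitzHugh–Nagumo relaxation oscillator
      dx/dt = x - x^3/3 - y + I_ext
      tau dy/dt = x + a - b y
  with tau = 12.5, a = 0.7, b = 0.8 and the external current drawn afresh
  each observation step from Normal(mean 0.7, variance 0.04) — process noise
  that keeps the oscillator jittering around its limit cycle.

* Line attractor:  dx/dt = -x, dy/dt = 0 (a continuum of fixed points along
  the y-axis).

* Ring attractor:  dx/dt = -(x^2 + y^2 - 1) x, dy/dt = -(x^2 + y^2 - 1) y
  (an attracting unit circle of fixed points around an unstable origin).

Datasets integrate the deterministic field with classical RK4 (ten substeps
per stored step) and add i.i.d. Gaussian observation noise to every stored
point (variance 0.1 per coordinate for the line and ring tasks, as the
training data prescribe; none for FitzHugh–Nagumo, whose noise enters through
the current).  Initial conditions are drawn uniformly over a per-system
region covering the attractor's basin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np

__all__ = [
    "FHNParams",
    "ForecastDataset",
    "fhn_field",
    "line_field",
    "ring_field",
    "generate_dataset",
    "SYSTEMS",
]


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh–Nagumo constants; ``I_var`` is a variance (std = sqrt)."""

    tau: float = 12.5
    a: float = 0.7
    b: float = 0.8
    I_mean: float = 0.7
    I_var: float = 0.04

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def fhn_field(w, p: FHNParams = FHNParams(), I: Optional[float] = None) -> np.ndarray:
    """FitzHugh–Nagumo right-hand side at ``w = (x, y)`` with current ``I``."""
    w = np.asarray(w, dtype=float)
    if I is None:
        I = p.I_mean
    x, y = w[..., 0], w[..., 1]
    return np.stack([x - x**3 / 3.0 - y + I, (x + p.a - p.b * y) / p.tau], axis=-1)


def line_field(w) -> np.ndarray:
    """Line attractor along the y-axis: ``(-x, 0)``."""
    w = np.asarray(w, dtype=float)
    return np.stack([-w[..., 0], np.zeros_like(w[..., 1])], axis=-1)


def ring_field(w) -> np.ndarray:
    """Attracting unit circle: radial relaxation ``-(|w|^2 - 1) w``."""
    w = np.asarray(w, dtype=float)
    x, y = w[..., 0], w[..., 1]
    c = x**2 + y**2 - 1.0
    return np.stack([-c * x, -c * y], axis=-1)


@dataclass
class ForecastDataset:
    """``n_traj`` planar trajectories of ``T+1`` points each, step ``dt``."""

    trajectories: np.ndarray  # (n_traj, T+1, 2)
    dt: float
    system: str
    noise_var: float
    seed: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.trajectories = np.asarray(self.trajectories, dtype=float)
        if self.trajectories.ndim != 3 or self.trajectories.shape[2] != 2:
            raise ValueError("trajectories must have shape (n_traj, T+1, 2)")
        if not np.all(np.isfinite(self.trajectories)):
            raise ValueError("trajectories contain non-finite values")

    @property
    def n_traj(self) -> int:
        return self.trajectories.shape[0]

    @property
    def horizon(self) -> int:
        return self.trajectories.shape[1] - 1

    def to_csv(self, path) -> None:
        import pandas as pd

        n, m, _ = self.trajectories.shape
        traj_id = np.repeat(np.arange(n), m)
        step = np.tile(np.arange(m), n)
        flat = self.trajectories.reshape(-1, 2)
        pd.DataFrame({"traj_id": traj_id, "step": step,
                      "x": flat[:, 0], "y": flat[:, 1]}).to_csv(path, index=False)
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(json.dumps({
            "system": self.system, "dt": self.dt, "noise_var": self.noise_var,
            "seed": self.seed, "n_traj": n, "T": m - 1, **self.extra}))


def _rk4_step(f: Callable, w: np.ndarray, dt: float, substeps: int = 10) -> np.ndarray:
    h = dt / substeps
    for _ in range(substeps):
        k1 = f(w)
        k2 = f(w + 0.5 * h * k1)
        k3 = f(w + 0.5 * h * k2)
        k4 = f(w + h * k3)
        w = w + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return w


# per-system defaults: (dt, observation-noise variance, initial-condition sampler)
def _fhn_ic(rng, n):
    return rng.uniform(-2.5, 2.5, size=(n, 2))


def _line_ic(rng, n):
    return rng.uniform(-1.5, 1.5, size=(n, 2))


def _ring_ic(rng, n):
    radius = rng.uniform(0.3, 1.7, size=n)
    angle = rng.uniform(0.0, 2 * np.pi, size=n)
    return np.stack([radius * np.cos(angle), radius * np.sin(angle)], axis=-1)


SYSTEMS = {
    "fhn": {"field": fhn_field, "dt": 1.0, "noise_var": 0.0, "ic": _fhn_ic},
    "line": {"field": line_field, "dt": 0.3, "noise_var": 0.1, "ic": _line_ic},
    "ring": {"field": ring_field, "dt": 0.3, "noise_var": 0.1, "ic": _ring_ic},
}


def generate_dataset(
    system: Union[str, Callable],
    n_traj: int = 667,
    T: int = 29,
    dt: Optional[float] = None,
    noise_var: Optional[float] = None,
    seed: int = 0,
    *,
    fhn_params: FHNParams = FHNParams(),
    ic_sampler: Optional[Callable] = None,
    substeps: int = 10,
) -> ForecastDataset:
    """Generate ``n_traj`` trajectories of ``T+1`` observations each.

    ``system`` is ``'fhn'``, ``'line'``, ``'ring'`` or a callable field.  The
    deterministic field is advanced with RK4 at ``dt/substeps``; observation
    noise Normal(0, ``noise_var`` I) is added independently to every stored
    point.  For FitzHugh–Nagumo the external current is resampled at every
    stored step and held across its substeps.  Fully reproducible from
    ``seed``.
    """
    if n_traj < 1 or T < 1:
        raise ValueError("n_traj and T must be at least 1")
    if isinstance(system, str):
        if system not in SYSTEMS:
            raise ValueError(f"unknown system {system!r}; choose from {sorted(SYSTEMS)}")
        cfg = SYSTEMS[system]
        name = system
        base_field = cfg["field"]
        dt = cfg["dt"] if dt is None else dt
        noise_var = cfg["noise_var"] if noise_var is None else noise_var
        sampler = ic_sampler or cfg["ic"]
    else:
        name = getattr(system, "__name__", "custom")
        base_field = system
        if dt is None or noise_var is None or ic_sampler is None:
            raise ValueError("custom systems need explicit dt, noise_var and ic_sampler")
        sampler = ic_sampler
    if dt <= 0:
        raise ValueError("dt must be positive")
    if noise_var < 0:
        raise ValueError("noise variance must be nonnegative")

    rng = np.random.default_rng(seed)
    w = sampler(rng, n_traj)
    states = np.empty((n_traj, T + 1, 2))
    states[:, 0] = w
    for k in range(T):
        if name == "fhn":
            I = rng.normal(fhn_params.I_mean, np.sqrt(fhn_params.I_var), size=n_traj)
            w = _rk4_step(lambda ww: fhn_field(ww, fhn_params, I=I), w, dt, substeps)
        else:
            w = _rk4_step(base_field, w, dt, substeps)
        states[:, k + 1] = w
    if noise_var > 0:
        states = states + rng.normal(0.0, np.sqrt(noise_var), size=states.shape)
    return ForecastDataset(trajectories=states, dt=float(dt), system=name,
                           noise_var=float(noise_var), seed=seed)
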