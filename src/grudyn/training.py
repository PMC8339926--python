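"""Multi-step closed-loop forecasting with a GRU and affine readout.

The model receives one planar observation ``w(0)``, folds it into the hidden
state with a single gated step, then evolves autonomously; every hidden state
is mapped to a prediction by an affine readout:

    h_0 = 0
    h_1 = GRU(h_0, x = w(0))
    h_{k+1} = GRU(h_k, x = 0),   k >= 1
    w_hat(k) = C h_k + c

Training minimizes the multi-step squared-error loss

    L(theta) = (1/T) sum_i sum_{k=1..T} || w_hat_i(k) - w_i(k) ||^2

over all trajectories at once (whole-batch) with ADAM.  Note the loss is
scaled by the horizon ``T`` only — duplicating trajectories doubles it.

Gradients are computed by exact reverse-mode backpropagation through the
unrolled recurrence (implemented here directly in numpy and verified against
finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .params import GRUParams
from .targets import ForecastDataset, generate_dataset

__all__ = [
    "ForecastModel",
    "TrainConfig",
    "TrainingRun",
    "init_forecast_model",
    "closed_loop_predict",
    "multistep_loss",
    "loss_and_gradients",
    "train",
    "analyze_learned",
    "pseudo_line_segment",
    "dimension_experiment",
]

_WEIGHT_KEYS = ("U_z", "U_r", "U_h", "b_z", "b_r", "b_h",
                "W_z", "W_r", "W_h", "C", "c")


@dataclass
class ForecastModel:
    """GRU with input matrices (p = 2) plus a 2-row affine readout."""

    gru: GRUParams
    readout_matrix: np.ndarray  # (2, d)
    readout_offset: np.ndarray  # (2,)

    def __post_init__(self):
        if not self.gru.has_input:
            raise ValueError("forecast model requires GRU input matrices")
        self.readout_matrix = np.asarray(self.readout_matrix, dtype=float)
        self.readout_offset = np.asarray(self.readout_offset, dtype=float).reshape(-1)
        if self.readout_matrix.shape != (2, self.gru.d):
            raise ValueError(f"readout matrix must be (2, {self.gru.d})")
        if self.readout_offset.shape != (2,):
            raise ValueError("readout offset must be a 2-vector")

    @property
    def d(self) -> int:
        return self.gru.d

    def copy(self) -> "ForecastModel":
        g = self.gru
        gru = GRUParams(g.U_z.copy(), g.U_r.copy(), g.U_h.copy(), g.b_z.copy(),
                        g.b_r.copy(), g.b_h.copy(), g.W_z.copy(), g.W_r.copy(),
                        g.W_h.copy())
        return ForecastModel(gru, self.readout_matrix.copy(),
                             self.readout_offset.copy())


def init_forecast_model(d: int, seed: int = 0, scale: float = 0.5) -> ForecastModel:
    """Uniform(-scale, scale) weights, zero biases and offset."""
    rng = np.random.default_rng(seed)

    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)

    gru = GRUParams(u(d, d), u(d, d), u(d, d), np.zeros(d), np.zeros(d),
                    np.zeros(d), u(d, 2), u(d, 2), u(d, 2))
    return ForecastModel(gru, u(2, d), np.zeros(2))


def _forward(model: ForecastModel, w0: np.ndarray, T: int):
    """Unrolled forward pass; returns predictions and per-step caches."""
    g = model.gru
    n, d = w0.shape[0], g.d
    h = np.zeros((n, d))
    cache = {"h": [h], "z": [], "r": [], "phi": [], "rh": []}
    preds = np.empty((n, T, 2))
    for t in range(T):
        if t == 0:
            az = w0 @ g.W_z.T + h @ g.U_z.T + g.b_z
            ar = w0 @ g.W_r.T + h @ g.U_r.T + g.b_r
        else:
            az = h @ g.U_z.T + g.b_z
            ar = h @ g.U_r.T + g.b_r
        z, r = expit(az), expit(ar)
        rh = r * h
        ah = rh @ g.U_h.T + g.b_h
        if t == 0:
            ah = ah + w0 @ g.W_h.T
        phi = np.tanh(ah)
        h = (1.0 - z) * phi + z * cache["h"][-1]
        cache["z"].append(z)
        cache["r"].append(r)
        cache["phi"].append(phi)
        cache["rh"].append(rh)
        cache["h"].append(h)
        preds[:, t] = h @ model.readout_matrix.T + model.readout_offset
    return preds, cache


def closed_loop_predict(model: ForecastModel, w0, T: int) -> np.ndarray:
    """Predictions ``w_hat(1..T)`` from initial observation(s) ``w0``.

    ``w0`` may be a single planar point or an ``(N, 2)`` batch; the result has
    a matching leading shape.  After the first step the hidden dynamics are
    autonomous, so the predictions depend on ``w0`` only through ``h_1``.
    """
    if T < 1:
        raise ValueError("horizon T must be at least 1")
    w0 = np.asarray(w0, dtype=float)
    single = w0.ndim == 1
    preds, _ = _forward(model, w0[None] if single else w0, T)
    return preds[0] if single else preds


def multistep_loss(model: ForecastModel, dataset: ForecastDataset) -> float:
    """The forecasting loss: ``(1/T) * sum_i sum_k ||w_hat - w||^2``."""
    traj = dataset.trajectories
    T = dataset.horizon
    preds, _ = _forward(model, traj[:, 0], T)
    return float(np.sum((preds - traj[:, 1:]) ** 2) / T)


def loss_and_gradients(model: ForecastModel, dataset: ForecastDataset):
    """Loss and exact gradients w.r.t. every trainable array (BPTT)."""
    g = model.gru
    traj = dataset.trajectories
    T = dataset.horizon
    w0 = traj[:, 0]
    targets = traj[:, 1:]
    preds, cache = _forward(model, w0, T)
    err = preds - targets
    loss = float(np.sum(err**2) / T)

    C = model.readout_matrix
    grads = {k: np.zeros_like(v) for k, v in {
        "U_z": g.U_z, "U_r": g.U_r, "U_h": g.U_h, "b_z": g.b_z, "b_r": g.b_r,
        "b_h": g.b_h, "W_z": g.W_z, "W_r": g.W_r, "W_h": g.W_h,
        "C": C, "c": model.readout_offset}.items()}

    dh_next = np.zeros_like(cache["h"][0])
    for t in range(T - 1, -1, -1):
        dout = (2.0 / T) * err[:, t]  # (n, 2)
        grads["C"] += dout.T @ cache["h"][t + 1]
        grads["c"] += dout.sum(axis=0)
        dh = dout @ C + dh_next

        z, r = cache["z"][t], cache["r"][t]
        phi, rh = cache["phi"][t], cache["rh"][t]
        h_prev = cache["h"][t]

        dz = dh * (h_prev - phi)
        daz = dz * z * (1.0 - z)
        dphi = dh * (1.0 - z)
        dah = dphi * (1.0 - phi**2)
        drh = dah @ g.U_h
        dr = drh * h_prev
        dar = dr * r * (1.0 - r)

        grads["U_h"] += dah.T @ rh
        grads["b_h"] += dah.sum(axis=0)
        grads["U_z"] += daz.T @ h_prev
        grads["b_z"] += daz.sum(axis=0)
        grads["U_r"] += dar.T @ h_prev
        grads["b_r"] += dar.sum(axis=0)
        if t == 0:
            grads["W_z"] += daz.T @ w0
            grads["W_r"] += dar.T @ w0
            grads["W_h"] += dah.T @ w0

        dh_next = (dh * z + daz @ g.U_z + dar @ g.U_r + drh * r)
    return loss, grads


@dataclass(frozen=True)
class TrainConfig:
    """Whole-batch ADAM settings (learning rate 1e-2, default moments)."""

    epochs: int = 4000
    lr: float = 1e-2
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0


@dataclass
class TrainingRun:
    config: TrainConfig
    loss_curve: np.ndarray
    model: ForecastModel

    @property
    def final_loss(self) -> float:
        return float(self.loss_curve[-1])


def _get_arrays(model: ForecastModel) -> dict:
    g = model.gru
    return {"U_z": g.U_z, "U_r": g.U_r, "U_h": g.U_h, "b_z": g.b_z,
            "b_r": g.b_r, "b_h": g.b_h, "W_z": g.W_z, "W_r": g.W_r,
            "W_h": g.W_h, "C": model.readout_matrix, "c": model.readout_offset}


def train(model: ForecastModel, dataset: ForecastDataset,
          config: TrainConfig = TrainConfig()) -> TrainingRun:
    """Whole-batch ADAM on the multi-step loss; deterministic given the seed.

    The input ``model`` is left untouched; the returned run holds the trained
    copy and the per-epoch loss curve.  Training aborts with the last finite
    state if the loss ever becomes non-finite.
    """
    model = model.copy()
    arrays = _get_arrays(model)
    m = {k: np.zeros_like(v) for k, v in arrays.items()}
    v = {k: np.zeros_like(val) for k, val in arrays.items()}
    curve = np.empty(config.epochs)
    last_finite = model.copy()
    for epoch in range(config.epochs):
        loss, grads = loss_and_gradients(model, dataset)
        if not np.isfinite(loss):
            curve = curve[:epoch]
            model = last_finite
            break
        curve[epoch] = loss
        last_finite = model.copy() if epoch % 50 == 0 else last_finite
        t = epoch + 1
        for k, arr in arrays.items():
            m[k] = config.beta1 * m[k] + (1 - config.beta1) * grads[k]
            v[k] = config.beta2 * v[k] + (1 - config.beta2) * grads[k] ** 2
            m_hat = m[k] / (1 - config.beta1**t)
            v_hat = v[k] / (1 - config.beta2**t)
            arr -= config.lr * m_hat / (np.sqrt(v_hat) + config.eps)
    return TrainingRun(config=config, loss_curve=curve, model=model)


def analyze_learned(model: ForecastModel, *, box=(-1.2, 1.2), grid_n: int = 30,
                    cycle_kwargs: Optional[dict] = None):
    """Topological summary of the trained network's autonomous hidden dynamics.

    Strips the input matrices and hands the autonomous GRU to the
    phase-analysis layer.  For ``d = 2`` this includes limit-cycle detection;
    for higher dimensions only fixed points are enumerated (from random
    Newton seeds) and cycle existence is probed from trajectories.
    """
    from .phase import find_fixed_points, topology_signature

    auto = model.gru.autonomous()
    if auto.d == 2:
        sig = topology_signature(auto, box=box, grid_n=grid_n,
                                 cycle_kwargs=cycle_kwargs)
        fps = find_fixed_points(auto, box=box, grid_n=grid_n)
        return sig, {"fixed_points": fps, "params": auto}
    from .phase import TopologySignature, STABILITY_CLASSES

    fps = find_fixed_points(auto, box=box, grid_n=grid_n)
    counts = {c: sum(fp.stability == c for fp in fps) for c in STABILITY_CLASSES}
    sig = TopologySignature(n_sink=counts["sink"], n_source=counts["source"],
                            n_saddle=counts["saddle"],
                            n_marginal=counts["marginal"])
    return sig, {"fixed_points": fps, "params": auto}


def pseudo_line_segment(params: GRUParams, *, speed_threshold: float = 1e-4,
                        sample_spacing: float = 0.005,
                        exclusion_radius: float = 1e-2,
                        t_trace: float = 20000.0) -> np.ndarray:
    """Slow samples along the saddle's unstable manifold (pseudo-line attractor).

    A trained pseudo-line attractor is the one-dimensional channel connecting
    the fixed points along the saddle's unstable manifold, with flow so slow
    it is effectively frozen at finite precision.  Both manifold branches are
    traced from small offsets along the unstable eigenvector, resampled at
    uniform arclength ``sample_spacing``, and samples with speed below
    ``speed_threshold`` that are at least ``exclusion_radius`` away from every
    fixed point are returned.
    """
    from .core import integrate, jacobian, vector_field
    from .phase import find_fixed_points

    fps = find_fixed_points(params)
    saddles = [fp for fp in fps if fp.stability == "saddle"]
    if not saddles:
        return np.empty((0, params.d))
    fp_locs = np.stack([fp.location for fp in fps])
    slow = []
    for saddle in saddles:
        J = jacobian(params, saddle.location)
        w, V = np.linalg.eig(J)
        v = np.real(V[:, np.argmax(w.real)])
        v = v / np.linalg.norm(v)
        for sign in (1.0, -1.0):
            tr = integrate(params, saddle.location + sign * 1e-5 * v, t_trace,
                           rtol=1e-10, atol=1e-13, max_step=5.0)
            pts = tr.states
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            if s[-1] < sample_spacing:
                continue
            su = np.arange(0.0, s[-1], sample_spacing)
            res = np.stack([np.interp(su, s, pts[:, i])
                            for i in range(params.d)], axis=1)
            speed = np.linalg.norm(vector_field(params, res), axis=-1)
            dist = np.min(np.linalg.norm(res[:, None, :] - fp_locs[None], axis=-1),
                          axis=1)
            slow.append(res[(speed < speed_threshold) & (dist > exclusion_radius)])
    if not slow:
        return np.empty((0, params.d))
    return np.concatenate(slow, axis=0)


def dimension_experiment(
    task: str,
    dims: Sequence[int] = (2, 4, 8, 16),
    seeds: Sequence[int] = (0, 1, 2),
    config: TrainConfig = TrainConfig(),
    *,
    n_traj: int = 667,
    T: int = 29,
    dataset_seed: int = 1234,
) -> dict:
    """Train ``len(dims) x len(seeds)`` models on one task; summarize by dim.

    Returns ``{"runs": {d: [TrainingRun...]}, "median_final_loss": {d: float}}``.
    Individual run failures are recorded and do not abort the experiment.
    """
    dataset = generate_dataset(task, n_traj=n_traj, T=T, seed=dataset_seed)
    runs: dict = {d: [] for d in dims}
    failures = []
    for d in dims:
        for seed in seeds:
            try:
                model = init_forecast_model(d, seed=seed)
                runs[d].append(train(model, dataset, replace(config, seed=seed)))
            except Exception as exc:
                failures.append(((d, seed), repr(exc)))
    medians = {d: float(np.median([r.final_loss for r in rs])) if rs else float("nan")
               for d, rs in runs.items()}
    return {"runs": runs, "median_final_loss": medians, "failures": failures,
            "task": task}
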