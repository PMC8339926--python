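"""Parameter/report serialization and phase-portrait rendering.

Parameters round-trip through JSON bit-exactly (row-major nested lists);
reports are JSON with every tolerance and seed needed to reproduce them.
Portraits overlay the two nullcline families (orange / pink), fixed points
marked by stability class, sampled trajectories, and a log-speed colormap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .params import GRUParams
from .phase import FixedPoint, TopologySignature

__all__ = ["load_params", "save_params", "AnalysisReport", "save_report",
           "render_portrait"]


def load_params(path) -> GRUParams:
    """Load a GRU parameter JSON; schema violations name the offending field."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"invalid JSON in {path}: {exc}") from exc
    return GRUParams.from_dict(data)


def save_params(params: GRUParams, path) -> None:
    params.save(path)


@dataclass
class AnalysisReport:
    """Everything needed to reproduce one topology analysis."""

    params: dict
    signature: TopologySignature
    fixed_points: list
    cycles: list = field(default_factory=list)
    bifurcations: list = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    version: str = ""

    def to_dict(self) -> dict:
        def fp_dict(fp: FixedPoint) -> dict:
            return {"location": fp.location.tolist(),
                    "eigenvalues_real": fp.eigenvalues.real.tolist(),
                    "eigenvalues_imag": fp.eigenvalues.imag.tolist(),
                    "stability": fp.stability, "spiral": fp.spiral,
                    "residual_speed": fp.residual_speed}

        return {"params": self.params, "signature": asdict(self.signature),
                "fixed_points": [fp_dict(fp) for fp in self.fixed_points],
                "cycles": self.cycles, "bifurcations": self.bifurcations,
                "settings": self.settings, "version": self.version}


def save_report(report: AnalysisReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


_FP_STYLE = {"sink": ("o", "tab:blue"), "source": ("o", "tab:red"),
             "saddle": ("x", "black"), "marginal": ("s", "tab:purple")}


def render_portrait(
    params: GRUParams,
    box: Sequence[float] = (-1.2, 1.2),
    path=None,
    *,
    grid_n: int = 201,
    trajectories: Optional[Sequence] = None,
    fixed_points: Optional[Sequence[FixedPoint]] = None,
    show_arrows: bool = True,
):
    """Phase portrait of a planar GRU; returns the matplotlib figure."""
    if params.d != 2:
        raise ValueError("portraits are only defined for d = 2")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .core import integrate, vector_field
    from .phase import find_fixed_points, nullclines

    lo, hi = float(box[0]), float(box[1])
    xs = np.linspace(lo, hi, grid_n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
    F = vector_field(params, pts)
    speed = np.linalg.norm(F, axis=-1).reshape(grid_n, grid_n)

    fig, ax = plt.subplots(figsize=(6, 6))
    pc = ax.pcolormesh(X, Y, np.log10(speed + 1e-16), shading="auto",
                       cmap="viridis", alpha=0.6)
    fig.colorbar(pc, ax=ax, label="log10 speed")
    for dim, color in ((0, "orange"), (1, "pink")):
        for curve in nullclines(params, dim, box=box, grid_n=grid_n):
            ax.plot(curve[:, 0], curve[:, 1], color=color, lw=1.5)
    if show_arrows:
        step = max(grid_n // 15, 1)
        U = F[:, 0].reshape(grid_n, grid_n)[::step, ::step]
        V = F[:, 1].reshape(grid_n, grid_n)[::step, ::step]
        norm = np.hypot(U, V) + 1e-16
        ax.quiver(X[::step, ::step], Y[::step, ::step], U / norm, V / norm,
                  color="black", scale=30, width=2e-3)
    if fixed_points is None:
        fixed_points = find_fixed_points(params, box=(lo, hi))
    for fp in fixed_points:
        marker, color = _FP_STYLE[fp.stability]
        ax.plot(*fp.location, marker=marker, color=color, ms=9, mew=2)
    if trajectories:
        for h0 in trajectories:
            tr = integrate(params, np.asarray(h0, dtype=float), 60.0, rtol=1e-6)
            ax.plot(tr.states[:, 0], tr.states[:, 1], color="purple", lw=0.8)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if path is not None:
        fig.savefig(path, dpi=130, bbox_inches="tight")
        plt.close(fig)
    return fig
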