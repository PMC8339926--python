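"""Parameter containers for gated recurrent units.

A GRU of hidden dimension ``d`` is specified by three square recurrent
matrices (update gate ``U_z``, reset gate ``U_r``, candidate ``U_h``), three
bias vectors, and — when the unit is driven by a ``p``-dimensional input —
three input matrices ``W_z``, ``W_r``, ``W_h``.  For autonomous phase-space
analysis the input matrices are absent (``p = 0``).

Two named two-dimensional families are provided:

* :func:`rotation_family` — the recurrent matrix is a rotation by ``alpha``
  scaled by a gain ``beta``, with a scalar reset bias ``s`` broadcast to both
  components.  Sweeping ``alpha`` at ``beta > 2`` takes the system through an
  Andronov–Hopf bifurcation and, at smaller angles, a cascade of four
  simultaneous saddle-node bifurcations.
* :func:`homoclinic_family` — a fixed clockwise rotation by pi/20 with gain 3
  and candidate bias ``[0.32, gamma]``; sweeping ``gamma`` produces a Hopf
  bifurcation followed by a homoclinic bifurcation where the limit cycle
  collides with a saddle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "GRUParams",
    "RotationFamily",
    "HomoclinicFamily",
    "rotation_family",
    "homoclinic_family",
]


def _as_matrix(name: str, value, d: int, cols: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (d, cols):
        raise ValueError(f"{name} must have shape ({d}, {cols}), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def _as_vector(name: str, value, d: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.shape != (d,):
        raise ValueError(f"{name} must have shape ({d},), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class GRUParams:
    """All weights and biases of one GRU of hidden dimension ``d``.

    Input matrices ``W_z/W_r/W_h`` are optional; when absent the unit is
    autonomous (input dimension ``p = 0``).
    """

    U_z: np.ndarray
    U_r: np.ndarray
    U_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray
    W_z: Optional[np.ndarray] = None
    W_r: Optional[np.ndarray] = None
    W_h: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        U_h = np.asarray(self.U_h, dtype=float)
        if U_h.ndim != 2 or U_h.shape[0] != U_h.shape[1]:
            raise ValueError(f"U_h must be square, got shape {U_h.shape}")
        d = U_h.shape[0]
        self.U_h = _as_matrix("U_h", U_h, d, d)
        self.U_z = _as_matrix("U_z", self.U_z, d, d)
        self.U_r = _as_matrix("U_r", self.U_r, d, d)
        self.b_z = _as_vector("b_z", self.b_z, d)
        self.b_r = _as_vector("b_r", self.b_r, d)
        self.b_h = _as_vector("b_h", self.b_h, d)
        ws = [self.W_z, self.W_r, self.W_h]
        if any(w is not None for w in ws):
            if any(w is None for w in ws):
                raise ValueError("W_z, W_r, W_h must be given together or not at all")
            p = np.asarray(self.W_z).shape[1] if np.asarray(self.W_z).ndim == 2 else -1
            if p < 1:
                raise ValueError("input matrices must be 2-D with at least one column")
            self.W_z = _as_matrix("W_z", self.W_z, d, p)
            self.W_r = _as_matrix("W_r", self.W_r, d, p)
            self.W_h = _as_matrix("W_h", self.W_h, d, p)

    @property
    def d(self) -> int:
        return self.U_h.shape[0]

    @property
    def p(self) -> int:
        return 0 if self.W_z is None else self.W_z.shape[1]

    @property
    def has_input(self) -> bool:
        return self.W_z is not None

    @classmethod
    def zeros(cls, d: int, p: int = 0) -> "GRUParams":
        """All-zero parameters (single sink at the origin)."""
        z = np.zeros((d, d))
        b = np.zeros(d)
        if p > 0:
            w = np.zeros((d, p))
            return cls(z.copy(), z.copy(), z.copy(), b.copy(), b.copy(), b.copy(),
                       w.copy(), w.copy(), w.copy())
        return cls(z.copy(), z.copy(), z.copy(), b.copy(), b.copy(), b.copy())

    def autonomous(self) -> "GRUParams":
        """Copy with input matrices stripped (for phase-space analysis)."""
        return GRUParams(self.U_z.copy(), self.U_r.copy(), self.U_h.copy(),
                         self.b_z.copy(), self.b_r.copy(), self.b_h.copy())

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "d": self.d,
            "U_z": self.U_z.tolist(),
            "U_r": self.U_r.tolist(),
            "U_h": self.U_h.tolist(),
            "b_z": self.b_z.tolist(),
            "b_r": self.b_r.tolist(),
            "b_h": self.b_h.tolist(),
        }
        if self.has_input:
            out["W_z"] = self.W_z.tolist()
            out["W_r"] = self.W_r.tolist()
            out["W_h"] = self.W_h.tolist()
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GRUParams":
        for key in ("U_z", "U_r", "U_h", "b_z", "b_r", "b_h"):
            if key not in data:
                raise ValueError(f"parameter file is missing required field '{key}'")
        kwargs = {k: np.asarray(data[k], dtype=float)
                  for k in ("U_z", "U_r", "U_h", "b_z", "b_r", "b_h")}
        if "W_z" in data or "W_r" in data or "W_h" in data:
            for key in ("W_z", "W_r", "W_h"):
                if key not in data:
                    raise ValueError(f"parameter file is missing required field '{key}'")
                kwargs[key] = np.asarray(data[key], dtype=float)
        params = cls(**kwargs)
        if "d" in data and int(data["d"]) != params.d:
            raise ValueError(
                f"declared dimension d={data['d']} conflicts with U_h shape {params.U_h.shape}")
        return params

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "GRUParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rotation_family(alpha: float, beta: float, s: float = 0.0) -> GRUParams:
    """Rotation-with-gain family: ``U_h = beta * R(alpha)``, ``b_r = [s, s]``.

    ``R(alpha)`` is the counter-clockwise rotation matrix.  ``beta`` must be
    positive.  The scalar reset bias ``s`` is broadcast to both components.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    c, sn = np.cos(alpha), np.sin(alpha)
    U_h = beta * np.array([[c, -sn], [sn, c]])
    z = np.zeros((2, 2))
    return GRUParams(z.copy(), z.copy(), U_h, np.zeros(2),
                     np.array([s, s], dtype=float), np.zeros(2))


def homoclinic_family(gamma: float) -> GRUParams:
    """Clockwise pi/20 rotation with gain 3 and ``b_h = [0.32, gamma]``."""
    c, sn = np.cos(np.pi / 20), np.sin(np.pi / 20)
    U_h = 3.0 * np.array([[c, sn], [-sn, c]])
    z = np.zeros((2, 2))
    return GRUParams(z.copy(), z.copy(), U_h, np.zeros(2), np.zeros(2),
                     np.array([0.32, gamma], dtype=float))


@dataclass(frozen=True)
class RotationFamily:
    """Declarative form of :func:`rotation_family` (angle, gain, reset bias)."""

    alpha: float
    beta: float
    s: float = 0.0

    def build(self) -> GRUParams:
        return rotation_family(self.alpha, self.beta, self.s)


@dataclass(frozen=True)
class HomoclinicFamily:
    """Declarative form of :func:`homoclinic_family` (candidate-bias scalar)."""

    gamma: float

    def build(self) -> GRUParams:
        return homoclinic_family(self.gamma)
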