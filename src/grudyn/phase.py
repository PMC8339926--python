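"""Fixed-point location and classification, nullclines, slow points, topology.

Fixed points of the GRU field are roots of the candidate residual
``tanh(U_h (r*h) + b_h) - h`` (the strictly positive update-gate factor cannot
create or destroy roots).  Every root satisfies ``h = tanh(...)`` and so lies
strictly inside ``(-1, 1)^d``.  Roots are found by Newton iteration seeded on
a regular grid, deduplicated, verified, and classified by the eigenvalues of
the analytic Jacobian of the full field:

* sink    — all real parts < -marginal_tol
* source  — all real parts > +marginal_tol
* saddle  — real parts of both signs
* marginal — some real part within marginal_tol of zero (bifurcation point)

A *slow point* is a local minimum of flow speed that is not a fixed point;
clusters of fixed points packed within numerical resolution (the
pseudo-codimension-2 arrangement of a sink, a source, and two saddles) are
reported via :func:`find_clusters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import candidate_jacobian, candidate_residual, gates, jacobian, vector_field
from .params import GRUParams

__all__ = [
    "FixedPoint",
    "FixedPointCluster",
    "TopologySignature",
    "find_fixed_points",
    "classify_fixed_point",
    "find_clusters",
    "nullclines",
    "slow_points",
    "update_gate_slow_directions",
    "topology_signature",
    "scalar_stability_structures",
]

STABILITY_CLASSES = ("sink", "source", "saddle", "marginal")


@dataclass
class FixedPoint:
    """A verified root of the vector field with its linearization."""

    location: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    spiral: bool
    residual_speed: float

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=complex)

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))

    def __repr__(self) -> str:  # compact, for reports
        loc = np.array2string(self.location, precision=6)
        return f"FixedPoint({loc}, {self.stability}{', spiral' if self.spiral else ''})"


@dataclass
class FixedPointCluster:
    """Fixed points packed within a small diameter, acting as one hybrid point."""

    members: list
    diameter: float


@dataclass
class TopologySignature:
    """Counts of fixed points by class plus cycle/cluster flags."""

    n_sink: int
    n_source: int
    n_saddle: int
    n_marginal: int
    n_clusters: int = 0
    has_limit_cycle: bool = False

    @property
    def n_fixed_points(self) -> int:
        return self.n_sink + self.n_source + self.n_saddle + self.n_marginal


def _classify(eigenvalues: np.ndarray, marginal_tol: float) -> str:
    re = eigenvalues.real
    if np.any(np.abs(re) <= marginal_tol):
        return "marginal"
    if np.all(re < 0):
        return "sink"
    if np.all(re > 0):
        return "source"
    return "saddle"


def classify_fixed_point(params: GRUParams, h_star, marginal_tol: float = 1e-6,
                         residual_tol: float = 1e-8) -> str:
    """Stability class of a (verified) fixed point from its Jacobian eigenvalues."""
    h_star = np.asarray(h_star, dtype=float)
    speed = float(np.linalg.norm(vector_field(params, h_star)))
    if speed > residual_tol:
        raise ValueError(f"not a fixed point: |field| = {speed:.3g} > {residual_tol:.3g}")
    eig = np.linalg.eigvals(jacobian(params, h_star))
    return _classify(eig, marginal_tol)


def _make_fixed_point(params: GRUParams, h: np.ndarray, marginal_tol: float) -> FixedPoint:
    eig = np.linalg.eigvals(jacobian(params, h))
    return FixedPoint(
        location=h,
        eigenvalues=eig,
        stability=_classify(eig, marginal_tol),
        spiral=bool(np.any(np.abs(eig.imag) > 1e-12)),
        residual_speed=float(np.linalg.norm(vector_field(params, h))),
    )


def _grid_seeds(box: Sequence[float], grid_n: int, d: int) -> np.ndarray:
    lo, hi = float(box[0]), float(box[1])
    axes = [np.linspace(lo, hi, grid_n)] * d
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def find_fixed_points(
    params: GRUParams,
    box: Sequence[float] = (-1.2, 1.2),
    grid_n: int = 30,
    tol: float = 1e-10,
    *,
    dedup_tol: float = 1e-6,
    marginal_tol: float = 1e-6,
    max_iter: int = 60,
    seeds: Optional[np.ndarray] = None,
) -> list:
    """Locate all fixed points inside ``box`` by grid-seeded Newton iteration.

    Newton runs on the candidate residual (batched over all seeds);
    converged roots are deduplicated at ``dedup_tol``, re-verified against
    ``tol`` on the full field, classified, and returned ordered
    lexicographically by location.  Raises if no root converges — the
    trapping region guarantees at least one fixed point exists.
    """
    d = params.d
    if seeds is None:
        if d <= 3:
            seeds = _grid_seeds(box, grid_n, d)
        else:
            # grid seeding is exponential in d; fall back to quasi-random seeds
            rng = np.random.default_rng(0)
            n = max(grid_n**2, 2000)
            seeds = rng.uniform(box[0], box[1], size=(n, d))
    h = np.array(seeds, dtype=float)
    alive = np.ones(len(h), dtype=bool)
    for _ in range(max_iter):
        g = candidate_residual(params, h[alive])
        if np.all(np.linalg.norm(g, axis=-1) < 1e-13):
            break
        J = candidate_jacobian(params, h[alive])
        try:
            step = np.linalg.solve(J, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # singular Jacobian at some seed: perturb via least squares
            step = np.stack([np.linalg.lstsq(Ji, gi, rcond=None)[0]
                             for Ji, gi in zip(J, g)])
        h_new = h[alive] - step
        bad = ~np.all(np.isfinite(h_new), axis=-1) | (np.max(np.abs(h_new), axis=-1) > 5.0)
        h_new[bad] = h[alive][bad]
        sub = alive.nonzero()[0]
        alive[sub[bad]] = False
        h[sub] = h_new

    g = candidate_residual(params, h)
    ok = np.linalg.norm(g, axis=-1) < 1e-11
    ok &= np.all(np.abs(h) < 1.0, axis=-1)  # roots satisfy h = tanh(.)
    roots = h[ok]
    if roots.size == 0:
        raise RuntimeError(
            "no fixed point converged — impossible for the trapped GRU field; "
            "increase grid_n or widen the box")

    # greedy dedup on lexicographically sorted roots
    order = np.lexsort(roots.T[::-1])
    roots = roots[order]
    unique: list[np.ndarray] = []
    for rt in roots:
        if not any(np.linalg.norm(rt - u) < dedup_tol for u in unique):
            unique.append(rt)

    fps = []
    for rt in unique:
        fp = _make_fixed_point(params, rt, marginal_tol)
        if fp.residual_speed < tol:
            fps.append(fp)
    fps.sort(key=lambda f: tuple(f.location))
    if not fps:
        raise RuntimeError("all candidate roots failed residual verification")
    return fps


def find_clusters(fps: Iterable[FixedPoint], threshold: float = 1e-8) -> list:
    """Group fixed points lying within ``threshold`` of one another.

    A sink, a source, and two saddles packed below numerical resolution act as
    a single hybrid (pseudo-codimension-2) fixed point; such groups are
    reported as clusters rather than merged.
    """
    fps = list(fps)
    n = len(fps)
    used = np.zeros(n, dtype=bool)
    clusters = []
    for i in range(n):
        if used[i]:
            continue
        group = [i]
        used[i] = True
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k in range(n):
                if not used[k] and np.linalg.norm(
                        fps[j].location - fps[k].location) < threshold:
                    used[k] = True
                    group.append(k)
                    frontier.append(k)
        if len(group) > 1:
            members = [fps[j] for j in group]
            diam = max(np.linalg.norm(a.location - b.location)
                       for a in members for b in members)
            clusters.append(FixedPointCluster(members=members, diameter=float(diam)))
    return clusters


def nullclines(params: GRUParams, dim: int, box: Sequence[float] = (-1.2, 1.2),
               grid_n: int = 401) -> list:
    """Zero-level contours of one field component (planar systems only).

    Returns connected polylines (arrays of ``(x, y)`` points) extracted by
    marching squares; intersections of the ``dim=0`` and ``dim=1`` families
    approximate the fixed points.
    """
    if params.d != 2:
        raise ValueError("nullclines are only defined for d = 2")
    if dim not in (0, 1):
        raise ValueError("dim must be 0 or 1")
    from skimage import measure

    lo, hi = float(box[0]), float(box[1])
    xs = np.linspace(lo, hi, grid_n)
    ys = np.linspace(lo, hi, grid_n)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
    Z = vector_field(params, pts)[:, dim].reshape(grid_n, grid_n)
    contours = measure.find_contours(Z, 0.0)
    scale = (hi - lo) / (grid_n - 1)
    return [np.stack([lo + c[:, 0] * scale, lo + c[:, 1] * scale], axis=-1)
            for c in contours]


def slow_points(
    params: GRUParams,
    speed_threshold: float = 1e-3,
    box: Sequence[float] = (-1.2, 1.2),
    grid_n: int = 20,
    *,
    fixed_point_tol: float = 1e-6,
    dedup_tol: float = 1e-4,
) -> list:
    """Local speed minima below ``speed_threshold`` that are not fixed points.

    Minimizes ``|F|^2 / 2`` by quasi-Newton descent (analytic gradient
    ``J^T F``) from every grid seed, then filters and deduplicates.
    Returns ``(location, speed)`` pairs sorted by speed.
    """
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be positive")
    seeds = _grid_seeds(box, grid_n, params.d)

    def objective(h):
        f = vector_field(params, h)
        return 0.5 * float(f @ f), jacobian(params, h).T @ f

    try:
        fps = find_fixed_points(params, box=box, grid_n=max(grid_n, 20))
        fp_locs = np.stack([fp.location for fp in fps])
    except RuntimeError:
        fp_locs = np.empty((0, params.d))

    found: list[tuple[np.ndarray, float]] = []
    for seed in seeds:
        res = minimize(objective, seed, jac=True, method="L-BFGS-B",
                       options={"gtol": 1e-14, "ftol": 1e-18})
        loc = res.x
        speed = float(np.linalg.norm(vector_field(params, loc)))
        if speed >= speed_threshold:
            continue
        if np.max(np.abs(loc)) > 1.5:
            continue
        if fp_locs.size and np.min(np.linalg.norm(fp_locs - loc, axis=1)) < fixed_point_tol:
            continue
        # descent can stall just short of an actual root; a Newton polish that
        # lands on a nearby root unmasks such pseudo-minima
        x = loc.copy()
        for _ in range(30):
            g = candidate_residual(params, x)
            try:
                x = x - np.linalg.solve(candidate_jacobian(params, x), g)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 5:
                break
        if (np.all(np.isfinite(x))
                and np.linalg.norm(candidate_residual(params, x)) < 1e-11
                and np.linalg.norm(x - loc) < 2e-3):
            continue  # the "minimum" was a fixed point seen at finite precision
        if any(np.linalg.norm(loc - p) < dedup_tol for p, _ in found):
            continue
        found.append((loc, speed))
    found.sort(key=lambda t: t[1])
    return found


def update_gate_slow_directions(
    params: GRUParams,
    z_threshold: float = 1.0 - 1e-6,
    box: Sequence[float] = (-1.2, 1.2),
    grid_n: int = 30,
) -> dict:
    """Map each grid point to the set of dimensions its update gate freezes.

    Where a component of ``z`` exceeds ``z_threshold`` the flow in that
    dimension is rescaled to near zero, creating a pseudo-attracting slow
    direction.  The gate acts independently of the rest of the field, so this
    map can be superimposed on the fixed-point structure.
    """
    if not (0.0 < z_threshold < 1.0):
        raise ValueError("z_threshold must lie in (0, 1)")
    seeds = _grid_seeds(box, grid_n, params.d)
    z, _ = gates(params, seeds)
    out = {}
    for point, zi in zip(seeds, z):
        dims = frozenset(np.nonzero(zi > z_threshold)[0].tolist())
        if dims:
            out[tuple(point)] = dims
    return out


def topology_signature(
    params: GRUParams,
    box: Sequence[float] = (-1.2, 1.2),
    grid_n: int = 30,
    *,
    cluster_threshold: float = 1e-8,
    detect_cycles: bool = True,
    cycle_kwargs: Optional[dict] = None,
) -> TopologySignature:
    """One-line topological summary: class counts, clusters, limit-cycle flag."""
    fps = find_fixed_points(params, box=box, grid_n=grid_n)
    counts = {c: sum(fp.stability == c for fp in fps) for c in STABILITY_CLASSES}
    clusters = find_clusters(fps, threshold=cluster_threshold)
    has_cycle = False
    if detect_cycles and params.d == 2:
        from .oscillations import detect_limit_cycle

        cycle = detect_limit_cycle(params, fps=fps, **(cycle_kwargs or {}))
        has_cycle = cycle is not None
    return TopologySignature(
        n_sink=counts["sink"], n_source=counts["source"],
        n_saddle=counts["saddle"], n_marginal=counts["marginal"],
        n_clusters=len(clusters), has_limit_cycle=has_cycle)


def _scalar_params(u: float, b: float) -> GRUParams:
    return GRUParams(np.zeros((1, 1)), np.zeros((1, 1)), np.array([[u]]),
                     np.zeros(1), np.zeros(1), np.array([b]))


def scalar_stability_structures(
    u_values: Sequence[float] = (0.5, 1.5, 3.0, 4.0),
    b_values: Sequence[float] = (-0.6, -0.3, -0.1, 0.05, 0.1, 0.3, 0.6),
    *,
    fold_bisection_steps: int = 60,
) -> set:
    """Enumerate the stability structures of the scalar (d = 1) GRU.

    Sweeps candidate gain ``u`` and bias ``b`` over a grid, recording the
    multiset of fixed-point classes for each cell; additionally bisects ``b``
    across a fixed-point-count change at large gain to land on the fold, where
    the merging pair is classified marginal (the half-stable structure).
    Exactly three structures exist: monostable, half-stable + stable, and
    bistable.
    """

    def structure(u: float, b: float) -> tuple:
        fps = find_fixed_points(_scalar_params(u, b), box=(-1.2, 1.2), grid_n=200)
        return tuple(sorted(fp.stability for fp in fps))

    structures = {structure(u, b) for u in u_values for b in b_values}

    # fold bisection at the largest gain: bracket a count change in b > 0
    u = max(u_values)
    bs = sorted(bv for bv in b_values if bv > 0)
    counts = {bv: len(find_fixed_points(_scalar_params(u, bv), grid_n=200)) for bv in bs}
    lo = hi = None
    for b1, b2 in zip(bs, bs[1:]):
        if counts[b1] != counts[b2]:
            lo, hi = b1, b2
            break
    if lo is not None:
        n_lo = counts[lo]
        for _ in range(fold_bisection_steps):
            mid = 0.5 * (lo + hi)
            if len(find_fixed_points(_scalar_params(u, mid), grid_n=200)) == n_lo:
                lo = mid
            else:
                hi = mid
        structures.add(structure(u, 0.5 * (lo + hi)))
    return structures
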