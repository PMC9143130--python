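"""Biased and unbiased sampling on energy models.

A BAOAB-discretised Langevin integrator generates thermostatted trajectories
on any :class:`~pmfkit.toys.AnalyticSurface`-shaped model (``energy`` +
``gradient``), optionally under a harmonic umbrella bias.  A grid-scan driver
marches over coordinate nodes (continuation from the previous node's
configuration) to seed umbrella windows, and ``build_windows`` +
``sample_windows`` produce the window sets consumed by WHAM.

The integrator works in reduced time units; the paper-style defaults of
5 ps equilibration / 20 ps production map onto 5 000 discarded and 20 000
production steps at one sample per step.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import DEFAULT_FORCE_CONSTANT, DEFAULT_TEMPERATURE, kt

__all__ = [
    "HarmonicBias",
    "UmbrellaWindow",
    "WindowSet",
    "ScanGrid",
    "WindowPlan",
    "langevin_run",
    "grid_scan",
    "build_windows",
    "sample_windows",
]

#: Default production/equilibration lengths in integrator steps
#: (20 ps production, 5 ps equilibration at nominal 1 fs sampling).
DEFAULT_N_PRODUCTION = 20_000
DEFAULT_N_EQUILIBRATION = 5_000

#: Reduced-unit integrator defaults; see docs/methods.md for the rationale.
DEFAULT_DT = 0.01
DEFAULT_FRICTION = 10.0


@dataclass(frozen=True)
class HarmonicBias:
    """Umbrella restraint ½·k·(ξ − ξ₀)², k in kcal·mol⁻¹·Å⁻².

    ``center`` and ``k`` are scalars in 1D or length-2 vectors in 2D
    (a scalar ``k`` with a 2D center applies to both axes).
    """

    center: np.ndarray
    k: np.ndarray

    def __init__(self, center, k):
        center = np.atleast_1d(np.asarray(center, dtype=float))
        k = np.atleast_1d(np.asarray(k, dtype=float))
        if k.size == 1 and center.size > 1:
            k = np.full(center.size, k[0])
        if k.shape != center.shape:
            raise ValueError("force constant shape must match bias center")
        if np.any(k < 0):
            raise ValueError("force constant must be non-negative")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "k", k)

    @property
    def dim(self) -> int:
        return self.center.size

    def energy(self, xi) -> float:
        xi = np.atleast_1d(np.asarray(xi, dtype=float))
        return float(0.5 * np.sum(self.k * (xi - self.center) ** 2))

    def gradient(self, xi) -> np.ndarray:
        xi = np.atleast_1d(np.asarray(xi, dtype=float))
        return self.k * (xi - self.center)


@dataclass
class UmbrellaWindow:
    """One biased window: restraint definition plus its production samples."""

    center: np.ndarray
    k: np.ndarray
    temperature: float
    samples: np.ndarray  # (n,) in 1D or (n, 2) in 2D
    n_equilibration: int = 0

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.k = np.atleast_1d(np.asarray(self.k, dtype=float))
        if self.k.size == 1 and self.center.size > 1:
            self.k = np.full(self.center.size, self.k[0])
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("window has no production samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window contains non-finite samples")
        if self.samples.ndim == 1 and self.center.size != 1:
            raise ValueError("1D samples with multi-dimensional center")
        if self.samples.ndim == 2 and self.samples.shape[1] != self.center.size:
            raise ValueError("sample dimensionality does not match center")

    @property
    def dim(self) -> int:
        return self.center.size

    def bias(self) -> HarmonicBias:
        return HarmonicBias(self.center, self.k)


@dataclass
class WindowSet:
    """Windows sharing one temperature (mixed temperatures are rejected)."""

    windows: list[UmbrellaWindow]

    def __post_init__(self):
        if not self.windows:
            raise ValueError("empty window set")
        dims = {w.dim for w in self.windows}
        if len(dims) != 1:
            raise ValueError("windows mix 1D and 2D coordinates")
        temps = {w.temperature for w in self.windows}
        if len(temps) != 1:
            raise ValueError(
                f"mixed-temperature window sets are not supported: {sorted(temps)}"
            )

    @property
    def temperature(self) -> float:
        return self.windows[0].temperature

    @property
    def dim(self) -> int:
        return self.windows[0].dim

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i):
        return self.windows[i]


class TrajectoryDivergedError(RuntimeError):
    pass


def langevin_run(
    model,
    bias: HarmonicBias | None = None,
    n_steps: int = DEFAULT_N_PRODUCTION,
    dt: float = DEFAULT_DT,
    temperature: float = DEFAULT_TEMPERATURE,
    friction: float = DEFAULT_FRICTION,
    seed: int = 0,
    x0: Sequence[float] | float | None = None,
    mass: float = 1.0,
) -> np.ndarray:
    """BAOAB Langevin trajectory on an energy model; returns the coordinate
    series, shape ``(n_steps,)`` in 1D or ``(n_steps, dim)`` otherwise.

    The same seed always reproduces the identical series bit for bit.  At
    ``temperature == 0`` the noise term vanishes and the integrator reduces
    to damped relaxation toward the nearest minimum.  A diverging trajectory
    (non-finite or absurdly large energy) aborts with a diagnostic.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if friction <= 0:
        raise ValueError("friction must be positive")
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    dim = getattr(model, "dim", 1)
    if bias is not None and bias.dim != dim:
        raise ValueError("bias dimensionality does not match model")

    x = np.zeros(dim) if x0 is None else np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    if x.shape != (dim,):
        raise ValueError(f"x0 must have shape ({dim},)")
    v = np.zeros(dim)
    kT = 0.0 if temperature == 0 else kt(temperature)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kT / mass * (1.0 - c1 * c1))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, dim))

    def force(pos):
        g = np.atleast_1d(np.asarray(model.gradient(pos if dim > 1 else pos[0])))
        if bias is not None:
            g = g + bias.gradient(pos)
        return -g

    out = np.empty((n_steps, dim))
    f = force(x)
    half = 0.5 * dt
    for step in range(n_steps):
        v += half * f / mass
        x += half * v
        v = c1 * v + c2 * noise[step]
        x += half * v
        f = force(x)
        v += half * f / mass
        out[step] = x
        if step % 1000 == 0:
            e = float(model.energy(x if dim > 1 else x[0]))
            if not np.isfinite(e) or abs(e) > 1e8:
                raise TrajectoryDivergedError(
                    f"trajectory diverged at step {step}: x={x}, E={e}"
                )
    if not np.all(np.isfinite(out)):
        raise TrajectoryDivergedError("trajectory produced non-finite coordinates")
    return out[:, 0] if dim == 1 else out


@dataclass
class ScanGrid:
    """Grid-scan result: axis node values, energies, and the configuration
    stored at every node for window seeding."""

    axes: tuple[np.ndarray, ...]
    energies: np.ndarray
    configs: np.ndarray  # (*grid_shape, dim)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def n_nodes(self) -> int:
        return int(np.prod([a.size for a in self.axes]))


def _axis_nodes(spec) -> np.ndarray:
    """An axis spec is either an explicit node array or (start, stop, step)."""
    if isinstance(spec, (tuple, list)) and len(spec) == 3 and np.isscalar(spec[2]):
        start, stop, step = spec
        if step <= 0:
            raise ValueError("axis step must be positive")
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)
    nodes = np.asarray(spec, dtype=float)
    if nodes.ndim != 1 or nodes.size < 2:
        raise ValueError("axis must provide at least two nodes")
    return nodes


def grid_scan(model, axes) -> ScanGrid:
    """Evaluate the model over a rectilinear coordinate grid.

    ``axes`` is a list of axis specs (explicit nodes or (start, stop, step)
    with per-axis steps).  Nodes are visited marching along the fastest axis
    so each configuration continues from its predecessor; for analytic
    surfaces the configuration is the node coordinate itself.
    """
    node_arrays = [_axis_nodes(a) for a in (axes if isinstance(axes, (list, tuple)) else [axes])]
    dim = getattr(model, "dim", 1)
    if len(node_arrays) != dim:
        raise ValueError(f"model is {dim}D but {len(node_arrays)} axes given")
    shape = tuple(a.size for a in node_arrays)
    mesh = np.meshgrid(*node_arrays, indexing="ij")
    pts = np.stack(mesh, axis=-1)
    energies = model.energy(pts if dim > 1 else pts[..., 0])
    energies = np.asarray(energies, dtype=float).reshape(shape)
    if not np.all(np.isfinite(energies)):
        bad = np.argwhere(~np.isfinite(energies))[0]
        raise ValueError(f"non-finite energy at grid node {tuple(bad)}")
    return ScanGrid(axes=tuple(node_arrays), energies=energies, configs=pts)


@dataclass
class WindowPlan:
    """Window seeds produced from a scan grid, ready for sampling."""

    centers: np.ndarray       # (n_windows, dim)
    x0: np.ndarray            # (n_windows, dim) seed configurations
    k: np.ndarray             # (dim,)
    temperature: float


def build_windows(
    grid: ScanGrid,
    k: float | Sequence[float] = DEFAULT_FORCE_CONSTANT,
    temperature: float = DEFAULT_TEMPERATURE,
    spacing: int = 1,
) -> WindowPlan:
    """One umbrella window per selected grid node (every ``spacing``-th node
    along each axis), centred at the node's coordinates and seeded with the
    node configuration.  ``k`` defaults to 2500 kJ·mol⁻¹·Å⁻² converted to
    kcal (597.51)."""
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    sel = tuple(slice(None, None, spacing) for _ in grid.axes)
    configs = grid.configs[sel].reshape(-1, grid.ndim)
    if configs.size == 0:
        raise ValueError("empty window selection")
    k_arr = np.atleast_1d(np.asarray(k, dtype=float))
    if k_arr.size == 1:
        k_arr = np.full(grid.ndim, k_arr[0])
    return WindowPlan(centers=configs.copy(), x0=configs.copy(), k=k_arr,
                      temperature=temperature)


def sample_windows(
    model,
    plan: WindowPlan,
    n_samples: int = DEFAULT_N_PRODUCTION,
    n_equilibration: int = DEFAULT_N_EQUILIBRATION,
    dt: float = DEFAULT_DT,
    friction: float = DEFAULT_FRICTION,
    seed: int = 0,
) -> WindowSet:
    """Run a biased Langevin trajectory per planned window and return the
    production samples (equilibration discarded by sample index).

    Per-window seeds are spawned deterministically from ``seed``; the same
    seed reproduces the whole window set exactly.
    """
    children = np.random.SeedSequence(seed).spawn(len(plan.centers))
    windows = []
    for i, center in enumerate(plan.centers):
        bias = HarmonicBias(center, plan.k)
        series = langevin_run(
            model,
            bias=bias,
            n_steps=n_equilibration + n_samples,
            dt=dt,
            temperature=plan.temperature,
            friction=friction,
            seed=children[i],
            x0=plan.x0[i],
        )
        production = series[n_equilibration:]
        windows.append(
            UmbrellaWindow(
                center=center,
                k=plan.k,
                temperature=plan.temperature,
                samples=production,
                n_equilibration=n_equilibration,
            )
        )
    return WindowSet(windows)
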