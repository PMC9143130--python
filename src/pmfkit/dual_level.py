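"""Dual-level spline energy correction.

A low-level surface (cheap Hamiltonian) is upgraded toward a high-level one
by adding an interpolated correction built from paired single-point energy
differences ΔE(ξ) = E_HL(ξ) − E_LL(ξ) on a rectilinear node grid:

    E(ξ) = E_LL(ξ) + S[ΔE](ξ).

``S`` is a cubic interpolating spline in 1D (not-a-knot boundary) and a
bicubic tensor-product spline in 2D; both reproduce the node values
exactly.  Evaluation is defined only inside the node hull — requests
outside it raise instead of extrapolating, because silent extrapolation is
the characteristic failure mode of dual-level schemes.

Implemented sklearn-style: :class:`SplineCorrection` is fit on nodes and
then transforms PMF or scan grids; :func:`build_correction` /
:func:`apply_correction` are thin functional wrappers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, RectBivariateSpline
from sklearn.base import BaseEstimator

from .sampling import ScanGrid
from .wham import PMFGrid

__all__ = ["SplineCorrection", "CorrectionGrid", "build_correction", "apply_correction",
           "HullError"]


class HullError(ValueError):
    """Evaluation outside the convex hull of the correction nodes."""


class SplineCorrection(BaseEstimator):
    """Interpolated HL−LL correction on a rectilinear node grid.

    Attributes after ``fit``: ``nodes_`` (axis arrays), ``delta_`` (node
    values), ``spline_`` and ``ndim_``.
    """

    def __init__(self, min_nodes: int = 4):
        # bicubic needs >= 4 nodes per axis; 1D cubic likewise
        self.min_nodes = min_nodes

    def fit(self, nodes, delta) -> "SplineCorrection":
        if isinstance(nodes, tuple) and len(nodes) == 2 and not np.isscalar(nodes[0]):
            xs = np.asarray(nodes[0], dtype=float)
            ys = np.asarray(nodes[1], dtype=float)
            delta = np.asarray(delta, dtype=float)
            self._validate_axis(xs, "xi1")
            self._validate_axis(ys, "xi2")
            if delta.shape != (xs.size, ys.size):
                raise ValueError(
                    f"delta shape {delta.shape} does not match node grid "
                    f"({xs.size}, {ys.size}); scattered nodes are not supported"
                )
            self.nodes_ = (xs, ys)
            self.delta_ = delta
            self.spline_ = RectBivariateSpline(xs, ys, delta, kx=3, ky=3, s=0)
            self.ndim_ = 2
        else:
            xs = np.asarray(nodes, dtype=float)
            delta = np.asarray(delta, dtype=float)
            self._validate_axis(xs, "xi")
            if delta.shape != xs.shape:
                raise ValueError("delta must have one value per node")
            self.nodes_ = (xs,)
            self.delta_ = delta
            # not-a-knot boundaries: reproduces polynomials up to cubic and
            # avoids the O(h²) boundary-layer error of natural splines
            self.spline_ = CubicSpline(xs, delta, bc_type="not-a-knot")
            self.ndim_ = 1
        return self

    def _validate_axis(self, xs: np.ndarray, name: str) -> None:
        if xs.ndim != 1:
            raise ValueError(f"{name} nodes must be a 1D axis array")
        if xs.size < self.min_nodes:
            raise ValueError(
                f"{name}: need at least {self.min_nodes} nodes for a cubic "
                f"spline, got {xs.size}"
            )
        if np.any(np.diff(xs) <= 0):
            raise ValueError(f"{name} nodes must be strictly increasing")

    def _check_hull(self, pts: np.ndarray) -> None:
        for d, axis in enumerate(self.nodes_):
            lo, hi = axis[0], axis[-1]
            vals = pts[..., d]
            tol = 1e-9 * max(1.0, abs(hi - lo))
            if np.any(vals < lo - tol) or np.any(vals > hi + tol):
                raise HullError(
                    f"evaluation outside correction hull on axis {d}: "
                    f"requested [{vals.min():.4g}, {vals.max():.4g}], "
                    f"hull [{lo:.4g}, {hi:.4g}]; no extrapolation"
                )

    def __call__(self, *coords):
        """Evaluate S(ξ) (scalar or broadcast arrays)."""
        if len(coords) != self.ndim_:
            raise ValueError(f"correction is {self.ndim_}D, got {len(coords)} coords")
        if self.ndim_ == 1:
            x = np.asarray(coords[0], dtype=float)
            self._check_hull(x[..., None])
            return self.spline_(x)
        x = np.asarray(coords[0], dtype=float)
        y = np.asarray(coords[1], dtype=float)
        pts = np.stack(np.broadcast_arrays(x, y), axis=-1)
        self._check_hull(pts)
        return self.spline_(pts[..., 0], pts[..., 1], grid=False)

    def transform(self, grid):
        """Apply the correction to a :class:`PMFGrid` or :class:`ScanGrid`.

        Energies at bin/node centers get S(ξ) added; PMF grids are
        re-referenced to min 0 afterwards (empty bins stay flagged).
        """
        if isinstance(grid, PMFGrid):
            if grid.ndim != self.ndim_:
                raise ValueError("correction and grid dimensionality differ")
            mesh = np.meshgrid(*grid.axes, indexing="ij")
            corr = self(*mesh) if self.ndim_ > 1 else self(mesh[0])
            values = grid.values + corr
            out = PMFGrid(grid.axes, values, grid.counts.copy(), grid.temperature,
                          grid.n_iter, grid.final_change)
            return out.referenced()
        if isinstance(grid, ScanGrid):
            if grid.ndim != self.ndim_:
                raise ValueError("correction and grid dimensionality differ")
            mesh = np.meshgrid(*grid.axes, indexing="ij")
            corr = self(*mesh) if self.ndim_ > 1 else self(mesh[0])
            return ScanGrid(grid.axes, grid.energies + corr, grid.configs)
        raise TypeError("transform expects a PMFGrid or ScanGrid")


@dataclass
class CorrectionGrid:
    """Functional-facade container pairing nodes/ΔE with the fitted spline."""

    nodes: tuple
    delta: np.ndarray
    spline: SplineCorrection

    def __call__(self, *coords):
        return self.spline(*coords)


def build_correction(nodes, delta_values) -> CorrectionGrid:
    """Fit the interpolating correction; exact at nodes, hull-bounded.

    ``nodes`` is a 1D node array or a tuple (x_nodes, y_nodes); ``delta``
    the matching E_HL − E_LL values (1D array, or 2D array on the node
    grid — scattered, non-rectilinear input is rejected).
    """
    spline = SplineCorrection().fit(nodes, delta_values)
    return CorrectionGrid(nodes=spline.nodes_, delta=spline.delta_, spline=spline)


def apply_correction(grid, corr: CorrectionGrid | SplineCorrection):
    """E(bin) = E_LL(bin) + S(ξ); PMF grids are min re-referenced."""
    spline = corr.spline if isinstance(corr, CorrectionGrid) else corr
    return spline.transform(grid)
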