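"""Weighted histogram analysis: 1D/2D PMFs, barriers, paths, profiles.

The central estimator recombines umbrella-window histograms into a potential
of mean force W(ξ) = C − kT·ln p(ξ), with the constant absorbed by
min-referencing.  Iteration follows the standard self-consistent WHAM
equations in log space,

    p_b ∝ H_b / Σ_i N_i exp(g_i − β w_i(ξ_b)),
    g_i = −ln Σ_b p_b exp(−β w_i(ξ_b)),

and stops when the largest change in the window normalisation free energies
g_i (dimensionless, i.e. in units of kT, after removing the arbitrary common
shift) drops below ``tolerance`` (default 10⁻³).

On 2D grids a maximum-probability route between two bins is traced with
Dijkstra on the 8-connected bin graph using node costs exp(+W/kT); the 1D
profile along the route integrates exp(−W/kT) over the direction
perpendicular to the local path tangent.  Labeled stationary points from one
or more surfaces are stitched into a :class:`FreeEnergyProfile` from which
forward/reverse barriers between any two states can be queried.
"""
from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .constants import kt
from .sampling import UmbrellaWindow, WindowSet

__all__ = [
    "PMFGrid",
    "StationaryPoint",
    "FreeEnergyProfile",
    "WHAM",
    "DisconnectedHistogramError",
    "ConvergenceError",
    "wham",
    "wham2d",
    "activation_free_energy",
    "trace_path",
    "assemble_profile",
    "barrier_query",
    "write_path_tsv",
]


class DisconnectedHistogramError(ValueError):
    """Window histograms do not overlap into a single connected range."""


class ConvergenceError(RuntimeError):
    """WHAM failed to converge; carries the last profile in ``pmf``."""

    def __init__(self, message: str, pmf: "PMFGrid"):
        super().__init__(message)
        self.pmf = pmf


@dataclass
class PMFGrid:
    """A min-referenced PMF on a rectilinear 1D or 2D bin grid.

    ``values`` holds W in kcal·mol⁻¹ with NaN in empty bins (flagged, never
    interpolated); ``counts`` holds the pooled sample counts per bin.
    """

    axes: tuple[np.ndarray, ...]
    values: np.ndarray
    counts: np.ndarray
    temperature: float
    n_iter: int = 0
    final_change: float = 0.0

    def __post_init__(self):
        self.axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        shape = tuple(a.size for a in self.axes)
        if self.values.shape != shape or self.counts.shape != shape:
            raise ValueError("values/counts shape does not match axes")
        covered = self.counts > 0
        if covered.any() and not np.all(np.isfinite(self.values[covered])):
            raise ValueError("non-finite W in covered bins")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def covered(self) -> np.ndarray:
        return self.counts > 0

    def referenced(self) -> "PMFGrid":
        """Return a copy with min(W over covered bins) = 0."""
        vals = self.values.copy()
        cov = self.covered
        if cov.any():
            vals = vals - np.nanmin(vals[cov])
        return PMFGrid(self.axes, vals, self.counts.copy(), self.temperature,
                       self.n_iter, self.final_change)

    def barrier(self) -> float:
        """max(W) − min(W) over covered bins — the crude grid barrier."""
        cov = self.covered
        return float(np.nanmax(self.values[cov]) - np.nanmin(self.values[cov]))


def _log_gauss_integral(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log ∫_a^b exp(−t²/2) dt, robust in far tails via log Φ."""
    from scipy.special import log_ndtr

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # exploit symmetry so the difference of CDFs is taken on the lower tail,
    # where log_ndtr stays accurate
    flip = (a + b) > 0
    a_, b_ = np.where(flip, -b, a), np.where(flip, -a, b)
    la = log_ndtr(a_)
    lb = log_ndtr(b_)
    with np.errstate(divide="ignore"):
        diff = lb + np.log1p(-np.exp(np.minimum(la - lb, 0.0)))
    return math.log(math.sqrt(2.0 * math.pi)) + diff


def _bin_centers(lo: float, hi: float, width: float) -> np.ndarray:
    n = max(int(math.ceil((hi - lo) / width)), 1)
    edges = lo + width * np.arange(n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _default_bin_width(centers: np.ndarray) -> float:
    """Half the smallest spacing between distinct window centers."""
    u = np.unique(centers)
    if u.size < 2:
        raise ValueError("cannot infer bin width from a single window center; pass bins")
    return 0.5 * float(np.min(np.diff(u)))


class WHAM(BaseEstimator):
    """Self-consistent WHAM estimator over umbrella windows (1D or 2D,
    auto-detected from the windows).

    Parameters
    ----------
    bins : int, sequence of int, array(s) of bin centers, or None
        Number of bins per axis, or explicit bin centers.  ``None`` uses a
        bin width of half the window spacing on each axis.
    tolerance : float
        Convergence threshold on the max change of the window normalisation
        free energies, in kT.
    max_iter : int
        Iteration cap; exceeding it raises :class:`ConvergenceError`
        carrying the last profile.

    Attributes (after ``fit``)
    --------------------------
    pmf_ : PMFGrid            min-referenced PMF
    n_iter_ : int             iterations used
    final_change_ : float     last g-change in kT
    converged_ : bool
    """

    def __init__(self, bins=None, tolerance: float = 1e-3, max_iter: int = 100_000,
                 bias_eval: str = "center"):
        self.bins = bins
        self.tolerance = tolerance
        self.max_iter = max_iter
        self.bias_eval = bias_eval

    # -- helpers ----------------------------------------------------------
    def _resolve_axes(self, windows: WindowSet, samples: np.ndarray) -> list[np.ndarray]:
        dim = windows.dim
        centers = np.array([w.center for w in windows])
        k_max = max(float(np.max(w.k)) for w in windows)
        kT = kt(windows.temperature)
        axes: list[np.ndarray] = []
        bins = self.bins
        if bins is not None and not isinstance(bins, (list, tuple)):
            bins = [bins] * dim
        for d in range(dim):
            lo = samples[:, d].min()
            hi = samples[:, d].max()
            if bins is None:
                # half the window spacing, but never wider than the thermal
                # width of the stiffest restraint (bias-at-bin-center needs
                # bins that resolve the window Gaussians)
                width = _default_bin_width(centers[:, d])
                if k_max > 0:
                    width = min(width, math.sqrt(kT / k_max))
                axes.append(_bin_centers(lo, hi + 1e-12, width))
            else:
                spec = bins[d]
                if np.isscalar(spec):
                    edges = np.linspace(lo, hi, int(spec) + 1)
                    axes.append(0.5 * (edges[:-1] + edges[1:]))
                else:
                    axes.append(np.asarray(spec, dtype=float))
        return axes

    @staticmethod
    def _check_connected(per_window_hist: np.ndarray) -> None:
        """Windows are connected when they share an occupied bin; the whole
        set must form one component."""
        occupied = per_window_hist > 0
        nw = occupied.shape[0]
        adj = (occupied @ occupied.T) > 0
        graph = csr_matrix(adj)
        n_comp, _ = connected_components(graph, directed=False)
        if n_comp > 1:
            raise DisconnectedHistogramError(
                f"disconnected histogram: {n_comp} non-overlapping window groups; "
                "add intermediate windows or widen bins"
            )

    @staticmethod
    def _presolve(logH, logN, bw, H) -> np.ndarray:
        """Warm-start the self-consistent iteration at the maximum of the
        convex WHAM log-likelihood,

            L(g) = Σ_i N_i g_i − Σ_b H_b ln Σ_i N_i exp(g_i − βw_ib),

        whose stationary point is exactly the WHAM fixed point.  Plain
        Picard iteration approaches that point geometrically and can stall
        far from self-consistency while per-iteration changes are already
        tiny; solving the likelihood first makes the stopping criterion on
        the subsequent iterations meaningful."""
        from scipy.optimize import minimize

        nw = bw.shape[0]
        if nw == 1:
            return np.zeros(1)
        N = np.exp(logN)
        covered = H > 0
        Hc = H[covered]
        bwc = bw[:, covered]

        def objective(g_free):
            g = np.concatenate([[0.0], g_free])
            inner = logN[:, None] + g[:, None] - bwc
            ls = logsumexp(inner, axis=0)
            f = -float(np.dot(N, g)) + float(np.dot(Hc, ls))
            # d/dg_i = -N_i + Σ_b H_b softmax_i(inner)
            soft = np.exp(inner - ls[None, :])
            grad = -N + soft @ Hc
            return f, grad[1:]

        res = minimize(objective, np.zeros(nw - 1), jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        g = np.concatenate([[0.0], res.x])

        # Newton polish to the fixed point at machine precision: makes the
        # solution independent of window ordering and of the L-BFGS path.
        scale = float(N.sum())
        for _ in range(50):
            inner = logN[:, None] + g[:, None] - bwc
            ls = logsumexp(inner, axis=0)
            soft = np.exp(inner - ls[None, :])          # (nw, n_covered)
            grad = -N + soft @ Hc
            if np.max(np.abs(grad)) < 1e-11 * scale:
                break
            hess = -(soft * Hc[None, :]) @ soft.T
            hess[np.diag_indices(nw)] += soft @ Hc
            # gauge: fix g[0] = 0, solve the reduced system
            try:
                step = np.linalg.solve(hess[1:, 1:], -grad[1:])
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            g = g.copy()
            g[1:] += step
            g -= g[0]
        return g - g.mean()

    # -- core -------------------------------------------------------------
    def fit(self, windows) -> "WHAM":
        if isinstance(windows, (list, tuple)):
            windows = WindowSet(list(windows))
        if not isinstance(windows, WindowSet):
            raise TypeError("fit expects a WindowSet or list of UmbrellaWindow")
        dim = windows.dim
        kT = kt(windows.temperature)
        beta = 1.0 / kT

        sample_list = [np.atleast_2d(w.samples.reshape(-1, dim) if w.samples.ndim > 1
                                     else w.samples[:, None]) for w in windows]
        all_samples = np.concatenate(sample_list, axis=0)
        axes = self._resolve_axes(windows, all_samples)
        shape = tuple(a.size for a in axes)
        nbins = int(np.prod(shape))
        edges = []
        for a in axes:
            if a.size == 1:
                w = 1.0
            else:
                w = a[1] - a[0]
            edges.append(np.concatenate([a - w / 2, [a[-1] + w / 2]]))

        nw = len(windows)
        hist = np.zeros((nw, nbins))
        for i, s in enumerate(sample_list):
            h, _ = np.histogramdd(s, bins=edges)
            hist[i] = h.reshape(-1)
        self._check_connected(hist)
        H = hist.sum(axis=0)
        N = hist.sum(axis=1)

        # Bias energy of every window in every bin, in kT.  The default
        # evaluates the restraint at the bin center; "bin-average" uses the
        # uniform bin average of the Boltzmann factor instead (exact via
        # Gaussian CDFs), which can help only when bins are wide AND the
        # underlying density is nearly flat within a bin — with stiff
        # springs the in-bin density is dominated by the window's own
        # Gaussian, and fine bins with center evaluation are more accurate.
        centers = np.array([w.center for w in windows])         # (nw, dim)
        ks = np.array([w.k for w in windows])                   # (nw, dim)
        if self.bias_eval == "center":
            mesh = np.meshgrid(*axes, indexing="ij")
            pts = np.stack([m.reshape(-1) for m in mesh], axis=-1)
            bw = beta * 0.5 * np.einsum(
                "wd,wbd->wb", ks, (pts[None, :, :] - centers[:, None, :]) ** 2
            )
        elif self.bias_eval == "bin-average":
            bw = np.zeros((nw, nbins))
            bin_idx = np.stack(
                [m.reshape(-1) for m in np.meshgrid(
                    *[np.arange(a.size) for a in axes], indexing="ij")],
                axis=-1,
            )
            for d, axis in enumerate(axes):
                lo = edges[d][:-1]
                hi = edges[d][1:]
                width = hi - lo
                log_avg = np.zeros((nw, axis.size))
                for i in range(nw):
                    k_i = ks[i, d]
                    if k_i <= 0:
                        continue
                    sigma = 1.0 / math.sqrt(beta * k_i)
                    log_avg[i] = (
                        _log_gauss_integral((lo - centers[i, d]) / sigma,
                                            (hi - centers[i, d]) / sigma)
                        + math.log(sigma) - np.log(width)
                    )
                bw -= log_avg[:, bin_idx[:, d]]
        else:
            raise ValueError("bias_eval must be 'center' or 'bin-average'")

        logH = np.where(H > 0, np.log(np.maximum(H, 1)), -np.inf)
        logN = np.log(N)
        g = self._presolve(logH, logN, bw, H)
        change = np.inf
        it = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            for it in range(1, self.max_iter + 1):
                # log denominator per bin: logsumexp_i (logN_i + g_i - bw_ib)
                log_denom = logsumexp(logN[:, None] + g[:, None] - bw, axis=0)
                log_p = logH - log_denom
                g_new = -logsumexp(log_p[None, :] - bw, axis=1)
                g_new -= g_new.mean()
                change = float(np.max(np.abs(g_new - g)))
                g = g_new
                if change < self.tolerance:
                    break
            log_p -= logsumexp(log_p)

        values = np.full(nbins, np.nan)
        covered = H > 0
        values[covered] = -kT * log_p[covered]
        values[covered] -= values[covered].min()
        if (~covered).any():
            warnings.warn(
                f"{int((~covered).sum())} empty bins in WHAM grid; they are "
                "flagged (NaN), not interpolated",
                stacklevel=2,
            )
        pmf = PMFGrid(
            axes=tuple(axes),
            values=values.reshape(shape),
            counts=H.reshape(shape).astype(int),
            temperature=windows.temperature,
            n_iter=it,
            final_change=change,
        )
        if change >= self.tolerance:
            raise ConvergenceError(
                f"WHAM did not converge in {self.max_iter} iterations "
                f"(last change {change:.3e} kT)", pmf
            )
        self.pmf_ = pmf
        self.n_iter_ = it
        self.final_change_ = change
        self.converged_ = True
        return self


def wham(windows, bins=None, tolerance: float = 1e-3, max_iter: int = 100_000) -> PMFGrid:
    """1D WHAM over a window set; returns the min-referenced PMF."""
    est = WHAM(bins=bins, tolerance=tolerance, max_iter=max_iter).fit(windows)
    if est.pmf_.ndim != 1:
        raise ValueError("windows are 2D; use wham2d")
    return est.pmf_


def wham2d(windows, bins_x=None, bins_y=None, tolerance: float = 1e-3,
           max_iter: int = 100_000) -> PMFGrid:
    """2D WHAM over windows biased on two coordinates."""
    bins = None if bins_x is None and bins_y is None else [bins_x, bins_y]
    est = WHAM(bins=bins, tolerance=tolerance, max_iter=max_iter).fit(windows)
    if est.pmf_.ndim != 2:
        raise ValueError("windows are 1D; use wham")
    return est.pmf_


# ---------------------------------------------------------------------------
# Barriers and regions
# ---------------------------------------------------------------------------

def _region_mask(grid: PMFGrid, region) -> np.ndarray:
    """Region = (lo, hi) in 1D or ((xlo, xhi), (ylo, yhi)) in 2D."""
    if grid.ndim == 1:
        lo, hi = region
        mask = (grid.axes[0] >= lo) & (grid.axes[0] <= hi)
    else:
        (xlo, xhi), (ylo, yhi) = region
        mx = (grid.axes[0] >= xlo) & (grid.axes[0] <= xhi)
        my = (grid.axes[1] >= ylo) & (grid.axes[1] <= yhi)
        mask = mx[:, None] & my[None, :]
    mask = mask & grid.covered
    if not mask.any():
        raise ValueError(f"region {region} contains no covered bins")
    return mask


def activation_free_energy(grid: PMFGrid, reactant_region, ts_region) -> float:
    """ΔW‡ = max W over the transition-state region − min W over the
    reactant region, in kcal·mol⁻¹.

    This is the direct PMF estimate of the activation free energy; the small
    Jacobian term G_ξ(ξ_R) associated with fixing the coordinate at the
    reactant is deliberately neglected, as is standard for umbrella-sampling
    profiles.
    """
    r_mask = _region_mask(grid, reactant_region)
    t_mask = _region_mask(grid, ts_region)
    return float(np.nanmax(grid.values[t_mask]) - np.nanmin(grid.values[r_mask]))


# ---------------------------------------------------------------------------
# Path tracing on 2D grids
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def trace_path(grid: PMFGrid, start_bin, end_bin, refine: bool = True,
               perp_halfwidth: int = 5):
    """Maximum-probability route between two bins of a 2D PMF.

    Dijkstra on the 8-connected bin graph with node cost exp(+W/kT) (edge
    weight = mean endpoint cost × step length, ties broken by lexicographic
    bin index); empty bins are impassable.  Returns ``(path, profile)`` where
    ``path`` is the ordered list of (i, j) bins and ``profile`` the 1D free
    energy along it, obtained by integrating exp(−W/kT) over
    ``perp_halfwidth`` bins each side of the local path tangent with
    bilinear interpolation, min-referenced.
    """
    if grid.ndim != 2:
        raise ValueError("trace_path requires a 2D PMF grid")
    start = tuple(int(v) for v in start_bin)
    end = tuple(int(v) for v in end_bin)
    covered = grid.covered
    for name, b in (("start", start), ("end", end)):
        if not (0 <= b[0] < covered.shape[0] and 0 <= b[1] < covered.shape[1]):
            raise ValueError(f"{name} bin {b} outside grid")
        if not covered[b]:
            raise ValueError(f"{name} bin {b} is empty (uncovered)")
    kT = kt(grid.temperature)
    cost = np.where(covered, np.exp(np.clip(grid.values / kT, None, 500.0)), np.inf)

    if start == end:
        return [start], np.array([0.0])

    dist = {start: 0.0}
    prev: dict = {}
    heap = [(0.0, start)]
    done = set()
    while heap:
        d, node = heapq.heappop(heap)
        if node in done:
            continue
        done.add(node)
        if node == end:
            break
        i, j = node
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if not (0 <= ni < covered.shape[0] and 0 <= nj < covered.shape[1]):
                continue
            if not covered[ni, nj]:
                continue
            step = math.sqrt(2.0) if di and dj else 1.0
            nd = d + 0.5 * (cost[i, j] + cost[ni, nj]) * step
            other = (ni, nj)
            if nd < dist.get(other, np.inf):
                dist[other] = nd
                prev[other] = node
                heapq.heappush(heap, (nd, other))
    if end not in done:
        raise DisconnectedHistogramError(
            "no connected route between the requested bins through covered bins"
        )
    path = [end]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()

    if refine:
        path = _descent_refine(path, grid.values, covered)

    profile = _perpendicular_profile(grid, path, perp_halfwidth)
    return path, profile


def _descent_refine(path, values, covered):
    """One local sweep: replace an interior node by a lower-W bin adjacent to
    both its path neighbours (deterministic lexicographic tie-break)."""
    def adjacent(a, b):
        return max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1

    out = list(path)
    for idx in range(1, len(out) - 1):
        a, b, c = out[idx - 1], out[idx], out[idx + 1]
        best = b
        best_w = values[b]
        for di, dj in _NEIGHBORS:
            cand = (b[0] + di, b[1] + dj)
            if not (0 <= cand[0] < values.shape[0] and 0 <= cand[1] < values.shape[1]):
                continue
            if not covered[cand] or cand in (a, c):
                continue
            if adjacent(cand, a) and adjacent(cand, c):
                w = values[cand]
                if w < best_w - 1e-12 or (abs(w - best_w) <= 1e-12 and cand < best):
                    best, best_w = cand, w
        out[idx] = best
    # collapse accidental duplicates
    dedup = [out[0]]
    for node in out[1:]:
        if node != dedup[-1]:
            dedup.append(node)
    return dedup


def _perpendicular_profile(grid: PMFGrid, path, halfwidth: int) -> np.ndarray:
    kT = kt(grid.temperature)
    xs, ys = grid.axes
    dx = xs[1] - xs[0] if xs.size > 1 else 1.0
    dy = ys[1] - ys[0] if ys.size > 1 else 1.0
    step = min(dx, dy)
    interp = RegularGridInterpolator(
        (xs, ys), grid.values, method="linear", bounds_error=False, fill_value=np.nan
    )
    pts = np.array([[xs[i], ys[j]] for i, j in path])
    n = len(pts)
    profile = np.empty(n)
    offsets = step * np.arange(-halfwidth, halfwidth + 1)
    for idx in range(n):
        lo = max(idx - 1, 0)
        hi = min(idx + 1, n - 1)
        tangent = pts[hi] - pts[lo]
        norm = np.linalg.norm(tangent)
        if norm < 1e-12:
            tangent = np.array([1.0, 0.0])
            norm = 1.0
        tangent /= norm
        perp = np.array([-tangent[1], tangent[0]])
        samples = pts[idx][None, :] + offsets[:, None] * perp[None, :]
        w = interp(samples)
        w = w[np.isfinite(w)]
        if w.size == 0:
            profile[idx] = grid.values[path[idx]]
        else:
            # mean, not sum: keeps the profile insensitive to how many
            # perpendicular points fall inside the grid near edges
            profile[idx] = -kT * logsumexp(-w / kT - math.log(w.size))
    return profile - profile.min()


# ---------------------------------------------------------------------------
# Stationary-point profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationaryPoint:
    """A labeled stationary state on the free-energy profile."""

    label: str
    value: float  # kcal·mol⁻¹ relative to the profile reference
    kind: str = "minimum"  # "minimum" | "saddle"

    def __post_init__(self):
        if self.kind not in ("minimum", "saddle"):
            raise ValueError(f"kind must be minimum or saddle, got {self.kind!r}")


@dataclass
class FreeEnergyProfile:
    """Ordered stationary points, alternating minima and saddles, with one
    reference state at W = 0."""

    points: list[StationaryPoint]
    reference: str

    def __post_init__(self):
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate state labels in profile")
        if self.reference not in labels:
            raise ValueError(f"reference state {self.reference!r} not in profile")
        for i, p in enumerate(self.points):
            expected = "minimum" if i % 2 == 0 else "saddle"
            if p.kind != expected:
                raise ValueError(
                    f"profile must alternate minimum/saddle starting from a "
                    f"minimum; state {p.label!r} at position {i} is {p.kind}"
                )
        for i, p in enumerate(self.points):
            if p.kind == "saddle":
                left = self.points[i - 1].value
                right = self.points[i + 1].value if i + 1 < len(self.points) else -np.inf
                if p.value < max(left, right) - 1e-9:
                    raise ValueError(
                        f"saddle {p.label!r} lies below a neighbouring minimum"
                    )

    def __getitem__(self, label: str) -> StationaryPoint:
        for p in self.points:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]


def assemble_profile(segments, reference: str | None = None) -> FreeEnergyProfile:
    """Stitch consecutive profile segments into one labeled profile.

    Each segment is an ordered sequence of ``(label, value)`` pairs starting
    and ending on minima; consecutive segments must share their junction
    state with matching value (within 1e-9).  The stitched profile is
    re-referenced so the first minimum (or ``reference``) sits at 0.
    """
    norm_segments = []
    for seg in segments:
        if isinstance(seg, FreeEnergyProfile):
            seg = [(p.label, p.value) for p in seg.points]
        elif isinstance(seg, dict):
            seg = list(seg.items())
        seg = [(str(l), float(v)) for l, v in seg]
        if len(seg) < 1:
            raise ValueError("empty profile segment")
        norm_segments.append(seg)
    merged = list(norm_segments[0])
    for seg in norm_segments[1:]:
        last_label, last_value = merged[-1]
        first_label, first_value = seg[0]
        if last_label != first_label:
            raise ValueError(
                f"segment junction mismatch: {last_label!r} vs {first_label!r}"
            )
        if abs(last_value - first_value) > 1e-9:
            raise ValueError(
                f"junction value mismatch at {last_label!r}: "
                f"{last_value!r} vs {first_value!r}"
            )
        merged.extend(seg[1:])
    ref_label = reference if reference is not None else merged[0][0]
    ref_value = dict(merged)[ref_label]
    points = [
        StationaryPoint(label=l, value=v - ref_value,
                        kind="minimum" if i % 2 == 0 else "saddle")
        for i, (l, v) in enumerate(merged)
    ]
    return FreeEnergyProfile(points=points, reference=ref_label)


def write_path_tsv(path, grid: PMFGrid, bins, profile) -> None:
    """Write a traced path as TSV: bin indices, coordinates, W along path."""
    from pathlib import Path as _Path

    lines = ["# pmfkit-path v1", "# columns: i\tj\txi1\txi2\tW"]
    for (i, j), w in zip(bins, profile):
        lines.append(
            f"{i}\t{j}\t{grid.axes[0][i]:.10g}\t{grid.axes[1][j]:.10g}\t{w:.10g}"
        )
    _Path(path).write_text("\n".join(lines) + "\n")


def barrier_query(profile: FreeEnergyProfile, from_state: str, to_state: str) -> float:
    """ΔG from ``from_state`` to ``to_state``: the highest intervening saddle
    minus W(from_state).  Zero when the states coincide."""
    labels = profile.labels
    try:
        i = labels.index(from_state)
        j = labels.index(to_state)
    except ValueError as exc:
        raise KeyError(f"unknown state: {exc}") from None
    if i == j:
        return 0.0
    lo, hi = sorted((i, j))
    saddles = [p.value for p in profile.points[lo + 1:hi] if p.kind == "saddle"]
    if not saddles:
        raise ValueError(
            f"no saddle separates {from_state!r} and {to_state!r}"
        )
    return float(max(saddles) - profile[from_state].value)
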