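"""Analytic stand-ins for the QM/MM engine.

Free-energy machinery is tested against energy models whose PMFs and barrier
heights are known in closed form.  The module provides

* 1D/2D analytic surfaces (harmonic, quartic double well, separable and
  coupled 2D forms) exposing ``energy`` and ``gradient``,
* low-level/high-level surface pairs with a closed-form difference, mirroring
  the dual-level single-point correction scheme,
* small molecular fixtures with prescribed nucleophilic-attack or
  hydrogen-bond geometry plus point charges and Lennard-Jones parameters, the
  exact inverses of the descriptor measurements in :mod:`pmfkit.geometry`,
* Boltzmann inversion of an analytic surface on a dense grid — the reference
  PMF that umbrella sampling + WHAM must reproduce.

Everything is gas phase: plain point sets, no periodic boundary conditions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .io import Atom, CoordinateFrame

__all__ = [
    "AnalyticSurface",
    "Harmonic",
    "DoubleWell",
    "Separable2D",
    "Coupled2D",
    "LLHLPair",
    "MolecularFixture",
    "make_double_well",
    "make_harmonic",
    "make_separable_2d",
    "make_coupled_2d",
    "make_llhl_pair",
    "make_attack_fixture",
    "make_hbond_fixture",
    "boltzmann_pmf",
    "write_fixture",
    "read_fixture_params",
]


class AnalyticSurface:
    """Energy model contract: ``energy``/``gradient`` at Å coordinates,
    energies in kcal·mol⁻¹.  Implementations accept arrays of shape
    ``(..., dim)`` (or scalars in 1D) and broadcast."""

    dim: int = 1
    form: str = "abstract"
    parameters: dict[str, float] = {}

    def energy(self, x):
        raise NotImplementedError

    def gradient(self, x):
        raise NotImplementedError

    def __add__(self, other: "AnalyticSurface") -> "AnalyticSurface":
        return _Sum(self, other)


class _Sum(AnalyticSurface):
    def __init__(self, a: AnalyticSurface, b: AnalyticSurface):
        if a.dim != b.dim:
            raise ValueError("cannot add surfaces of different dimensionality")
        self.a, self.b = a, b
        self.dim = a.dim
        self.form = f"{a.form}+{b.form}"
        self.parameters = {**a.parameters, **b.parameters}

    def energy(self, x):
        return self.a.energy(x) + self.b.energy(x)

    def gradient(self, x):
        return self.a.gradient(x) + self.b.gradient(x)


@dataclass
class Harmonic(AnalyticSurface):
    """V(x) = ½ κ (x − x₀)²."""

    kappa: float
    x0: float = 0.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        self.dim = 1
        self.form = "harmonic"
        self.parameters = {"kappa": self.kappa, "x0": self.x0}

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.kappa * (x - self.x0) ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return self.kappa * (x - self.x0)


@dataclass
class DoubleWell(AnalyticSurface):
    """Quartic double well V(x) = h·((x/b)² − 1)².

    Minima at ±b with V = 0, central barrier V(0) = h kcal·mol⁻¹.
    """

    h: float
    b: float

    def __post_init__(self):
        if self.h <= 0 or self.b <= 0:
            raise ValueError("barrier height h and well separation b must be positive")
        self.dim = 1
        self.form = "double_well"
        self.parameters = {"h": self.h, "b": self.b}

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.h * ((x / self.b) ** 2 - 1.0) ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        u = (x / self.b) ** 2 - 1.0
        return 4.0 * self.h * u * x / self.b**2


@dataclass
class Separable2D(AnalyticSurface):
    """V(x, y) = Vx(x) + Vy(y); the PMF along either axis is the 1D form."""

    vx: AnalyticSurface
    vy: AnalyticSurface

    def __post_init__(self):
        if self.vx.dim != 1 or self.vy.dim != 1:
            raise ValueError("component surfaces must be 1D")
        self.dim = 2
        self.form = "separable_2d"
        self.parameters = {
            **{f"x_{k}": v for k, v in self.vx.parameters.items()},
            **{f"y_{k}": v for k, v in self.vy.parameters.items()},
        }

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.vx.energy(x[..., 0]) + self.vy.energy(x[..., 1])

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return np.stack(
            [self.vx.gradient(x[..., 0]), self.vy.gradient(x[..., 1])], axis=-1
        )


@dataclass
class Coupled2D(AnalyticSurface):
    """Two 1D surfaces coupled bilinearly: V(x,y) = Vx(x) + Vy(y) + c·x·y.

    The origin is a stationary point whenever both component surfaces are
    stationary there; pairing a double well in x with a harmonic restoring
    term in y gives a single reaction channel whose index-1 saddle sits
    exactly at the origin by the (x,y) → (−x,−y) symmetry.
    """

    vx: AnalyticSurface
    vy: AnalyticSurface
    c: float = 0.0

    def __post_init__(self):
        self.dim = 2
        self.form = "coupled_2d"
        self.parameters = {"c": self.c}

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return (
            self.vx.energy(x[..., 0])
            + self.vy.energy(x[..., 1])
            + self.c * x[..., 0] * x[..., 1]
        )

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        gx = self.vx.gradient(x[..., 0]) + self.c * x[..., 1]
        gy = self.vy.gradient(x[..., 1]) + self.c * x[..., 0]
        return np.stack([gx, gy], axis=-1)


@dataclass
class LLHLPair:
    """A low-level/high-level surface pair with closed-form difference,
    the analytic analogue of semiempirical vs DFT single points."""

    low: AnalyticSurface
    high: AnalyticSurface

    def __post_init__(self):
        if self.low.dim != self.high.dim:
            raise ValueError("LL and HL surfaces must share dimensionality")

    @property
    def dim(self) -> int:
        return self.low.dim

    def delta(self, x):
        """ΔE(ξ) = E_HL(ξ) − E_LL(ξ)."""
        return self.high.energy(x) - self.low.energy(x)


def make_harmonic(kappa: float, x0: float = 0.0) -> Harmonic:
    return Harmonic(kappa=kappa, x0=x0)


def make_double_well(h: float, b: float) -> DoubleWell:
    """Quartic double well with barrier ``h`` (kcal·mol⁻¹) and minima at ±``b`` (Å)."""
    return DoubleWell(h=h, b=b)


def make_separable_2d(vx: AnalyticSurface, vy: AnalyticSurface) -> Separable2D:
    return Separable2D(vx=vx, vy=vy)


def make_coupled_2d(vx: AnalyticSurface, vy: AnalyticSurface, c: float) -> Coupled2D:
    return Coupled2D(vx=vx, vy=vy, c=c)


def make_llhl_pair(low: AnalyticSurface, high: AnalyticSurface) -> LLHLPair:
    return LLHLPair(low=low, high=high)


def boltzmann_pmf(
    surface: AnalyticSurface,
    bin_centers: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    oversample: int = 32,
):
    """Reference PMF by direct Boltzmann inversion on a dense grid.

    Integrates exp(−V/kT) within each bin (``oversample`` quadrature points
    per bin per axis) and returns W = −kT·ln p, min-referenced.  For 1D pass
    bin centers as an array; for 2D pass a tuple (x_centers, y_centers) and
    get a 2D array back.  This is an exhaustive-integration oracle that never
    touches the sampling/WHAM code path.
    """
    kT = kt(temperature)

    def _edges(centers):
        centers = np.asarray(centers, dtype=float)
        width = centers[1] - centers[0]
        return np.concatenate([centers - width / 2, [centers[-1] + width / 2]])

    if surface.dim == 1:
        edges = _edges(bin_centers)
        p = np.empty(len(edges) - 1)
        for i in range(len(p)):
            xs = np.linspace(edges[i], edges[i + 1], oversample)
            p[i] = np.trapezoid(np.exp(-surface.energy(xs) / kT), xs)
        w = -kT * np.log(p)
        return w - w.min()
    xc, yc = bin_centers
    ex, ey = _edges(xc), _edges(yc)
    p = np.empty((len(xc), len(yc)))
    for i in range(len(xc)):
        xs = np.linspace(ex[i], ex[i + 1], oversample)
        for j in range(len(yc)):
            ys = np.linspace(ey[j], ey[j + 1], oversample)
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            pts = np.stack([gx, gy], axis=-1)
            integ = np.trapezoid(np.exp(-surface.energy(pts) / kT), ys, axis=1)
            p[i, j] = np.trapezoid(integ, xs)
    w = -kT * np.log(p)
    return w - w.min()


# ---------------------------------------------------------------------------
# Molecular fixtures
# ---------------------------------------------------------------------------

@dataclass
class MolecularFixture:
    """A small point-set molecule with per-atom nonbonded parameters and
    named roles (nucleophile, electrophilic carbon, donors, …)."""

    frame: CoordinateFrame
    charges: np.ndarray           # e
    lj_epsilon: np.ndarray        # kcal·mol⁻¹
    lj_rmin_half: np.ndarray      # Å
    roles: dict[str, int] = field(default_factory=dict)
    total_charge: float = 0.0

    def __post_init__(self):
        n = len(self.frame)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, dtype=float)
        for arr, label in [(self.charges, "charges"),
                           (self.lj_epsilon, "lj_epsilon"),
                           (self.lj_rmin_half, "lj_rmin_half")]:
            if arr.shape != (n,):
                raise ValueError(f"{label} must have one entry per atom")
        for role, idx in self.roles.items():
            if not 0 <= idx < n:
                raise ValueError(f"role {role!r} maps to missing atom index {idx}")
        if abs(self.charges.sum() - self.total_charge) > 1e-9:
            raise ValueError(
                f"charges sum to {self.charges.sum():.12g}, declared "
                f"{self.total_charge:.12g}"
            )


def _atom(i: int, name: str, element: str, res: str = "FIX", resseq: int = 1) -> Atom:
    return Atom(serial=i + 1, name=name, element=element, res_name=res,
                res_seq=resseq, chain_id="A", het=True)


def make_attack_fixture(
    d_nu: float, alpha_bd: float, alpha_fl: float, seed: int = 0
) -> MolecularFixture:
    """Six-atom sp²-center fixture realising a prescribed nucleophilic-attack
    geometry.

    The carbonyl carbon sits at the origin with O along +x (1.22 Å) and two
    substituents trigonally in the xy-plane; the nucleophile is placed at
    distance ``d_nu`` so that the measured Bürgi–Dunitz angle equals
    ``alpha_bd`` and the Flippin–Lodge azimuth equals ``alpha_fl`` (signed,
    positive toward the first substituent).  A spectator hydrogen is placed
    at a random but seeded position well away from the reactive center.

    Raises ``ValueError`` for geometrically unreachable combinations
    (|sin α_FL| > sin α_BD: the azimuthal offset cannot exceed the total
    off-axis tilt).
    """
    if d_nu <= 0:
        raise ValueError("nucleophile distance must be positive")
    if not 0.0 <= alpha_bd <= 180.0:
        raise ValueError("alpha_bd must lie in [0, 180] degrees")
    if not -90.0 <= alpha_fl <= 90.0:
        raise ValueError("alpha_fl must lie in [-90, 90] degrees")
    bd = math.radians(alpha_bd)
    fl = math.radians(alpha_fl)
    if abs(math.sin(fl)) > math.sin(bd) + 1e-12:
        raise ValueError(
            f"unreachable geometry: |sin(alpha_fl)| = {abs(math.sin(fl)):.6f} "
            f"exceeds sin(alpha_bd) = {math.sin(bd):.6f}"
        )

    c = np.zeros(3)
    o = np.array([1.22, 0.0, 0.0])
    sub1 = 1.50 * np.array([math.cos(math.radians(120)), math.sin(math.radians(120)), 0.0])
    sub2 = 1.50 * np.array([math.cos(math.radians(-120)), math.sin(math.radians(-120)), 0.0])

    # Frame used by the measurement: u = C→O axis, n = plane normal oriented
    # so that w = u × n points toward sub1 (+y here), giving the sign
    # convention "alpha_fl positive toward sub1".
    u = np.array([1.0, 0.0, 0.0])
    n = np.array([0.0, 0.0, -1.0])  # unit cross(sub2−o, sub1−o)
    w = np.cross(u, n)              # +y

    b = math.sin(fl)
    a = math.sqrt(max(math.sin(bd) ** 2 - b**2, 0.0))
    v = math.cos(bd) * u + a * n + b * w
    nu = c + d_nu * v

    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    spectator = c + np.array([0.0, 0.0, 6.0]) + 1.5 * direction

    atoms = [
        _atom(0, "C1", "C"),
        _atom(1, "O1", "O"),
        _atom(2, "C2", "C"),
        _atom(3, "C3", "C"),
        _atom(4, "OG", "O", res="NUC", resseq=2),
        _atom(5, "HS", "H", res="SPC", resseq=3),
    ]
    coords = np.array([c, o, sub1, sub2, nu, spectator])
    charges = np.array([0.0, -0.45, -0.1, -0.1, -0.4, 0.413])
    charges[0] = -charges[1:].sum()  # neutral fixture by construction
    return MolecularFixture(
        frame=CoordinateFrame(atoms, coords),
        charges=charges,
        lj_epsilon=np.array([0.086, 0.21, 0.086, 0.086, 0.21, 0.015]),
        lj_rmin_half=np.array([1.908, 1.661, 1.908, 1.908, 1.721, 0.6]),
        roles={
            "electrophile": 0,
            "carbonyl_oxygen": 1,
            "substituent1": 2,
            "substituent2": 3,
            "nucleophile": 4,
            "spectator": 5,
        },
        total_charge=0.0,
    )


def make_hbond_fixture(
    d_da: float, theta_dha: float, r_dh: float = 1.0
) -> MolecularFixture:
    """Donor–hydrogen–acceptor triad with prescribed D···A distance and
    D-H···A angle.

    The donor sits at the origin, H on the +x axis at the covalent D–H
    length ``r_dh``; the acceptor position follows from the triangle with
    angle ``theta_dha`` at the hydrogen.  Combinations that admit no real
    acceptor position (d_da < r_dh·sin θ, or an acceptor on the wrong side
    of the hydrogen) are rejected.
    """
    if d_da <= 0:
        raise ValueError("donor-acceptor distance must be positive")
    if not 0.0 < theta_dha <= 180.0:
        raise ValueError("theta_dha must lie in (0, 180] degrees")
    if not 0.7 <= r_dh <= 1.3:
        raise ValueError(f"covalent D-H length {r_dh} outside [0.7, 1.3] Å")
    theta = math.radians(theta_dha)
    disc = d_da**2 - (r_dh * math.sin(theta)) ** 2
    if disc < 0:
        raise ValueError(
            f"no acceptor position: d_da = {d_da} < r_dh·sin(theta) = "
            f"{r_dh * math.sin(theta):.4f}"
        )
    ha = r_dh * math.cos(theta) + math.sqrt(disc)
    if ha <= 0:
        raise ValueError("acceptor would coincide with or pass the hydrogen")

    d = np.zeros(3)
    h = np.array([r_dh, 0.0, 0.0])
    # H→D is −x; H→A makes angle theta with it.
    direction = np.array([-math.cos(theta), math.sin(theta), 0.0])
    a = h + ha * direction

    atoms = [
        _atom(0, "N1", "N", res="DON", resseq=1),
        _atom(1, "H1", "H", res="DON", resseq=1),
        _atom(2, "O1", "O", res="ACC", resseq=2),
    ]
    charges = np.array([-0.7, 0.4, 0.3])
    return MolecularFixture(
        frame=CoordinateFrame(atoms, np.array([d, h, a])),
        charges=charges,
        lj_epsilon=np.array([0.17, 0.015, 0.21]),
        lj_rmin_half=np.array([1.824, 0.6, 1.661]),
        roles={"donor": 0, "hydrogen": 1, "acceptor": 2},
        total_charge=0.0,
    )


# ---------------------------------------------------------------------------
# Fixture persistence: PDB/XYZ via pmfkit.io plus a parameter sidecar
# ---------------------------------------------------------------------------

def write_fixture(path_prefix: str | Path, fixture: MolecularFixture) -> None:
    """Write ``<prefix>.pdb`` and a ``<prefix>.params`` sidecar
    (serial, charge, epsilon, rmin/2, role)."""
    from .io import write_pdb

    prefix = Path(path_prefix)
    write_pdb(prefix.with_suffix(".pdb"), fixture.frame)
    inverse_roles = {v: k for k, v in fixture.roles.items()}
    lines = [
        "# pmfkit-fixture-params v1",
        f"# total_charge= {fixture.total_charge:.10g}",
        "# columns: serial\tcharge\tepsilon\trmin_half\trole",
    ]
    for i, atom in enumerate(fixture.frame.atoms):
        role = inverse_roles.get(i, "-")
        lines.append(
            f"{atom.serial}\t{fixture.charges[i]:.10g}\t"
            f"{fixture.lj_epsilon[i]:.10g}\t{fixture.lj_rmin_half[i]:.10g}\t{role}"
        )
    prefix.with_suffix(".params").write_text("\n".join(lines) + "\n")


def read_fixture_params(path: str | Path):
    """Read a parameter sidecar; returns (charges, eps, rmin_half, roles, total)."""
    charges, eps, rmin, roles = [], [], [], {}
    total = 0.0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "total_charge=" in line:
                total = float(line.split("total_charge=")[1])
            continue
        serial, q, e, r, role = line.split("\t")
        idx = len(charges)
        charges.append(float(q))
        eps.append(float(e))
        rmin.append(float(r))
        if role != "-":
            roles[role] = idx
    return (np.array(charges), np.array(eps), np.array(rmin), roles, total)
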