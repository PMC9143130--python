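"""Coordinate containers and text file formats.

Houses the :class:`CoordinateFrame` container used by every structural module,
plus readers/writers for the plain-text interchange formats of the pipeline:

* PDB (wwPDB 3.3 fixed columns, ATOM/HETATM, single or multi-MODEL),
* multi-frame XYZ,
* umbrella-window sample files (``# center=…`` headers + one ξ per line),
* PMF grids, free-energy profiles and dual-level correction tables as TSV,
* a YAML run configuration with the pipeline's default parameters.

All formats carry ``#``-prefixed headers with a schema tag so stages can be
composed from a shell; results never go to stdout.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .constants import DEFAULT_FORCE_CONSTANT_KJ, DEFAULT_TEMPERATURE

__all__ = [
    "Atom",
    "CoordinateFrame",
    "Trajectory",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "read_xyz_traj",
    "write_xyz_traj",
    "write_window",
    "read_window",
    "write_pmf_tsv",
    "read_pmf_tsv",
    "write_profile_tsv",
    "read_profile_tsv",
    "read_correction_tsv",
    "write_correction_tsv",
    "RunConfig",
]

# Elements whose two-character symbol must be recognised when inferring from
# atom names (right-justified PDB names can be ambiguous).
_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "CU", "SE", "K", "LI",
}


@dataclass(frozen=True)
class Atom:
    """One atom record: identity only, coordinates live on the frame."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str = "A"
    het: bool = False


@dataclass
class CoordinateFrame:
    """A set of atoms with Cartesian coordinates in Å.

    Invariant: (chain_id, res_seq, name) triples are unique and coordinates
    are finite.  Enforced at construction.
    """

    atoms: list[Atom]
    coords: np.ndarray
    time: float | None = None  # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        triples = [(a.chain_id, a.res_seq, a.name) for a in self.atoms]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (chain, residue, atom name) triple")

    def __len__(self) -> int:
        return len(self.atoms)

    def index_of(self, chain_id: str, res_seq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if (a.chain_id, a.res_seq, a.name) == (chain_id, res_seq, name):
                return i
        raise KeyError(f"no atom {chain_id}/{res_seq}/{name}")

    def select(self, selection: str) -> np.ndarray:
        """Resolve a selection string to atom indices.

        Grammar (whitespace separated clauses, all must match):
        ``chain X``, ``resid N`` or ``resid N-M``, ``resname XXX``,
        ``name CA``, ``element C``, ``heavy`` (element != H), ``all``.
        """
        mask = np.ones(len(self.atoms), dtype=bool)
        tokens = selection.split()
        i = 0
        while i < len(tokens):
            key = tokens[i].lower()
            if key == "all":
                i += 1
                continue
            if key == "heavy":
                mask &= np.array([a.element.upper() != "H" for a in self.atoms])
                i += 1
                continue
            if i + 1 >= len(tokens):
                raise ValueError(f"selection clause {key!r} missing argument")
            val = tokens[i + 1]
            if key == "chain":
                mask &= np.array([a.chain_id == val for a in self.atoms])
            elif key == "resid":
                if "-" in val and not val.startswith("-"):
                    lo, hi = (int(v) for v in val.split("-", 1))
                    mask &= np.array([lo <= a.res_seq <= hi for a in self.atoms])
                else:
                    mask &= np.array([a.res_seq == int(val) for a in self.atoms])
            elif key == "resname":
                mask &= np.array([a.res_name == val for a in self.atoms])
            elif key == "name":
                mask &= np.array([a.name == val for a in self.atoms])
            elif key == "element":
                mask &= np.array(
                    [a.element.upper() == val.upper() for a in self.atoms]
                )
            else:
                raise ValueError(f"unknown selection keyword {key!r}")
            i += 2
        return np.nonzero(mask)[0]

    def translated(self, shift: Sequence[float]) -> "CoordinateFrame":
        return CoordinateFrame(self.atoms, self.coords + np.asarray(shift), self.time)

    def rotated(self, rotation: np.ndarray) -> "CoordinateFrame":
        return CoordinateFrame(self.atoms, self.coords @ np.asarray(rotation).T, self.time)


@dataclass
class Trajectory:
    """Ordered frames sharing one atom table."""

    frames: list[CoordinateFrame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        n = len(self.frames[0])
        if any(len(f) != n for f in self.frames):
            raise ValueError("frames have inconsistent atom counts")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def atoms(self) -> list[Atom]:
        return self.frames[0].atoms


class PDBFormatError(ValueError):
    """Malformed PDB content; message carries the 1-based line number."""


def _infer_element(name: str, line_no: int) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise PDBFormatError(f"line {line_no}: cannot infer element from name {name!r}")
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS:
        elem = stripped[0].upper() + stripped[1].lower()
    else:
        elem = stripped[0].upper()
    warnings.warn(
        f"line {line_no}: element column empty, inferred {elem!r} from atom "
        f"name {name!r}",
        stacklevel=3,
    )
    return elem


def _parse_atom_line(line: str, line_no: int) -> tuple[Atom, tuple[float, float, float]]:
    if len(line) < 54:
        raise PDBFormatError(f"line {line_no}: ATOM/HETATM record too short")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        icode = line[26:27]
        res_name = line[17:20].strip()
        chain_id = line[21:22].strip() or "A"
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBFormatError(f"line {line_no}: malformed ATOM record ({exc})") from None
    if icode.strip():
        raise PDBFormatError(f"line {line_no}: insertion codes are unsupported")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name, line_no)
    else:
        element = element[0].upper() + element[1:].lower()
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        het=line.startswith("HETATM"),
    )
    return atom, (x, y, z)


def read_pdb(path: str | Path) -> CoordinateFrame | list[CoordinateFrame]:
    """Read a PDB file; multi-MODEL files return a list of frames."""
    text = Path(path).read_text()
    if not text.strip():
        raise PDBFormatError(f"{path}: empty file")
    models: list[tuple[list[Atom], list[tuple[float, float, float]]]] = []
    atoms: list[Atom] = []
    xyz: list[tuple[float, float, float]] = []
    saw_model = False
    for line_no, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            if atoms:
                models.append((atoms, xyz))
                atoms, xyz = [], []
        elif rec == "ENDMDL":
            if atoms:
                models.append((atoms, xyz))
                atoms, xyz = [], []
        elif rec in ("ATOM", "HETATM"):
            a, r = _parse_atom_line(line, line_no)
            atoms.append(a)
            xyz.append(r)
    if atoms:
        models.append((atoms, xyz))
    if not models:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records")
    frames = [CoordinateFrame(a, np.array(r)) for a, r in models]
    if saw_model and len(frames) > 1:
        return frames
    return frames[0] if len(frames) == 1 else frames


def _format_atom_line(atom: Atom, pos: np.ndarray) -> str:
    rec = "HETATM" if atom.het else "ATOM  "
    name = atom.name
    # wwPDB: names of <4 chars start in column 14 unless a 2-char element.
    if len(name) < 4 and len(atom.element) < 2:
        name = f" {name}"
    return (
        f"{rec}{atom.serial:>5d} {name:<4s} {atom.res_name:<3s} "
        f"{atom.chain_id:1s}{atom.res_seq:>4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(path: str | Path, frames: CoordinateFrame | Iterable[CoordinateFrame]) -> None:
    """Write one or more frames; several frames become MODEL/ENDMDL blocks."""
    if isinstance(frames, CoordinateFrame):
        frames = [frames]
    frames = list(frames)
    lines: list[str] = []
    multi = len(frames) > 1
    for i, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4d}")
        for atom, pos in zip(frame.atoms, frame.coords):
            lines.append(_format_atom_line(atom, pos))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_traj(path: str | Path, template: CoordinateFrame | None = None) -> Trajectory:
    """Read a multi-frame XYZ file.

    XYZ carries only element symbols; residue/chain metadata comes from
    ``template`` when given, otherwise synthetic per-atom residues are used.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[CoordinateFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path} line {i+1}: expected atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        time = None
        if "time=" in comment:
            time = float(comment.split("time=")[1].split()[0])
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame at line {i+1}")
        elements, xyz = [], []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise ValueError(f"{path} line {i+3+j}: malformed XYZ row")
            elements.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        if template is not None:
            if len(template) != n:
                raise ValueError("template atom count mismatch")
            atoms = template.atoms
        else:
            atoms = [
                Atom(serial=j + 1, name=f"{el}{j+1}", element=el,
                     res_name="UNK", res_seq=j + 1)
                for j, el in enumerate(elements)
            ]
        frames.append(CoordinateFrame(atoms, np.array(xyz), time=time))
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames")
    return Trajectory(frames)


def write_xyz_traj(path: str | Path, traj: Trajectory | CoordinateFrame) -> None:
    if isinstance(traj, CoordinateFrame):
        traj = Trajectory([traj])
    lines: list[str] = []
    for frame in traj:
        lines.append(str(len(frame)))
        lines.append("" if frame.time is None else f"time={frame.time}")
        for atom, pos in zip(frame.atoms, frame.coords):
            lines.append(
                f"{atom.element:<2s} {pos[0]:14.8f} {pos[1]:14.8f} {pos[2]:14.8f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Window sample files
# ---------------------------------------------------------------------------

def write_window(path: str | Path, center, force_constant, temperature: float,
                 samples: np.ndarray) -> None:
    """Write one umbrella window as a headed text file.

    ``center``/``force_constant`` are scalars for 1D windows or length-2
    sequences for 2D windows; samples follow, one per line (two columns in 2D).
    """
    center = np.atleast_1d(np.asarray(center, dtype=float))
    k = np.atleast_1d(np.asarray(force_constant, dtype=float))
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    header = [
        "# pmfkit-window v1",
        "# center= " + " ".join(f"{c:.10g}" for c in center),
        "# k= " + " ".join(f"{v:.10g}" for v in k),
        f"# T= {temperature:.10g}",
    ]
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in samples)
    Path(path).write_text("\n".join(header) + "\n" + body + "\n")


def read_window(path: str | Path):
    """Read a window file; returns (center, k, temperature, samples)."""
    center = k = temperature = None
    rows: list[list[float]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("center="):
                center = np.array([float(v) for v in body[7:].split()])
            elif body.startswith("k="):
                k = np.array([float(v) for v in body[2:].split()])
            elif body.startswith("T="):
                temperature = float(body[2:])
            continue
        rows.append([float(v) for v in line.split()])
    if center is None or k is None or temperature is None:
        raise ValueError(f"{path}: missing center/k/T header")
    samples = np.array(rows)
    if samples.size == 0:
        raise ValueError(f"{path}: window has no samples")
    if samples.shape[1] == 1:
        samples = samples[:, 0]
    return center, k, temperature, samples


# ---------------------------------------------------------------------------
# PMF / profile / correction TSV
# ---------------------------------------------------------------------------

def write_pmf_tsv(path: str | Path, pmf) -> None:
    """Write a PMFGrid (1D or 2D) as TSV with `#` headers."""
    lines = [f"# pmfkit-pmf v1", f"# dim= {pmf.ndim}", f"# T= {pmf.temperature:.10g}"]
    if pmf.ndim == 1:
        lines.append("# columns: xi\tW\tcount")
        for x, w, c in zip(pmf.axes[0], pmf.values, pmf.counts):
            wtxt = "nan" if not np.isfinite(w) else f"{w:.10g}"
            lines.append(f"{x:.10g}\t{wtxt}\t{int(c)}")
    else:
        lines.append("# columns: xi1\txi2\tW\tcount")
        for i, x in enumerate(pmf.axes[0]):
            for j, y in enumerate(pmf.axes[1]):
                w = pmf.values[i, j]
                wtxt = "nan" if not np.isfinite(w) else f"{w:.10g}"
                lines.append(f"{x:.10g}\t{y:.10g}\t{wtxt}\t{int(pmf.counts[i, j])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pmf_tsv(path: str | Path):
    """Read a PMF TSV back into a PMFGrid."""
    from .wham import PMFGrid  # local import: io stays import-light

    dim = None
    temperature = DEFAULT_TEMPERATURE
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("dim="):
                dim = int(body[4:])
            elif body.startswith("T="):
                temperature = float(body[2:])
            continue
        rows.append([float(v) for v in line.split()])
    if dim is None or not rows:
        raise ValueError(f"{path}: not a pmfkit PMF file")
    data = np.array(rows)
    if dim == 1:
        return PMFGrid(
            axes=(data[:, 0],), values=data[:, 1], counts=data[:, 2].astype(int),
            temperature=temperature,
        )
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    values = np.full((xs.size, ys.size), np.nan)
    counts = np.zeros((xs.size, ys.size), dtype=int)
    xi = np.searchsorted(xs, data[:, 0])
    yi = np.searchsorted(ys, data[:, 1])
    values[xi, yi] = data[:, 2]
    counts[xi, yi] = data[:, 3].astype(int)
    return PMFGrid(axes=(xs, ys), values=values, counts=counts, temperature=temperature)


def write_profile_tsv(path: str | Path, profile) -> None:
    lines = ["# pmfkit-profile v1", "# columns: label\ttype\tdG"]
    for p in profile.points:
        lines.append(f"{p.label}\t{p.kind}\t{p.value:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_tsv(path: str | Path):
    from .wham import FreeEnergyProfile, StationaryPoint

    points = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, kind, val = line.split("\t")
        points.append(StationaryPoint(label=label, value=float(val), kind=kind))
    if not points:
        raise ValueError(f"{path}: empty profile")
    return FreeEnergyProfile(points=points, reference=points[0].label)


def write_correction_tsv(path: str | Path, nodes, delta) -> None:
    """Write correction nodes: 1D (xi, dE) or 2D (xi1, xi2, dE) rows."""
    lines = ["# pmfkit-correction v1"]
    if isinstance(nodes, tuple) and len(nodes) == 2:
        xs, ys = nodes
        delta = np.asarray(delta)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                lines.append(f"{x:.10g}\t{y:.10g}\t{delta[i, j]:.10g}")
    else:
        xs = np.asarray(nodes)
        for x, d in zip(xs, np.asarray(delta)):
            lines.append(f"{x:.10g}\t{d:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_correction_tsv(path: str | Path):
    """Read correction TSV; returns (nodes, delta).

    Accepts (xi, dE), (xi1, xi2, dE) and (xi1, xi2, E_LL, E_HL) layouts; the
    four-column form is differenced to ΔE = E_HL − E_LL on read.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(v) for v in line.split()])
    if not rows:
        raise ValueError(f"{path}: empty correction table")
    data = np.array(rows)
    if data.shape[1] == 2:
        return data[:, 0], data[:, 1]
    if data.shape[1] == 3:
        delta = data[:, 2]
    elif data.shape[1] == 4:
        delta = data[:, 3] - data[:, 2]
    else:
        raise ValueError(f"{path}: expected 2-4 columns, got {data.shape[1]}")
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    grid = np.full((xs.size, ys.size), np.nan)
    grid[np.searchsorted(xs, data[:, 0]), np.searchsorted(ys, data[:, 1])] = delta
    if np.isnan(grid).any():
        raise ValueError(f"{path}: correction nodes do not form a rectilinear grid")
    return (xs, ys), grid


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline defaults; every field can be overridden and the object
    round-trips losslessly through YAML."""

    temperature: float = DEFAULT_TEMPERATURE
    force_constant_kj: float = DEFAULT_FORCE_CONSTANT_KJ
    wham_tolerance: float = 1e-3
    wham_max_iter: int = 100_000
    grid_step_hydrogen: float = 0.05
    grid_step_heavy: float = 0.1
    hbond_distance_cutoff: float = 3.0
    hbond_angle_cutoff: float = 135.0
    switch_r_on: float = 14.5
    switch_r_off: float = 16.0
    equilibration_ps: float = 5.0
    production_ps: float = 20.0
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
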