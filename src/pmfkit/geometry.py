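"""Geometric descriptors of covalent-inhibition chemistry.

Implements the measurement side of the structural analyses used to
rationalise a free-energy profile: nucleophilic attack trajectory
(electrophile–nucleophile distance, Bürgi–Dunitz and Flippin–Lodge angles),
geometric hydrogen-bond detection with occupancies, Kabsch-superposed RMSD
series, signed ring-puckering dihedral series, series statistics, and
Eisenberg-consensus hydrophobicity mapping of binding-pocket residues.

Sign conventions: α_FL is signed, positive when the nucleophile deviates
toward the first substituent; reported experimental values are unsigned, so
comparisons should use |α_FL|.  H-bond thresholds are inclusive (≤ 3.0 Å,
≥ 135.0° at the defaults).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .coords import dihedral_angle
from .io import CoordinateFrame, Trajectory

__all__ = [
    "AttackGeometry",
    "HBondRecord",
    "SeriesStat",
    "attack_geometry",
    "detect_hbonds",
    "rmsd_series",
    "dihedral_series",
    "series_stats",
    "hydrophobicity_map",
    "EISENBERG_SCALE",
]

#: Eisenberg consensus (normalized) hydrophobicity scale, one value per
#: standard residue.
EISENBERG_SCALE: dict[str, float] = {
    "ALA": 0.62, "ARG": -2.53, "ASN": -0.78, "ASP": -0.90, "CYS": 0.29,
    "GLN": -0.85, "GLU": -0.74, "GLY": 0.48, "HIS": -0.40, "ILE": 1.38,
    "LEU": 1.06, "LYS": -1.50, "MET": 0.64, "PHE": 1.19, "PRO": 0.12,
    "SER": -0.18, "THR": -0.05, "TRP": 0.81, "TYR": 0.26, "VAL": 1.08,
}


@dataclass(frozen=True)
class AttackGeometry:
    """Nucleophilic attack descriptors: distance (Å), Bürgi–Dunitz angle
    (deg, in [0, 180]) and signed Flippin–Lodge angle (deg, in [−90, 90])."""

    d_nu_c: float
    alpha_bd: float
    alpha_fl: float

    def __post_init__(self):
        if not 0.0 <= self.alpha_bd <= 180.0:
            raise ValueError("alpha_bd outside [0, 180]")
        if not -90.0 <= self.alpha_fl <= 90.0:
            raise ValueError("alpha_fl outside [-90, 90]")


def attack_geometry(frame, nu: int, c: int, o: int, sub1: int, sub2: int) -> AttackGeometry:
    """Measure the attack trajectory of nucleophile ``nu`` onto the sp²
    carbon ``c`` bearing carbonyl oxygen ``o`` and substituents ``sub1``,
    ``sub2``.

    α_BD is the Nu···C=O angle.  α_FL = arcsin(v̂·ŵ) with v̂ the unit C→Nu
    vector, û the unit C→O vector, n̂ the unit normal of the carbonyl plane
    (o, sub1, sub2) oriented so that ŵ = û×n̂ points toward sub1; α_FL is
    therefore positive when the nucleophile tilts toward sub1.
    """
    x = frame.coords if isinstance(frame, CoordinateFrame) else np.asarray(frame, float)
    idx = (nu, c, o, sub1, sub2)
    if len(set(idx)) != 5:
        raise ValueError("nu, c, o, sub1, sub2 must be five distinct atoms")
    r_nu, r_c, r_o, r_1, r_2 = (x[i] for i in idx)

    v = r_nu - r_c
    u = r_o - r_c
    d = float(np.linalg.norm(v))
    if d < 1e-9 or np.linalg.norm(u) < 1e-9:
        raise ValueError("degenerate geometry at the electrophilic carbon")
    v_hat = v / d
    u_hat = u / np.linalg.norm(u)

    n = np.cross(r_2 - r_o, r_1 - r_o)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-9:
        raise ValueError("carbonyl plane undefined: o/sub1/sub2 collinear")
    n_hat = n / n_norm
    w = np.cross(u_hat, n_hat)
    w_norm = np.linalg.norm(w)
    if w_norm < 1e-9:
        raise ValueError("carbonyl plane normal parallel to the C=O axis")
    w_hat = w / w_norm

    alpha_bd = math.degrees(math.acos(np.clip(np.dot(v_hat, u_hat), -1.0, 1.0)))
    alpha_fl = math.degrees(math.asin(np.clip(np.dot(v_hat, w_hat), -1.0, 1.0)))
    return AttackGeometry(d_nu_c=d, alpha_bd=alpha_bd, alpha_fl=alpha_fl)


@dataclass(frozen=True)
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    d_da: float
    theta_dha: float
    frame: int


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    va = a - vertex
    vb = b - vertex
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("degenerate angle geometry")
    return math.degrees(math.acos(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)))


def detect_hbonds(
    traj,
    donors,
    acceptors,
    d_cut: float = 3.0,
    angle_cut: float = 135.0,
    dh_max: float = 1.3,
):
    """Geometric hydrogen-bond detection over a trajectory.

    For every frame and donor/acceptor pair, emits a record when the
    donor···acceptor distance is ≤ ``d_cut`` AND the donor-H···acceptor
    angle is ≥ ``angle_cut`` (both boundaries inclusive).  Hydrogens are
    located as H atoms within ``dh_max`` Å of the donor; donors with no
    attached hydrogen are skipped with a warning.  Returns
    ``(records, occupancy)`` with occupancy per (donor, acceptor) pair as
    the fraction of frames in which the bond is present.
    """
    if isinstance(traj, CoordinateFrame):
        traj = Trajectory([traj])
    atoms = traj.atoms
    donors = list(donors)
    acceptors = list(acceptors)

    donor_h: dict[int, list[int]] = {}
    x0 = traj[0].coords
    for d in donors:
        hs = [
            i for i, a in enumerate(atoms)
            if a.element.upper() == "H" and i != d
            and np.linalg.norm(x0[i] - x0[d]) <= dh_max
        ]
        if not hs:
            warnings.warn(f"donor atom {d} has no attached hydrogen; skipped",
                          stacklevel=2)
        else:
            donor_h[d] = hs

    records: list[HBondRecord] = []
    present: dict[tuple[int, int], int] = {
        (d, a): 0 for d in donor_h for a in acceptors if a != d
    }
    for fi, frame in enumerate(traj):
        x = frame.coords
        for d, hs in donor_h.items():
            for a in acceptors:
                if a == d or a in hs:
                    continue
                d_da = float(np.linalg.norm(x[d] - x[a]))
                # boundaries inclusive; 1e-9 guard absorbs float noise so a
                # geometry at exactly 3.0 Å / 135.0° is always detected
                if d_da > d_cut + 1e-9:
                    continue
                hit = None
                for h in hs:
                    theta = _angle_deg(x[d], x[h], x[a])
                    if theta >= angle_cut - 1e-9:
                        hit = (h, theta)
                        break
                if hit is not None:
                    records.append(HBondRecord(d, hit[0], a, d_da, hit[1], fi))
                    present[(d, a)] += 1
    occupancy = {pair: n / len(traj) for pair, n in present.items()}
    return records, occupancy


def rmsd_series(
    traj,
    ref_frame: CoordinateFrame,
    selection: str = "heavy",
    align_selection: str | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) of ``selection`` against a reference frame.

    With ``align_selection`` given, each frame is first rigid-body
    superposed (Kabsch) onto the reference using those atoms; without it
    the RMSD is measured in the laboratory frame.
    """
    if isinstance(traj, CoordinateFrame):
        traj = Trajectory([traj])
    sel = ref_frame.select(selection)
    if sel.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    ref_sel = ref_frame.coords[sel]
    out = np.empty(len(traj))
    align = None
    if align_selection is not None:
        align = ref_frame.select(align_selection)
        if align.size < 3:
            raise ValueError("alignment selection needs at least 3 atoms")
    for i, frame in enumerate(traj):
        if len(frame) != len(ref_frame):
            raise ValueError("frame/reference atom-count mismatch")
        coords = frame.coords
        if align is not None:
            mob = coords[align]
            ref = ref_frame.coords[align]
            mob_c = mob - mob.mean(axis=0)
            ref_c = ref - ref.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_c, mob_c)
            coords = rot.apply(coords - mob.mean(axis=0)) + ref.mean(axis=0)
        diff = coords[sel] - ref_sel
        out[i] = math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))
    return out


def dihedral_series(traj, a: int, b: int, c: int, d: int) -> np.ndarray:
    """Signed torsion (deg) per frame — the four-membered-ring puckering
    descriptor when the four atoms are the ring atoms; a sign change along a
    reaction step is a puckering inversion."""
    if isinstance(traj, CoordinateFrame):
        traj = Trajectory([traj])
    out = np.empty(len(traj))
    for i, frame in enumerate(traj):
        out[i] = dihedral_angle(frame.coords[a], frame.coords[b],
                                frame.coords[c], frame.coords[d])
    return out


@dataclass
class SeriesStat:
    mean: float
    sd: float
    bin_centers: np.ndarray
    counts: np.ndarray


def series_stats(series, bins: int = 50) -> SeriesStat:
    """Mean, sample SD (ddof=1; 0 for a single point) and histogram."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    counts, edges = np.histogram(series, bins=bins)
    sd = float(series.std(ddof=1)) if series.size > 1 else 0.0
    return SeriesStat(
        mean=float(series.mean()),
        sd=sd,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        counts=counts,
    )


def hydrophobicity_map(frame_or_residues, residues=None):
    """Per-residue Eisenberg consensus hydrophobicity.

    Accepts either a frame plus residue ids, or a plain list of residue
    names.  Returns a dict keyed by input residue; the pocket aggregate is
    the plain mean of its members.  Unknown residue names raise with the
    offending name listed.
    """
    if isinstance(frame_or_residues, CoordinateFrame):
        frame = frame_or_residues
        if residues is None:
            residues = sorted({(a.chain_id, a.res_seq) for a in frame.atoms})
        names = {}
        for chain, seq in residues:
            for a in frame.atoms:
                if (a.chain_id, a.res_seq) == (chain, seq):
                    names[(chain, seq)] = a.res_name
                    break
            else:
                raise KeyError(f"residue {chain}/{seq} not in frame")
        items = names.items()
    else:
        items = [(name, name) for name in frame_or_residues]
    out = {}
    for key, name in items:
        resname = name.upper()
        if resname not in EISENBERG_SCALE:
            raise ValueError(
                f"unknown residue name {name!r}; known: "
                + ", ".join(sorted(EISENBERG_SCALE))
            )
        out[key] = EISENBERG_SCALE[resname]
    return out


def pocket_hydrophobicity(residue_names) -> float:
    """Mean Eisenberg value over a pocket's member residues."""
    values = hydrophobicity_map(list(residue_names))
    return float(np.mean(list(values.values())))
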