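"""Trajectory geometry: RMSD/RMSF, B-factor conversion, hydrogen-bond
occupancy and mass-center distance series.

RMSDs are least-squares superposed (Kabsch); RMSFs are computed about
the mean structure after one superposition refinement pass and
averaged per residue over the selected backbone atoms.  Crystallographic
B-factors convert to fluctuations via RMSF = sqrt(3B/(8 pi^2)).
Hydrogen bonds are scored per frame by a donor-heavy-to-acceptor
distance cutoff and a donor-H-acceptor angle cutoff; occupancy is the
satisfied-frame fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molsys import AtomGroup, MolecularSystem, Trajectory, center_of_mass

__all__ = [
    "SuperpositionResult",
    "HBondRecord",
    "DistanceDefinition",
    "BFactorRecord",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "bfactor_to_rmsf",
    "rmsf_to_bfactor",
    "hbond_occupancy",
    "distance_series",
]

#: atoms defining the nucleotide backbone for RMSD/RMSF and backbone COMs
BACKBONE_ATOMS = ("P", "O3'", "O5'", "C3'", "C4'", "C5'")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False  # collinear/degenerate input -> translation-only fit


@dataclass
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    occupancy: float
    mean_distance: float  # A, over satisfying frames only
    mean_angle: float  # degrees, over satisfying frames only

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy outside [0, 1]")


@dataclass
class DistanceDefinition:
    """Labelled mass-center distance between two disjoint atom groups."""

    label: str
    group_a: AtomGroup
    group_b: AtomGroup

    def __post_init__(self) -> None:
        if len(self.group_a) == 0 or len(self.group_b) == 0:
            raise ValueError(f"distance {self.label}: empty group")
        if np.intersect1d(self.group_a.indices, self.group_b.indices).size:
            raise ValueError(f"distance {self.label}: groups overlap")


@dataclass
class BFactorRecord:
    author_resid: int
    b: float  # A^2

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("negative B-factor")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(ref: np.ndarray, mobile: np.ndarray, weights=None) -> SuperpositionResult:
    """Optimal least-squares superposition of ``mobile`` onto ``ref``.

    Returns the proper rotation (det = +1, enforced by sign correction
    on the smallest singular direction), translation and the residual
    RMSD.  Collinear or single-point inputs have no unique rotation;
    they are flagged and fit by translation only.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mobile must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 1:
        raise ValueError("at least one point required")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    ref_c = (w[:, None] * ref).sum(0)
    mob_c = (w[:, None] * mob).sum(0)
    a = ref - ref_c
    b = mob - mob_c
    cov = (w[:, None] * b).T @ a
    u, s, vt = np.linalg.svd(cov)
    rank2 = (s[1] > 1e-9 * max(s[0], 1e-300)) and n >= 3
    if not rank2:
        rot = np.eye(3)
        moved = b + ref_c
        rmsd = float(np.sqrt((w * ((moved - ref) ** 2).sum(1)).sum()))
        return SuperpositionResult(rot, ref_c - mob_c, rmsd, degenerate=True)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = b @ rot.T + ref_c
    rmsd = float(np.sqrt((w * ((moved - ref) ** 2).sum(1)).sum()))
    return SuperpositionResult(rot, ref_c - rot @ mob_c, rmsd, degenerate=False)


def apply_superposition(result: SuperpositionResult, coords: np.ndarray) -> np.ndarray:
    return coords @ result.rotation.T + result.translation


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------


def rmsd_series(
    trajectory: Trajectory,
    ref_frame: np.ndarray,
    selection: AtomGroup,
    bin_width: float = 0.1,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Superposed RMSD of each frame to a reference over a selection.

    Also returns a (bin_edges, counts) histogram of the series for
    distribution panels.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    idx = selection.indices
    ref = np.asarray(ref_frame, dtype=float)[idx]
    out = np.array(
        [kabsch_superpose(ref, frame[idx]).rmsd for frame in trajectory.frames]
    )
    lo = 0.0
    hi = max(out.max() + bin_width, bin_width)
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(out, bins=edges)
    return out, (edges, counts)


def _superpose_stack(frames: np.ndarray, ref: np.ndarray, idx: np.ndarray) -> np.ndarray:
    fitted = np.empty_like(frames[:, idx, :])
    for k, frame in enumerate(frames):
        sup = kabsch_superpose(ref, frame[idx])
        fitted[k] = apply_superposition(sup, frame[idx])
    return fitted


def rmsf(
    trajectory: Trajectory,
    selection: AtomGroup,
    per_residue: bool = True,
) -> pd.DataFrame:
    """Root-mean-square fluctuation about the mean structure.

    All frames are superposed onto the first frame, a mean structure is
    formed, and frames are re-superposed onto that mean (one refinement
    pass).  RMSF_i = sqrt(<|r_i - <r_i>|^2>).  With ``per_residue`` the
    atomic values are averaged within each residue of the selection.

    Returns a DataFrame with columns author_resid/residue_name/rmsf (or
    atom_id/rmsf when per_residue is False).
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    if trajectory.n_frames < 2:
        raise ValueError("need at least two frames")
    idx = selection.indices
    frames = trajectory.frames
    fitted = _superpose_stack(frames, frames[0][idx], idx)
    mean = fitted.mean(axis=0)
    fitted = np.empty_like(fitted)
    for k, frame in enumerate(frames):
        sup = kabsch_superpose(mean, frame[idx])
        fitted[k] = apply_superposition(sup, frame[idx])
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(((fitted - mean) ** 2).sum(-1).mean(axis=0))
    atoms = selection.atoms
    if not per_residue:
        return pd.DataFrame({"atom_id": [a.atom_id for a in atoms], "rmsf": per_atom})
    df = pd.DataFrame(
        {
            "author_resid": [a.author_resid for a in atoms],
            "residue_name": [a.residue_name for a in atoms],
            "rmsf": per_atom,
        }
    )
    out = (
        df.groupby(["author_resid", "residue_name"], sort=False)["rmsf"]
        .mean()
        .reset_index()
    )
    return out


def bfactor_to_rmsf(b: float) -> float:
    """Crystallographic temperature factor (A^2) to RMSF (A): sqrt(3B/(8 pi^2))."""
    if b < 0:
        raise ValueError("negative B-factor")
    return math.sqrt(3.0 * b / (8.0 * math.pi**2))


def rmsf_to_bfactor(rmsf_value: float) -> float:
    """Inverse of :func:`bfactor_to_rmsf`: B = (8 pi^2 / 3) RMSF^2."""
    if rmsf_value < 0:
        raise ValueError("negative RMSF")
    return 8.0 * math.pi**2 * rmsf_value**2 / 3.0


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

_POLAR = {"N", "O"}


def _donor_triples(system: MolecularSystem) -> list[tuple[int, int]]:
    """(donor_heavy, hydrogen) pairs from the bond list."""
    triples = []
    for b in system.bonds:
        ai, aj = system.atoms[b.i], system.atoms[b.j]
        if ai.element in _POLAR and aj.element == "H":
            triples.append((b.i, b.j))
        elif aj.element in _POLAR and ai.element == "H":
            triples.append((b.j, b.i))
    return triples


def hbond_occupancy(
    system: MolecularSystem,
    trajectory: Trajectory,
    donors: list[tuple[int, int]] | None = None,
    acceptors: list[int] | None = None,
    dist_cut: float = 3.5,
    angle_cut: float = 135.0,
    min_occupancy: float = 0.0,
) -> list[HBondRecord]:
    """Hydrogen-bond occupancies over a trajectory.

    A candidate donor(heavy)-H...acceptor triple satisfies a frame when
    the donor-heavy-to-acceptor distance is <= ``dist_cut`` (A) and the
    donor-H-acceptor angle is >= ``angle_cut`` (degrees).  Donors
    default to every N/O-H pair found in the bond list (donors listed
    without an attached hydrogen are skipped with a warning); acceptors
    default to all N/O atoms.  Records with occupancy below
    ``min_occupancy`` are dropped.
    """
    if donors is None:
        donors = _donor_triples(system)
    else:
        checked = []
        bonded = {(b.i, b.j) for b in system.bonds} | {(b.j, b.i) for b in system.bonds}
        for d, h in donors:
            if bonded and (d, h) not in bonded:
                warnings.warn(f"donor {d} has no bonded hydrogen {h}; skipped", UserWarning)
                continue
            checked.append((d, h))
        donors = checked
    if acceptors is None:
        acceptors = [a.atom_id for a in system.atoms if a.element in _POLAR]
    frames = trajectory.frames
    records: list[HBondRecord] = []
    for d, h in donors:
        for acc in acceptors:
            if acc in (d, h):
                continue
            dist = np.linalg.norm(frames[:, d, :] - frames[:, acc, :], axis=1)
            v1 = frames[:, d, :] - frames[:, h, :]
            v2 = frames[:, acc, :] - frames[:, h, :]
            cosang = (v1 * v2).sum(-1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ok = (dist <= dist_cut) & (ang >= angle_cut)
            occ = float(ok.mean())
            if occ < min_occupancy:
                continue
            records.append(
                HBondRecord(
                    donor=d,
                    hydrogen=h,
                    acceptor=acc,
                    occupancy=occ,
                    mean_distance=float(dist[ok].mean()) if ok.any() else float("nan"),
                    mean_angle=float(ang[ok].mean()) if ok.any() else float("nan"),
                )
            )
    return records


# ---------------------------------------------------------------------------
# distance series
# ---------------------------------------------------------------------------


def distance_series(
    trajectory: Trajectory, dd: DistanceDefinition
) -> tuple[np.ndarray, float, float]:
    """Per-frame distance between the two groups' mass centers.

    Returns (series in A, mean, sd).
    """
    out = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory.frames):
        ca = center_of_mass(dd.group_a, frame)
        cb = center_of_mass(dd.group_b, frame)
        out[k] = float(np.linalg.norm(ca - cb))
    return out, float(out.mean()), float(out.std(ddof=0))
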