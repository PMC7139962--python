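"""Synthetic inputs with planted ground truth.

Every input class the pipeline consumes can be generated here with a
known answer, so all downstream stages are testable without any
structure downloads or force-field files:

* small bead-molecule "toy" systems with fully specified charges, LJ
  and GB parameters (analytic energies available by brute force);
* two-state (open/closed) distance time series from a first-order
  Markov chain with Gaussian emission about the state means;
* per-frame energy-component tables with known means and spreads for
  replica-aggregation checks;
* fluctuating coordinate trajectories with a prescribed per-atom
  isotropic displacement scale, optionally wrapped in random global
  rigid motions to exercise superposition.

All generators are deterministic for a fixed seed.  Substreams are
derived from a single root seed through ``numpy`` ``SeedSequence``
spawn keys, one fixed key per generator, so adding a generator never
perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mmgbsa import EnergyComponents
from .molsys import AtomRecord, MolecularSystem, Trajectory
from .state_analysis import CLOSED, OPEN

__all__ = [
    "TwoStateSpec",
    "ToySystemSpec",
    "make_toy_system",
    "make_two_state_series",
    "make_energy_frames",
    "make_fluctuating_trajectory",
    "substream",
]

# fixed spawn keys so each generator owns an independent stream
_STREAM_KEYS = {
    "toy_system": 1,
    "two_state": 2,
    "energy_frames": 3,
    "fluctuating": 4,
}


def substream(seed: int, generator: str) -> np.random.Generator:
    """Independent, reproducible random stream for one generator."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_KEYS[generator],)))


@dataclass(frozen=True)
class TwoStateSpec:
    """Markov-switching two-state distance series specification.

    Stationary P(open) = (1-p_stay_closed) / ((1-p_stay_open) +
    (1-p_stay_closed)).
    """

    p_stay_open: float = 0.98
    p_stay_closed: float = 0.98
    mean_open: float = 22.98  # A
    mean_closed: float = 20.59  # A
    emission_sd: float = 0.5  # A
    n_frames: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_stay_open, self.p_stay_closed):
            if not 0.0 < p < 1.0:
                raise ValueError("stay probabilities must be in (0, 1)")
        if not self.mean_closed < self.mean_open:
            raise ValueError("mean_closed must be below mean_open")
        if self.emission_sd < 0:
            raise ValueError("emission_sd must be non-negative")

    @property
    def stationary_p_open(self) -> float:
        a = 1.0 - self.p_stay_open
        b = 1.0 - self.p_stay_closed
        return b / (a + b)


@dataclass(frozen=True)
class ToySystemSpec:
    """Random bead-molecule specification.

    The last ``n_ligand_atoms`` atoms form the "ligand" residue; the
    rest are grouped into receptor residues of ``atoms_per_residue``.
    """

    n_atoms: int = 12
    n_ligand_atoms: int = 3
    charge_range: tuple[float, float] = (-0.8, 0.8)
    rmin_half_range: tuple[float, float] = (1.2, 2.0)
    epsilon_range: tuple[float, float] = (0.05, 0.3)
    gb_radius_range: tuple[float, float] = (1.2, 1.8)
    gb_screen: float = 0.8
    mass_range: tuple[float, float] = (12.0, 16.0)
    min_separation: float = 2.8  # A
    box_factor: float = 2.2  # box edge = box_factor * n^(1/3) * min_separation
    net_charge: float = 0.0
    atoms_per_residue: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 2 or not 0 < self.n_ligand_atoms < self.n_atoms:
            raise ValueError("need n_atoms >= 2 and 0 < n_ligand_atoms < n_atoms")


def make_toy_system(spec: ToySystemSpec) -> tuple[MolecularSystem, np.ndarray]:
    """Random parameterized bead system with pairwise min-separation.

    Coordinates are drawn uniformly in a cube and re-drawn (bounded
    retries) until every pair is at least ``min_separation`` apart;
    charges are shifted uniformly to hit the requested net charge
    exactly.  Returns (system, frame).
    """
    rng = substream(spec.seed, "toy_system")
    n = spec.n_atoms
    edge = spec.box_factor * spec.min_separation * n ** (1.0 / 3.0)
    # sequential insertion with bounded per-atom retries
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(2000):
            cand = rng.uniform(0.0, edge, size=3)
            if all(np.linalg.norm(cand - p) >= spec.min_separation for p in placed):
                placed.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not pack {n} atoms at min separation {spec.min_separation} A"
            )
    coords = np.array(placed)
    q = rng.uniform(*spec.charge_range, size=n)
    q += (spec.net_charge - q.sum()) / n
    atoms = []
    n_receptor = n - spec.n_ligand_atoms
    for i in range(n):
        if i < n_receptor:
            res_idx = i // spec.atoms_per_residue
            res_name, author = "RES", res_idx + 1
        else:
            res_idx = (n_receptor + spec.atoms_per_residue - 1) // spec.atoms_per_residue
            res_name, author = "LIG", 900
        atoms.append(
            AtomRecord(
                atom_id=i,
                name=f"X{i + 1}",
                element="C",
                residue_index=res_idx,
                residue_name=res_name,
                author_resid=author,
                mass=float(rng.uniform(*spec.mass_range)),
                charge=float(q[i]),
                lj_rmin_half=float(rng.uniform(*spec.rmin_half_range)),
                lj_epsilon=float(rng.uniform(*spec.epsilon_range)),
                gb_radius=float(rng.uniform(*spec.gb_radius_range)),
                gb_screen=spec.gb_screen,
            )
        )
    # recompact residue indices (receptor residues may be ragged)
    seen: dict[int, int] = {}
    for a in atoms:
        if a.residue_index not in seen:
            seen[a.residue_index] = len(seen)
        a.residue_index = seen[a.residue_index]
    return MolecularSystem(atoms), coords


def receptor_ligand_split(system: MolecularSystem) -> tuple[np.ndarray, np.ndarray]:
    """Indices of receptor and ligand atoms in a toy system."""
    lig = np.array([a.atom_id for a in system.atoms if a.residue_name == "LIG"])
    rec = np.array([a.atom_id for a in system.atoms if a.residue_name != "LIG"])
    return rec, lig


def make_two_state_series(spec: TwoStateSpec) -> tuple[np.ndarray, np.ndarray]:
    """Markov-switching distance series and its true state labels."""
    rng = substream(spec.seed, "two_state")
    labels = np.empty(spec.n_frames, dtype=object)
    # start from the stationary distribution
    state_open = bool(rng.random() < spec.stationary_p_open)
    u = rng.random(spec.n_frames)
    for k in range(spec.n_frames):
        labels[k] = OPEN if state_open else CLOSED
        stay = spec.p_stay_open if state_open else spec.p_stay_closed
        if u[k] >= stay:
            state_open = not state_open
    means = np.where(labels == OPEN, spec.mean_open, spec.mean_closed).astype(float)
    series = means + rng.normal(0.0, spec.emission_sd, size=spec.n_frames)
    return series, labels


def make_energy_frames(
    means: dict[str, float],
    sds: dict[str, float],
    n_frames: int,
    n_replicas: int,
    seed: int = 0,
    between_replica_sd: dict[str, float] | None = None,
) -> dict[int, list[EnergyComponents]]:
    """Per-frame Gaussian energy-component draws grouped by replica.

    Each term is drawn independently per frame around the (optionally
    replica-shifted) planted mean.  With ``between_replica_sd`` each
    replica's own mean is first drawn around the global mean, giving a
    controlled replica-level spread for standard-error checks.
    """
    terms = ("dE_ele", "dE_vdw", "dE_int", "dG_pol", "dG_nonpol")
    for t in terms:
        if sds.get(t, 0.0) < 0:
            raise ValueError("negative sd")
    rng = substream(seed, "energy_frames")
    out: dict[int, list[EnergyComponents]] = {}
    for rep in range(n_replicas):
        rep_mean = {}
        for t in terms:
            shift = 0.0
            if between_replica_sd:
                shift = rng.normal(0.0, between_replica_sd.get(t, 0.0))
            rep_mean[t] = means.get(t, 0.0) + shift
        frames = []
        draws = {t: rng.normal(rep_mean[t], sds.get(t, 0.0), size=n_frames) for t in terms}
        for k in range(n_frames):
            frames.append(
                EnergyComponents(
                    e_ele=float(draws["dE_ele"][k]),
                    e_vdw=float(draws["dE_vdw"][k]),
                    e_int=float(draws["dE_int"][k]),
                    g_pol=float(draws["dG_pol"][k]),
                    g_nonpol=float(draws["dG_nonpol"][k]),
                )
            )
        out[rep] = frames
    return out


def make_fluctuating_trajectory(
    base: np.ndarray,
    per_atom_sd,
    n_frames: int,
    seed: int = 0,
    rigid_motion: bool = False,
    frame_interval: float = 10.0,
) -> Trajectory:
    """Isotropic Gaussian jitter about a base frame, per-atom scale.

    ``per_atom_sd`` is the standard deviation per Cartesian coordinate
    in A, so the expected RMSF of atom i is sd_i * sqrt(3).  With
    ``rigid_motion`` every frame additionally receives a random global
    rotation and translation, which superposition-based analyses must
    remove.
    """
    from .molsys import random_rotation, rigid_transform

    base = np.asarray(base, dtype=float)
    sd = np.asarray(per_atom_sd, dtype=float)
    if sd.shape != (base.shape[0],):
        raise ValueError("per_atom_sd length must equal atom count")
    rng = substream(seed, "fluctuating")
    frames = np.empty((n_frames, base.shape[0], 3))
    for k in range(n_frames):
        frame = base + rng.normal(size=base.shape) * sd[:, None]
        if rigid_motion:
            rot = random_rotation(rng)
            trans = rng.uniform(-20.0, 20.0, size=3)
            frame = rigid_transform(frame, rot, trans)
        frames[k] = frame
    return Trajectory(frames=frames, frame_interval=frame_interval)


def expected_rmsf(per_atom_sd) -> np.ndarray:
    """Planted RMSF: sqrt(3) * sd per atom (chi-distribution identity)."""
    return math.sqrt(3.0) * np.asarray(per_atom_sd, dtype=float)
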