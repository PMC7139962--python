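"""Implicit-solvent MM-GB/SA binding free energies.

End-point binding energetics for a receptor-ligand complex from
trajectory snapshots:

    dG_bind = dH_gas + dG_solv - T*dS
    dH_gas  = dE_int + dE_vdw + dE_ele
    dG_solv = dG_pol + dG_nonpol,   dG_nonpol = gamma*SASA + beta

The polar solvation term uses a generalized-Born model with OBC-style
effective radii for both totals and the per-nucleotide decomposition so
the two are mutually consistent.  The nonpolar term is linear in the
solvent-accessible surface area computed by Shrake-Rupley sphere-point
counting.  No distance cutoffs anywhere: systems are post-processed
solute snapshots and exact pair sums are affordable.

Under the single-trajectory convention (receptor and ligand coordinates
taken from the complex snapshot) the internal term cancels exactly and
dE_ele / dE_vdw reduce to inter-group sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molsys import AtomGroup, MolecularSystem, extract_subsystem

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyModelParams",
    "EnergyComponents",
    "BindingFreeEnergyResult",
    "ResidueContribution",
    "coulomb_energy",
    "lj_energy",
    "bond_energy",
    "effective_born_radii",
    "gb_polar_energy",
    "sasa",
    "nonpolar_energy",
    "species_components",
    "snapshot_binding_components",
    "aggregate_replicas",
    "per_residue_decomposition",
]

#: Coulomb constant in kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.0637

ENERGY_TERMS = ("dE_ele", "dE_vdw", "dE_int", "dG_pol", "dG_nonpol")
DERIVED_TERMS = ("dG_ele_pol", "dG_vdw_nonpol", "dH", "TdS", "dG_bind")


@dataclass(frozen=True)
class EnergyModelParams:
    """Physical constants and model switches for the energy engine.

    Defaults follow common implicit-solvent post-processing practice:
    interior dielectric 1, solvent dielectric 80, nonpolar surface
    coefficient gamma = 0.00542 kcal/(mol*A^2) with offset beta = 0.92
    kcal/mol, 1.4 A water probe, and OBC rescaling coefficients
    alpha=1.0, beta=0.8, gamma=4.85 with a 0.09 A radius offset.
    """

    coulomb_constant: float = COULOMB_CONSTANT
    interior_dielectric: float = 1.0
    solvent_dielectric: float = 80.0
    gamma: float = 0.00542  # kcal/(mol*A^2)
    beta_const: float = 0.92  # kcal/mol
    probe_radius: float = 1.4  # A
    sasa_points: int = 960
    one_four_ele_scale: float = 1.0 / 1.2
    one_four_vdw_scale: float = 0.5
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    gb_offset: float = 0.09  # A

    def __post_init__(self) -> None:
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectric constants must be positive")
        if self.sasa_points < 92:
            raise ValueError("sasa_points must be >= 92")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


DEFAULT_PARAMS = EnergyModelParams()


@dataclass
class EnergyComponents:
    """One snapshot's energy terms (absolute for a species, or deltas)."""

    e_ele: float
    e_vdw: float
    e_int: float
    g_pol: float
    g_nonpol: float
    sasa_total: float = 0.0

    def total_enthalpy(self) -> float:
        return self.e_ele + self.e_vdw + self.e_int + self.g_pol + self.g_nonpol

    def as_dict(self) -> dict[str, float]:
        return {
            "dE_ele": self.e_ele,
            "dE_vdw": self.e_vdw,
            "dE_int": self.e_int,
            "dG_pol": self.g_pol,
            "dG_nonpol": self.g_nonpol,
        }


@dataclass
class ResidueContribution:
    """Per-nucleotide share of the binding free energy (enthalpic part).

    The contribution is split into electrostatic, van der Waals, polar
    solvation and nonpolar solvation terms; pairwise terms are divided
    half to each partner residue, GB self terms stay with their own
    residue.  The constant beta of the nonpolar model is carried by a
    single pseudo-residue named ``offset``.
    """

    author_resid: int | None
    residue_name: str
    ele: float
    vdw: float
    pol: float
    nonpol: float

    @property
    def total(self) -> float:
        return self.ele + self.vdw + self.pol + self.nonpol


@dataclass
class BindingFreeEnergyResult:
    """Replica-aggregated binding free energy with standard errors.

    ``sigmas`` follow the sigma = sd(replica means)/sqrt(N) rule, where N
    is the number of independent replicas.
    """

    means: dict[str, float]
    sigmas: dict[str, float]
    n_replicas: int
    temperature: float = 300.0

    def __getitem__(self, term: str) -> float:
        return self.means[term]

    def sigma(self, term: str) -> float:
        return self.sigmas[term]

    def summary(self) -> pd.DataFrame:
        rows = []
        for term in ENERGY_TERMS + DERIVED_TERMS:
            rows.append(
                {
                    "term": term,
                    "mean": self.means[term],
                    "sigma": self.sigmas[term],
                    "cell": f"{self.means[term]:.2f} ± {self.sigmas[term]:.2f}",
                }
            )
        return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _indices(system: MolecularSystem, group) -> np.ndarray:
    if group is None:
        return np.arange(system.n_atoms)
    if isinstance(group, AtomGroup):
        return group.indices
    return np.asarray(group, dtype=int)


def _check_intergroup(ia: np.ndarray, ib: np.ndarray) -> None:
    if np.intersect1d(ia, ib).size:
        raise ValueError("inter-group energy requires disjoint groups")


def _pair_scale_masks(system: MolecularSystem, idx: np.ndarray, params: EnergyModelParams):
    """Ele/vdw scale matrices for intra-group sums (0 for 1-2/1-3 pairs)."""
    n = len(idx)
    pos = {int(a): k for k, a in enumerate(idx)}
    ele = np.ones((n, n))
    vdw = np.ones((n, n))
    np.fill_diagonal(ele, 0.0)
    np.fill_diagonal(vdw, 0.0)
    for (i, j) in system.exclusions_12_13:
        if i in pos and j in pos:
            a, b = pos[i], pos[j]
            ele[a, b] = ele[b, a] = 0.0
            vdw[a, b] = vdw[b, a] = 0.0
    for (i, j), (es, vs) in system.pairs_14.items():
        if i in pos and j in pos:
            a, b = pos[i], pos[j]
            ele[a, b] = ele[b, a] = es if es is not None else params.one_four_ele_scale
            vdw[a, b] = vdw[b, a] = vs if vs is not None else params.one_four_vdw_scale
    return ele, vdw


def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    d = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((d * d).sum(-1))


def _check_singularity(r: np.ndarray, mask: np.ndarray) -> None:
    if np.any((r < 1e-6) & mask):
        raise ValueError("atom pair closer than 1e-6 A: Coulomb/LJ singularity")


# ---------------------------------------------------------------------------
# gas-phase terms
# ---------------------------------------------------------------------------


def coulomb_energy(
    system: MolecularSystem,
    frame: np.ndarray,
    group_a=None,
    group_b=None,
    params: EnergyModelParams = DEFAULT_PARAMS,
) -> float:
    """Pairwise Coulomb energy, kcal/mol, no cutoff.

    With ``group_b`` given, sums all cross pairs between two disjoint
    groups (no exclusions apply across a non-bonded interface).  Without
    it, sums intra-group pairs with 1-2/1-3 exclusions removed and 1-4
    pairs scaled.
    """
    frame = np.asarray(frame, dtype=float)
    q = system.charges
    k = params.coulomb_constant
    ia = _indices(system, group_a)
    if group_b is not None:
        ib = _indices(system, group_b)
        _check_intergroup(ia, ib)
        d = frame[ia][:, None, :] - frame[ib][None, :, :]
        r = np.sqrt((d * d).sum(-1))
        _check_singularity(r, np.ones_like(r, bool))
        return float(k * (q[ia][:, None] * q[ib][None, :] / r).sum())
    r = _distance_matrix(frame[ia])
    ele_scale, _ = _pair_scale_masks(system, ia, params)
    _check_singularity(r, ele_scale != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(ele_scale != 0, q[ia][:, None] * q[ia][None, :] / np.where(r > 0, r, 1.0), 0.0)
    return float(0.5 * k * (e * ele_scale).sum())


def lj_energy(
    system: MolecularSystem,
    frame: np.ndarray,
    group_a=None,
    group_b=None,
    params: EnergyModelParams = DEFAULT_PARAMS,
) -> float:
    """12-6 Lennard-Jones energy with Lorentz-Berthelot combining.

    Rmin_ij = rmin_half_i + rmin_half_j, eps_ij = sqrt(eps_i * eps_j);
    E = sum eps_ij [(Rmin/r)^12 - 2 (Rmin/r)^6], no cutoff.
    """
    frame = np.asarray(frame, dtype=float)
    rh = system.array("lj_rmin_half")
    ep = system.array("lj_epsilon")
    ia = _indices(system, group_a)

    def pair_e(r, rmin, eps, mask):
        _check_singularity(r, mask)
        with np.errstate(divide="ignore", invalid="ignore"):
            x6 = np.where(mask, (rmin / np.where(r > 0, r, 1.0)) ** 6, 0.0)
        return eps * (x6 * x6 - 2.0 * x6)

    if group_b is not None:
        ib = _indices(system, group_b)
        _check_intergroup(ia, ib)
        d = frame[ia][:, None, :] - frame[ib][None, :, :]
        r = np.sqrt((d * d).sum(-1))
        rmin = rh[ia][:, None] + rh[ib][None, :]
        eps = np.sqrt(ep[ia][:, None] * ep[ib][None, :])
        return float(pair_e(r, rmin, eps, np.ones_like(r, bool)).sum())
    r = _distance_matrix(frame[ia])
    _, vdw_scale = _pair_scale_masks(system, ia, params)
    rmin = rh[ia][:, None] + rh[ia][None, :]
    eps = np.sqrt(ep[ia][:, None] * ep[ia][None, :])
    return float(0.5 * (pair_e(r, rmin, eps, vdw_scale != 0) * vdw_scale).sum())


def bond_energy(system: MolecularSystem, frame: np.ndarray) -> float:
    """Harmonic bond energy: sum (k/2)(r - r0)^2."""
    frame = np.asarray(frame, dtype=float)
    e = 0.0
    for b in system.bonds:
        r = float(np.linalg.norm(frame[b.i] - frame[b.j]))
        e += 0.5 * b.force_constant * (r - b.equilibrium) ** 2
    return e


# ---------------------------------------------------------------------------
# generalized Born polar solvation
# ---------------------------------------------------------------------------


def _descreen_integral(rho_i: np.ndarray, r: np.ndarray, sj: np.ndarray) -> np.ndarray:
    """Pairwise HCT descreening integral of neighbor spheres.

    ``rho_i`` is atom i's offset-reduced intrinsic radius, ``r`` the
    pair distance and ``sj`` the neighbor's screened, offset-reduced
    radius.  Vectorized over pairs.
    """
    out = np.zeros_like(r)
    engulfed = rho_i >= r + sj  # neighbor buried inside atom i: no descreening
    active = ~engulfed & (sj > 0)
    if not np.any(active):
        return out
    rho = rho_i[active] if np.ndim(rho_i) else np.full(active.sum(), rho_i)
    rr = r[active]
    ss = sj[active]
    upper = rr + ss
    lower = np.maximum(rho, np.abs(rr - ss))
    inv_l = 1.0 / lower
    inv_u = 1.0 / upper
    term = 0.5 * (
        (inv_l - inv_u)
        + 0.25 * rr * (inv_u**2 - inv_l**2)
        + 0.5 / rr * np.log(lower / upper)
        + 0.25 * ss**2 / rr * (inv_l**2 - inv_u**2)
    )
    inside = rho < (ss - rr)  # atom i's center inside the neighbor sphere
    term = term + np.where(inside, (1.0 / rho - inv_l), 0.0)
    out[active] = term
    return out


def effective_born_radii(
    system: MolecularSystem,
    frame: np.ndarray,
    group=None,
    params: EnergyModelParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """OBC effective Born radii (A) for the chosen species.

    The species is the subset of atoms in ``group`` considered alone:
    only those atoms descreen each other.  An isolated atom's effective
    radius equals its intrinsic radius minus the 0.09 A offset; burial
    monotonically increases the effective radius via the tanh rescaling
    Ri^-1 = rho_i^-1 - rho_int^-1 tanh(a*Psi - b*Psi^2 + g*Psi^3).
    """
    frame = np.asarray(frame, dtype=float)
    idx = _indices(system, group)
    rho_int = system.array("gb_radius")[idx]
    screen = system.array("gb_screen")[idx]
    if np.any(rho_int <= 0):
        raise ValueError("non-positive GB radius")
    rho = rho_int - params.gb_offset
    if np.any(rho <= 0):
        raise ValueError("GB radius smaller than offset")
    coords = frame[idx]
    n = len(idx)
    integral = np.zeros(n)
    if n > 1:
        r = _distance_matrix(coords)
        for i in range(n):
            mask = np.arange(n) != i
            integral[i] = _descreen_integral(
                np.full(n - 1, rho[i]), r[i, mask], (screen * rho)[mask]
            ).sum()
    psi = integral * rho
    arg = params.obc_alpha * psi - params.obc_beta * psi**2 + params.obc_gamma * psi**3
    inv_r = 1.0 / rho - np.tanh(arg) / rho_int
    if np.any(inv_r <= 0):
        raise ValueError("non-positive inverse effective radius (overlapping spheres?)")
    return 1.0 / inv_r


def _gb_pair_matrix(
    coords: np.ndarray, q: np.ndarray, radii: np.ndarray, params: EnergyModelParams
) -> np.ndarray:
    """Matrix M with M.sum() = GB polar energy; row sums give per-atom
    half-split shares (self energies on the diagonal)."""
    tau = 1.0 / params.interior_dielectric - 1.0 / params.solvent_dielectric
    r2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    rr = radii[:, None] * radii[None, :]
    fgb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    return -0.5 * params.coulomb_constant * tau * (q[:, None] * q[None, :]) / fgb


def gb_polar_energy(
    system: MolecularSystem,
    frame: np.ndarray,
    group=None,
    params: EnergyModelParams = DEFAULT_PARAMS,
    radii: np.ndarray | None = None,
) -> float:
    """GB polar solvation energy of the species in ``group``, kcal/mol.

    E = -(k/2)(1/e_in - 1/e_out) sum_ij qi qj / f_GB with
    f_GB = sqrt(r^2 + Ri Rj exp(-r^2/(4 Ri Rj))), i = j included.
    """
    frame = np.asarray(frame, dtype=float)
    idx = _indices(system, group)
    if radii is None:
        radii = effective_born_radii(system, frame, idx, params)
    q = system.charges[idx]
    return float(_gb_pair_matrix(frame[idx], q, radii, params).sum())


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def sasa(
    system: MolecularSystem,
    frame: np.ndarray,
    group=None,
    params: EnergyModelParams = DEFAULT_PARAMS,
    radii: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Atom radii default to the Lennard-Jones rmin_half (vdW radius); the
    probe is rolled over each sphere with ``params.sasa_points`` test
    points.  Returns (per-atom areas A^2, total A^2) for the species
    ``group`` considered alone.
    """
    frame = np.asarray(frame, dtype=float)
    idx = _indices(system, group)
    if radii is None:
        radii = system.array("lj_rmin_half")[idx]
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("SASA requires positive per-atom radii")
    coords = frame[idx]
    ext = radii + params.probe_radius
    pts = _sphere_points(params.sasa_points)
    n = len(idx)
    areas = np.zeros(n)
    if n == 1:
        areas[0] = 4.0 * math.pi * ext[0] ** 2
        return areas, float(areas.sum())
    d = _distance_matrix(coords)
    for i in range(n):
        neighbors = np.nonzero((d[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        surface = coords[i] + ext[i] * pts
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            dj = ((surface - coords[j]) ** 2).sum(-1)
            accessible &= dj >= ext[j] ** 2
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * accessible.mean()
    return areas, float(areas.sum())


def nonpolar_energy(sasa_total: float, params: EnergyModelParams = DEFAULT_PARAMS) -> float:
    """Cavity/dispersion nonpolar solvation term: gamma*SASA + beta."""
    if sasa_total < 0:
        raise ValueError("negative SASA")
    return params.gamma * sasa_total + params.beta_const


# ---------------------------------------------------------------------------
# binding components
# ---------------------------------------------------------------------------


def species_components(
    system: MolecularSystem,
    frame: np.ndarray,
    group=None,
    params: EnergyModelParams = DEFAULT_PARAMS,
) -> EnergyComponents:
    """Absolute single-species energy terms for one snapshot."""
    idx = _indices(system, group)
    sub_needed = group is not None and len(idx) != system.n_atoms
    if sub_needed:
        sub = extract_subsystem(system, idx)
        sub_frame = np.asarray(frame, dtype=float)[idx]
    else:
        sub, sub_frame = system, np.asarray(frame, dtype=float)
    e_ele = coulomb_energy(sub, sub_frame, params=params)
    e_vdw = lj_energy(sub, sub_frame, params=params)
    e_int = bond_energy(sub, sub_frame)
    g_pol = gb_polar_energy(sub, sub_frame, params=params)
    _, total_area = sasa(sub, sub_frame, params=params)
    return EnergyComponents(
        e_ele=e_ele,
        e_vdw=e_vdw,
        e_int=e_int,
        g_pol=g_pol,
        g_nonpol=nonpolar_energy(total_area, params),
        sasa_total=total_area,
    )


def snapshot_binding_components(
    system: MolecularSystem,
    frame: np.ndarray,
    receptor_group,
    ligand_group,
    params: EnergyModelParams = DEFAULT_PARAMS,
) -> EnergyComponents:
    """Delta components for one complex snapshot (single-trajectory).

    Each delta term is term(complex) - term(receptor) - term(ligand)
    with receptor/ligand coordinates taken from the same frame.  The
    gas-phase internal term vanishes by construction and dE_ele/dE_vdw
    reduce to exact inter-group sums, which are evaluated directly.
    """
    ir = _indices(system, receptor_group)
    il = _indices(system, ligand_group)
    if len(il) == 0:
        raise ValueError("empty ligand group")
    if len(ir) == 0:
        raise ValueError("empty receptor group")
    _check_intergroup(ir, il)
    if len(ir) + len(il) != system.n_atoms:
        raise ValueError("receptor and ligand groups must partition the system")
    frame = np.asarray(frame, dtype=float)
    de_ele = coulomb_energy(system, frame, ir, il, params)
    de_vdw = lj_energy(system, frame, ir, il, params)
    gp_c = gb_polar_energy(system, frame, params=params)
    gp_r = gb_polar_energy(system, frame, ir, params)
    gp_l = gb_polar_energy(system, frame, il, params)
    _, area_c = sasa(system, frame, params=params)
    _, area_r = sasa(system, frame, ir, params)
    _, area_l = sasa(system, frame, il, params)
    d_area = area_c - area_r - area_l
    dg_nonpol = (
        nonpolar_energy(area_c, params)
        - nonpolar_energy(area_r, params)
        - nonpolar_energy(area_l, params)
    )
    return EnergyComponents(
        e_ele=de_ele,
        e_vdw=de_vdw,
        e_int=0.0,
        g_pol=gp_c - gp_r - gp_l,
        g_nonpol=dg_nonpol,
        sasa_total=d_area,
    )


def binding_components_three_trajectory(
    complex_system: MolecularSystem,
    complex_frame: np.ndarray,
    receptor_system: MolecularSystem,
    receptor_frame: np.ndarray,
    ligand_system: MolecularSystem,
    ligand_frame: np.ndarray,
    params: EnergyModelParams = DEFAULT_PARAMS,
) -> EnergyComponents:
    """Delta components from independent complex/receptor/ligand frames.

    Unlike the single-trajectory convention, internal (bonded) and
    intra-species nonbonded terms do not cancel, so dE_int is nonzero
    when the separated species relax away from their bound geometry.
    """
    c = species_components(complex_system, complex_frame, params=params)
    r = species_components(receptor_system, receptor_frame, params=params)
    ligand = species_components(ligand_system, ligand_frame, params=params)
    return EnergyComponents(
        e_ele=c.e_ele - r.e_ele - ligand.e_ele,
        e_vdw=c.e_vdw - r.e_vdw - ligand.e_vdw,
        e_int=c.e_int - r.e_int - ligand.e_int,
        g_pol=c.g_pol - r.g_pol - ligand.g_pol,
        g_nonpol=c.g_nonpol - r.g_nonpol - ligand.g_nonpol,
        sasa_total=c.sasa_total - r.sasa_total - ligand.sasa_total,
    )


def aggregate_replicas(
    components_by_replica,
    t_delta_s: float = 0.0,
    t_delta_s_sigma: float = 0.0,
    temperature: float = 300.0,
) -> BindingFreeEnergyResult:
    """Aggregate per-frame components grouped by replica.

    ``components_by_replica`` is a mapping (or list) of per-replica
    lists of :class:`EnergyComponents`.  Per-replica means are averaged
    to a grand mean; the standard error of each term is the standard
    deviation of replica means divided by sqrt(N), N the replica count.
    ``t_delta_s`` is the T*dS entropy term in kcal/mol (negative when
    binding loses entropy), supplied with its own standard error.
    """
    if hasattr(components_by_replica, "values"):
        groups = list(components_by_replica.values())
    else:
        groups = list(components_by_replica)
    groups = [g for g in groups if len(g)]
    n = len(groups)
    if n == 0:
        raise ValueError("no replicas to aggregate")
    rep_means = {t: [] for t in ENERGY_TERMS}
    for g in groups:
        for t in ENERGY_TERMS:
            rep_means[t].append(float(np.mean([c.as_dict()[t] for c in g])))
    means: dict[str, float] = {}
    sigmas: dict[str, float] = {}
    for t in ENERGY_TERMS:
        vals = np.array(rep_means[t])
        means[t] = float(vals.mean())
        sigmas[t] = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    means["dG_ele_pol"] = means["dE_ele"] + means["dG_pol"]
    means["dG_vdw_nonpol"] = means["dE_vdw"] + means["dG_nonpol"]
    means["dH"] = sum(means[t] for t in ENERGY_TERMS)
    means["TdS"] = t_delta_s
    means["dG_bind"] = means["dH"] - t_delta_s
    # derived-term standard errors from replica-level sums
    for name, parts in (
        ("dG_ele_pol", ("dE_ele", "dG_pol")),
        ("dG_vdw_nonpol", ("dE_vdw", "dG_nonpol")),
        ("dH", ENERGY_TERMS),
    ):
        sums = np.array([np.sum([rep_means[p][k] for p in parts]) for k in range(n)])
        sigmas[name] = float(sums.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    sigmas["TdS"] = t_delta_s_sigma
    sigmas["dG_bind"] = math.hypot(sigmas["dH"], t_delta_s_sigma)
    return BindingFreeEnergyResult(means=means, sigmas=sigmas, n_replicas=n, temperature=temperature)


# ---------------------------------------------------------------------------
# per-residue decomposition
# ---------------------------------------------------------------------------


def _embed(matrix: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    out[np.ix_(idx, idx)] = matrix
    return out


def per_residue_decomposition(
    system: MolecularSystem,
    frames,
    receptor_group,
    ligand_group,
    params: EnergyModelParams = DEFAULT_PARAMS,
) -> list[ResidueContribution]:
    """Per-nucleotide decomposition of the binding enthalpy.

    Pairwise electrostatic, van der Waals and GB cross terms are split
    half to each partner's residue; GB self-energy changes stay with
    their residue; per-atom SASA differences are scaled by gamma and
    assigned to their residue.  The beta constant (which appears once
    per species in gamma*SASA + beta and hence contributes -beta to the
    delta) is booked on a pseudo-residue named ``offset``.  Column sums
    over residues reproduce the corresponding whole-system deltas.
    Results are averaged over the given frames.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    ir = _indices(system, receptor_group)
    il = _indices(system, ligand_group)
    if len(il) == 0 or len(ir) == 0:
        raise ValueError("receptor and ligand groups must be non-empty")
    _check_intergroup(ir, il)
    n = system.n_atoms
    res_of = np.array([a.residue_index for a in system.atoms])
    n_res = res_of.max() + 1
    q = system.charges
    rh = system.array("lj_rmin_half")
    ep = system.array("lj_epsilon")

    acc = np.zeros((n_res + 1, 4))  # last row = beta offset pseudo-residue
    for frame in frames:
        per_atom = np.zeros((n, 4))  # ele, vdw, pol, nonpol
        # electrostatic + vdW: inter-group pair matrices, half to each atom
        d = frame[ir][:, None, :] - frame[il][None, :, :]
        r = np.sqrt((d * d).sum(-1))
        _check_singularity(r, np.ones_like(r, bool))
        e_pair = params.coulomb_constant * q[ir][:, None] * q[il][None, :] / r
        x6 = ((rh[ir][:, None] + rh[il][None, :]) / r) ** 6
        v_pair = np.sqrt(ep[ir][:, None] * ep[il][None, :]) * (x6 * x6 - 2 * x6)
        per_atom[ir, 0] += 0.5 * e_pair.sum(axis=1)
        per_atom[il, 0] += 0.5 * e_pair.sum(axis=0)
        per_atom[ir, 1] += 0.5 * v_pair.sum(axis=1)
        per_atom[il, 1] += 0.5 * v_pair.sum(axis=0)
        # polar: delta GB pair matrix, row sums = self + half of pair terms
        rad_c = effective_born_radii(system, frame, None, params)
        rad_r = effective_born_radii(system, frame, ir, params)
        rad_l = effective_born_radii(system, frame, il, params)
        m_c = _gb_pair_matrix(frame, q, rad_c, params)
        m_r = _embed(_gb_pair_matrix(frame[ir], q[ir], rad_r, params), ir, n)
        m_l = _embed(_gb_pair_matrix(frame[il], q[il], rad_l, params), il, n)
        per_atom[:, 2] += (m_c - m_r - m_l).sum(axis=1)
        # nonpolar: per-atom SASA differences scaled by gamma
        a_c, _ = sasa(system, frame, None, params)
        a_r, _ = sasa(system, frame, ir, params)
        a_l, _ = sasa(system, frame, il, params)
        d_area = a_c.copy()
        d_area[ir] -= a_r
        d_area[il] -= a_l
        per_atom[:, 3] += params.gamma * d_area
        for col in range(4):
            np.add.at(acc[:n_res, col], res_of, per_atom[:, col])
        acc[n_res, 3] += -params.beta_const  # beta appears once per species: +1 -2
    acc /= len(frames)

    out: list[ResidueContribution] = []
    for res in system.residues:
        i = system.atoms[res.start].residue_index
        out.append(
            ResidueContribution(
                author_resid=res.author_resid,
                residue_name=res.residue_name,
                ele=float(acc[i, 0]),
                vdw=float(acc[i, 1]),
                pol=float(acc[i, 2]),
                nonpol=float(acc[i, 3]),
            )
        )
    out.append(
        ResidueContribution(
            author_resid=None,
            residue_name="offset",
            ele=0.0,
            vdw=0.0,
            pol=0.0,
            nonpol=float(acc[n_res, 3]),
        )
    )
    return out


def decomposition_frame(contribs: list[ResidueContribution]) -> pd.DataFrame:
    """Tabulate residue contributions (one row per residue)."""
    rows = [
        {
            "residue": f"{c.residue_name}{c.author_resid}" if c.author_resid is not None else c.residue_name,
            "ele": c.ele,
            "vdw": c.vdw,
            "pol": c.pol,
            "nonpol": c.nonpol,
            "total": c.total,
        }
        for c in contribs
    ]
    return pd.DataFrame(rows)
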