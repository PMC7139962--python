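"""Harmonic normal-mode vibrational entropy for the -T*dS term.

Each selected snapshot is energy-minimized, a mass-weighted Hessian is
built by central finite differences of the analytic gradient, and the
vibrational entropy of the harmonic oscillator ensemble

    S = R sum_i [ x_i/(exp(x_i)-1) - ln(1-exp(-x_i)) ],  x_i = h*c*nu_i/(kB*T)

is evaluated over the 3N-6 (nonlinear) or 3N-5 (linear) genuine modes.
T*dS for binding is T*(S_complex - S_receptor - S_ligand) averaged over
snapshots.  Rigid-body modes are identified by a |nu| < 1 cm^-1
threshold; snapshots with imaginary modes are dropped and logged rather
than silently included.

The potential is the package's own implicit-solvent surface: harmonic
bonds + intramolecular Coulomb/LJ (with exclusions and 1-4 scaling) +
GB polar + SASA nonpolar.  Gradients of the bonded and gas-phase terms
are analytic; the GB term is differentiated by central differences, and
the sphere-point SASA term is locally piecewise-constant so its
gradient is taken as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.constants as const
from scipy.optimize import minimize as _scipy_minimize

from .mmgbsa import (
    DEFAULT_PARAMS,
    EnergyModelParams,
    _indices,
    _pair_scale_masks,
    bond_energy,
    coulomb_energy,
    gb_polar_energy,
    lj_energy,
    nonpolar_energy,
    sasa,
)
from .molsys import MolecularSystem, extract_subsystem

__all__ = [
    "GAS_CONSTANT",
    "NormalModeResult",
    "EntropyTermResult",
    "total_energy",
    "total_gradient",
    "minimize",
    "hessian",
    "normal_modes",
    "vibrational_entropy",
    "entropy_term",
]

#: gas constant, kcal/(mol*K)
GAS_CONSTANT = 0.0019872

# sqrt(kcal/mol / (amu * A^2)) -> angular frequency in s^-1
_OMEGA_SI = math.sqrt(
    (const.calorie * 1e3 / const.Avogadro) / (const.atomic_mass * 1e-20)
)
# eigenvalue lambda [kcal/(mol A^2 amu)] -> wavenumber cm^-1
_WAVENUMBER = _OMEGA_SI / (2.0 * math.pi * const.c * 100.0)
# h*c*(1 cm^-1)/kB in K
_CM_TO_K = const.h * const.c * 100.0 / const.k


@dataclass
class NormalModeResult:
    """Vibrational frequencies and bookkeeping for one minimized species."""

    frequencies: np.ndarray  # cm^-1, genuine modes, ascending
    n_zero_modes: int
    n_imaginary: int
    s_vib: float | None  # kcal/(mol K); None when imaginary modes block it
    minimized_energy: float
    gradient_rms: float


@dataclass
class MinimizationResult:
    frame: np.ndarray
    energy: float
    gradient_rms: float
    converged: bool
    n_steps: int


@dataclass
class EntropyTermResult:
    """T*dS of binding with its standard error over snapshots."""

    t_delta_s: float  # kcal/mol
    sigma: float
    temperature: float
    n_used: int
    n_dropped: int
    log: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# potential energy surface
# ---------------------------------------------------------------------------


def total_energy(
    system: MolecularSystem,
    coords: np.ndarray,
    params: EnergyModelParams = DEFAULT_PARAMS,
    include_solvation: bool = True,
) -> float:
    """Implicit-solvent potential energy of one species, kcal/mol."""
    coords = np.asarray(coords, dtype=float)
    e = bond_energy(system, coords)
    e += coulomb_energy(system, coords, params=params)
    e += lj_energy(system, coords, params=params)
    if include_solvation and np.any(system.charges != 0):
        # GB vanishes identically without charges.  The sphere-point
        # nonpolar term is piecewise-constant in coordinates: it adds no
        # curvature and its step discontinuities defeat line searches,
        # so the harmonic surface deliberately omits it.
        e += gb_polar_energy(system, coords, params=params)
    if not np.isfinite(e):
        raise ValueError("non-finite energy")
    return float(e)


def _gas_gradient(
    system: MolecularSystem, coords: np.ndarray, params: EnergyModelParams
) -> np.ndarray:
    """Analytic gradient of bonds + intramolecular Coulomb + LJ."""
    n = system.n_atoms
    grad = np.zeros((n, 3))
    for b in system.bonds:
        d = coords[b.i] - coords[b.j]
        r = float(np.linalg.norm(d))
        if r > 0:
            f = b.force_constant * (r - b.equilibrium) * d / r
            grad[b.i] += f
            grad[b.j] -= f
    if n > 1:
        idx = np.arange(n)
        ele_scale, vdw_scale = _pair_scale_masks(system, idx, params)
        diff = coords[:, None, :] - coords[None, :, :]
        r2 = (diff * diff).sum(-1)
        np.fill_diagonal(r2, 1.0)
        r = np.sqrt(r2)
        q = system.charges
        # d/dr (k q q / r) = -k q q / r^2 ; force along diff/r
        ce = -params.coulomb_constant * q[:, None] * q[None, :] / r2 * ele_scale
        rh = system.array("lj_rmin_half")
        ep = system.array("lj_epsilon")
        rmin = rh[:, None] + rh[None, :]
        eps = np.sqrt(ep[:, None] * ep[None, :])
        x6 = (rmin / r) ** 6
        # dE/dr for eps[(Rmin/r)^12 - 2 (Rmin/r)^6] = -12 eps (x12 - x6)/r
        cl = -12.0 * eps * (x6 * x6 - x6) / r * vdw_scale
        coef = (ce + cl) / r
        np.fill_diagonal(coef, 0.0)
        grad += (coef[:, :, None] * diff).sum(axis=1)
    return grad


def total_gradient(
    system: MolecularSystem,
    coords: np.ndarray,
    params: EnergyModelParams = DEFAULT_PARAMS,
    include_solvation: bool = True,
    fd_step: float = 1e-5,
) -> np.ndarray:
    """Gradient of :func:`total_energy`, shape (n_atoms, 3).

    Gas-phase terms analytic; GB polar by central differences (the SASA
    term is piecewise-constant in coordinates and contributes none).
    """
    coords = np.asarray(coords, dtype=float)
    grad = _gas_gradient(system, coords, params)
    if include_solvation and np.any(system.charges != 0):
        flat = coords.ravel().copy()
        g = np.zeros_like(flat)
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + fd_step
            ep = gb_polar_energy(system, flat.reshape(-1, 3), params=params)
            flat[k] = orig - fd_step
            em = gb_polar_energy(system, flat.reshape(-1, 3), params=params)
            flat[k] = orig
            g[k] = (ep - em) / (2.0 * fd_step)
        grad += g.reshape(-1, 3)
    return grad


# ---------------------------------------------------------------------------
# minimization, Hessian, modes
# ---------------------------------------------------------------------------


def minimize(
    system: MolecularSystem,
    frame: np.ndarray,
    gradient_tol: float = 1e-4,
    max_steps: int = 2000,
    params: EnergyModelParams = DEFAULT_PARAMS,
    include_solvation: bool = True,
) -> MinimizationResult:
    """Energy-minimize a frame to RMS gradient <= gradient_tol.

    Quasi-Newton (L-BFGS) on the package potential; convergence is
    checked on the root-mean-square Cartesian gradient in
    kcal/(mol*A).  Non-convergence within ``max_steps`` is flagged, not
    raised.
    """
    frame = np.asarray(frame, dtype=float)
    shape = frame.shape

    def fun(x):
        return total_energy(system, x.reshape(shape), params, include_solvation)

    def jac(x):
        return total_gradient(system, x.reshape(shape), params, include_solvation).ravel()

    res = _scipy_minimize(
        fun,
        frame.ravel(),
        jac=jac,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": 1e-12, "ftol": 1e-15},
    )
    out = res.x.reshape(shape)
    g = total_gradient(system, out, params, include_solvation)
    rms = float(np.sqrt((g**2).mean()))
    return MinimizationResult(
        frame=out,
        energy=float(res.fun),
        gradient_rms=rms,
        converged=rms <= gradient_tol,
        n_steps=int(res.nit),
    )


def hessian(
    system: MolecularSystem,
    frame: np.ndarray,
    step: float = 1e-4,
    params: EnergyModelParams = DEFAULT_PARAMS,
    include_solvation: bool = True,
) -> np.ndarray:
    """3N x 3N Hessian by central differences of the gradient, symmetrized."""
    frame = np.asarray(frame, dtype=float)
    flat = frame.ravel().copy()
    m = flat.size
    h = np.empty((m, m))
    for k in range(m):
        orig = flat[k]
        flat[k] = orig + step
        gp = total_gradient(system, flat.reshape(-1, 3), params, include_solvation).ravel()
        flat[k] = orig - step
        gm = total_gradient(system, flat.reshape(-1, 3), params, include_solvation).ravel()
        flat[k] = orig
        h[:, k] = (gp - gm) / (2.0 * step)
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite Hessian entries")
    return 0.5 * (h + h.T)


def normal_modes(
    hess: np.ndarray,
    masses: np.ndarray,
    zero_threshold: float = 1.0,
) -> tuple[np.ndarray, int, int]:
    """Frequencies (cm^-1) of the mass-weighted Hessian.

    Returns (genuine frequencies ascending, n_zero_modes, n_imaginary).
    Modes with |nu| below ``zero_threshold`` cm^-1 are treated as
    rigid-body translations/rotations; eigenvalues that map to negative
    curvature beyond the threshold count as imaginary.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    w = np.repeat(1.0 / np.sqrt(masses), 3)
    mw = hess * w[:, None] * w[None, :]
    evals = np.linalg.eigvalsh(mw)
    nu = np.sign(evals) * np.sqrt(np.abs(evals)) * _WAVENUMBER
    zero = np.abs(nu) < zero_threshold
    imag = (nu <= -zero_threshold)
    genuine = np.sort(nu[~zero & ~imag])
    return genuine, int(zero.sum()), int(imag.sum())


def vibrational_entropy(frequencies: np.ndarray, temperature: float) -> float:
    """Harmonic-oscillator vibrational entropy, kcal/(mol*K).

    S = R sum_i [ x/(e^x - 1) - ln(1 - e^-x) ] with x = h c nu / (kB T).
    """
    nu = np.asarray(frequencies, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("vibrational entropy requires strictly positive frequencies")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = nu * _CM_TO_K / temperature
    with np.errstate(over="ignore"):
        s = x / np.expm1(x) - np.log(-np.expm1(-x))
    return float(GAS_CONSTANT * np.nan_to_num(s, nan=0.0).sum())


def analyze_species(
    system: MolecularSystem,
    frame: np.ndarray,
    temperature: float = 300.0,
    params: EnergyModelParams = DEFAULT_PARAMS,
    include_solvation: bool = True,
    gradient_tol: float = 1e-4,
    zero_threshold: float = 1.0,
    linear: bool | None = None,
) -> NormalModeResult:
    """Minimize one species and compute its vibrational entropy."""
    mini = minimize(system, frame, gradient_tol=gradient_tol, params=params,
                    include_solvation=include_solvation)
    h = hessian(system, mini.frame, params=params, include_solvation=include_solvation)
    freqs, n_zero, n_imag = normal_modes(h, system.masses, zero_threshold)
    s = vibrational_entropy(freqs, temperature) if (n_imag == 0 and len(freqs)) else (
        0.0 if len(freqs) == 0 else None
    )
    return NormalModeResult(
        frequencies=freqs,
        n_zero_modes=n_zero,
        n_imaginary=n_imag,
        s_vib=s,
        minimized_energy=mini.energy,
        gradient_rms=mini.gradient_rms,
    )


def entropy_term(
    system: MolecularSystem,
    trajectory,
    receptor_group,
    ligand_group,
    temperature: float = 300.0,
    n_snapshots: int = 5,
    params: EnergyModelParams = DEFAULT_PARAMS,
    include_solvation: bool = True,
) -> EntropyTermResult:
    """T*dS of binding from normal modes on a thinned snapshot subset.

    For each selected frame the complex, receptor and ligand are
    minimized independently (receptor/ligand starting from their bound
    coordinates); T*dS = T*(S_cplx - S_rcpt - S_lig).  Snapshots whose
    minimization leaves imaginary modes in any species are dropped and
    logged.  The standard error is sd/sqrt(N) over used snapshots.
    """
    ir = _indices(system, receptor_group)
    il = _indices(system, ligand_group)
    if len(il) == 0:
        raise ValueError("empty ligand group")
    if len(ir) == 0:
        raise ValueError("empty receptor group")
    frames = trajectory.frames if hasattr(trajectory, "frames") else np.asarray(trajectory)
    if frames.ndim == 2:
        frames = frames[None]
    pick = np.unique(np.linspace(0, len(frames) - 1, min(n_snapshots, len(frames))).astype(int))
    rec_sys = extract_subsystem(system, ir)
    lig_sys = extract_subsystem(system, il)
    rows = []
    values = []
    for k in pick:
        frame = frames[k]
        res_c = analyze_species(system, frame, temperature, params, include_solvation)
        res_r = analyze_species(rec_sys, frame[ir], temperature, params, include_solvation)
        res_l = analyze_species(lig_sys, frame[il], temperature, params, include_solvation)
        n_imag = res_c.n_imaginary + res_r.n_imaginary + res_l.n_imaginary
        ok = n_imag == 0 and None not in (res_c.s_vib, res_r.s_vib, res_l.s_vib)
        tds = temperature * (res_c.s_vib - res_r.s_vib - res_l.s_vib) if ok else np.nan
        rows.append(
            {
                "snapshot": int(k),
                "S_cplx": res_c.s_vib,
                "S_rcpt": res_r.s_vib,
                "S_lig": res_l.s_vib,
                "TdS": tds,
                "n_imaginary": n_imag,
            }
        )
        if ok:
            values.append(tds)
    if not values:
        raise ValueError("all snapshots dropped (imaginary modes)")
    values_arr = np.array(values)
    sigma = float(values_arr.std(ddof=1) / math.sqrt(len(values_arr))) if len(values_arr) > 1 else 0.0
    return EntropyTermResult(
        t_delta_s=float(values_arr.mean()),
        sigma=sigma,
        temperature=temperature,
        n_used=len(values_arr),
        n_dropped=len(pick) - len(values_arr),
        log=pd.DataFrame(rows),
    )
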