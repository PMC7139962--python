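"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately written as explicit
double loops with the formulas transcribed from first principles, so
they share no code path with the package's vectorized engine.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ribostate.molsys import AtomRecord, Bond, MolecularSystem
from ribostate.synthetic_data import ToySystemSpec, make_toy_system, receptor_ligand_split

K_COULOMB = 332.0637


# ---------------------------------------------------------------------------
# oracle energy implementations (naive double loops)
# ---------------------------------------------------------------------------


def oracle_coulomb_inter(system, frame, ia, ib):
    e = 0.0
    for i in ia:
        for j in ib:
            r = math.dist(frame[i], frame[j])
            e += K_COULOMB * system.atoms[i].charge * system.atoms[j].charge / r
    return e


def oracle_coulomb_intra(system, frame, ele_14_scale=1.0 / 1.2):
    n = system.n_atoms
    excl = {tuple(sorted(p)) for p in system.exclusions_12_13}
    p14 = {tuple(sorted(p)): s for p, s in system.pairs_14.items()}
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            key = (i, j)
            if key in excl:
                continue
            scale = p14[key][0] if key in p14 else 1.0
            if scale is None:
                scale = ele_14_scale
            r = math.dist(frame[i], frame[j])
            e += scale * K_COULOMB * system.atoms[i].charge * system.atoms[j].charge / r
    return e


def oracle_lj(system, frame, ia, ib):
    e = 0.0
    for i in ia:
        for j in ib:
            ai, aj = system.atoms[i], system.atoms[j]
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            eps = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            r = math.dist(frame[i], frame[j])
            x6 = (rmin / r) ** 6
            e += eps * (x6 * x6 - 2.0 * x6)
    return e


def oracle_born_radii(system, frame, indices, alpha=1.0, beta=0.8, gamma=4.85, offset=0.09):
    """OBC radii via the pairwise descreening integral, explicit loops."""
    idx = list(indices)
    radii = []
    for i in idx:
        rho_int = system.atoms[i].gb_radius
        rho = rho_int - offset
        integral = 0.0
        for j in idx:
            if j == i:
                continue
            s = system.atoms[j].gb_screen * (system.atoms[j].gb_radius - offset)
            r = math.dist(frame[i], frame[j])
            if rho >= r + s or s <= 0:
                continue
            upper = r + s
            lower = max(rho, abs(r - s))
            term = 0.5 * (
                (1.0 / lower - 1.0 / upper)
                + 0.25 * r * (1.0 / upper**2 - 1.0 / lower**2)
                + 0.5 / r * math.log(lower / upper)
                + 0.25 * s * s / r * (1.0 / lower**2 - 1.0 / upper**2)
            )
            if rho < s - r:
                term += 1.0 / rho - 1.0 / lower
            integral += term
        psi = integral * rho
        t = math.tanh(alpha * psi - beta * psi**2 + gamma * psi**3)
        radii.append(1.0 / (1.0 / rho - t / rho_int))
    return np.array(radii)


def oracle_gb_energy(system, frame, indices, eps_in=1.0, eps_out=80.0):
    idx = list(indices)
    radii = oracle_born_radii(system, frame, idx)
    tau = 1.0 / eps_in - 1.0 / eps_out
    e = 0.0
    for a, i in enumerate(idx):
        for b, j in enumerate(idx):
            r2 = sum((frame[i][k] - frame[j][k]) ** 2 for k in range(3))
            rr = radii[a] * radii[b]
            fgb = math.sqrt(r2 + rr * math.exp(-r2 / (4.0 * rr)))
            e += system.atoms[i].charge * system.atoms[j].charge / fgb
    return -0.5 * K_COULOMB * tau * e


def oracle_two_sphere_sasa(r1, r2, d, probe):
    """Analytic accessible area of two intersecting augmented spheres."""
    e1, e2 = r1 + probe, r2 + probe
    if d >= e1 + e2:
        return 4 * math.pi * (e1 * e1 + e2 * e2)
    area = 0.0
    for ra, rb in ((e1, e2), (e2, e1)):
        if d + ra <= rb:
            continue  # fully buried
        x = (d * d + ra * ra - rb * rb) / (2.0 * d)
        h = ra - x
        area += 4 * math.pi * ra * ra - 2 * math.pi * ra * max(0.0, h)
    return area


# ---------------------------------------------------------------------------
# system builders
# ---------------------------------------------------------------------------


def make_atom(i, resi=0, resname="MOL", author=1, **kw):
    element = kw.pop("element", "C")
    name = kw.pop("name", f"X{i + 1}")
    defaults = dict(mass=12.0, charge=0.0, lj_rmin_half=1.6, lj_epsilon=0.1,
                    gb_radius=1.7, gb_screen=0.8)
    defaults.update(kw)
    return AtomRecord(atom_id=i, name=name, element=element,
                      residue_index=resi, residue_name=resname, author_resid=author,
                      **defaults)


def diatomic(mass=12.0, k=500.0, r0=1.5):
    atoms = [make_atom(i, lj_rmin_half=0.0, lj_epsilon=0.0) for i in range(2)]
    for a in atoms:
        a.mass = mass
    return MolecularSystem(atoms, bonds=[Bond(0, 1, k, r0)], exclusions_12_13={(0, 1)})


@pytest.fixture
def toy_complex():
    """12-bead random complex (9 receptor + 3 ligand atoms), net neutral."""
    system, frame = make_toy_system(ToySystemSpec(n_atoms=12, n_ligand_atoms=3, seed=11))
    rec, lig = receptor_ligand_split(system)
    return system, frame, rec, lig


def random_toy(seed, n_atoms=None, n_ligand=3):
    rng = np.random.default_rng(seed)
    n = int(n_atoms if n_atoms is not None else rng.integers(6, 21))
    system, frame = make_toy_system(ToySystemSpec(n_atoms=n, n_ligand_atoms=min(n_ligand, n - 1),
                                                  seed=seed))
    return system, frame
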