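"""Published reference values for the riboswitch-ligand complexes.

Literature MM-PB/SA binding free energies (mean ± standard error over
10 replica simulations, kcal/mol) for five ligands — adenine (ADE),
2,6-diaminopurine (6AP) and the pyrimidine analogues 3AY, 3TT, 2DY —
bound to the C74U-mutated guanine riboswitch aptamer, GR(C74U), and to
the adenine riboswitch aptamer, AR; plus the reported open/closed state
percentages and pocket mass-center distances per complex.

These numbers are inputs to desk-scale consistency analyses: the
component rows are recombined through the package's own identities
(dH = dE_ele + dE_vdw + dE_int + dG_pol + dG_nonpol, dG_bind = dH -
TdS, ...) and correlated against the experimental affinities.  Energies
derived from trajectories we do not possess are never asserted, only
their printed arithmetic.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "LIGANDS",
    "APTAMERS",
    "binding_energy_table",
    "experimental_dg",
    "state_table",
]

LIGANDS = ("ADE", "6AP", "3AY", "3TT", "2DY")
APTAMERS = ("GR(C74U)", "AR")

# (ligand, aptamer) -> term -> (mean, sigma); sigma = sd / sqrt(10)
_BINDING: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("ADE", "GR(C74U)"): {
        "dE_ele": (-31.48, 0.45), "dE_vdw": (-25.45, 0.28), "dE_int": (1.42, 0.02),
        "dG_nonpol": (-2.86, 0.02), "dG_pol": (35.54, 0.72),
        "dG_ele_pol": (4.06, 0.46), "dG_vdw_nonpol": (-28.30, 0.28),
        "dH": (-22.83, 0.62), "TdS": (-13.31, 0.24), "dG_bind": (-9.53, 0.73),
    },
    ("ADE", "AR"): {
        "dE_ele": (-31.67, 0.61), "dE_vdw": (-25.98, 0.40), "dE_int": (1.48, 0.02),
        "dG_nonpol": (-2.84, 0.02), "dG_pol": (33.64, 0.91),
        "dG_ele_pol": (1.97, 0.43), "dG_vdw_nonpol": (-28.83, 0.39),
        "dH": (-25.38, 0.57), "TdS": (-13.62, 0.31), "dG_bind": (-11.76, 0.41),
    },
    ("6AP", "GR(C74U)"): {
        "dE_ele": (-34.35, 0.90), "dE_vdw": (-27.56, 0.32), "dE_int": (1.39, 0.02),
        "dG_nonpol": (-3.01, 0.02), "dG_pol": (36.35, 0.01),
        "dG_ele_pol": (2.00, 1.15), "dG_vdw_nonpol": (-30.57, 0.65),
        "dH": (-27.18, 0.31), "TdS": (-14.58, 0.79), "dG_bind": (-12.60, 0.40),
    },
    ("6AP", "AR"): {
        "dE_ele": (-36.87, 0.89), "dE_vdw": (-27.49, 0.38), "dE_int": (1.50, 0.02),
        "dG_nonpol": (-3.00, 0.02), "dG_pol": (36.45, 0.01),
        "dG_ele_pol": (-0.42, 0.89), "dG_vdw_nonpol": (-30.48, 0.18),
        "dH": (-29.40, 0.38), "TdS": (-14.03, 0.46), "dG_bind": (-15.37, 0.31),
    },
    ("3AY", "GR(C74U)"): {
        "dE_ele": (-30.77, 0.76), "dE_vdw": (-23.55, 0.42), "dE_int": (1.39, 0.02),
        "dG_nonpol": (-2.81, 0.01), "dG_pol": (34.63, 1.41),
        "dG_ele_pol": (3.85, 1.25), "dG_vdw_nonpol": (-26.36, 0.42),
        "dH": (-21.12, 1.42), "TdS": (-14.69, 0.33), "dG_bind": (-6.42, 1.55),
    },
    ("3AY", "AR"): {
        "dE_ele": (-29.49, 0.55), "dE_vdw": (-23.21, 0.47), "dE_int": (1.48, 0.02),
        "dG_nonpol": (-2.81, 0.01), "dG_pol": (32.31, 1.17),
        "dG_ele_pol": (2.81, 1.17), "dG_vdw_nonpol": (-26.01, 0.47),
        "dH": (-21.72, 1.18), "TdS": (-14.46, 0.28), "dG_bind": (-7.27, 0.98),
    },
    ("3TT", "GR(C74U)"): {
        "dE_ele": (-32.23, 1.09), "dE_vdw": (-22.90, 0.48), "dE_int": (1.40, 0.01),
        "dG_nonpol": (-2.75, 0.02), "dG_pol": (34.88, 1.50),
        "dG_ele_pol": (2.66, 1.60), "dG_vdw_nonpol": (-25.64, 0.47),
        "dH": (-21.59, 1.90), "TdS": (-15.29, 0.20), "dG_bind": (-6.30, 1.86),
    },
    ("3TT", "AR"): {
        "dE_ele": (-32.10, 0.49), "dE_vdw": (-22.48, 0.54), "dE_int": (1.45, 0.02),
        "dG_nonpol": (-2.76, 0.01), "dG_pol": (32.89, 1.06),
        "dG_ele_pol": (0.80, 1.13), "dG_vdw_nonpol": (-25.23, 0.54),
        "dH": (-22.98, 1.18), "TdS": (-15.30, 0.22), "dG_bind": (-7.68, 1.10),
    },
    ("2DY", "GR(C74U)"): {
        "dE_ele": (-25.57, 1.49), "dE_vdw": (-20.93, 0.44), "dE_int": (1.37, 0.02),
        "dG_nonpol": (-2.70, 0.01), "dG_pol": (29.52, 1.55),
        "dG_ele_pol": (3.96, 1.23), "dG_vdw_nonpol": (-23.63, 0.43),
        "dH": (-18.31, 1.06), "TdS": (-13.72, 0.25), "dG_bind": (-4.58, 1.21),
    },
    ("2DY", "AR"): {
        "dE_ele": (-24.71, 1.13), "dE_vdw": (-20.43, 0.44), "dE_int": (1.51, 0.02),
        "dG_nonpol": (-2.73, 0.01), "dG_pol": (28.74, 0.87),
        "dG_ele_pol": (4.03, 0.93), "dG_vdw_nonpol": (-23.17, 0.43),
        "dH": (-17.63, 1.10), "TdS": (-13.22, 0.22), "dG_bind": (-4.41, 1.14),
    },
}

# experimental dG = -RT ln Kd, kcal/mol (7 complexes with measured Kd)
_DG_EXP: dict[tuple[str, str], float] = {
    ("ADE", "GR(C74U)"): -8.78,
    ("ADE", "AR"): -9.20,
    ("6AP", "GR(C74U)"): -10.57,
    ("6AP", "AR"): -11.53,
    ("3AY", "GR(C74U)"): -6.45,
    ("3AY", "AR"): -7.82,
    ("3TT", "GR(C74U)"): -6.45,
}

# per-complex open/closed percentages and pocket distance (A): the
# mass-center distance between U51+A52 and C74+C75 backbone groups
_STATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "GR(C74U)": {
        "ADE": (19.82, 43.22, 10.08),
        "6AP": (18.33, 48.49, 10.00),
        "3AY": (19.44, 49.12, 10.25),
        "3TT": (11.76, 56.64, 9.89),
        "2DY": (18.69, 46.28, 10.38),
    },
    "AR": {
        "ADE": (19.82, 43.22, 10.08),
        "6AP": (23.83, 39.74, 10.07),
        "3AY": (15.88, 52.27, 10.14),
        "3TT": (13.26, 55.36, 10.06),
        "2DY": (28.23, 35.44, 10.59),
    },
}


def binding_energy_table() -> pd.DataFrame:
    """Long-form energy table: one row per (ligand, aptamer, term).

    Columns: ligand, aptamer, term, mean, sigma.
    """
    rows = []
    for (ligand, aptamer), terms in _BINDING.items():
        for term, (mean, sigma) in terms.items():
            rows.append(
                {"ligand": ligand, "aptamer": aptamer, "term": term, "mean": mean, "sigma": sigma}
            )
    return pd.DataFrame(rows)


def experimental_dg() -> pd.DataFrame:
    """Experimental binding free energies for the seven measured complexes."""
    rows = [
        {"ligand": lig, "aptamer": apt, "dG_exp": v} for (lig, apt), v in _DG_EXP.items()
    ]
    return pd.DataFrame(rows)


def state_table() -> pd.DataFrame:
    """Per-complex state percentages and pocket distances.

    Columns: aptamer, ligand, pct_open, pct_closed, distance.
    """
    rows = []
    for aptamer, per_lig in _STATES.items():
        for lig, (p_open, p_closed, dist) in per_lig.items():
            rows.append(
                {
                    "aptamer": aptamer,
                    "ligand": lig,
                    "pct_open": p_open,
                    "pct_closed": p_closed,
                    "distance": dist,
                }
            )
    return pd.DataFrame(rows)
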