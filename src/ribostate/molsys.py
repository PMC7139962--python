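"""Molecular system and trajectory data model.

Holds the solute-only, implicit-solvent view of a nucleic-acid/ligand
complex used throughout the package: an ordered atom table carrying
point charges, Lennard-Jones parameters, generalized-Born radii and
screening factors, plus bonded topology (bonds, 1-2/1-3 exclusions and
scaled 1-4 pairs).  Coordinates are always in Angstrom, masses in amu,
charges in elementary charge units, energies downstream in kcal/mol.

Author (PDB) residue numbering is preserved verbatim on every atom and
used in all reports, so labels match the crystallographic convention
(U51, C74, ...); internal residue indices are 0-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "Bond",
    "Residue",
    "MolecularSystem",
    "Trajectory",
    "AtomGroup",
    "PDBFormatError",
    "ParameterizationError",
    "SelectionError",
    "EmptySelectionWarning",
    "load_structure",
    "load_trajectory",
    "load_parameters",
    "parse_parameter_table",
    "select_atoms",
    "center_of_mass",
    "extract_subsystem",
    "write_pdb",
    "write_atom_table",
]


class PDBFormatError(ValueError):
    """Raised for unparsable or structurally inconsistent PDB input."""


class ParameterizationError(ValueError):
    """Raised when a parameter table does not cover the system."""


class SelectionError(ValueError):
    """Raised for syntax errors in atom-selection expressions."""


class EmptySelectionWarning(UserWarning):
    """Emitted when a syntactically valid selection matches no atoms."""


@dataclass
class AtomRecord:
    """One atom with force-field and solvation parameters.

    ``author_resid`` is the residue number as printed in the source PDB
    file; it is never renumbered.
    """

    atom_id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    author_resid: int
    mass: float = 0.0
    charge: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0
    gb_radius: float = 0.0
    gb_screen: float = 0.0
    bfactor: float = 0.0


@dataclass(frozen=True)
class Bond:
    """Harmonic bond i-j with E = (k/2)(r - r0)^2, k in kcal/(mol A^2)."""

    i: int
    j: int
    force_constant: float
    equilibrium: float


@dataclass(frozen=True)
class Residue:
    residue_name: str
    author_resid: int
    start: int  # first atom index
    stop: int  # one past last atom index


@dataclass
class MolecularSystem:
    atoms: list[AtomRecord]
    bonds: list[Bond] = field(default_factory=list)
    exclusions_12_13: set[tuple[int, int]] = field(default_factory=set)
    # pair -> (ele_scale, vdw_scale)
    pairs_14: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate_topology()

    # -- topology checks -------------------------------------------------
    def _validate_topology(self) -> None:
        n = len(self.atoms)
        for pair in self.exclusions_12_13 | set(self.pairs_14):
            i, j = pair
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid atom pair {pair}")
        overlap = self.exclusions_12_13 & set(self.pairs_14)
        if overlap:
            raise ValueError(f"exclusion and 1-4 sets overlap: {sorted(overlap)}")
        for b in self.bonds:
            key = (min(b.i, b.j), max(b.i, b.j))
            if key not in self.exclusions_12_13:
                raise ValueError(f"bonded pair {key} missing from exclusions_12_13")

    # -- derived views ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        for a in self.atoms:
            if out and a.residue_index == len(out) - 1:
                out[-1] = replace(out[-1], stop=a.atom_id + 1)
            else:
                if a.residue_index != len(out):
                    raise ValueError("residue_index values are not contiguous")
                out.append(Residue(a.residue_name, a.author_resid, a.atom_id, a.atom_id + 1))
        return out

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return self.array("mass")

    @property
    def charges(self) -> np.ndarray:
        return self.array("charge")

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def all_atoms(self) -> "AtomGroup":
        return AtomGroup(self, np.arange(self.n_atoms))


@dataclass
class Trajectory:
    """Ordered coordinate frames (n_frames, n_atoms, 3) in Angstrom."""

    frames: np.ndarray
    frame_interval: float = 10.0  # ps
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


class AtomGroup:
    """Ordered, duplicate-free subset of a system's atoms."""

    def __init__(self, system: MolecularSystem, indices) -> None:
        idx = np.asarray(indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate atom indices in group")
        if len(idx) and (idx.min() < 0 or idx.max() >= system.n_atoms):
            raise ValueError("atom index out of range")
        self.system = system
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def __and__(self, other: "AtomGroup") -> "AtomGroup":
        mask = np.isin(self.indices, other.indices)
        return AtomGroup(self.system, self.indices[mask])

    def __or__(self, other: "AtomGroup") -> "AtomGroup":
        merged = np.union1d(self.indices, other.indices)
        return AtomGroup(self.system, merged)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [self.system.atoms[i] for i in self.indices]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_ELEMENT_TWO = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE"}


def _infer_element(name: str) -> str:
    stripped = name.strip()
    head = "".join(c for c in stripped if not c.isdigit())
    if head[:2].upper() in _ELEMENT_TWO:
        return head[:2].capitalize()
    return head[:1].upper() if head else "X"


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        resname = line[17:21].strip()
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"unparsable ATOM/HETATM record at line {lineno}: {exc}") from exc
    if altloc not in ("", "A"):
        raise PDBFormatError(f"alternate location '{altloc}' at line {lineno} not supported")
    bfac_field = line[60:66].strip()
    bfactor = float(bfac_field) if bfac_field else 0.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name)
    else:
        element = element.capitalize()
    chain = line[21:22]
    icode = line[26:27]
    return name, resname, resseq, chain, icode, (x, y, z), bfactor, element


def _parse_models(pdb_text: str):
    """Split PDB text into per-model atom record lists."""
    models: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    saw_model_kw = False
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model_kw = True
            if current:
                models.append(current)
                current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBFormatError("no ATOM/HETATM records found")
    del in_model, saw_model_kw
    return models


def _system_from_records(records: list[tuple]) -> tuple[MolecularSystem, np.ndarray]:
    atoms: list[AtomRecord] = []
    coords = np.empty((len(records), 3))
    res_key = None
    res_index = -1
    for i, (name, resname, resseq, chain, icode, xyz, bfac, element) in enumerate(records):
        key = (chain, resseq, icode, resname)
        if key != res_key:
            res_index += 1
            res_key = key
        atoms.append(
            AtomRecord(
                atom_id=i,
                name=name,
                element=element,
                residue_index=res_index,
                residue_name=resname,
                author_resid=resseq,
                bfactor=bfac,
            )
        )
        coords[i] = xyz
    return MolecularSystem(atoms), coords


def load_structure(pdb_text: str) -> tuple[MolecularSystem, np.ndarray]:
    """Parse single-model PDB text into a system skeleton plus coordinates.

    Multi-model input is accepted with a warning; only the first model's
    coordinates are returned.  Parameters (charges, LJ, GB, masses) are
    left zero until :func:`load_parameters` fills them.
    """
    models = _parse_models(pdb_text)
    if len(models) > 1:
        warnings.warn(
            f"input contains {len(models)} models; using model 1 only", UserWarning, stacklevel=2
        )
    return _system_from_records(models[0])


def load_trajectory(pdb_text: str, frame_interval: float = 10.0, replica_id: int = 0) -> Trajectory:
    """Parse multi-model PDB text into a Trajectory (one frame per model)."""
    models = _parse_models(pdb_text)
    n0 = len(models[0])
    for k, m in enumerate(models):
        if len(m) != n0:
            raise PDBFormatError(
                f"model {k + 1} has {len(m)} atoms but model 1 has {n0}"
            )
    frames = np.array([[rec[5] for rec in m] for m in models], dtype=float)
    return Trajectory(frames=frames, frame_interval=frame_interval, replica_id=replica_id)


def write_pdb(system: MolecularSystem, frames: np.ndarray) -> str:
    """Serialize one or more frames as (multi-)model PDB text."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    lines: list[str] = []
    multi = frames.shape[0] > 1
    for m, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for a, xyz in zip(system.atoms, frame):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.atom_id + 1:5d} {name:<4s} {a.residue_name:<3.3s} "
                f"{a.author_resid:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{a.bfactor:6.2f}          {a.element:>2.2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

_PARAM_HEADER = ["atom_key", "mass", "charge", "rmin_half", "epsilon", "gb_radius", "gb_screen"]


def parse_parameter_table(text: str) -> dict[str, tuple[float, ...]]:
    """Parse the tab-separated parameter table into a key -> values map.

    Keys are either ``RESNAME:ATOMNAME`` or a bare integer atom id.
    """
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise ParameterizationError("empty parameter table")
    header = rows[0].split("\t")
    if [h.strip() for h in header] != _PARAM_HEADER:
        raise ParameterizationError(
            f"parameter table header must be {_PARAM_HEADER}, got {header}"
        )
    table: dict[str, tuple[float, ...]] = {}
    for ln in rows[1:]:
        parts = ln.split("\t")
        if len(parts) != len(_PARAM_HEADER):
            raise ParameterizationError(f"malformed parameter row: {ln!r}")
        key = parts[0].strip()
        vals = tuple(float(p) for p in parts[1:])
        if key in table and table[key] != vals:
            raise ParameterizationError(f"duplicate key {key!r} with conflicting values")
        table[key] = vals
    return table


def load_parameters(param_table: str, system: MolecularSystem) -> MolecularSystem:
    """Populate mass/charge/LJ/GB fields from a columnar table.

    Every atom must be covered by either its ``RESNAME:NAME`` key or its
    integer atom id (the id key wins when both are present).
    """
    table = parse_parameter_table(param_table)
    missing = []
    for a in system.atoms:
        vals = table.get(str(a.atom_id))
        if vals is None:
            vals = table.get(f"{a.residue_name}:{a.name}")
        if vals is None:
            missing.append(f"{a.residue_name}{a.author_resid}:{a.name}")
            continue
        a.mass, a.charge, a.lj_rmin_half, a.lj_epsilon, a.gb_radius, a.gb_screen = vals
        if a.mass <= 0:
            raise ParameterizationError(f"non-positive mass for atom {a.atom_id}")
        if a.gb_radius <= 0:
            raise ParameterizationError(f"non-positive GB radius for atom {a.atom_id}")
    if missing:
        raise ParameterizationError("atoms without parameters: " + ", ".join(missing))
    return system


def write_atom_table(system: MolecularSystem) -> str:
    """Dump the atom table (with parameters) as TSV."""
    lines = ["\t".join(_PARAM_HEADER)]
    for a in system.atoms:
        lines.append(
            f"{a.residue_name}:{a.name}\t{a.mass:.6g}\t{a.charge:.6g}\t"
            f"{a.lj_rmin_half:.6g}\t{a.lj_epsilon:.6g}\t{a.gb_radius:.6g}\t{a.gb_screen:.6g}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or", "not", "(", ")"}
_FIELDS = {"resid", "name", "resname"}


def _tokenize(expr: str):
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser for the tiny selection grammar.

    expr   := term (or term)*
    term   := factor (and factor)*
    factor := not factor | ( expr ) | field value+
    """

    def __init__(self, system: MolecularSystem, expr: str) -> None:
        self.system = system
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self._expr()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r} at position {at}")
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self.peek()[0] == "or":
            self.pos += 1
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self.peek()[0] == "and":
            self.pos += 1
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok, at = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of expression at position {at}")
        if tok == "not":
            self.pos += 1
            return ~self._factor()
        if tok == "(":
            self.pos += 1
            mask = self._expr()
            tok2, at2 = self.peek()
            if tok2 != ")":
                raise SelectionError(f"missing ')' at position {at2}")
            self.pos += 1
            return mask
        if tok in _FIELDS:
            self.pos += 1
            values: list[str] = []
            while True:
                nxt, _ = self.peek()
                if nxt is None or nxt in _KEYWORDS or nxt in _FIELDS:
                    break
                values.append(nxt)
                self.pos += 1
            if not values:
                raise SelectionError(f"field {tok!r} at position {at} needs at least one value")
            return self._match(tok, values, at)
        raise SelectionError(f"unexpected token {tok!r} at position {at}")

    def _match(self, fieldname: str, values: list[str], at: int) -> np.ndarray:
        atoms = self.system.atoms
        if fieldname == "resid":
            try:
                wanted = {int(v) for v in values}
            except ValueError as exc:
                raise SelectionError(f"non-integer resid near position {at}: {exc}") from exc
            return np.array([a.author_resid in wanted for a in atoms])
        if fieldname == "name":
            wanted_s = set(values)
            return np.array([a.name in wanted_s for a in atoms])
        wanted_s = set(values)
        return np.array([a.residue_name in wanted_s for a in atoms])


def select_atoms(system: MolecularSystem, expr: str) -> AtomGroup:
    """Select atoms by a boolean expression over resid/name/resname.

    Example: ``"resid 51 74 and name P"``; ``resid`` refers to author
    (PDB) numbering.  An empty result is legal but warned about.
    """
    mask = _Parser(system, expr).parse()
    indices = np.nonzero(mask)[0]
    if len(indices) == 0:
        warnings.warn(f"selection {expr!r} matched no atoms", EmptySelectionWarning, stacklevel=2)
    return AtomGroup(system, indices)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def center_of_mass(group: AtomGroup, frame: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of the group in the given frame."""
    if len(group) == 0:
        raise ValueError("center of mass of an empty group")
    frame = np.asarray(frame, dtype=float)
    m = group.system.masses[group.indices]
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass; are parameters loaded?")
    return (m[:, None] * frame[group.indices]).sum(axis=0) / total


def extract_subsystem(system: MolecularSystem, indices) -> MolecularSystem:
    """Build a standalone system from a subset of atoms.

    Bonds, exclusions and 1-4 pairs wholly inside the subset are kept and
    reindexed; residue indices are recompacted while author numbering is
    preserved.
    """
    idx = np.asarray(indices, dtype=int)
    old2new = {int(o): n for n, o in enumerate(idx)}
    atoms: list[AtomRecord] = []
    res_map: dict[int, int] = {}
    for n, o in enumerate(idx):
        a = system.atoms[int(o)]
        if a.residue_index not in res_map:
            res_map[a.residue_index] = len(res_map)
        atoms.append(replace(a, atom_id=n, residue_index=res_map[a.residue_index]))
    bonds = [
        Bond(old2new[b.i], old2new[b.j], b.force_constant, b.equilibrium)
        for b in system.bonds
        if b.i in old2new and b.j in old2new
    ]
    excl = {
        (min(old2new[i], old2new[j]), max(old2new[i], old2new[j]))
        for (i, j) in system.exclusions_12_13
        if i in old2new and j in old2new
    }
    p14 = {
        (min(old2new[i], old2new[j]), max(old2new[i], old2new[j])): sc
        for (i, j), sc in system.pairs_14.items()
        if i in old2new and j in old2new
    }
    return MolecularSystem(atoms, bonds=bonds, exclusions_12_13=excl, pairs_14=p14)


def pairwise_distances(frame: np.ndarray) -> np.ndarray:
    diff = frame[:, None, :] - frame[None, :, :]
    return np.sqrt((diff * diff).sum(axis=-1))


def rigid_transform(frame: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply r' = R r + t to every atom (used in invariance tests and fixtures)."""
    return frame @ np.asarray(rotation).T + np.asarray(translation)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def kabsch_rotation(ref: np.ndarray, mobile: np.ndarray, weights=None):
    # retained for backward import convenience; canonical home is traj_geometry
    from .traj_geometry import kabsch_superpose

    return kabsch_superpose(ref, mobile, weights)


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
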