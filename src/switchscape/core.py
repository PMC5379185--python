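"""Structure/ensemble data model, file I/O and geometric primitives.

This module holds the containers every other stage consumes — a
:class:`Topology` (atom identity, author residue numbering, optional
charges/Lennard-Jones parameters and group tags) and a
:class:`ConformationalEnsemble` (frames of coordinates over one topology) —
plus the geometric primitives: signed dihedral angles, internal-coordinate
backbone reconstruction, Kabsch superposition RMSD, RMSF and
minimum-distance series.

Internal unit system: Angstrom, kcal/mol, ps, radians.  File interfaces
report degrees where that is conventional (dihedral tables).

Residue numbering follows the source file throughout ("author numbering"):
a Switch I loop spanning residues 28-40 keeps those ids end to end, so
selections like ``resid 28-40 and name CA`` read as in the literature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import (
    AlignmentError,
    ConsistencyError,
    DihedralError,
    GeometryError,
    ParseError,
    SelectionError,
    SizeError,
)

# ---------------------------------------------------------------------------
# Constants (single internal unit system: A, kcal/mol, ps, rad)
# ---------------------------------------------------------------------------

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872041
#: Default analysis temperature, K
DEFAULT_TEMPERATURE = 300.0
#: kT at 300 K, kcal/mol
KT_300 = KB_KCAL * DEFAULT_TEMPERATURE

#: Residue names treated as water when inferring group tags.
WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "SPC"}
#: Residue names treated as nucleotide.
NUCLEOTIDE_RESNAMES = {"GTP", "GDP", "GNP", "GSP", "ATP", "ADP"}
#: Residue names treated as (monatomic) ions.
ION_RESNAMES = {"MG", "NA", "CL", "K", "CA2", "ZN", "MN"}

#: Standard amino-acid residue names (used for group inference).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: chi1 terminal atom per residue type (N-CA-CB-<this atom>); None = no chi1.
CHI1_ATOMS = {
    "ALA": None, "GLY": None,
    "VAL": "CG1", "ILE": "CG1", "THR": "OG1", "SER": "OG", "CYS": "SG",
    # default for everything else (incl. TYR, PHE, TRP, LEU, ...) is CG
}

#: Ideal backbone internal coordinates used by rebuild_backbone.
BACKBONE_GEOMETRY = {
    "bond_n_ca": 1.458,     # A
    "bond_ca_c": 1.525,     # A
    "bond_c_n": 1.329,      # A
    "angle_n_ca_c": math.radians(111.2),
    "angle_ca_c_n": math.radians(116.2),
    "angle_c_n_ca": math.radians(121.7),
    "omega": math.pi,       # trans peptide bond
}


def chi1_terminal_atom(res_name: str) -> str | None:
    """Name of the fourth chi1 atom for a residue type (None if undefined)."""
    return CHI1_ATOMS.get(res_name.upper(), "CG")


def infer_group(res_name: str) -> str:
    """Default group tag from the residue name."""
    rn = res_name.upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in NUCLEOTIDE_RESNAMES:
        return "nucleotide"
    if rn in ION_RESNAMES:
        return "ion"
    if rn in AMINO_ACIDS:
        return "protein"
    return "other"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

VALID_GROUPS = ("protein", "water", "nucleotide", "ion", "other")


@dataclass
class Topology:
    """Per-atom identity and (optional) nonbonded parameters.

    ``charge`` (elementary charges), ``lj_epsilon`` (kcal/mol) and
    ``lj_rmin_half`` (A, Rmin/2 convention) may be None as long as the
    ensemble never reaches the energetics operations.
    """

    atom_id: np.ndarray
    atom_name: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    element: np.ndarray
    charge: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    lj_rmin_half: np.ndarray | None = None
    group: np.ndarray | None = None

    def __post_init__(self):
        self.atom_id = np.asarray(self.atom_id, dtype=int)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        n = len(self.atom_id)
        for name in ("atom_name", "res_id", "res_name", "element"):
            if len(getattr(self, name)) != n:
                raise ConsistencyError(f"topology field {name!r} length mismatch")
        if n and not np.all(np.diff(self.atom_id) > 0):
            raise ConsistencyError("atom_id must be unique and strictly increasing")
        if self.group is None:
            self.group = np.array([infer_group(rn) for rn in self.res_name],
                                  dtype=object)
        else:
            self.group = np.asarray(self.group, dtype=object)
            bad = set(self.group) - set(VALID_GROUPS)
            if bad:
                raise ConsistencyError(f"unknown group tag(s): {sorted(bad)}")
        for name in ("charge", "lj_epsilon", "lj_rmin_half"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if arr.shape != (n,):
                    raise ConsistencyError(f"topology field {name!r} length mismatch")
                setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    @property
    def has_parameters(self) -> bool:
        return (self.charge is not None and self.lj_epsilon is not None
                and self.lj_rmin_half is not None)

    def residue_ids(self) -> np.ndarray:
        """Distinct residue ids in order of first appearance."""
        _, idx = np.unique(self.res_id, return_index=True)
        return self.res_id[np.sort(idx)]


@dataclass
class ConformationalEnsemble:
    """Ordered frames of coordinates (A) over a single topology."""

    topology: Topology
    coords: np.ndarray                    # (n_frames, n_atoms, 3)
    times: np.ndarray | None = None       # ps, strictly increasing

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConsistencyError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ConsistencyError("ensemble needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ConsistencyError(
                f"coords have {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}")
        if not np.all(np.isfinite(self.coords)):
            raise ConsistencyError("non-finite coordinates")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.coords.shape[0],):
                raise ConsistencyError("times length must match n_frames")
            if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
                raise ConsistencyError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def select(self, spec: str) -> np.ndarray:
        return select_atoms(self, spec)

    def subset_frames(self, indices) -> "ConformationalEnsemble":
        times = self.times[indices] if self.times is not None else None
        return ConformationalEnsemble(self.topology, self.coords[indices], times)


@dataclass
class DihedralSeries:
    """Per-frame dihedral angles (radians, wrapped to (-pi, pi])."""

    labels: list  # [(res_id, angle_name)], angle_name in {phi, psi, chi1}
    values: np.ndarray  # (n_frames, n_angles)

    def __post_init__(self):
        self.labels = [(int(r), str(a)) for r, a in self.labels]
        if len(set(self.labels)) != len(self.labels):
            raise ConsistencyError("duplicate dihedral labels")
        self.values = wrap_angle(np.asarray(self.values, dtype=float))
        if self.values.ndim == 1:
            self.values = self.values[None]
        if self.values.shape[1] != len(self.labels):
            raise ConsistencyError("one column per label required")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_angles(self) -> int:
        return self.values.shape[1]

    def row(self, i: int) -> "DihedralSeries":
        return DihedralSeries(self.labels, self.values[i:i + 1])

    def column(self, res_id: int, angle: str) -> np.ndarray:
        try:
            j = self.labels.index((int(res_id), angle))
        except ValueError:
            raise AlignmentError(f"no dihedral column ({res_id}, {angle})")
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table ``frame,resid,angle,value_deg``."""
        n_f, n_a = self.values.shape
        recs = []
        for j, (rid, ang) in enumerate(self.labels):
            for i in range(n_f):
                recs.append((i, rid, ang, math.degrees(self.values[i, j])))
        return pd.DataFrame(recs, columns=["frame", "resid", "angle", "value_deg"])


# ---------------------------------------------------------------------------
# Angle helpers
# ---------------------------------------------------------------------------

def wrap_angle(theta):
    """Wrap angle(s) to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = -((-theta + math.pi) % (2.0 * math.pi) - math.pi)
    return wrapped


def angular_difference(a, b):
    """Minimum-image signed difference a - b on the circle, in (-pi, pi]."""
    return wrap_angle(np.asarray(a) - np.asarray(b))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

SIDECAR_COLUMNS = ["atom_id", "charge", "epsilon", "rmin_half", "group"]


def _first_malformed_atom_line(path: Path) -> int | None:
    """Best-effort scan for the first ATOM/HETATM record with bad coordinates."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return lineno
    return None


def read_structure(path, topology_sidecar=None) -> ConformationalEnsemble:
    """Read a (multi-MODEL) PDB file or a whitespace coordinate table.

    The optional sidecar is a CSV keyed by ``atom_id`` with columns
    ``charge, epsilon, rmin_half, group`` supplying nonbonded parameters and
    group tags.  Author residue numbering is preserved.
    """
    path = Path(path)
    if path.suffix.lower() in {".pdb", ".ent"}:
        ens = _read_pdb(path)
    else:
        ens = _read_coordinate_table(path)
    if topology_sidecar is not None:
        _apply_sidecar(ens.topology, Path(topology_sidecar))
    return ens


def _read_pdb(path: Path) -> ConformationalEnsemble:
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises several types
        msg = str(exc)
        if "atoms" in msg.lower() and ("model" in msg.lower() or "unequal" in msg.lower()):
            raise ConsistencyError(
                f"{path}: MODELs contain different atom sets ({msg})") from exc
        lineno = _first_malformed_atom_line(path)
        where = f" at line {lineno}" if lineno else ""
        raise ParseError(f"{path}: malformed PDB record{where}: {msg}") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    element = np.asarray(stack.element, dtype=object)
    # biotite may leave the element blank for nonstandard files
    element = np.array(
        [e if e else str(a)[0] for e, a in zip(element, stack.atom_name)],
        dtype=object)
    topo = Topology(
        atom_id=np.arange(1, n_atoms + 1),
        atom_name=np.asarray(stack.atom_name, dtype=object),
        res_id=np.asarray(stack.res_id, dtype=int),
        res_name=np.asarray(stack.res_name, dtype=object),
        element=element,
    )
    return ConformationalEnsemble(topo, coords)


def _read_coordinate_table(path: Path) -> ConformationalEnsemble:
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse coordinate table: {exc}") from exc
    required = {"atom_name", "res_id", "res_name", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: coordinate table lacks columns {sorted(missing)}")
    if "frame" not in df.columns:
        df["frame"] = 0
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    n_atoms = len(first)
    coords = np.empty((len(frames), n_atoms, 3))
    for k, fr in enumerate(frames):
        sub = df[df["frame"] == fr]
        if len(sub) != n_atoms:
            raise ConsistencyError(
                f"{path}: frame {fr} has {len(sub)} atoms, expected {n_atoms}")
        coords[k] = sub[["x", "y", "z"]].to_numpy(dtype=float)
    element = (first["element"].astype(str).to_numpy(dtype=object)
               if "element" in df.columns
               else np.array([str(n)[0] for n in first["atom_name"]], dtype=object))
    topo = Topology(
        atom_id=(first["atom_id"].to_numpy(dtype=int)
                 if "atom_id" in df.columns else np.arange(1, n_atoms + 1)),
        atom_name=first["atom_name"].astype(str).to_numpy(dtype=object),
        res_id=first["res_id"].to_numpy(dtype=int),
        res_name=first["res_name"].astype(str).to_numpy(dtype=object),
        element=element,
    )
    return ConformationalEnsemble(topo, coords)


def _apply_sidecar(topo: Topology, sidecar: Path) -> None:
    try:
        df = pd.read_csv(sidecar)
    except Exception as exc:
        raise ParseError(f"{sidecar}: cannot parse sidecar CSV: {exc}") from exc
    missing = set(SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{sidecar}: sidecar lacks columns {sorted(missing)}")
    df = df.set_index("atom_id")
    ids = topo.atom_id
    absent = set(ids) - set(df.index)
    extra = set(df.index) - set(ids)
    if absent or extra:
        raise ConsistencyError(
            f"{sidecar}: sidecar atom_id mismatch "
            f"(missing {sorted(absent)[:5]}, unknown {sorted(extra)[:5]})")
    sub = df.loc[ids]
    topo.charge = sub["charge"].to_numpy(dtype=float)
    topo.lj_epsilon = sub["epsilon"].to_numpy(dtype=float)
    topo.lj_rmin_half = sub["rmin_half"].to_numpy(dtype=float)
    group = sub["group"].astype(str).to_numpy(dtype=object)
    bad = set(group) - set(VALID_GROUPS)
    if bad:
        raise ConsistencyError(f"{sidecar}: unknown group tag(s) {sorted(bad)}")
    topo.group = group


def write_structure(ens: ConformationalEnsemble, path, sidecar_path=None) -> None:
    """Write a multi-MODEL PDB (and optionally the topology sidecar CSV)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    n_f, n_a = ens.n_frames, ens.n_atoms
    stack = struc.AtomArrayStack(n_f, n_a)
    stack.coord = ens.coords.astype(np.float32)
    topo = ens.topology
    stack.chain_id = np.full(n_a, "A", dtype="U4")
    stack.res_id = topo.res_id.astype(int)
    stack.res_name = topo.res_name.astype("U5")
    stack.atom_name = topo.atom_name.astype("U6")
    stack.element = topo.element.astype("U2")
    stack.hetero = np.array([g != "protein" for g in topo.group])
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    if sidecar_path is not None:
        write_sidecar(topo, sidecar_path)


def write_sidecar(topo: Topology, path) -> None:
    """Write the ``atom_id,charge,epsilon,rmin_half,group`` sidecar CSV."""
    n = topo.n_atoms
    df = pd.DataFrame({
        "atom_id": topo.atom_id,
        "charge": topo.charge if topo.charge is not None else np.zeros(n),
        "epsilon": topo.lj_epsilon if topo.lj_epsilon is not None else np.zeros(n),
        "rmin_half": (topo.lj_rmin_half if topo.lj_rmin_half is not None
                      else np.zeros(n)),
        "group": topo.group,
    })
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_SELECTION_KEYWORDS = {"resid", "name", "group"}


def select_atoms(ens: ConformationalEnsemble, spec: str) -> np.ndarray:
    """Resolve a selection expression to a sorted array of atom indices.

    Grammar: conjunctions of clauses joined by ``and``; clauses are
    ``resid a-b`` (or a single id, or a comma list of either), ``name X``
    and ``group Y`` (comma lists allowed).  Empty selections are legal.
    """
    topo = ens.topology
    tokens = spec.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = np.ones(topo.n_atoms, dtype=bool)
    i = 0
    expect_clause = True
    while i < len(tokens):
        tok = tokens[i]
        if tok == "and":
            if expect_clause:
                raise SelectionError(f"misplaced 'and' in {spec!r}")
            expect_clause = True
            i += 1
            continue
        if tok not in _SELECTION_KEYWORDS:
            raise SelectionError(f"unknown token {tok!r} in selection {spec!r}")
        if i + 1 >= len(tokens):
            raise SelectionError(f"keyword {tok!r} lacks a value in {spec!r}")
        value = tokens[i + 1]
        mask &= _clause_mask(topo, tok, value, spec)
        expect_clause = False
        i += 2
    if expect_clause:
        raise SelectionError(f"trailing 'and' in {spec!r}")
    return np.flatnonzero(mask)


def _clause_mask(topo: Topology, keyword: str, value: str, spec: str) -> np.ndarray:
    parts = value.split(",")
    mask = np.zeros(topo.n_atoms, dtype=bool)
    if keyword == "resid":
        for part in parts:
            if "-" in part[1:]:  # allow negative ids just in case
                lo_s, hi_s = part.rsplit("-", 1)
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError:
                    raise SelectionError(f"bad resid range {part!r} in {spec!r}")
                mask |= (topo.res_id >= lo) & (topo.res_id <= hi)
            else:
                try:
                    rid = int(part)
                except ValueError:
                    raise SelectionError(f"bad resid {part!r} in {spec!r}")
                mask |= topo.res_id == rid
    elif keyword == "name":
        for part in parts:
            mask |= topo.atom_name == part
    elif keyword == "group":
        for part in parts:
            if part not in VALID_GROUPS:
                raise SelectionError(f"unknown group {part!r} in {spec!r}")
            mask |= topo.group == part
    return mask


# ---------------------------------------------------------------------------
# Dihedral primitives
# ---------------------------------------------------------------------------

_COLLINEAR_TOL = 1e-8


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (rad) of the chain p1-p2-p3-p4, IUPAC convention.

    cis = 0, trans = pi; positive for a right-handed twist about p2->p3.
    """
    return float(dihedral_batch(np.asarray([p1], float), np.asarray([p2], float),
                                np.asarray([p3], float), np.asarray([p4], float))[0])


def dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorised signed dihedral for stacked points of shape (..., 3)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    b1n = np.linalg.norm(b1, axis=-1, keepdims=True)
    if np.any(b1n < _COLLINEAR_TOL):
        raise GeometryError("central bond has zero length")
    b1u = b1 / b1n
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    nv = np.linalg.norm(v, axis=-1)
    nw = np.linalg.norm(w, axis=-1)
    if np.any(nv < _COLLINEAR_TOL) or np.any(nw < _COLLINEAR_TOL):
        raise GeometryError("collinear points: dihedral undefined")
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    ang = np.arctan2(y, x)
    # map -pi to +pi so the range is (-pi, pi]
    return wrap_angle(ang)


def extract_dihedrals(ens: ConformationalEnsemble, residues, angles) -> DihedralSeries:
    """Extract phi/psi/chi1 series for the requested residues.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    chi1 = N-CA-CB-<terminal> with the terminal atom from a per-residue-type
    table (Tyr/Phe use CG).  Terminal residues lacking phi or psi are skipped
    with a warning; a missing named atom raises :class:`DihedralError`.
    """
    topo = ens.topology
    angles = list(angles)
    order = {"phi": 0, "psi": 1, "chi1": 2}
    for a in angles:
        if a not in order:
            raise DihedralError(f"unknown angle name {a!r}")
    lookup = {}
    res_names = {}
    for idx in range(topo.n_atoms):
        lookup[(int(topo.res_id[idx]), str(topo.atom_name[idx]))] = idx
        res_names[int(topo.res_id[idx])] = str(topo.res_name[idx])
    present = set(res_names)

    labels = []
    quads = []
    for rid in residues:
        rid = int(rid)
        if rid not in present:
            raise DihedralError(f"residue {rid} not in topology")
        for ang in sorted(set(angles), key=order.get):
            if ang == "phi":
                if rid - 1 not in present:
                    warnings.warn(f"residue {rid}: no preceding residue, phi skipped")
                    continue
                names = [(rid - 1, "C"), (rid, "N"), (rid, "CA"), (rid, "C")]
            elif ang == "psi":
                if rid + 1 not in present:
                    warnings.warn(f"residue {rid}: no following residue, psi skipped")
                    continue
                names = [(rid, "N"), (rid, "CA"), (rid, "C"), (rid + 1, "N")]
            else:  # chi1
                term = chi1_terminal_atom(res_names[rid])
                if term is None:
                    raise DihedralError(
                        f"residue {rid} ({res_names[rid]}): chi1 undefined "
                        f"(no side chain beyond CB)")
                names = [(rid, "N"), (rid, "CA"), (rid, "CB"), (rid, term)]
            quad = []
            for key in names:
                if key not in lookup:
                    raise DihedralError(
                        f"residue {rid}, angle {ang}: missing atom "
                        f"{key[1]!r} of residue {key[0]}")
                quad.append(lookup[key])
            labels.append((rid, ang))
            quads.append(quad)
    if not labels:
        raise DihedralError("no dihedral could be built from the request")
    quads = np.asarray(quads)  # (n_angles, 4)
    c = ens.coords
    values = dihedral_batch(
        c[:, quads[:, 0]], c[:, quads[:, 1]], c[:, quads[:, 2]], c[:, quads[:, 3]])
    return DihedralSeries(labels, values)


# ---------------------------------------------------------------------------
# Backbone reconstruction (internal coordinates / NeRF chain extension)
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond, angle, torsion):
    """Place atom D from A,B,C so |CD|=bond, angle(B,C,D)=angle and
    dihedral(A,B,C,D)=torsion (same sign convention as compute_dihedral)."""
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_u)
    n_norm = np.linalg.norm(n)
    if n_norm < _COLLINEAR_TOL:
        raise GeometryError("cannot place atom from collinear predecessors")
    n_u = n / n_norm
    m_u = np.cross(n_u, bc_u)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc_u + d_local[1] * m_u + d_local[2] * n_u


def rebuild_backbone(phi_psi, n_res=None, geometry=None) -> np.ndarray:
    """Build N/CA/C backbone coordinates from per-residue (phi, psi) angles.

    ``phi_psi`` is an (n_res, 2) array in radians; phi of the first residue
    and psi of the last are irrelevant to the geometry (no neighbour) but
    must be present.  Ideal bond lengths/angles come from
    :data:`BACKBONE_GEOMETRY`; the peptide omega is fixed trans.

    Returns coordinates of shape (3*n_res, 3) ordered N,CA,C per residue.
    Self-consistency: ``extract_dihedrals`` on the result recovers the
    interior inputs to ~1e-6 rad.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    if phi_psi.ndim != 2 or phi_psi.shape[1] != 2:
        raise SizeError("phi_psi must have shape (n_res, 2)")
    if n_res is None:
        n_res = phi_psi.shape[0]
    if n_res < 2:
        raise SizeError("need at least 2 residues to rebuild a backbone")
    if phi_psi.shape[0] != n_res:
        raise SizeError("phi_psi rows must equal n_res")
    geo = dict(BACKBONE_GEOMETRY)
    if geometry:
        geo.update(geometry)

    coords = np.empty((3 * n_res, 3))
    # first residue in a canonical pose
    n0 = np.zeros(3)
    ca0 = np.array([geo["bond_n_ca"], 0.0, 0.0])
    ang = math.pi - geo["angle_n_ca_c"]
    c0 = ca0 + geo["bond_ca_c"] * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords[0], coords[1], coords[2] = n0, ca0, c0
    for i in range(n_res - 1):
        n_i, ca_i, c_i = coords[3 * i], coords[3 * i + 1], coords[3 * i + 2]
        n_next = _place_atom(n_i, ca_i, c_i, geo["bond_c_n"],
                             geo["angle_ca_c_n"], phi_psi[i, 1])      # psi_i
        ca_next = _place_atom(ca_i, c_i, n_next, geo["bond_n_ca"],
                              geo["angle_c_n_ca"], geo["omega"])       # omega
        c_next = _place_atom(c_i, n_next, ca_next, geo["bond_ca_c"],
                             geo["angle_n_ca_c"], phi_psi[i + 1, 0])   # phi_{i+1}
        coords[3 * i + 3] = n_next
        coords[3 * i + 4] = ca_next
        coords[3 * i + 5] = c_next
    return coords


def make_backbone_topology(n_res: int, start_resid: int = 28,
                           res_names=None) -> Topology:
    """Topology matching :func:`rebuild_backbone` output (N/CA/C per residue)."""
    if res_names is None:
        res_names = ["ALA"] * n_res
    atom_name, res_id, res_name, element = [], [], [], []
    for i in range(n_res):
        for nm, el in (("N", "N"), ("CA", "C"), ("C", "C")):
            atom_name.append(nm)
            res_id.append(start_resid + i)
            res_name.append(res_names[i])
            element.append(el)
    return Topology(
        atom_id=np.arange(1, 3 * n_res + 1),
        atom_name=np.array(atom_name, dtype=object),
        res_id=np.array(res_id),
        res_name=np.array(res_name, dtype=object),
        element=np.array(element, dtype=object),
    )


# ---------------------------------------------------------------------------
# Superposition, RMSF, distances
# ---------------------------------------------------------------------------

def superpose_rmsd(mobile, ref, atoms=None):
    """Least-squares (Kabsch) superposition RMSD.

    Returns ``(rmsd, rotation, translation)`` such that
    ``rotation @ x + translation`` maps mobile onto ref in the least-squares
    sense.  The rotation is always proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if atoms is not None:
        atoms = np.asarray(atoms, dtype=int)
        mobile_sel, ref_sel = mobile[atoms], ref[atoms]
    else:
        mobile_sel, ref_sel = mobile, ref
    if mobile_sel.shape != ref_sel.shape:
        raise SizeError("mobile and reference selections differ in size")
    n = mobile_sel.shape[0]
    if n < 3:
        raise SizeError("superposition needs at least 3 atoms")
    cm_m = mobile_sel.mean(axis=0)
    cm_r = ref_sel.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sel - cm_r, mobile_sel - cm_m)
    rmat = rot.as_matrix()
    trans = cm_r - rmat @ cm_m
    # rmsd from the residuals directly (the rssd shortcut loses precision
    # to cancellation near zero)
    resid = mobile_sel @ rmat.T + trans - ref_sel
    rmsd = math.sqrt(np.mean(np.sum(resid ** 2, axis=1)))
    return float(rmsd), rmat, trans


def rmsf(ens: ConformationalEnsemble, atoms=None) -> np.ndarray:
    """Root-mean-square fluctuation per atom after mean-structure alignment.

    Two passes of align-to-mean remove rigid-body drift before measuring the
    fluctuation about the mean position (the full 3-D magnitude, so isotropic
    jitter of per-axis sigma gives RMSF = sqrt(3) * sigma).
    """
    if ens.n_frames < 2:
        raise SizeError("RMSF undefined for a single frame")
    if atoms is None:
        atoms = np.arange(ens.n_atoms)
    atoms = np.asarray(atoms, dtype=int)
    frames = ens.coords[:, atoms, :].copy()
    ref = frames[0]
    for _ in range(2):
        for k in range(frames.shape[0]):
            _, rot, trans = superpose_rmsd(frames[k], ref)
            frames[k] = frames[k] @ rot.T + trans
        ref = frames.mean(axis=0)
    disp = frames - ref[None]
    return np.sqrt(np.mean(np.sum(disp ** 2, axis=2), axis=0))


def min_distance_series(ens: ConformationalEnsemble, group_a, group_b) -> np.ndarray:
    """Per-frame minimum distance between two disjoint atom groups (A).

    No periodic imaging: ensembles are treated as whole molecules.
    """
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise SelectionError("both groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise SelectionError("groups overlap")
    out = np.empty(ens.n_frames)
    for k in range(ens.n_frames):
        out[k] = cdist(ens.coords[k, a], ens.coords[k, b]).min()
    return out
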