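"""Two-reference conformational comparison: DRMSD and the dihedral-similarity S CV.

Distance-based RMSD (DRMSD) compares conformations through their internal
pairwise-distance matrices, so no superposition is needed.  Because a single
reference cannot resolve which of two distant states a conformation belongs
to, every projection here is computed against a *pair* of references — a
GDP-bound-like "inactive" structure and a GTP-bound-like "active" one — and
each frame becomes a point (x, y) = (deviation/similarity w.r.t. inactive,
w.r.t. active).

The dihedral-similarity collective variable S scores how close a frame's
backbone phi/psi angles are to a reference row; larger S = more similar,
with maximum n_angles when every angle matches.  Two functional forms are
provided: a half-cosine sum (default; smooth and range-stable) and a
Gaussian kernel of configurable width.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .core import (
    ConformationalEnsemble,
    DihedralSeries,
    angular_difference,
    extract_dihedrals,
    select_atoms,
)
from .errors import AlignmentError, SizeError, SwitchscapeError

S_FORMS = ("half_cosine", "gaussian_kernel")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferencePair:
    """Inactive ("GDP-bound") and active ("GTP-bound") reference structures.

    ``atom_selection`` is the selection expression used for DRMSD (loop
    C-alpha atoms by convention); ``dihedral_refs`` holds one reference
    phi/psi row per reference structure for the S CV.
    """

    ref_inactive: ConformationalEnsemble
    ref_active: ConformationalEnsemble
    atom_selection: str
    dihedral_refs: tuple  # (DihedralSeries row inactive, row active)

    def __post_init__(self):
        if self.ref_inactive.n_frames != 1 or self.ref_active.n_frames != 1:
            raise SizeError("reference structures must be single-frame")
        ref_in, ref_ac = self.dihedral_refs
        if ref_in.labels != ref_ac.labels:
            raise AlignmentError("reference dihedral rows have different labels")

    @classmethod
    def from_ensembles(cls, ref_inactive, ref_active,
                       atom_selection="name CA",
                       dihedral_angles=("phi", "psi")) -> "ReferencePair":
        """Build a pair from two single-frame ensembles, extracting the
        reference dihedral rows from their shared residue range."""
        res_in = ref_inactive.topology.residue_ids()
        res_ac = ref_active.topology.residue_ids()
        if list(res_in) != list(res_ac):
            raise AlignmentError("references do not share residue ids")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # terminal phi/psi skips
            row_in = extract_dihedrals(ref_inactive, res_in, dihedral_angles)
            row_ac = extract_dihedrals(ref_active, res_ac, dihedral_angles)
        return cls(ref_inactive, ref_active, atom_selection, (row_in, row_ac))

    def swapped(self) -> "ReferencePair":
        return ReferencePair(self.ref_active, self.ref_inactive,
                             self.atom_selection,
                             (self.dihedral_refs[1], self.dihedral_refs[0]))

    @property
    def n_angles(self) -> int:
        return self.dihedral_refs[0].n_angles


@dataclass
class ProjectionSeries:
    """Per-frame (x, y) values against the inactive (x) and active (y) refs."""

    x: np.ndarray
    y: np.ndarray
    metric_tag: str  # "drmsd" or "s_similarity"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise SizeError("x and y series must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise SizeError("non-finite projection values")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "x": self.x, "y": self.y,
            "metric": self.metric_tag,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# DRMSD
# ---------------------------------------------------------------------------

def drmsd(conf, ref, atoms=None) -> float:
    """Distance-based RMSD between two frames over a common atom selection.

    sqrt( (1/P) * sum_{i<j} [d(x_i,x_j) - d(x_i_ref,x_j_ref)]^2 ) over all
    P = N(N-1)/2 unordered pairs; alignment-free by construction.
    """
    conf = np.asarray(conf, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if atoms is not None:
        atoms = np.asarray(atoms, dtype=int)
        conf, ref = conf[atoms], ref[atoms]
    if conf.shape != ref.shape:
        raise SizeError("conformation and reference selections differ in size")
    n = conf.shape[0]
    if n < 2:
        raise SizeError("DRMSD needs at least 2 atoms")
    diff = pdist(conf) - pdist(ref)
    return float(math.sqrt(np.mean(diff ** 2)))


def drmsd_projection(ens: ConformationalEnsemble,
                     refs: ReferencePair) -> ProjectionSeries:
    """Per-frame DRMSD against both references -> (x, y) series."""
    sel = select_atoms(ens, refs.atom_selection)
    sel_in = select_atoms(refs.ref_inactive, refs.atom_selection)
    sel_ac = select_atoms(refs.ref_active, refs.atom_selection)
    ref_in = refs.ref_inactive.coords[0, sel_in]
    ref_ac = refs.ref_active.coords[0, sel_ac]
    d_in = pdist(ref_in)
    d_ac = pdist(ref_ac)
    if len(sel) != len(sel_in) or len(sel) != len(sel_ac):
        raise SizeError("selection sizes differ between ensemble and references")
    x = np.empty(ens.n_frames)
    y = np.empty(ens.n_frames)
    for k in range(ens.n_frames):
        d = pdist(ens.coords[k, sel])
        x[k] = math.sqrt(np.mean((d - d_in) ** 2))
        y[k] = math.sqrt(np.mean((d - d_ac) ** 2))
    return ProjectionSeries(x, y, "drmsd")


# ---------------------------------------------------------------------------
# Dihedral-similarity S
# ---------------------------------------------------------------------------

def s_similarity(dih: DihedralSeries, ref: DihedralSeries,
                 form: str = "half_cosine", width: float | None = None):
    """Dihedral similarity S of each frame in ``dih`` against a reference row.

    half_cosine:      S = sum_i (1 + cos(dtheta_i)) / 2
    gaussian_kernel:  S = sum_i exp(-dtheta_i^2 / (2 width^2))

    with dtheta the minimum-image angular difference (rad).  Both forms lie
    in [0, n_angles] and are maximal iff every angle equals its reference.
    Returns a scalar for a single-frame ``dih``, else an array.
    """
    if form not in S_FORMS:
        raise ValueError(f"unknown S form {form!r}; choose from {S_FORMS}")
    if dih.labels != ref.labels:
        raise AlignmentError("dihedral labels do not match the reference row")
    if ref.n_frames != 1:
        raise SizeError("reference must be a single row")
    delta = angular_difference(dih.values, ref.values[0][None, :])
    if form == "half_cosine":
        s = np.sum(0.5 * (1.0 + np.cos(delta)), axis=1)
    else:
        if width is None or width <= 0:
            raise ValueError("gaussian_kernel form requires width > 0 (radians)")
        s = np.sum(np.exp(-delta ** 2 / (2.0 * width ** 2)), axis=1)
    return float(s[0]) if dih.n_frames == 1 else s


def s_projection(ens: ConformationalEnsemble, refs: ReferencePair,
                 form: str = "half_cosine",
                 width: float | None = None) -> ProjectionSeries:
    """Per-frame (S_inactive, S_active) similarity series, i.e. the
    (S_GDP, S_GTP)-style projection of an ensemble."""
    row_in, row_ac = refs.dihedral_refs
    residues = sorted({rid for rid, _ in row_in.labels})
    angles = sorted({ang for _, ang in row_in.labels},
                    key={"phi": 0, "psi": 1, "chi1": 2}.get)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dih = extract_dihedrals(ens, residues, angles)
    if dih.labels != row_in.labels:
        raise AlignmentError(
            "ensemble dihedral labels do not match the reference rows")
    x = np.atleast_1d(s_similarity(dih, row_in, form, width))
    y = np.atleast_1d(s_similarity(dih, row_ac, form, width))
    return ProjectionSeries(x, y, "s_similarity")


def map_structures(structures, refs: ReferencePair,
                   form: str = "half_cosine", width: float | None = None,
                   ids=None) -> pd.DataFrame:
    """Map single-frame structures onto the (S_inactive, S_active) plane.

    Returns a table ``structure_id, s_gdp, s_gtp`` with one row per input.
    Structures missing the loop residues are skipped with a warning so the
    rest can proceed.
    """
    if ids is None:
        ids = [f"structure_{i}" for i in range(len(structures))]
    rows = []
    for sid, struct in zip(ids, structures):
        try:
            proj = s_projection(struct, refs, form, width)
        except SwitchscapeError as exc:  # per-structure failure must not abort
            warnings.warn(f"structure {sid!r} skipped: {exc}")
            continue
        rows.append((sid, float(proj.x[0]), float(proj.y[0])))
    return pd.DataFrame(rows, columns=["structure_id", "s_gdp", "s_gtp"])


def geodesic_interpolation(row_from: DihedralSeries, row_to: DihedralSeries,
                           n_points: int = 21) -> DihedralSeries:
    """Interpolate dihedral rows along the per-angle minimum-image geodesic.

    Useful for monotonicity checks of the S projection: moving from one
    reference to the other, similarity to the origin decreases while
    similarity to the target increases.
    """
    if row_from.labels != row_to.labels:
        raise AlignmentError("rows have different labels")
    a = row_from.values[0]
    delta = angular_difference(row_to.values[0], a)
    ts = np.linspace(0.0, 1.0, n_points)
    vals = a[None, :] + ts[:, None] * delta[None, :]
    return DihedralSeries(row_from.labels, vals)
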