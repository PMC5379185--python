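"""Seeded generators for every input class the pipeline consumes.

Each generator emits its ground truth alongside the data, so every stage of
the analysis — projections, metadynamics surfaces, clustering, hydration,
energetics — can be validated end to end without external structure
downloads:

* multi-state loop ensembles with von Mises dihedral noise around
  prescribed per-state phi/psi means (the default 13-residue loop mirrors a
  switch-I-sized segment numbered 28-40, so documented selections read
  naturally);
* noise-free reference pairs standing in for inactive/active crystal
  structures;
* homogeneous Poisson point solvent of known density for hydration checks;
* small charged/LJ toy systems realizing a prescribed sign pattern of
  per-group interaction energies (the "energetic see-saw").

von Mises noise (not wrapped normal) is used for angles because its density
is closed-form, which makes distributional tests exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConformationalEnsemble,
    Topology,
    make_backbone_topology,
    rebuild_backbone,
    wrap_angle,
)
from .drmsd import ReferencePair
from .environment import group_interaction
from .errors import SpecError

DEFAULT_N_RES = 13        # loop length; mirrors switch I residues 28-40
DEFAULT_START_RESID = 28


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class StateDef:
    """One conformational state: per-residue phi/psi means (degrees),
    a shared von Mises concentration and a mixture weight."""

    phi_mean: float | np.ndarray
    psi_mean: float | np.ndarray
    kappa: float
    weight: float
    reporter_distance: tuple | None = None   # (mean A, sd A) of the reporter

    def __post_init__(self):
        if self.kappa <= 0:
            raise SpecError("kappa must be positive")
        if self.weight < 0:
            raise SpecError("weights must be non-negative")


@dataclass
class StateSpec:
    """Mixture of conformational states for the loop generator."""

    states: list

    def __post_init__(self):
        if not self.states:
            raise SpecError("at least one state required")
        total = sum(s.weight for s in self.states)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SpecError(f"mixture weights sum to {total}, expected 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @classmethod
    def two_state(cls, separation_deg=90.0, kappa=50.0, weights=(0.5, 0.5),
                  reporter=None) -> "StateSpec":
        """Inactive/active pair with phi/psi means ``separation_deg`` apart.

        ``reporter``: optional pair of (mean, sd) reporter distances, one
        per state, emulating a side chain that sits near the nucleotide in
        one state and far in the other.
        """
        base_phi, base_psi = -70.0, -40.0
        reps = reporter if reporter is not None else (None, None)
        return cls([
            StateDef(base_phi, base_psi, kappa, weights[0], reps[0]),
            StateDef(base_phi + separation_deg, base_psi + separation_deg,
                     kappa, weights[1], reps[1]),
        ])

    @classmethod
    def four_state(cls, kappa=50.0, weights=(0.4, 0.3, 0.2, 0.1),
                   separation_deg=60.0) -> "StateSpec":
        """Four states with phi/psi means at least ``separation_deg`` apart."""
        means = [(-150.0, -150.0), (-150.0 + separation_deg * 1.5, -150.0),
                 (-150.0, -150.0 + separation_deg * 1.5),
                 (-150.0 + separation_deg * 1.5, -150.0 + separation_deg * 1.5)]
        return cls([StateDef(p, s, kappa, w)
                    for (p, s), w in zip(means, weights)])


@dataclass
class ToySystemSpec:
    """Point sites with charges/LJ parameters and group tags for the
    energetics toys."""

    positions: np.ndarray      # (n, 3), A
    charges: np.ndarray        # e
    epsilons: np.ndarray       # kcal/mol
    rmin_halves: np.ndarray    # A
    groups: np.ndarray         # tags
    names: np.ndarray | None = None
    res_names: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.positions)
        for fname in ("charges", "epsilons", "rmin_halves"):
            arr = np.asarray(getattr(self, fname), dtype=float)
            if arr.shape != (n,):
                raise SpecError(f"{fname} must have length {n}")
            setattr(self, fname, arr)
        self.groups = np.asarray(self.groups, dtype=object)
        if not np.all(np.isfinite(self.positions)):
            raise SpecError("non-finite site positions")

    def to_ensemble(self, n_frames=1, jitter=0.0, seed=0) -> ConformationalEnsemble:
        n = len(self.positions)
        names = (self.names if self.names is not None
                 else np.array([f"X{i + 1}" for i in range(n)], dtype=object))
        res_names = (self.res_names if self.res_names is not None
                     else np.array(["TOY"] * n, dtype=object))
        topo = Topology(
            atom_id=np.arange(1, n + 1),
            atom_name=names,
            res_id=np.arange(1, n + 1),
            res_name=res_names,
            element=np.array([str(nm)[0] for nm in names], dtype=object),
            charge=self.charges,
            lj_epsilon=self.epsilons,
            lj_rmin_half=self.rmin_halves,
            group=self.groups,
        )
        rng = np.random.default_rng(seed)
        coords = np.repeat(self.positions[None], n_frames, axis=0)
        if jitter > 0:
            coords = coords + rng.normal(0.0, jitter, size=coords.shape)
        return ConformationalEnsemble(topo, coords)


# ---------------------------------------------------------------------------
# Loop ensembles
# ---------------------------------------------------------------------------

def _state_means(state: StateDef, n_res: int) -> np.ndarray:
    phi = np.broadcast_to(np.asarray(state.phi_mean, dtype=float), (n_res,))
    psi = np.broadcast_to(np.asarray(state.psi_mean, dtype=float), (n_res,))
    return np.radians(np.column_stack([phi, psi]))


def _loop_topology_with_reporter(n_res, start_resid, with_reporter):
    topo = make_backbone_topology(n_res, start_resid)
    if not with_reporter:
        return topo
    return Topology(
        atom_id=np.append(topo.atom_id, topo.atom_id[-1] + 1),
        atom_name=np.append(topo.atom_name, "PG"),
        res_id=np.append(topo.res_id, 999),
        res_name=np.append(topo.res_name, "GTP"),
        element=np.append(topo.element, "P"),
    )


def gen_loop_ensemble(spec: StateSpec, n_res: int = DEFAULT_N_RES,
                      n_frames: int = 1000, seed: int = 0,
                      start_resid: int = DEFAULT_START_RESID):
    """Multi-state loop ensemble with known per-frame state labels.

    Per frame: draw a state by mixture weight, draw phi/psi per residue
    from von Mises around that state's means, rebuild 3-D coordinates by
    internal-coordinate chain extension.  If any state defines a reporter
    distance, a single nucleotide-tagged site ('PG') is appended at that
    distance from the middle residue's C-alpha, giving a ground-truth
    minimum-distance signature.

    Returns (ensemble, labels) with labels the true state index per frame.
    """
    if n_res < 4:
        raise SpecError("n_res must be at least 4")
    rng = np.random.default_rng(seed)
    weights = np.array([s.weight for s in spec.states])
    labels = rng.choice(spec.n_states, size=n_frames, p=weights)
    means = [_state_means(s, n_res) for s in spec.states]
    with_reporter = any(s.reporter_distance is not None for s in spec.states)
    topo = _loop_topology_with_reporter(n_res, start_resid, with_reporter)
    n_atoms = topo.n_atoms
    mid_ca = 3 * (n_res // 2) + 1  # CA of the middle residue
    coords = np.empty((n_frames, n_atoms, 3))
    for k in range(n_frames):
        st = spec.states[labels[k]]
        pp = rng.vonmises(means[labels[k]], st.kappa)
        bb = rebuild_backbone(pp, n_res)
        coords[k, :3 * n_res] = bb
        if with_reporter:
            if st.reporter_distance is None:
                raise SpecError("all states need reporter_distance when any has one")
            mean_d, sd_d = st.reporter_distance
            d = max(0.1, rng.normal(mean_d, sd_d))
            # place along a fixed lab direction from the middle C-alpha
            coords[k, -1] = bb[mid_ca] + d * np.array([0.0, 0.0, 1.0])
    return ConformationalEnsemble(topo, coords), labels


def gen_reference_pair(spec: StateSpec, n_res: int = DEFAULT_N_RES,
                       start_resid: int = DEFAULT_START_RESID) -> ReferencePair:
    """Noise-free conformations at the means of state 0 ('inactive') and
    state 1 ('active'), with dihedral reference rows attached."""
    if spec.n_states < 2:
        raise SpecError("reference pair needs at least 2 states")
    topo = make_backbone_topology(n_res, start_resid)
    ens = []
    for state in spec.states[:2]:
        bb = rebuild_backbone(_state_means(state, n_res), n_res)
        ens.append(ConformationalEnsemble(topo, bb[None]))
    return ReferencePair.from_ensembles(ens[0], ens[1],
                                        atom_selection="name CA")


def write_ground_truth(labels, path) -> None:
    pd.DataFrame({"frame": np.arange(len(labels)),
                  "state": labels}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Point solvent
# ---------------------------------------------------------------------------

def gen_solvated_frame(ens: ConformationalEnsemble, density: float,
                       margin: float = 6.0, seed: int = 0,
                       frame: int = 0) -> ConformationalEnsemble:
    """Augment one frame with a homogeneous Poisson point solvent.

    Oxygen-only water sites are placed uniformly in the frame's bounding
    box extended by ``margin`` (A); the expected count is
    density * box volume (density in A^-3).
    """
    if density < 0:
        raise SpecError("density must be non-negative")
    rng = np.random.default_rng(seed)
    xyz = ens.coords[frame]
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    volume = float(np.prod(hi - lo))
    n_w = rng.poisson(density * volume)
    waters = rng.uniform(lo, hi, size=(n_w, 3))
    topo = ens.topology
    last_id = topo.atom_id[-1] if topo.n_atoms else 0
    last_res = int(topo.res_id.max()) if topo.n_atoms else 0
    new_topo = Topology(
        atom_id=np.concatenate([topo.atom_id, last_id + 1 + np.arange(n_w)]),
        atom_name=np.concatenate([topo.atom_name, np.array(["OW"] * n_w, object)]),
        res_id=np.concatenate([topo.res_id, last_res + 1 + np.arange(n_w)]),
        res_name=np.concatenate([topo.res_name, np.array(["HOH"] * n_w, object)]),
        element=np.concatenate([topo.element, np.array(["O"] * n_w, object)]),
        group=np.concatenate([topo.group, np.array(["water"] * n_w, object)]),
    )
    coords = np.vstack([xyz, waters])[None]
    return ConformationalEnsemble(new_topo, coords)


# ---------------------------------------------------------------------------
# Energetics toys
# ---------------------------------------------------------------------------

def seesaw_specs() -> tuple:
    """(active, inactive) ToySystemSpec pair realizing the energetic see-saw.

    The focal "loop" site is charged; in the inactive system the solvent
    sites sit close (favourable solvation) and the nucleotide far, in the
    active system the solvent is pushed out while an oppositely charged
    nucleotide moves in close — so dE_water > 0, dE_nucleotide < 0 and the
    larger nucleotide gain makes dE_total < 0.
    """
    def build(water_d, nuc_d):
        positions = np.array([
            [0.0, 0.0, 0.0],            # focal loop site (protein)
            [12.0, 0.0, 0.0],           # distant protein partner
            [0.0, water_d, 0.0],        # water site 1
            [0.0, -water_d, 0.0],       # water site 2
            [nuc_d, 0.0, 0.0],          # nucleotide site
            [0.0, 0.0, 8.0],            # Mg2+-like ion
        ])
        charges = np.array([0.5, -0.2, -0.4, -0.4, -1.0, 2.0])
        eps = np.full(6, 0.1)
        rmin_half = np.full(6, 1.8)
        groups = np.array(["protein", "protein", "water", "water",
                           "nucleotide", "ion"], dtype=object)
        names = np.array(["CB", "CX", "OW", "OW2", "PG", "MG"], dtype=object)
        res_names = np.array(["ALA", "GLY", "HOH", "HOH", "GTP", "MG"],
                             dtype=object)
        return ToySystemSpec(positions, charges, eps, rmin_half, groups,
                             names, res_names)

    active = build(water_d=6.5, nuc_d=3.6)
    inactive = build(water_d=3.2, nuc_d=8.5)
    return active, inactive


def gen_toy_energetics(spec_active: ToySystemSpec, spec_inactive: ToySystemSpec,
                       n_frames: int = 1, jitter: float = 0.0, seed: int = 0,
                       check_pattern: bool = True):
    """Two single-state ensembles with full nonbonded parameters.

    When ``check_pattern`` is set the prescribed see-saw sign pattern
    (dE_water > 0, dE_nucleotide < 0, dE_total < 0) is verified at
    generation time by direct summation over the mean geometries.
    Returns (ens_active, ens_inactive).
    """
    ens_a = spec_active.to_ensemble(n_frames, jitter, seed)
    ens_i = spec_inactive.to_ensemble(n_frames, jitter, seed + 1)
    if check_pattern:
        deltas = {}
        for gname in ("water", "nucleotide"):
            vals = {}
            for tag, spec, ens in (("a", spec_active, ens_a),
                                   ("i", spec_inactive, ens_i)):
                focal = np.flatnonzero((spec.groups == "protein"))[:1]
                partner = np.flatnonzero(spec.groups == gname)
                cou, lj = group_interaction(spec.positions, ens.topology,
                                            focal, partner, cutoff=None)
                vals[tag] = cou + lj
            deltas[gname] = vals["a"] - vals["i"]
        if not (deltas["water"] > 0 and deltas["nucleotide"] < 0
                and sum(deltas.values()) < 0):
            raise SpecError(f"toy systems do not realize the see-saw "
                            f"pattern: {deltas}")
    return ens_a, ens_i
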