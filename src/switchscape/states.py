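"""Unsupervised sub-state discovery and side-chain signature classification.

Frames pooled across systems are embedded as (sin, cos) pairs of selected
phi/psi/chi1 dihedrals — the standard seam-free representation of circular
data — and clustered with k-means (k = 4 by default, matching the
four-cluster protocol for switch-loop sub-states).  Per-system cluster
populations, chi-angle histograms and threshold-rule classification of
open/closed/intermediate side-chain orientations complete the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import ConformationalEnsemble, DihedralSeries, wrap_angle
from .errors import AlignmentError, SelectionError, SizeError, SpecError

DEFAULT_K = 4  # number of sub-state clusters


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """(sin, cos)-embedded dihedral features, rows tagged by system."""

    data: np.ndarray          # (n_rows, 2 * n_angles), values in [-1, 1]
    column_labels: list       # [(res_id, angle_name, "sin"|"cos")]
    system_tags: np.ndarray   # (n_rows,) str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.system_tags = np.asarray(self.system_tags, dtype=object)
        if self.data.shape[0] != len(self.system_tags):
            raise SizeError("one system tag per row required")
        if self.data.shape[1] != len(self.column_labels):
            raise SizeError("one label per column required")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{r}_{a}_{t}" for r, a, t in self.column_labels]
        df = pd.DataFrame(self.data, columns=cols)
        df.insert(0, "system", self.system_tags)
        return df


def build_features(series) -> FeatureMatrix:
    """Embed dihedral series as (sin, cos) columns, pooled across systems.

    ``series`` is a list of (system_tag, DihedralSeries); all series must
    share identical labels.  Each angle contributes exactly one (sin, cos)
    column pair, so Euclidean distance in feature space is the chord length
    2|sin(dtheta/2)| per angle — monotone in angular distance on (0, pi).
    """
    if not series:
        raise SizeError("no dihedral series given")
    ref_labels = series[0][1].labels
    for tag, s in series:
        if s.labels != ref_labels:
            raise AlignmentError(
                f"system {tag!r}: dihedral labels differ from the first system")
    blocks, tags = [], []
    for tag, s in series:
        emb = np.empty((s.n_frames, 2 * s.n_angles))
        emb[:, 0::2] = np.sin(s.values)
        emb[:, 1::2] = np.cos(s.values)
        blocks.append(emb)
        tags.extend([tag] * s.n_frames)
    column_labels = []
    for rid, ang in ref_labels:
        column_labels.append((rid, ang, "sin"))
        column_labels.append((rid, ang, "cos"))
    return FeatureMatrix(np.vstack(blocks), column_labels,
                         np.array(tags, dtype=object))


def build_features_raw(series) -> FeatureMatrix:
    """Raw-angle feature mode (radians, no embedding) for fidelity
    comparisons with pipelines that clustered dihedrals directly; suffers
    from the +-180 degree seam, hence not the default."""
    if not series:
        raise SizeError("no dihedral series given")
    ref_labels = series[0][1].labels
    for tag, s in series:
        if s.labels != ref_labels:
            raise AlignmentError(f"system {tag!r}: label mismatch")
    data = np.vstack([s.values for _, s in series])
    tags = np.concatenate([[tag] * s.n_frames for tag, s in series])
    cols = [(rid, ang, "raw") for rid, ang in ref_labels]
    return FeatureMatrix(data, cols, tags.astype(object))


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Fitted k-means model over a FeatureMatrix."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    seed: int
    system_tags: np.ndarray = field(default=None)

    def __post_init__(self):
        if set(np.unique(self.assignments)) - set(range(self.k)):
            raise SpecError("assignment labels outside [0, k)")


def kmeans(features: FeatureMatrix, k: int = DEFAULT_K, seed: int = 0,
           n_init: int = 10) -> ClusterModel:
    """k-means++ / Lloyd clustering, best of ``n_init`` restarts by inertia.

    Fully reproducible per seed.  Raises on degenerate data with fewer
    distinct rows than clusters.
    """
    x = features.data
    if x.shape[0] < k:
        raise SizeError(f"{x.shape[0]} rows < k={k}")
    if np.unique(x, axis=0).shape[0] < k:
        raise SpecError("fewer distinct rows than clusters: degenerate data")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=500, tol=1e-6, random_state=seed)
    labels = km.fit_predict(x)
    # guard the "every centroid owns >= 1 row" invariant
    counts = np.bincount(labels, minlength=k)
    if np.any(counts == 0):  # pragma: no cover - sklearn re-seeds empty clusters
        raise SpecError("empty cluster in fitted model")
    inertia = float(np.sum((x - km.cluster_centers_[labels]) ** 2))
    return ClusterModel(k, km.cluster_centers_.copy(), labels, inertia, seed,
                        features.system_tags)


def population_table(model: ClusterModel, system_tags=None) -> pd.DataFrame:
    """Per-system cluster fractions (rows sum to 1)."""
    tags = system_tags if system_tags is not None else model.system_tags
    if tags is None or len(tags) != len(model.assignments):
        raise AlignmentError("system tags do not align with assignments")
    df = pd.DataFrame({"system": tags, "cluster": model.assignments})
    table = (df.groupby(["system", "cluster"]).size()
             .unstack(fill_value=0)
             .reindex(columns=range(model.k), fill_value=0))
    return table.div(table.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# chi histograms
# ---------------------------------------------------------------------------

def chi_histogram(angles, bins=36):
    """Normalized periodic histogram of a dihedral column over (-180, 180].

    ``angles`` in radians; returns (bin_edges_deg, probabilities) with
    probabilities summing to 1.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise SizeError("empty angle series")
    deg = np.degrees(wrap_angle(angles))
    if np.isscalar(bins):
        edges = np.linspace(-180.0, 180.0, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if edges[0] != -180.0 or edges[-1] != 180.0:
            raise SpecError("bins must partition (-180, 180]")
    # (-180, 180] convention: put exact -180 into the last bin via wrap
    deg = np.where(deg <= -180.0, 180.0, deg)
    hist, _ = np.histogram(deg, bins=edges)
    return edges, hist / hist.sum()


# ---------------------------------------------------------------------------
# Signature classification
# ---------------------------------------------------------------------------

@dataclass
class SignatureRule:
    """One observable threshold band mapping to a state label.

    observable: "min_distance" (between two selections, A) or "chi_angle"
    (chi1 of a residue, degrees).  The band is [lower, upper): the lower
    bound is inclusive, the upper exclusive (strict ``<``), so a frame
    exactly at a threshold belongs to the band above it.
    """

    observable: str
    label: str
    lower: float
    upper: float
    selection_a: str | None = None
    selection_b: str | None = None
    residue: int | None = None


@dataclass
class StateSignature:
    """Mutually exclusive, exhaustive threshold rules over one observable.

    Example (closed/intermediate/open by reporter side-chain-to-nucleotide
    distance, hydrogen-bond range below 3.5 A):

    >>> sig = StateSignature.distance_bands("name CG", "group nucleotide",
    ...                                     closed_below=3.5, open_above=5.5)
    """

    rules: list

    def __post_init__(self):
        if not self.rules:
            raise SpecError("signature needs at least one rule")
        obs = {r.observable for r in self.rules}
        if len(obs) != 1:
            raise SpecError("all rules must share one observable")
        bands = sorted((r.lower, r.upper) for r in self.rules)
        lo = bands[0][0]
        for a, b in bands:
            if a != lo:
                raise SpecError(f"rule gap or overlap at {a}")
            if b <= a:
                raise SpecError("empty rule band")
            lo = b
        if not math.isinf(bands[0][0]) or not math.isinf(bands[-1][1]):
            raise SpecError("rules must be exhaustive (outer bands unbounded)")

    @classmethod
    def distance_bands(cls, selection_a, selection_b,
                       closed_below=3.5, open_above=5.5) -> "StateSignature":
        """closed if d < closed_below, open if d >= open_above, else
        intermediate (hydrogen-bond range motivates the default 3.5 A).
        Setting both thresholds equal yields a two-way closed/open split."""
        mk = lambda label, lo, hi: SignatureRule(
            "min_distance", label, lo, hi, selection_a, selection_b)
        rules = [mk("closed", -math.inf, closed_below)]
        if open_above > closed_below:
            rules.append(mk("intermediate", closed_below, open_above))
        elif open_above < closed_below:
            raise SpecError("open_above must be >= closed_below")
        rules.append(mk("open", open_above, math.inf))
        return cls(rules)


def classify_frames(ens: ConformationalEnsemble, signature: StateSignature):
    """Label every frame by the signature rules.

    Returns (labels, fractions) where labels is a per-frame array and
    fractions a dict summing to 1.  Rule gaps are rejected at signature
    construction, not here.
    """
    from .core import extract_dihedrals, min_distance_series, select_atoms

    rule0 = signature.rules[0]
    if rule0.observable == "min_distance":
        a = select_atoms(ens, rule0.selection_a)
        b = select_atoms(ens, rule0.selection_b)
        values = min_distance_series(ens, a, b)
    elif rule0.observable == "chi_angle":
        series = extract_dihedrals(ens, [rule0.residue], ["chi1"])
        values = np.degrees(series.values[:, 0])
    else:
        raise SpecError(f"unknown observable {rule0.observable!r}")
    labels = np.empty(len(values), dtype=object)
    for rule in signature.rules:
        sel = (values >= rule.lower) & (values < rule.upper)
        labels[sel] = rule.label
    if any(l is None for l in labels):
        raise SelectionError("frame outside every rule band")
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    fractions = dict(zip(uniq, counts / counts.sum()))
    return labels, fractions


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def silhouette_summary(features: FeatureMatrix, model: ClusterModel) -> float:
    """Mean silhouette coefficient of the fitted model (diagnostic only;
    k is never auto-selected from it)."""
    from sklearn.metrics import silhouette_score
    return float(silhouette_score(features.data, model.assignments))


def cluster_report(model: ClusterModel, populations: pd.DataFrame) -> str:
    """Plain-text cluster summary."""
    lines = [f"k-means sub-state model: k={model.k}, seed={model.seed}, "
             f"inertia={model.inertia:.4f}"]
    counts = np.bincount(model.assignments, minlength=model.k)
    for c in range(model.k):
        lines.append(f"  cluster C{c + 1}: {counts[c]} frames "
                     f"({counts[c] / len(model.assignments):.1%})")
    lines.append("per-system populations:")
    lines.append(populations.to_string(float_format=lambda v: f"{v:.4f}"))
    return "\n".join(lines)
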