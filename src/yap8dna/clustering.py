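"""Conformational clustering of trajectory frames.

Frames are compared by best-fit heavy-atom RMSD: each pair of frames is
superposed on a reference atom set (by default the response-element heavy
atoms, so that motion of the flexible N-terminal tails *relative to the
binding site* drives the distance) and the RMSD is then measured over a
second atom set (by default the DNA heavy atoms outside the response
element, minus two terminal base pairs at each end, plus the protein tail
residues 7-16).  The resulting F x F matrix feeds DBSCAN, and the largest
cluster's medoid frame is reported as the representative structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.cluster import DBSCAN

from .errors import ConfigurationError, NoClusterError
from .structures_io import Topology, Trajectory, select

#: default selection expressions of the RMSD metric
SUPERPOSE_EXPR = "(region y8re_W or region y8re_C) and heavy"
RMSD_EXPR_WITH_TAILS = (
    "((role dna and heavy) minus (region y8re_W or region y8re_C)"
    " minus (resid 1-2 or resid 24-25))"
    " or (role protein and resid 7-16 and heavy)"
)
RMSD_EXPR_DNA_ONLY = (
    "(role dna and heavy) minus (region y8re_W or region y8re_C)"
    " minus (resid 1-2 or resid 24-25)"
)


@dataclass
class RmsdMetricSpec:
    """Atom sets defining the frame-to-frame distance.

    ``superpose_selection`` may be ``None`` to skip the best-fit step and
    compute a raw coordinate RMSD.
    """

    superpose_selection: np.ndarray | None
    rmsd_selection: np.ndarray

    def __post_init__(self) -> None:
        self.rmsd_selection = np.asarray(self.rmsd_selection, dtype=int)
        if self.rmsd_selection.size == 0:
            raise ConfigurationError("rmsd_selection is empty")
        if self.superpose_selection is not None:
            self.superpose_selection = np.asarray(self.superpose_selection, dtype=int)
            if self.superpose_selection.size == 0:
                raise ConfigurationError("superpose_selection is empty")


def default_metric_spec(topology: Topology, include_tails: bool = True) -> RmsdMetricSpec:
    """Build the standard metric from the topology's region annotations."""
    expr = RMSD_EXPR_WITH_TAILS if include_tails else RMSD_EXPR_DNA_ONLY
    return RmsdMetricSpec(
        superpose_selection=select(topology, SUPERPOSE_EXPR),
        rmsd_selection=select(topology, expr),
    )


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-frame integer label, -1 = noise
    sizes: dict[int, int]  # cluster label -> frame count
    representative_frame: int | None
    params: tuple[float, int]  # (eps, min_samples)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def n_noise(self) -> int:
        return int((self.labels == -1).sum())


def _fit_rmsd(ref_sup: np.ndarray, mov_sup: np.ndarray,
              ref_rmsd: np.ndarray, mov_rmsd: np.ndarray,
              superpose: bool) -> float:
    if superpose:
        mu_r = ref_sup.mean(axis=0)
        mu_m = mov_sup.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_sup - mu_r, mov_sup - mu_m)
        moved = rot.apply(mov_rmsd - mu_m) + mu_r
    else:
        moved = mov_rmsd
    delta = moved - ref_rmsd
    return float(np.sqrt((delta * delta).sum(axis=1).mean()))


def pairwise_rmsd(trajectory: Trajectory, spec: RmsdMetricSpec) -> np.ndarray:
    """F x F symmetric best-fit RMSD matrix, Angstrom."""
    coords = trajectory.coordinates
    F = trajectory.n_frames
    superpose = spec.superpose_selection is not None
    sup = coords[:, spec.superpose_selection] if superpose else coords[:, :1]
    sel = coords[:, spec.rmsd_selection]
    D = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            d = _fit_rmsd(sup[i], sup[j], sel[i], sel[j], superpose)
            D[i, j] = D[j, i] = d
    return D


def dbscan_cluster(distances: np.ndarray, eps: float, min_samples: int) -> ClusterResult:
    """DBSCAN on a precomputed distance matrix.

    Deterministic for a fixed frame ordering.  The representative frame
    (largest-cluster medoid; ties broken toward the lower cluster label
    and then the lower frame index) is attached when any cluster exists.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if eps <= 0:
        raise ConfigurationError("eps must be positive")
    if min_samples < 1:
        raise ConfigurationError("min_samples must be >= 1")

    labels = DBSCAN(eps=eps, min_samples=min_samples,
                    metric="precomputed").fit_predict(distances)
    sizes = {int(l): int((labels == l).sum()) for l in np.unique(labels) if l != -1}
    rep = None
    if sizes:
        rep = representative_frame(distances, labels)
    return ClusterResult(labels=labels, sizes=sizes,
                         representative_frame=rep,
                         params=(float(eps), int(min_samples)))


def representative_frame(distances: np.ndarray, labels: np.ndarray) -> int:
    """Medoid of the largest cluster.

    The medoid minimises the summed distance to the other members; exact
    ties go to the lowest frame index, and equal-size clusters resolve to
    the lowest cluster label.
    """
    labels = np.asarray(labels)
    sizes = {int(l): int((labels == l).sum()) for l in np.unique(labels) if l != -1}
    if not sizes:
        raise NoClusterError("all frames are noise; no representative exists")
    best_label = min(sizes, key=lambda l: (-sizes[l], l))
    members = np.flatnonzero(labels == best_label)
    sums = distances[np.ix_(members, members)].sum(axis=1)
    return int(members[np.argmin(sums)])  # argmin takes the first (lowest) index
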