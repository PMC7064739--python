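"""Distance-cutoff (single-linkage) cluster analysis of dye molecules.

Two molecules are linked when their center-of-mass minimum-image distance
is at or below a cutoff; clusters are connected components of the link
graph with at least ``min_size`` members. Defaults follow the analysis of
dye aggregation in bilayer simulations: cutoff 17 A (first and second
neighbor shells) and minimum cluster size 2.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Configuration, Trajectory, compute_axis_frame

__all__ = ["ClusterParams", "ClusterAssignment", "UNCLUSTERED",
           "find_clusters", "membership_fraction_series",
           "cluster_size_histogram"]

#: sentinel label for molecules not in any cluster of size >= min_size
UNCLUSTERED = -1

#: molecule count above which a periodic k-d tree replaces the all-pairs scan
_TREE_THRESHOLD = 200


@dataclass(frozen=True)
class ClusterParams:
    """Cutoff distance (A) and minimum cluster size."""

    cutoff: float = 17.0
    min_size: int = 2

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_size < 2:
            raise ValueError("min_size must be at least 2")


@dataclass
class ClusterAssignment:
    """Per-molecule cluster labels for one frame.

    ``labels[k]`` is the cluster index of the k-th molecule, or
    ``UNCLUSTERED`` (-1). Labels are deterministic: clusters are numbered
    0, 1, ... by their smallest member position in the frame.
    """

    molecule_ids: np.ndarray
    labels: np.ndarray
    cluster_sizes: list[int]
    params: ClusterParams
    frame_index: int = 0

    @property
    def n_molecules(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def membership_fraction(self) -> float:
        """Percent of molecules belonging to clusters of size >= min_size."""
        if self.n_molecules == 0:
            return 0.0
        return 100.0 * sum(self.cluster_sizes) / self.n_molecules


class _DisjointSet:
    """Union-find with path compression (plain, no rank: n is small)."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _linked_pairs(coms: np.ndarray, box, cutoff: float) -> np.ndarray:
    """Index pairs (i < j) with minimum-image distance <= cutoff."""
    n = len(coms)
    if n > _TREE_THRESHOLD:
        wrapped = box.wrap(coms)
        # boxsize requires points strictly inside [0, L)
        wrapped = np.minimum(wrapped, np.nextafter(box.lengths, 0.0))
        tree = cKDTree(wrapped, boxsize=box.lengths)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        return pairs
    iu, ju = np.triu_indices(n, k=1)
    d = coms[ju] - coms[iu]
    L = box.lengths
    d -= L * np.ceil(d / L - 0.5)
    dist = np.linalg.norm(d, axis=1)
    sel = dist <= cutoff
    return np.column_stack([iu[sel], ju[sel]])


def find_clusters(config: Configuration,
                  params: ClusterParams = ClusterParams()) -> ClusterAssignment:
    """Single-linkage clusters of molecules under a COM distance cutoff.

    Molecules i and j are linked when their minimum-image COM distance is
    <= ``params.cutoff``; connected components with at least
    ``params.min_size`` members become clusters, numbered by their
    smallest member position. Everything else is labelled UNCLUSTERED.
    """
    if params.cutoff >= config.box.half_min_edge:
        raise ValueError(
            f"cutoff {params.cutoff} A must be below half the smallest box "
            f"edge ({config.box.half_min_edge} A) for unambiguous images"
        )
    af = compute_axis_frame(config)
    n = af.n_molecules
    dsu = _DisjointSet(n)
    for i, j in _linked_pairs(af.coms, config.box, params.cutoff):
        dsu.union(int(i), int(j))
    roots = np.array([dsu.find(k) for k in range(n)])
    labels = np.full(n, UNCLUSTERED, dtype=int)
    sizes: list[int] = []
    next_label = 0
    component_of_root: dict[int, int] = {}
    root_counts = Counter(roots.tolist())
    for k in range(n):  # ascending order gives deterministic labels
        r = roots[k]
        if root_counts[r] < params.min_size:
            continue
        if r not in component_of_root:
            component_of_root[r] = next_label
            sizes.append(root_counts[r])
            next_label += 1
        labels[k] = component_of_root[r]
    return ClusterAssignment(molecule_ids=af.molecule_ids, labels=labels,
                             cluster_sizes=sizes, params=params,
                             frame_index=config.frame_index)


def membership_fraction_series(
    traj: Trajectory, params: ClusterParams = ClusterParams()
) -> tuple[np.ndarray, float]:
    """Per-frame cluster-membership percentages and their unweighted mean."""
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    fractions = np.array([
        find_clusters(frame, params).membership_fraction for frame in traj
    ])
    return fractions, float(fractions.mean())


def cluster_size_histogram(
    traj: Trajectory, params: ClusterParams = ClusterParams()
) -> tuple[dict[int, int], int]:
    """Cluster counts by size pooled over frames, plus the max size seen.

    Returns ``(histogram, max_size)``; the histogram is empty and
    max_size is 0 when no clusters are found.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    hist: Counter = Counter()
    for frame in traj:
        hist.update(find_clusters(frame, params).cluster_sizes)
    max_size = max(hist) if hist else 0
    return dict(sorted(hist.items())), max_size
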