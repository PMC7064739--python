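"""Distance-resolved orientational order, angle distributions, COM RDF.

The pairwise orientational order parameter is

    O(r) = < P2(cos theta_ij) >  over molecule pairs with COM separation r,

where theta_ij is the angle between the molecules' longest principal
axes and P2 is the second Legendre polynomial: O = 1 for parallel or
anti-parallel pairs, 0 for random mutual orientation, -0.5 for
perpendicular pairs. Distances use the minimum image convention; the
average pools every pair observation across frames (an ensemble and time
average) by default, with per-frame-mean averaging as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import Trajectory, compute_axis_frame, p2

__all__ = ["OrderProfile", "AngleDistribution", "RdfProfile",
           "order_profile", "angle_distribution", "com_rdf",
           "first_neighbor_cutoff"]


@dataclass
class OrderProfile:
    """Binned O(r): values are NaN (undefined), never 0, in empty bins."""

    bin_edges: np.ndarray
    o_values: np.ndarray
    pair_counts: np.ndarray
    frames_used: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class AngleDistribution:
    """Normalized pair-angle histogram for close pairs (separation <= r_max).

    ``density`` is a per-degree probability density; it integrates to 1
    over the bin range. ``oriented`` records whether the underlying axes
    carried a head/tail sign (range [0, 180]) or were folded to [0, 90].
    """

    bin_edges: np.ndarray
    density: np.ndarray
    pair_count: int
    r_max: float
    oriented: bool

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class RdfProfile:
    """Center-of-mass radial distribution function g(r).

    Normalized against the homogeneous ideal gas at the same density:
    g(r) = observed pair count in shell / (N(N-1)/2 * V_shell / V_box),
    averaged over frames. The 3D-homogeneity assumption is recorded in
    ``anisotropy_note`` because slab-confined systems violate it.
    """

    bin_edges: np.ndarray
    g_values: np.ndarray
    counts: np.ndarray
    n_molecules: int
    box_volume: float
    frames_used: int
    anisotropy_note: Optional[str] = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _pair_arrays(frame):
    """Minimum-image COM distances and axis dot-products for all pairs."""
    af = compute_axis_frame(frame)
    n = af.n_molecules
    iu, ju = np.triu_indices(n, k=1)
    d = af.coms[ju] - af.coms[iu]
    L = frame.box.lengths
    d -= L * np.ceil(d / L - 0.5)
    dist = np.linalg.norm(d, axis=1)
    cosang = np.clip(np.einsum("ij,ij->i", af.axes[iu], af.axes[ju]), -1.0, 1.0)
    return dist, cosang, af.oriented


def _check_traj(traj: Trajectory, r_max: float) -> None:
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    for frame in traj:
        if frame.n_molecules < 2:
            raise ValueError("need at least 2 molecules per frame")
        if r_max > frame.box.half_min_edge:
            raise ValueError(
                f"r_max {r_max} A exceeds half the smallest box edge "
                f"({frame.box.half_min_edge} A): minimum-image ambiguity"
            )


def order_profile(traj: Trajectory, bin_width: float = 0.5,
                  r_max: float = 20.0, averaging: str = "pooled") -> OrderProfile:
    """Distance-resolved pairwise orientational order parameter O(r).

    Parameters
    ----------
    averaging : {"pooled", "per_frame"}
        "pooled" gives every pair observation across all frames equal
        weight; "per_frame" averages per-frame bin means over the frames
        in which the bin is populated.
    """
    _check_traj(traj, r_max)
    if averaging not in ("pooled", "per_frame"):
        raise ValueError("averaging must be 'pooled' or 'per_frame'")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    nbins = len(edges) - 1
    counts = np.zeros(nbins, dtype=int)
    if averaging == "pooled":
        sums = np.zeros(nbins)
        for frame in traj:
            dist, cosang, _ = _pair_arrays(frame)
            sel = dist < edges[-1]
            idx = np.minimum((dist[sel] / bin_width).astype(int), nbins - 1)
            np.add.at(sums, idx, p2(cosang[sel]))
            np.add.at(counts, idx, 1)
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    else:
        frame_means = np.full((traj.n_frames, nbins), np.nan)
        for f, frame in enumerate(traj):
            dist, cosang, _ = _pair_arrays(frame)
            sel = dist < edges[-1]
            idx = np.minimum((dist[sel] / bin_width).astype(int), nbins - 1)
            s = np.zeros(nbins)
            c = np.zeros(nbins, dtype=int)
            np.add.at(s, idx, p2(cosang[sel]))
            np.add.at(c, idx, 1)
            frame_means[f, c > 0] = s[c > 0] / c[c > 0]
            counts += c
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            values = np.nanmean(frame_means, axis=0)
    return OrderProfile(bin_edges=edges, o_values=values, pair_counts=counts,
                        frames_used=traj.n_frames)


def angle_distribution(traj: Trajectory, r_max: float = 10.0,
                       bin_width: float = 5.0) -> AngleDistribution:
    """Distribution of inter-axis angles for pairs with separation <= r_max.

    Oriented axes (head/tail defined on every molecule) give angles on
    [0, 180] degrees; otherwise angles are folded to [0, 90] and a
    warning is issued.
    """
    _check_traj(traj, r_max)
    angles = []
    oriented = True
    for frame in traj:
        dist, cosang, frame_oriented = _pair_arrays(frame)
        oriented = oriented and frame_oriented
        angles.append(cosang[dist <= r_max])
    cosang = np.concatenate(angles)
    if cosang.size == 0:
        raise ValueError(
            f"no molecule pairs within r_max = {r_max} A across "
            f"{traj.n_frames} frame(s)"
        )
    if not oriented:
        warnings.warn(
            "axes carry no head/tail orientation; angles folded to [0, 90] degrees",
            stacklevel=2,
        )
        cosang = np.abs(cosang)
        theta_max = 90.0
    else:
        theta_max = 180.0
    theta = np.degrees(np.arccos(cosang))
    edges = np.arange(0.0, theta_max + bin_width, bin_width)
    hist, _ = np.histogram(theta, bins=edges)
    density = hist / (hist.sum() * bin_width)
    return AngleDistribution(bin_edges=edges, density=density,
                             pair_count=int(hist.sum()), r_max=r_max,
                             oriented=oriented)


def com_rdf(traj: Trajectory, bin_width: float = 0.5,
            r_max: float = 40.0) -> RdfProfile:
    """Center-of-mass radial distribution function.

    Shell volumes are exact ((4/3) pi (r2^3 - r1^3)); normalization
    assumes an isotropic homogeneous system.
    """
    _check_traj(traj, r_max)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    nbins = len(edges) - 1
    counts = np.zeros(nbins, dtype=int)
    n = traj[0].n_molecules
    vol = traj[0].box.volume
    for frame in traj:
        if frame.n_molecules != n:
            raise ValueError("frames must have a constant molecule count")
        dist, _, _ = _pair_arrays(frame)
        sel = dist < edges[-1]
        idx = np.minimum((dist[sel] / bin_width).astype(int), nbins - 1)
        np.add.at(counts, idx, 1)
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = traj.n_frames * (n * (n - 1) / 2.0) * shell / vol
    g = counts / ideal
    return RdfProfile(bin_edges=edges, g_values=g, counts=counts,
                      n_molecules=n, box_volume=vol,
                      frames_used=traj.n_frames,
                      anisotropy_note="normalization assumes 3D homogeneity")


def first_neighbor_cutoff(rdf: RdfProfile, smooth_window: int = 1) -> float:
    """Right edge of the first peak's basin in g(r), in Angstrom.

    Locates the first local maximum of g(r) (optionally smoothed with a
    centered moving average of ``smooth_window`` bins for noisy data) and
    then the first local minimum after it; returns the bin edge where the
    basin ends (the left edge of the minimum's bin). Used to justify a
    neighbor/cluster cutoff from the data rather than hard-coding one.

    Raises
    ------
    ValueError
        If g(r) is monotone or flat (no interior maximum followed by a
        minimum).
    """
    g = np.asarray(rdf.g_values, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        g = np.convolve(g, kernel, mode="same")
    # first local maximum: strictly above the left neighbor, not below right
    peak = None
    for i in range(1, len(g) - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 0:
            peak = i
            break
    if peak is None:
        raise ValueError("g(r) has no interior peak: cannot locate a "
                         "first-neighbor shell")
    for i in range(peak + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] <= g[i + 1]:
            return float(rdf.bin_edges[i])
    raise ValueError("g(r) has no local minimum beyond the first peak: "
                     "featureless or monotone tail")
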