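"""End-to-end analysis pipeline: order -> angles -> RDF -> clusters -> J/H.

A :class:`RunConfig` describes one run (input, selection, binning, cluster
parameters, seed, output directory). :func:`run_pipeline` executes every
stage, writes tidy CSV tables plus a machine-readable ``summary.json``,
and is byte-deterministic for a fixed config and seed: every output file
records the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as jio
from .clusters import ClusterParams, cluster_size_histogram, find_clusters, \
    membership_fraction_series
from .geometry import Trajectory
from .order import angle_distribution, com_rdf, order_profile
from .stacking import classify_clusters

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("jaggr.pipeline")

#: minimum number of close pairs required before attempting J/H statistics
MIN_PAIRS_FOR_CLASSIFICATION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    ``input_csv`` points at the tabular configuration format; alternatively
    ``structure`` (+ optional ``trajectory``) are standard files read via
    MDAnalysis with ``selection``. Bin widths and r_max are in Angstrom.
    """

    input_csv: Optional[str] = None
    structure: Optional[str] = None
    trajectory: Optional[str] = None
    selection: str = "all"
    head_atom_name: Optional[str] = None
    tail_atom_name: Optional[str] = None
    expected_count: Optional[int] = None
    order_bin_width: float = 0.5
    order_r_max: float = 20.0
    angle_bin_width: float = 5.0
    angle_r_max: float = 10.0
    rdf_bin_width: float = 0.5
    rdf_r_max: float = 40.0
    cluster_cutoff: float = 17.0
    cluster_min_size: int = 2
    close_range: float = 10.0
    seed: int = 0
    output_dir: str = "jaggr_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load(config: RunConfig) -> Trajectory:
    if config.input_csv:
        return jio.read_configuration_csv(config.input_csv)
    if config.structure:
        return jio.read_trajectory(
            config.structure, config.trajectory, config.selection,
            head_atom_name=config.head_atom_name,
            tail_atom_name=config.tail_atom_name,
            expected_count=config.expected_count,
        )
    raise ValueError("config must set input_csv or structure")


def _profile_frame(profile, value_col: str) -> pd.DataFrame:
    values = getattr(profile, {"o": "o_values", "g": "g_values",
                               "density": "density"}[value_col])
    counts = getattr(profile, "pair_counts",
                     getattr(profile, "counts", None))
    df = pd.DataFrame({
        "bin_left": profile.bin_edges[:-1],
        "bin_right": profile.bin_edges[1:],
        "value": values,
    })
    if counts is not None:
        df["count"] = counts
    return df


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the summary dictionary that is also written to
    ``summary.json``. The summary holds the mean cluster-membership
    percentage, max cluster size, the order-parameter plateau over the
    close range (mean of populated O(r) bins at r <= close_range), and
    the fraction of linked close pairs classified J (NaN when too few
    pairs qualify).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("pipeline start: hash=%s seed=%d", chash, config.seed)

    def stage(name, fn):
        try:
            logger.info("stage %s", name)
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    traj = stage("load", lambda: _load(config))

    order = stage("order_profile", lambda: order_profile(
        traj, bin_width=config.order_bin_width, r_max=config.order_r_max))
    _write_csv(_profile_frame(order, "o"), outdir / "order_profile.csv", chash)

    def _angles():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return angle_distribution(traj, r_max=config.angle_r_max,
                                      bin_width=config.angle_bin_width)
    angles = stage("angle_distribution", _angles)
    _write_csv(_profile_frame(angles, "density"),
               outdir / "angle_distribution.csv", chash)

    rdf = stage("rdf", lambda: com_rdf(
        traj, bin_width=config.rdf_bin_width, r_max=config.rdf_r_max))
    _write_csv(_profile_frame(rdf, "g"), outdir / "rdf.csv", chash)

    params = ClusterParams(cutoff=config.cluster_cutoff,
                           min_size=config.cluster_min_size)
    fractions, mean_fraction = stage(
        "clusters", lambda: membership_fraction_series(traj, params))
    _write_csv(pd.DataFrame({"frame": np.arange(len(fractions)),
                             "membership_percent": fractions}),
               outdir / "membership.csv", chash)
    hist, max_size = cluster_size_histogram(traj, params)
    _write_csv(pd.DataFrame({"size": list(hist.keys()),
                             "count": list(hist.values())}),
               outdir / "cluster_sizes.csv", chash)

    def _classify():
        rows = []
        n_j = n_linked = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for frame in traj:
                assignment = find_clusters(frame, params)
                for cc in classify_clusters(frame, assignment):
                    rows.append((frame.frame_index, cc.cluster_label, cc.size,
                                 cc.n_linked_pairs, cc.j_pair_fraction,
                                 cc.label))
                    if np.isfinite(cc.j_pair_fraction):
                        n_j += cc.j_pair_fraction * cc.n_linked_pairs
                        n_linked += cc.n_linked_pairs
        df = pd.DataFrame(rows, columns=["frame", "cluster", "size",
                                         "linked_pairs", "j_pair_fraction",
                                         "label"])
        frac = n_j / n_linked if n_linked >= MIN_PAIRS_FOR_CLASSIFICATION \
            else float("nan")
        return df, frac, n_linked
    cluster_table, j_fraction, n_linked = stage("classify", _classify)
    _write_csv(cluster_table, outdir / "cluster_classification.csv", chash)

    # pooled (pair-count-weighted) order parameter over the close range
    close = (order.bin_edges[1:] <= config.close_range) & (order.pair_counts > 0)
    if close.any():
        plateau = float(
            np.sum(order.o_values[close] * order.pair_counts[close])
            / order.pair_counts[close].sum())
    else:
        plateau = float("nan")

    per_mol = find_clusters(traj[0], params)
    _write_csv(pd.DataFrame({"molecule_id": per_mol.molecule_ids,
                             "cluster": per_mol.labels}),
               outdir / "labels_frame0.csv", chash)

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_frames": traj.n_frames,
        "n_molecules": traj[0].n_molecules,
        "membership_percent_mean": round(mean_fraction, 10),
        "membership_percent_per_frame": [round(float(v), 10) for v in fractions],
        "max_cluster_size": int(max_size),
        "cluster_size_histogram": {str(k): int(v) for k, v in hist.items()},
        "order_plateau_close_range": None if np.isnan(plateau)
        else round(plateau, 10),
        "close_range_A": config.close_range,
        "j_pair_fraction": None if np.isnan(j_fraction)
        else round(float(j_fraction), 10),
        "n_linked_pairs_classified": int(n_linked),
        "parameters": dataclasses.asdict(config),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline done: %s", outdir / "summary.json")
    return summary
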