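"""Motion scrubbing, inclusion rules, and connectivity-matrix construction.

The pipeline starts from denoised node time series (volumes x nodes) with a
per-volume framewise-displacement (FD) trace.  Volumes whose FD reaches the
scrubbing threshold (default 0.2 mm, removal rule ``FD >= threshold``) are
censored; subjects retaining fewer than a minimum number of volumes (default
120, i.e. "shorter than 120 volumes" excludes only counts below 120) are
excluded.  Connectivity is the Fisher r-to-z transform of node-by-node
Pearson correlations, stored as a symmetric matrix with zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import Atlas

#: Default FD scrubbing threshold in millimetres.
FD_THRESHOLD_MM = 0.2
#: Default minimum number of retained volumes for inclusion.
MIN_VOLUMES = 120
#: Correlations are capped at +/- (1 - R_CAP_EPS) before the Fisher transform
#: so that z stays finite on perfectly (anti-)correlated series.
R_CAP_EPS = 1e-7


@dataclass(frozen=True)
class TimeSeries:
    """Node time series (volumes x nodes) with an aligned FD trace in mm."""

    values: np.ndarray
    fd_per_volume: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        fd = np.asarray(self.fd_per_volume, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (volumes x nodes) array")
        if fd.ndim != 1 or fd.shape[0] != values.shape[0]:
            raise ValueError(
                f"fd_per_volume length {fd.shape[0] if fd.ndim == 1 else fd.shape} "
                f"does not match {values.shape[0]} volumes"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "fd_per_volume", fd)

    @property
    def n_volumes(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.values.shape[1])


def scrub_timeseries(ts: TimeSeries, fd_threshold: float = FD_THRESHOLD_MM) -> TimeSeries:
    """Remove volumes with FD at or above the threshold, preserving order.

    A volume with FD exactly equal to ``fd_threshold`` is removed.
    """
    if fd_threshold <= 0:
        raise ValueError("fd_threshold must be positive")
    keep = ts.fd_per_volume < fd_threshold
    return TimeSeries(values=ts.values[keep], fd_per_volume=ts.fd_per_volume[keep])


def passes_inclusion(ts_scrubbed: TimeSeries, min_volumes: int = MIN_VOLUMES) -> bool:
    """True iff the scrubbed series retains at least ``min_volumes`` volumes."""
    if min_volumes < 1:
        raise ValueError("min_volumes must be >= 1")
    return ts_scrubbed.n_volumes >= min_volumes


def fisher_z(r: np.ndarray, cap: float = 1.0 - R_CAP_EPS) -> np.ndarray:
    """Fisher r-to-z transform with |r| capped below 1 to keep z finite."""
    return np.arctanh(np.clip(r, -cap, cap))


def build_matrix(ts: TimeSeries, atlas: Atlas | None = None,
                 cap: float = 1.0 - R_CAP_EPS) -> np.ndarray:
    """Fisher-z connectivity matrix from node time series.

    Pearson correlations between all node pairs are Fisher transformed;
    the result is exactly symmetric with a zero diagonal.

    Raises
    ------
    ValueError
        If fewer than 3 volumes remain, a node has zero variance (named in
        the message), or the node count mismatches the atlas.
    """
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 volumes to estimate correlations")
    if atlas is not None and x.shape[1] != atlas.n_nodes:
        raise ValueError(
            f"time series has {x.shape[1]} nodes but atlas has {atlas.n_nodes}"
        )
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd <= 1e-12 * np.maximum(np.abs(x).max(axis=0), 1.0))
    if dead.size:
        names = [atlas.node_ids[i] if atlas is not None else i for i in dead]
        raise ValueError(f"zero-variance node(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    z = fisher_z(r, cap=cap)
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    np.fill_diagonal(z, 0.0)
    return z
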