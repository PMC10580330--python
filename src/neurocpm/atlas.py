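"""Parcellation atlas: node identifiers and their macroscale region labels.

An :class:`Atlas` assigns each network node to exactly one of a small set of
macroscale brain regions.  The default vocabulary holds the eleven regions
conventionally used to summarize the Shen 268-node functional parcellation
(prefrontal, motor strip, insula, parietal, temporal, occipital, limbic,
cerebellum, thalamus, basal ganglia, brainstem), but any label set can be
supplied for reduced or alternative parcellations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MACROSCALE_REGIONS: tuple[str, ...] = (
    "prefrontal",
    "motor_strip",
    "insula",
    "parietal",
    "temporal",
    "occipital",
    "limbic",
    "cerebellum",
    "thalamus",
    "basal_ganglia",
    "brainstem",
)


@dataclass(frozen=True)
class Atlas:
    """Ordered node identifiers and a node -> region mapping.

    Parameters
    ----------
    node_ids
        Integer node identifiers in matrix row/column order (typically 1..N).
    regions
        Region label for each node, aligned with ``node_ids``.
    vocabulary
        Allowed region labels.  Defaults to the eleven macroscale regions.
    """

    node_ids: tuple[int, ...]
    regions: tuple[str, ...]
    vocabulary: tuple[str, ...] = field(default=MACROSCALE_REGIONS)

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(self.regions):
            raise ValueError("node_ids and regions must have equal length")
        if len(self.node_ids) < 2:
            raise ValueError("an atlas needs at least 2 nodes")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        unknown = set(self.regions) - set(self.vocabulary)
        if unknown:
            raise ValueError(f"region labels outside vocabulary: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def region_labels(self) -> tuple[str, ...]:
        """Distinct region labels present, in vocabulary order."""
        present = set(self.regions)
        return tuple(r for r in self.vocabulary if r in present)

    def nodes_in_region(self, region: str) -> np.ndarray:
        """0-based positional indices of the nodes belonging to ``region``."""
        if region not in self.vocabulary:
            raise KeyError(f"unknown region {region!r}")
        return np.flatnonzero(np.asarray(self.regions, dtype=object) == region)

    def region_of_index(self) -> np.ndarray:
        """Region label per positional node index, as an object array."""
        return np.asarray(self.regions, dtype=object)

    def index_of_node(self, node_id: int) -> int:
        """Positional index of an atlas node id."""
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"node id {node_id} not in atlas") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": self.node_ids, "region_label": self.regions})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, vocabulary: tuple[str, ...] = MACROSCALE_REGIONS) -> "Atlas":
        missing = {"node_id", "region_label"} - set(frame.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        return cls(
            node_ids=tuple(int(v) for v in frame["node_id"]),
            regions=tuple(str(v) for v in frame["region_label"]),
            vocabulary=vocabulary,
        )

    @classmethod
    def uniform(cls, n_nodes: int, region_labels: tuple[str, ...] = MACROSCALE_REGIONS,
                sizes: dict[str, int] | None = None) -> "Atlas":
        """Build an atlas partitioning ``n_nodes`` into contiguous region blocks.

        Without ``sizes`` the nodes are split as evenly as possible over
        ``region_labels`` (earlier regions get the remainder).  ``sizes`` may
        fix the node count of specific regions; the rest share the remainder.
        """
        if n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        sizes = dict(sizes or {})
        unknown = set(sizes) - set(region_labels)
        if unknown:
            raise ValueError(f"sizes given for unknown regions: {sorted(unknown)}")
        fixed = sum(sizes.values())
        free = [r for r in region_labels if r not in sizes]
        remaining = n_nodes - fixed
        if remaining < 0 or (free and remaining < len(free)):
            raise ValueError("region sizes exceed n_nodes or leave a region empty")
        counts: list[int] = []
        for i, r in enumerate(region_labels):
            if r in sizes:
                counts.append(sizes[r])
            else:
                k = free.index(r)
                base, extra = divmod(remaining, len(free))
                counts.append(base + (1 if k < extra else 0))
        labels: list[str] = []
        for r, c in zip(region_labels, counts):
            labels.extend([r] * c)
        return cls(node_ids=tuple(range(1, n_nodes + 1)), regions=tuple(labels),
                   vocabulary=region_labels)
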