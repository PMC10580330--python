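"""Connection-pattern comparison between two connectomes.

Two predictive connectomes (e.g. for two different symptoms) are compared
at three levels.  At the node and region level, each node's or region's
*contribution* to a network is the fraction of the network's connections
incident to it; Pearson correlation between aligned contribution vectors
measures pattern similarity.  At the connection level, the overlap count of
two edge sets is tested against the hypergeometric law of drawing ``n``
edges from the ``M`` possible pairs of which ``K`` belong to the other set.
The default overlap p follows the exclusive convention
``p = 1 - HypergeomCDF(x; M, K, n) = P(X > x)``; the inclusive
field-standard enrichment form ``P(X >= x)`` is available via a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas
from .edges import EdgeMask, edge_pairs, n_edges

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContributionVector:
    """Per-node or per-region share of a network's connections."""

    level: str                # "node" | "region"
    labels: tuple            # node ids or region labels, aligned with values
    values: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.labels), name=self.level)


def _network_edges(mask: EdgeMask, sign: str) -> np.ndarray:
    if sign == "pos":
        return mask.pos_edges
    if sign == "neg":
        return mask.neg_edges
    raise ValueError("sign must be 'pos' or 'neg'")


def contribution(mask: EdgeMask, sign: str, atlas: Atlas,
                 level: str = "node") -> ContributionVector:
    """Contribution of each node or region to one network of a connectome.

    Node level: incident-edge count / network edge total (sums to 2 since
    each edge has two endpoints).  Region level: an edge counts once per
    distinct endpoint region, so a within-region edge counts once and the
    vector sums to between 1 and 2.
    """
    edges = _network_edges(mask, sign)
    if edges.size == 0:
        raise ValueError(f"the {sign} network is empty")
    if atlas.n_nodes != mask.n_nodes:
        raise ValueError("atlas and mask node counts differ")
    iu, ju = edge_pairs(mask.n_nodes)
    ei, ej = iu[edges], ju[edges]
    total = edges.size
    if level == "node":
        counts = np.bincount(ei, minlength=mask.n_nodes).astype(float)
        counts += np.bincount(ej, minlength=mask.n_nodes)
        return ContributionVector("node", tuple(atlas.node_ids), counts / total)
    if level == "region":
        regions = atlas.region_labels
        pos = {r: k for k, r in enumerate(regions)}
        node_region = np.array([pos[r] for r in atlas.regions])
        counts = np.zeros(len(regions))
        ri, rj = node_region[ei], node_region[ej]
        np.add.at(counts, ri, 1.0)
        between = ri != rj
        np.add.at(counts, rj[between], 1.0)
        return ContributionVector("region", regions, counts / total)
    raise ValueError("level must be 'node' or 'region'")


def compare_contributions(c1: ContributionVector,
                          c2: ContributionVector) -> tuple[float, float]:
    """Pearson correlation (r, p) between two aligned contribution vectors.

    Zero-variance input leaves the correlation undefined; logged and
    returned as (nan, nan).
    """
    if c1.level != c2.level or c1.labels != c2.labels:
        raise ValueError("contribution vectors must share level and atlas")
    a, b = c1.values, c2.values
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("zero-variance contribution vector: correlation undefined")
        return float("nan"), float("nan")
    r = stats.pearsonr(a, b)
    return float(r.statistic), float(r.pvalue)


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap test between two edge sets."""

    x: int        # overlap count
    M: int        # total possible edges
    K: int        # size of set A
    n: int        # size of set B
    p: float
    inclusive: bool = False


def _edge_set(mask_or_edges) -> np.ndarray:
    if isinstance(mask_or_edges, EdgeMask):
        return mask_or_edges.all_edges()
    return np.unique(np.asarray(mask_or_edges, dtype=np.int64))


def overlap_test(mask_a, mask_b, n_nodes: int | None = None,
                 m_total: int | None = None, inclusive: bool = False) -> OverlapResult:
    """Significance of the edge overlap between two networks.

    Accepts :class:`EdgeMask` objects (their full edge sets) or arrays of
    edge indices.  ``M`` defaults to all node pairs of the atlas.  The
    default (exclusive) convention is ``p = 1 - CDF(x) = P(X > x)``;
    ``inclusive=True`` gives ``P(X >= x)``.
    """
    a = _edge_set(mask_a)
    b = _edge_set(mask_b)
    if n_nodes is None:
        if isinstance(mask_a, EdgeMask):
            n_nodes = mask_a.n_nodes
        else:
            raise ValueError("n_nodes required when passing raw edge arrays")
    m = n_edges(n_nodes) if m_total is None else int(m_total)
    if a.size > m or b.size > m:
        raise ValueError("edge set larger than the edge universe M")
    x = int(np.intersect1d(a, b).size)
    dist = stats.hypergeom(m, a.size, b.size)
    p = float(dist.sf(x)) if not inclusive else float(dist.sf(x - 1))
    return OverlapResult(x=x, M=m, K=int(a.size), n=int(b.size), p=p,
                         inclusive=inclusive)


def cross_compare(connectome_a: EdgeMask, connectome_b: EdgeMask,
                  atlas: Atlas, inclusive: bool = False) -> pd.DataFrame:
    """All four sign-by-sign comparisons of two connectomes.

    For each pair in (A+,B+), (A-,B-), (A+,B-), (A-,B+): node-level and
    region-level contribution correlations plus the connection-level
    overlap test.  Pairs involving an empty network are skipped with a log
    entry (row retained, statistics NaN).
    """
    rows = []
    for sa, sb in (("pos", "pos"), ("neg", "neg"), ("pos", "neg"), ("neg", "pos")):
        ea = _network_edges(connectome_a, sa)
        eb = _network_edges(connectome_b, sb)
        row = {"network_a": sa, "network_b": sb,
               "n_a": int(ea.size), "n_b": int(eb.size), "skipped": False}
        if ea.size == 0 or eb.size == 0:
            logger.info("skipping comparison (A %s, B %s): empty network", sa, sb)
            row.update({"skipped": True, "node_r": np.nan, "node_p": np.nan,
                        "region_r": np.nan, "region_p": np.nan,
                        "overlap_x": np.nan, "overlap_p": np.nan})
            rows.append(row)
            continue
        for level in ("node", "region"):
            ca = contribution(connectome_a, sa, atlas, level)
            cb = contribution(connectome_b, sb, atlas, level)
            r, p = compare_contributions(ca, cb)
            row[f"{level}_r"] = r
            row[f"{level}_p"] = p
        ov = overlap_test(ea, eb, n_nodes=atlas.n_nodes, inclusive=inclusive)
        row["overlap_x"] = ov.x
        row["overlap_p"] = ov.p
        rows.append(row)
    return pd.DataFrame(rows)
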