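"""Delimited-text I/O for subject tables, atlases, matrices, and edge masks.

All formats are plain text.  Subject table: CSV with header ``id, age,
gender, duration_years, score_ar, score_tremor, mean_fd, group``.  Atlas
table: CSV with ``node_id, region_label``.  Connectivity matrices: one
whitespace-delimited N x N file per subject, named ``<id>.txt``.  Edge
masks: CSV with ``node_i, node_j, sign`` using 1-based atlas node ids;
pairs are canonicalized to i < j on read and write.  Floats are written
with 17 significant digits so write-then-read round trips bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, MACROSCALE_REGIONS
from .edges import EdgeMask, edge_pairs, edge_index

SUBJECT_COLUMNS = (
    "id", "age", "gender", "duration_years", "score_ar", "score_tremor",
    "mean_fd", "group",
)

FLOAT_FMT = "%.17g"


def read_subject_table(path) -> pd.DataFrame:
    """Read and validate a subject table; missing columns raise."""
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table {path}: missing column(s) {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"subject table {path}: duplicate id {dup!r}")
    bad_gender = ~df["gender"].isin(["M", "F"]) & df["gender"].notna()
    if bad_gender.any():
        line = int(bad_gender.idxmax()) + 2  # header + 1-based
        raise ValueError(f"subject table {path}, line {line}: gender must be M or F")
    bad_group = ~df["group"].isin(["patient", "control"])
    if bad_group.any():
        line = int(bad_group.idxmax()) + 2
        raise ValueError(
            f"subject table {path}, line {line}: group must be patient or control"
        )
    return df


def write_subject_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing column(s) {missing}")
    df.to_csv(path, index=False)


def read_atlas(path, vocabulary=MACROSCALE_REGIONS) -> Atlas:
    df = pd.read_csv(path)
    return Atlas.from_frame(df, vocabulary=vocabulary)


def write_atlas(atlas: Atlas, path) -> None:
    atlas.to_frame().to_csv(path, index=False)


def read_matrix(path, n_nodes: int | None = None) -> np.ndarray:
    """Read one N x N connectivity matrix; optionally check dimensions."""
    z = np.loadtxt(path, ndmin=2)
    if z.shape[0] != z.shape[1]:
        raise ValueError(f"matrix file {path}: shape {z.shape} is not square")
    if n_nodes is not None and z.shape[0] != n_nodes:
        raise ValueError(
            f"matrix file {path}: {z.shape[0]} nodes, atlas expects {n_nodes}"
        )
    return z


def write_matrix(z: np.ndarray, path) -> None:
    z = np.asarray(z, float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("matrix must be square")
    np.savetxt(path, z, fmt=FLOAT_FMT)


def matrix_path(directory, subject_id: str) -> Path:
    return Path(directory) / f"{subject_id}.txt"


def write_matrices(matrices: np.ndarray, ids, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for z, sid in zip(matrices, ids):
        write_matrix(z, matrix_path(directory, sid))


def read_matrices(directory, ids, n_nodes: int | None = None) -> np.ndarray:
    """Stack of per-subject matrices keyed by subject id."""
    out = []
    for sid in ids:
        p = matrix_path(directory, sid)
        if not p.exists():
            raise FileNotFoundError(f"no matrix file for subject {sid!r}: {p}")
        out.append(read_matrix(p, n_nodes=n_nodes))
    shapes = {z.shape for z in out}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent matrix dimensions: {sorted(shapes)}")
    return np.stack(out)


def read_mask(path, n_nodes: int) -> EdgeMask:
    """Read a signed edge list (1-based node ids); pairs canonicalized."""
    df = pd.read_csv(path)
    missing = {"node_i", "node_j", "sign"} - set(df.columns)
    if missing:
        raise ValueError(f"mask file {path}: missing column(s) {sorted(missing)}")
    pos_pairs, neg_pairs = [], []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        i, j, sign = int(row.node_i) - 1, int(row.node_j) - 1, int(row.sign)
        if not (0 <= i < n_nodes and 0 <= j < n_nodes) or i == j:
            raise ValueError(f"mask file {path}, line {row_num}: bad pair "
                             f"({row.node_i}, {row.node_j}) for {n_nodes} nodes")
        if sign == 1:
            pos_pairs.append((i, j))
        elif sign == -1:
            neg_pairs.append((i, j))
        else:
            raise ValueError(f"mask file {path}, line {row_num}: sign must be +1/-1")
    return EdgeMask.from_pairs(n_nodes, pos_pairs, neg_pairs)


def write_mask(mask: EdgeMask, path) -> None:
    iu, ju = edge_pairs(mask.n_nodes)
    rows = []
    for sign, edges in ((1, mask.pos_edges), (-1, mask.neg_edges)):
        for k in edges:
            rows.append({"node_i": int(iu[k]) + 1, "node_j": int(ju[k]) + 1,
                         "sign": sign})
    pd.DataFrame(rows, columns=["node_i", "node_j", "sign"]).to_csv(path, index=False)


def read_truth(path, n_nodes: int):
    """Read a planted-truth edge list (node_i, node_j, sign, slope)."""
    df = pd.read_csv(path)
    missing = {"node_i", "node_j", "sign", "slope"} - set(df.columns)
    if missing:
        raise ValueError(f"truth file {path}: missing column(s) {sorted(missing)}")
    idx = np.asarray(edge_index(df["node_i"].to_numpy() - 1,
                                df["node_j"].to_numpy() - 1, n_nodes))
    sign = df["sign"].to_numpy()
    return (np.sort(idx[sign > 0]), np.sort(idx[sign < 0]),
            dict(zip(idx.tolist(), df["slope"].tolist())))
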