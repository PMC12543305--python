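"""Readers and writers for the pipeline's text formats.

On-disk unit conventions: SWC skeleton coordinates and atlas CSV coordinates
are micrometers (a header comment in SWC declares the scale); everything in
memory is millimeters.  Networks travel either as dense CSV with header
labels or as 3-column edge-list TSV (source, target, weight; weight = w_ij =
flow from source to target); both dialects produce identical matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, split_label
from .skeleton import SkeletonTree

UM_PER_MM = 1000.0


# -- SWC skeletons -----------------------------------------------------------

def read_swc(path, unit_scale_um_per_mm: float = UM_PER_MM) -> SkeletonTree:
    """Read a standard 7-column SWC file into a skeleton (coordinates → mm)."""
    node_ids, types, xyz, parents = [], [], [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid, t = int(parts[0]), int(parts[1])
            x, y, z, _r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparsable SWC row") from exc
        node_ids.append(nid)
        types.append(t)
        xyz.append((x, y, z))
        parents.append(parent)
    if not node_ids:
        raise ValueError(f"{path}: empty SWC file")
    try:
        return SkeletonTree(
            node_ids=np.array(node_ids),
            parents=np.array(parents),
            xyz=np.array(xyz) / unit_scale_um_per_mm,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_swc(tree: SkeletonTree, path, unit_scale_um_per_mm: float = UM_PER_MM) -> None:
    """Write a skeleton as SWC (coordinates scaled to µm)."""
    lines = [
        "# SWC skeleton; coordinates in micrometers "
        f"({unit_scale_um_per_mm:g} um per mm internal unit)",
        "# id type x y z radius parent",
    ]
    for k, nid in enumerate(tree.node_ids):
        x, y, z = tree.xyz[k] * unit_scale_um_per_mm
        t = 1 if int(tree.parents[k]) == -1 else 0
        lines.append(f"{int(nid)} {t} {x:.6f} {y:.6f} {z:.6f} 1.0 {int(tree.parents[k])}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_synapse_nodes(tree: SkeletonTree, path) -> None:
    """Synaptic-point TSV keyed by SWC node id (node_id, role)."""
    rows = [(int(n), "pre") for n in sorted(tree.presyn_nodes)]
    rows += [(int(n), "post") for n in sorted(tree.postsyn_nodes)]
    pd.DataFrame(rows, columns=["node_id", "role"]).to_csv(path, sep="\t", index=False)


def attach_synapses(tree: SkeletonTree, path) -> SkeletonTree:
    """Return a copy of the tree with synaptic nodes from a TSV attached."""
    df = pd.read_csv(path, sep="\t")
    pre = frozenset(df.loc[df["role"] == "pre", "node_id"].astype(int))
    post = frozenset(df.loc[df["role"] == "post", "node_id"].astype(int))
    return SkeletonTree(
        node_ids=tree.node_ids,
        parents=tree.parents,
        xyz=tree.xyz,
        presyn_nodes=pre,
        postsyn_nodes=post,
        neuron_id=tree.neuron_id,
    )


# -- atlas -------------------------------------------------------------------

def write_atlas_csv(atlas: RegionAtlas, path) -> None:
    """Atlas CSV: label, hemisphere, x, y, z (coordinates in µm)."""
    rows = []
    for lab, (x, y, z) in zip(atlas.labels, atlas.centroids * UM_PER_MM):
        rows.append((lab, split_label(lab)[1], x, y, z))
    pd.DataFrame(rows, columns=["label", "hemisphere", "x_um", "y_um", "z_um"]).to_csv(
        path, index=False
    )


def read_atlas_csv(path) -> RegionAtlas:
    df = pd.read_csv(path)
    return RegionAtlas(
        labels=tuple(df["label"]),
        centroids=df[["x_um", "y_um", "z_um"]].to_numpy() / UM_PER_MM,
    )


# -- networks ----------------------------------------------------------------

def write_network_csv(w: np.ndarray, labels, path) -> None:
    pd.DataFrame(np.asarray(w, float), index=list(labels), columns=list(labels)).to_csv(path)


def write_edge_list(w: np.ndarray, labels, path) -> None:
    w = np.asarray(w, float)
    labels = list(labels)
    i, j = np.nonzero(w)
    df = pd.DataFrame(
        dict(
            source=[labels[a] for a in i],
            target=[labels[b] for b in j],
            weight=w[i, j],
        )
    )
    df.to_csv(path, sep="\t", index=False)


def read_network(path) -> tuple[np.ndarray, tuple]:
    """Read a labeled weight matrix from dense CSV or edge-list TSV.

    Returns ``(w, labels)``.  Duplicate edge rows with conflicting weights
    raise an error.
    """
    path = Path(path)
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    if "\t" in head:
        df = pd.read_csv(path, sep="\t")
        labels = sorted(set(df["source"]) | set(df["target"]))
        idx = {l: k for k, l in enumerate(labels)}
        n = len(labels)
        w = np.zeros((n, n))
        seen = {}
        for s, t, v in df[["source", "target", "weight"]].itertuples(index=False):
            key = (s, t)
            if key in seen and not np.isclose(seen[key], v):
                raise ValueError(f"conflicting duplicate edge {key} in {path}")
            seen[key] = v
            w[idx[s], idx[t]] = v
        return w, tuple(labels)
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: dense CSV row/column labels differ")
    return df.to_numpy(dtype=float), tuple(df.columns)


def read_edge_list_with_labels(path, labels) -> np.ndarray:
    """Edge-list TSV against a declared label set (empty list → zero matrix)."""
    labels = list(labels)
    idx = {l: k for k, l in enumerate(labels)}
    n = len(labels)
    w = np.zeros((n, n))
    df = pd.read_csv(path, sep="\t")
    for s, t, v in df[["source", "target", "weight"]].itertuples(index=False):
        w[idx[s], idx[t]] = v
    return w


# -- tables / json -----------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
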