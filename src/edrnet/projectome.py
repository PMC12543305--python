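"""Region-level weighted network (projectome) construction.

A neuron's information flow is summarized by the fractions of its postsynaptic
sites (incoming) and presynaptic sites (outgoing) per region.  Treating the
incoming and outgoing placement as independent, the outer product of the two
fraction vectors gives that neuron's region-to-region flow matrix; summing
over all intrinsic neurons yields the raw connectivity matrix ``W_raw``.
Column normalization turns it into ``w``, where ``w[i, j]`` is the probability
of information from region i flowing to region j and each column with any
flow sums to 1 — the analogue of the fraction-of-labeled-neurons convention of
retrograde tracing studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

log = logging.getLogger(__name__)

DEFAULT_MIN_SYNAPSES = 5


class EmptyProjectomeError(ValueError):
    pass


@dataclass(frozen=True)
class Projectome:
    """Directed region-level weighted network.

    Attributes
    ----------
    labels : tuple of str
    W_raw : (N, N) array
        Summed per-neuron flow matrices (nonnegative).
    w : (N, N) array
        Column-normalized weights.
    """

    labels: tuple
    W_raw: np.ndarray
    w: np.ndarray
    _A: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        W = np.asarray(self.W_raw, dtype=float)
        w = np.asarray(self.w, dtype=float)
        N = len(self.labels)
        if W.shape != (N, N) or w.shape != (N, N):
            raise ValueError("matrix shapes must be (N, N) matching labels")
        if (W < 0).any() or (w < 0).any():
            raise ValueError("projectome weights must be nonnegative")
        colsums = w.sum(axis=0)
        bad = (colsums > 0) & ~np.isclose(colsums, 1.0, atol=1e-9)
        if bad.any():
            raise ValueError("columns of w with positive entries must sum to 1")
        A = (w > 0).astype(np.int8)
        np.fill_diagonal(A, 0)
        object.__setattr__(self, "W_raw", W)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "_A", A)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def A(self) -> np.ndarray:
        """Binary adjacency: A[i, j] = 1 iff w[i, j] > 0 (diagonal excluded)."""
        return self._A.copy()

    @property
    def M(self) -> int:
        """Number of directed binary links (positive off-diagonal weights)."""
        return int(self._A.sum())

    @property
    def density_percent(self) -> float:
        """Link density 100·M/(N(N−1)) in percent."""
        N = self.n_regions
        return 100.0 * self.M / (N * (N - 1))

    def offdiag_weights(self) -> np.ndarray:
        """Positive off-diagonal weights (the link weights)."""
        mask = self._A.astype(bool)
        return self.w[mask]


def density_percent(N: int, M: int) -> float:
    """Directed link density in percent, 100·M/(N(N−1))."""
    if N < 2:
        raise ValueError("need at least 2 regions")
    return 100.0 * M / (N * (N - 1))


def synapse_fractions(
    neuron_rows: pd.DataFrame, atlas: RegionAtlas
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region in/out synapse fractions for one neuron.

    ``in`` fractions come from postsynaptic rows, ``out`` fractions from
    presynaptic rows; each vector sums to 1.
    """
    N = atlas.n_regions
    in_counts = np.zeros(N)
    out_counts = np.zeros(N)
    for role, region in zip(neuron_rows["role"], neuron_rows["region"]):
        idx = atlas.index_of(region)  # KeyError for unknown regions
        if role == "post":
            in_counts[idx] += 1
        elif role == "pre":
            out_counts[idx] += 1
        else:
            raise ValueError(f"unknown synapse role {role!r}")
    if in_counts.sum() == 0 or out_counts.sum() == 0:
        raise ValueError("neuron needs at least one synapse of each role")
    return in_counts / in_counts.sum(), out_counts / out_counts.sum()


def neuron_flow_matrix(in_fraction: np.ndarray, out_fraction: np.ndarray) -> np.ndarray:
    """Outer product of in/out fraction vectors; entries sum to 1."""
    return np.outer(np.asarray(in_fraction, float), np.asarray(out_fraction, float))


def threshold_connections(connections: pd.DataFrame, min_synapses: int = DEFAULT_MIN_SYNAPSES) -> pd.DataFrame:
    """Keep neuron-to-neuron connections with at least ``min_synapses`` synapses.

    ``connections`` must have a ``count`` column (plus any identifying
    columns).  Connections below the threshold are dropped entirely, so their
    synapses never enter fraction computation.
    """
    if min_synapses < 1:
        raise ValueError("min_synapses must be >= 1")
    return connections[connections["count"] >= min_synapses].reset_index(drop=True)


def column_normalize(W_raw: np.ndarray) -> np.ndarray:
    """Divide each column by its sum; zero columns are left zero (and logged)."""
    W = np.asarray(W_raw, dtype=float)
    if (W < 0).any():
        raise ValueError("matrix must be nonnegative")
    colsums = W.sum(axis=0)
    zero = colsums == 0
    if zero.any():
        log.warning("column_normalize: %d zero column(s) left unnormalized", int(zero.sum()))
    safe = np.where(zero, 1.0, colsums)
    return W / safe


def build_projectome(
    synapses: pd.DataFrame,
    classes: pd.DataFrame,
    atlas: RegionAtlas,
    min_synapses: int = DEFAULT_MIN_SYNAPSES,
    connections: pd.DataFrame | None = None,
) -> Projectome:
    """Build the projectome from a synapse table.

    Only neurons classed ``intrinsic`` contribute.  If a neuron-pair
    ``connections`` table (pre_id, post_id, count) is supplied it is
    thresholded at ``min_synapses`` first and synapses of dropped connections
    are excluded (the packaged synthetic tables are already per-point, so by
    default no connection filter applies).
    """
    intrinsic = set(classes.loc[classes["class"] == "intrinsic", "neuron_id"])
    syn = synapses[synapses["neuron_id"].isin(intrinsic)]
    if connections is not None:
        kept = threshold_connections(connections, min_synapses)
        kept_ids = set(kept["pre_id"]) | set(kept["post_id"])
        syn = syn[syn["neuron_id"].isin(kept_ids)]

    unknown = set(syn["region"]) - set(atlas.labels)
    if unknown:
        raise KeyError(f"unknown region label(s): {sorted(unknown)}")

    N = atlas.n_regions
    # counts[neuron, region] per role, via a pivot; W_raw = InFrac^T @ OutFrac
    table = (
        syn.groupby(["neuron_id", "role", "region"], sort=False)
        .size()
        .rename("count")
        .reset_index()
    )
    region_idx = {lab: i for i, lab in enumerate(atlas.labels)}
    neuron_ids = sorted(set(table["neuron_id"]))
    nid_idx = {n: i for i, n in enumerate(neuron_ids)}
    n_neu = len(neuron_ids)
    in_counts = np.zeros((n_neu, N))
    out_counts = np.zeros((n_neu, N))
    for nid, role, region, count in table.itertuples(index=False):
        k = nid_idx[nid]
        if role == "post":
            in_counts[k, region_idx[region]] += count
        else:
            out_counts[k, region_idx[region]] += count
    has_both = (in_counts.sum(axis=1) > 0) & (out_counts.sum(axis=1) > 0)
    n_skipped = int((~has_both).sum())
    if n_skipped:
        log.warning("build_projectome: skipped %d neuron(s) missing a synapse role", n_skipped)
    in_counts = in_counts[has_both]
    out_counts = out_counts[has_both]
    if len(in_counts) == 0:
        raise EmptyProjectomeError("no intrinsic neuron contributes both synapse roles")
    in_frac = in_counts / in_counts.sum(axis=1, keepdims=True)
    out_frac = out_counts / out_counts.sum(axis=1, keepdims=True)
    W_raw = in_frac.T @ out_frac
    return Projectome(labels=atlas.labels, W_raw=W_raw, w=column_normalize(W_raw))


def distance_matrix(atlas: RegionAtlas) -> np.ndarray:
    """Euclidean centroid distance matrix in mm (symmetric, zero diagonal)."""
    return atlas.distance_matrix()
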