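"""Binary and weighted network statistics, and data-vs-model RMSD comparison.

Conventions used throughout:

* ``A`` is a square 0/1 adjacency matrix with zero diagonal; ``A[i, j] = 1``
  means a directed link i→j.
* ``w`` is a nonnegative weight matrix with weights in [0, 1]; link lengths
  are ``l_ij = −ln w_ij`` (natural log — shortest-path structure and RMSD
  argmins are invariant under the base, which only rescales all lengths).
* Node distances ("resistances") r_ij are weighted shortest-path lengths on
  l; conductance 1/r enters the global and local communication efficiencies.
* For clustering coefficient and local efficiency the neighborhood of a node
  is the union of its in- and out-neighbors, while connectivity *among* the
  neighbors is read from the directed matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.diag(A).any():
        raise ValueError("adjacency diagonal must be zero")
    return (A != 0).astype(np.int8)


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if (w > 1).any():
        raise ValueError("weights must not exceed 1 (they are probabilities)")
    return w


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


# ---------------------------------------------------------------------------
# binary properties
# ---------------------------------------------------------------------------

def degree_spectra(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (descending) in-degree and out-degree vectors."""
    A = _check_adjacency(A)
    k_in = np.sort(A.sum(axis=0))[::-1]
    k_out = np.sort(A.sum(axis=1))[::-1]
    return k_in, k_out


def reciprocity_counts(A: np.ndarray) -> tuple[int, int]:
    """(unidirectional, bidirectional) unordered pair counts."""
    A = _check_adjacency(A)
    both = A & A.T
    either = A | A.T
    n_bi = int(np.triu(both, 1).sum())
    n_uni = int(np.triu(either, 1).sum()) - n_bi
    return n_uni, n_bi


@dataclass(frozen=True)
class PathLengthResult:
    value: float
    n_unreachable: int


def average_binary_path_length(A: np.ndarray) -> PathLengthResult:
    """Mean directed hop distance over reachable ordered pairs i≠j."""
    A = _check_adjacency(A)
    n = A.shape[0]
    d = shortest_path(csr_array(A), method="D", directed=True, unweighted=True)
    off = d[_offdiag_mask(n)]
    finite = np.isfinite(off)
    n_inf = int((~finite).sum())
    value = float(off[finite].mean()) if finite.any() else float("nan")
    return PathLengthResult(value=value, n_unreachable=n_inf)


def clustering_coefficient(A: np.ndarray) -> float:
    """Mean over nodes of the directed-link density among each node's neighbors.

    Neighbors are the union of in- and out-neighbors; a node with fewer than
    two neighbors contributes 0.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    und = (A | A.T).astype(bool)
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(und[i])
        k = len(nb)
        if k < 2:
            continue
        sub = A[np.ix_(nb, nb)]
        total += sub.sum() / (k * (k - 1))
    return total / n if n else float("nan")


# -- triad census ------------------------------------------------------------

def _build_triad_lookup() -> tuple[np.ndarray, int]:
    """Map each 6-bit labeled 3-node digraph code to its isomorphism class.

    Bit order of the code for nodes (x, y, z):
    (x→y, y→x, x→z, z→x, y→z, z→y).  Classes are ordered by (edge count,
    canonical code), so the last class is the fully reciprocal triangle.
    """
    perms = list(itertools.permutations(range(3)))

    def decode(code):
        a = np.zeros((3, 3), dtype=int)
        pairs = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        for b, (x, y) in enumerate(pairs):
            a[x, y] = (code >> b) & 1
        return a

    def encode(a):
        pairs = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        return sum(a[x, y] << b for b, (x, y) in enumerate(pairs))

    canon = np.zeros(64, dtype=int)
    for code in range(64):
        a = decode(code)
        canon[code] = min(encode(a[np.ix_(p, p)]) for p in perms)
    classes = sorted(set(canon.tolist()), key=lambda c: (bin(c).count("1"), c))
    cls_index = {c: k for k, c in enumerate(classes)}
    lookup = np.array([cls_index[c] for c in canon], dtype=np.int64)
    return lookup, len(classes)


TRIAD_LOOKUP, N_TRIAD_CLASSES = _build_triad_lookup()


def triad_census(A: np.ndarray) -> np.ndarray:
    """Counts of the 16 directed 3-node configurations; sums to C(N, 3)."""
    A = _check_adjacency(A)
    n = A.shape[0]
    if n < 3:
        return np.zeros(N_TRIAD_CLASSES, dtype=np.int64)
    trips = np.array(list(itertools.combinations(range(n), 3)), dtype=np.int64)
    x, y, z = trips[:, 0], trips[:, 1], trips[:, 2]
    codes = (
        A[x, y]
        | (A[y, x] << 1)
        | (A[x, z] << 2)
        | (A[z, x] << 3)
        | (A[y, z] << 4)
        | (A[z, y] << 5)
    )
    return np.bincount(TRIAD_LOOKUP[codes.astype(np.int64)], minlength=N_TRIAD_CLASSES)


# -- cliques -----------------------------------------------------------------

def _reciprocal_graph(A: np.ndarray) -> ig.Graph:
    A = _check_adjacency(A)
    sym = np.triu(A & A.T, 1)
    edges = list(zip(*np.nonzero(sym)))
    return ig.Graph(n=A.shape[0], edges=edges, directed=False)


def clique_counts(A: np.ndarray, sizes) -> dict[int, int]:
    """Number of complete subgraphs per requested size.

    A directed k-clique is k nodes pairwise connected in both directions, so
    cliques are counted on the undirected graph of reciprocal pairs.  Counts
    include *all* complete subgraphs of each size, not only maximal ones.
    """
    g = _reciprocal_graph(A)
    n = g.vcount()
    out = {}
    for s in sizes:
        s = int(s)
        if s > n:
            out[s] = 0
        elif s == 1:
            out[s] = n
        else:
            out[s] = len(g.cliques(min=s, max=s))
    return out


@dataclass(frozen=True)
class MaxCliqueSummary:
    size: int
    count: int
    members: frozenset


def max_clique_summary(A: np.ndarray) -> MaxCliqueSummary:
    """Size and multiplicity of the maximum cliques and their member union."""
    g = _reciprocal_graph(A)
    largest = g.largest_cliques()
    if not largest or len(largest[0]) == 0:
        return MaxCliqueSummary(size=0, count=0, members=frozenset())
    members = frozenset(v for c in largest for v in c)
    return MaxCliqueSummary(size=len(largest[0]), count=len(largest), members=members)


# ---------------------------------------------------------------------------
# weighted properties
# ---------------------------------------------------------------------------

def link_lengths(w: np.ndarray) -> np.ndarray:
    """l_ij = −ln w_ij for present links; absent links are NaN."""
    w = _check_weights(w)
    l = np.full(w.shape, np.nan)
    pos = w > 0
    l[pos] = -np.log(w[pos])
    if np.any(w == 1):
        log.warning("link_lengths: weight exactly 1 gives zero-length link")
    return l


def _length_graph(w: np.ndarray) -> csr_array:
    w = _check_weights(w)
    n = w.shape[0]
    mask = (w > 0) & _offdiag_mask(n)
    i, j = np.nonzero(mask)
    return csr_array((-np.log(w[mask]), (i, j)), shape=(n, n))


def node_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path lengths on l = −ln w (inf if unreachable)."""
    return shortest_path(_length_graph(w), method="D", directed=True)


def global_efficiency(w: np.ndarray, r: np.ndarray | None = None) -> float:
    """Mean conductance 1/r over ordered pairs; unreachable pairs contribute 0.

    Pairs at distance exactly 0 (chains of weight-1 links) are excluded from
    the mean and logged.
    """
    if r is None:
        r = node_distances(w)
    n = r.shape[0]
    off = r[_offdiag_mask(n)]
    zero = off == 0
    if zero.any():
        log.warning("global_efficiency: excluded %d zero-distance pair(s)", int(zero.sum()))
    off = off[~zero]
    if off.size == 0:
        return 0.0
    inv = np.where(np.isfinite(off), 1.0 / np.where(off == 0, 1, off), 0.0)
    return float(inv.mean())


def local_efficiency(w: np.ndarray) -> float:
    """Mean over nodes of neighbor-to-neighbor conductance with the node removed."""
    w = _check_weights(w)
    n = w.shape[0]
    A = (w > 0) & _offdiag_mask(n)
    und = A | A.T
    total = 0.0
    L = _length_graph(w)
    for i in range(n):
        nb = np.flatnonzero(und[i])
        k = len(nb)
        if k < 2:
            continue
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = L[keep][:, keep]
        nb_sub = np.searchsorted(np.flatnonzero(keep), nb)
        r = shortest_path(sub, method="D", directed=True, indices=nb_sub)
        rr = r[:, nb_sub]
        mask = ~np.eye(k, dtype=bool)
        vals = rr[mask]
        inv = np.where(np.isfinite(vals) & (vals > 0), 1.0 / np.where(vals == 0, 1, vals), 0.0)
        total += inv.sum() / (k * (k - 1))
    return total / n if n else float("nan")


def _sorted_edges(w: np.ndarray, order: str) -> list[tuple[int, int]]:
    n = w.shape[0]
    mask = (w > 0) & _offdiag_mask(n)
    i, j = np.nonzero(mask)
    vals = w[i, j]
    if order == "weakest_first":
        key = np.lexsort((j, i, vals))
    elif order == "strongest_first":
        key = np.lexsort((j, i, -vals))
    else:
        raise ValueError("order must be 'weakest_first' or 'strongest_first'")
    return [(int(a), int(b)) for a, b in zip(i[key], j[key])]


def efficiency_vs_density(
    w: np.ndarray,
    order: str = "weakest_first",
    density_grid=None,
    compute_local: bool = True,
) -> pd.DataFrame:
    """E_g (and E_l) as links are removed one by one in weight order.

    Removal happens without renormalization; ties are broken by
    (weight, source, target) for determinism.  Densities are fractions of
    N(N−1).  The curve starts at the intact network's efficiencies.
    """
    w = _check_weights(w)
    n = w.shape[0]
    edges = _sorted_edges(w, order)
    M0 = len(edges)
    cap = n * (n - 1)
    if density_grid is None:
        density_grid = np.linspace(M0 / cap, 0.02, 20)
    rows = []
    for dens in density_grid:
        m_keep = int(np.clip(round(dens * cap), 0, M0))
        w_cur = w.copy()
        for (a, b) in edges[: M0 - m_keep]:
            w_cur[a, b] = 0.0
        eg = global_efficiency(w_cur)
        el = local_efficiency(w_cur) if compute_local else np.nan
        rows.append(dict(density=m_keep / cap, n_links=m_keep, E_g=eg, E_l=el))
    return pd.DataFrame(rows)


def _is_connected(w_mask: np.ndarray, mode: str) -> bool:
    n = w_mask.shape[0]
    g = csr_array(w_mask.astype(np.int8))
    ncomp, _ = connected_components(
        g, directed=True, connection="strong" if mode == "strong" else "weak"
    )
    return ncomp == 1


def extract_backbone(w: np.ndarray, mode: str, target_density: float) -> np.ndarray:
    """Greedy weakest-link-removal backbone preserving connectivity.

    Repeatedly deletes the weakest remaining link whose deletion keeps the
    network strongly (``mode='strong'``) or weakly (``mode='weak'``)
    connected, skipping links whose removal would disconnect it, until the
    target density (fraction of N(N−1)) is reached or nothing more is
    removable.  Returns the boolean kept-link matrix.

    A link skipped as a bridge can never become removable later (connectivity
    only degrades as links are removed), so a single ascending pass suffices.
    """
    if mode not in ("strong", "weak"):
        raise ValueError("mode must be 'strong' or 'weak'")
    w = _check_weights(w)
    n = w.shape[0]
    mask = (w > 0) & _offdiag_mask(n)
    if not _is_connected(mask, mode):
        raise ValueError(f"intact network is not {mode}ly connected")
    cap = n * (n - 1)
    target_links = int(np.ceil(target_density * cap))
    for (a, b) in _sorted_edges(w, "weakest_first"):
        if mask.sum() <= target_links:
            break
        mask[a, b] = False
        if not _is_connected(mask, mode):
            mask[a, b] = True  # bridge: keep permanently
    return mask


# ---------------------------------------------------------------------------
# RMSD comparison
# ---------------------------------------------------------------------------

def rmsd(x, y) -> float:
    """Root-mean-square difference of two equal-length vectors."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((x - y) ** 2)))


DEFAULT_REPORT_PROPERTIES = (
    "degree_spectra",
    "reciprocity",
    "log10_weights",
    "out_strength",
    "node_distances",
    "triad_census",
    "apl",
    "clustering",
)


@dataclass
class PropertyReport:
    """Named properties of one network (raw samples for histogram properties)."""

    n_nodes: int = 0
    n_links: int = 0
    in_degree_sorted: np.ndarray | None = None
    out_degree_sorted: np.ndarray | None = None
    n_unidirectional: int | None = None
    n_bidirectional: int | None = None
    apl: float | None = None
    n_unreachable: int | None = None
    clustering: float | None = None
    triad_census: np.ndarray | None = None
    clique_counts: dict | None = None
    log10_weights: np.ndarray | None = None
    out_strength: np.ndarray | None = None
    node_distances: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def compute_report(
    w: np.ndarray, properties=DEFAULT_REPORT_PROPERTIES, clique_sizes=None
) -> PropertyReport:
    """Compute a :class:`PropertyReport` for a weighted directed network."""
    w = _check_weights(w)
    n = w.shape[0]
    A = ((w > 0) & _offdiag_mask(n)).astype(np.int8)
    rep = PropertyReport(n_nodes=n, n_links=int(A.sum()))
    props = set(properties)
    if "degree_spectra" in props:
        rep.in_degree_sorted, rep.out_degree_sorted = degree_spectra(A)
    if "reciprocity" in props:
        rep.n_unidirectional, rep.n_bidirectional = reciprocity_counts(A)
    if "apl" in props:
        res = average_binary_path_length(A)
        rep.apl, rep.n_unreachable = res.value, res.n_unreachable
    if "clustering" in props:
        rep.clustering = clustering_coefficient(A)
    if "triad_census" in props:
        rep.triad_census = triad_census(A)
    if "log10_weights" in props:
        mask = A.astype(bool)
        rep.log10_weights = np.log10(w[mask]) if mask.any() else np.array([])
    if "out_strength" in props:
        wo = w.copy()
        np.fill_diagonal(wo, 0.0)
        rep.out_strength = wo.sum(axis=1)
    if "node_distances" in props:
        r = node_distances(w)
        off = r[_offdiag_mask(n)]
        rep.node_distances = off[np.isfinite(off)]
    if clique_sizes is not None:
        rep.clique_counts = clique_counts(A, clique_sizes)
    return rep


def summarize_reports(reports) -> pd.DataFrame:
    """Mean and SD of the scalar properties across an ensemble of reports."""
    scalars = {}
    for name in ("n_links", "n_unidirectional", "n_bidirectional", "apl", "clustering"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if vals:
            arr = np.asarray(vals, float)
            scalars[name] = dict(mean=float(arr.mean()), sd=float(arr.std(ddof=0)))
    return pd.DataFrame(scalars).T


_HIST_PROPS = {"log10_weights", "out_strength", "node_distances"}
_HIST_BINS = 24


def _comparison_vector(rep: PropertyReport, prop: str, edges=None) -> np.ndarray:
    if prop == "degree_spectra":
        return np.concatenate([rep.in_degree_sorted, rep.out_degree_sorted]).astype(float)
    if prop == "reciprocity":
        return np.array([rep.n_unidirectional, rep.n_bidirectional], float)
    if prop == "triad_census":
        c = np.asarray(rep.triad_census, float)
        return c / c.sum() if c.sum() else c
    if prop == "apl":
        return np.array([rep.apl], float)
    if prop == "clustering":
        return np.array([rep.clustering], float)
    if prop in _HIST_PROPS:
        samples = getattr(rep, prop)
        h, _ = np.histogram(samples, bins=edges)
        tot = h.sum()
        return h / tot if tot else h.astype(float)
    raise ValueError(f"unknown comparison property {prop!r}")


def compare_to_ensemble(
    data_report: PropertyReport,
    ensembles: dict[float, list],
    properties,
) -> pd.DataFrame:
    """Mean RMSD between the data and each λ-ensemble, per property.

    Histogram properties share fixed bin edges computed from the data network
    (RMSD is meaningless across mismatched supports).  Each model network is
    compared individually and RMSDs averaged over the ensemble.  The pooled
    column averages per-property curves normalized by their own mean.
    """
    edges = {
        p: np.histogram_bin_edges(getattr(data_report, p), bins=_HIST_BINS)
        for p in properties
        if p in _HIST_PROPS
    }
    data_vecs = {
        p: _comparison_vector(data_report, p, edges.get(p)) for p in properties
    }
    rows = []
    for lam in sorted(ensembles):
        row = {"lambda": lam}
        for p in properties:
            vals = [
                rmsd(data_vecs[p], _comparison_vector(rep, p, edges.get(p)))
                for rep in ensembles[lam]
            ]
            row[p] = float(np.mean(vals))
        rows.append(row)
    curve = pd.DataFrame(rows)
    norm = []
    for p in properties:
        m = curve[p].mean()
        norm.append(curve[p] / m if m > 0 else curve[p])
    curve["pooled"] = np.mean(norm, axis=0)
    return curve
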