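"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a bilaterally
symmetric region atlas, EDR-generated projectomes with controllable
directional weight asymmetry, neuron skeletons whose main-cable lengths follow
an exponential law with known decay rate, and the synapse/classification
tables derived from those skeletons.

The generators emulate the statistical structure of the fly projectome data:

* atlas centroids sampled inside a mirrored ellipsoid, so the pairwise-distance
  histogram is unimodal (truncated-Gaussian-like);
* main-cable lengths ~ Exp(λ) with a tortuosity factor ``a`` relating tree-path
  length to straight-line (Euclidean) length, ``cable ≈ a · euclid``;
* lognormal-looking link weights arising from the EDR generative process;
* optional multiplicative direction bias ``exp(±β·Δh)`` along an imposed
  per-region hierarchy score ``h``, leaving homotopic (left↔right same-region)
  pairs unbiased.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

# Fly-brain-like ellipsoid semi-axes (mm) as fractions of spatial_scale_mm.
_AXES_FRAC = np.array([1.0, 0.625, 0.44])
DEFAULT_SPATIAL_SCALE_MM = 0.28


@dataclass(frozen=True)
class AtlasSpec:
    """Parameters of a synthetic bilateral atlas.

    ``n_pairs`` bilateral region pairs mirrored across the x=0 midplane plus
    ``n_central`` midline regions; total N = 2·n_pairs + n_central.
    """

    n_pairs: int
    n_central: int = 0
    spatial_scale_mm: float = DEFAULT_SPATIAL_SCALE_MM
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_central < 0:
            raise ValueError("n_central must be >= 0")
        if self.spatial_scale_mm <= 0:
            raise ValueError("spatial_scale_mm must be positive")

    @property
    def n_regions(self) -> int:
        return 2 * self.n_pairs + self.n_central


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a synthetic cohort.

    Parameters
    ----------
    lambda_true_per_mm : float
        EDR decay rate λ (mm⁻¹) of the main-cable-length law p(d) ∝ exp(−λd).
    tortuosity_a : float
        Path-to-Euclidean scaling factor a ≥ 1 (cable ≈ a · euclid).
    asym_profile : array or None
        Per-region hierarchy scores in [0, 1]; None means flat (no bias).
    seed : int
        RNG seed for everything drawn under this truth.
    """

    lambda_true_per_mm: float = 33.0
    tortuosity_a: float = 1.5
    asym_profile: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.lambda_true_per_mm <= 0:
            raise ValueError("lambda_true_per_mm must be positive")
        if self.tortuosity_a < 1:
            raise ValueError("tortuosity_a must be >= 1")
        if self.asym_profile is not None:
            prof = tuple(float(h) for h in self.asym_profile)
            if any(h < 0 or h > 1 for h in prof):
                raise ValueError("asym_profile scores must lie in [0, 1]")
            object.__setattr__(self, "asym_profile", prof)

    def with_profile(self, profile) -> "SyntheticTruth":
        return replace(self, asym_profile=tuple(float(h) for h in profile))


def _sample_in_ellipsoid(rng: np.random.Generator, n: int, axes: np.ndarray) -> np.ndarray:
    """Uniform points inside an axis-aligned ellipsoid centred at the origin."""
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-1, 1, size=(2 * (n - got) + 8, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        cand = cand[keep][: n - got]
        pts[got : got + len(cand)] = cand
        got += len(cand)
    return pts * axes


def make_atlas(spec: AtlasSpec) -> RegionAtlas:
    """Generate a bilaterally symmetric synthetic atlas.

    Bilateral pairs are exact mirror images across the x=0 plane and carry
    ``_L``/``_R`` suffixes; central regions sit on the midplane.
    """
    rng = np.random.default_rng(spec.seed)
    axes = spec.spatial_scale_mm * _AXES_FRAC
    # Right-hemisphere representatives: keep |x| away from the midline so
    # homotopic partners are distinct and distances stay positive.
    base = _sample_in_ellipsoid(rng, spec.n_pairs, axes)
    base[:, 0] = 0.12 * axes[0] + np.abs(base[:, 0]) * 0.88
    labels: list[str] = []
    cents: list[np.ndarray] = []
    for k in range(spec.n_pairs):
        right = base[k]
        left = right * np.array([-1.0, 1.0, 1.0])
        labels += [f"R{k}_L", f"R{k}_R"]
        cents += [left, right]
    central = _sample_in_ellipsoid(rng, max(spec.n_central, 1), axes)[: spec.n_central]
    for k in range(spec.n_central):
        c = central[k]
        c[0] = 0.0
        labels.append(f"C{k}")
        cents.append(c)
    return RegionAtlas(labels=tuple(labels), centroids=np.array(cents))


def make_projectome(
    atlas: RegionAtlas,
    truth: SyntheticTruth,
    M: int,
    beta: float = 0.0,
    bin_width_mm: float | None = None,
):
    """EDR-generated projectome with optional injected weight asymmetry.

    Runs the EDR generator at ``truth.lambda_true_per_mm`` with ``M`` binary
    links, then multiplies each non-homotopic reciprocal pair's raw weights by
    direction biases ``exp(±β·Δh/2)`` (flow toward the higher hierarchy score
    up-weighted) and re-normalizes columns.  Homotopic pairs get factor 1.

    Returns an :class:`edrnet.projectome.Projectome`.
    """
    from .edr_model import EDRGenerator
    from .projectome import Projectome, column_normalize

    N = atlas.n_regions
    if M > N * (N - 1):
        raise ValueError(f"M={M} exceeds capacity N(N-1)={N * (N - 1)}")
    gen = EDRGenerator(atlas.distance_matrix(), bin_width_mm=bin_width_mm)
    net = gen.generate(truth.lambda_true_per_mm, M, seed=truth.seed)
    W = net.counts.astype(float)

    if beta != 0.0 and truth.asym_profile is not None:
        h = np.asarray(truth.asym_profile, dtype=float)
        if len(h) != N:
            raise ValueError("asym_profile length must equal the number of regions")
        homotopic = set()
        for i, j in atlas.homotopic_pairs():
            homotopic.add((i, j))
            homotopic.add((j, i))
        dh = h[None, :] - h[:, None]  # dh[i, j] = h_j - h_i
        factor = np.exp(0.5 * beta * dh)
        for i, j in homotopic:
            factor[i, j] = 1.0
        np.fill_diagonal(factor, 1.0)
        W = W * factor

    w = column_normalize(W)
    return Projectome(labels=atlas.labels, W_raw=W, w=w)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_orthonormal(rng: np.random.Generator, u: np.ndarray) -> np.ndarray:
    """A unit vector orthogonal to u, uniformly random in its plane."""
    r = rng.normal(size=3)
    r -= r.dot(u) * u
    n = np.linalg.norm(r)
    if n < 1e-12:  # pathological draw
        r = np.array([u[1], -u[0], 0.0])
        n = np.linalg.norm(r)
    return r / n


def make_skeletons(
    atlas: RegionAtlas,
    truth: SyntheticTruth,
    n_neurons: int,
    jitter: float = 0.02,
    arbor_radius_mm: float = 0.02,
) -> tuple[list, pd.DataFrame]:
    """Generate neuron skeletons with known main-cable ground truth.

    Each neuron has a soma on the domain surface, a primary neurite to a
    branch point, a dendritic arbor (≥1 postsynaptic point) and an axonal
    arbor (≥1 presynaptic point).  The tree-path length between the closest
    postsynaptic and closest presynaptic point is drawn from Exp(λ_true); the
    straight-line distance between those two points equals that length divided
    by ``tortuosity_a`` times (1 + jitter), jitter uniform in ±``jitter``
    (relative, ≤ 5%).

    Returns ``(skeletons, truth_table)`` where the table records per neuron
    the true cable and Euclidean cable lengths.
    """
    from .skeleton import SkeletonTree

    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if not (0 <= jitter <= 0.05):
        raise ValueError("jitter must be a relative fraction in [0, 0.05]")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x5CE1]))
    axes = DEFAULT_SPATIAL_SCALE_MM * _AXES_FRAC
    if atlas.n_regions:
        span = np.ptp(atlas.centroids, axis=0)
        axes = np.maximum(span / 2.0, 1e-3)
        center = atlas.centroids.mean(axis=0)
    else:
        center = np.zeros(3)

    lam = truth.lambda_true_per_mm
    a = truth.tortuosity_a
    skeletons = []
    rows = []
    for nid in range(n_neurons):
        L = float(rng.exponential(1.0 / lam))
        eps = float(rng.uniform(-jitter, jitter)) if jitter > 0 else 0.0
        E = L / a * (1.0 + eps)
        # Split the main cable at the branch point: dendritic leg f·L,
        # axonal leg (1-f)·L with the dendritic leg the shorter one.
        f = float(rng.uniform(0.2, 0.5))
        d_post, d_pre = f * L, (1.0 - f) * L

        # soma on ellipsoid surface; branch point inside
        u = _unit(rng.normal(size=3))
        soma = center + axes * u
        B = center + 0.8 * axes * _sample_in_ellipsoid(rng, 1, np.ones(3))[0]
        mid_pn = 0.5 * (soma + B)  # primary neurite waypoint

        # closest postsynaptic point P0: straight dendritic trunk
        e1 = _unit(rng.normal(size=3))
        P0 = B + d_post * e1
        # closest presynaptic point A0 at Euclidean E from P0, with
        # |A0 - B| = r <= d_pre so a bent axonal trunk of path length d_pre fits.
        lo, hi = abs(d_post - E), d_post + E
        r = float(np.clip(0.95 * d_pre, lo, hi))
        if d_post > 1e-15 and r > 1e-15:
            cosphi = np.clip((d_post**2 + r**2 - E**2) / (2 * d_post * r), -1.0, 1.0)
            e2 = _random_orthonormal(rng, e1)
            dirA = cosphi * e1 + np.sqrt(max(0.0, 1 - cosphi**2)) * e2
        else:
            dirA = e1
        A0 = B + r * dirA
        # bend the axonal trunk so its path length is exactly d_pre
        h2 = max(0.0, (d_pre / 2.0) ** 2 - (r / 2.0) ** 2)
        bend = 0.5 * (B + A0) + np.sqrt(h2) * _random_orthonormal(rng, _unit(A0 - B) if r > 1e-15 else e1)

        n_post = int(rng.integers(3, 21))
        n_pre = int(rng.integers(3, 21))
        # star-like arbors strictly beyond P0 / A0 so those stay closest to soma
        post_pts = P0 + arbor_radius_mm * rng.uniform(0.05, 1.0, (n_post - 1, 1)) * _rand_units(rng, n_post - 1)
        pre_pts = A0 + arbor_radius_mm * rng.uniform(0.05, 1.0, (n_pre - 1, 1)) * _rand_units(rng, n_pre - 1)

        xyz = [soma, mid_pn, B, P0, A0, bend]
        parents = [-1, 0, 1, 2, 5, 2]  # soma<-mid<-B; P0<-B; A0<-bend<-B
        post_ids = [3]
        pre_ids = [4]
        for p in post_pts:
            xyz.append(p)
            parents.append(3)
            post_ids.append(len(xyz) - 1)
        for p in pre_pts:
            xyz.append(p)
            parents.append(4)
            pre_ids.append(len(xyz) - 1)
        node_ids = np.arange(len(xyz))
        parent_ids = np.array(parents)
        tree = SkeletonTree(
            node_ids=node_ids,
            parents=parent_ids,
            xyz=np.array(xyz),
            presyn_nodes=frozenset(pre_ids),
            postsyn_nodes=frozenset(post_ids),
            neuron_id=nid,
        )
        skeletons.append(tree)
        rows.append(
            dict(
                neuron_id=nid,
                cable_true_mm=L,
                euclid_true_mm=E,
                n_pre=n_pre,
                n_post=n_post,
            )
        )
    return skeletons, pd.DataFrame(rows)


def _rand_units(rng: np.random.Generator, n: int) -> np.ndarray:
    if n == 0:
        return np.empty((0, 3))
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_synapse_table(
    skeletons,
    atlas: RegionAtlas,
    n_afferent_decoys: int = 0,
    n_efferent_decoys: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate synaptic points and neuron classes.

    One row per synaptic point: ``neuron_id, role (pre|post), region`` with the
    region assigned by nearest centroid.  The class table marks every skeleton
    neuron ``intrinsic``; optional afferent/efferent decoys (with no synapse
    rows) exercise the downstream class filter.
    """
    syn_rows = []
    cls_rows = []
    for tree in skeletons:
        for role, nodes in (("pre", tree.presyn_nodes), ("post", tree.postsyn_nodes)):
            if not nodes:
                continue
            pts = np.array([tree.node_xyz(n) for n in sorted(nodes)])
            regions = atlas.nearest_region(pts)
            for r in regions:
                syn_rows.append((tree.neuron_id, role, atlas.labels[int(r)]))
        cls_rows.append((tree.neuron_id, "intrinsic"))
    next_id = (max((t.neuron_id for t in skeletons), default=-1)) + 1
    for k in range(n_afferent_decoys):
        cls_rows.append((next_id + k, "afferent"))
    next_id += n_afferent_decoys
    for k in range(n_efferent_decoys):
        cls_rows.append((next_id + k, "efferent"))
    synapses = pd.DataFrame(syn_rows, columns=["neuron_id", "role", "region"])
    classes = pd.DataFrame(cls_rows, columns=["neuron_id", "class"])
    return synapses, classes
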