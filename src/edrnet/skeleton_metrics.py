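"""Cable-length morphometry and EDR decay-rate estimation on neuron trees.

The main transmission cable of a fly neuron runs between its dendritic and
axonal arbor.  Per neuron we compute soma-path distances to every pre- and
postsynaptic point, identify the closest of each, and measure

* ``cable_mm`` — the tree-path length between the closest postsynaptic and the
  closest presynaptic point (the path runs through the arbors' common branch
  point, never through the soma or primary neurite unless they lie between);
* ``euclid_mm`` — the straight-line distance between the same two points.

Neurons whose mean-minus-min soma-path distances are large (for either synapse
role) are likely affected by synapse-prediction errors or nontraditional
synapses and are removed by the arbor-consistency filter (default threshold
0.15 mm).

The decay rate of the exponential length law p(d) = c·exp(−λd) is estimated
from the length histogram by ordinary least squares on log probability versus
bin center, repeated over several bin sizes; the spread of per-bin-size
estimates gives the reported [λ_lo, λ_hi] interval.  This mirrors reading the
slope off a log-scale histogram; a maximum-likelihood cross-check
(λ_MLE = 1/mean) is provided separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .skeleton import SkeletonTree

DEFAULT_THRESHOLD_MM = 0.15
DEFAULT_BIN_SIZES_MM = (0.01, 0.02, 0.05)
DEFAULT_MIN_BIN_COUNT = 5
DEFAULT_MIDLINE_HALFWIDTH_MM = 0.01


class MeasurementError(ValueError):
    pass


def path_length_to_node(tree: SkeletonTree, node_id: int) -> float:
    """Cable length of the unique soma-to-node path (mm)."""
    return tree.path_length_to_root(node_id)


def side_of(x: float, midline_halfwidth_mm: float = DEFAULT_MIDLINE_HALFWIDTH_MM) -> str:
    """Hemisphere tag of an x-coordinate: left (x<0), right (x>0) or center."""
    if x < -midline_halfwidth_mm:
        return "left"
    if x > midline_halfwidth_mm:
        return "right"
    return "center"


@dataclass(frozen=True)
class CableRecord:
    """Per-neuron cable measurements (all lengths in mm)."""

    neuron_id: int
    pre_min_mm: float
    pre_mean_mm: float
    post_min_mm: float
    post_mean_mm: float
    cable_mm: float
    euclid_mm: float
    hemi_class: str
    kept: bool = True


def measure_neuron(
    tree: SkeletonTree,
    midline_halfwidth_mm: float = DEFAULT_MIDLINE_HALFWIDTH_MM,
) -> CableRecord:
    """Measure main-cable and Euclidean cable lengths of one neuron."""
    if not tree.presyn_nodes:
        raise MeasurementError(f"neuron {tree.neuron_id}: no presynaptic points")
    if not tree.postsyn_nodes:
        raise MeasurementError(f"neuron {tree.neuron_id}: no postsynaptic points")

    pre = sorted(tree.presyn_nodes)
    post = sorted(tree.postsyn_nodes)
    pre_d = np.array([tree.path_length_to_root(n) for n in pre])
    post_d = np.array([tree.path_length_to_root(n) for n in post])
    pre0 = pre[int(np.argmin(pre_d))]
    post0 = post[int(np.argmin(post_d))]

    cable = tree.path_length_between(post0, pre0)
    p_pre, p_post = tree.node_xyz(pre0), tree.node_xyz(post0)
    euclid = float(np.linalg.norm(p_pre - p_post))
    same_side = side_of(p_pre[0], midline_halfwidth_mm) == side_of(
        p_post[0], midline_halfwidth_mm
    )
    return CableRecord(
        neuron_id=tree.neuron_id,
        pre_min_mm=float(pre_d.min()),
        pre_mean_mm=float(pre_d.mean()),
        post_min_mm=float(post_d.min()),
        post_mean_mm=float(post_d.mean()),
        cable_mm=float(cable),
        euclid_mm=euclid,
        hemi_class="intra" if same_side else "inter",
    )


def measure_cohort(skeletons, **kwargs) -> pd.DataFrame:
    """Measure every skeleton; one row per neuron."""
    return pd.DataFrame([measure_neuron(t, **kwargs).__dict__ for t in skeletons])


def arbor_consistency_filter(
    records: pd.DataFrame, threshold_mm: float = DEFAULT_THRESHOLD_MM
) -> tuple[pd.DataFrame, dict]:
    """Flag neurons whose closest synaptic points are consistent with their arbors.

    Kept iff (pre_mean − pre_min) ≤ threshold AND (post_mean − post_min) ≤
    threshold.  Returns the records with updated ``kept`` flags and a summary.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    out = records.copy()
    kept = (
        (out["pre_mean_mm"] - out["pre_min_mm"] <= threshold_mm)
        & (out["post_mean_mm"] - out["post_min_mm"] <= threshold_mm)
    )
    out["kept"] = kept
    summary = dict(
        n_total=int(len(out)),
        n_kept=int(kept.sum()),
        kept_fraction=float(kept.mean()) if len(out) else float("nan"),
        threshold_mm=float(threshold_mm),
    )
    return out, summary


# ---------------------------------------------------------------------------
# exponential decay-rate fit (model/results pair)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EDRFit:
    """Fitted exponential decay: p(d) = c · exp(−λ·d).

    ``lambda_per_mm`` / ``intercept_c`` come from the smallest requested bin
    size; ``lambda_interval`` spans the per-bin-size estimates.
    """

    lambda_per_mm: float
    intercept_c: float
    bin_sizes_mm: tuple
    per_bin_size: dict
    lambda_interval: tuple
    statistic: str
    n: int

    def summary(self) -> str:
        lo, hi = self.lambda_interval
        lines = [
            "Exponential distance rule fit: p(d) = c exp(-lambda d)",
            "=" * 54,
            f"sample: n={self.n} {self.statistic}-cable lengths (mm)",
            f"lambda = {self.lambda_per_mm:.3g} mm^-1   c = {self.intercept_c:.3g}",
            f"lambda interval over bin sizes: [{lo:.3g}, {hi:.3g}] mm^-1",
            "per bin size:",
        ]
        for bs, lam in self.per_bin_size.items():
            lines.append(f"  bin {bs:g} mm: lambda = {lam:.4g} mm^-1")
        return "\n".join(lines)


class ExponentialDecayModel:
    """OLS log-histogram estimator of the exponential length-law decay rate."""

    def __init__(self, lengths_mm, statistic: str = "min"):
        lengths = np.asarray(lengths_mm, dtype=float)
        lengths = lengths[np.isfinite(lengths)]
        if lengths.size < 2:
            raise ValueError("need at least 2 finite lengths")
        if (lengths < 0).any():
            raise ValueError("lengths must be nonnegative")
        if np.ptp(lengths) == 0:
            raise ValueError("degenerate sample: all lengths equal")
        if statistic not in ("min", "mean"):
            raise ValueError("statistic must be 'min' or 'mean'")
        self.lengths = lengths
        self.statistic = statistic

    def fit(
        self,
        bin_sizes_mm=DEFAULT_BIN_SIZES_MM,
        min_count: int = DEFAULT_MIN_BIN_COUNT,
    ) -> EDRFit:
        """Fit λ per bin size and report the spanning interval.

        For each bin size: histogram the lengths, take all bins from the modal
        bin upward with at least ``min_count`` entries, and regress log
        probability density on bin centers.

        The left edge of empirical length histograms is depleted by geometry,
        so the fit starts at the modal bin.  Far-tail bins with very few
        entries are excluded (default ``min_count=5``) because conditioning on
        a nonzero count inflates the apparent density of near-empty bins and
        biases the slope toward zero.
        """
        per = {}
        intercepts = {}
        for bs in bin_sizes_mm:
            lam, c = self._fit_one(float(bs), min_count)
            per[float(bs)] = lam
            intercepts[float(bs)] = c
        lams = list(per.values())
        smallest = float(min(bin_sizes_mm))
        return EDRFit(
            lambda_per_mm=per[smallest],
            intercept_c=intercepts[smallest],
            bin_sizes_mm=tuple(float(b) for b in bin_sizes_mm),
            per_bin_size=per,
            lambda_interval=(float(min(lams)), float(max(lams))),
            statistic=self.statistic,
            n=int(self.lengths.size),
        )

    def _fit_one(self, bin_size: float, min_count: int) -> tuple[float, float]:
        x = self.lengths
        n_bins = max(2, int(np.ceil((x.max() + 1e-12) / bin_size)))
        edges = np.arange(n_bins + 1) * bin_size
        counts, _ = np.histogram(x, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        modal = int(np.argmax(counts))
        sel = (np.arange(n_bins) >= modal) & (counts >= max(1, min_count))
        if sel.sum() < 2:
            raise ValueError(
                f"degenerate histogram at bin size {bin_size} mm: "
                f"fewer than 2 usable bins"
            )
        density = counts[sel] / (x.size * bin_size)
        slope, intercept = np.polyfit(centers[sel], np.log(density), 1)
        return float(-slope), float(np.exp(intercept))

    def mle_lambda(self) -> float:
        """Maximum-likelihood rate of a pure exponential, 1/mean (cross-check)."""
        return float(1.0 / self.lengths.mean())


def fit_edr(
    lengths_mm,
    bin_sizes_mm=DEFAULT_BIN_SIZES_MM,
    statistic: str = "min",
    min_count: int = DEFAULT_MIN_BIN_COUNT,
) -> EDRFit:
    """Fit the EDR decay rate from a length sample (functional wrapper)."""
    return ExponentialDecayModel(lengths_mm, statistic).fit(bin_sizes_mm, min_count)


def scaling_factor(cable_mm, euclid_mm) -> tuple[float, float]:
    """Through-origin slope of cable on Euclidean length, and Pearson r.

    Zero Euclidean distance must imply zero cable length, hence the
    through-origin regression: a = Σ(c·e)/Σe².
    """
    c = np.asarray(cable_mm, dtype=float)
    e = np.asarray(euclid_mm, dtype=float)
    if c.shape != e.shape or c.ndim != 1:
        raise ValueError("cable and euclid samples must be equal-length 1-D arrays")
    if c.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(c) == 0 or np.ptp(e) == 0:
        raise ValueError("constant input: correlation undefined")
    slope = float((c * e).sum() / (e * e).sum())
    r = float(stats.pearsonr(c, e).statistic)
    return slope, r
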