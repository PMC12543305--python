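"""Weight asymmetry of reciprocal links and the derived hierarchy ranking.

For a connected node pair the relative weight asymmetry is

    ASYM_ij = |w_ij − w_ji| / (w_ij + w_ji)  ∈ [0, 1],

0 for perfectly symmetric pairs, 1 for unidirectional ones.  Geometry-only
null models built on a symmetric distance matrix produce few strongly
asymmetric reciprocal pairs, so a data-vs-model excess of high ASYM values is
a functionally relevant signature.  Orienting one link per pair toward the
predominant flow direction (i→j iff w_ij > w_ji) with weight ASYM gives the
asymmetry network; its out-strength ranks regions from the bottom of the
functional hierarchy (sensory-like, mostly outgoing asymmetry) upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .atlas import split_label


class PairClass(str, Enum):
    HOMOTOPIC = "homotopic"
    IPSILATERAL = "ipsilateral"
    CONTRALATERAL = "contralateral"
    UNPAIRED = "unpaired"


def asym(w_ij: float, w_ji: float) -> float:
    """Relative weight asymmetry |w_ij − w_ji|/(w_ij + w_ji)."""
    if w_ij < 0 or w_ji < 0:
        raise ValueError("weights must be nonnegative")
    s = w_ij + w_ji
    if s == 0:
        raise ValueError("pair is not connected (both weights zero)")
    return abs(w_ij - w_ji) / s


def classify_pair(label_i: str, label_j: str) -> PairClass:
    """Homotopic / ipsilateral / contralateral classification of a label pair.

    Center (unsuffixed) regions are ipsilateral with each other and with
    nothing else; a center–hemisphere pair is unpaired.
    """
    base_i, hemi_i = split_label(label_i)
    base_j, hemi_j = split_label(label_j)
    if base_i == base_j and {hemi_i, hemi_j} == {"left", "right"}:
        return PairClass.HOMOTOPIC
    if hemi_i == hemi_j:
        return PairClass.IPSILATERAL
    if "center" in (hemi_i, hemi_j):
        return PairClass.UNPAIRED
    return PairClass.CONTRALATERAL


def _pair_table(w: np.ndarray, labels) -> pd.DataFrame:
    """One row per connected unordered pair with weights, ASYM and class."""
    w = np.asarray(w, float)
    n = w.shape[0]
    if labels is None:
        labels = [f"n{i}" for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            wij, wji = w[i, j], w[j, i]
            if wij == 0 and wji == 0:
                continue
            rows.append(
                dict(
                    i=i,
                    j=j,
                    label_i=labels[i],
                    label_j=labels[j],
                    w_ij=wij,
                    w_ji=wji,
                    bidirectional=(wij > 0 and wji > 0),
                    asym=asym(wij, wji),
                    pair_class=classify_pair(labels[i], labels[j]).value,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "i", "j", "label_i", "label_j", "w_ij", "w_ji",
            "bidirectional", "asym", "pair_class",
        ],
    )


def asymmetry_values(
    w: np.ndarray,
    labels=None,
    pair_class: str = "all",
    include_unidirectional: bool = False,
) -> np.ndarray:
    """ASYM values over connected pairs of the selected class.

    By default only bidirectional pairs enter (the histogram convention);
    unidirectional pairs, all with ASYM = 1, can be included.
    """
    table = _pair_table(w, labels)
    if not include_unidirectional and len(table):
        table = table[table["bidirectional"]]
    if pair_class != "all" and len(table):
        table = table[table["pair_class"] == pair_class]
    return table["asym"].to_numpy()


def asymmetry_distribution(
    w: np.ndarray,
    labels=None,
    pair_class: str = "all",
    bins: int = 20,
    include_unidirectional: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized ASYM histogram on [0, 1] for the selected pair class."""
    vals = asymmetry_values(w, labels, pair_class, include_unidirectional)
    edges = np.linspace(0.0, 1.0, bins + 1)
    if vals.size == 0:
        import warnings

        warnings.warn(f"no pairs in class {pair_class!r}; empty histogram")
        return np.zeros(bins), edges
    hist, _ = np.histogram(vals, bins=edges)
    return hist / hist.sum(), edges


@dataclass(frozen=True)
class AsymmetryNetwork:
    """One directed ASYM-weighted link per connected unordered pair.

    ``S[i, j] = ASYM_ij`` iff w_ij > w_ji (flow predominantly i→j);
    unidirectional pairs carry weight 1 in their existing direction; exact
    ties produce no link (their weight would be 0).
    """

    S: np.ndarray
    labels: tuple

    @property
    def in_strength(self) -> np.ndarray:
        return self.S.sum(axis=0)

    @property
    def out_strength(self) -> np.ndarray:
        return self.S.sum(axis=1)


def build_asymmetry_network(
    w: np.ndarray, labels=None, include_unidirectional: bool = True
) -> AsymmetryNetwork:
    """Construct the asymmetry network from a weight matrix."""
    w = np.asarray(w, float)
    n = w.shape[0]
    if labels is None:
        labels = tuple(f"n{i}" for i in range(n))
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            wij, wji = w[i, j], w[j, i]
            if wij == 0 and wji == 0:
                continue
            if not include_unidirectional and (wij == 0 or wji == 0):
                continue
            if wij > wji:
                S[i, j] = asym(wij, wji)
            elif wji > wij:
                S[j, i] = asym(wij, wji)
            # exact tie: no link
    return AsymmetryNetwork(S=S, labels=tuple(labels))


def asymmetry_strengths(net: AsymmetryNetwork) -> pd.DataFrame:
    """Per-region asymmetry in/out-strengths, ranked by descending out-strength.

    Ties are broken by label for determinism.
    """
    df = pd.DataFrame(
        dict(
            label=list(net.labels),
            in_strength=net.in_strength,
            out_strength=net.out_strength,
        )
    )
    df = df.sort_values(
        ["out_strength", "label"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
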