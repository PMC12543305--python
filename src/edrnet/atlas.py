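"""Region atlases: labeled 3D centroids of brain regions (neuropils).

Labels follow the hemisphere-suffix convention used throughout the package:
``<BASE>_L`` / ``<BASE>_R`` for bilateral regions, an unsuffixed label for
midline (center) regions.  All coordinates are stored in millimeters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


def split_label(label: str) -> tuple[str, str]:
    """Return ``(base_name, hemisphere)`` for a region label.

    Hemisphere is ``"left"``, ``"right"`` or ``"center"``.
    """
    if label.endswith("_L"):
        return label[:-2], "left"
    if label.endswith("_R"):
        return label[:-2], "right"
    return label, "center"


@dataclass(frozen=True)
class RegionAtlas:
    """A set of labeled region centroids.

    Parameters
    ----------
    labels : sequence of str
        Unique region labels with the ``_L``/``_R`` suffix convention.
    centroids : (N, 3) array
        Centroid coordinates in mm.
    """

    labels: tuple[str, ...]
    centroids: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        cent = np.asarray(self.centroids, dtype=float)
        if cent.shape != (len(labels), 3):
            raise ValueError(
                f"centroids shape {cent.shape} does not match {len(labels)} labels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        object.__setattr__(self, "centroids", cent)
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(labels)})

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def base_names(self) -> tuple[str, ...]:
        return tuple(split_label(l)[0] for l in self.labels)

    @property
    def hemispheres(self) -> tuple[str, ...]:
        return tuple(split_label(l)[1] for l in self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown region label: {label!r}") from None

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) of left/right instances of the same base name."""
        left = {}
        for i, lab in enumerate(self.labels):
            base, hemi = split_label(lab)
            if hemi == "left":
                left[base] = i
        pairs = []
        for j, lab in enumerate(self.labels):
            base, hemi = split_label(lab)
            if hemi == "right" and base in left:
                pairs.append((left[base], j))
        return pairs

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances in mm (symmetric, zero diagonal)."""
        if self.n_regions < 2:
            raise ValueError("distance matrix requires at least 2 regions")
        D = cdist(self.centroids, self.centroids)
        off = D[~np.eye(self.n_regions, dtype=bool)]
        if np.any(off == 0):
            warnings.warn("atlas contains coincident centroids (off-diagonal zero distances)")
        return D

    def nearest_region(self, points: np.ndarray) -> np.ndarray:
        """Index of the nearest centroid for each row of ``points`` (mm)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.argmin(cdist(points, self.centroids), axis=1)


def distance_matrix(atlas: RegionAtlas) -> np.ndarray:
    """Functional alias for :meth:`RegionAtlas.distance_matrix`."""
    return atlas.distance_matrix()
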