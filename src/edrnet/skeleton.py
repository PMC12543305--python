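"""Neuron skeletons: rooted trees of 3D points with attached synaptic sites.

A skeleton is the digital tree representation of a neuron: the soma is the
root, edges connect each node to its parent, and pre-/post-synaptic points are
recorded as sets of node ids.  Fly neurons have a characteristic layout — the
soma sits in a cell-body layer on the brain surface and a primary neurite dives
inward before splitting into a dendritic and an axonal arbor — so the soma is
never part of the dendrite-to-axon transmission path.

Coordinates are in millimeters internally; SWC files on disk use micrometers
(see :mod:`edrnet.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SkeletonTree:
    """Rooted neuron tree.

    Parameters
    ----------
    node_ids : (n,) int array
        Arbitrary unique node identifiers (SWC sample numbers).
    parents : (n,) int array
        Parent node id per node; exactly one node has parent ``-1`` (the soma).
    xyz : (n, 3) float array
        Node coordinates in mm.
    presyn_nodes, postsyn_nodes : set of int
        Node ids bearing presynaptic / postsynaptic sites.
    neuron_id : int
        External identifier.
    """

    node_ids: np.ndarray
    parents: np.ndarray
    xyz: np.ndarray
    presyn_nodes: frozenset = frozenset()
    postsyn_nodes: frozenset = frozenset()
    neuron_id: int = 0

    _pos: dict = field(init=False, repr=False)
    _parent_pos: np.ndarray = field(init=False, repr=False)
    _root_pos: int = field(init=False, repr=False)
    _edge_len: np.ndarray = field(init=False, repr=False)
    _cumlen: np.ndarray = field(init=False, repr=False)
    _depth: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.presyn_nodes = frozenset(int(i) for i in self.presyn_nodes)
        self.postsyn_nodes = frozenset(int(i) for i in self.postsyn_nodes)
        n = len(self.node_ids)
        if len(set(self.node_ids.tolist())) != n:
            raise ValueError("duplicate node ids")
        self._pos = {int(nid): k for k, nid in enumerate(self.node_ids)}
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        self._root_pos = int(roots[0])
        parent_pos = np.empty(n, dtype=np.int64)
        for k in range(n):
            p = int(self.parents[k])
            if p == -1:
                parent_pos[k] = -1
            elif p not in self._pos:
                raise ValueError(f"orphan parent id {p} for node {int(self.node_ids[k])}")
            else:
                parent_pos[k] = self._pos[p]
        self._parent_pos = parent_pos
        # Edge lengths, root-path lengths and depths via iterative resolution;
        # also detects cycles / disconnected components.
        edge_len = np.zeros(n)
        mask = parent_pos >= 0
        edge_len[mask] = np.linalg.norm(
            self.xyz[mask] - self.xyz[parent_pos[mask]], axis=1
        )
        self._edge_len = edge_len
        cumlen = np.full(n, np.nan)
        depth = np.full(n, -1, dtype=np.int64)
        cumlen[self._root_pos] = 0.0
        depth[self._root_pos] = 0
        pending = list(range(n))
        progress = True
        while pending and progress:
            progress = False
            nxt = []
            for k in pending:
                if depth[k] >= 0:
                    progress = True
                    continue
                p = parent_pos[k]
                if depth[p] >= 0:
                    depth[k] = depth[p] + 1
                    cumlen[k] = cumlen[p] + edge_len[k]
                    progress = True
                else:
                    nxt.append(k)
            pending = nxt
        if pending:
            raise ValueError("skeleton is not a connected rooted tree (cycle or orphan subtree)")
        self._cumlen = cumlen
        self._depth = depth
        for nid in self.presyn_nodes | self.postsyn_nodes:
            if nid not in self._pos:
                raise ValueError(f"synaptic node id {nid} not in tree")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def root_id(self) -> int:
        return int(self.node_ids[self._root_pos])

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.xyz[self._root_pos]

    # -- path geometry ---------------------------------------------------

    def path_length_to_root(self, node_id: int) -> float:
        """Cable length of the unique root-to-node path (mm)."""
        if int(node_id) not in self._pos:
            raise KeyError(f"unknown node id {node_id}")
        return float(self._cumlen[self._pos[int(node_id)]])

    def _lca_pos(self, a: int, b: int) -> int:
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self._parent_pos[a]
            da -= 1
        while db > da:
            b = self._parent_pos[b]
            db -= 1
        while a != b:
            a = self._parent_pos[a]
            b = self._parent_pos[b]
        return a

    def path_length_between(self, u: int, v: int) -> float:
        """Cable length of the unique tree path between two nodes (mm).

        The path runs through the lowest common ancestor; it does not traverse
        the root unless the root lies between the two nodes.
        """
        for nid in (u, v):
            if int(nid) not in self._pos:
                raise KeyError(f"unknown node id {nid}")
        pu, pv = self._pos[int(u)], self._pos[int(v)]
        pl = self._lca_pos(pu, pv)
        return float(self._cumlen[pu] + self._cumlen[pv] - 2.0 * self._cumlen[pl])

    def node_xyz(self, node_id: int) -> np.ndarray:
        return self.xyz[self._pos[int(node_id)]]
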