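"""Independent brute-force oracles used to cross-check the implementation."""

from collections import deque
from itertools import product

import numpy as np


def neighbor_offsets(connectivity: int):
    """Explicit 3D neighbor offsets for 6/18/26-connectivity.

    Built directly from the definition: 6 = face neighbors (one axis
    differs), 18 = face + edge (at most two axes differ), 26 = all offsets
    in the 3x3x3 cube except the center.
    """
    offsets = []
    for d in product((-1, 0, 1), repeat=3):
        n_diff = sum(1 for x in d if x != 0)
        if n_diff == 0:
            continue
        if connectivity == 6 and n_diff > 1:
            continue
        if connectivity == 18 and n_diff > 2:
            continue
        offsets.append(d)
    return offsets


def flood_fill_components(mask: np.ndarray, connectivity: int):
    """Partition of the set voxels into connected components (BFS).

    Returns a list of frozensets of voxel index tuples, independent of the
    scipy-based implementation under test.
    """
    offsets = neighbor_offsets(connectivity)
    shape = mask.shape
    unvisited = set(zip(*np.nonzero(mask)))
    components = []
    while unvisited:
        start = unvisited.pop()
        comp = {start}
        queue = deque([start])
        while queue:
            v = queue.popleft()
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < shape[i] for i in range(3)) and w in unvisited:
                    unvisited.discard(w)
                    comp.add(w)
                    queue.append(w)
        components.append(frozenset(comp))
    return components


def partition_from_labels(labels: np.ndarray):
    """Component partition (set of frozensets) from an integer label grid."""
    out = {}
    for v in zip(*np.nonzero(labels)):
        out.setdefault(labels[v], set()).add(v)
    return {frozenset(s) for s in out.values()}
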