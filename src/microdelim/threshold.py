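"""Fixed-threshold barcode delimitation.

Specimens are clustered at a fixed genetic distance cutoff (the classic
DNA-barcoding rule; 3.2% K2P for carychiid microsnails).  Single linkage is
the default reading of "cluster at threshold": two specimens share a lineage
whenever a chain of pairwise distances at or below the cutoff connects them.
Complete linkage is available behind a flag.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import complete, fcluster
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix
from .errors import InputError
from .io import Partition

__all__ = ["threshold_partition"]


def threshold_partition(
    dm: DistanceMatrix, threshold: float, linkage: str = "single"
) -> Partition:
    """Partition specimens at a distance cutoff.

    ``linkage="single"`` takes connected components of the graph with an
    edge wherever d(i, j) <= threshold (transitive closure).  Saturated
    distances (+inf) exceed any threshold.
    """
    if not threshold > 0:
        raise InputError("threshold must be positive")
    if linkage == "single":
        adj = dm.matrix <= threshold
        _, comp = connected_components(adj, directed=False)
    elif linkage == "complete":
        cond = squareform(dm.matrix, checks=False)
        finite_max = np.max(cond[np.isfinite(cond)], initial=0.0)
        cond = np.where(np.isfinite(cond), cond, 10.0 * finite_max + threshold + 1.0)
        comp = fcluster(complete(cond), t=threshold, criterion="distance")
    else:
        raise InputError(f"unknown linkage {linkage!r}")
    blocks: dict[int, list[str]] = {}
    for sid, c in zip(dm.ids, comp):
        blocks.setdefault(int(c), []).append(sid)
    return Partition.from_blocks(blocks.values(), ids=dm.ids)
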