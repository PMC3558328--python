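"""Pairwise genetic distances and haplotype collapsing.

Implements the Kimura two-parameter (K2P) distance used throughout DNA
barcoding, with pairwise deletion of gaps/missing data, plus a plain
Hamming step count used by the statistical-parsimony method.

For a pair of sequences compared over ``n`` mutually resolved sites, with
transition fraction ``P`` and transversion fraction ``Q``:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Pairs that saturate the formula (an argument of the logarithm <= 0) get the
sentinel ``+inf`` and are flagged; they sit "above any threshold" in
threshold clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, UndefinedDistanceError
from .io import Alignment

__all__ = [
    "DistanceMatrix",
    "k2p_distance",
    "build_distance_matrix",
    "collapse_haplotypes",
    "write_phylip",
]

# A,G share code>>1 == 0; C,T share code>>1 == 1 (purines vs pyrimidines),
# so a mismatch is a transition iff the high bits agree.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair effective site counts."""

    ids: tuple[str, ...]
    matrix: np.ndarray  # (n, n) float; +inf marks saturated pairs
    model: str  # "K2P" or "HAMMING"
    n_sites: np.ndarray  # (n, n) int, comparable sites per pair

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise InputError("matrix shape does not match id count")
        if not np.array_equal(m, m.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise InputError("distance matrix diagonal must be zero")
        finite = m[np.isfinite(m)]
        if np.any(finite < 0):
            raise InputError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.isinf(np.triu(self.matrix)))
        return [(self.ids[a], self.ids[b]) for a, b in zip(i, j)]

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(k) for k in keep]
        return DistanceMatrix(
            ids=tuple(keep),
            matrix=self.matrix[np.ix_(idx, idx)],
            model=self.model,
            n_sites=self.n_sites[np.ix_(idx, idx)],
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]


def _k2p_from_counts(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, float, float, int]:
    """K2P distance for one pair: returns ``(d, P, Q, n_sites)``.

    Sites where either sequence has a gap, ``N`` or any non-ACGT character
    are excluded (pairwise deletion).  Saturated pairs return ``d = inf``.
    """
    if len(seq_a) != len(seq_b):
        raise InputError("sequences differ in length")
    a = _encode(seq_a.upper())
    b = _encode(seq_b.upper())
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites for this pair")
    av, bv = a[valid], b[valid]
    diff = av != bv
    transitions = int((diff & ((av >> 1) == (bv >> 1))).sum())
    transversions = int(diff.sum()) - transitions
    P = transitions / n
    Q = transversions / n
    return _k2p_from_counts(P, Q), P, Q, n


def build_distance_matrix(aln: Alignment, model: str = "K2P") -> DistanceMatrix:
    """All-pairs distance matrix under ``model`` ("K2P" or "HAMMING").

    HAMMING counts mismatches over mutually resolved sites (an integer step
    count, not a fraction), as needed for haplotype networks.
    """
    model = model.upper()
    if model not in ("K2P", "HAMMING"):
        raise InputError(f"unknown distance model {model!r}")
    if aln.n_sequences < 2:
        raise InputError("need at least 2 sequences")
    codes = np.stack([_encode(s) for s in aln.seqs])
    n = aln.n_sequences
    dist = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=int)
    undefined: list[tuple[str, str]] = []
    valid = codes < 4
    for i in range(n):
        vi = valid[i]
        ci = codes[i]
        for j in range(i + 1, n):
            both = vi & valid[j]
            m = int(both.sum())
            sites[i, j] = sites[j, i] = m
            if m == 0:
                undefined.append((aln.ids[i], aln.ids[j]))
                continue
            ai, aj = ci[both], codes[j][both]
            diff = ai != aj
            nd = int(diff.sum())
            if model == "HAMMING":
                d = float(nd)
            else:
                ts = int((diff & ((ai >> 1) == (aj >> 1))).sum())
                d = _k2p_from_counts(ts / m, (nd - ts) / m)
            dist[i, j] = dist[j, i] = d
        sites[i, i] = int(vi.sum())
    if undefined:
        raise UndefinedDistanceError(
            f"pairs with no comparable sites: {undefined}"
        )
    return DistanceMatrix(ids=aln.ids, matrix=dist, model=model, n_sites=sites)


def collapse_haplotypes(aln: Alignment) -> tuple[Alignment, dict[str, list[str]]]:
    """Merge exactly identical sequences into haplotypes.

    Exact string equality is used: sequences differing only by missing data
    are kept apart (conservative; avoids chaining specimens through Ns).
    The haplotype id is the first member's id; the map covers all specimens.
    """
    members: dict[str, list[str]] = {}
    order: list[str] = []
    for sid, seq in zip(aln.ids, aln.seqs):
        if seq in members:
            members[seq].append(sid)
        else:
            members[seq] = [sid]
            order.append(seq)
    hap_ids = tuple(members[seq][0] for seq in order)
    hap_aln = Alignment(ids=hap_ids, seqs=tuple(order))
    return hap_aln, {members[seq][0]: members[seq] for seq in order}


def write_phylip(dm: DistanceMatrix, path: str) -> None:
    """Square PHYLIP distance matrix for interoperability."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for sid, row in zip(dm.ids, dm.matrix):
            cells = " ".join(f"{x:.6f}" if np.isfinite(x) else "inf" for x in row)
            fh.write(f"{sid[:10]:<10} {cells}\n")
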