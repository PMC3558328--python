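"""Conservative consensus over delimitation methods and morphospecies
cross-validation.

The consensus rule is the partition-lattice join: two specimens fall into
the same consensus lineage whenever a chain of co-membership edges taken
from *any* input partition connects them ("the most comprehensive grouping
predicted by any method").  The join is order-independent, commutative,
associative and idempotent, and deliberately risks taxonomic lumping rather
than splitting.

Cross-validation compares the consensus lineages (ELs) against the initial
morphospecies hypotheses.  Per morphospecies the status is one of:

* ``match``  - occupies exactly one EL, and that EL holds no other name;
* ``split``  - occupies >= 2 ELs, none of which holds another name;
* ``lumped`` - occupies one EL that also holds other names;
* ``mixed``  - split across ELs and at least one of them is shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import InputError
from .io import MorphoLabels, Partition

__all__ = ["join_partitions", "crossvalidate_morphospecies", "CrossValReport"]


class _DSU:
    def __init__(self, items: Sequence[str]):
        self.parent = {i: i for i in items}

    def find(self, a: str) -> str:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def join_partitions(partitions: Sequence[Partition]) -> Partition:
    """Lattice join: merge blocks that share members across any input."""
    if not partitions:
        raise InputError("no partitions to join")
    ids = partitions[0].ids
    id_set = set(ids)
    for p in partitions[1:]:
        if set(p.ids) != id_set:
            raise InputError("partitions cover different specimen sets")
    dsu = _DSU(ids)
    for p in partitions:
        for block in p.blocks:
            members = sorted(block)
            for other in members[1:]:
                dsu.union(members[0], other)
    blocks: dict[str, list[str]] = {}
    for sid in ids:
        blocks.setdefault(dsu.find(sid), []).append(sid)
    return Partition.from_blocks(blocks.values(), ids=ids)


@dataclass
class CrossValReport:
    """Morphospecies-versus-EL cross-validation summary."""

    status: dict[str, str]  # morphospecies name -> match/split/lumped/mixed
    splits: dict[str, int]  # split (or mixed) name -> number of ELs occupied
    contingency: pd.DataFrame  # rows = EL labels, columns = morphospecies
    n_matches: int
    n_split: int
    n_lumped: int
    n_mixed: int
    n_unrecognized_els: int  # ELs inside split names beyond the first
    lumped_els: list[str]  # EL labels holding more than one morphospecies

    @property
    def n_morphospecies(self) -> int:
        return len(self.status)


def crossvalidate_morphospecies(
    consensus: Partition, labels: MorphoLabels
) -> CrossValReport:
    """Cross-validate consensus lineages against morphospecies labels."""
    missing = [i for i in consensus.ids if i not in labels.labels]
    if missing:
        raise InputError(f"unlabeled specimens: {missing}")
    rows = [
        {"EL": consensus.assignment[i], "morphospecies": labels[i]}
        for i in consensus.ids
    ]
    df = pd.DataFrame(rows)
    contingency = pd.crosstab(df["EL"], df["morphospecies"])
    els_of = {
        name: set(df.loc[df["morphospecies"] == name, "EL"]) for name in labels.names
        if name in set(df["morphospecies"])
    }
    names_in_el = {el: set(df.loc[df["EL"] == el, "morphospecies"]) for el in contingency.index}
    status: dict[str, str] = {}
    splits: dict[str, int] = {}
    for name, els in els_of.items():
        shared = any(len(names_in_el[el]) > 1 for el in els)
        if len(els) == 1:
            status[name] = "lumped" if shared else "match"
        else:
            status[name] = "mixed" if shared else "split"
            splits[name] = len(els)
    n_unrecognized = sum(k - 1 for k in splits.values())
    return CrossValReport(
        status=status,
        splits=splits,
        contingency=contingency,
        n_matches=sum(1 for s in status.values() if s == "match"),
        n_split=sum(1 for s in status.values() if s == "split"),
        n_lumped=sum(1 for s in status.values() if s == "lumped"),
        n_mixed=sum(1 for s in status.values() if s == "mixed"),
        n_unrecognized_els=n_unrecognized,
        lumped_els=sorted(el for el, names in names_in_el.items() if len(names) > 1),
    )
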