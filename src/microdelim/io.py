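"""Shared domain types and readers/writers for the standard file formats.

The pipeline's common currencies are defined here: an :class:`Alignment` of
equal-length nucleotide sequences, a :class:`Partition` of specimens into
evolutionary lineages, a rooted :class:`UltrametricTree` and a table of
:class:`MorphoLabels` (specimen -> morphospecies name).  FASTA is read and
written through Biopython, Newick through dendropy, and tab-separated tables
through pandas.

Sites are 0-based internally; user-facing reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, InputError, ValidationError

__all__ = [
    "Alignment",
    "Partition",
    "UltrametricTree",
    "MorphoLabels",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_newick_ultrametric",
    "write_newick",
    "write_partition_table",
    "read_partition_table",
]

@dataclass(frozen=True)
class Alignment:
    """Aligned nucleotide sequences with unique specimen identifiers.

    Sequences are uppercase IUPAC strings of equal length; gaps are ``-``
    and missing data ``N``.  Other ambiguity codes are retained verbatim
    (distance computation treats them as missing).
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    meta: dict | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in count")
        if len(self.ids) == 0:
            raise InputError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate specimen ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.length == 0:
            raise AlignmentError("zero-length alignment")

    @property
    def length(self) -> int:
        """Number of alignment sites."""
        return len(self.seqs[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def sequence(self, specimen_id: str) -> str:
        return self.seqs[self.ids.index(specimen_id)]

    def subset(self, keep: Sequence[str]) -> "Alignment":
        index = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in keep if i not in index]
        if missing:
            raise InputError(f"unknown specimen ids: {missing}")
        return Alignment(
            ids=tuple(keep), seqs=tuple(self.seqs[index[i]] for i in keep)
        )


def _normalize_seq(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read a FASTA file as an :class:`Alignment`.

    Lowercase is normalized to uppercase and RNA ``U`` to ``T``; gap and
    missing characters pass through verbatim.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(_normalize_seq(str(r.seq)) for r in records)
    return Alignment(ids=ids, seqs=seqs)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


class Partition:
    """An assignment of specimens to disjoint blocks (evolutionary lineages).

    Blocks are canonically labelled by their smallest member id (ordered by
    the partition's id order), which makes serialized output deterministic.
    """

    def __init__(self, assignment: Mapping[str, str], ids: Sequence[str] | None = None):
        if not assignment:
            raise InputError("empty partition")
        self.ids: tuple[str, ...] = tuple(ids) if ids is not None else tuple(assignment)
        if set(self.ids) != set(assignment):
            raise InputError("partition id order does not match assignment keys")
        order = {sid: k for k, sid in enumerate(self.ids)}
        by_label: dict[str, list[str]] = {}
        for sid in self.ids:
            by_label.setdefault(assignment[sid], []).append(sid)
        # canonical label: the member that comes first in id order
        self.assignment: dict[str, str] = {}
        for members in by_label.values():
            label = min(members, key=order.__getitem__)
            for sid in members:
                self.assignment[sid] = label
        self.blocks: tuple[frozenset[str], ...] = tuple(
            sorted(
                (frozenset(m) for m in by_label.values()),
                key=lambda b: min(order[x] for x in b),
            )
        )

    @classmethod
    def from_blocks(
        cls, blocks: Iterable[Iterable[str]], ids: Sequence[str] | None = None
    ) -> "Partition":
        assignment: dict[str, str] = {}
        for block in blocks:
            block = list(block)
            if not block:
                raise InputError("empty block in partition")
            label = min(block)
            for sid in block:
                if sid in assignment:
                    raise InputError(f"specimen {sid!r} appears in two blocks")
                assignment[sid] = label
        return cls(assignment, ids=ids)

    @classmethod
    def singletons(cls, ids: Sequence[str]) -> "Partition":
        return cls({i: i for i in ids}, ids=ids)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, specimen_id: str) -> frozenset[str]:
        label = self.assignment[specimen_id]
        for block in self.blocks:
            if specimen_id in block:
                return block
        raise KeyError(specimen_id)  # pragma: no cover

    def same_block(self, a: str, b: str) -> bool:
        return self.assignment[a] == self.assignment[b]

    def restrict(self, keep: Sequence[str]) -> "Partition":
        keep_set = set(keep)
        return Partition(
            {i: self.assignment[i] for i in self.ids if i in keep_set},
            ids=[i for i in self.ids if i in keep_set],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return set(self.blocks) == set(other.blocks)

    def __hash__(self) -> int:
        return hash(frozenset(self.blocks))

    def __repr__(self) -> str:
        return f"Partition(n={len(self.ids)}, blocks={self.n_blocks})"


class UltrametricTree:
    """A rooted tree whose tips are equidistant from the root.

    Wraps a :class:`dendropy.Tree`; tip ages must agree with the root-to-tip
    depth within ``tolerance * depth`` (relative tolerance, default 1e-6,
    loose enough for trees written by Bayesian dating software).
    """

    DEFAULT_TOLERANCE = 1e-6

    def __init__(
        self,
        tree: dendropy.Tree,
        tolerance: float = DEFAULT_TOLERANCE,
        enforce: bool = True,
    ):
        self.tree = tree
        self.tolerance = tolerance
        root = tree.seed_node
        if root.edge.length is None:
            root.edge.length = 0.0
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise InputError("tree has a branch without a length")
            if node.edge.length < 0:
                raise ValidationError("negative branch length")
        self._depth_from_root: dict = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            base = self._depth_from_root[parent] if parent is not None else 0.0
            self._depth_from_root[node] = base + (node.edge.length or 0.0)
        tip_depths = [self._depth_from_root[t] for t in tree.leaf_node_iter()]
        if len(tip_depths) < 2:
            raise InputError("tree must have at least 2 tips")
        self.depth = max(tip_depths)
        if self.depth <= 0:
            raise ValidationError("tree has zero depth")
        spread = max(abs(d - self.depth) for d in tip_depths)
        if enforce and spread > tolerance * self.depth:
            raise ValidationError(
                f"tree is not ultrametric: tip depth spread {spread:g} exceeds "
                f"{tolerance:g} x depth {self.depth:g}"
            )
        # age = time before present; tips are treated as exactly contemporary
        self.age: dict = {
            node: max(self.depth - d, 0.0) for node, d in self._depth_from_root.items()
        }

    @classmethod
    def from_newick(
        cls,
        source: str,
        tolerance: float = DEFAULT_TOLERANCE,
        enforce: bool = True,
    ) -> "UltrametricTree":
        tree = dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)
        return cls(tree, tolerance=tolerance, enforce=enforce)

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [t.taxon.label for t in self.tree.leaf_node_iter()]

    def internal_ages(self) -> list[float]:
        """Ages (before present) of internal nodes, sorted descending."""
        return sorted(
            (self.age[n] for n in self.tree.preorder_internal_node_iter()),
            reverse=True,
        )

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def read_newick_ultrametric(
    path: str | Path,
    tolerance: float = UltrametricTree.DEFAULT_TOLERANCE,
    enforce: bool = True,
) -> UltrametricTree:
    """Read a rooted Newick tree and validate ultrametricity.

    Set ``enforce=False`` to accept trees whose tip depths differ by more
    than the tolerance (the depth is then the maximum root-to-tip distance).
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return UltrametricTree(tree, tolerance=tolerance, enforce=enforce)


def write_newick(tree: UltrametricTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


@dataclass(frozen=True)
class MorphoLabels:
    """Specimen id -> morphospecies name."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise InputError("empty label table")
        for sid, name in self.labels.items():
            if not name:
                raise InputError(f"empty morphospecies name for specimen {sid!r}")

    def __getitem__(self, sid: str) -> str:
        return self.labels[sid]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.labels)

    @property
    def names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for name in self.labels.values():
            seen.setdefault(name)
        return tuple(seen)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MorphoLabels":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise InputError("label table needs two columns: specimen, morphospecies")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"specimen": list(self.labels), "morphospecies": list(self.labels.values())}
        ).to_csv(path, sep="\t", index=False)


def write_partition_table(
    partitions: Mapping[str, Partition], path: str | Path, consensus: Partition | None = None
) -> None:
    """Serialize method partitions side by side as a TSV.

    One row per specimen (input id order of the first partition), one column
    per method, plus a ``consensus`` column when given.  Block labels are the
    smallest member id, so output is deterministic.
    """
    if not partitions:
        raise InputError("no partitions to write")
    names = list(partitions)
    first = partitions[names[0]]
    id_set = set(first.ids)
    for name in names[1:]:
        if set(partitions[name].ids) != id_set:
            raise InputError(f"partition {name!r} covers a different specimen set")
    columns: dict[str, list[str]] = {"specimen": list(first.ids)}
    for name in names:
        columns[name] = [partitions[name].assignment[i] for i in first.ids]
    if consensus is not None:
        if set(consensus.ids) != id_set:
            raise InputError("consensus covers a different specimen set")
        columns["consensus"] = [consensus.assignment[i] for i in first.ids]
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False)


def read_partition_table(path: str | Path) -> dict[str, Partition]:
    """Read a partition TSV back into one :class:`Partition` per column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "specimen" not in df.columns:
        raise InputError("partition table lacks a 'specimen' column")
    ids = list(df["specimen"])
    out: dict[str, Partition] = {}
    for col in df.columns:
        if col == "specimen":
            continue
        out[col] = Partition(dict(zip(ids, df[col])), ids=ids)
    return out
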