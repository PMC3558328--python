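"""Synthetic-data generators for every pipeline stage.

Each generator is seeded explicitly, uses a single NumPy RNG per call, and
embeds its full parameter set (including the seed) in the output's
provenance so any dataset can be regenerated bit-identically.

Generators:

* ultrametric trees from pure-birth (Yule), birth-death and two-rate Yule
  processes, conditioned on the tip count;
* species trees with within-species coalescent tip clusters (the GMYC
  generative model), with a controllable speciation/coalescent depth
  separation;
* K80 sequence evolution along a tree;
* planted barcode-gap datasets (intra- and interspecific distances kept on
  opposite sides of a gap, rejection-checked against the realized K2P
  distances);
* morphospecies labels derived from true lineages with controlled lumping
  and splitting;
* pairs of Gaussian-bump suitability grids with tunable overlap.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .distances import build_distance_matrix
from .errors import InputError, NumericalError
from .io import Alignment, MorphoLabels, Partition, UltrametricTree
from .niche import SuitabilityGrid

__all__ = [
    "SimSpec",
    "sim_tree",
    "sim_species_coalescent_tree",
    "sim_sequences_k80",
    "make_planted_gap_dataset",
    "assign_morphospecies_labels",
    "make_suitability_grids",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a tree-generating process.

    ``shift_frac`` (yule2rate) is the target rate-shift age as a fraction
    of the tree depth before the present; the absolute shift age is solved
    from the two-regime expected depth, so the realized fraction varies
    around the target.  ``a`` is the extinction fraction d/b of the
    birth-death process.
    """

    process: str = "yule"
    n_tips: int = 50
    r1: float = 1.0
    r2: float | None = None
    a: float = 0.0
    shift_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in ("yule", "birthdeath", "yule2rate"):
            raise InputError(f"unknown process {self.process!r}")
        if self.n_tips < 3:
            raise InputError("need at least 3 tips")
        if self.r1 <= 0 or (self.r2 is not None and self.r2 <= 0):
            raise InputError("rates must be positive")
        if not (0.0 <= self.a < 1.0):
            raise InputError("extinction fraction must be in [0, 1)")


class _Lin:
    __slots__ = ("start", "end", "children", "label", "alive")

    def __init__(self, start: float):
        self.start = start
        self.end: float | None = None
        self.children: list["_Lin"] | None = None
        self.label: str | None = None
        self.alive = True


def _newick(node: _Lin, present: float) -> str:
    end = node.end if node.end is not None else present
    length = end - node.start
    if node.children:
        inner = ",".join(_newick(c, present) for c in node.children)
        return f"({inner}):{length:.12g}"
    return f"{node.label}:{length:.12g}"


def _assemble(root_children: list[_Lin], present: float, provenance: dict) -> UltrametricTree:
    tip_counter = [0]

    def label(node: _Lin) -> None:
        if node.children:
            for c in node.children:
                label(c)
        elif node.label is None:
            tip_counter[0] += 1
            node.label = f"t{tip_counter[0]}"

    for c in root_children:
        label(c)
    newick = "(" + ",".join(_newick(c, present) for c in root_children) + ");"
    tree = UltrametricTree.from_newick(newick, tolerance=1e-5)
    tree.provenance = provenance
    return tree


def sim_tree(spec: SimSpec) -> UltrametricTree:
    """Simulate an ultrametric tree conditioned on the final tip count.

    Pure-birth intervals are Exp(n * rate) with a final waiting interval
    before the (unobserved) next event, so the youngest branching age is
    strictly positive; the two-rate process is simulated backward from the
    present so the rate shift sits at an exact age.  Birth-death runs a
    forward Gillespie simulation and retries on whole-tree extinction
    (bounded).
    """
    rng = np.random.default_rng(spec.seed)
    prov = {"generator": "sim_tree", **asdict(spec)}
    if spec.process == "birthdeath":
        return _sim_birthdeath(spec, rng, prov)
    if spec.process == "yule2rate":
        if spec.r2 is None:
            raise InputError("yule2rate needs r2")
        st = _shift_age(spec)
        ages = _twostage_event_ages(spec.n_tips, spec.r1, spec.r2, st, rng)
    else:
        # inter-event intervals are Exp(n * r1) while n lineages exist,
        # plus a final waiting interval before the (unobserved) next event
        counts = np.arange(2, spec.n_tips + 1)
        waits = rng.exponential(1.0 / (counts * spec.r1))
        times = np.cumsum(waits)
        ages = list(times[-1] - np.concatenate([[0.0], times[:-1]]))

    present = ages[0]
    a, b = _Lin(0.0), _Lin(0.0)
    active = [a, b]
    for age in ages[1:]:
        t = present - age
        parent = active.pop(int(rng.integers(len(active))))
        parent.end = t
        parent.children = [_Lin(t), _Lin(t)]
        active.extend(parent.children)
    return _assemble([a, b], present, prov)


def _shift_age(spec: SimSpec) -> float:
    """Absolute shift age targeting a relative position ``shift_frac``:
    solved self-consistently from the two-regime expected depth (the
    realized relative age still varies from tree to tree)."""
    n, r1, r2, f = spec.n_tips, spec.r1, spec.r2, spec.shift_frac
    st = f * sum(1.0 / (k * r1) for k in range(2, n + 1))
    for _ in range(3):
        acc, k = 0.0, n
        while k > 2 and acc + 1.0 / (k * r2) < st:
            acc += 1.0 / (k * r2)
            k -= 1
        depth = st + sum(1.0 / (j * r1) for j in range(2, k + 1))
        st = f * depth
    return st


def _twostage_event_ages(n_tips: int, r1: float, r2: float, st: float,
                         rng: np.random.Generator) -> list[float]:
    """Branching ages of a two-rate pure-birth tree conditioned on the tip
    count, simulated backward from the present so the rate shift sits at
    exactly age ``st`` (rate r2 below, r1 above)."""
    age = 0.0
    ages: list[float] = []
    for n in range(n_tips, 1, -1):
        rate = r2 if age < st else r1
        w = rng.exponential(1.0 / (n * rate))
        if age < st < age + w:
            w = (st - age) + rng.exponential(1.0 / (n * r1))
        age += w
        ages.append(age)
    return ages[::-1]  # oldest (root) first


def _sim_birthdeath(spec: SimSpec, rng: np.random.Generator, prov: dict,
                    max_tries: int = 1000) -> UltrametricTree:
    b = spec.r1 / (1.0 - spec.a)  # r1 is the net rate b - d
    d = b * spec.a
    for _ in range(max_tries):
        roots = [_Lin(0.0), _Lin(0.0)]
        active = list(roots)
        t = 0.0
        failed = False
        while len(active) < spec.n_tips:
            t += rng.exponential(1.0 / (len(active) * (b + d)))
            k = int(rng.integers(len(active)))
            node = active.pop(k)
            node.end = t
            if rng.random() < b / (b + d):
                node.children = [_Lin(t), _Lin(t)]
                active.extend(node.children)
            else:
                node.alive = False
                if not active:
                    failed = True
                    break
        if failed:
            continue
        present = t + rng.exponential(1.0 / (len(active) * (b + d)))
        pruned = [_prune(r, present) for r in roots]
        if any(p is None for p in pruned):
            continue  # one side of the root died out; reconstructed root differs
        return _assemble(list(pruned), present, prov)
    raise NumericalError("birth-death simulation kept going extinct")


def _prune(node: _Lin, present: float) -> _Lin | None:
    """Reconstructed (extant-only) tree: drop extinct branches, splice
    single-child nodes."""
    if node.children is None:
        return node if node.alive else None
    kept = [p for p in (_prune(c, present) for c in node.children) if p is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.start = node.start
        return child
    node.children = kept
    return node


def sim_species_coalescent_tree(
    n_species: int,
    tips_per_species: int,
    separation: float = 20.0,
    species_rate: float = 1.0,
    seed: int = 0,
) -> tuple[UltrametricTree, Partition]:
    """Yule species tree with Kingman coalescent tip clusters.

    Within-species coalescent depths are scaled to the youngest speciation
    age divided by ``separation`` (jittered down to half that), so larger
    separations produce cleaner species boundaries.  Returns the combined
    ultrametric tree and the true species partition.
    """
    if n_species < 2 or tips_per_species < 1:
        raise InputError("need >= 2 species and >= 1 tip per species")
    if separation <= 1:
        raise InputError("separation must exceed 1")
    rng = np.random.default_rng(seed)
    a, b = _Lin(0.0), _Lin(0.0)
    active = [a, b]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (len(active) * species_rate))
        parent = active.pop(int(rng.integers(len(active))))
        parent.end = t
        parent.children = [_Lin(t), _Lin(t)]
        active.extend(parent.children)
    present = t + rng.exponential(1.0 / (len(active) * species_rate))
    ages = [present - n.end
            for n in _iter_lineages([a, b]) if n.end is not None]
    youngest = min(ages)  # age of the most recent speciation event
    blocks: list[list[str]] = []
    for i, leaf in enumerate(active, start=1):
        tips = [f"sp{i}_t{j}" for j in range(1, tips_per_species + 1)]
        blocks.append(tips)
        if tips_per_species == 1:
            leaf.label = tips[0]
            continue
        # every within-species genealogy is guaranteed to be at least
        # `separation` times shallower than the shallowest species
        # boundary (the same hard-bound contract the planted-gap
        # generator gives for distances)
        depth_target = (youngest / separation) * rng.uniform(0.5, 1.0)
        _attach_coalescent(leaf, depth_target, present, tips, rng)
    tree = _assemble([a, b], present, {
        "generator": "sim_species_coalescent_tree",
        "n_species": n_species, "tips_per_species": tips_per_species,
        "separation": separation, "species_rate": species_rate, "seed": seed,
    })
    ids = [t for b in blocks for t in b]
    return tree, Partition.from_blocks(blocks, ids=ids)


def _iter_lineages(roots: list[_Lin]):
    stack = list(roots)
    while stack:
        node = stack.pop()
        yield node
        if node.children:
            stack.extend(node.children)


def _attach_coalescent(leaf: _Lin, depth: float, present: float,
                       labels: Sequence[str], rng: np.random.Generator) -> None:
    """Replace a species-tree tip with a Kingman genealogy of its
    specimens, rescaled so its basal node sits at exactly ``depth``
    before the present.

    Kingman labelled histories are uniform, so the topology can be built
    top-down by splitting a uniformly chosen lineage at each successive
    coalescence age.
    """
    k = len(labels)
    waits = [rng.exponential(2.0 / (j * (j - 1))) for j in range(2, k + 1)]
    scale = depth / sum(waits)
    ages = [depth]
    for w in waits[:-1]:
        ages.append(ages[-1] - w * scale)
    leaf.end = present - ages[0]
    leaf.children = [_Lin(leaf.end), _Lin(leaf.end)]
    active = list(leaf.children)
    for age in ages[1:]:
        t = present - age
        node = active.pop(int(rng.integers(len(active))))
        node.end = t
        node.children = [_Lin(t), _Lin(t)]
        active.extend(node.children)
    for lab, node in zip(labels, active):
        node.label = lab


# ---------------------------------------------------------------------------
# sequence evolution


_TS_PARTNER = np.array([1, 0, 3, 2])  # A<->G, C<->T
_TV_PARTNERS = np.array([[2, 3], [2, 3], [0, 1], [0, 1]])
_BASES = np.array(list("AGCT"))


def _k80_probs(branch: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after ``branch`` expected
    substitutions per site under K80 with ts/tv rate ratio ``kappa``."""
    beta_t = branch / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_tv_each = 0.25 - 0.25 * math.exp(-4.0 * beta_t)
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * (alpha_t + beta_t))
    return p_ts, p_tv_each


def _evolve(parent: np.ndarray, branch: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    if branch <= 0:
        return parent.copy()
    p_ts, p_tv = _k80_probs(branch, kappa)
    u = rng.random(parent.size)
    child = parent.copy()
    ts = u < p_ts
    tv1 = (~ts) & (u < p_ts + p_tv)
    tv2 = (~ts) & (~tv1) & (u < p_ts + 2 * p_tv)
    child[ts] = _TS_PARTNER[parent[ts]]
    child[tv1] = _TV_PARTNERS[parent[tv1], 0]
    child[tv2] = _TV_PARTNERS[parent[tv2], 1]
    return child


def sim_sequences_k80(
    tree: UltrametricTree, length: int, kappa: float = 2.0,
    scale: float = 1.0, seed: int = 0,
) -> Alignment:
    """Evolve sequences down ``tree`` under K80.

    The root sequence is uniform over ACGT; each branch applies the K80
    transition probabilities for ``branch length x scale`` expected
    substitutions per site.
    """
    if length < 1:
        raise InputError("length must be >= 1")
    if kappa <= 0:
        raise InputError("kappa must be positive")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    seqs: dict = {}
    stack = [(tree.tree.seed_node, root_seq)]
    ids, out = [], []
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            child_seq = _evolve(seq, (child.edge.length or 0.0) * scale, kappa, rng)
            if child.is_leaf():
                ids.append(child.taxon.label)
                out.append("".join(_BASES[child_seq]))
            else:
                stack.append((child, child_seq))
    if not ids:  # degenerate: root only
        ids, out = ["t1"], ["".join(_BASES[root_seq])]
    return Alignment(
        ids=tuple(ids), seqs=tuple(out),
        meta={"generator": "sim_sequences_k80", "length": length,
              "kappa": kappa, "scale": scale, "seed": seed},
    )


# ---------------------------------------------------------------------------
# planted barcode gap


def make_planted_gap_dataset(
    n_species: int,
    tips_per_species: int,
    intra_max: float = 0.01,
    inter_min: float = 0.06,
    length: int = 607,
    seed: int = 0,
    kappa: float = 2.0,
    max_tries: int = 40,
) -> tuple[Alignment, Partition]:
    """Sequences with a guaranteed barcode gap plus the true partition.

    Species are arranged as a star (long stems, shallow tip fans), which
    keeps the rejection rate low: stems carry ``inter_min`` expected
    substitutions each (so interspecific pairs sit near 2x ``inter_min``)
    and tip branches ``intra_max / 8``.  Realized K2P distances are
    checked (all intra <= intra_max, all inter >= inter_min) and the draw
    is repeated on violation.
    """
    if inter_min <= intra_max:
        raise InputError("inter_min must exceed intra_max")
    if n_species < 2 or tips_per_species < 1:
        raise InputError("need >= 2 species and >= 1 tip per species")
    rng = np.random.default_rng(seed)
    stem = inter_min
    tip_branch = intra_max / 8.0
    ids, blocks = [], []
    for s in range(1, n_species + 1):
        tips = [f"sp{s}_t{j}" for j in range(1, tips_per_species + 1)]
        ids.extend(tips)
        blocks.append(tips)
    truth = Partition.from_blocks(blocks, ids=ids)
    for attempt in range(max_tries):
        root = rng.integers(0, 4, size=length)
        seqs: list[str] = []
        for s in range(n_species):
            anc = _evolve(root, stem, kappa, rng)
            for _ in range(tips_per_species):
                seqs.append("".join(_BASES[_evolve(anc, tip_branch, kappa, rng)]))
        aln = Alignment(
            ids=tuple(ids), seqs=tuple(seqs),
            meta={"generator": "make_planted_gap_dataset", "n_species": n_species,
                  "tips_per_species": tips_per_species, "intra_max": intra_max,
                  "inter_min": inter_min, "length": length, "seed": seed,
                  "kappa": kappa, "attempt": attempt},
        )
        dm = build_distance_matrix(aln, model="K2P")
        ok = True
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = dm.matrix[i, j]
                if truth.same_block(ids[i], ids[j]):
                    ok = ok and d <= intra_max
                else:
                    ok = ok and np.isfinite(d) and d >= inter_min
            if not ok:
                break
        if ok:
            return aln, truth
    raise NumericalError(
        f"could not realize the requested gap in {max_tries} attempts"
    )


# ---------------------------------------------------------------------------
# morphospecies labels and suitability grids


def assign_morphospecies_labels(
    true_partition: Partition, n_lumps: int = 0, n_splits: int = 0, seed: int = 0
) -> tuple[MorphoLabels, list[dict]]:
    """Morphospecies names derived from true lineages with controlled
    errors: each lump merges a pair of adjacent lineages under one name
    (the name then spans 2 lineages -> reported as *split* by molecular
    cross-validation); each split gives half of one multi-specimen lineage
    a second name (the lineage then holds 2 names -> its names are
    *lumped*).  Lumped and split lineages are disjoint; the edit log is
    returned alongside the labels."""
    blocks = list(true_partition.blocks)
    if 2 * n_lumps + n_splits > len(blocks):
        raise InputError("not enough lineages for the requested edits")
    rng = np.random.default_rng(seed)
    labels: dict[str, str] = {}
    log: list[dict] = []
    name_idx = 0

    def next_name() -> str:
        nonlocal name_idx
        name_idx += 1
        return f"M{name_idx:02d}"

    idx = 0
    for _ in range(n_lumps):
        name = next_name()
        pair = blocks[idx], blocks[idx + 1]
        for block in pair:
            for sid in block:
                labels[sid] = name
        log.append({"edit": "lump", "name": name,
                    "lineages": [min(b) for b in pair]})
        idx += 2
    splittable = [k for k in range(idx, len(blocks)) if len(blocks[k]) >= 2]
    if n_splits > len(splittable):
        raise InputError("not enough multi-specimen lineages to split")
    split_set = set(splittable[:n_splits])
    for k in range(idx, len(blocks)):
        block = sorted(blocks[k])
        if k in split_set:
            half = max(1, len(block) // 2)
            order = list(rng.permutation(len(block)))
            name_a, name_b = next_name(), next_name()
            for pos in order[:half]:
                labels[block[pos]] = name_a
            for pos in order[half:]:
                labels[block[pos]] = name_b
            log.append({"edit": "split", "lineage": min(block),
                        "names": [name_a, name_b]})
        else:
            name = next_name()
            for sid in block:
                labels[sid] = name
    return MorphoLabels(labels), log


def make_suitability_grids(
    shape: tuple[int, int] = (40, 40),
    centers: tuple[float, float] | None = None,
    widths: tuple[float, float] = (5.0, 5.0),
    separation: float = 0.0,
    seed: int = 0,
    noise: float = 0.0,
) -> tuple[SuitabilityGrid, SuitabilityGrid]:
    """Two Gaussian-bump suitability surfaces whose centers are
    ``separation`` cells apart along the x axis; overlap decreases
    monotonically with separation.  Optional multiplicative noise."""
    rows, cols = shape
    if rows < 2 or cols < 2:
        raise InputError("grid must be at least 2 x 2")
    rng = np.random.default_rng(seed)
    cy = centers[0] if centers else (rows - 1) / 2.0
    cx = centers[1] if centers else (cols - 1) / 2.0
    y, x = np.mgrid[0:rows, 0:cols]
    w1, w2 = widths

    def bump(cx_off: float, w: float) -> np.ndarray:
        d2 = (y - cy) ** 2 + (x - (cx + cx_off)) ** 2
        v = np.exp(-d2 / (2.0 * w * w))
        if noise > 0:
            v = v * np.exp(noise * rng.standard_normal(v.shape))
        return v

    g1 = SuitabilityGrid.from_array(bump(-separation / 2.0, w1))
    g2 = SuitabilityGrid.from_array(bump(+separation / 2.0, w2))
    return g1, g2
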