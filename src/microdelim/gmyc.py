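"""Generalized mixed Yule-coalescent (GMYC) delimitation.

The model views an ultrametric tree as the concatenation of two branching
regimes separated by a threshold age T: *diversification* (speciation)
older than T and *within-species coalescence* younger than T.  Branches
crossing the threshold found independent coalescent groups.  Both regimes
are generalized branching processes: in an inter-event interval ``i`` the
total event rate is

    R_i = lambda_d * n_d,i ** p_d  +  lambda_c * sum_j n_j,i ** p_c

with ``n_d,i`` the diversification lineage count and ``n_j,i`` the lineage
count of coalescent group ``j`` (the ``n ** p`` generalized-Yule dialect
rather than the literal ``n (n-1) / 2``).  The log-likelihood sums
per-event log-rates (of the component producing each event) and subtracts
``sum_i R_i * x_i`` over interval durations.

Conventions follow the mechanics of the two processes:

* A coalescent event's rate uses the lineage count on its *younger* side
  (the merging pair's count, the backward-time convention), so a group's
  basal node scores n = 2; diversification events use the forward-Yule
  count (the count just before the split).
* A group is a single lineage between the threshold and its basal node;
  one lineage cannot coalesce, so that segment carries zero rate.  A tip
  that never joins a multi-specimen group stays in the diversification
  class down to the present.
* The exponent search ranges span the mechanistically meaningful
  families: per-lineage speciation up to linear in n (Yule, with
  density-dependent slowdowns allowed), coalescence between uniform and
  the Kingman-like n^2 scaling.

Threshold placement is discrete (observed branching times).  The single
mode searches one global threshold; the multiple mode greedily refines:
each accepted step gives the inside of one cluster its own, younger
threshold (its upper structure reverts to the diversification class),
while the likelihood improves.  For each candidate classification the
rate scalings profile out in closed form and only the exponents need a
bounded 1-D search, keeping the full threshold sweep fast.  The null mode
fits the whole tree as one class.

Each threshold adds three free parameters (the threshold plus its class's
rate and exponent); this is the degrees-of-freedom convention for the
likelihood-ratio tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .errors import InputError, NumericalError
from .io import Partition, UltrametricTree

__all__ = ["EventTable", "GmycFit", "event_table", "gmyc_loglik", "fit_gmyc", "lr_test"]

# exponent search ranges span the mechanistically meaningful families:
# per-lineage speciation up to linear (Yule) with density-dependent
# slowdowns allowed, coalescence between uniform and Kingman-like n^2
_P_BOUNDS = (-2.0, 2.0)
_P_BOUNDS_DIV = (-2.0, 1.0)
_P_BOUNDS_COAL = (0.0, 2.0)
_IMPROVE_TOL = 1e-4


# ---------------------------------------------------------------------------
# classification of branch segments given threshold domains


@dataclass
class _Classification:
    div_nodes: list  # internal nodes whose event is diversification
    div_segments: list  # (hi, lo) age spans in the diversification class
    clusters: list  # (root node, members: list of internal nodes incl. root)


def _classify(tree: UltrametricTree, domains: dict) -> _Classification:
    """Walk the tree applying per-clade thresholds.

    ``domains`` maps a clade root to the threshold governing that clade
    (the tree root must be present).  Within a domain with threshold T,
    nodes at age >= T are diversification; each maximal subtree younger
    than T is a coalescent group unless it is itself a refined domain.
    """
    age = tree.age
    root = tree.tree.seed_node
    out = _Classification([], [], [])

    def cluster(node) -> None:
        members = [v for v in node.preorder_internal_node_iter()]
        out.clusters.append((node, members))

    def walk(node, t: float) -> None:
        if age[node] < t:  # the whole (sub)tree is one coalescent group
            cluster(node)
            return
        out.div_nodes.append(node)
        for ch in node.child_nodes():
            if ch in domains:
                # refined clade: its own threshold governs it, stem included
                out.div_segments.append((age[node], age[ch]))
                walk(ch, domains[ch])
            elif ch.is_leaf():
                # a single-specimen lineage never enters a coalescent
                # group; it stays in the diversification class throughout
                out.div_segments.append((age[node], 0.0))
            elif age[ch] >= t:
                out.div_segments.append((age[node], age[ch]))
                walk(ch, t)
            else:
                out.div_segments.append((age[node], t))
                cluster(ch)

    walk(root, domains[root])
    return out


def _domains_from_thresholds(tree: UltrametricTree, thresholds: list[float]) -> dict:
    """Interpret a descending list of global thresholds as nested domains:
    the oldest threshold governs the whole tree; each younger one refines
    every cluster deep enough to contain it."""
    root = tree.tree.seed_node
    if not thresholds:
        return {root: 0.0}
    ts = sorted(thresholds, reverse=True)
    domains = {root: ts[0]}
    for t in ts[1:]:
        cls = _classify(tree, domains)
        for r, _members in cls.clusters:
            if tree.age[r] >= t:
                domains[r] = t
    return domains


@dataclass
class EventTable:
    """Inter-event intervals from root to present with per-class counts.

    ``durations`` covers the whole depth; ``n_div`` counts diversification
    lineages per interval; ``group_counts`` (groups x intervals) the
    coalescent group sizes (zero while a group is a single lineage).
    Event-count arrays hold the lineage count entering each event's rate
    term.
    """

    durations: np.ndarray
    n_div: np.ndarray
    group_counts: np.ndarray
    div_event_counts: np.ndarray
    coal_event_counts: np.ndarray
    depth: float

    def __post_init__(self) -> None:
        if np.any(self.durations < -1e-12):
            raise InputError("negative interval duration")
        if abs(self.durations.sum() - self.depth) > 1e-6 * max(self.depth, 1.0):
            raise InputError("interval durations do not sum to tree depth")


def _table_from_classification(tree: UltrametricTree, cls: _Classification) -> EventTable:
    age = tree.age
    depth = tree.depth
    breaks = {depth, 0.0}
    breaks.update(age[v] for v in tree.tree.preorder_internal_node_iter())
    for hi, lo in cls.div_segments:
        breaks.add(min(max(lo, 0.0), depth))
    bounds = sorted(breaks, reverse=True)
    mids = [(a + b) / 2.0 for a, b in zip(bounds[:-1], bounds[1:])]
    durations = np.array([a - b for a, b in zip(bounds[:-1], bounds[1:])])
    segs = [(hi, max(lo, 0.0)) for hi, lo in cls.div_segments]
    n_div = np.array(
        [sum(1 for hi, lo in segs if lo <= m <= hi) for m in mids], dtype=int
    )
    group_counts = np.zeros((len(cls.clusters), len(mids)), dtype=int)
    coal_events: list[int] = []
    for g, (r, members) in enumerate(cls.clusters):
        member_ages = np.array(sorted((age[v] for v in members), reverse=True))
        for k, m in enumerate(mids):
            if m < member_ages[0]:
                group_counts[g, k] = 1 + int(np.sum(member_ages > m))
        # every coalescent event (the basal one included) carries a term
        coal_events.extend(
            1 + int(np.sum(member_ages >= age[v])) for v in members
        )
    # the root event only starts the diversification process (two initial
    # lineages) and carries no event term, matching the Yule convention
    root = tree.tree.seed_node
    div_events = [
        sum(1 for hi, lo in segs if lo <= age[v] < hi)
        for v in cls.div_nodes
        if v is not root
    ]
    return EventTable(
        durations=durations,
        n_div=n_div,
        group_counts=group_counts,
        div_event_counts=np.array(div_events, dtype=int),
        coal_event_counts=np.array(coal_events, dtype=int),
        depth=depth,
    )


def event_table(tree: UltrametricTree, thresholds: list[float] | None = None) -> EventTable:
    """Interval/count table for a set of global threshold ages.

    No thresholds: the whole tree is the diversification class (the table
    then encodes a plain generalized-Yule tree).  A threshold above the
    root makes the tree one coalescent group.  Younger extra thresholds
    refine inside the clusters of the older ones.
    """
    thresholds = list(thresholds or [])
    for t in thresholds:
        if not 0.0 <= t <= tree.depth * (1.0 + 1e-6):
            raise InputError("threshold outside [0, depth]")
    domains = _domains_from_thresholds(tree, thresholds)
    return _table_from_classification(tree, _classify(tree, domains))


# ---------------------------------------------------------------------------
# likelihood


def _class_arrays(table: EventTable, which: str):
    """(event counts, waiting xs, waiting ns) for one class."""
    if which == "div":
        events = table.div_event_counts
        mask = table.n_div > 0
        xs = table.durations[mask]
        ns = table.n_div[mask].astype(float)
    else:
        events = table.coal_event_counts
        gx = np.broadcast_to(table.durations, table.group_counts.shape)
        mask = table.group_counts > 0
        xs = gx[mask]
        ns = table.group_counts[mask].astype(float)
    return events.astype(float), xs, ns


def _class_loglik(events, xs, ns, lam, p):
    if lam < 0:
        raise InputError("rates must be non-negative")
    if lam == 0:
        return -math.inf if events.size else 0.0
    waiting = float(np.sum(xs * np.power(ns, p)))
    out = float(events.size * math.log(lam) + p * np.sum(np.log(events))) - lam * waiting
    if not np.isfinite(out):
        raise NumericalError("non-finite GMYC likelihood term")
    return out


def gmyc_loglik(
    table: EventTable, lambda_d: float, p_d: float, lambda_c: float, p_c: float
) -> float:
    """Mixed-model log-likelihood at given rate scalings and exponents."""
    out = 0.0
    for which, lam, p in (("div", lambda_d, p_d), ("coal", lambda_c, p_c)):
        events, xs, ns = _class_arrays(table, which)
        if events.size == 0 and (xs.size == 0 or lam == 0.0):
            continue  # empty class drops out in the rate -> 0 limit
        out += _class_loglik(events, xs, ns, lam, p)
    return out


def _fit_class(events, xs, ns, fix_p: float | None = None, bounds=_P_BOUNDS):
    """Profile maximum likelihood for one class.

    For fixed exponent p the rate MLE is (number of events)/sum(x * n**p),
    so only p needs a bounded 1-D search (coarse grid, then refinement).
    Returns (lnL, lambda_hat, p_hat); an eventless class contributes 0.
    """
    n_events = events.size
    if n_events == 0:
        return 0.0, 0.0, float("nan")
    ln_ns = np.log(ns)
    sum_ln_events = float(np.sum(np.log(events)))

    def profile(p: float) -> float:
        w = float(np.sum(xs * np.exp(p * ln_ns)))
        if w <= 0:
            return math.inf
        return -(n_events * (math.log(n_events / w) - 1.0) + p * sum_ln_events)

    if fix_p is not None:
        p_hat = fix_p
    else:
        grid = np.linspace(*bounds, 9)
        vals = [profile(p) for p in grid]
        p0 = grid[int(np.argmin(vals))]
        res = minimize_scalar(
            profile,
            bounds=(max(bounds[0], p0 - 0.6), min(bounds[1], p0 + 0.6)),
            method="bounded",
        )
        p_hat = float(res.x) if res.fun <= min(vals) else float(p0)
    w = float(np.sum(xs * np.exp(p_hat * ln_ns)))
    return -profile(p_hat), n_events / w, p_hat


@dataclass
class GmycFit:
    """A fitted GMYC model and its entity partition.

    ``n_entities`` counts delimited units (coalescent groups plus
    unclustered tips); ``n_clusters`` only the groups with >= 2 tips.
    """

    mode: str
    thresholds: tuple[float, ...]
    lambda_d: float
    p_d: float
    lambda_c: float
    p_c: float
    loglik: float
    n_entities: int
    n_clusters: int
    partition: Partition
    n_thresholds: int
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise NumericalError("non-finite GMYC log-likelihood")


def _partition_from(tree: UltrametricTree, cls: _Classification) -> Partition:
    blocks, clustered = [], set()
    for r, _members in cls.clusters:
        tips = [t.taxon.label for t in r.leaf_iter()]
        blocks.append(tips)
        clustered.update(tips)
    tip_order = tree.tip_labels
    blocks.extend([t] for t in tip_order if t not in clustered)
    return Partition.from_blocks(blocks, ids=tip_order)


def _fit_domains(tree: UltrametricTree, domains: dict, fix_p):
    cls = _classify(tree, domains)
    table = _table_from_classification(tree, cls)
    ln_d, lam_d, p_d = _fit_class(*_class_arrays(table, "div"), fix_p=fix_p,
                                  bounds=_P_BOUNDS_DIV)
    ln_c, lam_c, p_c = _fit_class(*_class_arrays(table, "coal"), fix_p=fix_p,
                                  bounds=_P_BOUNDS_COAL)
    return ln_d + ln_c, (lam_d, p_d, lam_c, p_c), cls


def fit_gmyc(tree: UltrametricTree, mode: str = "single", fix_p: float | None = None) -> GmycFit:
    """Maximum-likelihood GMYC fit in ``null``, ``single`` or ``multiple``
    threshold mode.  ``fix_p`` pins both exponents (1 = plain Yule mix)."""
    if tree.n_tips < 3:
        raise InputError("GMYC needs at least 3 tips")
    if mode not in ("null", "single", "multiple"):
        raise InputError(f"unknown mode {mode!r}")
    root = tree.tree.seed_node
    if mode == "null":
        best_lnl, best_params, _ = _fit_domains(tree, {root: 0.0}, fix_p)
        part = Partition.from_blocks([tree.tip_labels], ids=tree.tip_labels)
        return GmycFit(
            mode="null", thresholds=(), lambda_d=best_params[0], p_d=best_params[1],
            lambda_c=best_params[2], p_c=best_params[3], loglik=best_lnl,
            n_entities=1, n_clusters=1, partition=part, n_thresholds=0,
        )
    candidates = [0.0] + sorted(set(tree.internal_ages()))
    best = None
    for t in candidates:
        lnl, params, cls = _fit_domains(tree, {root: t}, fix_p)
        if best is None or lnl > best[0]:
            best = (lnl, params, cls, t)
    best_lnl, best_params, best_cls, best_t = best
    domains = {root: best_t}
    n_thresholds = 1
    if mode == "multiple":
        improved = True
        while improved:
            improved = False
            step = None
            for r, members in best_cls.clusters:
                if len(members) < 2 or r in domains:
                    continue
                for t in sorted({tree.age[v] for v in members}, reverse=True):
                    trial = dict(domains)
                    trial[r] = t
                    lnl, params, cls = _fit_domains(tree, trial, fix_p)
                    if lnl > best_lnl + _IMPROVE_TOL and (step is None or lnl > step[0]):
                        step = (lnl, params, cls, trial)
            if step is not None:
                best_lnl, best_params, best_cls, domains = step
                n_thresholds += 1
                improved = True
    part = _partition_from(tree, best_cls)
    lam_d, p_d, lam_c, p_c = best_params
    return GmycFit(
        mode=mode,
        thresholds=tuple(sorted(domains.values(), reverse=True)),
        lambda_d=lam_d, p_d=p_d, lambda_c=lam_c, p_c=p_c,
        loglik=best_lnl,
        n_entities=part.n_blocks,
        n_clusters=sum(1 for b in part.blocks if len(b) > 1),
        partition=part,
        n_thresholds=n_thresholds,
    )


def lr_test(lnl_general: float, lnl_restricted: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio test: 2 (lnL_general - lnL_restricted) against the
    upper tail of a chi-square with ``df`` degrees of freedom."""
    if df < 1:
        raise InputError("df must be >= 1")
    delta = lnl_general - lnl_restricted
    if delta < -1e-6:
        raise InputError("general model fits worse than the restricted one")
    stat = max(2.0 * delta, 0.0)
    return stat, float(chi2.sf(stat, df))
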