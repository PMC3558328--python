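"""Diversification-rate model fitting, AIC model selection, the simulated
delta-AIC rate-constancy test, LTT data and recent-history truncation.

Five models are fitted to the branching times of an ultrametric tree:

* ``pureBirth``  - constant speciation rate r1 (rate-constant, RC)
* ``bd``         - constant birth-death in net rate r1 = b - d and
                   extinction fraction a = d / b (RC), via the Nee-style
                   conditional likelihood on branching times
* ``DDL``        - logistic density dependence, lambda(n) = r1 (1 - n / k)
* ``DDX``        - power-law density dependence, lambda(n) = r1 * n**(-xp)
* ``yule2rate``  - one rate shift: r1 before the shift age st, r2 after

The pure-birth family uses the generalized-Yule likelihood over inter-event
intervals (root starts with two lineages; the final interval carries only a
waiting term); no conditioning constant on survival or tip count is added,
so absolute log-likelihoods are comparable only within this convention.
AIC = 2P - 2 lnL.  Rate-constancy is tested by the difference in AIC
between the best rate-constant and best rate-variable model, calibrated
against the same statistic on pure-birth trees simulated at the fitted
rate (a parametric bootstrap guarding against the test's type-I inflation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .errors import InputError, NumericalError
from .io import UltrametricTree

__all__ = [
    "BranchingTimes",
    "DivModelFit",
    "branching_times",
    "generalized_yule_loglik",
    "fit_div_model",
    "model_selection_table",
    "delta_aic_null_test",
    "ltt_points",
    "truncate_recent_history",
    "simulate_purebirth_ages",
]

MODELS = ("pureBirth", "bd", "DDL", "DDX", "yule2rate")
RATE_CONSTANT = ("pureBirth", "bd")
RATE_VARIABLE = ("DDL", "DDX", "yule2rate")
_N_PARAMS = {"pureBirth": 1, "bd": 2, "DDL": 2, "DDX": 2, "yule2rate": 3}


@dataclass(frozen=True)
class BranchingTimes:
    """Internal-node ages (time before present), sorted descending."""

    ages: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        if ages.size < 1:
            raise InputError("need at least one branching time")
        if np.any(np.diff(ages) > 0):
            raise InputError("ages must be sorted descending")
        if np.any(ages <= 0) or not np.all(np.isfinite(ages)):
            raise InputError("ages must be finite and strictly positive")
        object.__setattr__(self, "ages", ages)

    @property
    def n(self) -> int:
        """Number of tips (one more than the number of branching events)."""
        return self.ages.size + 1

    @property
    def depth(self) -> float:
        return float(self.ages[0])

    def intervals(self) -> tuple[np.ndarray, np.ndarray]:
        """(durations, lineage counts) for the N-1 inter-event intervals,
        from the root interval (2 lineages) to the final one (N)."""
        bounds = np.concatenate([self.ages, [0.0]])
        durations = -np.diff(bounds)
        counts = np.arange(2, self.n + 1, dtype=float)
        return durations, counts


def branching_times(tree: UltrametricTree) -> BranchingTimes:
    """Extract node ages from an (already validated) ultrametric tree."""
    return BranchingTimes(np.array(tree.internal_ages(), dtype=float))


def generalized_yule_loglik(bt: BranchingTimes, rate_fn) -> float:
    """Generalized-Yule log-likelihood with per-lineage rate
    ``rate_fn(n, t)`` (t = age at the start of the interval).

    lnL = sum over events of ln(n * lambda) minus the lineage-time integral
    of the total rate; the rate must be positive over the tree's span.
    """
    durations, counts = bt.intervals()
    starts = bt.ages  # age at the older end of each interval
    rates = np.array([rate_fn(int(n), float(t)) for n, t in zip(counts, starts)])
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        bad = int(np.argmax(~((rates > 0) & np.isfinite(rates))))
        raise NumericalError(f"non-positive rate in interval {bad}")
    event_terms = np.log(counts[:-1] * rates[:-1])  # final interval has no event
    waiting = np.sum(counts * rates * durations)
    return float(np.sum(event_terms) - waiting)


# ---------------------------------------------------------------------------
# model fits


@dataclass
class DivModelFit:
    """One fitted diversification model (a Table-4-style row)."""

    model: str
    mtype: str  # "RC" or "RV"
    loglik: float
    n_params: int
    params: dict
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise NumericalError(f"non-finite log-likelihood for {self.model}")


def _lineage_time_sums(bt: BranchingTimes):
    durations, counts = bt.intervals()
    lt = counts * durations  # lineage-time per interval
    event_ns = counts[:-1]  # lineage count at each of the N-2 events
    const = float(np.sum(np.log(event_ns)))  # = ln (N-1)!
    return durations, counts, lt, event_ns, const


def _fit_purebirth(bt: BranchingTimes) -> DivModelFit:
    _, _, lt, event_ns, const = _lineage_time_sums(bt)
    total_lt = float(lt.sum())
    e = event_ns.size
    r1 = e / total_lt
    lnl = const + e * math.log(r1) - r1 * total_lt
    return DivModelFit("pureBirth", "RC", lnl, 1, {"r1": r1})


def _fit_yule2rate(bt: BranchingTimes) -> DivModelFit:
    ages = bt.ages
    durations, counts, lt, event_ns, const = _lineage_time_sums(bt)
    n = bt.n
    if n < 5:
        raise InputError("yule2rate needs at least 5 tips")
    event_ages = ages[1:]  # ages of the N-2 non-root events
    best = None
    for k in range(2, n):  # shift at a (non-root) branching age
        st = float(ages[k - 1])
        # lineage-time above the shift age: per-interval overlap with [st, depth]
        starts = ages
        ends = np.concatenate([ages[1:], [0.0]])
        above = np.clip(starts - np.maximum(ends, st), 0.0, None)
        w1 = float(np.sum(counts * above))
        w2 = float(lt.sum()) - w1
        e1 = int(np.sum(event_ages >= st))
        e2 = event_ages.size - e1
        if e1 < 1 or w1 <= 0 or w2 <= 0:
            continue
        # an eventless young regime is admissible: its rate MLE is the
        # lambda -> 0 supremum (no events, no waiting penalty), which is
        # how a recent, still eventless slowdown is expressed
        lnl = const + e1 * (math.log(e1 / w1) - 1.0)
        r2 = 0.0
        if e2 >= 1:
            lnl += e2 * (math.log(e2 / w2) - 1.0)
            r2 = e2 / w2
        if best is None or lnl > best[0] + 1e-12:
            best = (lnl, st, e1 / w1, r2)
    if best is None:
        raise NumericalError("no admissible shift time")
    lnl, st, r1, r2 = best
    return DivModelFit(
        "yule2rate", "RV", lnl, 3,
        {"r1": r1, "r2": max(r2, np.finfo(float).tiny), "st": st},
    )


def _profile_rate_fit(bt: BranchingTimes, model: str, shape_fn, grid, bounds):
    """1-D profile fit for DDL/DDX: lambda(n) = r1 * shape(n; theta)."""
    durations, counts, lt, event_ns, const = _lineage_time_sums(bt)
    e = event_ns.size

    def neg_profile(theta: float) -> float:
        shape_waiting = shape_fn(counts, theta)
        shape_events = shape_fn(event_ns, theta)
        if np.any(shape_waiting <= 0) or np.any(shape_events <= 0):
            return math.inf
        w = float(np.sum(lt * shape_waiting))
        return -(const + float(np.sum(np.log(shape_events)))
                 + e * (math.log(e / w) - 1.0))

    vals = [neg_profile(t) for t in grid]
    t0 = grid[int(np.argmin(vals))]
    span = (grid[1] - grid[0]) if len(grid) > 1 else 1.0
    lo = max(bounds[0], t0 - span)
    hi = min(bounds[1], t0 + span)
    res = minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded")
    theta = float(res.x) if res.fun <= min(vals) else float(t0)
    w = float(np.sum(lt * shape_fn(counts, theta)))
    r1 = e / w
    return -neg_profile(theta), r1, theta


def _fit_ddl(bt: BranchingTimes) -> DivModelFit:
    n = bt.n
    # carrying capacity k > N so the rate stays positive; k = N + exp(u)
    grid = np.linspace(-4.0, 18.0, 23)
    lnl, r1, u = _profile_rate_fit(
        bt, "DDL", lambda m, uu: 1.0 - m / (n + math.exp(uu)), grid, (-6.0, 20.0)
    )
    k = n + math.exp(u)
    pb = _fit_purebirth(bt)
    if pb.loglik > lnl:  # k -> inf limit is pure birth
        lnl, r1, k = pb.loglik, pb.params["r1"], n + math.exp(20.0)
    return DivModelFit("DDL", "RV", lnl, 2, {"r1": r1, "k": k})


def _fit_ddx(bt: BranchingTimes) -> DivModelFit:
    grid = np.linspace(-5.0, 5.0, 21)
    lnl, r1, xp = _profile_rate_fit(
        bt, "DDX", lambda m, x: np.power(m, -x), grid, (-5.0, 5.0)
    )
    return DivModelFit("DDX", "RV", lnl, 2, {"r1": r1, "xp": xp})


def _bd_loglik(bt: BranchingTimes, r: float, a: float) -> float:
    """Nee-style birth-death likelihood in (net rate r, extinction
    fraction a), sharing the pure-birth constant so that a = 0 reproduces
    the pureBirth log-likelihood exactly."""
    ages = bt.ages
    n = bt.n
    if r <= 0 or not (0.0 <= a < 1.0):
        return -math.inf
    rx = r * ages
    # log(exp(r x) - a) computed stably as r x + log1p(-a exp(-r x))
    log_terms = rx + np.log1p(-a * np.exp(-rx))
    lnl = (
        math.lgamma(n)
        + (n - 2) * math.log(r)
        + r * float(np.sum(ages[1:]))
        + n * math.log1p(-a)
        - 2.0 * float(np.sum(log_terms))
    )
    return lnl


def _fit_bd(bt: BranchingTimes) -> DivModelFit:
    pb = _fit_purebirth(bt)
    r0 = pb.params["r1"]

    def neg(theta):
        lr, logit_a = theta
        a = 1.0 / (1.0 + math.exp(-logit_a))
        out = _bd_loglik(bt, math.exp(lr), a)
        return -out if np.isfinite(out) else 1e12

    best_lnl, best_r, best_a, ok = pb.loglik, r0, 0.0, True
    for a_start in (0.2, 0.7):
        theta0 = np.array([math.log(r0), math.log(a_start / (1 - a_start))])
        res = minimize(neg, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
        lnl = -res.fun
        if lnl > best_lnl:
            a = 1.0 / (1.0 + math.exp(-res.x[1]))
            best_lnl, best_r, best_a = lnl, math.exp(res.x[0]), a
            ok = bool(res.success)
    return DivModelFit("bd", "RC", best_lnl, 2, {"r1": best_r, "a": best_a},
                       converged=ok)


_FITTERS = {
    "pureBirth": _fit_purebirth,
    "bd": _fit_bd,
    "DDL": _fit_ddl,
    "DDX": _fit_ddx,
    "yule2rate": _fit_yule2rate,
}


def fit_div_model(bt: BranchingTimes, model: str) -> DivModelFit:
    """Fit one named diversification model by maximum likelihood."""
    if model not in _FITTERS:
        raise InputError(f"unknown model {model!r}; choose from {MODELS}")
    if bt.n < 4:
        raise InputError("diversification fits need at least 4 tips")
    return _FITTERS[model](bt)


def model_selection_table(bt: BranchingTimes) -> list[DivModelFit]:
    """All five fits ranked by AIC (ties broken by fewer parameters);
    each fit's delta-AIC is stored under ``params['delta_aic']``."""
    fits = [fit_div_model(bt, m) for m in MODELS]
    fits.sort(key=lambda f: (f.aic, f.n_params))
    best = fits[0].aic
    for f in fits:
        f.params["delta_aic"] = f.aic - best
    return fits


# ---------------------------------------------------------------------------
# the simulated delta-AIC rate-constancy test


def simulate_purebirth_ages(n_tips: int, rate: float, rng: np.random.Generator) -> BranchingTimes:
    """Branching ages of a pure-birth tree conditioned on ``n_tips``:
    inter-event intervals are Exp(n * rate) while n lineages exist, with a
    final waiting interval before the (unobserved) next event."""
    counts = np.arange(2, n_tips + 1)
    waits = rng.exponential(1.0 / (counts * rate))
    times = np.cumsum(waits)  # event times from the root; last = present
    depth = times[-1]
    ages = depth - np.concatenate([[0.0], times[:-1]])
    return BranchingTimes(ages)


def _rc_rv_stat(bt: BranchingTimes) -> float:
    fits = {m: fit_div_model(bt, m) for m in MODELS}
    best_rc = min(fits[m].aic for m in RATE_CONSTANT)
    best_rv = min(fits[m].aic for m in RATE_VARIABLE)
    return best_rc - best_rv


def delta_aic_null_test(
    bt: BranchingTimes, n_sims: int = 500, seed: int = 0
) -> tuple[float, np.ndarray, float]:
    """Test rate constancy with a simulated null distribution.

    The statistic is AIC(best rate-constant) - AIC(best rate-variable);
    the null resamples it from ``n_sims`` pure-birth trees with the same
    tip count at the fitted pure-birth rate.  Returns
    (observed statistic, null statistics, add-one smoothed p-value).
    """
    if n_sims < 1:
        raise InputError("n_sims must be >= 1")
    observed = _rc_rv_stat(bt)
    rate = fit_div_model(bt, "pureBirth").params["r1"]
    rng = np.random.default_rng(seed)
    null = np.array([
        _rc_rv_stat(simulate_purebirth_ages(bt.n, rate, rng)) for _ in range(n_sims)
    ])
    p = (1.0 + float(np.sum(null >= observed))) / (n_sims + 1.0)
    return observed, null, p


# ---------------------------------------------------------------------------
# LTT data and recent-history truncation


def ltt_points(bt: BranchingTimes) -> list[tuple[float, int]]:
    """Lineage-through-time step points on the relative time scale
    (present = 0, root = -1): (-1, 2) at the root, then one point per
    subsequent branching up to (nearly) the present."""
    pts = [(-1.0, 2)]
    for k, age in enumerate(bt.ages[1:], start=1):
        pts.append((-float(age) / bt.depth, k + 2))
    return pts


def _truncated_newick(tree: UltrametricTree, node, cut: float) -> str:
    parts = []
    for child in node.child_nodes():
        if tree.age[child] >= cut:
            sub = _truncated_newick(tree, child, cut)
            parts.append(f"{sub}:{tree.age[node] - tree.age[child]:.12g}")
        else:
            rep = child.taxon.label if child.is_leaf() else next(
                child.leaf_iter()
            ).taxon.label
            parts.append(f"{rep}:{tree.age[node] - cut:.12g}")
    return "(" + ",".join(parts) + ")"


def truncate_recent_history(tree: UltrametricTree, fraction: float = 0.05) -> UltrametricTree:
    """Drop the most recent ``fraction`` of the tree's history.

    The tree is sliced at age = fraction * depth before the present; every
    lineage crossing the slice becomes a tip, so cherries younger than the
    slice merge.  The result is ultrametric with depth (1 - fraction) *
    depth.  ``fraction = 0`` returns an unchanged copy.
    """
    if not (0.0 <= fraction < 1.0):
        raise InputError("fraction must be in [0, 1)")
    cut = fraction * tree.depth
    root = tree.tree.seed_node
    if tree.age[root] <= cut:
        raise InputError("slice is above the root")
    if fraction == 0.0:
        return UltrametricTree.from_newick(tree.as_newick(), tolerance=tree.tolerance)
    newick = _truncated_newick(tree, root, cut) + ";"
    return UltrametricTree.from_newick(newick, tolerance=max(tree.tolerance, 1e-6))
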