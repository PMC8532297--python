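"""Phylogenetic-informativeness (PI) profiling on an ultrametric tree.

Per-site substitution rates are estimated by maximum likelihood under
Jukes-Cantor with Felsenstein pruning: every alignment column gets the
rate multiplier lambda that maximizes its likelihood on the fixed,
depth-normalized ultrametric tree.  Per-site informativeness at time
depth t then follows the quartet-internode approximation

    rho(t; lambda) = 16 lambda^2 t exp(-4 lambda t)

which peaks at t = 1/(4 lambda) with value 4/e for lambda = 1: a site is
most informative at the depth matching its rate.  Net PI of a partition
sums rho over its sites; per-site PI divides by the site count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .genome_io import AlignmentBlock
from .phylo_trees import is_ultrametric

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SiteRates:
    """Per-site JC rate multipliers for one partition."""
    partition: str
    rates: np.ndarray
    rate_cap: float
    n_invariant: int
    n_capped: int

    @property
    def n_sites(self) -> int:
        return int(self.rates.size)


@dataclass
class PIProfile:
    """Net and per-site informativeness over a time grid."""
    partition: str
    times: np.ndarray
    net: np.ndarray
    per_site: np.ndarray

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.net))])


class _PruningTree:
    """Postorder arrays for fast repeated JC pruning on a fixed tree."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children = [[self.index[id(c)] for c in n.child_nodes()]
                         for n in nodes]
        self.edge_len = np.array([n.edge.length or 0.0 for n in nodes])
        self.tip_index = {n.taxon.label: self.index[id(n)]
                          for n in nodes if n.is_leaf()}
        self.root = self.n_nodes - 1

    def column_likelihood(self, partials: np.ndarray, lam: float) -> float:
        """Pruning likelihood of one column at rate multiplier ``lam``.

        ``partials`` is an (n_nodes, 4) array whose tip rows hold the
        observation vectors (ones for missing data); internal rows are
        overwritten.  Uniform 1/4 root frequencies.
        """
        if lam < 0:
            raise ValueError("rate multiplier must be nonnegative")
        L = partials.copy()
        e = np.exp(-4.0 * lam * self.edge_len / 3.0)
        for i in range(self.n_nodes):
            kids = self.children[i]
            if not kids:
                continue
            prod = np.ones(4)
            for k in kids:
                ek = e[k]
                # JC: P(same) = 1/4 + 3/4 e, P(diff) = 1/4 - 1/4 e
                msg = 0.25 * (1 - ek) * L[k].sum() + ek * L[k]
                prod *= msg
            L[i] = prod
        return float(0.25 * L[self.root].sum())

    def loglik_grid(self, partials: np.ndarray, lams: np.ndarray
                    ) -> np.ndarray:
        """Column log-likelihood at every rate in ``lams`` (vectorized)."""
        G = lams.size
        L = np.broadcast_to(partials[:, None, :],
                            (self.n_nodes, G, 4)).copy()
        e = np.exp(-4.0 * np.outer(self.edge_len, lams) / 3.0)
        for i in range(self.n_nodes):
            kids = self.children[i]
            if not kids:
                continue
            prod = np.ones((G, 4))
            for k in kids:
                ek = e[k][:, None]
                msg = 0.25 * (1 - ek) * L[k].sum(axis=1, keepdims=True) \
                    + ek * L[k]
                prod *= msg
            L[i] = prod
        lk = 0.25 * L[self.root].sum(axis=1)
        with np.errstate(divide="ignore"):
            return np.log(lk)


def column_likelihood(column: dict, tree: dendropy.Tree,
                      lam: float) -> float:
    """Likelihood of one column pattern ({tip: base}) at multiplier lam.

    Gaps, N and absent taxa are treated as missing data (partial vector of
    ones).  Branch lengths are multiplied by lam; Jukes-Cantor model with
    uniform base frequencies.
    """
    pt = _PruningTree(tree)
    partials = _column_partials(pt, column)
    return pt.column_likelihood(partials, lam)


def _column_partials(pt: _PruningTree, column: dict) -> np.ndarray:
    partials = np.ones((pt.n_nodes, 4))
    for tip, base in column.items():
        if tip not in pt.tip_index:
            raise KeyError(f"tip {tip!r} absent from tree")
        idx = _BASE_INDEX.get(base)
        if idx is not None:
            vec = np.zeros(4)
            vec[idx] = 1.0
            partials[pt.tip_index[tip]] = vec
    return partials


def estimate_site_rates(block: AlignmentBlock, tree: dendropy.Tree,
                        rate_cap: float = 20.0,
                        tol: float = 1e-6,
                        partition: str | None = None) -> SiteRates:
    """ML rate multiplier per alignment column on a depth-1 ultrametric tree.

    Invariant columns (and columns with fewer than two non-missing taxa)
    short-circuit to rate 0; variable columns maximize the pruning
    likelihood over [0, rate_cap] by bounded 1-D search.  Columns whose
    optimum sits at the cap are counted so saturation artifacts stay
    visible.  Identical column patterns are solved once.
    """
    if not is_ultrametric(tree, tol=1e-3):
        raise ValueError("rate estimation expects an ultrametric tree")
    pt = _PruningTree(tree)
    m = block.matrix
    n_samples, n_sites = m.shape
    tips = block.samples
    missing_tree = [t for t in tips if t not in pt.tip_index]
    if missing_tree:
        raise KeyError(f"samples absent from tree: {missing_tree}")

    rates = np.zeros(n_sites)
    n_invariant = n_capped = 0
    cache: dict = {}
    for j in range(n_sites):
        col = tuple(m[:, j])
        if col in cache:
            rates[j] = cache[col]
            if rates[j] >= rate_cap:
                n_capped += 1
            elif rates[j] == 0.0:
                n_invariant += 1
            continue
        observed = [b for b in col if b in _BASE_INDEX]
        if len(observed) < 2 or len(set(observed)) == 1:
            cache[col] = 0.0
            n_invariant += 1
            continue
        partials = _column_partials(pt, dict(zip(tips, col)))
        # the column likelihood can be multimodal in lambda: bracket the
        # global maximum on a coarse grid first, then refine
        coarse = np.linspace(0.0, rate_cap, 201)
        ll = pt.loglik_grid(partials, coarse)
        best = int(np.argmax(ll))
        lo = coarse[max(best - 1, 0)]
        hi = coarse[min(best + 1, coarse.size - 1)]
        res = minimize_scalar(
            lambda lam: -_loglik(pt, partials, lam),
            bounds=(lo, hi), method="bounded", options={"xatol": tol})
        lam_hat = float(res.x)
        if -res.fun < ll[best]:
            lam_hat = float(coarse[best])
        if lam_hat >= rate_cap * (1 - 1e-6):
            lam_hat = rate_cap
            n_capped += 1
        cache[col] = lam_hat
        rates[j] = lam_hat
    return SiteRates(partition=partition or block.gene, rates=rates,
                     rate_cap=rate_cap, n_invariant=n_invariant,
                     n_capped=n_capped)


def _loglik(pt: _PruningTree, partials: np.ndarray, lam: float) -> float:
    lk = pt.column_likelihood(partials, lam)
    return math.log(lk) if lk > 0 else -1e300


def per_site_pi(t, lam) -> np.ndarray:
    """rho(t; lambda) = 16 lambda^2 t exp(-4 lambda t)."""
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return 16.0 * lam ** 2 * t * np.exp(-4.0 * lam * t)


def default_time_grid(n: int = 200, depth: float = 1.0) -> np.ndarray:
    """n uniform points on (0, depth]."""
    return np.linspace(depth / n, depth, n)


def pi_profile(rates: SiteRates, times=None) -> PIProfile:
    """Net and per-site PI of one partition over a time grid."""
    times = default_time_grid() if times is None else np.asarray(times,
                                                                 dtype=float)
    if rates.n_sites == 0:
        zero = np.zeros_like(times)
        return PIProfile(rates.partition, times, zero, zero)
    net = per_site_pi(times[:, None], rates.rates[None, :]).sum(axis=1)
    return PIProfile(rates.partition, times, net, net / rates.n_sites)


def rank_partitions(profiles, t: float, use: str = "net") -> list:
    """Partition labels sorted by PI at time t, descending; ties by label."""
    ranked = []
    for prof in profiles:
        hits = np.nonzero(np.isclose(prof.times, t))[0]
        if hits.size == 0:
            raise ValueError(f"time {t} not on the profile grid of "
                             f"{prof.partition}")
        value = (prof.net if use == "net" else prof.per_site)[hits[0]]
        ranked.append((-value, prof.partition))
    return [label for _, label in sorted(ranked)]
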