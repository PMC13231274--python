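"""Phylogenetic models of sex-chromosome turnover.

Two models live here:

* A two-state Mk (continuous-time Markov) model of the binary character
  "derived X present" with rates q01 (turnover gain) and q10 (reversal).
  ER constrains q01 = q10; ARD frees both.  Branches can be partitioned
  into rate regimes (e.g. Schizophora vs background), each regime with its
  own rates.  Likelihoods are computed by Felsenstein pruning with the
  closed-form 2-state transition matrix; nested fits are compared with
  likelihood-ratio tests.

* Brownian-motion ancestral reconstruction of a continuous trait (the
  percentage of mapped genes on element F).  Maximum-likelihood node
  values are obtained by solving the weighted tree-Laplacian system with
  tips clamped (equivalent to generalized least squares under the BM tree
  covariance); per-node variances come from the inverse Laplacian scaled
  by the ML rate estimate.

Newick I/O is handled by dendropy; computations run on flat index arrays
extracted from the dendropy tree.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats

logger = logging.getLogger("mullerx")


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------

class Phylogeny:
    """A rooted tree with branch lengths, flattened to index arrays.

    Nodes are indexed in postorder (root last).  ``labels[i]`` is the taxon
    label for tips and a stable ``node<i>`` identifier for unlabelled
    internal nodes; ``blen[i]`` is the length of the edge above node ``i``
    (0 for the root).
    """

    def __init__(
        self,
        parent: np.ndarray,
        blen: np.ndarray,
        labels: list[str],
        is_tip: np.ndarray,
        dendropy_tree: dendropy.Tree | None = None,
    ) -> None:
        self.parent = parent
        self.blen = blen
        self.labels = labels
        self.is_tip = is_tip
        self.n_nodes = len(labels)
        self.root = self.n_nodes - 1
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes - 1):
            self.children[self.parent[i]].append(i)
        self.postorder = np.arange(self.n_nodes)  # construction order is postorder
        self.tip_labels = [labels[i] for i in range(self.n_nodes) if is_tip[i]]
        self.index = {lab: i for i, lab in enumerate(labels)}
        self._dendropy = dendropy_tree

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        seen_tips: set[str] = set()
        order: list[dendropy.Node] = []
        for node in tree.postorder_node_iter():
            order.append(node)
        idx = {id(node): i for i, node in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n, dtype=np.float64)
        labels: list[str] = []
        is_tip = np.zeros(n, dtype=bool)
        for i, node in enumerate(order):
            if node.parent_node is not None:
                parent[i] = idx[id(node.parent_node)]
                if node.edge.length is None:
                    name = node.taxon.label if node.taxon else (node.label or f"node{i}")
                    raise ValueError(f"missing branch length on the edge above {name!r}")
                if node.edge.length < 0:
                    raise ValueError("negative branch length")
                if node.edge.length == 0:
                    logger.info("zero-length branch above node %d", i)
                blen[i] = float(node.edge.length)
            if node.is_leaf():
                if node.taxon is None:
                    raise ValueError("tip without a label")
                lab = node.taxon.label
                if lab in seen_tips:
                    raise ValueError(f"duplicate tip label {lab!r}")
                seen_tips.add(lab)
                labels.append(lab)
                is_tip[i] = True
            else:
                labels.append(node.label or f"node{i}")
        return cls(parent, blen, labels, is_tip, tree)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(tree)

    # -- queries -----------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def internal_labels(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if not self.is_tip[i]]

    @property
    def root_label(self) -> str:
        return self.labels[self.root]

    def total_length(self) -> float:
        return float(self.blen.sum())

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):  # preorder (reverse postorder)
            d[i] = d[self.parent[i]] + self.blen[i]
        return d

    def subtree_nodes(self, node_idx: int) -> list[int]:
        out = [node_idx]
        stack = [node_idx]
        while stack:
            cur = stack.pop()
            for c in self.children[cur]:
                out.append(c)
                stack.append(c)
        return out

    def mrca(self, tip_labels: Iterable[str]) -> int:
        """Index of the most recent common ancestor of the given tips."""
        targets = set(tip_labels)
        missing = targets - set(self.tip_labels)
        if missing:
            raise ValueError(f"unknown tips: {sorted(missing)}")
        # count target tips below each node; MRCA = deepest node covering all
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        for i in self.postorder:
            if self.is_tip[i]:
                counts[i] = 1 if self.labels[i] in targets else 0
            else:
                counts[i] = sum(counts[c] for c in self.children[i])
        k = len(targets)
        for i in self.postorder:
            if counts[i] == k:
                return int(i)
        return self.root

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if self.is_tip[i]:
                body = self.labels[i]
            else:
                body = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if i == self.root:
                return body + ";"
            return f"{body}:{self.blen[i]:.10g}"

        return rec(self.root)


def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    text = Path(path).read_text()
    return Phylogeny.from_newick(text)


# ---------------------------------------------------------------------------
# Regime maps
# ---------------------------------------------------------------------------

@dataclass
class RegimeMap:
    """Assignment of every branch (edge above each non-root node) to a regime."""

    regimes: list[str]
    branch_regime: np.ndarray  # regime index per node (edge above the node)

    @property
    def n_regimes(self) -> int:
        return len(self.regimes)


def single_regime_map(tree: Phylogeny, name: str = "all") -> RegimeMap:
    return RegimeMap([name], np.zeros(tree.n_nodes, dtype=np.int64))


def regime_map_from_clade(
    tree: Phylogeny,
    clade_tips: Iterable[str],
    focal: str = "focal",
    background: str = "background",
) -> RegimeMap:
    """Two-regime map: the focal clade (including its stem branch) vs the rest."""
    mrca = tree.mrca(clade_tips)
    assign = np.zeros(tree.n_nodes, dtype=np.int64)
    for i in tree.subtree_nodes(mrca):
        assign[i] = 1  # includes the stem edge above the MRCA
    return RegimeMap([background, focal], assign)


# ---------------------------------------------------------------------------
# Mk model
# ---------------------------------------------------------------------------

class MkModel(str, enum.Enum):
    ER = "ER"
    ARD = "ARD"


def mk_transition_probs(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form 2-state transition matrix for elapsed time ``t``.

    With s = q01 + q10:  P(0->1) = (q01/s)(1 - e^{-st}), and analogously
    for the other entries; rows sum to 1.
    """
    if q01 <= 0 or q10 <= 0:
        raise ValueError("rates must be positive")
    if t < 0:
        raise ValueError("time must be non-negative")
    s = q01 + q10
    e = math.exp(-s * t)
    pi0, pi1 = q10 / s, q01 / s
    return np.array(
        [
            [pi0 + pi1 * e, pi1 * (1.0 - e)],
            [pi0 * (1.0 - e), pi1 + pi0 * e],
        ]
    )


def _normalize_rates(
    rates: Mapping[str, tuple[float, float]] | tuple[float, float] | Sequence[float],
    regime_map: RegimeMap,
) -> list[tuple[float, float]]:
    if isinstance(rates, Mapping):
        try:
            return [tuple(map(float, rates[r])) for r in regime_map.regimes]
        except KeyError as exc:
            raise ValueError(f"missing rates for regime {exc.args[0]!r}") from exc
    pair = tuple(map(float, rates))
    if len(pair) != 2:
        raise ValueError("rates must be (q01, q10)")
    return [pair] * regime_map.n_regimes


def mk_loglik(
    tree: Phylogeny,
    tip_states: Mapping[str, int],
    rates: Mapping[str, tuple[float, float]] | tuple[float, float],
    regime_map: RegimeMap | None = None,
    root_prior: str = "flat",
) -> float:
    """Felsenstein-pruning log-likelihood of binary tip states.

    ``rates`` is ``(q01, q10)`` for a homogeneous tree or a mapping
    regime -> (q01, q10) matched against ``regime_map``; each branch uses
    its regime's transition matrix.  The root is combined under a flat
    (1/2, 1/2) prior by default, or the stationary distribution of the
    regime of the root's child edges (``root_prior='stationary'``).
    """
    if regime_map is None:
        regime_map = single_regime_map(tree)
    rate_list = _normalize_rates(rates, regime_map)
    missing = [t for t in tree.tip_labels if t not in tip_states]
    if missing:
        raise ValueError(f"missing tip states for {missing}")

    # precompute per (regime, node) transition entries lazily per call
    L0 = np.empty(tree.n_nodes)
    L1 = np.empty(tree.n_nodes)
    logscale = 0.0
    for i in tree.postorder:
        if tree.is_tip[i]:
            s = int(tip_states[tree.labels[i]])
            if s not in (0, 1):
                raise ValueError(f"tip state must be 0/1, got {s}")
            L0[i], L1[i] = (1.0, 0.0) if s == 0 else (0.0, 1.0)
            continue
        l0 = 1.0
        l1 = 1.0
        for c in tree.children[i]:
            q01, q10 = rate_list[regime_map.branch_regime[c]]
            srate = q01 + q10
            e = math.exp(-srate * tree.blen[c])
            pi0, pi1 = q10 / srate, q01 / srate
            c0, c1 = L0[c], L1[c]
            m0 = (pi0 + pi1 * e) * c0 + (pi1 * (1.0 - e)) * c1
            m1 = (pi0 * (1.0 - e)) * c0 + (pi1 + pi0 * e) * c1
            l0 *= m0
            l1 *= m1
        norm = l0 + l1
        if norm <= 0.0:
            return -math.inf
        L0[i] = l0 / norm
        L1[i] = l1 / norm
        logscale += math.log(norm)

    if root_prior == "flat":
        p0 = p1 = 0.5
    elif root_prior == "stationary":
        child = tree.children[tree.root][0]
        q01, q10 = rate_list[regime_map.branch_regime[child]]
        p0, p1 = q10 / (q01 + q10), q01 / (q01 + q10)
    else:
        raise ValueError(f"unknown root prior {root_prior!r}")
    lik = p0 * L0[tree.root] + p1 * L1[tree.root]
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + logscale


@dataclass
class MkModelFit:
    model: MkModel
    regimes: list[str]
    rates: dict[str, tuple[float, float]]
    loglik: float
    converged: bool
    n_params: int
    root_prior: str = "flat"

    def to_dict(self) -> dict:
        return {
            "model": self.model.value,
            "regimes": self.regimes,
            "rates": {r: list(q) for r, q in self.rates.items()},
            "loglik": self.loglik,
            "converged": self.converged,
            "n_params": self.n_params,
            "root_prior": self.root_prior,
        }


#: bounds for log10 rates during optimization
_LOG10_RATE_BOUNDS = (-8.0, 3.0)


def fit_mk(
    tree: Phylogeny,
    tip_states: Mapping[str, int],
    model: MkModel | str = MkModel.ER,
    regime_map: RegimeMap | None = None,
    root_prior: str = "flat",
    n_starts: int = 5,
    seed: int = 0,
    init_rates: Mapping[str, tuple[float, float]] | tuple[float, float] | None = None,
) -> MkModelFit:
    """Maximum-likelihood Mk fit by bounded multi-start optimization.

    Parameters are log10 rates in [1e-8, 1e3]: 1 for single-regime ER, 2
    for single-regime ARD or two-regime ER, and 2 per regime for
    multi-regime ARD.  Starting points are jittered reproducibly from
    ``seed``.  ``init_rates`` adds one deterministic start (e.g. the rates
    of a nested fit, broadcast across regimes), which guarantees a nested
    alternative never scores below its null.  If the optimizer never
    converges, the best values found are returned with ``converged=False``.
    """
    model = MkModel(model)
    if regime_map is None:
        regime_map = single_regime_map(tree)
    states = {int(tip_states[t]) for t in tree.tip_labels if t in tip_states}
    if len(states) < 2:
        logger.warning("degenerate data: all tips share one state; rates will hit bounds")

    k = regime_map.n_regimes
    n_params = k if model is MkModel.ER else 2 * k

    def unpack(x: np.ndarray) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for i, r in enumerate(regime_map.regimes):
            if model is MkModel.ER:
                q = 10.0 ** x[i]
                out[r] = (q, q)
            else:
                out[r] = (10.0 ** x[2 * i], 10.0 ** x[2 * i + 1])
        return out

    def neg_loglik(x: np.ndarray) -> float:
        ll = mk_loglik(tree, tip_states, unpack(x), regime_map, root_prior)
        return -ll if math.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    # centre starts around one expected change across the tree
    base = math.log10(max(1.0 / max(tree.total_length(), 1e-6), 1e-6))
    starts: list[np.ndarray] = []
    if init_rates is not None:
        pairs = _normalize_rates(init_rates, regime_map)
        x0 = []
        for i in range(k):
            if model is MkModel.ER:
                x0.append(math.log10(pairs[i][0]))
            else:
                x0.extend([math.log10(pairs[i][0]), math.log10(pairs[i][1])])
        starts.append(np.clip(np.array(x0), *_LOG10_RATE_BOUNDS))
    for _ in range(max(n_starts, 1)):
        jitter = np.full(n_params, base) + rng.uniform(-1.5, 1.5, size=n_params)
        starts.append(np.clip(jitter, *_LOG10_RATE_BOUNDS))

    best_x: np.ndarray | None = None
    best_val = math.inf
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            neg_loglik,
            x0,
            method="L-BFGS-B",
            bounds=[_LOG10_RATE_BOUNDS] * n_params,
            options={"ftol": 1e-10, "gtol": 1e-8},
        )
        if res.fun < best_val:
            best_val = res.fun
            best_x = res.x
            converged = bool(res.success)
        elif res.success and abs(res.fun - best_val) < 1e-6:
            converged = True
    assert best_x is not None
    return MkModelFit(
        model=model,
        regimes=list(regime_map.regimes),
        rates=unpack(best_x),
        loglik=-best_val,
        converged=converged,
        n_params=n_params,
        root_prior=root_prior,
    )


@dataclass
class LRTResult:
    loglik_null: float
    loglik_alt: float
    df: int
    statistic: float
    p: float


def lrt(fit_null: MkModelFit, fit_alt: MkModelFit, tolerance: float = 1e-4) -> LRTResult:
    """Likelihood-ratio test of nested Mk fits (chi-square reference)."""
    df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("models are not nested (alt must have more parameters)")
    if fit_alt.loglik < fit_null.loglik - tolerance:
        raise ValueError(
            "alternative log-likelihood below null: optimization failure "
            f"({fit_alt.loglik:.6f} < {fit_null.loglik:.6f})"
        )
    statistic = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    p = float(stats.chi2.sf(statistic, df))
    return LRTResult(fit_null.loglik, fit_alt.loglik, df, statistic, p)


# ---------------------------------------------------------------------------
# Brownian-motion ancestral states
# ---------------------------------------------------------------------------

@dataclass
class AncestralStateEstimate:
    """Per-internal-node ML estimates under Brownian motion."""

    nodes: dict[str, tuple[float, float, float, float]]  # estimate, variance, lo, hi
    sigma2: float
    root_label: str

    def estimate(self, label: str) -> float:
        return self.nodes[label][0]

    def ci95(self, label: str) -> tuple[float, float]:
        _, _, lo, hi = self.nodes[label]
        return lo, hi

    @property
    def root_estimate(self) -> float:
        return self.nodes[self.root_label][0]


def bm_ancestral_states(
    tree: Phylogeny,
    tip_values: Mapping[str, float],
) -> AncestralStateEstimate:
    """ML ancestral values of a continuous trait under Brownian motion.

    Internally solves the weighted tree-Laplacian system (edge weights
    1/branch length) with tip values clamped; the solution equals the
    generalized-least-squares reconstruction under the BM tree covariance.
    The BM rate sigma^2 is estimated by ML from the minimized quadratic
    form; per-node variances are sigma^2 times the diagonal of the inverse
    internal Laplacian, and the 95% CI is estimate +/- 1.96*sqrt(variance).
    """
    missing = [t for t in tree.tip_labels if t not in tip_values]
    if missing:
        raise ValueError(f"missing tip values for {missing}")
    if np.any(tree.blen[: tree.root] <= 0):
        raise ValueError("all branch lengths must be > 0 (collapse zero branches first)")

    n = tree.n_nodes
    L = np.zeros((n, n))
    for i in range(n - 1):
        p = tree.parent[i]
        w = 1.0 / tree.blen[i]
        L[i, i] += w
        L[p, p] += w
        L[i, p] -= w
        L[p, i] -= w

    internal = np.array([i for i in range(n) if not tree.is_tip[i]])
    tips = np.array([i for i in range(n) if tree.is_tip[i]])
    x_t = np.array([float(tip_values[tree.labels[i]]) for i in tips])

    L_ii = L[np.ix_(internal, internal)]
    L_it = L[np.ix_(internal, tips)]
    try:
        L_ii_inv = np.linalg.inv(L_ii)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance structure (degenerate tree)") from exc
    a_internal = L_ii_inv @ (-L_it @ x_t)

    values = np.empty(n)
    values[tips] = x_t
    values[internal] = a_internal

    # minimized quadratic form == GLS residual form; ML rate uses n_tips
    q = 0.0
    for i in range(n - 1):
        diff = values[i] - values[tree.parent[i]]
        q += diff * diff / tree.blen[i]
    n_tips = len(tips)
    sigma2 = q / n_tips

    variances = sigma2 * np.diag(L_ii_inv)
    nodes: dict[str, tuple[float, float, float, float]] = {}
    for k, i in enumerate(internal):
        est = float(a_internal[k])
        var = float(max(variances[k], 0.0))
        half = 1.96 * math.sqrt(var)
        nodes[tree.labels[i]] = (est, var, est - half, est + half)
    return AncestralStateEstimate(nodes=nodes, sigma2=float(sigma2), root_label=tree.root_label)


@dataclass
class NodeSetComparison:
    p: float
    median_a: float
    median_b: float
    direction: str  # "a_lower", "a_higher", "ns"
    n_a: int
    n_b: int


def compare_node_sets(
    est: AncestralStateEstimate,
    clade_nodes: Iterable[str],
    other_nodes: Iterable[str],
    alpha: float = 0.05,
) -> NodeSetComparison:
    """Two-sided Mann–Whitney U comparison of node estimates between sets."""
    a_set = set(clade_nodes)
    b_set = set(other_nodes)
    if not a_set or not b_set:
        raise ValueError("both node sets must be nonempty")
    if a_set & b_set:
        raise ValueError(f"node sets overlap: {sorted(a_set & b_set)}")
    a = np.array([est.nodes[k][0] for k in sorted(a_set)])
    b = np.array([est.nodes[k][0] for k in sorted(b_set)])
    pooled = np.concatenate([a, b])
    method = "exact" if len(np.unique(pooled)) == len(pooled) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if res.pvalue < alpha:
        direction = "a_lower" if med_a < med_b else "a_higher"
    else:
        direction = "ns"
    return NodeSetComparison(float(res.pvalue), med_a, med_b, direction, len(a), len(b))
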