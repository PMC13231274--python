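"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: tree
likelihoods by exhaustive enumeration over internal-state assignments,
Fisher p-values by exact rational hypergeometric tail sums, and ancestral
states by explicit covariance-matrix GLS.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from mullerx.phylo import Phylogeny, RegimeMap, mk_transition_probs, single_regime_map


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def random_binary_tree(rng: np.random.Generator, n_tips: int,
                       blen_range=(0.05, 2.0)) -> Phylogeny:
    """Random rooted binary tree: join random fragment pairs with random lengths."""
    frags = [f"t{i}" for i in range(n_tips)]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        la, lb = rng.uniform(*blen_range, size=2)
        frags.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return Phylogeny.from_newick(frags[0] + ";")


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("((a:1,b:1):1,c:2);")


# ---------------------------------------------------------------------------
# Mk brute-force oracle
# ---------------------------------------------------------------------------

def mk_brute_loglik(tree: Phylogeny, tip_states, rates, regime_map: RegimeMap | None = None,
                    root_prior: str = "flat") -> float:
    """Likelihood by summing path probabilities over all internal-state
    assignments (feasible for small trees only)."""
    if regime_map is None:
        regime_map = single_regime_map(tree)
    if isinstance(rates, dict):
        rate_list = [rates[r] for r in regime_map.regimes]
    else:
        rate_list = [tuple(rates)] * regime_map.n_regimes
    internal = [i for i in range(tree.n_nodes) if not tree.is_tip[i]]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        state = {}
        for i, s in zip(internal, assign):
            state[i] = s
        for i in range(tree.n_nodes):
            if tree.is_tip[i]:
                state[i] = int(tip_states[tree.labels[i]])
        if root_prior == "flat":
            p = 0.5
        else:
            q01, q10 = rate_list[regime_map.branch_regime[tree.children[tree.root][0]]]
            p = (q10 if state[tree.root] == 0 else q01) / (q01 + q10)
        for i in range(tree.n_nodes - 1):
            q01, q10 = rate_list[regime_map.branch_regime[i]]
            P = mk_transition_probs(q01, q10, tree.blen[i])
            p *= P[state[tree.parent[i]], state[i]]
        total += p
    return math.log(total)


# ---------------------------------------------------------------------------
# Fisher one-sided oracle
# ---------------------------------------------------------------------------

def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for [[a, b], [c, d]] by exact
    rational hypergeometric tail summation."""
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    total = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        total += (
            Fraction(math.comb(col1, k))
            * Fraction(math.comb(n - col1, row1 - k))
            / Fraction(math.comb(n, row1))
        )
    return float(total)


# ---------------------------------------------------------------------------
# Brownian-motion GLS oracle
# ---------------------------------------------------------------------------

def bm_gls_oracle(tree: Phylogeny, tip_values):
    """Ancestral estimates and variances by explicit covariance construction.

    Builds the BM tip covariance C (shared root-to-MRCA path lengths),
    estimates the root by GLS, and each internal node by the conditional
    normal mean; variances include root-estimate uncertainty.
    """
    depths = tree.depths()
    ancestors: list[list[int]] = []
    for i in range(tree.n_nodes):
        chain = [i]
        while chain[-1] != tree.root:
            chain.append(int(tree.parent[chain[-1]]))
        ancestors.append(chain)

    def shared_depth(i: int, j: int) -> float:
        common = set(ancestors[i]) & set(ancestors[j])
        return max(depths[k] for k in common)

    tips = [i for i in range(tree.n_nodes) if tree.is_tip[i]]
    internal = [i for i in range(tree.n_nodes) if not tree.is_tip[i]]
    x = np.array([float(tip_values[tree.labels[i]]) for i in tips])
    n = len(tips)
    C = np.empty((n, n))
    for ii, i in enumerate(tips):
        for jj, j in enumerate(tips):
            C[ii, jj] = depths[i] if i == j else shared_depth(i, j)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    a0 = float(one @ Cinv @ x) / float(one @ Cinv @ one)
    resid = x - a0
    sigma2 = float(resid @ Cinv @ resid) / n

    out = {}
    for k in internal:
        ck = np.array([shared_depth(k, j) for j in tips])
        est = a0 + float(ck @ Cinv @ resid)
        var = sigma2 * (
            depths[k]
            - float(ck @ Cinv @ ck)
            + (1.0 - float(one @ Cinv @ ck)) ** 2 / float(one @ Cinv @ one)
        )
        out[tree.labels[k]] = (est, var)
    return out, sigma2
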