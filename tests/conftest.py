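"""Shared fixtures and independent brute-force oracles.

The enumeration oracles deliberately avoid the package's pruning code
paths: they sum over all joint internal-state assignments with explicit
products of transition-matrix entries.
"""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from baromega.treekit import parse_newick


# ---------------------------------------------------------------------------
# Brute-force Mk likelihood / marginals (any state count, tiny trees only)


def brute_mk_likelihood(tree, traits, Q, prior):
    """Sum over all internal-node state assignments."""
    n_states = Q.shape[0]
    P = {b.id: expm(Q * b.length) for b in tree.branches()}
    internals = [n for n in tree.nodes if not n.is_leaf]
    prior = np.asarray(prior, dtype=float)
    total = 0.0
    for assign in itertools.product(range(n_states), repeat=len(internals)):
        state = {n.id: s for n, s in zip(internals, assign)}
        for leaf in tree.leaves:
            state[leaf.id] = int(traits[leaf.label])
        term = prior[state[tree.root_id]]
        for b in tree.branches():
            term *= P[b.id][state[b.parent], state[b.id]]
        total += term
    return np.log(total)


def brute_mk_marginals(tree, traits, Q, prior):
    """Exact per-node posterior state probabilities by enumeration."""
    n_states = Q.shape[0]
    P = {b.id: expm(Q * b.length) for b in tree.branches()}
    internals = [n for n in tree.nodes if not n.is_leaf]
    prior = np.asarray(prior, dtype=float)
    post = np.zeros((len(tree.nodes), n_states))
    for assign in itertools.product(range(n_states), repeat=len(internals)):
        state = {n.id: s for n, s in zip(internals, assign)}
        for leaf in tree.leaves:
            state[leaf.id] = int(traits[leaf.label])
        term = prior[state[tree.root_id]]
        for b in tree.branches():
            term *= P[b.id][state[b.parent], state[b.id]]
        for nid, s in state.items():
            post[nid, s] += term
    return post / post.sum(axis=1, keepdims=True)


def brute_codon_likelihood(tree, aln, P, pi):
    """Enumeration oracle for the codon pruning likelihood.

    ``P`` maps branch_id -> 61x61 matrix; gaps (codon index -1) marginalize.
    Feasible only for <= 3 leaves.
    """
    internals = [n for n in tree.nodes if not n.is_leaf]
    n_codons = len(pi)
    seq = {lab: aln.codons[aln.labels.index(lab)] for lab in aln.labels}
    total_ll = 0.0
    for site in range(aln.n_codons):
        total = 0.0
        for assign in itertools.product(range(n_codons), repeat=len(internals)):
            state = {n.id: s for n, s in zip(internals, assign)}
            term_base = pi[state[tree.root_id]]
            leaf_states = {}
            for leaf in tree.leaves:
                leaf_states[leaf.id] = int(seq[leaf.label][site])
            term = term_base
            ok = True
            for b in tree.branches():
                if b.is_leaf:
                    c = leaf_states[b.id]
                    if c < 0:
                        term *= P[b.id][state[b.parent]].sum()
                    else:
                        term *= P[b.id][state[b.parent], c]
                else:
                    term *= P[b.id][state[b.parent], state[b.id]]
            if ok:
                total += term
        total_ll += np.log(total)
    return total_ll


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def cherry():
    return parse_newick("(A:1.0,B:1.0);")


@pytest.fixture
def quartet():
    return parse_newick("((A:0.8,B:1.2):0.5,(C:0.4,D:0.9):0.7);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_tiny_tree(rng, max_leaves=6):
    """Random bifurcating tree with 2..max_leaves leaves and random lengths."""
    n = int(rng.integers(2, max_leaves + 1))
    labels = [f"t{i}" for i in range(n)]
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.05, 2.0, size=2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return parse_newick(nodes[0] + ";"), labels
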