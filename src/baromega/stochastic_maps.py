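"""Stochastic character maps: joint samples of ancestral node states.

Samples are drawn exactly from P(internal states | tip states, Q) by
backward filtering (pruning partials) followed by forward sampling: the
root state from its marginal conditional, then each node top-down from
P(child state | parent state, subtree data).  Each branch in each sample is
classified by comparing child and parent node states — gain if the bar
count increased, loss if it decreased, same otherwise — and per-branch
class proportions over samples form the transition weights used downstream.

Multiple hits within one branch collapse to the net endpoint change by
construction; only node states are sampled, matching how branches are
classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .mk_ancestral import (
    N_STATES,
    _check_traits,
    _downward_partials,
    _root_prior,
    transition_matrices,
)
from .treekit import PhyloTree

GAIN, LOSS, SAME = "gain", "loss", "same"


@dataclass
class StateSamples:
    """Joint node-state samples; ``states[k, v]`` = state of node v in sample k."""

    states: np.ndarray  # (n_samples, n_nodes) int8
    tree: PhyloTree
    seed: int | None

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n_samples, n_nodes = self.states.shape
        return pd.DataFrame(
            {
                "sample_id": np.repeat(np.arange(n_samples), n_nodes),
                "node_id": np.tile(np.arange(n_nodes), n_samples),
                "state": self.states.ravel(),
            }
        )


def sample_node_states(
    tree: PhyloTree,
    traits: Mapping[str, int],
    Q: np.ndarray,
    root_prior="flat",
    n_samples: int = 100,
    seed: int | None = None,
) -> StateSamples:
    """Draw joint ancestral-state samples conditional on the tip data."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    _check_traits(tree, traits)
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (N_STATES, N_STATES) or not np.allclose(Q.sum(axis=1), 0, atol=1e-8):
        raise ValueError("Q must be a 4x4 generator with zero row sums")
    rng = np.random.default_rng(seed)

    D = _downward_partials(tree, traits, Q)
    P = transition_matrices(tree, Q)
    pi = _root_prior(root_prior, D[tree.root_id], Q)

    n_nodes = len(tree.nodes)
    states = np.empty((n_samples, n_nodes), dtype=np.int8)

    def draw(prob: np.ndarray) -> np.ndarray:
        # vectorized categorical draw, one row per sample
        total = prob.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise FloatingPointError("zero-probability state distribution")
        cdf = np.cumsum(prob / total, axis=1)
        u = rng.random((prob.shape[0], 1))
        return (u > cdf).sum(axis=1).astype(np.int8)

    root_prob = np.broadcast_to(pi * D[tree.root_id], (n_samples, N_STATES))
    states[:, tree.root_id] = draw(np.ascontiguousarray(root_prob))
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[:, node.parent]
        prob = P[node.id][parent_states] * D[node.id]
        states[:, node.id] = draw(prob)
    return StateSamples(states=states, tree=tree, seed=seed)


def classify_branch(parent_state: int, child_state: int) -> str:
    """gain if child > parent, loss if child < parent, else same."""
    for s in (parent_state, child_state):
        if not 0 <= int(s) < N_STATES or int(s) != s:
            raise ValueError(f"state out of range: {s}")
    if child_state > parent_state:
        return GAIN
    if child_state < parent_state:
        return LOSS
    return SAME


def compute_branch_weights(samples: StateSamples, tree: PhyloTree) -> pd.DataFrame:
    """Per-branch gain/loss/same proportions over samples.

    ``weight_diff = gain_w - loss_w``; per branch the three weights sum to 1.
    Branches are classified within each sample, then averaged.
    """
    if samples.tree is not tree and samples.states.shape[1] != len(tree.nodes):
        raise ValueError("samples were drawn on a different tree")
    states = samples.states
    rows = []
    for node in tree.branches():
        child = states[:, node.id].astype(int)
        parent = states[:, node.parent].astype(int)
        gain_w = float(np.mean(child > parent))
        loss_w = float(np.mean(child < parent))
        same_w = float(np.mean(child == parent))
        rows.append(
            {
                "branch_id": node.id,
                "child_node": node.id,
                "gain_w": gain_w,
                "loss_w": loss_w,
                "same_w": same_w,
                "weight_diff": gain_w - loss_w,
                "n_samples": samples.n_samples,
            }
        )
    return pd.DataFrame(rows)


def summarize_maps(samples: StateSamples, tree: PhyloTree) -> pd.DataFrame:
    """Per-node state frequencies across samples (rows sum to 1)."""
    states = samples.states
    n_nodes = states.shape[1]
    freq = np.zeros((n_nodes, N_STATES))
    for s in range(N_STATES):
        freq[:, s] = np.mean(states == s, axis=0)
    return pd.DataFrame(
        freq, columns=[f"freq_state{i}" for i in range(N_STATES)]
    ).rename_axis("node_id").reset_index()


def label_branches(weights: pd.DataFrame, cutoff: float = 0.5) -> pd.DataFrame:
    """Discrete G/L/S branch labels: the majority class if its weight exceeds
    ``cutoff``, otherwise 'same'.  The weights themselves remain the primary
    output; this labeling only feeds foreground selection."""
    out = weights.copy()
    cls = np.where(
        (out.gain_w > cutoff) & (out.gain_w >= out.loss_w), GAIN,
        np.where((out.loss_w > cutoff) & (out.loss_w > out.gain_w), LOSS, SAME),
    )
    out["label"] = cls
    return out
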