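"""Mk models for the number of vertical bars (4 ordinal states: 0..3).

Six transition-rate schemes are supported, from the saturated all-rates-
different model down to a single-rate ordinal ("biological") model that only
permits changes between consecutive bar counts:

====  ==========  ====================================================  ===
id    name        constraint                                            k
====  ==========  ====================================================  ===
1     ARD         one free rate per ordered state pair                  12
2     SYM         rate(i->j) = rate(j->i)                               6
3     ER          all transitions share one rate                        1
4     bioARD      only |i-j| = 1 transitions, each direction free       6
5     bioSYM      only |i-j| = 1, symmetric                             3
6     bioER       only |i-j| = 1, single shared rate                    1
====  ==========  ====================================================  ===

Likelihoods use Felsenstein pruning with per-branch transition matrices
``expm(Q t)``; models are compared by AIC = 2k - 2 lnL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .treekit import PhyloTree

N_STATES = 4
MODEL_NAMES = {1: "ARD", 2: "SYM", 3: "ER", 4: "bioARD", 5: "bioSYM", 6: "bioER"}

# For each model: list of parameter groups; each group is the list of (i, j)
# off-diagonal cells sharing one free rate.
_PAIRS_ALL = [(i, j) for i in range(N_STATES) for j in range(N_STATES) if i != j]
_PAIRS_ADJ = [(i, j) for (i, j) in _PAIRS_ALL if abs(i - j) == 1]

MODEL_GROUPS: dict[int, list[list[tuple[int, int]]]] = {
    1: [[p] for p in _PAIRS_ALL],
    2: [[(i, j), (j, i)] for i in range(N_STATES) for j in range(i + 1, N_STATES)],
    3: [list(_PAIRS_ALL)],
    4: [[p] for p in _PAIRS_ADJ],
    5: [[(i, i + 1), (i + 1, i)] for i in range(N_STATES - 1)],
    6: [list(_PAIRS_ADJ)],
}


def n_free_rates(model_id: int) -> int:
    return len(MODEL_GROUPS[model_id])


def build_rate_matrix(model_id: int, theta: Sequence[float]) -> np.ndarray:
    """Assemble the 4x4 generator for one of the six rate schemes.

    ``theta`` holds one positive rate per parameter group (see
    :data:`MODEL_GROUPS`); rows of the result sum to zero.
    """
    if model_id not in MODEL_GROUPS:
        raise ValueError(f"unknown model id {model_id}")
    groups = MODEL_GROUPS[model_id]
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(groups),):
        raise ValueError(
            f"model {model_id} needs {len(groups)} rates, got {theta.shape}"
        )
    if np.any(theta <= 0):
        raise ValueError("rates must be positive")
    Q = np.zeros((N_STATES, N_STATES))
    for rate, cells in zip(theta, groups):
        for i, j in cells:
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# Likelihood


def _check_traits(tree: PhyloTree, traits: Mapping[str, int]) -> None:
    for leaf in tree.leaves:
        if leaf.label not in traits:
            raise ValueError(f"no trait state for leaf '{leaf.label}'")
        s = traits[leaf.label]
        if int(s) != s or not 0 <= int(s) < N_STATES:
            raise ValueError(f"state for '{leaf.label}' must be an integer 0..3")


def _root_prior(policy, partial_root: np.ndarray, Q: np.ndarray) -> np.ndarray:
    if isinstance(policy, (list, tuple, np.ndarray)):
        pi = np.asarray(policy, dtype=float)
        return pi / pi.sum()
    if policy == "flat":
        return np.full(N_STATES, 1.0 / N_STATES)
    if policy == "stationary":
        return stationary_distribution(Q)
    if policy == "fitzjohn":
        w = partial_root / partial_root.sum()
        return w
    raise ValueError(f"unknown root prior policy {policy!r}")


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of Q, normalized to a probability vector."""
    A = np.vstack([Q.T, np.ones(Q.shape[0])])
    b = np.zeros(Q.shape[0] + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _downward_partials(tree: PhyloTree, traits: Mapping[str, int], Q: np.ndarray) -> np.ndarray:
    """Post-order conditional likelihoods, one row per node (no scaling:
    4 states on trees this small stay comfortably inside double range)."""
    n_nodes = len(tree.nodes)
    partials = np.empty((n_nodes, N_STATES))
    P = transition_matrices(tree, Q)
    for node in tree.postorder():
        if node.is_leaf:
            v = np.zeros(N_STATES)
            v[int(traits[node.label])] = 1.0
            partials[node.id] = v
        else:
            v = np.ones(N_STATES)
            for cid in node.children:
                v = v * (P[cid] @ partials[cid])
            partials[node.id] = v
    return partials


def transition_matrices(tree: PhyloTree, Q: np.ndarray) -> dict[int, np.ndarray]:
    """expm(Q t) for every branch, keyed by child node id."""
    out = {}
    for node in tree.branches():
        P = expm(Q * node.length)
        if not np.all(np.isfinite(P)):
            raise FloatingPointError("non-finite transition matrix")
        out[node.id] = np.clip(P, 0.0, None)
    return out


def mk_log_likelihood(
    tree: PhyloTree,
    traits: Mapping[str, int],
    Q: np.ndarray,
    root_prior="flat",
) -> float:
    """Log-probability of the tip states under the Mk process."""
    _check_traits(tree, traits)
    partials = _downward_partials(tree, traits, Q)
    root = partials[tree.root_id]
    pi = _root_prior(root_prior, root, Q)
    lik = float(pi @ root)
    if lik <= 0:
        return -np.inf
    return float(np.log(lik))


# ---------------------------------------------------------------------------
# Fitting and model selection


@dataclass
class MkFit:
    model_id: int
    theta: np.ndarray
    Q: np.ndarray
    lnL: float
    k: int
    aic: float
    converged: bool
    n_restarts: int
    root_prior: object = "flat"

    @property
    def model_name(self) -> str:
        return MODEL_NAMES[self.model_id]


_LOG_BOUNDS = (np.log(1e-8), np.log(1e3))


def fit_mk(
    tree: PhyloTree,
    traits: Mapping[str, int],
    model_id: int,
    n_restarts: int = 5,
    seed: int | None = None,
    root_prior="flat",
) -> MkFit:
    """Maximize the Mk likelihood over the model's free rates.

    Optimization runs on log-rates (bounds [1e-8, 1e3]) with L-BFGS-B from
    ``n_restarts`` random initial points; the best restart is kept.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    _check_traits(tree, traits)
    k = n_free_rates(model_id)
    rng = np.random.default_rng(seed)

    def nll(log_theta: np.ndarray) -> float:
        Q = build_rate_matrix(model_id, np.exp(log_theta))
        ll = mk_log_likelihood(tree, traits, Q, root_prior)
        return -ll if np.isfinite(ll) else 1e10

    # crude scale: one expected change per tree depth
    depth = _tree_depth(tree)
    base = np.log(max(1.0 / max(depth, 1e-6), 1e-6))
    best = None
    any_ok = False
    for r in range(n_restarts):
        x0 = np.full(k, base) + (rng.uniform(-2.0, 2.0, size=k) if r else 0.0)
        x0 = np.clip(x0, *_LOG_BOUNDS)
        res = minimize(nll, x0, method="L-BFGS-B", bounds=[_LOG_BOUNDS] * k)
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    theta = np.exp(best.x)
    Q = build_rate_matrix(model_id, theta)
    lnL = -float(best.fun)
    return MkFit(
        model_id=model_id,
        theta=theta,
        Q=Q,
        lnL=lnL,
        k=k,
        aic=2 * k - 2 * lnL,
        converged=any_ok,
        n_restarts=n_restarts,
        root_prior=root_prior,
    )


def _tree_depth(tree: PhyloTree) -> float:
    depth = {tree.root_id: 0.0}
    best = 0.0
    for node in tree.preorder():
        if node.parent is not None:
            depth[node.id] = depth[node.parent] + node.length
            best = max(best, depth[node.id])
    return best


def select_model(fits: Sequence[MkFit]) -> MkFit:
    """Lowest AIC wins; ties broken by fewer parameters, then lower model id."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.k, f.model_id))


def fit_all_models(
    tree: PhyloTree,
    traits: Mapping[str, int],
    model_ids: Sequence[int] = (1, 2, 3, 4, 5, 6),
    n_restarts: int = 5,
    seed: int | None = None,
    root_prior="flat",
) -> list[MkFit]:
    return [
        fit_mk(tree, traits, m, n_restarts=n_restarts, seed=None if seed is None else seed + m,
               root_prior=root_prior)
        for m in model_ids
    ]


def fit_report(fits: Sequence[MkFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "model_id": f.model_id,
                "model": f.model_name,
                "k": f.k,
                "lnL": f.lnL,
                "AIC": f.aic,
                "rates": ",".join(format(t, ".6g") for t in f.theta),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Marginal ancestral states


def marginal_ancestral(
    tree: PhyloTree,
    traits: Mapping[str, int],
    Q: np.ndarray,
    root_prior="flat",
) -> pd.DataFrame:
    """Marginal posterior state probabilities for every node.

    Combines the downward (pruning) partials with upward/outside partials;
    each row of the returned table sums to one.
    """
    _check_traits(tree, traits)
    D = _downward_partials(tree, traits, Q)
    P = transition_matrices(tree, Q)
    pi = _root_prior(root_prior, D[tree.root_id], Q)

    # outside[v][i]: likelihood of all data outside subtree(v), given state i at v
    outside = np.empty_like(D)
    outside[tree.root_id] = pi
    for node in tree.preorder():
        if node.is_leaf:
            continue
        for cid in node.children:
            sib = [c for c in node.children if c != cid]
            f = outside[node.id].copy()
            for s in sib:
                f = f * (P[s] @ D[s])
            outside[cid] = f @ P[cid]

    post = D * outside
    norm = post.sum(axis=1, keepdims=True)
    if np.any(norm <= 0):
        raise FloatingPointError("zero total likelihood at a node")
    post = post / norm
    return pd.DataFrame(
        post,
        columns=[f"p_state{i}" for i in range(N_STATES)],
    ).rename_axis("node_id").reset_index()


# ---------------------------------------------------------------------------
# I/O


def read_traits_csv(path) -> dict[str, int]:
    """Read a species,bars CSV (header required) into a trait mapping."""
    df = pd.read_csv(path)
    if not {"species", "bars"} <= set(df.columns):
        raise ValueError("trait CSV must have columns: species, bars")
    return {str(r.species): int(r.bars) for r in df.itertuples()}


def write_traits_csv(traits: Mapping[str, int], path) -> None:
    pd.DataFrame(
        {"species": list(traits.keys()), "bars": list(traits.values())}
    ).to_csv(path, index=False)
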