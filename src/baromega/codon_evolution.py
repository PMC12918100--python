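"""Codon substitution models: per-branch omega (dN/dS), Delta-omega, and the
branch-site positive-selection test.

The substitution process is MG94xHKY: codons evolve by single-nucleotide
steps, each step's rate carrying the target-nucleotide frequency at the
changed position, a transition/transversion factor kappa, and omega when the
change is nonsynonymous.  omega < 1 indicates purifying selection, omega = 1
neutrality, omega > 1 positive selection.

Two inference layers sit on top of the pruning likelihood:

* :func:`fit_branch_omegas` — penalized ML with one free omega per branch
  and a quadratic parent-child penalty on log omega.  The penalty is the MAP
  analogue of a Brownian prior on log omega along the tree; its strength
  ``lam`` interpolates between fully independent branch omegas (lam = 0) and
  a single global omega (lam -> inf).  Delta-omega of a branch is its omega
  minus its parent branch's omega.

* :func:`fit_branch_site` — model A: site classes 0 (0 < omega0 < 1
  everywhere), 1 (neutral everywhere), 2a/2b (omega2 >= 1 on designated
  foreground branches, background as class 0/1).  The null fixes
  omega2 = 1; 2*(lnL1 - lnL0) is referred to chi-square with df = 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Data import CodonTable
from scipy.optimize import minimize
from scipy.stats import chi2

from .treekit import PhyloTree

# ---------------------------------------------------------------------------
# Genetic code (standard table) and single-step structure

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
NUCS = "ACGT"
_NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

CODONS: list[str] = sorted(
    "".join(c) for c in itertools.product(NUCS, repeat=3)
    if "".join(c) not in _STANDARD.stop_codons
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS = [_STANDARD.forward_table[c] for c in CODONS]
STOP_CODONS = set(_STANDARD.stop_codons)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _single_steps():
    """All ordered sense-codon pairs differing at exactly one position."""
    steps = []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            is_ts = frozenset((ci[p], cj[p])) in _TRANSITIONS
            is_syn = AMINO_ACIDS[i] == AMINO_ACIDS[j]
            steps.append((i, j, p, _NUC_INDEX[cj[p]], is_ts, is_syn))
    return steps

_STEPS = _single_steps()
_STEP_I = np.array([s[0] for s in _STEPS])
_STEP_J = np.array([s[1] for s in _STEPS])
_STEP_POS = np.array([s[2] for s in _STEPS])
_STEP_TGT = np.array([s[3] for s in _STEPS])
_STEP_TS = np.array([s[4] for s in _STEPS])
_STEP_SYN = np.array([s[5] for s in _STEPS])


# ---------------------------------------------------------------------------
# Alignments


class AlignmentError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """Codon-indexed alignment; ``codons[k, s]`` is the codon index of
    sequence k at site s, or -1 for a gap/ambiguous codon."""

    labels: list[str]
    codons: np.ndarray  # (n_seq, L) int16

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    @property
    def n_sequences(self) -> int:
        return self.codons.shape[0]

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "CodonAlignment":
        labels = list(seqs.keys())
        lengths = {len(str(s)) for s in seqs.values()}
        if len(lengths) != 1:
            raise AlignmentError("sequences have unequal lengths")
        (L,) = lengths
        if L % 3 != 0:
            raise AlignmentError(f"alignment length {L} not divisible by 3")
        mat = np.empty((len(labels), L // 3), dtype=np.int16)
        for k, lab in enumerate(labels):
            s = str(seqs[lab]).upper().replace("U", "T")
            for site in range(L // 3):
                cod = s[3 * site : 3 * site + 3]
                if cod in CODON_INDEX:
                    mat[k, site] = CODON_INDEX[cod]
                elif cod in STOP_CODONS:
                    raise AlignmentError(
                        f"in-frame stop codon {cod} in '{lab}' at codon {site}"
                    )
                else:
                    mat[k, site] = -1  # gap / ambiguity -> missing
        aln = cls(labels=labels, codons=mat)
        for k, lab in enumerate(labels):
            if np.all(mat[k] == -1):
                raise AlignmentError(f"sequence '{lab}' is entirely missing")
        return aln

    def sequence(self, label: str) -> str:
        k = self.labels.index(label)
        return "".join(
            CODONS[c] if c >= 0 else "---" for c in self.codons[k]
        )


def read_codon_fasta(path) -> CodonAlignment:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise AlignmentError(f"no sequences in {path}")
    return CodonAlignment.from_sequences(seqs)


def read_codon_phylip(path) -> CodonAlignment:
    aln = AlignIO.read(str(path), "phylip-sequential")
    return CodonAlignment.from_sequences({rec.id: str(rec.seq) for rec in aln})


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for lab in aln.labels:
            fh.write(f">{lab}\n{aln.sequence(lab)}\n")


# ---------------------------------------------------------------------------
# Codon frequencies


@dataclass
class CodonFrequencies:
    """Position-specific nucleotide frequencies and the implied codon
    stationary distribution (restricted to sense codons)."""

    pos_freqs: np.ndarray  # (3, 4)

    def __post_init__(self):
        pf = np.asarray(self.pos_freqs, dtype=float)
        if pf.shape != (3, 4) or np.any(pf < 0):
            raise ValueError("pos_freqs must be a nonnegative (3, 4) array")
        self.pos_freqs = pf / pf.sum(axis=1, keepdims=True)

    @property
    def codon_pi(self) -> np.ndarray:
        pi = np.ones(N_CODONS)
        for i, cod in enumerate(CODONS):
            for p in range(3):
                pi[i] *= self.pos_freqs[p, _NUC_INDEX[cod[p]]]
        return pi / pi.sum()

    @classmethod
    def equal(cls) -> "CodonFrequencies":
        return cls(np.full((3, 4), 0.25))

    @classmethod
    def from_alignment(cls, aln: CodonAlignment, kind: str = "F3x4") -> "CodonFrequencies":
        counts = np.ones((3, 4))  # +1 pseudocount avoids zero frequencies
        for k in range(aln.n_sequences):
            for c in aln.codons[k]:
                if c < 0:
                    continue
                for p in range(3):
                    counts[p, _NUC_INDEX[CODONS[c][p]]] += 1
        if kind == "F3x4":
            return cls(counts)
        if kind == "F1x4":
            tot = counts.sum(axis=0)
            return cls(np.tile(tot / tot.sum(), (3, 1)))
        if kind == "equal":
            return cls.equal()
        raise ValueError(f"unknown frequency policy {kind!r}")


def resolve_frequencies(freqs, aln: Optional[CodonAlignment]) -> CodonFrequencies:
    if isinstance(freqs, CodonFrequencies):
        return freqs
    if isinstance(freqs, str):
        if freqs == "equal" or aln is None:
            return CodonFrequencies.equal()
        return CodonFrequencies.from_alignment(aln, freqs)
    raise ValueError("freqs must be a CodonFrequencies or a policy name")


# ---------------------------------------------------------------------------
# Generator


def rate_parts(kappa: float, freqs: CodonFrequencies) -> tuple[np.ndarray, np.ndarray]:
    """Synonymous (A) and nonsynonymous (B) off-diagonal rate parts so that
    the unnormalized generator is A + omega * B (diagonals excluded)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    factor = freqs.pos_freqs[_STEP_POS, _STEP_TGT] * np.where(_STEP_TS, kappa, 1.0)
    A = np.zeros((N_CODONS, N_CODONS))
    B = np.zeros((N_CODONS, N_CODONS))
    A[_STEP_I[_STEP_SYN], _STEP_J[_STEP_SYN]] = factor[_STEP_SYN]
    B[_STEP_I[~_STEP_SYN], _STEP_J[~_STEP_SYN]] = factor[~_STEP_SYN]
    return A, B


def build_codon_generator(
    kappa: float,
    omega: float,
    freqs: CodonFrequencies | np.ndarray | None = None,
    normalize: bool = True,
    reference_omega: float | None = None,
) -> np.ndarray:
    """61x61 MG94xHKY generator; rows sum to zero.

    When ``normalize`` the generator is scaled so the expected substitution
    rate at stationarity is one (branch lengths then read as expected
    substitutions per codon site).  With ``reference_omega`` the scaling
    constant is instead the stationary rate *at that omega*: generators for
    several omega values then share one time scale, so sites or branches
    with elevated omega genuinely accumulate more (nonsynonymous)
    substitutions rather than just a different composition.
    """
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    if freqs is None:
        freqs = CodonFrequencies.equal()
    if isinstance(freqs, np.ndarray):
        # plain 61-vector: GY-style target-codon frequency factor
        pi = np.asarray(freqs, dtype=float)
        if pi.shape != (N_CODONS,) or np.any(pi < 0):
            raise ValueError("pi must be a nonnegative 61-vector")
        pi = pi / pi.sum()
        factor = pi[_STEP_J] * np.where(_STEP_TS, kappa, 1.0)
        Q = np.zeros((N_CODONS, N_CODONS))
        Q[_STEP_I, _STEP_J] = factor * np.where(_STEP_SYN, 1.0, omega)
        if kappa <= 0:
            raise ValueError("kappa must be positive")
    else:
        A, B = rate_parts(kappa, freqs)
        pi = freqs.codon_pi
        Q = A + omega * B
    np.fill_diagonal(Q, 0.0)
    if reference_omega is not None and not isinstance(freqs, np.ndarray):
        Qref = A + reference_omega * B
        mu = float(pi @ Qref.sum(axis=1))
    else:
        mu = float(pi @ Q.sum(axis=1))
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        if mu <= 0:
            raise ValueError("degenerate generator (zero total rate)")
        Q = Q / mu
    return Q


def stationary_rate(kappa: float, omega: float, freqs: CodonFrequencies) -> float:
    """Expected substitutions per codon site per unit time for the
    *unnormalized* generator (the normalization constant mu)."""
    A, B = rate_parts(kappa, freqs)
    pi = freqs.codon_pi
    return float(pi @ (A + omega * B).sum(axis=1))


def _reference_Q_and_domega(kappa, omega, freqs: CodonFrequencies,
                            reference_omega: float):
    """Generator Q(omega) scaled by the stationary rate at the reference
    omega, and dQ/domega under that fixed scaling (both with diagonals)."""
    A, B = rate_parts(kappa, freqs)
    pi = freqs.codon_pi
    mu = float(pi @ (A + reference_omega * B).sum(axis=1))
    Q = (A + omega * B) / mu
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    dQ = B / mu
    np.fill_diagonal(dQ, dQ.diagonal() - dQ.sum(axis=1))
    return Q, dQ, pi


# ---------------------------------------------------------------------------
# Eigendecomposition-based transition matrices (Q reversible w.r.t. pi)


class _EigenQ:
    """Spectral form of a reversible generator: P(t) and dP(t) cheaply for
    many branch lengths."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.pi = pi
        d = np.sqrt(pi)
        self._d = d
        S = (Q * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)
        lam, U = np.linalg.eigh(S)
        self.lam = lam
        self.U = U
        self._left = U.T * d[None, :]      # U' D^{1/2}
        self._right = (U / d[:, None])     # D^{-1/2} U

    def P(self, t: float) -> np.ndarray:
        M = (self._right * np.exp(self.lam * t)) @ self._left
        return np.clip(M, 0.0, None)

    def dP_dir(self, t: float, dQ: np.ndarray) -> np.ndarray:
        """Directional derivative of expm(Q t) for a generator perturbation
        dQ (Daleckii-Krein divided-difference formula in the eigenbasis)."""
        dS = (dQ * self._d[:, None]) / self._d[None, :]
        G = self.U.T @ dS @ self.U
        e = np.exp(self.lam * t)
        den = self.lam[:, None] - self.lam[None, :]
        num = e[:, None] - e[None, :]
        close = np.abs(den) < 1e-10
        Phi = np.where(close, t * 0.5 * (e[:, None] + e[None, :]),
                       num / np.where(close, 1.0, den))
        dM = self.U @ (G * Phi) @ self.U.T
        return (dM / self._d[:, None]) * self._d[None, :]


# ---------------------------------------------------------------------------
# Pruning likelihood with pattern compression


def compress_patterns(aln: CodonAlignment, leaf_order: Sequence[str]):
    rows = []
    for lab in leaf_order:
        if lab not in aln.labels:
            raise AlignmentError(f"tree leaf '{lab}' missing from alignment")
        rows.append(aln.codons[aln.labels.index(lab)])
    mat = np.vstack(rows)  # (n_leaves, L)
    patterns, inverse, counts = np.unique(
        mat, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse


def _tip_partials(patterns: np.ndarray) -> np.ndarray:
    """(n_leaves, n_pat, 61) one-hot partials; missing codons -> all ones."""
    n_leaves, n_pat = patterns.shape
    out = np.zeros((n_leaves, n_pat, N_CODONS))
    for k in range(n_leaves):
        miss = patterns[k] < 0
        out[k, miss, :] = 1.0
        obs = ~miss
        out[k, obs, patterns[k, obs]] = 1.0
    return out


def _prune_inside(tree: PhyloTree, tips: np.ndarray, leaf_row: dict[int, int],
                  P: dict[int, np.ndarray]):
    """Scaled post-order partials.

    Returns (inside, logscale): ``inside[v]`` is (n_pat, 61) with per-pattern
    max one; true partial = inside * exp(logscale[v])."""
    n_nodes = len(tree.nodes)
    n_pat = tips.shape[1]
    inside = [None] * n_nodes
    logscale = np.zeros((n_nodes, n_pat))
    for node in tree.postorder():
        if node.is_leaf:
            inside[node.id] = tips[leaf_row[node.id]]
        else:
            val = np.ones((n_pat, N_CODONS))
            sc = np.zeros(n_pat)
            for cid in node.children:
                val = val * (inside[cid] @ P[cid].T)
                sc = sc + logscale[cid]
            m = val.max(axis=1)
            bad = m <= 0
            if np.any(bad):
                m = np.where(bad, 1.0, m)
            val = val / m[:, None]
            logscale[node.id] = sc + np.log(np.where(m > 0, m, 1.0))
            inside[node.id] = val
    return inside, logscale


def _pattern_logliks(tree, inside, logscale, pi) -> np.ndarray:
    root = tree.root_id
    lik = inside[root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale[root]


def _prune_loglik_multi(tree: PhyloTree, tips: np.ndarray,
                        leaf_row: dict[int, int],
                        P_multi: dict[int, np.ndarray],
                        pi: np.ndarray) -> np.ndarray:
    """Pruning log-likelihoods for K models at once (shared tips).

    ``P_multi[child]`` is (K, 61, 61); returns (K, n_pat).
    """
    K = next(iter(P_multi.values())).shape[0]
    n_pat = tips.shape[1]
    n_nodes = len(tree.nodes)
    inside = [None] * n_nodes
    logscale = np.zeros((n_nodes, K, n_pat))
    for node in tree.postorder():
        if node.is_leaf:
            inside[node.id] = np.broadcast_to(
                tips[leaf_row[node.id]], (K, n_pat, N_CODONS))
        else:
            val = np.ones((K, n_pat, N_CODONS))
            sc = np.zeros((K, n_pat))
            for cid in node.children:
                val = val * np.matmul(inside[cid],
                                      np.transpose(P_multi[cid], (0, 2, 1)))
                sc = sc + logscale[cid]
            m = val.max(axis=2)
            m = np.where(m > 0, m, 1.0)
            val = val / m[:, :, None]
            logscale[node.id] = sc + np.log(m)
            inside[node.id] = val
    root = tree.root_id
    lik = inside[root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale[root]


@dataclass
class CodonModelParams:
    """Parameters of the codon substitution process.

    ``omega`` may be a scalar (global) or a mapping branch_id -> omega.
    ``scale`` multiplies all branch lengths.
    """

    kappa: float = 2.0
    omega: float | Mapping[int, float] = 0.2
    freqs: object = "F3x4"
    scale: float = 1.0


def _branch_P(tree, params: CodonModelParams, freqs: CodonFrequencies):
    omegas = params.omega
    if np.isscalar(omegas):
        omegas = {b.id: float(omegas) for b in tree.branches()}
    eigs: dict[float, _EigenQ] = {}
    P = {}
    for node in tree.branches():
        w = float(omegas[node.id])
        if w not in eigs:
            Q = build_codon_generator(params.kappa, w, freqs)
            eigs[w] = _EigenQ(Q, freqs.codon_pi)
        P[node.id] = eigs[w].P(node.length * params.scale)
    return P


def codon_log_likelihood(tree: PhyloTree, aln: CodonAlignment,
                         params: CodonModelParams) -> float:
    """Site-independent pruning log-likelihood; gaps are missing data."""
    freqs = resolve_frequencies(params.freqs, aln)
    leaf_order = [n.label for n in tree.leaves]
    patterns, counts, _ = compress_patterns(aln, leaf_order)
    tips = _tip_partials(patterns)
    leaf_row = {n.id: i for i, n in enumerate(tree.leaves)}
    P = _branch_P(tree, params, freqs)
    inside, logscale = _prune_inside(tree, tips, leaf_row, P)
    site_ll = _pattern_logliks(tree, inside, logscale, freqs.codon_pi)
    return float(counts @ site_ll)


# ---------------------------------------------------------------------------
# Global (M0-style) fit: kappa, omega, tree scale


def fit_global_omega(tree: PhyloTree, aln: CodonAlignment, freqs="F3x4",
                     x0=(2.0, 0.3, 1.0)) -> dict:
    """Profile fit of a single omega, kappa and a global tree-scale."""
    cf = resolve_frequencies(freqs, aln)
    leaf_order = [n.label for n in tree.leaves]
    patterns, counts, _ = compress_patterns(aln, leaf_order)
    tips = _tip_partials(patterns)
    leaf_row = {n.id: i for i, n in enumerate(tree.leaves)}
    lens = np.array([b.length for b in tree.branches()])
    ids = [b.id for b in tree.branches()]

    def nll(x):
        kappa, omega, scale = np.exp(x)
        Q = build_codon_generator(kappa, omega, cf)
        eig = _EigenQ(Q, cf.codon_pi)
        P = {bid: eig.P(t * scale) for bid, t in zip(ids, lens)}
        inside, logscale = _prune_inside(tree, tips, leaf_row, P)
        ll = counts @ _pattern_logliks(tree, inside, logscale, cf.codon_pi)
        return -ll if np.isfinite(ll) else 1e12

    # branch lengths may be in time units far from substitution scale;
    # seed the tree-scale from a coarse grid before the quasi-Newton polish
    kappa0, omega0, _ = x0
    grid = [1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0]
    scale0 = min(grid, key=lambda s: nll(np.log([kappa0, omega0, s])))
    res = minimize(
        nll, np.log(np.asarray([kappa0, omega0, scale0])), method="L-BFGS-B",
        bounds=[(np.log(0.05), np.log(50)), (np.log(1e-4), np.log(20)),
                (np.log(1e-3), np.log(1e3))],
    )
    kappa, omega, scale = np.exp(res.x)
    return {"kappa": kappa, "omega": omega, "scale": scale,
            "lnL": -float(res.fun), "converged": bool(res.success)}


# ---------------------------------------------------------------------------
# Per-branch omega with Brownian-style smoothing penalty


def _penalty_pairs(tree: PhyloTree):
    """(child_branch, parent_branch) index pairs for the log-omega penalty;
    the two root-child branches are tied to their geometric mean."""
    ids = [b.id for b in tree.branches()]
    pos = {bid: k for k, bid in enumerate(ids)}
    pairs = []
    root_children = tree.root.children
    for b in tree.branches():
        if b.parent == tree.root_id:
            continue
        pairs.append((pos[b.id], pos[b.parent]))
    return ids, pos, pairs, [pos[c] for c in root_children]


def fit_branch_omegas(
    tree: PhyloTree,
    aln: CodonAlignment,
    lam: float = 1.0,
    freqs="F3x4",
    kappa: Optional[float] = None,
    max_iter: int = 300,
    warn_below: int = 100,
) -> pd.DataFrame:
    """Penalized-ML per-branch omega and Delta-omega for one gene.

    Objective: -lnL + lam * sum_branches (log w_b - log w_parent)^2, with
    kappa profiled from a global fit and a free overall tree-scale.  Returns
    a table with columns branch_id, omega, delta_omega and metadata in
    ``DataFrame.attrs``.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if aln.n_codons < warn_below:
        import warnings
        warnings.warn(f"alignment has only {aln.n_codons} codons; "
                      "per-branch omega will be noisy")
    cf = resolve_frequencies(freqs, aln)
    pi = cf.codon_pi
    g0 = fit_global_omega(tree, aln, cf)
    if kappa is None:
        kappa = g0["kappa"]
    # all branch generators share the time scale of the globally fitted
    # omega: branches with higher omega then evolve genuinely faster
    omega_ref = float(g0["omega"])

    leaf_order = [n.label for n in tree.leaves]
    patterns, counts, _ = compress_patterns(aln, leaf_order)
    tips = _tip_partials(patterns)
    leaf_row = {n.id: i for i, n in enumerate(tree.leaves)}
    branches = tree.branches()
    ids, pos, pairs, root_kids = _penalty_pairs(tree)
    nb = len(branches)
    lens = np.array([b.length for b in branches])

    def unpack(x):
        return x[:nb], x[nb]  # log-omegas, log-scale

    def value_and_grad(x):
        logw, logs = unpack(x)
        w = np.exp(logw)
        s = np.exp(logs)
        eigs, dQs = {}, {}
        P, Qfull = {}, {}
        for k, b in enumerate(branches):
            wk = w[k]
            if wk not in eigs:
                Qn, dQn, _ = _reference_Q_and_domega(kappa, wk, cf, omega_ref)
                eigs[wk] = _EigenQ(Qn * s, pi)
                dQs[wk] = (Qn * s, dQn * s)
            P[b.id] = eigs[wk].P(lens[k])
        inside, logscale = _prune_inside(tree, tips, leaf_row, P)
        site_ll = _pattern_logliks(tree, inside, logscale, pi)
        if not np.all(np.isfinite(site_ll)):
            return 1e12, np.zeros_like(x)
        lnL = float(counts @ site_ll)

        # outside pass (scaled; common scale factors cancel in the gradient
        # ratios below).  Fctx[c] is the likelihood of all data outside
        # subtree(c), as a function of the state at c's *parent*; Out[c] is
        # the same propagated across c's branch.
        n_nodes = len(tree.nodes)
        grad = np.zeros_like(x)
        Fctx = [None] * n_nodes
        Fctx[tree.root_id] = np.broadcast_to(pi, inside[tree.root_id].shape)
        order = [n for n in tree.preorder() if not n.is_leaf]
        Out = [None] * n_nodes
        Out[tree.root_id] = Fctx[tree.root_id]
        for node in order:
            for cid in node.children:
                f = np.asarray(Out[node.id]).copy()
                for sid in node.children:
                    if sid != cid:
                        f = f * (inside[sid] @ P[sid].T)
                m = f.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                f = f / m[:, None]
                Fctx[cid] = f
                Out[cid] = f @ P[cid]
        for k, b in enumerate(branches):
            wk = w[k]
            F = Fctx[b.id]
            In = inside[b.id]
            denom = ((F @ P[b.id]) * In).sum(axis=1)
            denom = np.where(denom > 0, denom, np.inf)
            Qf, dQn = dQs[wk]
            # d/d log w_b
            dP_w = eigs[wk].dP_dir(lens[k], dQn * wk)
            num_w = ((F @ dP_w) * In).sum(axis=1)
            grad[k] -= float(counts @ (num_w / denom))
            # d/d log s: dP = (Qfull * t) P
            dP_s = (Qf * lens[k]) @ P[b.id]
            num_s = ((F @ dP_s) * In).sum(axis=1)
            grad[nb] -= float(counts @ (num_s / denom))

        # penalty
        pen = 0.0
        for ci, pi_ in pairs:
            d = logw[ci] - logw[pi_]
            pen += d * d
            grad[ci] += 2 * lam * d
            grad[pi_] -= 2 * lam * d
        if len(root_kids) == 2:
            # tying the two root-child branches to their midpoint gives
            # pen = d^2 / 2 with d = logw_a - logw_b
            a, bb = root_kids
            d = logw[a] - logw[bb]
            pen += 0.5 * d * d
            grad[a] += lam * d
            grad[bb] -= lam * d
        return -lnL + lam * pen, grad

    x0 = np.concatenate([np.full(nb, np.log(max(g0["omega"], 1e-3))),
                         [np.log(g0["scale"])]])
    bounds = [(np.log(1e-4), np.log(50))] * nb + [(np.log(1e-3), np.log(1e3))]
    res = minimize(value_and_grad, x0, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": max_iter})
    logw, logs = unpack(res.x)
    w = np.exp(logw)
    omega_by_id = {bid: w[pos[bid]] for bid in ids}
    rows = []
    for b in branches:
        if b.parent == tree.root_id:
            parent_w = float(np.exp(np.mean([logw[k] for k in root_kids])))
        else:
            parent_w = omega_by_id[b.parent]
        rows.append({"branch_id": b.id, "omega": omega_by_id[b.id],
                     "delta_omega": omega_by_id[b.id] - parent_w})
    out = pd.DataFrame(rows)
    out.attrs.update(
        kappa=float(kappa), scale=float(np.exp(logs)), lam=float(lam),
        lnL=-float(res.fun) if np.isfinite(res.fun) else np.nan,
        penalized_objective=float(res.fun), converged=bool(res.success),
        global_fit=g0,
    )
    return out


# ---------------------------------------------------------------------------
# Branch-site model A


@dataclass
class BranchSiteFit:
    foreground: tuple[int, ...]
    kappa: float
    scale: float
    lnL0: float
    lnL1: float
    p0: float
    p1: float
    p2a: float
    p2b: float
    omega0: float
    omega2: float
    null_p0: float = np.nan
    null_p1: float = np.nan
    null_omega0: float = np.nan
    converged: bool = True
    n_restarts: int = 3

    @property
    def lrt(self) -> float:
        return max(0.0, 2.0 * (self.lnL1 - self.lnL0))

    @property
    def pvalue(self) -> float:
        return float(chi2.sf(self.lrt, df=1))


def _class_weights(s: float, q: float) -> np.ndarray:
    """Model-A class proportions (0, 1, 2a, 2b) from the background
    proportion s = p0 + p1 and the conserved fraction q = p0/(p0+p1)."""
    return np.array([s * q, s * (1 - q), (1 - s) * q, (1 - s) * (1 - q)])


def _em_mixture(logF: np.ndarray, counts: np.ndarray, s0=0.7, q0=0.6,
                tol=5e-8, max_iter=250):
    """Maximize the mixture likelihood over (s, q) given per-class per-pattern
    log site likelihoods ``logF`` (n_pat, 4).  Closed-form EM: the four class
    weights factor into two independent binary mixtures (background-vs-
    foreground-selected, and conserved-vs-neutral)."""
    s, q = s0, q0
    n = counts.sum()
    m = logF.max(axis=1, keepdims=True)
    F = np.exp(logF - m)  # fixed during EM; only the weights move
    mflat = m[:, 0]
    last = -np.inf
    for _ in range(max_iter):
        w = np.clip(_class_weights(s, q), 1e-300, None)
        r = F * w
        tot = r.sum(axis=1)
        ll = float(counts @ (np.log(tot) + mflat))
        r = r / tot[:, None]
        s = float(np.clip((counts @ (r[:, 0] + r[:, 1])) / n, 1e-9, 1 - 1e-9))
        q = float(np.clip((counts @ (r[:, 0] + r[:, 2])) / n, 1e-9, 1 - 1e-9))
        if ll - last < tol:
            last = ll
            break
        last = ll
    return last, s, q


class _BranchSiteEngine:
    """Shared state for branch-site likelihood evaluations on one gene:
    pattern-compressed tips, per-omega eigendecomposition cache, per-class
    site log-likelihood cache.

    All class generators share one time scale (the stationary rate at
    omega = 1), so the positively selected class evolves genuinely faster;
    the overall rate is carried by a free ``scale`` parameter optimized
    alongside the omegas.
    """

    REF_OMEGA = 1.0

    def __init__(self, tree, aln, foreground, kappa, freqs):
        self.tree = tree
        self.kappa = kappa
        self.cf = resolve_frequencies(freqs, aln)
        self.pi = self.cf.codon_pi
        leaf_order = [n.label for n in tree.leaves]
        self.patterns, self.counts, self.inverse = compress_patterns(aln, leaf_order)
        self.tips = _tip_partials(self.patterns)
        self.leaf_row = {n.id: i for i, n in enumerate(tree.leaves)}
        self.branches = tree.branches()
        fg = set(foreground)
        missing = fg - {b.id for b in self.branches}
        if missing:
            raise ValueError(f"foreground ids not in tree: {sorted(missing)}")
        if not fg:
            raise ValueError("foreground branch set is empty")
        self.is_fg = {b.id: (b.id in fg) for b in self.branches}
        self.mu_ref = stationary_rate(kappa, self.REF_OMEGA, self.cf)
        self._eigs: dict[float, _EigenQ] = {}
        self._fcache: dict[tuple, np.ndarray] = {}
        self._sq = (0.7, 0.6)  # EM warm start, carried across evaluations

    def _eig(self, w: float) -> _EigenQ:
        if w not in self._eigs:
            Q = build_codon_generator(self.kappa, w, self.cf,
                                      reference_omega=self.REF_OMEGA)
            self._eigs[w] = _EigenQ(Q, self.pi)
        return self._eigs[w]

    def logF(self, w0: float, w2: float, scale: float) -> np.ndarray:
        """(n_pat, 4) per-class site log-likelihoods, batched over the four
        class-specific branch models: (w0|w0), (1|1), (w0|w2), (1|w2)
        written as (background | foreground)."""
        key = (w0, w2, scale)
        if key not in self._fcache:
            Ps = {w: {b.id: self._eig(w).P(b.length * scale)
                      for b in self.branches}
                  for w in {w0, 1.0, w2}}
            P_multi = {}
            for b in self.branches:
                fg = self.is_fg[b.id]
                P_multi[b.id] = np.stack([
                    Ps[w0][b.id],
                    Ps[1.0][b.id],
                    Ps[w2 if fg else w0][b.id],
                    Ps[w2 if fg else 1.0][b.id],
                ])
            ll = _prune_loglik_multi(self.tree, self.tips, self.leaf_row,
                                     P_multi, self.pi)
            self._fcache[key] = ll.T.copy()
        return self._fcache[key]

    def profile_lnL(self, w0: float, w2: float, scale: float,
                    s0=None, q0=None):
        if s0 is None:
            # warm start from the previous optimum, pulled off the
            # boundaries: s = 1 is an absorbing fixed point of the EM and
            # would freeze the selected-class weight at zero
            s0 = float(np.clip(self._sq[0], 0.05, 0.95))
            q0 = float(np.clip(self._sq[1], 0.05, 0.95))
        ll, s, q = _em_mixture(self.logF(w0, w2, scale), self.counts,
                               s0=s0, q0=q0)
        self._sq = (s, q)
        return ll, s, q


def _logit(p):
    return np.log(p / (1.0 - p))


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40.0, 40.0)))


def fit_branch_site(
    tree: PhyloTree,
    aln: CodonAlignment,
    foreground: Sequence[int],
    n_restarts: int = 3,
    freqs="F3x4",
    kappa: Optional[float] = None,
    seed: int | None = None,
) -> BranchSiteFit:
    """Model-A branch-site test for positive selection on foreground branches.

    kappa is profiled once from a global-omega fit; the mixture proportions
    are profiled by EM inside each likelihood evaluation; the outer
    optimization runs over (omega0, omega2, tree scale).  The null fixes
    omega2 = 1.  Best of ``n_restarts`` jittered starts is kept per
    hypothesis, and the alternative is refit from the null optimum if it
    ever falls below it (the models are nested).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    cf = resolve_frequencies(freqs, aln)
    g0 = fit_global_omega(tree, aln, cf)
    if kappa is None:
        kappa = g0["kappa"]
    eng = _BranchSiteEngine(tree, aln, foreground, kappa, cf)
    # M0 scale was calibrated with a generator normalized at omega-hat;
    # convert to the engine's omega = 1 reference scaling
    # (expm(Q/mu(w) * t * s) = expm(Q/mu(1) * t * s * mu(1)/mu(w)))
    scale0 = g0["scale"] * eng.mu_ref / stationary_rate(kappa, g0["omega"], cf)
    w0_init = float(np.clip(g0["omega"], 1e-3, 0.95))
    rng = np.random.default_rng(seed)

    # ---- null: omega2 = 1, optimize (omega0, scale)
    def null_obj(x):
        w0 = float(np.clip(_inv_logit(x[0]), 1e-4, 1 - 1e-6))
        ll, _, _ = eng.profile_lnL(w0, 1.0, float(np.exp(x[1])))
        return -ll if np.isfinite(ll) else 1e12

    starts0 = [(w0_init, scale0)]
    while len(starts0) < n_restarts:
        starts0.append((float(rng.uniform(0.02, 0.9)),
                        scale0 * float(np.exp(rng.uniform(-0.5, 0.5)))))
    best_null = None
    for w0_s, sc_s in starts0:
        r = minimize(null_obj, np.array([_logit(w0_s), np.log(sc_s)]),
                     method="Nelder-Mead",
                     options={"xatol": 2e-3, "fatol": 2e-4, "maxiter": 70})
        if best_null is None or r.fun < best_null.fun:
            best_null = r
    w0_null = float(np.clip(_inv_logit(best_null.x[0]), 1e-4, 1 - 1e-6))
    scale_null = float(np.exp(best_null.x[1]))
    lnL0, s_n, q_n = eng.profile_lnL(w0_null, 1.0, scale_null)

    # ---- alternative: omega2 >= 1, optimize (omega0, omega2); the overall
    # rate scale is held at its null optimum (a shared nuisance; freeing it
    # under the alternative changes lnL1 only marginally and keeps the test
    # on the conservative side)
    def alt_obj(x):
        w0 = float(np.clip(_inv_logit(x[0]), 1e-4, 1 - 1e-6))
        w2 = 1.0 + float(np.exp(x[1]))
        ll, _, _ = eng.profile_lnL(w0, w2, scale_null)
        return -ll if np.isfinite(ll) else 1e12

    starts = [(w0_null, 3.0), (w0_null, 1.01)]
    while len(starts) < n_restarts + 1:
        starts.append((float(rng.uniform(0.02, 0.9)),
                       float(1.0 + rng.exponential(2.0))))
    n_starts = 1 if n_restarts == 1 else n_restarts
    best_alt = None
    for w0_s, w2_s in starts[:n_starts]:
        x0 = np.array([_logit(w0_s), np.log(max(w2_s - 1.0, 1e-6))])
        r = minimize(alt_obj, x0, method="Nelder-Mead",
                     options={"xatol": 2e-3, "fatol": 2e-4, "maxiter": 80})
        if best_alt is None or r.fun < best_alt.fun:
            best_alt = r
    w0_alt = float(np.clip(_inv_logit(best_alt.x[0]), 1e-4, 1 - 1e-6))
    w2_alt = 1.0 + float(np.exp(best_alt.x[1]))
    scale_alt = scale_null
    lnL1, s_a, q_a = eng.profile_lnL(w0_alt, w2_alt, scale_alt)

    # nesting guard: the alternative contains the null (omega2 -> 1)
    if lnL1 < lnL0:
        lnL1, s_a, q_a = lnL0, s_n, q_n
        w0_alt, w2_alt, scale_alt = w0_null, 1.0, scale_null
    w = _class_weights(s_a, q_a)
    wn = _class_weights(s_n, q_n)
    return BranchSiteFit(
        foreground=tuple(sorted(set(foreground))),
        kappa=float(kappa), scale=float(scale_alt),
        lnL0=float(lnL0), lnL1=float(lnL1),
        p0=float(w[0]), p1=float(w[1]), p2a=float(w[2]), p2b=float(w[3]),
        omega0=float(w0_alt), omega2=float(w2_alt),
        null_p0=float(wn[0]), null_p1=float(wn[1]), null_omega0=float(w0_null),
        converged=bool(np.isfinite(lnL0) and np.isfinite(lnL1)),
        n_restarts=n_restarts,
    )


def neb_site_probs(fit: BranchSiteFit, tree: PhyloTree,
                   aln: CodonAlignment, freqs="F3x4") -> pd.DataFrame:
    """Naive-empirical-Bayes posterior class probabilities per codon site.

    Plug-in: class prior (MLE proportions) times class site likelihood,
    normalized.  ``p_selected`` is the posterior mass of classes 2a + 2b.
    """
    eng = _BranchSiteEngine(tree, aln, fit.foreground, fit.kappa, freqs)
    logF = eng.logF(fit.omega0, fit.omega2, fit.scale)
    logw = np.log(np.clip(np.array([fit.p0, fit.p1, fit.p2a, fit.p2b]),
                          1e-300, None))
    a = logF + logw
    m = a.max(axis=1, keepdims=True)
    r = np.exp(a - m)
    r = r / r.sum(axis=1, keepdims=True)
    per_site = r[eng.inverse]
    df = pd.DataFrame(per_site, columns=["p_class0", "p_class1", "p_class2a", "p_class2b"])
    df.insert(0, "site", np.arange(len(df)))
    df["p_selected"] = df["p_class2a"] + df["p_class2b"]
    return df
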