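"""Synthetic studies with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, a study design of a clownfish-like
radiation: a Yule species tree; an ordinal 4-state bar-count trait evolving
under the single-rate consecutive-state (tridiagonal) Mk model; per-gene
codon alignments whose omega is shifted on branches carrying true trait
gains for a known subset of "effect" genes; a per-gene, per-branch
Delta-omega table (true Delta-omega plus Gaussian estimation noise); a skin
RNA-seq count matrix with planted expression classes; and a gene-term
annotation table with one term enriched among effect genes.  Everything is
reproducible byte-for-byte from the master seed, and truth tables make
confusion matrices computable for every downstream stage.

Time units: the tree depth defaults to 12 (mirroring a ~12-unit-deep crown
age), the trait rate to 0.12 changes per unit time (matching a transition
density of several gains and losses per tree, as in the empirical study
design), and codon branch lengths to ``codon_scale`` expected substitutions
per codon site per unit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .codon_evolution import (
    CodonAlignment,
    CodonFrequencies,
    N_CODONS,
    _EigenQ,
    build_codon_generator,
    write_codon_fasta,
)
from .mk_ancestral import build_rate_matrix, N_STATES
from .treekit import PhyloTree, parse_newick, write_newick
from .stochastic_maps import classify_branch, GAIN, LOSS


# ---------------------------------------------------------------------------
# Trees


def simulate_tree(n_leaves: int, birth_rate: float = 1.0,
                  seed: Optional[int] = None, depth: float = 12.0) -> PhyloTree:
    """Yule (pure-birth) tree rescaled so every root-to-tip path has the
    stated depth (ultrametric)."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("birth", "children", "split")

        def __init__(self, birth):
            self.birth = birth
            self.children = None
            self.split = None

    root = _N(0.0)
    active = [root]
    t = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node = active[k]
        node.split = t
        node.children = (_N(t), _N(t))
        active[k] = node.children[0]
        active.append(node.children[1])
    total = t + rng.exponential(1.0 / (birth_rate * len(active)))
    # the rendered root is the first split: rescale time since then
    scale = depth / (total - root.split)
    labels = iter(f"sp{i + 1:02d}" for i in range(n_leaves))

    def render(n: _N) -> str:
        if n.children is None:
            return f"{next(labels)}:{(total - n.birth) * scale:.10g}"
        a, b = n.children
        return f"({render(a)},{render(b)}):{(n.split - n.birth) * scale:.10g}"

    if root.children is None:
        raise RuntimeError("degenerate Yule simulation")
    a, b = root.children
    newick = f"({render(a)},{render(b)});"
    return parse_newick(newick)


# ---------------------------------------------------------------------------
# Trait histories


@dataclass
class TraitHistory:
    node_states: dict[int, int]          # every node, root included
    traits: dict[str, int]               # tip label -> state
    gain_branches: set[int]              # branch ids (child node) with net gain
    loss_branches: set[int]
    n_events: int                        # total Gillespie events


def simulate_trait_history(tree: PhyloTree, Q: np.ndarray, root_state: int = 3,
                           seed: Optional[int] = None) -> TraitHistory:
    """Forward Gillespie simulation of the Mk process along every branch.

    Branch truth labels (gain/loss) come from comparing endpoint node
    states, the same rule used to classify stochastic-map samples.
    """
    Q = np.asarray(Q, dtype=float)
    if not 0 <= root_state < N_STATES:
        raise ValueError("root_state out of range")
    rng = np.random.default_rng(seed)
    states: dict[int, int] = {tree.root_id: int(root_state)}
    n_events = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        s = states[node.parent]
        remaining = node.length
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait > remaining:
                break
            remaining -= wait
            probs = np.clip(Q[s].copy(), 0, None)
            probs[s] = 0.0
            s = int(rng.choice(N_STATES, p=probs / probs.sum()))
            n_events += 1
        states[node.id] = s
    traits = {n.label: states[n.id] for n in tree.leaves}
    gain, loss = set(), set()
    for b in tree.branches():
        cls = classify_branch(states[b.parent], states[b.id])
        if cls == GAIN:
            gain.add(b.id)
        elif cls == LOSS:
            loss.add(b.id)
    return TraitHistory(states, traits, gain, loss, n_events)


# ---------------------------------------------------------------------------
# Codon alignments


def simulate_codon_alignment(
    tree: PhyloTree,
    branch_omega: dict[int, float],
    n_codons: int,
    seed: Optional[int] = None,
    kappa: float = 2.0,
    freqs: Optional[CodonFrequencies] = None,
    codon_scale: float = 1.0,
    reference_omega: Optional[float] = None,
) -> CodonAlignment:
    """Evolve codon sequences along the tree with per-branch omega.

    Root codons are drawn from the stationary distribution; each branch uses
    an MG94xHKY generator at its omega.  With the default normalization,
    ``length * codon_scale`` is the expected substitutions per codon site on
    every branch.  Passing ``reference_omega`` instead normalizes all
    generators by the stationary rate at that omega, so branches with
    elevated omega accumulate proportionally more (nonsynonymous)
    substitutions — the realistic regime when omega shifts reflect relaxed
    or positive selection rather than rate compensation.  No stop codons can
    arise (the state space is the 61 sense codons).
    """
    if freqs is None:
        freqs = CodonFrequencies.equal()
    missing = {b.id for b in tree.branches()} - set(branch_omega)
    if missing:
        raise ValueError(f"branch_omega missing branches {sorted(missing)}")
    rng = np.random.default_rng(seed)
    pi = freqs.codon_pi
    eigs: dict[float, _EigenQ] = {}
    states = {tree.root_id: rng.choice(N_CODONS, size=n_codons, p=pi)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        w = float(branch_omega[node.id])
        if w not in eigs:
            Q = build_codon_generator(kappa, w, freqs,
                                      reference_omega=reference_omega)
            eigs[w] = _EigenQ(Q, pi)
        P = eigs[w].P(node.length * codon_scale)
        rows = P[states[node.parent]]
        rows = rows / rows.sum(axis=1, keepdims=True)
        u = rng.random((n_codons, 1))
        states[node.id] = (u > np.cumsum(rows, axis=1)).sum(axis=1)
    from .codon_evolution import CODONS
    seqs = {
        n.label: "".join(CODONS[c] for c in states[n.id]) for n in tree.leaves
    }
    return CodonAlignment.from_sequences(seqs)


# ---------------------------------------------------------------------------
# Whole studies


@dataclass
class StudyConfig:
    n_leaves: int = 16
    n_genes: int = 200
    n_codons: int = 200
    fraction_effect_genes: float = 0.2
    effect_size_on_gain: float = 3.0
    baseline_omega: float = 0.2
    kappa: float = 2.0
    tree_depth: float = 12.0
    trait_rate: float = 0.12
    root_state: int = 3
    codon_scale: float = 0.02
    delta_noise_sd: float = 0.1
    with_alignments: bool = True
    seed: int = 0


@dataclass
class SyntheticStudy:
    config: StudyConfig
    tree: PhyloTree
    history: TraitHistory
    truth_genes: pd.DataFrame          # gene, is_effect
    branch_omegas: dict[str, dict[int, float]]
    delta_table: pd.DataFrame          # gene, branch_id, delta_omega (noisy)
    alignments: dict[str, CodonAlignment] = field(default_factory=dict)
    counts: Optional[pd.DataFrame] = None
    lengths: Optional[pd.Series] = None
    sample_condition: Optional[pd.Series] = None
    annotation: Optional[pd.DataFrame] = None

    @property
    def traits(self) -> dict[str, int]:
        return self.history.traits

    def truth_branches(self) -> pd.DataFrame:
        rows = []
        for b in self.tree.branches():
            cls = classify_branch(self.history.node_states[b.parent],
                                  self.history.node_states[b.id])
            rows.append({"branch_id": b.id, "true_class": cls,
                         "parent_state": self.history.node_states[b.parent],
                         "child_state": self.history.node_states[b.id]})
        return pd.DataFrame(rows)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "tree.newick").write_text(write_newick(self.tree) + "\n")
        pd.DataFrame({"species": list(self.traits), "bars": list(self.traits.values())}
                     ).to_csv(path / "traits.csv", index=False)
        self.truth_branches().to_csv(path / "truth_branches.tsv", sep="\t",
                                     index=False)
        self.truth_genes.to_csv(path / "truth_genes.tsv", sep="\t", index=False)
        self.delta_table.to_csv(path / "delta_omega.tsv", sep="\t", index=False,
                                float_format="%.8g")
        if self.alignments:
            gdir = path / "genes"
            gdir.mkdir(exist_ok=True)
            for g, aln in self.alignments.items():
                write_codon_fasta(aln, gdir / f"{g}.fasta")
        if self.counts is not None:
            out = self.counts.copy()
            out.insert(0, "length", self.lengths)
            out.rename_axis("gene").reset_index().to_csv(
                path / "counts.tsv", sep="\t", index=False)
            pd.DataFrame({"sample": self.sample_condition.index,
                          "condition": self.sample_condition.values}
                         ).to_csv(path / "sample_map.tsv", sep="\t", index=False)
        if self.annotation is not None:
            self.annotation.to_csv(path / "annotation.tsv", sep="\t", index=False)
        (path / "study_config.yaml").write_text(
            yaml.safe_dump(asdict(self.config), sort_keys=True))


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i + 1:04d}" for i in range(n)]


def make_study(config: StudyConfig | None = None, **overrides) -> SyntheticStudy:
    """Build a complete synthetic study from a master seed.

    Effect genes have omega multiplied by ``effect_size_on_gain`` on the
    branches whose *true* simulated history is a gain; the Delta-omega table
    is the true per-branch Delta-omega plus N(0, delta_noise_sd) noise,
    emulating estimation error.
    """
    cfg = config or StudyConfig()
    if overrides:
        cfg = StudyConfig(**{**asdict(cfg), **overrides})
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=6)

    tree = simulate_tree(cfg.n_leaves, seed=int(seeds[0]), depth=cfg.tree_depth)
    Q = build_rate_matrix(6, [cfg.trait_rate])

    # Histories must be informative: at least two tip states, and — when
    # effect genes are requested — at least two gain branches, emulating the
    # repeated-gain design of the empirical tree (several independent gain
    # and loss branches).  A single ambiguous transition cannot support the
    # association analysis the study exists to exercise.
    need_gain = cfg.fraction_effect_genes > 0 and cfg.effect_size_on_gain != 1.0
    hist_rng = np.random.default_rng(int(seeds[1]))
    history = None
    for _ in range(500):
        history = simulate_trait_history(
            tree, Q, cfg.root_state, seed=int(hist_rng.integers(2**31 - 1)))
        ok = len(set(history.traits.values())) >= 2
        if need_gain:
            ok = ok and len(history.gain_branches) >= 2
        if ok:
            break
    if history is None:
        raise RuntimeError("trait history simulation failed")

    genes = _gene_ids(cfg.n_genes)
    n_effect = int(round(cfg.n_genes * cfg.fraction_effect_genes))
    eff_rng = np.random.default_rng(int(seeds[2]))
    effect_idx = set(eff_rng.choice(cfg.n_genes, size=n_effect, replace=False).tolist())
    truth_genes = pd.DataFrame({
        "gene": genes,
        "is_effect": [i in effect_idx for i in range(cfg.n_genes)],
    })

    branch_ids = [b.id for b in tree.branches()]
    parent_of = {}
    root_kids = tree.root.children
    for b in tree.branches():
        parent_of[b.id] = b.parent
    # omega evolves with memory along lineages (the Brownian-omega picture):
    # an effect gene's omega is multiplied on each true-gain branch and the
    # new level persists in all descendants, so Delta-omega is concentrated
    # on the gain branches themselves.
    preorder_branches = [n for n in tree.preorder() if n.parent is not None]
    branch_omegas: dict[str, dict[int, float]] = {}
    for i, g in enumerate(genes):
        w: dict[int, float] = {}
        if i not in effect_idx:
            w = {bid: cfg.baseline_omega for bid in branch_ids}
        else:
            level = {tree.root_id: cfg.baseline_omega}
            for b in preorder_branches:
                lv = level[b.parent]
                if b.id in history.gain_branches:
                    lv = lv * cfg.effect_size_on_gain
                level[b.id] = lv
                w[b.id] = lv
        branch_omegas[g] = w

    # noisy Delta-omega table (true parent-child differences + noise)
    noise_rng = np.random.default_rng(int(seeds[3]))
    rows = []
    for g in genes:
        w = branch_omegas[g]
        logw = {bid: np.log(w[bid]) for bid in branch_ids}
        root_ref = float(np.exp(np.mean([logw[c] for c in root_kids])))
        for bid in branch_ids:
            parent = parent_of[bid]
            pw = root_ref if parent == tree.root_id else w[parent]
            true_dw = w[bid] - pw
            rows.append({"gene": g, "branch_id": bid,
                         "delta_omega": true_dw + noise_rng.normal(0.0, cfg.delta_noise_sd)})
    delta_table = pd.DataFrame(rows)

    alignments: dict[str, CodonAlignment] = {}
    if cfg.with_alignments:
        aln_rng = np.random.default_rng(int(seeds[4]))
        for g in genes:
            alignments[g] = simulate_codon_alignment(
                tree, branch_omegas[g], cfg.n_codons,
                seed=int(aln_rng.integers(2**31 - 1)),
                kappa=cfg.kappa, codon_scale=cfg.codon_scale,
                reference_omega=cfg.baseline_omega,
            )

    counts, lengths, sample_condition, annotation = _expression_and_annotation(
        genes, truth_genes, int(seeds[5]))

    return SyntheticStudy(
        config=cfg, tree=tree, history=history, truth_genes=truth_genes,
        branch_omegas=branch_omegas, delta_table=delta_table,
        alignments=alignments, counts=counts, lengths=lengths,
        sample_condition=sample_condition, annotation=annotation,
    )


def _expression_and_annotation(genes, truth_genes, seed):
    """Counts with planted expression classes and a term table in which one
    term (T01) is enriched among effect genes."""
    rng = np.random.default_rng(seed)
    samples = [f"{c}_{r}" for c in ("orange", "white") for r in (1, 2, 3)]
    sample_condition = pd.Series(
        ["orange"] * 3 + ["white"] * 3, index=samples, name="condition")
    n = len(genes)
    lengths = pd.Series(rng.integers(300, 3000, size=n), index=genes, name="length")
    klass = rng.choice(["both", "white_only", "orange_only", "neither"],
                       size=n, p=[0.8, 0.07, 0.03, 0.1])
    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    base = rng.lognormal(3.0, 1.0, size=n)
    for i, g in enumerate(genes):
        for cond in ("orange", "white"):
            on = klass[i] == "both" or klass[i] == f"{cond}_only"
            lam = base[i] if on else 0.02
            expect = lam * lengths.iloc[i] / 1000.0
            cols = [s for s in samples if s.startswith(cond)]
            counts.loc[g, cols] = rng.poisson(expect, size=3)
    is_effect = truth_genes.set_index("gene")["is_effect"]
    rows = []
    for g in genes:
        p_t1 = 0.5 if is_effect[g] else 0.1
        if rng.random() < p_t1:
            rows.append({"gene": g, "term": "T01"})
        for t in range(2, 11):
            if rng.random() < 0.08:
                rows.append({"gene": g, "term": f"T{t:02d}"})
    annotation = pd.DataFrame(rows, columns=["gene", "term"])
    counts.attrs["true_class"] = dict(zip(genes, klass))
    return counts, lengths, sample_condition, annotation
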