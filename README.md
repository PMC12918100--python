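# baromega

Tools for asking whether gains and losses of a discrete morphological trait
on a phylogeny — the motivating case is the number of white vertical bars in
clownfishes (*Amphiprioninae*, 28 species) — are associated with shifts in
the selective pressure acting on protein-coding genes.

The pipeline chains five analyses:

1. **Ancestral reconstruction** of an ordinal 4-state trait (0–3 bars)
   under six Mk rate schemes (all-rates-different, symmetric, equal-rates,
   and their "biological" variants restricted to transitions between
   consecutive states), compared by AIC.
2. **Stochastic character maps**: exact joint samples of ancestral node
   states given the tips; each branch is classified per map as *gain*,
   *loss* or *same* by comparing child and parent states, and the per-branch
   class proportions over maps (gain/loss/same weights, and the weight
   difference gain − loss) carry reconstruction uncertainty downstream.
3. **Per-branch ω (dN/dS) and Δω** under an MG94×HKY codon model with one
   ω per branch, regularized by a quadratic parent–child penalty on log ω
   (the penalized-ML analogue of a Brownian prior on ω along the tree);
   Δω<sub>b</sub> = ω<sub>b</sub> − ω<sub>parent(b)</sub>.
4. **Association**: per gene and per direction, OLS of Δω on the branch
   gain (or loss) weight, a two-sided *t* test on the slope, and
   Benjamini–Hochberg correction across genes; plus the branch-site model A
   likelihood-ratio test (H1: ω₂ ≥ 1 on foreground branches vs H0: ω₂ = 1;
   2ΔlnL ~ χ²(1)) with NEB per-site posteriors, and Fisher-exact gene-set
   enrichment.
5. **Expression filtering**: TPM normalization and the rule
   "expressed ⇔ TPM > 1 in ≥ 2 of 3 replicates" per skin type, combined
   into both / white-only / orange-only / neither classes.

A synthetic-data module generates complete studies — Yule trees, Gillespie
trait histories under the tridiagonal Mk model, codon alignments with ω
shifted ×k on true-gain branches, Δω tables, count matrices, annotations —
with truth tables, so every stage is testable with no external data.

## Worked example

```python
import baromega as bm

study = bm.make_study(bm.StudyConfig(
    n_leaves=16, n_genes=200, fraction_effect_genes=0.2,
    with_alignments=False, seed=12))

fit = bm.fit_mk(study.tree, study.traits, model_id=6, n_restarts=3, seed=12)
maps = bm.sample_node_states(study.tree, study.traits, fit.Q,
                             n_samples=100, seed=12)
weights = bm.compute_branch_weights(maps, study.tree)

res = bm.associate_genes(study.delta_table, weights)
res = res.merge(study.truth_genes, on="gene")
gain = res[res.direction == "gain"]
print(f"fitted transition rate: {fit.theta[0]:.4f}")
print(f"true gain branches: {sorted(study.history.gain_branches)}")
print(f"genes with q < 0.05: {(gain.q < 0.05).sum()}")
print(f"hit rate among true effect genes: "
      f"{(gain[gain.is_effect].q < 0.05).mean():.2f}")
```

prints

```
fitted transition rate: 0.0725
true gain branches: [0, 3, 7, 8, 18]
genes with q < 0.05: 17
hit rate among true effect genes: 0.40
```

The trait history behind this study carries five true gain branches; 16 of
the 17 discoveries are genuine effect genes (ω multiplied ×3 along the
gain lineages), i.e. 40% power at one false discovery in 160 null genes.
The fitted transition rate (0.073) is within a factor ~1.7 of the
generating value (0.12) — typical for a single 16-leaf history.

There is also a CLI over the same functions:

```bash
baromega simulate --out study --seed 7 --n-leaves 16 --n-genes 50
baromega --config pipeline.yaml ancestral
baromega --config pipeline.yaml associate
baromega --config pipeline.yaml branch-site --direction gain
```

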