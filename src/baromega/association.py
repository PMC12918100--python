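"""Gene-level trait-rate association and enrichment statistics.

For each gene, per-branch Delta-omega is regressed on the stochastic-map
transition weight of one direction (gain_w or loss_w); uncertainty in the
ancestral history thus enters through the predictor.  The slope is tested
with a two-sided t test (n - 2 df) and p-values are Benjamini-Hochberg
corrected across genes, separately per direction.  Gene-set
over-representation uses a one-sided Fisher exact test per term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DIRECTIONS = ("gain", "loss")


@dataclass
class GeneAssociationResult:
    gene: str
    direction: str
    beta: float
    se: float
    t: float
    p: float
    q: float = np.nan
    n_branches: int = 0
    flag: str = "ok"  # ok | untestable | perfect_fit | too_few_branches


def regress_delta_omega(
    delta: Mapping[int, float] | pd.Series,
    weights: pd.DataFrame,
    direction: str,
    gene: str = "",
    min_branches: int = 3,
) -> GeneAssociationResult:
    """OLS of one gene's per-branch Delta-omega on the direction weight.

    ``delta`` maps branch_id -> Delta-omega; ``weights`` is the
    compute_branch_weights table.  Branches with non-finite Delta-omega are
    dropped (and not counted in n_branches).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    d = pd.Series(dict(delta)) if not isinstance(delta, pd.Series) else delta
    w = weights.set_index("branch_id")[f"{direction}_w"]
    joined = pd.concat({"y": d, "x": w}, axis=1, join="inner").dropna()
    joined = joined[np.isfinite(joined.y)]
    n = len(joined)
    if n < min_branches:
        return GeneAssociationResult(gene, direction, np.nan, np.nan, np.nan,
                                     np.nan, n_branches=n, flag="too_few_branches")
    x = joined.x.to_numpy()
    y = joined.y.to_numpy()
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        return GeneAssociationResult(gene, direction, np.nan, np.nan, np.nan,
                                     np.nan, n_branches=n, flag="untestable")
    beta = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    alpha = float(y.mean() - beta * x.mean())
    resid = y - (alpha + beta * x)
    rss = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    dof = n - 2
    if dof <= 0 or rss <= 1e-14 * max(ss_tot, 1e-300):
        return GeneAssociationResult(gene, direction, beta, 0.0, np.inf, 0.0,
                                     n_branches=n, flag="perfect_fit")
    se = float(np.sqrt(rss / dof / sxx))
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), dof))
    return GeneAssociationResult(gene, direction, beta, se, t, p, n_branches=n)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    NaNs propagate and are excluded from the number of tests m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if np.any((pm < 0) | (pm > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qs = np.empty(m)
    qs[order] = q
    out[mask] = qs
    return out


def associate_genes(
    delta_table: pd.DataFrame,
    weights: pd.DataFrame,
    directions: Iterable[str] = DIRECTIONS,
    min_branches: int = 10,
) -> pd.DataFrame:
    """Run the per-gene regression for every gene and direction.

    ``delta_table`` has columns gene, branch_id, delta_omega.  BH correction
    is applied across genes within each direction (genes flagged untestable
    keep q = NaN).  Genes with fewer than ``min_branches`` finite
    Delta-omega branches are excluded from testing.
    """
    required = {"gene", "branch_id", "delta_omega"}
    if not required <= set(delta_table.columns):
        raise ValueError(f"delta table needs columns {sorted(required)}")
    rows = []
    for direction in directions:
        for g, sub in delta_table.groupby("gene", sort=True):
            d = pd.Series(sub.delta_omega.to_numpy(), index=sub.branch_id.to_numpy())
            res = regress_delta_omega(d, weights, direction, gene=str(g),
                                      min_branches=min_branches)
            rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows])
    for direction in directions:
        sel = df.direction == direction
        df.loc[sel, "q"] = bh_adjust(df.loc[sel, "p"].to_numpy())
    return df


@dataclass
class EnrichmentResult:
    term: str
    study_count: int
    study_size: int
    pop_count: int
    pop_size: int
    p: float
    q: float = np.nan


def fisher_enrichment(
    study_genes: set[str],
    annotation: pd.DataFrame,
    population: Optional[set[str]] = None,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher exact test per term.

    ``annotation`` is a two-column frame (gene, term), one row per
    gene-term pair.  The population defaults to all annotated genes plus the
    study set; unannotated genes count in the totals.
    """
    if not {"gene", "term"} <= set(annotation.columns):
        raise ValueError("annotation needs columns gene, term")
    ann = annotation[["gene", "term"]].drop_duplicates()
    if population is None:
        population = set(ann.gene) | set(study_genes)
    if not set(study_genes) <= population:
        raise ValueError("study genes must be a subset of the population")
    if not study_genes:
        raise ValueError("empty study set")
    ann = ann[ann.gene.isin(population)]
    N = len(population)
    n = len(study_genes)
    rows = []
    for term, sub in ann.groupby("term", sort=True):
        term_genes = set(sub.gene)
        K = len(term_genes)
        k = len(term_genes & study_genes)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentResult(str(term), k, n, K, N, min(p, 1.0)))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "term"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    return df
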