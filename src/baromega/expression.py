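"""TPM normalization and the expressed / tissue-class rules for skin RNA-seq.

A gene counts as expressed in a skin type when its TPM is strictly greater
than 1 in at least two of the three biological replicates; combining the
orange- and white-skin calls yields the four classes both / white_only /
orange_only / neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("orange", "white")
CLASSES = ("both", "white_only", "orange_only", "neither")


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and gene lengths (bases).

    Per sample: rate_g = count_g / length_g, TPM_g = rate_g / sum(rates) * 1e6.
    Columns of the result sum to 1e6; all-zero samples are set to NaN and
    reported via ``result.attrs['flagged_samples']``.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene length(s)")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts < 0).to_numpy().any():
        raise ValueError("counts must be nonnegative")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    flagged = list(total.index[total <= 0])
    tpm = rate.div(total.where(total > 0), axis=1) * 1e6
    tpm.attrs["flagged_samples"] = flagged
    return tpm


def call_expressed(tpms: Sequence[float], threshold: float = 1.0,
                   min_reps: int = 2) -> bool:
    """True iff TPM > threshold (strict) in at least min_reps replicates."""
    v = np.asarray(list(tpms), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one replicate")
    return int(np.sum(v > threshold)) >= min_reps


@dataclass
class ExpressionCall:
    gene: str
    expressed_orange: bool
    expressed_white: bool
    mean_tpm_orange: float
    mean_tpm_white: float

    @property
    def klass(self) -> str:
        if self.expressed_orange and self.expressed_white:
            return "both"
        if self.expressed_white:
            return "white_only"
        if self.expressed_orange:
            return "orange_only"
        return "neither"


def classify_expression(gene: str, orange: Sequence[float], white: Sequence[float],
                        threshold: float = 1.0, min_reps: int = 2) -> ExpressionCall:
    return ExpressionCall(
        gene=gene,
        expressed_orange=call_expressed(orange, threshold, min_reps),
        expressed_white=call_expressed(white, threshold, min_reps),
        mean_tpm_orange=float(np.mean(list(orange))),
        mean_tpm_white=float(np.mean(list(white))),
    )


def classify_table(counts: pd.DataFrame, lengths: pd.Series,
                   sample_condition: pd.Series, threshold: float = 1.0,
                   min_reps: int = 2) -> pd.DataFrame:
    """Full-matrix driver: TPM-normalize then classify every gene.

    ``sample_condition`` maps sample (column) name -> 'orange' or 'white'.
    """
    bad = set(sample_condition.unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    tpm = counts_to_tpm(counts, lengths)
    orange_cols = sample_condition.index[sample_condition == "orange"]
    white_cols = sample_condition.index[sample_condition == "white"]
    if len(orange_cols) == 0 or len(white_cols) == 0:
        raise ValueError("each condition needs at least one replicate")
    rows = []
    for gene in tpm.index:
        call = classify_expression(
            str(gene), tpm.loc[gene, orange_cols], tpm.loc[gene, white_cols],
            threshold, min_reps,
        )
        rows.append({
            "gene": call.gene, "class": call.klass,
            "mean_tpm_orange": call.mean_tpm_orange,
            "mean_tpm_white": call.mean_tpm_white,
        })
    return pd.DataFrame(rows)


def read_counts_tsv(path):
    """Counts TSV with columns gene, length, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "length"} <= set(df.columns):
        raise ValueError("counts TSV needs columns gene, length, <samples...>")
    df = df.set_index("gene")
    lengths = df.pop("length")
    return df, lengths


def read_sample_map_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "condition"} <= set(df.columns):
        raise ValueError("sample map needs columns sample, condition")
    return df.set_index("sample")["condition"]
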