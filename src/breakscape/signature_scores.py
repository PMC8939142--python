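"""Gene-signature scoring: NORAD Activity Score (NAS) and DDR score.

Expression values are log2(x+1)-transformed, each gene is z-scored across
samples (constant genes dropped), and a signature score is the per-sample
mean of z-scores over the signature gene set — one score per sample per
signature.  Scores can then be correlated genome-wide (Pearson, BH-FDR) or
dichotomised into top/bottom quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionTable


@dataclass
class SignatureScore:
    signature_name: str
    per_sample_scores: "pd.Series"
    gene_set: List[str]
    missing_genes: List[str]


def log2_pseudocount(expr: ExpressionTable) -> ExpressionTable:
    """x -> log2(x + 1); rejects negative input."""
    if (expr.values < 0).any():
        raise ValueError("expression values must be non-negative")
    return ExpressionTable(np.log2(expr.df + 1.0))


def zscore_genes(expr: ExpressionTable, ddof: int = 1) -> Tuple[pd.DataFrame, int]:
    """Per-gene z-score across samples; returns (z table, n genes dropped).

    Genes with zero variance across samples carry no ranking information and
    are dropped (counted) rather than set to zero.
    """
    if len(expr.samples) < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    df = expr.df
    sd = df.std(axis=1, ddof=ddof)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    kept = df.loc[keep]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z, n_dropped


def signature_score(
    zexpr: pd.DataFrame, gene_set: Sequence[str], signature_name: str = "signature"
) -> SignatureScore:
    """Per-sample mean of z-scored expression over the signature genes."""
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in zexpr.index]
    missing = [g for g in gene_set if g not in zexpr.index]
    if not present:
        raise ValueError(
            f"none of the {len(gene_set)} requested signature genes are in the "
            f"expression table: {gene_set}"
        )
    scores = zexpr.loc[present].mean(axis=0)
    return SignatureScore(
        signature_name=signature_name,
        per_sample_scores=scores,
        gene_set=present,
        missing_genes=missing,
    )


def correlate_signature(score: SignatureScore, zexpr: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (two-sided p) of the score against every gene, BH-adjusted."""
    s = score.per_sample_scores.loc[zexpr.columns].to_numpy()
    if s.size < 3:
        raise ValueError("correlation requires at least 3 samples")
    rows = []
    for gene, values in zexpr.iterrows():
        r, p = stats.pearsonr(s, values.to_numpy())
        rows.append((gene, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "r", "p"])
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone q-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return q


def quartile_dichotomize(
    values: pd.Series,
) -> Tuple[List[str], List[str], List[str]]:
    """Split samples into (high, low, middle) by value quartile.

    Linear-interpolation quantiles; a sample is high if strictly above Q3
    and low if strictly below Q1.  All-equal input leaves both extreme
    groups empty, which is an error (quartiles undefined).
    """
    if len(values) < 4:
        raise ValueError("quartile dichotomisation requires at least 4 samples")
    v = values.astype(float)
    q1, q3 = np.quantile(v.to_numpy(), [0.25, 0.75])
    high = sorted(v.index[v > q3].tolist())
    low = sorted(v.index[v < q1].tolist())
    if not high or not low:
        raise ValueError(
            "quartiles are undefined: too many tied values to form non-empty "
            "extreme groups (consider checking the input for constant scores)"
        )
    middle = sorted(v.index[(v >= q1) & (v <= q3)].tolist())
    return high, low, middle
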