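"""Downstream integration: methylation-expression correlation and
miRNA-target network assembly.

The correlation screen asks, gene by gene, whether promoter methylation is
negatively associated with expression across samples (Pearson r below a
threshold, two-sided p from the exact t-transform with n-2 df).  The network
builder intersects two predicted target lists (each filtered by its score
cutoff) per miRNA and keeps only targets that are also differential genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationRecord:
    """Methylation-expression association for one gene."""

    gene: str
    r: float
    p: float
    passed: bool
    note: str = ""


def methylation_expression_screen(
    expression: OmicsMatrix | pd.DataFrame,
    methylation: OmicsMatrix | pd.DataFrame,
    gene_pairs: Sequence[tuple[str, str]] | None = None,
    r_threshold: float = -0.5,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Pearson correlation of promoter methylation with expression per gene.

    ``gene_pairs`` lists (expression feature, methylation feature) pairs to
    test; by default genes present in both matrices are paired by ID.  A
    gene passes when r < ``r_threshold`` and p < ``p_threshold``.
    Zero-variance vectors give an undefined r and a flagged record.
    """
    expr = expression.values if isinstance(expression, OmicsMatrix) else expression
    meth = methylation.values if isinstance(methylation, OmicsMatrix) else methylation
    common_samples = expr.index.intersection(meth.index)
    if len(common_samples) < 3:
        raise ValueError("need >= 3 paired samples for a correlation p-value")
    expr = expr.loc[common_samples]
    meth = meth.loc[common_samples]

    if gene_pairs is None:
        shared = expr.columns.intersection(meth.columns)
        gene_pairs = [(g, g) for g in shared]
    records = []
    for expr_id, meth_id in gene_pairs:
        if expr_id not in expr.columns or meth_id not in meth.columns:
            records.append(CorrelationRecord(expr_id, np.nan, np.nan, False, "missing feature"))
            continue
        x = meth[meth_id].to_numpy(dtype=float)
        y = expr[expr_id].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            records.append(CorrelationRecord(expr_id, np.nan, np.nan, False, "zero variance"))
            continue
        res = stats.pearsonr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
        records.append(CorrelationRecord(expr_id, r, p, r < r_threshold and p < p_threshold))
    df = pd.DataFrame(
        [{"gene": c.gene, "r": c.r, "p": c.p, "pass": c.passed, "note": c.note}
         for c in records]
    ).set_index("gene")
    flagged = int(df["note"].ne("").sum())
    if flagged:
        logger.info("methylation_expression_screen: %d flagged records", flagged)
    return df


def build_mirna_target_network(
    differential_mirnas: Iterable[str],
    differential_genes: Iterable[str],
    targets_a: pd.DataFrame,
    targets_b: pd.DataFrame,
    cutoff_a: float = 80.0,
    cutoff_b: float = 0.8,
) -> pd.DataFrame:
    """Edge list (mirna, gene) of the filtered two-database intersection.

    ``targets_a`` / ``targets_b`` carry columns ``mirna``, ``gene``,
    ``score``; list A is filtered by score > ``cutoff_a`` (e.g. a prediction
    score) and list B by score > ``cutoff_b`` (e.g. a conservation
    probability).  Per differential miRNA, the target genes present in both
    filtered lists AND the differential-gene set become edges.  Duplicate
    rows and input order do not affect the result; empty inputs give an
    empty network.
    """
    dem = set(differential_mirnas)
    deg = set(differential_genes)
    edges: set[tuple[str, str]] = set()
    if dem and deg and len(targets_a) and len(targets_b):
        fa = targets_a[targets_a["score"] > cutoff_a]
        fb = targets_b[targets_b["score"] > cutoff_b]
        for mirna in sorted(dem):
            ga = set(fa.loc[fa["mirna"] == mirna, "gene"])
            gb = set(fb.loc[fb["mirna"] == mirna, "gene"])
            for gene in ga & gb & deg:
                edges.add((mirna, gene))
    df = pd.DataFrame(sorted(edges), columns=["mirna", "gene"])
    logger.info("build_mirna_target_network: %d edges", len(df))
    return df
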