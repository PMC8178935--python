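"""Expression-methylation correlation and gene-set over-representation.

Signature genes' expression (log2(count+1) by default) is correlated with
their signature-CpG beta values by Pearson r, with the usual t-transform
p-value.  Over-representation of a query gene list in GMT gene sets is
tested with the one-sided upper-tail hypergeometric distribution and
Bonferroni correction over the sets actually tested.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dm import Signature

logger = logging.getLogger(__name__)


def filter_expressed(
    counts: pd.DataFrame, min_count: int = 10, min_fraction: float = 0.9
) -> pd.DataFrame:
    """Keep genes with >= ``min_count`` reads in >= ``min_fraction`` of samples.

    The boundary is inclusive: a gene passing in exactly 90% of samples is
    retained with the defaults.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    frac = (counts.to_numpy() >= min_count).mean(axis=1)
    return counts.loc[frac >= min_fraction]


def correlate_expression_methylation(
    counts: pd.DataFrame,
    beta: pd.DataFrame,
    signature: Signature,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per signature (gene, CpG) Pearson correlation of expression vs beta.

    Samples are intersected between the two matrices; at least 3 shared
    samples are required.  Constant vectors yield NaN r with a flag.
    """
    shared = counts.columns.intersection(beta.columns)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, found {len(shared)}")
    rows = []
    for cpg in signature.cpgs:
        gene = signature.cpg_to_gene.get(cpg)
        if gene is None or gene not in counts.index:
            logger.warning("signature gene for CpG %s absent from count matrix", cpg)
            continue
        if cpg not in beta.index:
            logger.warning("signature CpG %s absent from beta matrix", cpg)
            continue
        x = counts.loc[gene, shared].to_numpy(dtype=float)
        if log_transform:
            x = np.log2(x + 1.0)
        b = beta.loc[cpg, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(b) == 0:
            rows.append((gene, cpg, np.nan, np.nan, len(shared), True))
            continue
        r, p = stats.pearsonr(x, b)
        rows.append((gene, cpg, float(r), float(p), len(shared), False))
    return pd.DataFrame(
        rows, columns=["gene", "cpg", "r", "p", "n", "constant_input"]
    )


def ora(
    query_genes: Iterable[str],
    universe_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each gene set.

    For a universe of N genes, a set covering K of them and a query of n,
    the p-value is P(X >= k) for the observed overlap k.  Bonferroni
    multiplies by the number of sets tested (sets with zero universe
    overlap are skipped and logged, not tested).

    Raises
    ------
    ValueError
        If the universe is empty or the query is not a subset of it.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty background universe")
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            logger.info("gene set %s has no overlap with the universe; skipped", name)
            continue
        k = len(query & in_universe)
        big_k = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append((name, k, big_k, n_query, n_universe, p))
    n_tested = len(rows)
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_hyper"])
    df["p_bonf"] = np.minimum(1.0, df["p_hyper"] * n_tested)
    return df.sort_values("p_hyper", kind="mergesort").reset_index(drop=True)
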