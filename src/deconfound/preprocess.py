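"""Taxa-table preprocessing: rarefaction, genus binning, the prevalence /
abundance / variance filter chain, and Shannon alpha diversity.

The filter chain mirrors common microbiome practice for small cohorts:
counts are rarefied to a fixed per-sample depth (multivariate
hypergeometric subsampling, i.e. without replacement), binned to
genus-level groups to concentrate signal, converted to relative
abundances, filtered, and natural-log transformed for rank-based linear
modeling.  Every removal is logged with its reason so the chain is
auditable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .random import substream
from .tables import FeatureTable, TaxonomyMap

logger = logging.getLogger(__name__)

__all__ = ["rarefy", "bin_to_genus", "filter_and_transform",
           "shannon_entropy", "shannon_per_sample"]


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total count is below ``depth`` are dropped; the drop
    list is recorded under ``meta['rarefaction_dropped']`` and logged.
    Deterministic given ``seed``.
    """
    if table.state != "counts":
        raise ValueError("rarefy expects a counts table")
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = substream(seed, f"rarefy:{table.space}")
    counts = table.data.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.data.index[~keep])
    if dropped:
        logger.info("rarefy(%s, depth=%d): dropped %d samples below depth: %s",
                    table.space, depth, len(dropped), dropped)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for i, row in enumerate(counts[keep]):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    data = pd.DataFrame(out, index=table.data.index[keep],
                        columns=table.data.columns)
    return table.copy_with(data, state="counts",
                           rarefaction_depth=depth,
                           rarefaction_dropped=dropped)


def bin_to_genus(table: FeatureTable, taxonomy: TaxonomyMap,
                 unassigned: str = "unassigned") -> FeatureTable:
    """Sum feature columns into genus-level bins; per-sample totals are
    conserved exactly.  Unmapped features go to the ``unassigned`` bin."""
    if table.state != "counts":
        raise ValueError("bin_to_genus expects a counts table")
    bins = [taxonomy.get(str(f), unassigned) for f in table.data.columns]
    data = table.data.T.groupby(pd.Index(bins)).sum().T
    data.columns.name = None
    return table.copy_with(data, state="counts", genus_binned=True)


def filter_and_transform(table: FeatureTable,
                         min_prevalence: float = 0.2,
                         min_mean_abundance: float = 1e-4,
                         pseudocount: str | float = "half-min",
                         ) -> FeatureTable:
    """Relative-abundance conversion, quality filters, log transform.

    Features are removed when they are (a) nonzero in strictly less than
    ``min_prevalence`` of samples, (b) have mean relative abundance below
    ``min_mean_abundance``, or (c) have zero variance.  Survivors are
    natural-log transformed after adding a per-feature pseudocount (half
    the smallest nonzero relative abundance of that feature by default).
    Removal reasons land in ``meta['filter_removed']``; the pseudocounts
    used are recorded in ``meta['pseudocounts']``.
    """
    if table.state != "counts":
        raise ValueError("filter_and_transform expects a counts table")
    if table.data.empty:
        raise ValueError("empty table")
    counts = table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    nonzero_rows = totals > 0
    if not nonzero_rows.all():
        bad = list(table.data.index[~nonzero_rows])
        logger.warning("dropping %d all-zero samples before normalization: %s",
                       len(bad), bad)
        counts = counts[nonzero_rows]
        totals = totals[nonzero_rows]
    index = table.data.index[nonzero_rows]
    rel = counts / totals[:, None]

    removed: dict[str, list[str]] = {}
    n = rel.shape[0]
    prevalence = (rel > 0).sum(axis=0) / n
    mean_ab = rel.mean(axis=0)
    # ptp == 0 is exact constancy; np.var on identical floats can leave
    # ~1e-33 of accumulation noise
    variance = np.ptp(rel, axis=0)
    for j, feat in enumerate(table.data.columns):
        reasons = []
        if prevalence[j] < min_prevalence:
            reasons.append("prevalence")
        if mean_ab[j] < min_mean_abundance:
            reasons.append("mean_abundance")
        if variance[j] == 0:
            reasons.append("zero_variance")
        if reasons:
            removed[str(feat)] = reasons
    keep = [f for f in table.data.columns if str(f) not in removed]
    if not keep:
        logger.warning("filter_and_transform(%s): all %d features removed",
                       table.space, table.data.shape[1])
        empty = pd.DataFrame(index=index, columns=[], dtype=float)
        return table.copy_with(empty, state="log", filter_removed=removed,
                               pseudocounts={})
    rel_df = pd.DataFrame(rel, index=index, columns=table.data.columns)[keep]

    pseudo: dict[str, float] = {}
    logged = {}
    for feat in keep:
        col = rel_df[feat].to_numpy()
        if pseudocount == "half-min":
            nz = col[col > 0]
            pc = 0.5 * nz.min()
        else:
            pc = float(pseudocount)
        pseudo[str(feat)] = pc
        logged[feat] = np.log(col + pc)
    out = pd.DataFrame(logged, index=index)
    logger.info("filter_and_transform(%s): removed %d / %d features",
                table.space, len(removed), table.data.shape[1])
    return table.copy_with(out, state="log", filter_removed=removed,
                           pseudocounts=pseudo)


def shannon_entropy(sample_counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) of one sample's counts."""
    counts = np.asarray(sample_counts, dtype=float).ravel()
    if counts.size == 0 or (counts < 0).any():
        raise ValueError("counts must be a non-empty, non-negative vector")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no defined entropy")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: FeatureTable) -> pd.Series:
    """Shannon entropy for every sample of a counts table."""
    if table.state != "counts":
        raise ValueError("shannon_per_sample expects a counts table")
    vals = [shannon_entropy(row) for row in table.data.to_numpy()]
    return pd.Series(vals, index=table.data.index, name="shannon_diversity")
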