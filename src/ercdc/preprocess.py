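"""Expression-matrix preprocessing.

Probe-to-gene collapse, informative-gene filtering, z-score
standardization, log transformation, per-group medians, and a helper for
complete-linkage leaf ordering.  Sample variance uses the n-1 denominator
throughout; variance ties are broken by first occurrence in input order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


def collapse_probesets(m: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Zero-variance probes are removed first; for each gene the mapped probe
    with the highest sample variance is retained verbatim.  Probes absent
    from the map are dropped with a logged count.
    """
    unmapped = m.index.difference(probe_map.index)
    if len(unmapped) > 0:
        logger.warning("dropping %d unmapped probes: %s%s", len(unmapped),
                       list(unmapped[:5]), "..." if len(unmapped) > 5 else "")
    kept = m.loc[m.index.intersection(probe_map.index, sort=False)]
    variances = kept.var(axis=1, ddof=1)
    kept = kept.loc[variances > 0]
    variances = variances.loc[kept.index]

    genes = probe_map.loc[kept.index]
    # stable argmax: first occurrence wins on ties
    order = pd.DataFrame({"gene": genes.to_numpy(), "var": variances.to_numpy(),
                          "probe": kept.index})
    best = {}
    for gene, var, probe in order.itertuples(index=False):
        if gene not in best or var > best[gene][0]:
            best[gene] = (var, probe)
    rows = {gene: kept.loc[probe] for gene, (_v, probe) in best.items()}
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    out.columns = m.columns
    return out


def filter_informative(m: pd.DataFrame, quantile: float = 0.5) -> pd.DataFrame:
    """Keep the most variable half of the nonzero-variance genes.

    With G' genes of positive variance, the top ``ceil(quantile * G')`` by
    variance are retained, in their input order.  Ties broken by first
    occurrence.
    """
    if m.shape[1] < 2:
        raise ValueError("filter_informative needs at least 2 samples")
    variances = m.var(axis=1, ddof=1)
    nonzero = m.loc[variances > 0]
    g_prime = nonzero.shape[0]
    n_keep = int(np.ceil(quantile * g_prime))
    if n_keep == 0:
        return nonzero.iloc[:0]
    v = variances.loc[nonzero.index].to_numpy()
    # stable selection of the n_keep largest (first occurrence wins ties)
    order = np.argsort(-v, kind="stable")[:n_keep]
    keep_mask = np.zeros(g_prime, dtype=bool)
    keep_mask[order] = True
    return nonzero.loc[keep_mask]


def standardize_genes(m: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (mean 0, SD 1 with n-1 denominator)."""
    sd = m.std(axis=1, ddof=1)
    zero = sd.index[sd == 0]
    if len(zero) > 0:
        raise ValueError(f"zero-variance genes cannot be standardized: {list(zero[:5])}")
    return m.sub(m.mean(axis=1), axis=0).div(sd, axis=0)


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) for linear-scale (e.g. FPKM-UQ) values; input must be >= 0."""
    if (m.to_numpy() < 0).any():
        raise ValueError("log_transform requires nonnegative values")
    return np.log2(m + 1.0)


def median_by_group(m: pd.DataFrame, ann: pd.DataFrame, group_key: str) -> pd.DataFrame:
    """Per-gene median expression for each group label (one column per group)."""
    missing = m.columns.difference(ann.index)
    if len(missing) > 0:
        raise ValueError(f"samples without annotation: {list(missing[:5])}")
    labels = ann.loc[m.columns, group_key]
    out = {}
    for g in pd.unique(labels):
        cols = m.columns[(labels == g).to_numpy()]
        if len(cols) == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = m[cols].median(axis=1)
    result = pd.DataFrame(out)
    result.index.name = "gene_id"
    return result


def hierarchical_order(m: pd.DataFrame, axis: int = 0) -> list:
    """Leaf order from complete-linkage clustering on Euclidean distances."""
    data = m.to_numpy() if axis == 0 else m.to_numpy().T
    labels = m.index if axis == 0 else m.columns
    if data.shape[0] < 2:
        return list(labels)
    z = linkage(pdist(data, metric="euclidean"), method="complete")
    return [labels[i] for i in leaves_list(z)]
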