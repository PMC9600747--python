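"""Cross-study merging with parametric empirical-Bayes batch correction.

The adjustment follows the classic location/scale ComBat model: per-gene
standardization against a pooled model, method-of-moments hyperpriors per
batch (normal prior on the location effect, inverse-gamma on the scale
effect), iterative conditional updates of the shrunken effects until the
maximum absolute change falls below a tolerance, then back-transformation.
The covariate design is intercept-only: studies are merged whole and
samples of interest are selected afterwards.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _postmean(gamma_hat, gamma_bar, n, delta_sq, tau_sq):
    return (tau_sq * n * gamma_hat + delta_sq * gamma_bar) / (tau_sq * n + delta_sq)


def combat_merge(
    matrices: Sequence[pd.DataFrame] | pd.DataFrame,
    batches: pd.DataFrame | pd.Series,
    batch_key: str = "study_batch",
    tol: float = 1e-4,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Concatenate expression studies and remove batch effects.

    Parameters
    ----------
    matrices
        One or more genes x samples matrices (log2 scale).  Gene universes
        are intersected; genes absent from any study are dropped.
    batches
        Per-sample batch labels: a Series indexed by sample id, or an
        annotation frame with a ``study_batch`` column.
    tol, max_iter
        Convergence tolerance (max absolute change of the shrunken effects)
        and iteration cap for the EB conditional updates.

    Returns
    -------
    The merged, batch-adjusted genes x samples matrix.
    """
    if isinstance(matrices, pd.DataFrame):
        matrices = [matrices]
    matrices = list(matrices)
    genes = matrices[0].index
    for m in matrices[1:]:
        genes = genes.intersection(m.index, sort=False)
    if len(genes) == 0:
        raise ValueError("empty gene intersection across studies")
    merged = pd.concat([m.loc[genes] for m in matrices], axis=1)
    if merged.columns.duplicated().any():
        raise ValueError("duplicate sample ids across studies")

    labels = batches[batch_key] if isinstance(batches, pd.DataFrame) else batches
    missing = merged.columns.difference(labels.index)
    if len(missing) > 0:
        raise ValueError(f"samples without a batch label: {list(missing[:5])}")
    labels = labels.loc[merged.columns]
    batch_names = list(pd.unique(labels))
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small) > 0:
        raise ValueError(
            f"each batch needs >= 2 samples; offending: {dict(small)}"
        )
    if len(batch_names) == 1:
        logger.info("single batch %r: nothing to correct", batch_names[0])
        return merged

    x = merged.to_numpy(dtype=float)  # genes x samples
    n_total = x.shape[1]
    masks = {b: (labels == b).to_numpy() for b in batch_names}
    n_b = {b: int(masks[b].sum()) for b in batch_names}

    # pooled model: weighted grand mean over batch means, residual variance
    batch_means = {b: x[:, masks[b]].mean(axis=1) for b in batch_names}
    grand_mean = sum((n_b[b] / n_total) * batch_means[b] for b in batch_names)
    resid = x.copy()
    for b in batch_names:
        resid[:, masks[b]] -= batch_means[b][:, None]
    var_pooled = (resid ** 2).sum(axis=1) / n_total
    if (var_pooled <= 0).any():
        raise ValueError(
            "genes with zero pooled residual variance cannot be adjusted: "
            f"{list(merged.index[var_pooled <= 0][:5])}"
        )
    sd_pooled = np.sqrt(var_pooled)
    z = (x - grand_mean[:, None]) / sd_pooled[:, None]

    adjusted = np.empty_like(z)
    for b in batch_names:
        zb = z[:, masks[b]]
        n = n_b[b]
        gamma_hat = zb.mean(axis=1)
        delta_hat_sq = zb.var(axis=1, ddof=1)

        gamma_bar = gamma_hat.mean()
        tau_bar_sq = gamma_hat.var(ddof=1)
        d_mean = delta_hat_sq.mean()
        d_var = delta_hat_sq.var(ddof=1)

        if d_var <= 0:
            # degenerate inverse-gamma hyperprior: no information to shrink
            gamma_star = np.full_like(gamma_hat, gamma_bar) if tau_bar_sq == 0 \
                else gamma_hat.copy()
            delta_star_sq = delta_hat_sq.copy()
            if tau_bar_sq > 0:
                gamma_star = _postmean(gamma_hat, gamma_bar, n, delta_star_sq,
                                       tau_bar_sq)
        else:
            a_prior = (2 * d_var + d_mean ** 2) / d_var
            b_prior = (d_mean * d_var + d_mean ** 3) / d_var
            gamma_star = gamma_hat.copy()
            delta_star_sq = delta_hat_sq.copy()
            for _ in range(max_iter):
                g_new = _postmean(gamma_hat, gamma_bar, n, delta_star_sq, tau_bar_sq)
                sum_sq = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * sum_sq + b_prior) / (n / 2 + a_prior - 1)
                change = max(np.abs(g_new - gamma_star).max(),
                             np.abs(d_new - delta_star_sq).max())
                gamma_star, delta_star_sq = g_new, d_new
                if change < tol:
                    break
            else:
                logger.warning("EB updates for batch %r did not converge in %d "
                               "iterations", b, max_iter)

        adjusted[:, masks[b]] = (zb - gamma_star[:, None]) / np.sqrt(
            delta_star_sq
        )[:, None]

    out = adjusted * sd_pooled[:, None] + grand_mean[:, None]
    return pd.DataFrame(out, index=merged.index, columns=merged.columns)
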