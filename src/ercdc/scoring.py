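"""The ercDC score and the cytotoxic-infiltrate score.

The ercDC score is a single-reference deconvolution statistic: the median
log2 expression of the marker genes across the sorted ercDC reference
arrays defines a reference vector ``r``, and a tumor's score is the slope
of the ordinary least-squares fit of its (log2(x+1)) marker-gene
expression on ``r``.  A tumor rich in the target cell type tracks the
reference steeply; one poor in it is flat.

The cytotoxic-infiltrate score is the per-sample mean of CD8A and NKG7
log expression, cohort z-standardized — a proxy for CD8 T/NK abundance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .preprocess import log_transform

CYTOTOXIC_GENES = ("CD8A", "NKG7")


def build_reference_signature(ercdc_expr: pd.DataFrame,
                              markers: pd.DataFrame | list[str]) -> pd.Series:
    """Median log2 expression of the marker genes over the reference samples."""
    genes = list(markers.index) if isinstance(markers, pd.DataFrame) else list(markers)
    missing = [g for g in genes if g not in ercdc_expr.index]
    if missing:
        raise ValueError(f"marker genes absent from the reference: {missing[:10]}")
    sig = ercdc_expr.loc[genes].median(axis=1)
    sig.name = "r_g"
    sig.index.name = "gene_id"
    return sig


def ercdc_score(sample_expr: pd.DataFrame, signature: pd.Series,
                min_genes: int = 3, coverage_warn: float = 0.8) -> pd.DataFrame:
    """Per-sample regression-slope scores against the reference signature.

    ``sample_expr`` must already be on the log scale (log2(x+1) for
    FPKM-like cohorts).  Signature genes absent from the matrix are dropped
    and recorded in ``n_genes_used``.

    Returns a frame indexed by sample id with columns ``score`` (the OLS
    slope), ``intercept``, ``r_squared`` and ``n_genes_used``.
    """
    present = signature.index.intersection(sample_expr.index)
    if len(present) < min_genes:
        raise ValueError(
            f"only {len(present)} signature genes present; need >= {min_genes}"
        )
    if len(present) < coverage_warn * len(signature):
        warnings.warn(
            f"signature coverage {len(present)}/{len(signature)} below "
            f"{coverage_warn:.0%}", stacklevel=2)
    x = signature.loc[present].to_numpy(dtype=float)
    x_var = x.var(ddof=1)
    if x_var == 0:
        raise ValueError("degenerate signature: reference values have zero variance")
    y = sample_expr.loc[present].to_numpy(dtype=float)  # genes x samples
    x_c = x - x.mean()
    slope = (x_c @ (y - y.mean(axis=0))) / (x_c @ x_c)
    intercept = y.mean(axis=0) - slope * x.mean()
    resid = y - (intercept + np.outer(x, slope))
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_sq = np.where(ss_tot > 0, 1.0 - (resid ** 2).sum(axis=0) / ss_tot, np.nan)
    return pd.DataFrame(
        {
            "score": slope,
            "intercept": intercept,
            "r_squared": r_sq,
            "n_genes_used": len(present),
        },
        index=pd.Index(sample_expr.columns, name="sample_id"),
    )


class SignatureScorer(BaseEstimator):
    """Estimator wrapper around the reference-regression ercDC score.

    ``fit`` collapses the sorted-reference expression of the marker genes
    to their medians (the signature); ``transform`` scores a cohort by the
    per-sample OLS slope against that signature.

    Parameters
    ----------
    transform_log2p1 : bool, default=False
        Apply log2(x+1) to the cohort before scoring (for linear-scale
        FPKM-like inputs; microarray inputs are already log scale).
    """

    def __init__(self, transform_log2p1: bool = False):
        self.transform_log2p1 = transform_log2p1

    def fit(self, reference_expr: pd.DataFrame, markers) -> "SignatureScorer":
        self.signature_ = build_reference_signature(reference_expr, markers)
        return self

    def transform(self, cohort_expr: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "signature_")
        if self.transform_log2p1:
            cohort_expr = log_transform(cohort_expr)
        return ercdc_score(cohort_expr, self.signature_)

    def fit_transform(self, reference_expr, markers, cohort_expr) -> pd.DataFrame:
        return self.fit(reference_expr, markers).transform(cohort_expr)


def cytotoxic_score(cohort_expr: pd.DataFrame,
                    genes: tuple[str, str] = CYTOTOXIC_GENES) -> pd.DataFrame:
    """Mean CD8A/NKG7 log expression per sample, cohort z-standardized."""
    missing = [g for g in genes if g not in cohort_expr.index]
    if missing:
        raise ValueError(f"cytotoxic genes absent from the cohort: {missing}")
    raw = cohort_expr.loc[list(genes)].mean(axis=0)
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("cytotoxic score is constant across the cohort (SD = 0)")
    return pd.DataFrame(
        {"raw": raw, "z": (raw - raw.mean()) / sd},
        index=pd.Index(cohort_expr.columns, name="sample_id"),
    )


def score_infiltrate_contrast(scores: pd.DataFrame,
                              cyto: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Standardized cytotoxic-vs-ercDC contrast per sample, plus correlation.

    Both scores are cohort z-standardized; the per-sample contrast is
    ``z_cyto - z_score`` (positive: cytotoxic infiltrate dominates).
    Returns the per-sample table and the cohort Pearson correlation of the
    two z-scores.
    """
    if set(scores.index) != set(cyto.index):
        raise ValueError("score and cytotoxic tables cover different samples")
    cyto = cyto.loc[scores.index]
    s = scores["score"]
    z_score = (s - s.mean()) / s.std(ddof=1)
    z_cyto = cyto["z"]
    corr = float(np.corrcoef(z_cyto.to_numpy(), z_score.to_numpy())[0, 1])
    table = pd.DataFrame(
        {"z_cyto": z_cyto, "z_score": z_score, "contrast": z_cyto - z_score},
        index=scores.index,
    )
    return table, corr
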